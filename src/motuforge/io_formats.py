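"""Reading, writing and QC of barcode reference libraries.

A reference library couples an aligned COI FASTA with a flat specimen
metadata table (tab-separated, UTF-8) holding the taxonomy and provenance
of every sequence.  Species names may be empty for unidentified records:
such records are excluded from species-level statistics but still take
part in DNA-based delimitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import AlignmentError, FormatError, ValidationError
from .partition import Partition

METADATA_COLUMNS = ["sequence_id", "species", "genus", "family", "order", "source", "site"]
SOURCES = {"trawl", "market", "mined", ""}

# Encoding used throughout the distance stage: A,C,G,T -> 0..3; everything
# else (gaps, N, any IUPAC ambiguity) -> 4 and is treated as missing.
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i  # lower case

_VALID_CHARS = set("ACGTUNRYSWKMBDHV-acgtunryswkmbdhv.")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (4 = missing/ambiguous)."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class SequenceRecord:
    id: str
    seq: str
    species: str = ""
    genus: str = ""
    family: str = ""
    order: str = ""
    source: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            raise FormatError(f"record {self.id!r}: invalid characters {sorted(bad)}")


@dataclass
class ReferenceLibrary:
    """An aligned barcode library plus per-sequence metadata."""

    records: list[SequenceRecord]
    alignment_length: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("a reference library needs at least one record")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.alignment_length == 0:
            self.alignment_length = lengths.pop()
        elif self.alignment_length not in lengths:
            raise AlignmentError(
                f"alignment_length={self.alignment_length} does not match sequences"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dups}")
        _check_taxonomy_consistency(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def species_of(self) -> dict[str, str]:
        """id -> species name ('' where unidentified)."""
        return {r.id: r.species for r in self.records}

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 code matrix in record order."""
        return np.vstack([encode_sequence(r.seq) for r in self.records])

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sequence_id": r.id,
                    "species": r.species,
                    "genus": r.genus,
                    "family": r.family,
                    "order": r.order,
                    "source": r.source,
                    "site": r.site,
                }
                for r in self.records
            ]
        )

    def subset(self, keep_ids: Iterable[str]) -> "ReferenceLibrary":
        keep = set(keep_ids)
        return ReferenceLibrary([r for r in self.records if r.id in keep])


def _check_taxonomy_consistency(records: Sequence[SequenceRecord]) -> None:
    by_species: dict[str, set[tuple[str, str, str]]] = {}
    for r in records:
        if r.species:
            by_species.setdefault(r.species, set()).add((r.genus, r.family, r.order))
    offending = sorted(s for s, combos in by_species.items() if len(combos) > 1)
    if offending:
        raise ValidationError(
            "inconsistent taxonomy (same species, different genus/family/order) "
            f"for: {offending}"
        )


def read_library(fasta_path, metadata_path) -> ReferenceLibrary:
    """Read an aligned FASTA plus its TSV metadata into a validated library.

    Every FASTA record must have a metadata row keyed by ``sequence_id``;
    metadata rows without a sequence are ignored with a warning.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id in FASTA: {rec.id!r}")
        seqs[rec.id] = str(rec.seq)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata is missing columns: {missing_cols}")
    if meta["sequence_id"].duplicated().any():
        dups = sorted(meta.loc[meta["sequence_id"].duplicated(), "sequence_id"])
        raise FormatError(f"duplicate sequence ids in metadata: {dups}")

    rows = meta.set_index("sequence_id")
    orphans = [i for i in seqs if i not in rows.index]
    if orphans:
        raise ValidationError(f"sequences with no metadata row: {sorted(orphans)}")
    unused = [i for i in rows.index if i not in seqs]
    if unused:
        warnings.warn(f"{len(unused)} metadata rows without sequences were ignored")

    bad_sources = sorted(set(rows.loc[list(seqs), "source"]) - SOURCES)
    if bad_sources:
        raise ValidationError(
            f"unknown source values {bad_sources}; expected one of {sorted(SOURCES - {''})}"
        )

    records = [
        SequenceRecord(
            id=sid,
            seq=seq,
            species=rows.at[sid, "species"],
            genus=rows.at[sid, "genus"],
            family=rows.at[sid, "family"],
            order=rows.at[sid, "order"],
            source=rows.at[sid, "source"],
            site=rows.at[sid, "site"],
        )
        for sid, seq in seqs.items()
    ]
    return ReferenceLibrary(records)


def write_library(library: ReferenceLibrary, fasta_path, metadata_path) -> None:
    """Write the library back to FASTA + TSV (round-trip inverse of read_library)."""
    bio_records = [
        BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in library.records
    ]
    SeqIO.write(bio_records, str(fasta_path), "fasta")
    library.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stop-codon QC
# ---------------------------------------------------------------------------

def check_stop_codons(library: ReferenceLibrary, genetic_code: int = 2) -> pd.DataFrame:
    """Translate each sequence in all three forward frames and flag stop codons.

    Gaps are removed before translation; the reading frame of a trimmed COI
    fragment is unknown, so the frame with the fewest stop codons is
    reported.  A genuine in-frame COI barcode has zero stops in one frame;
    ``flag`` is True when even the best frame contains a stop, a classic
    symptom of a NUMT or sequencing artefact.

    genetic_code 2 is the vertebrate mitochondrial table.
    """
    out = []
    for r in library.records:
        ungapped = r.seq.replace("-", "").replace(".", "").upper().replace("U", "T")
        if len(ungapped) < 3:
            out.append(
                {"sequence_id": r.id, "min_stops": -1, "frame": -1,
                 "flag": True, "untranslatable": True}
            )
            continue
        best_stops, best_frame = None, 0
        for frame in range(3):
            sub = ungapped[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate(table=genetic_code))
            stops = aa.count("*")
            if best_stops is None or stops < best_stops:
                best_stops, best_frame = stops, frame
        out.append(
            {"sequence_id": r.id, "min_stops": int(best_stops), "frame": best_frame,
             "flag": best_stops > 0, "untranslatable": False}
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Partition tables
# ---------------------------------------------------------------------------

def write_partition_table(partitions: Sequence[Partition], path) -> None:
    """Write one row per sequence, one column per delimitation method."""
    if not partitions:
        raise ValidationError("no partitions to write")
    id_sets = [frozenset(p.assignment) for p in partitions]
    if len(set(id_sets)) != 1:
        raise ValidationError("partitions cover different sequence id sets")
    ids = sorted(id_sets[0])
    data = {"sequence_id": ids}
    for p in partitions:
        data[p.method] = [p.assignment[i] for i in ids]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_partition_table(path) -> list[Partition]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sequence_id" not in df.columns:
        raise FormatError("partition table lacks a 'sequence_id' column")
    ids = list(df["sequence_id"])
    return [
        Partition(method=col, assignment=dict(zip(ids, df[col])))
        for col in df.columns
        if col != "sequence_id"
    ]
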