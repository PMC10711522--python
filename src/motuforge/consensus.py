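"""Majority-rule consensus of delimitation schemes and conflict reporting.

Two sequences land in the same consensus MOTU when they share a MOTU in a
strict majority of the input partitions (votes > m * n_inputs; an exact
tie means NO edge, which leans toward splitting and is the conservative
choice when flagging candidate cryptic lineages).  Consensus MOTUs are
the connected components of the resulting co-membership graph; a
component that contains a non-voted pair is intransitive -- it is kept
whole but counted and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import SpeciesGapRecord
from .errors import ValidationError
from .partition import Partition

__all__ = ["ConsensusResult", "ConflictReport", "consensus_partition", "conflict_report"]


@dataclass
class ConsensusResult:
    partition: Partition
    votes: np.ndarray              # symmetric pairwise co-membership counts
    ids: list[str]
    m: float                       # majority fraction used
    input_methods: list[str]
    n_intransitive_components: int
    intransitive_pairs: int


def consensus_partition(partitions: Sequence[Partition], m: float = 0.5) -> ConsensusResult:
    if len(partitions) < 2:
        raise ValidationError("consensus needs at least 2 partitions")
    id_sets = {p.ids for p in partitions}
    if len(id_sets) != 1:
        raise ValidationError("partitions cover different sequence id sets")
    ids = sorted(id_sets.pop())
    n = len(ids)
    votes = np.zeros((n, n), dtype=np.int16)
    for p in partitions:
        labels = np.array([p.assignment[i] for i in ids])
        votes += (labels[:, None] == labels[None, :]).astype(np.int16)
    np.fill_diagonal(votes, len(partitions))

    edges = votes > m * len(partitions)
    n_comp, comp = connected_components(csr_matrix(edges), directed=False)

    intransitive_components = 0
    intransitive_pairs = 0
    for c in range(n_comp):
        idx = np.where(comp == c)[0]
        if len(idx) < 2:
            continue
        sub = edges[np.ix_(idx, idx)]
        missing = int((~sub).sum()) // 2
        if missing:
            intransitive_components += 1
            intransitive_pairs += missing

    assignment = {sid: f"CONS{int(c) + 1:04d}" for sid, c in zip(ids, comp)}
    return ConsensusResult(
        partition=Partition("CONSENSUS", assignment),
        votes=votes,
        ids=ids,
        m=m,
        input_methods=[p.method for p in partitions],
        n_intransitive_components=intransitive_components,
        intransitive_pairs=intransitive_pairs,
    )


@dataclass
class SpeciesConflict:
    species: str
    category: str                  # match | split | lump
    motus: list[str]
    max_intra: float | None
    nn_dist: float | None
    shared_with: list[str] = field(default_factory=list)


@dataclass
class ConflictReport:
    splits: list[SpeciesConflict]
    lumps: list[SpeciesConflict]
    matches: list[SpeciesConflict]

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.splits + self.lumps + self.matches:
            rows.append({
                "species": rec.species, "category": rec.category,
                "motus": ";".join(rec.motus),
                "max_intra": None if rec.max_intra is None else round(rec.max_intra, 4),
                "nn_dist": None if rec.nn_dist is None else round(rec.nn_dist, 4),
                "shared_with": ";".join(rec.shared_with),
            })
        return pd.DataFrame(rows)


def conflict_report(
    consensus: ConsensusResult,
    species_labels: Mapping[str, str],
    gap_records: Sequence[SpeciesGapRecord],
) -> ConflictReport:
    """Classify every labelled species as match, split or lump.

    A species mapped to more than one consensus MOTU is a split; a
    species whose single MOTU also contains other species is a lump
    (split takes priority in the rare case a species is both, so every
    species falls in exactly one category).  Distances are taken from the
    per-species barcode-gap records.
    """
    gap_by_species = {g.species: g for g in gap_records}
    assignment = consensus.partition.assignment
    motus_of: dict[str, set[str]] = {}
    species_in_motu: dict[str, set[str]] = {}
    for sid, sp in species_labels.items():
        if not sp or sid not in assignment:
            continue
        motu = assignment[sid]
        motus_of.setdefault(sp, set()).add(motu)
        species_in_motu.setdefault(motu, set()).add(sp)

    splits, lumps, matches = [], [], []
    for sp in sorted(motus_of):
        gaps = gap_by_species.get(sp)
        max_intra = gaps.max_intra if gaps else None
        nn = gaps.nn_dist if gaps else None
        motus = sorted(motus_of[sp])
        if len(motus) > 1:
            splits.append(SpeciesConflict(sp, "split", motus, max_intra, nn))
            continue
        partners = sorted(species_in_motu[motus[0]] - {sp})
        if partners:
            lumps.append(
                SpeciesConflict(sp, "lump", motus, max_intra, nn, shared_with=partners)
            )
        else:
            matches.append(SpeciesConflict(sp, "match", motus, max_intra, nn))
    return ConflictReport(splits=splits, lumps=lumps, matches=matches)
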