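"""Kimura 2-parameter distances and barcode-gap statistics.

The K2P distance separates transitions (A<->G, C<->T) from transversions:
with P and Q the proportions of transition- and transversion-differing
sites among the m jointly resolved sites,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap, N or any other ambiguity code
are dropped pair by pair (pairwise deletion).  When the logarithm domain
fails (saturation) the cell is flagged undefined (NaN) and excluded from
summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SingleSpeciesError, UndefinedComparisonError
from .io_formats import ReferenceLibrary, encode_sequence

__all__ = [
    "PairwiseCounts",
    "DistanceMatrix",
    "SpeciesGapRecord",
    "RankSummary",
    "count_site_patterns",
    "k2p_distance",
    "pairwise_matrix",
    "species_gap_records",
    "rank_summaries",
]


@dataclass(frozen=True)
class PairwiseCounts:
    ts: int  # transition-differing sites
    tv: int  # transversion-differing sites
    m: int   # jointly resolved sites

    def __post_init__(self) -> None:
        if self.ts < 0 or self.tv < 0 or self.m < 0 or self.ts + self.tv > self.m:
            raise ValueError(f"inconsistent counts {self}")

    @property
    def p(self) -> float:
        return self.ts / self.m

    @property
    def q(self) -> float:
        return self.tv / self.m


def count_site_patterns(seq_a: str, seq_b: str) -> PairwiseCounts:
    """Classify aligned site differences into transitions/transversions.

    Raises UndefinedComparisonError when no site is resolved in both
    sequences.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    ok = (a < 4) & (b < 4)
    m = int(ok.sum())
    if m == 0:
        raise UndefinedComparisonError("no jointly resolved sites")
    diff = ok & (a != b)
    # purines (A=0, G=2) are even codes, pyrimidines (C=1, T=3) odd
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return PairwiseCounts(ts=ts, tv=tv, m=m)


def k2p_distance(counts: PairwiseCounts) -> float:
    """K2P distance from site-pattern counts; NaN on saturation."""
    p, q = counts.p, counts.q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with NaN-flagged saturated cells."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_saturated(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.d[iu]).sum())

    def submatrix(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        pos = {sid: i for i, sid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in keep_ids], dtype=int)
        return DistanceMatrix(list(keep_ids), self.d[np.ix_(idx, idx)])

    def condensed(self, impute_saturated: bool = False) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        vals = self.d[iu].copy()
        if impute_saturated and np.isnan(vals).any():
            vals[np.isnan(vals)] = np.nanmax(vals)
        return vals

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    {"id_a": self.ids[i], "id_b": self.ids[j],
                     "k2p": round(float(self.d[i, j]), 4)}
                )
        return pd.DataFrame(rows)


def pairwise_matrix(library: ReferenceLibrary) -> DistanceMatrix:
    """All-pairs K2P distances with pairwise deletion, vectorised per row."""
    codes = library.encoded()
    n, _ = codes.shape
    resolved = codes < 4
    parity = codes & 1
    d = np.zeros((n, n))
    n_sat = 0
    for i in range(n - 1):
        ok = resolved[i] & resolved[i + 1:]
        m = ok.sum(axis=1).astype(float)
        diff = ok & (codes[i] != codes[i + 1:])
        ts = (diff & (parity[i] == parity[i + 1:])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            p = ts / m
            q = tv / m
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            row = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan)
        row = np.where(m == 0, np.nan, row)
        n_sat += int(np.isnan(row).sum())
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    if n_sat:
        warnings.warn(f"{n_sat} saturated/undefined pairwise distances (flagged NaN)")
    return DistanceMatrix(library.ids, d)


# ---------------------------------------------------------------------------
# Barcode-gap records
# ---------------------------------------------------------------------------

@dataclass
class SpeciesGapRecord:
    species: str
    n_seqs: int
    max_intra: float | None        # None when the species has one sequence
    nn_dist: float
    nn_taxon: str
    fold: float | None             # nn/max_intra; None if max_intra is 0/undefined
    gap_present: bool | None       # nn > max_intra; None when max_intra undefined


def species_gap_records(
    matrix: DistanceMatrix, species_labels: Mapping[str, str]
) -> list[SpeciesGapRecord]:
    """Per-species maximum intraspecific and nearest-neighbour distances.

    Records with an empty species label are ignored.  The nearest
    neighbour of species X is the species attaining the minimum distance
    over all heterospecific pairs involving X.
    """
    labels = np.array([species_labels.get(i, "") for i in matrix.ids])
    labelled = labels != ""
    uniq = sorted(set(labels[labelled]))
    if len(uniq) < 2:
        raise SingleSpeciesError(
            "nearest-neighbour distances need at least two labelled species"
        )
    d = matrix.d
    out = []
    for sp in uniq:
        mine = labelled & (labels == sp)
        other = labelled & ~mine
        idx = np.where(mine)[0]
        n_seqs = len(idx)
        if n_seqs >= 2:
            sub = d[np.ix_(idx, idx)]
            iu = np.triu_indices(n_seqs, k=1)
            vals = sub[iu]
            max_intra = float(np.nanmax(vals)) if not np.all(np.isnan(vals)) else None
        else:
            max_intra = None
        hetero = d[np.ix_(idx, np.where(other)[0])]
        if np.all(np.isnan(hetero)):
            nn_dist, nn_taxon = math.nan, ""
        else:
            flat = np.nanmin(hetero, axis=0)
            j = int(np.nanargmin(flat))
            nn_dist = float(flat[j])
            nn_taxon = str(labels[np.where(other)[0][j]])
        if max_intra is None:
            fold, gap = None, None
        else:
            fold = nn_dist / max_intra if max_intra > 0 else None
            gap = bool(nn_dist > max_intra)
        out.append(
            SpeciesGapRecord(
                species=sp, n_seqs=n_seqs, max_intra=max_intra,
                nn_dist=nn_dist, nn_taxon=nn_taxon, fold=fold, gap_present=gap,
            )
        )
    return out


def gap_records_frame(records: Sequence[SpeciesGapRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    for col in ("max_intra", "nn_dist", "fold"):
        df[col] = df[col].astype(float).round(4)
    return df


# ---------------------------------------------------------------------------
# Rank-level summaries
# ---------------------------------------------------------------------------

@dataclass
class RankSummary:
    level: str          # within_species / within_genus / within_family
    n_groups: int       # species/genera/families represented
    n_pairs: int
    min: float
    mean: float
    max: float
    se: float           # sd of the pooled distances / sqrt(pool size)


def _summarise(level: str, n_groups: int, pool: np.ndarray) -> RankSummary | None:
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        return None
    sd = float(np.std(pool, ddof=1)) if pool.size > 1 else 0.0
    return RankSummary(
        level=level, n_groups=n_groups, n_pairs=int(pool.size),
        min=float(pool.min()), mean=float(pool.mean()), max=float(pool.max()),
        se=sd / math.sqrt(pool.size),
    )


def rank_summaries(
    matrix: DistanceMatrix,
    taxonomy: pd.DataFrame,
    inclusive: bool = False,
) -> dict[str, RankSummary | None]:
    """Pooled pairwise-distance summaries at species, genus and family rank.

    With ``inclusive=False`` (default) the three pools are disjoint:
    within_genus excludes conspecific pairs and within_family excludes
    congeneric pairs.  ``inclusive=True`` additionally keeps the lower-rank
    pairs in the higher-rank pools (which can drag the genus/family minima
    to zero); both variants are reported by the pipeline because published
    summary tables do not always state which pooling they used.

    ``taxonomy`` needs columns sequence_id/species/genus/family; rows with
    an empty species are excluded.
    """
    tax = taxonomy.set_index("sequence_id")
    species = np.array([str(tax.at[i, "species"]) if i in tax.index else "" for i in matrix.ids])
    genus = np.array([str(tax.at[i, "genus"]) if i in tax.index else "" for i in matrix.ids])
    family = np.array([str(tax.at[i, "family"]) if i in tax.index else "" for i in matrix.ids])
    labelled = species != ""

    n = matrix.n
    iu, ju = np.triu_indices(n, k=1)
    ok = labelled[iu] & labelled[ju]
    iu, ju = iu[ok], ju[ok]
    vals = matrix.d[iu, ju]

    same_sp = species[iu] == species[ju]
    same_gen = (genus[iu] == genus[ju]) & (genus[iu] != "")
    same_fam = (family[iu] == family[ju]) & (family[iu] != "")

    if inclusive:
        gen_mask = same_gen
        fam_mask = same_fam
    else:
        gen_mask = same_gen & ~same_sp
        fam_mask = same_fam & ~same_gen

    return {
        "within_species": _summarise(
            "within_species", len(set(species[labelled])), vals[same_sp]
        ),
        "within_genus": _summarise(
            "within_genus", len(set(genus[labelled]) - {""}), vals[gen_mask]
        ),
        "within_family": _summarise(
            "within_family", len(set(family[labelled]) - {""}), vals[fam_mask]
        ),
    }


def rank_summary_frame(summaries: Mapping[str, RankSummary | None]) -> pd.DataFrame:
    rows = []
    for level, s in summaries.items():
        if s is None:
            rows.append({"level": level, "n_groups": 0, "n_pairs": 0,
                         "min": math.nan, "mean": math.nan, "max": math.nan,
                         "se": math.nan})
        else:
            rows.append({"level": s.level, "n_groups": s.n_groups, "n_pairs": s.n_pairs,
                         "min": round(s.min, 4), "mean": round(s.mean, 4),
                         "max": round(s.max, 4), "se": round(s.se, 4)})
    return pd.DataFrame(rows)
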