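"""ASAP-style hierarchical partitioning of pairwise distances.

Candidate partitions are the successive levels of the single-linkage
dendrogram of the K2P matrix (from all-singletons to one group).  Three
quantities drive the ranking:

* ``p_panmixia`` -- a probability-style score of the merge that would
  destroy the partition (the next merge up the dendrogram).  A merge at
  height h whose children's internal structure reaches h_int makes a
  jump of h - h_int; under panmixia such jumps are exponential on the
  scale of the merges made so far, so p = exp(-(h - h_int)/mu) with mu
  the running mean merge height plus the distance quantum (the smallest
  positive pairwise distance, about one substitution -- this keeps
  clusters of identical haplotypes from being spuriously rejected).
  Pooling the scale across groups is what gives the test its power: a
  jump to 5% is damning when every within-group merge so far sat near
  0.4%.  A low p means the merge bridges a genuine barcode gap and the
  partition below it is good.
* a panmixia veto -- single-linkage partitions are nested, so any
  rejected merge is lumped by every coarser level; a partition whose
  Bonferroni-adjusted running-minimum merge p falls below 0.05 already
  lumps distinct species and is ranked after every non-vetoed candidate.
* ``W`` -- the relative barcode-gap width: the gap between the
  partition's largest intra-group distance and the next pairwise
  distance, divided by the mean spacing of the distinct distance values
  in a window around the gap (a wide gap in a sparse region of the
  distance distribution is unremarkable).

The asap_score is the mean of the two ranks (ascending p, descending W);
the list is returned sorted best-first with vetoed candidates last.  The
published method's exact scoring constants are not public; every choice
made here is logged in the per-partition notes for auditability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from ..distances import DistanceMatrix
from ..errors import ValidationError
from ..partition import Partition

__all__ = ["ASAPPartition", "asap_partitions"]

_PANMIXIA_VETO = 0.05
_W_WINDOW = 25


@dataclass
class ASAPPartition:
    threshold: float          # merge level at which the partition forms
    partition: Partition
    p_panmixia: float         # score of the partition-destroying merge
    w: float                  # relative barcode-gap width
    asap_score: float         # mean of the two ranks (>= 1)
    notes: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.partition.k


def asap_partitions(matrix: DistanceMatrix) -> list[ASAPPartition]:
    n = matrix.n
    if n < 2:
        raise ValidationError("ASAP needs at least 2 sequences")
    vals = matrix.condensed(impute_saturated=True)
    if np.allclose(vals, vals[0]):
        warnings.warn("all pairwise distances are equal; single trivial candidate")
        part = Partition("ASAP", {i: "ASAP0001" for i in matrix.ids})
        return [ASAPPartition(threshold=float(vals[0]), partition=part,
                              p_panmixia=1.0, w=0.0, asap_score=1.0,
                              notes={"degenerate": True})]

    Z = linkage(vals, method="single")
    heights = Z[:, 2]
    uniq_vals = np.unique(vals)
    positive = uniq_vals[uniq_vals > 0]
    quantum = float(positive.min()) if positive.size else 0.0

    def gap_width(lo: float, hi: float) -> float:
        """Gap divided by the mean spacing of the distinct distance values
        in a window of _W_WINDOW values on each side (gap included)."""
        i_lo = int(np.searchsorted(uniq_vals, lo + 1e-15, side="left"))
        i_hi = int(np.searchsorted(uniq_vals, hi - 1e-15, side="left"))
        a = max(i_lo - _W_WINDOW, 0)
        b = min(i_hi + _W_WINDOW, len(uniq_vals) - 1)
        span = float(uniq_vals[b] - uniq_vals[a])
        if span <= 0 or b == a:
            return 0.0
        return (hi - lo) / (span / (b - a))

    # scipy node indexing: leaf i < n, merge step j -> node n + j
    internal = np.zeros(2 * n - 1)   # height of a node's own root merge
    for j in range(n - 1):
        internal[n + j] = heights[j]

    # Panmixia p-value of each merge, against the pooled within-group
    # scale of everything merged so far: a merge whose height jump
    # (h - h_int) dwarfs the running mean merge height bridges a barcode
    # gap.  The distance quantum keeps clusters of identical haplotypes
    # from being spuriously rejected.
    p_merge = np.empty(n - 1)
    prefix = 0.0
    for j in range(n - 1):
        a, b = int(Z[j, 0]), int(Z[j, 1])
        h = heights[j]
        mu = (prefix / j if j else 0.0) + quantum
        if h <= 0 or mu <= 0:
            p_merge[j] = 1.0
        else:
            h_int = max(internal[a], internal[b])
            p_merge[j] = float(math.exp(-(h - h_int) / mu))
        prefix += h

    # Single-linkage partitions are nested, so a rejected merge is lumped
    # by every level at or above it: the veto is the Bonferroni-adjusted
    # running minimum of the merge p-values.
    run_min = np.minimum.accumulate(p_merge)
    veto_after_merge = np.minimum(run_min * (np.arange(n - 1) + 1), 1.0)

    # candidate partitions: all singletons, then after each distinct height
    levels = []  # (threshold, labels, p_break, p_own)
    levels.append((0.0, np.arange(1, n + 1), p_merge[0], 1.0))
    distinct = np.unique(heights)
    for h in distinct:
        labels = fcluster(Z, t=h, criterion="distance")
        above = np.where(heights > h)[0]
        p_break = p_merge[above[0]] if len(above) else 1.0
        last = int(np.where(heights <= h)[0][-1])
        levels.append((float(h), labels, p_break, float(veto_after_merge[last])))

    iu, ju = np.triu_indices(n, k=1)
    d_pairs = matrix.d[iu, ju]
    d_pairs = np.where(np.isnan(d_pairs), np.nanmax(d_pairs), d_pairs)

    thresholds, all_labels, p_scores, own_scores, w_scores = [], [], [], [], []
    for t, labels, p_break, p_own in levels:
        same = labels[iu] == labels[ju]
        max_intra = float(d_pairs[same].max()) if same.any() else 0.0
        larger = d_pairs[d_pairs > max_intra + 1e-15]
        w_score = gap_width(max_intra, float(larger.min())) if larger.size else 0.0
        thresholds.append(t)
        all_labels.append(labels)
        p_scores.append(p_break)
        own_scores.append(p_own)
        w_scores.append(w_score)

    vetoed = np.array(own_scores) < _PANMIXIA_VETO
    rank_p = rankdata(p_scores, method="average")                # low p_break good
    rank_w = rankdata([-w for w in w_scores], method="average")  # wide gap good
    scores = (rank_p + rank_w) / 2.0

    out = []
    for t, labels, p, p_own, w, s, v in zip(
        thresholds, all_labels, p_scores, own_scores, w_scores, scores, vetoed
    ):
        assignment = {sid: f"ASAP{int(l):04d}" for sid, l in zip(matrix.ids, labels)}
        out.append(
            ASAPPartition(
                threshold=t,
                partition=Partition("ASAP", assignment),
                p_panmixia=float(p),
                w=float(w),
                asap_score=float(s),
                notes={
                    "p_rule": "breaking-merge exp(-(h-h_int)/mu), pooled scale",
                    "w_rule": f"gap over mean distinct-value spacing, +-{_W_WINDOW}",
                    "veto_rule": f"per-group Fisher, Bonferroni min < {_PANMIXIA_VETO}",
                    "p_own": float(p_own),
                    "vetoed": bool(v),
                },
            )
        )
    out.sort(key=lambda a: (a.notes["vetoed"], a.asap_score, -a.w))
    return out
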