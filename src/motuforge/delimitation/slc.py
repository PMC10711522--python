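"""Threshold single-linkage clustering (RESL/BIN stand-in).

Sequences are joined whenever their K2P distance is at or below the
threshold (default 2.2%, the conventional barcode seed threshold); MOTUs
are the connected components of the resulting graph.  An optional
refinement pass re-examines each component: it is split at its widest
internal single-linkage gap when the split shows strong silhouette
structure, loosely mirroring the refinement stage of BOLD's algorithm.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from ..distances import DistanceMatrix
from ..partition import Partition

SEED_THRESHOLD = 0.022
_SILHOUETTE_MIN = 0.25  # minimum mean silhouette for a refinement split


def slc_cluster(
    matrix: DistanceMatrix,
    threshold: float = SEED_THRESHOLD,
    refine: bool = False,
) -> Partition:
    d = matrix.d.copy()
    nan = np.isnan(d)
    if nan.any():
        d[nan] = np.nanmax(d) if not np.all(nan) else 1.0
    adj = csr_matrix(d <= threshold)
    n_comp, labels = connected_components(adj, directed=False)

    if refine:
        labels = labels.copy()
        next_label = n_comp
        for comp in range(n_comp):
            idx = np.where(labels == comp)[0]
            if len(idx) < 4:
                continue
            sub = d[np.ix_(idx, idx)]
            Z = linkage(squareform(sub, checks=False), method="single")
            gaps = np.diff(np.concatenate([[0.0], Z[:, 2]]))
            cut = int(np.argmax(gaps))
            if gaps[cut] <= 0:
                continue
            split = fcluster(Z, t=Z[cut, 2] - 1e-12, criterion="distance")
            if len(set(split)) < 2 or len(set(split)) == len(idx):
                continue
            try:
                score = silhouette_score(sub, split, metric="precomputed")
            except ValueError:
                continue
            if score >= _SILHOUETTE_MIN:
                for sub_label in set(split):
                    if sub_label == split[0]:
                        continue
                    labels[idx[split == sub_label]] = next_label
                    next_label += 1

    assignment = {sid: f"SLC{int(l) + 1:04d}" for sid, l in zip(matrix.ids, labels)}
    return Partition(method="SLC", assignment=assignment)
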