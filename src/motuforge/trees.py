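"""Distance-based trees and haplotype collapsing.

The delimitation stage needs a metric tree (neighbour joining on K2P
distances) and a rooted ultrametric tree (UPGMA here; externally inferred
chronograms can be supplied instead wherever an ultrametric tree is
accepted).  Saturated (undefined) distance cells are imputed with the
matrix maximum before tree building, with a warning -- NJ and UPGMA need
complete matrices and saturation is rare at COI divergences.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Mapping

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from .distances import DistanceMatrix
from .errors import ValidationError
from .io_formats import ReferenceLibrary, SequenceRecord

__all__ = [
    "nj_tree",
    "upgma_tree",
    "collapse_haplotypes",
    "is_ultrametric",
    "read_newick",
    "write_newick",
    "midpoint_root",
    "scale_to_time",
]

CLOCK_RATE_PER_MYR = 0.012  # strict clock: 1.2% pairwise divergence per Myr


def _complete(matrix: DistanceMatrix) -> np.ndarray:
    d = matrix.d.copy()
    if np.isnan(d).any():
        warnings.warn(
            f"{int(np.isnan(d).sum()) // 2} undefined distance cells imputed with the matrix maximum"
        )
        d[np.isnan(d)] = np.nanmax(d)
    return d


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; unrooted, branch lengths in subst/site.

    Negative branch-length estimates are clamped to zero.
    """
    if matrix.n < 3:
        raise ValidationError("neighbour joining needs at least 3 sequences")
    d = _complete(matrix)
    sk = skbio_nj(SkbioDM(d, ids=matrix.ids))
    buf = io.StringIO()
    sk.write(buf, format="newick")
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
    for e in tree.edges():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    return tree


def upgma_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration; rooted ultrametric tree.

    Node heights equal half the merge distance, so leaf-to-leaf path
    lengths approximate the input distances.
    """
    if matrix.n < 2:
        raise ValidationError("UPGMA needs at least 2 sequences")
    d = _complete(matrix)
    n = matrix.n
    iu = np.triu_indices(n, k=1)
    Z = linkage(d[iu], method="average")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, sid in enumerate(matrix.ids):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label=sid)
        nodes[i] = (node, 0.0)
    for step, (a, b, dist, _count) in enumerate(Z):
        height = dist / 2.0
        parent = dendropy.Node()
        for child_idx in (int(a), int(b)):
            child, child_h = nodes.pop(child_idx)
            parent.add_child(child)
            child.edge.length = max(height - child_h, 0.0)
        nodes[n + step] = (parent, height)
    root_node, _root_height = nodes.popitem()[1]
    tree.seed_node = root_node
    tree.is_rooted = True
    return tree


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> tuple[bool, str, float]:
    """Check equal root-to-leaf path lengths; returns (ok, worst_leaf, spread)."""
    depths = {}
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label if leaf.taxon else id(leaf)] = depth
    vals = np.array(list(depths.values()))
    spread = float(vals.max() - vals.min())
    worst = max(depths, key=lambda k: abs(depths[k] - vals.mean()))
    return spread <= tol, str(worst), spread


def collapse_haplotypes(
    library: ReferenceLibrary,
) -> tuple[ReferenceLibrary, dict[str, list[str]]]:
    """Merge sequences identical at all jointly resolved sites.

    The representative is the first member in input order.  Identity at
    jointly resolved sites is not transitive in the presence of missing
    data; each sequence joins the first existing representative it
    matches, which keeps the result deterministic.
    """
    codes = library.encoded()
    resolved = codes < 4
    reps: list[int] = []
    members: dict[str, list[str]] = {}
    for i, rec in enumerate(library.records):
        joined = None
        for r in reps:
            both = resolved[i] & resolved[r]
            if not np.any(codes[i][both] != codes[r][both]):
                joined = library.records[r].id
                break
        if joined is None:
            reps.append(i)
            members[rec.id] = [rec.id]
        else:
            members[joined].append(rec.id)
    reduced = ReferenceLibrary([library.records[i] for i in reps])
    return reduced, members


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=True)
    # zero-length branches can leave the root sitting on a named leaf;
    # push that taxon back onto an explicit child so no leaf disappears
    if t.seed_node.taxon is not None:
        leaf = dendropy.Node()
        leaf.taxon = t.seed_node.taxon
        t.seed_node.taxon = None
        t.seed_node.add_child(leaf)
        leaf.edge.length = 0.0
    return t


def scale_to_time(divergence: float, clock_rate: float = CLOCK_RATE_PER_MYR) -> float:
    """Convert a pairwise divergence (subst/site) to Myr under a strict clock.

    Reporting convenience only; the clock rate is pairwise divergence per
    million years (default 1.2%/Myr, the conventional COI fish clock).
    """
    return divergence / clock_rate
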