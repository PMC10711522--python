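"""Synthetic barcode libraries with known truth.

The generative model mirrors how a multi-species barcode library arises:
a Yule (pure-birth) tree over species, a Kingman coalescent genealogy
within each species, and strict-clock K80 sequence evolution along the
combined genealogy.  Branch lengths are expressed directly in expected
substitutions per site, so the K2P estimator applied downstream is exactly
matched to the generator and the expected conspecific pairwise distance
equals ``theta`` analytically.

Default parameters emulate a coastal marine fish COI library: 652 bp
fragments, 1--23 sequences per species with mean 4 (truncated geometric),
mean conspecific divergence ~0.36%, congener-scale species divergences of
roughly 5--10% with a hard floor (``stem_scale``) that guarantees a
barcode gap on the "easy" preset, and deepest splits around 30%
(family-level divergences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import dendropy
import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .io_formats import ReferenceLibrary, SequenceRecord

__all__ = [
    "SimConfig",
    "TruthSet",
    "Feature",
    "simulate_reference_library",
    "inject_features",
    "simulate_preset",
    "PRESETS",
]

_BASES = "ACGT"


@dataclass
class SimConfig:
    n_species: int = 20
    seqs_min: int = 1
    seqs_max: int = 23
    seqs_mean: float = 4.0
    birth_rate: float = 1.0          # Yule rate; relative ages only (tree is rescaled)
    theta: float = 0.0036            # expected conspecific pairwise divergence
    stem_scale: float = 0.05         # minimum interspecific divergence (floor)
    crown_depth: float = 0.30        # deepest pairwise species divergence
    kappa: float = 8.0               # K80 transition/transversion rate ratio
    seq_length: int = 652
    clock_rate: float = 0.012        # divergence per Myr, for time annotation only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if self.seq_length < 100:
            raise ValidationError("seq_length must be >= 100")
        for name in ("birth_rate", "theta", "stem_scale", "crown_depth", "kappa",
                     "clock_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (1 <= self.seqs_min <= self.seqs_mean <= self.seqs_max):
            raise ValidationError("need seqs_min <= seqs_mean <= seqs_max")


@dataclass
class TruthSet:
    """Ground truth accompanying a simulated library."""

    nominal: dict[str, str]       # morphology-like species labels
    molecular: dict[str, str]     # true lineage labels (differ after cryptic splits)
    genealogy: dendropy.Tree      # ultrametric gene tree over all sequences
    species_tree: dendropy.Tree
    summaries: dict[str, float] = field(default_factory=dict)


@dataclass
class Feature:
    kind: str                     # cryptic_split | shallow_pair | singleton
    depth: float = 0.086          # cryptic_split: nominal-internal divergence
    divergence: float = 0.008     # shallow_pair: sister-species divergence
    target_species: str | None = None


# ---------------------------------------------------------------------------
# sample sizes: truncated geometric on [lo, hi] with prescribed mean
# ---------------------------------------------------------------------------

def _trunc_geometric_p(lo: int, hi: int, mean: float) -> float:
    # p < 0 gives increasing weights, covering means above the uniform
    # midpoint of [lo, hi]
    k = np.arange(lo, hi + 1)

    def mean_of(p: float) -> float:
        w = (1 - p) ** (k - lo)
        return float((k * w).sum() / w.sum()) - mean

    return brentq(mean_of, -20.0, 1 - 1e-9)


def _draw_sample_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.seqs_min == cfg.seqs_max:
        return np.full(cfg.n_species, cfg.seqs_min, dtype=int)
    p = _trunc_geometric_p(cfg.seqs_min, cfg.seqs_max, cfg.seqs_mean)
    k = np.arange(cfg.seqs_min, cfg.seqs_max + 1)
    w = (1 - p) ** (k - cfg.seqs_min)
    return rng.choice(k, size=cfg.n_species, p=w / w.sum())


# ---------------------------------------------------------------------------
# trees (lightweight internal nodes; exported as dendropy at the end)
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "age", "label")

    def __init__(self, age: float = 0.0, label: str | None = None):
        self.children: list[_Node] = []
        self.age = age
        self.label = label

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def postorder(self) -> Iterable["_Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self


def _yule_tree(n: int, birth_rate: float, rng: np.random.Generator) -> _Node:
    """Pure-birth tree with n tips; tips at age 0, ages grow rootward."""
    root = _Node()
    if n == 1:
        root.age = 0.0
        return root
    split_time: dict[int, float] = {}
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        split_time[id(node)] = t
        node.children = [_Node(), _Node()]
        active.extend(node.children)
    # run the clock to where the next speciation would occur: gives the
    # youngest split a positive age instead of age exactly zero
    present = t + rng.exponential(1.0 / (birth_rate * n))
    for node in root.postorder():
        node.age = present - split_time[id(node)] if node.children else 0.0
    return root


def _scale_and_floor(root: _Node, crown_depth: float, floor_div: float) -> None:
    """Rescale so the root sits at crown_depth/2, then floor shallow splits.

    Flooring raises every internal node to at least floor_div/2 so the
    youngest species pair diverges by at least floor_div; parent > child
    ordering is restored afterwards with a small spacing.
    """
    if not root.children:
        return
    factor = (crown_depth / 2.0) / root.age
    floor_age = floor_div / 2.0
    for node in root.postorder():
        if node.children:
            node.age = max(node.age * factor, floor_age)
            child_max = max(c.age for c in node.children)
            if node.age <= child_max:
                node.age = child_max + 1e-6


def _coalescent(k: int, theta: float, rng: np.random.Generator) -> _Node:
    """Kingman coalescent over k tips; heights scaled so that the expected
    pairwise divergence (twice the expected pairwise coalescence height)
    equals theta."""
    nodes = [_Node() for _ in range(k)]
    t = 0.0
    while len(nodes) > 1:
        j = len(nodes)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = nodes[int(i1)], nodes[int(i2)]
        parent = _Node(age=t * theta / 2.0)
        parent.children = [a, b]
        nodes = [x for x in nodes if x is not a and x is not b] + [parent]
    return nodes[0]


def _cut_tree(root: _Node, threshold_age: float) -> list[list[str]]:
    """Maximal clades whose root age <= threshold (used for genus/family labels)."""
    clusters: list[list[str]] = []

    def walk(node: _Node) -> None:
        if node.age <= threshold_age or not node.children:
            clusters.append([leaf.label for leaf in node.leaves()])
        else:
            for c in node.children:
                walk(c)

    walk(root)
    return clusters


def _to_dendropy(root: _Node) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: _Node, parent_age: float) -> dendropy.Node:
        dn = dendropy.Node()
        dn.edge.length = max(parent_age - node.age, 0.0)
        if not node.children:
            dn.taxon = taxa.new_taxon(label=node.label)
        for c in node.children:
            dn.add_child(build(c, node.age))
        return dn

    seed = build(root, root.age)
    seed.edge.length = None
    tree.seed_node = seed
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# K80 sequence evolution
# ---------------------------------------------------------------------------

def _k80_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after expected divergence d."""
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # split equally over the two transversion targets
    return p_ts, p_tv


def evolve_k80(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence along a branch of d expected subst/site."""
    if d <= 0:
        return seq.copy()
    p_ts, p_tv = _k80_probs(d, kappa)   # p_tv is per transversion target
    u = rng.random(seq.shape[0])
    out = seq.copy()
    ts_partner = seq ^ 2            # A<->G, C<->T
    tv1 = (seq + 1) & 3             # one transversion target
    tv2 = (seq + 3) & 3             # the other
    out = np.where(u < p_ts, ts_partner, out)
    out = np.where((u >= p_ts) & (u < p_ts + p_tv), tv1, out)
    out = np.where((u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv), tv2, out)
    return out.astype(np.uint8)


def _evolve_tree(root: _Node, seq_length: int, kappa: float,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    root_seq = rng.integers(0, 4, size=seq_length, dtype=np.uint8)
    out: dict[str, np.ndarray] = {}

    def walk(node: _Node, seq: np.ndarray, parent_age: float) -> None:
        branch = max(parent_age - node.age, 0.0)
        child_seq = evolve_k80(seq, branch, kappa, rng)
        if not node.children:
            out[node.label] = child_seq
        for c in node.children:
            walk(c, child_seq, node.age)

    walk(root, root_seq, root.age)
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_reference_library(config: SimConfig) -> tuple[ReferenceLibrary, TruthSet]:
    """Simulate an aligned COI library plus its ground truth.

    Deterministic under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _draw_sample_sizes(config, rng)

    sp_tree = _yule_tree(config.n_species, config.birth_rate, rng)
    _scale_and_floor(sp_tree, config.crown_depth, config.stem_scale)
    sp_tips = sp_tree.leaves()
    species_names = [f"sp{i + 1:03d}" for i in range(config.n_species)]
    for tip, name in zip(sp_tips, species_names):
        tip.label = name

    # genus/family labels from fixed divergence cuts of the species tree
    genus_of: dict[str, str] = {}
    for g, clade in enumerate(_cut_tree(sp_tree, 0.06 / 2.0)):
        for sp in clade:
            genus_of[sp] = f"gen{g + 1:02d}"
    family_of: dict[str, str] = {}
    for f, clade in enumerate(_cut_tree(sp_tree, 0.125 / 2.0)):
        for sp in clade:
            family_of[sp] = f"fam{f + 1:02d}"

    # graft a within-species coalescent beneath each species tip
    parent_age = {}
    for node in sp_tree.postorder():
        for c in node.children:
            parent_age[id(c)] = node.age
    nominal: dict[str, str] = {}
    for tip, name, k in zip(sp_tips, species_names, sizes):
        coal = _coalescent(int(k), config.theta, rng)
        stem = parent_age.get(id(tip), math.inf)  # unconstrained for a lone species
        if coal.age >= 0.9 * stem:  # keep the genealogy inside the species branch
            shrink = (0.9 * stem) / coal.age
            for cn in coal.postorder():
                cn.age *= shrink
        tip.children = coal.children if coal.children else []
        tip.age = coal.age
        leaves = tip.leaves()
        for i, leaf in enumerate(leaves):
            leaf.label = f"{name.upper()}-{i + 1:02d}"
            nominal[leaf.label] = name

    seqs = _evolve_tree(sp_tree, config.seq_length, config.kappa, rng)

    sources = rng.choice(["trawl", "market", "mined"], size=len(nominal),
                         p=[0.35, 0.38, 0.27])
    sites = rng.integers(1, 25, size=len(nominal))
    records = []
    for i, (sid, sp) in enumerate(sorted(nominal.items())):
        records.append(
            SequenceRecord(
                id=sid, seq=_decode(seqs[sid]), species=sp,
                genus=genus_of[sp], family=family_of[sp], order="ordsim",
                source=str(sources[i]), site=f"S{int(sites[i]):02d}",
            )
        )
    library = ReferenceLibrary(records)

    truth = TruthSet(
        nominal=dict(nominal),
        molecular=dict(nominal),
        genealogy=_to_dendropy(sp_tree),
        species_tree=_species_tree_dendropy(sp_tree, species_names, nominal),
        summaries=_tree_divergence_summaries(sp_tree, nominal),
    )
    return library, truth


def _species_tree_dendropy(full_root: _Node, species_names, nominal) -> dendropy.Tree:
    """Collapse the grafted genealogy back to one tip per species."""
    import copy

    root = copy.deepcopy(full_root)

    def collapse(node: _Node) -> None:
        leaves = node.leaves()
        species = {nominal[l.label] for l in leaves}
        if len(species) == 1:
            node.children = []
            node.age = 0.0
            node.label = species.pop()
        else:
            for c in node.children:
                collapse(c)

    collapse(root)
    return _to_dendropy(root)


def _tree_divergence_summaries(root: _Node, nominal: dict[str, str]) -> dict[str, float]:
    """Expected pairwise divergences read off the genealogy (2 x MRCA age)."""
    leaves = root.leaves()
    labels = [l.label for l in leaves]
    n = len(leaves)
    mrca_age = np.zeros((n, n))
    index = {id(l): i for i, l in enumerate(leaves)}

    def fill(node: _Node) -> list[int]:
        if not node.children:
            return [index[id(node)]]
        sets = [fill(c) for c in node.children]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        mrca_age[i, j] = mrca_age[j, i] = node.age
        return [i for s in sets for i in s]

    fill(root)
    sp = np.array([nominal[l] for l in labels])
    iu, ju = np.triu_indices(n, k=1)
    div = 2.0 * mrca_age[iu, ju]
    same = sp[iu] == sp[ju]
    out: dict[str, float] = {}
    if same.any():
        out["mean_intraspecific_divergence"] = float(div[same].mean())
        out["max_intraspecific_divergence"] = float(div[same].max())
    if (~same).any():
        out["min_interspecific_divergence"] = float(div[~same].min())
        out["mean_interspecific_divergence"] = float(div[~same].mean())
    return out


# ---------------------------------------------------------------------------
# feature injection
# ---------------------------------------------------------------------------

def _clades_of_species(truth: TruthSet, species: str) -> tuple[list[str], list[str]]:
    """Leaf ids of the two deepest clades within a species' genealogy."""
    members = sorted(i for i, sp in truth.nominal.items() if sp == species)
    taxa = [t for t in truth.genealogy.taxon_namespace if t.label in members]
    mrca = truth.genealogy.mrca(taxa=taxa)
    kids = mrca.child_nodes()
    if len(kids) < 2:
        half = max(1, len(members) // 2)
        return members[:half], members[half:]
    left = {l.taxon.label for l in kids[0].leaf_iter()} & set(members)
    right = set(members) - left
    return sorted(left), sorted(right)


def _between_mean_k2p(library: ReferenceLibrary, group_a: list[str],
                      group_b: list[str]) -> float:
    from .distances import count_site_patterns, k2p_distance

    vals = []
    for a in group_a:
        for b in group_b:
            vals.append(k2p_distance(count_site_patterns(
                library.record(a).seq, library.record(b).seq)))
    return float(np.nanmean(vals)) if vals else 0.0


def _shift_clade(library: ReferenceLibrary, member_ids: list[str], depth: float,
                 kappa: float, rng: np.random.Generator) -> ReferenceLibrary:
    """Apply one shared K80 substitution pattern of the given expected depth
    to every member of a clade, creating a divergence of ~depth between the
    clade and the rest of its species while preserving within-clade
    structure."""
    from .io_formats import encode_sequence

    ref = encode_sequence(library.record(member_ids[0]).seq)
    shifted = evolve_k80(ref, depth, kappa, rng)
    changed = np.where(shifted != ref)[0]
    new_records = []
    for r in library.records:
        if r.id in member_ids:
            codes = encode_sequence(r.seq)
            codes[changed] = shifted[changed]
            new_records.append(SequenceRecord(
                id=r.id, seq=_decode(codes), species=r.species, genus=r.genus,
                family=r.family, order=r.order, source=r.source, site=r.site,
            ))
        else:
            new_records.append(r)
    return ReferenceLibrary(new_records)


def inject_features(
    library: ReferenceLibrary,
    truth: TruthSet,
    feature: Feature,
    seed: int = 0,
    kappa: float = 8.0,
) -> tuple[ReferenceLibrary, TruthSet]:
    """Inject a cryptic split, a shallow species pair, or a singleton.

    cryptic_split: the two deepest clades of one species are pushed apart
    by ``feature.depth`` expected substitutions/site; the nominal label is
    kept (morphology sees one species) while the molecular truth records
    two lineages.

    shallow_pair: half of one species is relabelled as a new sister
    species diverged by only ``feature.divergence`` -- a genuine (nominal
    and molecular) species pair that delimitation methods may lump.

    singleton: one species is pruned to a single sequence.

    The injected substitutions are applied as a single shared pattern so
    within-clade diversity is untouched; the stored genealogy is not
    re-estimated (it remains the pre-injection tree).
    """
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for sp in truth.nominal.values():
        counts[sp] = counts.get(sp, 0) + 1

    def pick(min_size: int) -> str:
        if feature.target_species is not None:
            if counts.get(feature.target_species, 0) < min_size:
                raise ValidationError(
                    f"species {feature.target_species!r} has fewer than "
                    f"{min_size} sequences"
                )
            return feature.target_species
        eligible = [sp for sp, c in sorted(counts.items()) if c >= min_size]
        if not eligible:
            raise ValidationError(f"no species with >= {min_size} sequences")
        return max(eligible, key=lambda sp: counts[sp])

    if feature.kind == "cryptic_split":
        sp = pick(2)
        left, right = _clades_of_species(truth, sp)
        # the clades already diverge; add only the remaining depth
        d0 = _between_mean_k2p(library, left, right)
        lib2 = _shift_clade(library, right, max(feature.depth - d0, 0.0), kappa, rng)
        molecular = dict(truth.molecular)
        for i in left:
            molecular[i] = f"{sp}_A"
        for i in right:
            molecular[i] = f"{sp}_B"
        truth2 = TruthSet(dict(truth.nominal), molecular, truth.genealogy,
                          truth.species_tree, dict(truth.summaries))
        return lib2, truth2

    if feature.kind == "shallow_pair":
        sp = pick(4)
        # graft the sister around the first member's nearest relatives so
        # the realized divergence stays close to the requested value
        members = sorted(i for i, s in truth.nominal.items() if s == sp)
        ref = members[0]
        by_dist = sorted(
            members[1:],
            key=lambda m: _between_mean_k2p(library, [ref], [m]),
        )
        right = [ref] + by_dist[: len(members) // 2 - 1]
        left = [m for m in members if m not in right]
        if not left or not right:
            raise ValidationError(f"species {sp!r} cannot be split in two")
        new_name = f"{sp}x"
        d0 = _between_mean_k2p(library, left, right)
        lib2 = _shift_clade(library, right, max(feature.divergence - d0, 0.0),
                            kappa, rng)
        records = []
        for r in lib2.records:
            if r.id in right:
                records.append(SequenceRecord(
                    id=r.id, seq=r.seq, species=new_name, genus=r.genus,
                    family=r.family, order=r.order, source=r.source, site=r.site,
                ))
            else:
                records.append(r)
        nominal = dict(truth.nominal)
        molecular = dict(truth.molecular)
        for i in right:
            nominal[i] = new_name
            molecular[i] = new_name
        truth2 = TruthSet(nominal, molecular, truth.genealogy,
                          truth.species_tree, dict(truth.summaries))
        return ReferenceLibrary(records), truth2

    if feature.kind == "singleton":
        sp = pick(2)
        members = sorted(i for i, s in truth.nominal.items() if s == sp)
        keep = set(library.ids) - set(members[1:])
        lib2 = library.subset(keep)
        nominal = {i: s for i, s in truth.nominal.items() if i in keep}
        molecular = {i: s for i, s in truth.molecular.items() if i in keep}
        truth2 = TruthSet(nominal, molecular, truth.genealogy,
                          truth.species_tree, dict(truth.summaries))
        return lib2, truth2

    raise ValidationError(f"unknown feature kind {feature.kind!r}")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS = ("easy", "cryptic", "shallow")


def simulate_preset(name: str, seed: int) -> tuple[ReferenceLibrary, TruthSet]:
    """easy: clear barcode gap; cryptic: easy + one cryptic split at 0.086;
    shallow: easy + one species pair at 0.008 divergence."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {PRESETS}")
    cfg = SimConfig(seed=seed)
    library, truth = simulate_reference_library(cfg)
    if name == "cryptic":
        return inject_features(library, truth, Feature(kind="cryptic_split"),
                               seed=seed + 1, kappa=cfg.kappa)
    if name == "shallow":
        return inject_features(library, truth, Feature(kind="shallow_pair"),
                               seed=seed + 1, kappa=cfg.kappa)
    return library, truth
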