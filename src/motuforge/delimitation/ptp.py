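"""Poisson tree processes (PTP / mPTP) on a metric tree.

Branches of a rooted metric tree are classified into a between-species
(speciation) class and within-species (coalescent) classes; branch
lengths in each class are modelled as exponential with their own rate
(one shared coalescent rate in single-rate mode, one per species in
multi-rate mode).  A delimitation is a set of "crown" nodes forming an
antichain that covers every leaf: the edge into a crown and everything
above it belongs to the speciation class, everything below a crown is
coalescent within that species.

The search greedily flips crown edges (split a crown into its children /
merge sibling crowns) from the root partition, with seeded
simulated-annealing restarts.  Single- vs multi-rate is chosen by AIC.

Because the partition is itself searched, the naive likelihood-ratio
test against the one-species null is badly anti-conservative; the null
is therefore calibrated by parametric bootstrap: branch lengths are
redrawn from the fitted single-exponential null on the same topology,
the search is re-run on each replicate, and the Monte-Carlo p-value of
the observed likelihood gain decides whether the one-species null is
rejected at ``alpha``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from ..errors import ValidationError
from ..partition import Partition

__all__ = ["PTPModel", "ptp_fit"]

MIN_BRANCH = 1e-8
MIN_RESOLVED = 1e-4   # branches shorter than ~1/10 substitution are unresolvable


@dataclass
class PTPModel:
    mode: str                       # "single" or "multi"
    lambda_sp: float | None
    lambda_coal: float | dict[str, float] | None
    logL: float
    n_params: int
    aic: float
    null_logL: float
    lrt_stat: float
    lrt_p: float
    significant: bool
    k: int
    notes: dict = field(default_factory=dict)


class _RTree:
    """Array view of a rooted tree for fast crown-set likelihoods."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        self.n = len(nodes)
        self.index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=int)
        self.length = np.zeros(self.n)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.leaf_label: list[str | None] = [None] * self.n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self.index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.length[i] = max(nd.edge.length or 0.0, MIN_BRANCH)
            if nd.is_leaf():
                self.leaf_label[i] = nd.taxon.label if nd.taxon else f"leaf{i}"
        # subtree edge count/sum (edges strictly below each node);
        # branches below the resolution limit carry no length information
        # and are excluded from the likelihood, as in mPTP's minbr rule
        self.resolved = self.length >= MIN_RESOLVED
        self.resolved[0] = False
        self.sub_n = np.zeros(self.n)
        self.sub_sum = np.zeros(self.n)
        for i in range(self.n - 1, -1, -1):
            for c in self.children[i]:
                self.sub_n[i] += self.sub_n[c] + (1 if self.resolved[c] else 0)
                self.sub_sum[i] += self.sub_sum[c] + (
                    self.length[c] if self.resolved[c] else 0.0
                )
        self.total_n = float(self.sub_n[0])
        self.total_sum = float(self.sub_sum[0])

    def refresh_sums(self) -> None:
        """Recompute subtree sums after self.length was replaced."""
        self.sub_n[:] = 0.0
        self.sub_sum[:] = 0.0
        for i in range(self.n - 1, -1, -1):
            for c in self.children[i]:
                self.sub_n[i] += self.sub_n[c] + (1 if self.resolved[c] else 0)
                self.sub_sum[i] += self.sub_sum[c] + (
                    self.length[c] if self.resolved[c] else 0.0
                )
        self.total_n = float(self.sub_n[0])
        self.total_sum = float(self.sub_sum[0])

    def leaves_below(self, i: int) -> list[str]:
        out, stack = [], [i]
        while stack:
            v = stack.pop()
            if self.leaf_label[v] is not None:
                out.append(self.leaf_label[v])
            stack.extend(self.children[v])
        return out


def _exp_loglik(n: float, s: float) -> float:
    if n <= 0:
        return 0.0
    return n * (math.log(n / s) - 1.0)


def _state_loglik(rt: _RTree, crowns: frozenset[int], multi: bool) -> tuple[float, int]:
    """(logL, n_params) of a crown set under the single or multi model."""
    co_n = sum(rt.sub_n[c] for c in crowns)
    co_s = sum(rt.sub_sum[c] for c in crowns)
    sp_n = rt.total_n - co_n
    sp_s = rt.total_sum - co_s
    logL = _exp_loglik(sp_n, sp_s)
    n_params = 1 if sp_n > 0 else 0
    if multi:
        for c in crowns:
            if rt.sub_n[c] > 0:
                logL += _exp_loglik(rt.sub_n[c], rt.sub_sum[c])
                n_params += 1
    else:
        logL += _exp_loglik(co_n, co_s)
        if co_n > 0:
            n_params += 1
    return logL, n_params


def _neighbors(rt: _RTree, crowns: frozenset[int]):
    for c in crowns:
        if rt.children[c]:
            yield crowns - {c} | frozenset(rt.children[c])
    parents = {rt.parent[c] for c in crowns if rt.parent[c] >= 0}
    for p in parents:
        if all(ch in crowns for ch in rt.children[p]):
            yield crowns - frozenset(rt.children[p]) | {p}


def _random_antichain(rt: _RTree, rng: np.random.Generator) -> frozenset[int]:
    out, stack = [], [0]
    while stack:
        v = stack.pop()
        if not rt.children[v] or rng.random() < 0.4:
            out.append(v)
        else:
            stack.extend(rt.children[v])
    return frozenset(out)


def _anneal_then_climb(
    rt: _RTree, start: frozenset[int], multi: bool, rng: np.random.Generator
) -> tuple[frozenset[int], float, int]:
    state = start
    logL, _ = _state_loglik(rt, state, multi)
    temp = 1.0
    for _step in range(120):
        nbrs = list(_neighbors(rt, state))
        if not nbrs:
            break
        cand = nbrs[int(rng.integers(len(nbrs)))]
        cand_logL, _ = _state_loglik(rt, cand, multi)
        delta = cand_logL - logL
        if delta > 0 or rng.random() < math.exp(min(delta / max(temp, 1e-9), 0.0)):
            state, logL = cand, cand_logL
        temp *= 0.95
    # greedy polish
    improved = True
    while improved:
        improved = False
        best, best_logL = None, logL
        for cand in _neighbors(rt, state):
            cand_logL, _ = _state_loglik(rt, cand, multi)
            if cand_logL > best_logL + 1e-12:
                best, best_logL = cand, cand_logL
        if best is not None:
            state, logL = best, best_logL
            improved = True
    _ll, n_params = _state_loglik(rt, state, multi)
    return state, logL, n_params


def ptp_fit(
    tree: dendropy.Tree,
    mode: str = "auto",
    n_restarts: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    n_bootstrap: int = 39,
) -> tuple[Partition, PTPModel]:
    """Fit a PTP delimitation on a rooted metric tree.

    mode: "single" (one shared coalescent rate), "multi" (per-species
    rates, mPTP-style) or "auto" (fit both, choose by AIC).  The
    one-species null is kept unless the parametric-bootstrap test
    (``n_bootstrap`` replicates of the fitted null) rejects it at
    ``alpha``.  Zero-length branches are perturbed to 1e-8; branches
    below the resolution limit are excluded from the likelihood.
    """
    if mode not in ("single", "multi", "auto"):
        raise ValidationError(f"unknown PTP mode {mode!r}")
    leaves = [l for l in tree.leaf_node_iter()]
    if len(leaves) < 4:
        raise ValidationError("PTP needs a tree with at least 4 leaves")
    rt = _RTree(tree)
    if not any(rt.children[c] for c in rt.children[0]):
        warnings.warn("star tree: PTP has no internal structure to classify")
    rng = np.random.default_rng(seed)

    null_crowns = frozenset([0])
    null_logL, _ = _state_loglik(rt, null_crowns, multi=False)

    modes = ("single", "multi") if mode == "auto" else (mode,)
    results = {}
    for m in modes:
        multi = m == "multi"
        best = _anneal_then_climb(rt, null_crowns, multi, rng)
        for _r in range(max(n_restarts - 1, 0)):
            cand = _anneal_then_climb(rt, _random_antichain(rt, rng), multi, rng)
            if cand[1] > best[1]:
                best = cand
        results[m] = best

    def aic_of(m: str) -> float:
        state, logL, n_params = results[m]
        return 2.0 * n_params - 2.0 * logL

    chosen = min(results, key=aic_of)
    state, logL, n_params = results[chosen]
    aic = aic_of(chosen)

    # parametric bootstrap of the one-species null: redraw branch
    # lengths from the fitted exponential, re-run the same search
    lrt = max(2.0 * (logL - null_logL), 0.0)
    multi = chosen == "multi"
    if len(state) > 1 and rt.total_n > 0:
        lam_null = rt.total_n / rt.total_sum
        saved = rt.length.copy()
        exceed = 0
        for _b in range(n_bootstrap):
            draws = rng.exponential(1.0 / lam_null, size=rt.n)
            rt.length = np.where(rt.resolved, draws, saved)
            rt.refresh_sums()
            b_null, _ = _state_loglik(rt, null_crowns, multi=False)
            b_best = _anneal_then_climb(rt, null_crowns, multi, rng)
            for _r in range(max(n_restarts - 1, 0)):
                cand = _anneal_then_climb(rt, _random_antichain(rt, rng), multi, rng)
                if cand[1] > b_best[1]:
                    b_best = cand
            if 2.0 * (b_best[1] - b_null) >= lrt:
                exceed += 1
        rt.length = saved
        rt.refresh_sums()
        lrt_p = (1.0 + exceed) / (n_bootstrap + 1.0)
    else:
        lrt_p = 1.0
    significant = lrt_p < alpha and len(state) > 1

    if not significant:
        if len(state) > 1:
            warnings.warn(
                f"PTP null model not rejected (LRT p={lrt_p:.3f}); returning one MOTU"
            )
        state = null_crowns

    method = "mPTP" if chosen == "multi" else "PTP"
    assignment = {}
    for i, c in enumerate(sorted(state)):
        for label in rt.leaves_below(c):
            assignment[label] = f"{method}{i + 1:04d}"
    partition = Partition(method, assignment)

    co_rates: float | dict[str, float] | None
    sp_n = rt.total_n - sum(rt.sub_n[c] for c in state)
    sp_s = rt.total_sum - sum(rt.sub_sum[c] for c in state)
    lambda_sp = sp_n / sp_s if sp_n > 0 else None
    if chosen == "multi":
        co_rates = {}
        for i, c in enumerate(sorted(state)):
            if rt.sub_n[c] > 0:
                co_rates[f"{method}{i + 1:04d}"] = float(rt.sub_n[c] / rt.sub_sum[c])
    else:
        co_n = sum(rt.sub_n[c] for c in state)
        co_s = sum(rt.sub_sum[c] for c in state)
        co_rates = float(co_n / co_s) if co_n > 0 else None

    model = PTPModel(
        mode=chosen, lambda_sp=lambda_sp, lambda_coal=co_rates,
        logL=float(logL), n_params=int(n_params), aic=float(aic),
        null_logL=float(null_logL), lrt_stat=float(lrt), lrt_p=lrt_p,
        significant=bool(significant), k=partition.k,
        notes={"n_restarts": n_restarts, "seed": seed, "alpha": alpha},
    )
    return partition, model
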