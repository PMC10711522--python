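"""General mixed Yule-coalescent (GMYC) threshold model.

On a rooted, binary, ultrametric tree the model places a threshold age T:
nodes older than T are speciation events of a Yule process, nodes younger
than T are coalescent events inside the species clusters that T cuts out.
Conditioning on the root, the waiting time across each inter-node
interval is exponential with the pooled branching rate

    b = lambda_yule * (n_yule^p_yule - 1)
        + lambda_coal * sum_k n_k * (n_k - 1)^p_coal

where n_yule counts species lineages crossing the interval and n_k the
lineages of coalescent cluster k; the exponents p_* bend the rates away
from the pure Yule/Kingman expectations (p = 1).  The log-likelihood is
sum(log b_i) over intervals that end in a node minus sum(b_i * dt_i) over
all intervals.  Every node age is scanned as a candidate threshold, the
four parameters being re-optimised (Nelder-Mead, warm-started) at each
candidate, so the reported optimum is an exhaustive maximum.  Equal node
ages are separated by a seeded 1e-10 jitter.

``mode="multiple"`` greedily adds per-cluster thresholds (promoting a
cluster root to a speciation event) while AIC improves.  A likelihood
ratio test against the single-coalescent null uses the 50:50
chi2(df)/chi2(df+1) mixture with df = n_params - 2; the null partition
(one species) is returned when the test does not reject at ``alpha``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from ..errors import ValidationError
from ..partition import Partition

__all__ = ["GMYCModel", "gmyc_fit"]

_P_BOUNDS = (1e-3, 5.0)


@dataclass
class GMYCModel:
    mode: str                      # "single" or "multiple"
    thresholds: list[float]        # threshold node ages (speciation cut points)
    lambda_yule: float | None
    p_yule: float | None
    lambda_coal: float | None
    p_coal: float | None
    logL: float
    n_params: int
    aic: float
    null_logL: float
    lrt_stat: float
    lrt_p: float
    significant: bool
    k: int
    notes: dict = field(default_factory=dict)


class _UTree:
    """Sorted-age array view of a rooted binary ultrametric tree."""

    def __init__(self, tree: dendropy.Tree, tol: float, rng: np.random.Generator):
        tree = tree.clone(depth=1)
        internals = []
        for nd in tree.preorder_node_iter():
            if nd.is_internal():
                if len(nd.child_nodes()) != 2:
                    raise ValidationError("GMYC needs a fully resolved (binary) tree")
                internals.append(nd)
        depth: dict[int, float] = {id(tree.seed_node): 0.0}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
        leaf_depths = {
            (nd.taxon.label if nd.taxon else str(id(nd))): depth[id(nd)]
            for nd in tree.leaf_node_iter()
        }
        dmax, dmin = max(leaf_depths.values()), min(leaf_depths.values())
        if dmax - dmin > tol:
            med = float(np.median(list(leaf_depths.values())))
            worst = max(leaf_depths, key=lambda k: abs(leaf_depths[k] - med))
            raise ValidationError(
                f"tree is not ultrametric within {tol:g} "
                f"(worst leaf {worst!r}, spread {dmax - dmin:g})"
            )
        height = dmax
        ages = {id(nd): height - depth[id(nd)] for nd in internals}
        jitter = np.abs(rng.normal(0.0, 1e-10, size=len(internals)))
        # sort oldest first; the preorder index breaks exact-age ties so a
        # parent always ranks before its child even on zero-length branches
        order = sorted(
            range(len(internals)),
            key=lambda i: (-ages[id(internals[i])], i),
        )
        self.m = len(internals)
        age = np.array([ages[id(internals[i])] for i in order]) + jitter[:self.m]
        for i in range(1, self.m):              # strictly decreasing ages
            if age[i] >= age[i - 1]:
                age[i] = age[i - 1] - 1e-12
        self.age = np.maximum(age, 0.0)
        node_rank = {id(internals[i]): r for r, i in enumerate(order)}
        self.parent = np.full(self.m, -1, dtype=int)
        self.leaf_children: list[list[str]] = [[] for _ in range(self.m)]
        self.children: list[list[int]] = [[] for _ in range(self.m)]
        for i in order:
            nd = internals[i]
            r = node_rank[id(nd)]
            if nd.parent_node is not None:
                self.parent[r] = node_rank[id(nd.parent_node)]
                self.children[self.parent[r]].append(r)
            for ch in nd.child_nodes():
                if ch.is_leaf():
                    self.leaf_children[r].append(
                        ch.taxon.label if ch.taxon else str(id(ch))
                    )
        # intervals i = 0..m-1: from age[i] down to age[i+1] (age[m] = 0)
        bounds = np.concatenate([self.age, [0.0]])
        self.dt = bounds[:-1] - bounds[1:]

    def clusters(self, spec: np.ndarray) -> list[list[int]]:
        """Coalescent clusters (sorted internal-node ranks, root first) for
        an upward-closed speciation mask."""
        out: dict[int, list[int]] = {}
        root_of = np.full(self.m, -1, dtype=int)
        for r in range(self.m):
            if spec[r]:
                continue
            p = self.parent[r]
            if p < 0 or spec[p]:
                root_of[r] = r
                out[r] = [r]
            else:
                root_of[r] = root_of[p]
                out[root_of[r]].append(r)
        return list(out.values())

    def leaves_under(self, r: int) -> list[str]:
        out, stack = [], [r]
        while stack:
            v = stack.pop()
            out.extend(self.leaf_children[v])
            stack.extend(self.children[v])
        return out


def _rate_structure(ut: _UTree, spec: np.ndarray):
    """Per-interval lineage structure for a speciation mask.

    Returns (n1, C, sizes): n1[i] = species lineages during interval i;
    C[i, s] = number of coalescent clusters with sizes[s] lineages during
    interval i.
    """
    m = ut.m
    cum = np.cumsum(spec.astype(int))
    n1 = (1 + cum).astype(float)
    clusters = ut.clusters(spec)
    max_size = max((len(c) + 1 for c in clusters), default=1)
    C = np.zeros((m, max(max_size - 1, 1)))     # column s -> size s+2
    for members in clusters:
        members = sorted(members)
        for r_pos, rank in enumerate(members):
            size = r_pos + 2
            hi = members[r_pos + 1] if r_pos + 1 < len(members) else m
            C[rank:hi, size - 2] += 1.0
    sizes = np.arange(2, C.shape[1] + 2, dtype=float)
    return n1, C, sizes


def _fit(ut: _UTree, spec: np.ndarray, x0: np.ndarray | None = None):
    """Maximise the pooled-rate likelihood for one speciation mask.

    Returns (logL, params dict, x_opt).
    """
    m = ut.m
    n1, C, sizes = _rate_structure(ut, spec)
    dt = ut.dt
    yule_on = bool((n1 >= 2).any())
    coal_on = bool(C.any())
    n_free = (2 if yule_on else 0) + (2 if coal_on else 0)
    if n_free == 0:
        return 0.0, {"lambda_yule": None, "p_yule": None,
                     "lambda_coal": None, "p_coal": None}, np.empty(0)

    def unpack(x):
        idx = 0
        lam1 = p1 = lam2 = p2 = None
        if yule_on:
            lam1, p1 = math.exp(x[0]), x[1]
            idx = 2
        if coal_on:
            lam2, p2 = math.exp(x[idx]), x[idx + 1]
        return lam1, p1, lam2, p2

    def nll(x):
        lam1, p1, lam2, p2 = unpack(x)
        b = np.zeros(m)
        if yule_on:
            if not (_P_BOUNDS[0] <= p1 <= _P_BOUNDS[1]) or lam1 > 1e12:
                return math.inf
            b = b + lam1 * (np.power(n1, p1) - 1.0)
        if coal_on:
            if not (_P_BOUNDS[0] <= p2 <= _P_BOUNDS[1]) or lam2 > 1e12:
                return math.inf
            f = sizes * np.power(sizes - 1.0, p2)
            b = b + lam2 * (C @ f)
        with np.errstate(divide="ignore"):
            logs = np.log(b[: m - 1])
        if np.any(~np.isfinite(logs)):
            return math.inf
        return -(float(logs.sum()) - float((b * dt).sum()))

    if x0 is None or len(x0) != n_free:
        # moment-style initialisation at p = 1
        x0_list = []
        if yule_on:
            expo = float(((n1 - 1.0) * dt).sum())
            n_ev = max(float(np.sum(spec[1:])), 0.5)
            x0_list += [math.log(max(n_ev / max(expo, 1e-12), 1e-6)), 1.0]
        if coal_on:
            f = sizes * (sizes - 1.0)
            expo = float(((C @ f) * dt).sum())
            n_ev = max(float((~spec[1:]).sum()), 0.5)
            x0_list += [math.log(max(n_ev / max(expo, 1e-12), 1e-6)), 1.0]
        x0 = np.array(x0_list)

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 400 * n_free, "xatol": 1e-5, "fatol": 1e-7})
    lam1, p1, lam2, p2 = unpack(res.x)
    params = {"lambda_yule": lam1, "p_yule": p1,
              "lambda_coal": lam2, "p_coal": p2}
    return -float(res.fun), params, res.x


def _n_params(spec: np.ndarray, n_extra_thresholds: int) -> int:
    has_yule = bool(spec.any())
    has_coal = not bool(spec.all())
    return (2 if has_yule else 0) + (2 if has_coal else 0) + n_extra_thresholds


def gmyc_fit(
    tree: dendropy.Tree,
    mode: str = "single",
    alpha: float = 0.05,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[Partition, GMYCModel]:
    """Fit a GMYC delimitation on a rooted binary ultrametric tree.

    All node ages are scanned as candidate thresholds; ``mode="multiple"``
    then greedily promotes cluster roots to speciation events while AIC
    improves.  Returns the null (one-species) partition when the LRT does
    not reject it at ``alpha``.
    """
    if mode not in ("single", "multiple"):
        raise ValidationError(f"unknown GMYC mode {mode!r}")
    rng = np.random.default_rng(seed)
    leaves = [l.taxon.label if l.taxon else str(id(l)) for l in tree.leaf_node_iter()]
    method = "mGMYC" if mode == "multiple" else "GMYC"
    if len(leaves) < 3:
        warnings.warn("GMYC on < 3 leaves is degenerate; returning one MOTU")
        part = Partition(method, {l: f"{method}0001" for l in leaves})
        model = GMYCModel(mode=mode, thresholds=[], lambda_yule=None, p_yule=None,
                          lambda_coal=None, p_coal=None, logL=0.0, n_params=0,
                          aic=0.0, null_logL=0.0, lrt_stat=0.0, lrt_p=1.0,
                          significant=False, k=1)
        return part, model

    ut = _UTree(tree, tol=tol, rng=rng)
    m = ut.m

    null_logL, null_params, _x = _fit(ut, np.zeros(m, dtype=bool))

    best = None
    warm = None
    scan = []
    for j in range(1, m + 1):
        spec = np.zeros(m, dtype=bool)
        spec[:j] = True
        logL, params, warm = _fit(ut, spec, warm)
        scan.append((float(ut.age[j - 1]), float(logL)))
        if best is None or logL > best[1]:
            best = (j, logL, params)

    best_j, logL, params = best
    spec = np.zeros(m, dtype=bool)
    spec[:best_j] = True
    thresholds = [float(ut.age[best_j - 1])]
    n_extra = 0

    if mode == "multiple":
        improved = True
        while improved:
            improved = False
            aic_now = 2.0 * _n_params(spec, n_extra) - 2.0 * logL
            best_cand = None
            for members in ut.clusters(spec):
                if len(members) < 2:
                    continue
                cand = spec.copy()
                cand[min(members)] = True
                cand_logL, cand_params, _ = _fit(ut, cand)
                cand_aic = 2.0 * _n_params(cand, n_extra + 1) - 2.0 * cand_logL
                if cand_aic < aic_now - 1e-9 and (
                    best_cand is None or cand_logL > best_cand[1]
                ):
                    best_cand = (cand, cand_logL, cand_params, min(members))
            if best_cand is not None:
                spec, logL, params, promoted = best_cand
                thresholds.append(float(ut.age[promoted]))
                n_extra += 1
                improved = True

    n_params = _n_params(spec, n_extra)
    aic = 2.0 * n_params - 2.0 * logL
    df = max(n_params - 2, 1)
    lrt = max(2.0 * (logL - null_logL), 0.0)
    lrt_p = float(0.5 * (chi2.sf(lrt, df) + chi2.sf(lrt, df + 1)))
    significant = lrt_p < alpha

    if significant:
        assignment: dict[str, str] = {}
        idx = 0
        for members in ut.clusters(spec):
            idx += 1
            label = f"{method}{idx:04d}"
            for leaf in ut.leaves_under(min(members)):
                assignment[leaf] = label
        for r in range(m):          # singleton species hanging off speciation nodes
            if spec[r]:
                for leaf in ut.leaf_children[r]:
                    idx += 1
                    assignment[leaf] = f"{method}{idx:04d}"
        partition = Partition(method, assignment)
    else:
        logL = max(logL, null_logL)     # the one-species null stands
        params = null_params
        partition = Partition(method, {l: f"{method}0001" for l in leaves})

    model = GMYCModel(
        mode=mode, thresholds=thresholds,
        lambda_yule=params.get("lambda_yule"), p_yule=params.get("p_yule"),
        lambda_coal=params.get("lambda_coal"), p_coal=params.get("p_coal"),
        logL=float(logL), n_params=int(n_params), aic=float(aic),
        null_logL=float(null_logL), lrt_stat=float(lrt), lrt_p=lrt_p,
        significant=bool(significant), k=partition.k,
        notes={"scan": scan, "seed": seed, "alpha": alpha},
    )
    return partition, model
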