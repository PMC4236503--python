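"""Desk-scale divergence dating: ML branch lengths on a fixed topology and a
weighted least-squares strict-clock fit of node ages to those lengths.

The strict-clock surrogate makes the phenomenon of interest measurable
without MCMC: homoplasy-distorted branch lengths distort the fitted node
ages, and pruning saturated partitions changes the branch lengths and hence
the ages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._felsenstein import LikelihoodEngine, TreeIndex
from .seqio import Alignment, Chronogram
from .subst_models import SubstitutionModel, transition_probabilities

__all__ = ["Calibration", "CalibrationSet", "DatingResult",
           "estimate_branch_lengths", "date_tree", "jc_distance"]

_BL_BOUNDS = (1e-9, 20.0)


def jc_distance(p: float) -> float:
    """Closed-form Jukes-Cantor distance from a proportion of differing sites."""
    if p >= 0.75:
        raise ValueError("proportion of differences is saturated (>= 3/4)")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass
class Calibration:
    """Age constraint on the MRCA of a taxon set."""

    taxa: frozenset
    min_age: float
    max_age: float | None = None  # None = unbounded above
    kind: str = "bounded"  # "fixed" pins the age to min_age

    def __post_init__(self) -> None:
        self.taxa = frozenset(self.taxa)
        if self.kind == "fixed":
            self.max_age = self.min_age
        if self.max_age is not None and self.min_age > self.max_age:
            raise ValueError("calibration min_age > max_age")


CalibrationSet = list  # list[Calibration]


@dataclass
class DatingResult:
    ages: dict  # clade frozenset -> estimated age (Ma)
    rate: float  # global substitutions/site/Ma
    objective: float
    errors: dict | None = None  # clade -> signed error vs truth

    def rmse(self) -> float:
        if not self.errors:
            raise ValueError("no truth supplied")
        e = np.array(list(self.errors.values()))
        return float(np.sqrt(np.mean(e ** 2)))

    def mean_signed_error(self, younger_than: float | None = None,
                          truth: dict | None = None) -> float:
        if not self.errors:
            raise ValueError("no truth supplied")
        items = self.errors.items()
        if younger_than is not None:
            items = [(k, v) for k, v in items if truth[k] < younger_than]
        vals = [v for _, v in items]
        return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Branch-length estimation
# ---------------------------------------------------------------------------

def estimate_branch_lengths(aln: Alignment, topology, model: SubstitutionModel,
                            *, tol: float = 1e-6, max_sweeps: int = 50,
                            init: float = 0.05):
    """ML branch lengths (expected substitutions/site) on a fixed rooted
    topology by coordinate-wise bracketed optimization with cached
    rest-of-tree partial likelihoods.

    Returns (TreeIndex, lengths array indexed by child node, log-likelihood).
    Convergence: max per-sweep length change < ``tol``; on hitting the sweep
    cap a warning is emitted and the best-found lengths are returned.
    """
    engine = LikelihoodEngine(aln, topology, model)
    t = engine.tree
    lengths = np.full(t.n_nodes, float(init))
    lengths[t.root] = 0.0
    # With exactly two root children the likelihood depends only on the sum
    # of their lengths (reversible-model pulley ridge); pin one edge near
    # zero so the sum is carried by its sibling and the coordinate sweep
    # cannot oscillate along the ridge.
    root_kids = t.children[t.root]
    pinned = root_kids[1] if len(root_kids) == 2 else None
    if pinned is not None:
        lengths[pinned] = _BL_BOUNDS[0]
    from .subst_models import category_rates_and_weights
    cat_rates, cat_w = category_rates_and_weights(model)
    ncat = len(cat_rates)
    pi = model.base_frequencies
    n_sites = engine.n_sites

    def _norm(x):
        m = x.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        return x / m[:, None]

    def edge_nll(b, F_c, down_c):
        # whole-data likelihood as a function of one edge length, up to
        # per-site constants shared across b
        per_cat = []
        for k, r in enumerate(cat_rates):
            P = transition_probabilities(model, b * r)
            site_l = np.einsum("sx,xy,sy->s", F_c[k], P, down_c[k])
            per_cat.append(np.log(np.maximum(site_l, 1e-300)))
        per_cat = np.stack(per_cat)
        mx = per_cat.max(axis=0)
        return -float((mx + np.log(
            np.tensordot(cat_w, np.exp(per_cat - mx), axes=1))).sum())

    converged = False
    for _ in range(max_sweeps):
        # subtree (down) partials with the current lengths, per category
        downs = [engine._postorder(lengths * r)[0] for r in cat_rates]
        max_change = 0.0
        # preorder Gauss-Seidel pass: each edge is optimized against the
        # already-updated lengths of its ancestors (rest-of-tree partials G
        # are rebuilt on the way down), which prevents the parent/child
        # trade oscillation a stale-environment update suffers from
        G = {t.root: [np.tile(pi, (n_sites, 1)) for _ in range(ncat)]}
        for p in range(t.n_nodes - 1, -1, -1):
            kids = t.children[p]
            if not kids:
                continue
            msgs = {c: [downs[k][c] @ transition_probabilities(
                model, lengths[c] * r).T
                for k, r in enumerate(cat_rates)] for c in kids}
            def rest_of_tree(c):
                f = [G[p][k].copy() for k in range(ncat)]
                for s in kids:
                    if s != c:
                        for k in range(ncat):
                            f[k] *= msgs[s][k]
                return [_norm(fk) for fk in f]

            for c in kids:
                if c == pinned:
                    continue
                res = minimize_scalar(
                    edge_nll, args=(rest_of_tree(c),
                                    [downs[k][c] for k in range(ncat)]),
                    bounds=_BL_BOUNDS, method="bounded",
                    options={"xatol": tol / 10})
                max_change = max(max_change, abs(res.x - lengths[c]))
                lengths[c] = res.x
                msgs[c] = [downs[k][c] @ transition_probabilities(
                    model, lengths[c] * r).T
                    for k, r in enumerate(cat_rates)]
            for c in kids:  # G with every sibling at its final length
                if t.children[c]:
                    f = rest_of_tree(c)
                    G[c] = [_norm(np.einsum(
                        "sx,xy->sy", f[k],
                        transition_probabilities(model, lengths[c] * r)))
                        for k, r in enumerate(cat_rates)]
            del G[p]
        if max_change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"branch-length optimization hit the sweep cap "
                      f"({max_sweeps}); returning best found")
    ll = engine.loglik_branch_lengths(lengths)
    return t, lengths, float(ll)


def two_taxon_ml_distance(aln: Alignment, model: SubstitutionModel,
                          tol: float = 1e-10) -> float:
    """ML evolutionary distance between exactly two sequences."""
    if aln.n_taxa != 2:
        raise ValueError("need exactly two taxa")
    a, b = aln.data
    from ._felsenstein import _PARTIAL_TABLE
    La = np.stack([_PARTIAL_TABLE[s] for s in a])
    Lb = np.stack([_PARTIAL_TABLE[s] for s in b])
    pi = model.base_frequencies

    def nll(d):
        P = transition_probabilities(model, d)
        site = np.einsum("sx,x,xy,sy->s", La, pi, P, Lb)
        return -float(np.log(np.maximum(site, 1e-300)).sum())

    res = minimize_scalar(nll, bounds=(1e-12, 20.0), method="bounded",
                          options={"xatol": 1e-8, "maxiter": 2000})
    # Newton polish on the analytic score (the likelihood is numerically
    # flat at double precision near the optimum, which limits Brent)
    from .subst_models import _eig_decomposition
    w, U, Uinv, _ = _eig_decomposition(model)
    d = float(res.x)
    for _ in range(30):
        E = np.exp(w * d)
        P = (U * E) @ Uinv
        P1 = (U * (w * E)) @ Uinv
        P2 = (U * (w ** 2 * E)) @ Uinv
        v = np.einsum("sx,x,xy,sy->s", La, pi, P, Lb)
        v1 = np.einsum("sx,x,xy,sy->s", La, pi, P1, Lb)
        v2 = np.einsum("sx,x,xy,sy->s", La, pi, P2, Lb)
        score = float((v1 / v).sum())
        hess = float(((v2 * v - v1 ** 2) / v ** 2).sum())
        if hess >= 0:
            break
        step = score / hess
        d = min(max(d - step, 1e-12), 20.0)
        if abs(step) < tol * max(d, 1.0) / 10:
            break
    return d


# ---------------------------------------------------------------------------
# Least-squares strict-clock dating
# ---------------------------------------------------------------------------

def _clade_of(t: TreeIndex, i: int) -> frozenset:
    tips = []
    stack = [i]
    while stack:
        j = stack.pop()
        if not t.children[j]:
            tips.append(t.tip_labels[t.tip_ids.index(j)])
        else:
            stack.extend(t.children[j])
    return frozenset(tips)


def date_tree(tree: TreeIndex | Chronogram, lengths: np.ndarray,
              calibrations: CalibrationSet, *,
              truth: dict | None = None,
              weight_eps: float = 1e-4) -> DatingResult:
    """Fit internal node ages t and a global rate r minimizing

        sum_e w_e (b_e - r (t_parent - t_child))^2,   w_e = 1/(b_e + eps)

    subject to parent >= child ordering and the calibration bounds; tips sit
    at age 0.  The two root-child edges of a rooted tree are
    likelihood-confounded under reversible models, so their residuals are
    merged into one term on their summed length.  At least one calibration
    must carry finite age information (a fixed age or a finite maximum).
    """
    t = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    lengths = np.asarray(lengths, dtype=float)
    internal = t.internal_ids()
    clades = {i: _clade_of(t, i) for i in internal}
    var_of = {i: k for k, i in enumerate(internal)}
    n_var = len(internal)

    # calibration bounds on the age variables
    lb = np.zeros(n_var)
    ub = np.full(n_var, np.inf)
    by_clade = {clades[i]: i for i in internal}
    for cal in calibrations:
        node = by_clade.get(frozenset(cal.taxa))
        if node is None:
            raise ValueError(f"calibration taxa {sorted(cal.taxa)} do not "
                             f"select an internal node of the topology")
        k = var_of[node]
        lb[k] = max(lb[k], cal.min_age)
        if cal.max_age is not None:
            ub[k] = min(ub[k], cal.max_age)
        if lb[k] > ub[k] + 1e-12:
            raise ValueError(f"infeasible calibration on {sorted(cal.taxa)}: "
                             f"min {lb[k]} > max {ub[k]}")
    if not np.any(np.isfinite(ub)):
        raise ValueError("need at least one calibration with a finite "
                         "maximum or fixed age (ages are unidentifiable)")
    # propagate: a descendant's min age bounds every ancestor from below
    for i in internal:  # postorder: children before parents
        p = t.parent[i]
        if p >= 0:
            lb[var_of[p]] = max(lb[var_of[p]], lb[var_of[i]])
            if lb[var_of[i]] > ub[var_of[p]] + 1e-12:
                raise ValueError(
                    f"infeasible calibrations: node {sorted(clades[i])} min "
                    f"{lb[var_of[i]]} exceeds ancestor max {ub[var_of[p]]}")

    # design matrix: dt_term = A @ ages ; b_term observed length
    root_kids = t.children[t.root]
    merge_root = len(root_kids) == 2
    rows, b_obs = [], []
    for i in range(t.n_nodes):
        p = t.parent[i]
        if p < 0:
            continue
        if merge_root and p == t.root:
            if i == root_kids[0]:
                row = np.zeros(n_var)
                row[var_of[t.root]] = 2.0
                for c in root_kids:
                    if c in var_of:
                        row[var_of[c]] -= 1.0
                rows.append(row)
                b_obs.append(lengths[root_kids[0]] + lengths[root_kids[1]])
            continue
        row = np.zeros(n_var)
        row[var_of[p]] = 1.0
        if i in var_of:
            row[var_of[i]] = -1.0
        rows.append(row)
        b_obs.append(lengths[i])
    A = np.vstack(rows)
    b = np.asarray(b_obs)
    w = 1.0 / (b + weight_eps)
    sw = np.sqrt(w)

    def split(x):
        return x[:n_var], x[n_var]

    def objective(x):
        ages, r = split(x)
        resid = sw * (b - r * (A @ ages))
        return float(resid @ resid)

    def grad(x):
        ages, r = split(x)
        dt = A @ ages
        core = w * (b - r * dt)
        g = np.empty_like(x)
        g[:n_var] = -2.0 * r * (A.T @ core)
        g[n_var] = -2.0 * float(core @ dt)
        return g

    # ordering constraints t_parent - t_child >= 0 for internal-internal edges
    ord_rows = []
    for i in internal:
        p = t.parent[i]
        if p >= 0:
            row = np.zeros(n_var + 1)
            row[var_of[p]] = 1.0
            row[var_of[i]] = -1.0
            ord_rows.append(row)
    constraints = []
    if ord_rows:
        M = np.vstack(ord_rows)
        constraints = [{"type": "ineq", "fun": lambda x: M @ x,
                        "jac": lambda x: M}]

    # feasible start: ages proportional to max root-ward path length, scaled
    # to the root's calibration window, then clipped into bounds with the
    # ordering repaired root-ward
    depth = np.zeros(t.n_nodes)
    for i in range(t.n_nodes):
        if t.children[i]:
            depth[i] = max(depth[c] + max(lengths[c], 1e-9)
                           for c in t.children[i])
    rk = var_of[t.root]
    root_target = ub[rk] if np.isfinite(ub[rk]) else max(1.0, 1.5 * lb.max())
    root_target = max(root_target, lb[rk])
    ages0 = depth[internal] / max(depth[t.root], 1e-300) * root_target
    ages0 = np.maximum(ages0, lb)
    ages0 = np.where(np.isfinite(ub), np.minimum(ages0, ub), ages0)
    for _ in range(n_var):
        ok = True
        for i in internal:
            p = t.parent[i]
            if p >= 0 and ages0[var_of[i]] > ages0[var_of[p]]:
                k = var_of[p]
                ages0[k] = ages0[var_of[i]]
                if ages0[k] > ub[k] + 1e-9:
                    raise ValueError("could not build a feasible start from "
                                     "the calibration set")
                ok = False
        if ok:
            break
    dt0 = A @ ages0
    denom = float(w @ dt0 ** 2)
    r0 = max(float(w @ (b * dt0)) / denom, 1e-10) if denom > 0 else 1e-4
    x0 = np.concatenate([ages0, [r0]])

    bounds = [(float(l), float(u) if np.isfinite(u) else None)
              for l, u in zip(lb, ub)] + [(1e-12, None)]
    res = minimize(objective, x0, jac=grad, method="SLSQP", bounds=bounds,
                   constraints=constraints,
                   options={"maxiter": 1000, "ftol": 1e-16})
    x = res.x if objective(res.x) <= objective(x0) else x0
    ages, r = split(x)

    result_ages = {clades[i]: float(ages[var_of[i]]) for i in internal}
    errors = None
    if truth is not None:
        errors = {c: result_ages[c] - truth[c]
                  for c in result_ages if c in truth}
    return DatingResult(result_ages, float(r), objective(x), errors)
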