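"""Pruning-algorithm likelihood engine, vectorized across alignment sites.

The tree is flattened to postorder index arrays once; likelihood evaluations
then loop over nodes (not sites), so per-site rate vectors and scalar branch
lengths share the same core.  Partial likelihoods are rescaled per site to
avoid underflow, with the log scale factors accumulated separately.
"""

from __future__ import annotations

import numpy as np

from .seqio import IUPAC, _BASE_INDEX, Alignment, Chronogram
from .subst_models import (SubstitutionModel, category_rates_and_weights,
                           transition_probabilities,
                           transition_probabilities_batch)

_TINY = 1e-300


def state_partial(symbol: str) -> np.ndarray:
    """Indicator partial-likelihood row for one IUPAC symbol."""
    row = np.zeros(4)
    for b in IUPAC[symbol.upper()]:
        row[_BASE_INDEX[b]] = 1.0
    return row


_PARTIAL_TABLE = {sym: state_partial(sym) for sym in IUPAC}


class TreeIndex:
    """Postorder-flattened rooted tree.

    Node ids are postorder positions (root last).  Every non-root node owns
    the edge to its parent; ``durations[i]`` is that edge's length (Ma for
    chronograms, expected substitutions for phylograms).
    """

    def __init__(self, tree_or_chronogram, taxa_order: list[str] | None = None):
        tree = (tree_or_chronogram.tree
                if isinstance(tree_or_chronogram, Chronogram)
                else tree_or_chronogram)
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.node_objs = nodes
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.durations = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.tip_ids: list[int] = []
        self.tip_labels: list[str] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                if isinstance(tree_or_chronogram, Chronogram):
                    self.durations[i] = nd.parent_node.age - nd.age
                else:
                    self.durations[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                self.tip_ids.append(i)
                self.tip_labels.append(nd.taxon.label)
        self.root = self.n_nodes - 1
        if taxa_order is not None:
            missing = set(taxa_order) ^ set(self.tip_labels)
            if missing:
                raise ValueError(
                    f"taxon labels do not match between tree and alignment: "
                    f"{sorted(missing)}")

    def internal_ids(self):
        return [i for i in range(self.n_nodes) if self.children[i]]


def tip_partials(aln: Alignment, tree: TreeIndex) -> np.ndarray:
    """(n_nodes-indexed dict-free) tip partials, shape (n_tips, n_sites, 4),
    ordered as tree.tip_ids."""
    row_of = {t: r for r, t in enumerate(aln.taxa)}
    out = np.empty((len(tree.tip_ids), aln.length, 4))
    lut = np.stack([_PARTIAL_TABLE[s] for s in sorted(IUPAC)])
    codes = {s: k for k, s in enumerate(sorted(IUPAC))}
    for k, label in enumerate(tree.tip_labels):
        seq = aln.data[row_of[label]]
        idx = np.fromiter((codes[s] for s in seq), dtype=int, count=aln.length)
        out[k] = lut[idx]
    return out


class LikelihoodEngine:
    """Per-site pruning likelihoods for one alignment on one fixed tree."""

    def __init__(self, aln: Alignment, tree, model: SubstitutionModel):
        self.tree = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, aln.taxa)
        if set(self.tree.tip_labels) != set(aln.taxa):
            raise ValueError("taxon labels do not match between tree and alignment")
        self.model = model
        self.n_sites = aln.length
        self._tipL = tip_partials(aln, self.tree)
        self._tip_slot = {tid: k for k, tid in enumerate(self.tree.tip_ids)}
        self.pi = model.base_frequencies

    # -- per-site rate mode (distances = rate_i * duration_e) ---------------
    def loglik_per_site(self, rates: np.ndarray) -> np.ndarray:
        """Per-site log-likelihood with site-specific rates (len n_sites or
        scalar), distances = rate * branch duration."""
        rates = np.asarray(rates, dtype=float)
        scalar = rates.ndim == 0
        t = self.tree
        partial = [None] * t.n_nodes
        scale = np.zeros(self.n_sites)
        for i in range(t.n_nodes):
            if not t.children[i]:
                partial[i] = self._tipL[self._tip_slot[i]]
                continue
            acc = np.ones((self.n_sites, 4))
            for c in t.children[i]:
                if scalar:
                    P = transition_probabilities(
                        self.model, float(rates) * t.durations[c])
                    msg = partial[c] @ P.T
                else:
                    P = transition_probabilities_batch(
                        self.model, rates * t.durations[c])
                    msg = np.einsum("sxy,sy->sx", P, partial[c])
                acc *= msg
                partial[c] = None
            m = acc.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            acc /= m[:, None]
            scale += np.log(m)
            partial[i] = acc
        site_l = partial[t.root] @ self.pi
        return np.log(np.maximum(site_l, _TINY)) + scale

    # -- scalar branch-length mode (distances = b_e, mixture over rates) ----
    def loglik_branch_lengths(self, lengths: np.ndarray) -> float:
        return float(self.sitewise_loglik_branch_lengths(lengths).sum())

    def sitewise_loglik_branch_lengths(self, lengths: np.ndarray) -> np.ndarray:
        """Per-site log-likelihood for per-edge distances in expected
        substitutions/site, honouring the model's +Γ/+I mixture."""
        cat_rates, cat_w = category_rates_and_weights(self.model)
        per_cat = []
        for r in cat_rates:
            down, scale = self._postorder(np.asarray(lengths) * r)
            site_l = np.maximum(down[self.tree.root] @ self.pi, _TINY)
            per_cat.append((np.log(site_l) + scale))
        per_cat = np.stack(per_cat)  # (ncat, n_sites)
        mx = per_cat.max(axis=0)
        return mx + np.log(np.tensordot(cat_w, np.exp(per_cat - mx), axes=1))

    def _postorder(self, dists: np.ndarray):
        t = self.tree
        down = [None] * t.n_nodes
        scale = np.zeros(self.n_sites)
        for i in range(t.n_nodes):
            if not t.children[i]:
                down[i] = self._tipL[self._tip_slot[i]]
                continue
            acc = np.ones((self.n_sites, 4))
            for c in t.children[i]:
                P = transition_probabilities(self.model, float(dists[c]))
                acc *= down[c] @ P.T
            m = acc.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            acc /= m[:, None]
            scale += np.log(m)
            down[i] = acc
        return down, scale

    def edge_environments(self, lengths: np.ndarray, cat_rate: float = 1.0):
        """Down partials and rest-of-tree (F) partials per edge, for
        single-edge likelihood evaluation during branch-length optimization.

        Returns (down, F) where, for non-root node c with parent p,
        sitewise L = sum_x F[c]_x sum_y P_xy(b_c) down[c]_y up to per-site
        scale constants (constant in b_c).
        """
        t = self.tree
        dists = np.asarray(lengths) * cat_rate
        down = [None] * t.n_nodes
        for i in range(t.n_nodes):
            if not t.children[i]:
                down[i] = self._tipL[self._tip_slot[i]]
            else:
                acc = np.ones((self.n_sites, 4))
                for c in t.children[i]:
                    P = transition_probabilities(self.model, float(dists[c]))
                    acc *= down[c] @ P.T
                m = acc.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                down[i] = acc / m[:, None]
        G = [None] * t.n_nodes
        G[t.root] = np.tile(self.pi, (self.n_sites, 1))
        F = [None] * t.n_nodes
        for i in range(t.n_nodes - 1, -1, -1):
            kids = t.children[i]
            if not kids:
                continue
            msgs = {}
            for c in kids:
                P = transition_probabilities(self.model, float(dists[c]))
                msgs[c] = down[c] @ P.T
            for c in kids:
                f = G[i].copy()
                for s in kids:
                    if s != c:
                        f *= msgs[s]
                m = f.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                f /= m[:, None]
                F[c] = f
                P = transition_probabilities(self.model, float(dists[c]))
                g = np.einsum("sx,xy->sy", f, P)
                m = g.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                G[c] = g / m[:, None]
        return down, F


def brute_force_site_log_likelihood(column: dict[str, str], chronogram,
                                    model: SubstitutionModel,
                                    rate: float) -> float:
    """Exhaustive sum over ancestral-state assignments (oracle for small trees).

    ``column`` maps taxon label -> IUPAC symbol.  Exponential in the number
    of internal nodes; intended for trees with at most ~6 taxa.
    """
    import itertools

    t = TreeIndex(chronogram)
    internals = t.internal_ids()
    pi = model.base_frequencies
    Ps = {i: transition_probabilities(model, rate * t.durations[i])
          for i in range(t.n_nodes) if t.parent[i] >= 0}
    tipstate = {}
    for tid, label in zip(t.tip_ids, t.tip_labels):
        tipstate[tid] = _PARTIAL_TABLE[column[label].upper()]
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internals)):
        states = dict(zip(internals, assign))
        p = pi[states[t.root]]
        for i in range(t.n_nodes):
            par = t.parent[i]
            if par < 0:
                continue
            if i in states:  # internal child
                p *= Ps[i][states[par], states[i]]
            else:  # tip: sum over compatible observed states
                p *= float(Ps[i][states[par]] @ tipstate[i])
        total += p
    return float(np.log(max(total, _TINY)))
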