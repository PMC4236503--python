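"""Per-site substitution-rate estimation on a fixed chronogram.

Each alignment column gets its own maximum-likelihood rate (substitutions/
site/Ma) by bracketed scalar optimization of the pruning-algorithm
likelihood on log rate.  Branch durations come from the chronogram in Ma,
so the estimates sit directly on the time axis used by informativeness
profiles.  No +Γ/+I mixture is used here: the free per-site rate subsumes
both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._felsenstein import LikelihoodEngine, brute_force_site_log_likelihood
from .seqio import IUPAC, Alignment, Chronogram
from .subst_models import SubstitutionModel

__all__ = [
    "SiteRates", "estimate_site_rates", "estimate_site_rate",
    "site_log_likelihood", "empirical_frequencies",
    "brute_force_site_log_likelihood",
]

CONVERGED = "converged"
AT_LOWER = "at_lower_bound"
AT_UPPER = "at_upper_bound"
UNINFORMATIVE = "uninformative"

_MISSING = {"-", "?", "N"}
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class SiteRates:
    """Estimated per-site rates with per-site log-likelihoods and flags."""

    rates: np.ndarray
    log_likelihoods: np.ndarray
    flags: np.ndarray  # dtype object/str
    bounds: tuple[float, float]

    def __len__(self) -> int:
        return len(self.rates)

    def informative_mask(self) -> np.ndarray:
        """Sites usable in informativeness profiles: estimable rates above the
        lower bound (constant and near-empty columns carry no profile signal);
        at_upper_bound sites are kept."""
        return (self.flags != UNINFORMATIVE) & (self.flags != AT_LOWER)

    def to_frame(self, scheme=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "site": np.arange(1, len(self.rates) + 1),
            "rate": self.rates,
            "logL": self.log_likelihoods,
            "flag": self.flags,
        })
        if scheme is not None:
            lookup = scheme.site_to_subset()
            df.insert(1, "subset", [lookup.get(s, "") for s in df["site"]])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   bounds=(1e-8, 10.0)) -> "SiteRates":
        df = df.sort_values("site")
        return cls(df["rate"].to_numpy(float), df["logL"].to_numpy(float),
                   df["flag"].to_numpy(object), bounds)


def empirical_frequencies(aln: Alignment, sites=None,
                          pseudocount: float = 1.0) -> np.ndarray:
    """Empirical base frequencies over the given 1-based sites (default all);
    ambiguity codes are split evenly among their compatible bases."""
    counts = np.full(4, pseudocount)
    cols = aln.data if sites is None else aln.data[:, np.asarray(sorted(sites)) - 1]
    symbols, n = np.unique(cols, return_counts=True)
    from .seqio import _BASE_INDEX
    for sym, k in zip(symbols, n):
        if sym in _MISSING:
            continue
        bases = IUPAC[sym]
        for b in bases:
            counts[_BASE_INDEX[b]] += k / len(bases)
    return counts / counts.sum()


def site_log_likelihood(column: dict[str, str], tree: Chronogram,
                        model: SubstitutionModel, rate: float) -> float:
    """Pruning log-likelihood of a single column at the given rate."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    taxa = list(column)
    aln = Alignment(taxa, np.array([[column[t]] for t in taxa], dtype="<U1"))
    engine = LikelihoodEngine(aln, tree, model)
    return float(engine.loglik_per_site(np.array([rate]))[0])


def _uninformative_mask(aln: Alignment, min_states: int = 4) -> np.ndarray:
    """Columns with fewer than ``min_states`` non-missing observations."""
    missing = np.isin(aln.data, list(_MISSING))
    return (~missing).sum(axis=0) < min_states


def estimate_site_rates(aln: Alignment, tree: Chronogram,
                        model: SubstitutionModel, *,
                        bounds: tuple[float, float] = (1e-8, 10.0),
                        tol: float = 1e-8,
                        n_grid: int = 33) -> SiteRates:
    """ML rate per column by log-spaced grid bracketing + golden-section
    refinement, vectorized across columns.

    Deterministic given inputs; column results are mutually independent.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError("need 0 < lower bound < upper bound")
    engine = LikelihoodEngine(aln, tree, model)
    n = aln.length
    grid = np.log(np.geomspace(lo, hi, n_grid))
    ll_grid = np.empty((n_grid, n))
    for k, g in enumerate(grid):
        ll_grid[k] = engine.loglik_per_site(np.exp(np.float64(g)))
    if not np.all(np.isfinite(ll_grid)):
        bad = np.where(~np.isfinite(ll_grid))[1][:5] + 1
        raise FloatingPointError(
            f"non-finite likelihood in rate bracket at sites {bad.tolist()}")
    best = ll_grid.argmax(axis=0)

    # golden-section search on log-rate inside the bracketing interval,
    # vectorized across sites with one likelihood pass per iteration
    a = grid[np.maximum(best - 1, 0)]
    b = grid[np.minimum(best + 1, n_grid - 1)]
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1 = engine.loglik_per_site(np.exp(x1))
    f2 = engine.loglik_per_site(np.exp(x2))
    width0 = max((b - a).max(), tol)
    n_iter = int(np.ceil(np.log(tol / width0) / np.log(_GOLDEN))) + 2
    for _ in range(max(n_iter, 1)):
        left = f1 >= f2  # maximum lies in [a, x2]
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
        x2_new = np.where(left, x1, a + _GOLDEN * (b - a))
        x1_new = np.where(left, b - _GOLDEN * (b - a), x2)
        x_eval = np.where(left, x1_new, x2_new)
        f_eval = engine.loglik_per_site(np.exp(x_eval))
        # left: new x2 inherits old x1's value, new x1 is the fresh point;
        # right: new x1 inherits old x2's value, new x2 is fresh
        f1, f2 = (np.where(left, f_eval, f2), np.where(left, f1, f_eval))
        x1, x2 = x1_new, x2_new
        if (b - a).max() <= tol:
            break
    rates = np.exp((a + b) / 2.0)

    flags = np.full(n, CONVERGED, dtype=object)
    at_lo = best == 0
    at_hi = best == n_grid - 1
    rates[at_lo] = lo
    rates[at_hi] = hi
    flags[at_lo] = AT_LOWER
    flags[at_hi] = AT_UPPER
    ll = engine.loglik_per_site(rates)
    uninf = _uninformative_mask(aln)
    flags[uninf] = UNINFORMATIVE
    return SiteRates(rates, ll, flags, bounds)


def estimate_site_rate(column: dict[str, str], tree: Chronogram,
                       model: SubstitutionModel, *,
                       bounds: tuple[float, float] = (1e-8, 10.0),
                       tol: float = 1e-8):
    """Single-column convenience wrapper; returns (rate, logL, flag)."""
    taxa = list(column)
    aln = Alignment(taxa, np.array([[column[t]] for t in taxa], dtype="<U1"))
    sr = estimate_site_rates(aln, tree, model, bounds=bounds, tol=tol)
    return float(sr.rates[0]), float(sr.log_likelihoods[0]), str(sr.flags[0])
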