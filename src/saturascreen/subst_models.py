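"""Reversible continuous-time nucleotide substitution models.

GTR and its nested cases (JC, F81, K80, HKY, SYM) with optional discrete-Γ
rate heterogeneity and a proportion of invariant sites.  Generators are
normalized to one expected substitution per unit evolutionary distance.
Bases are ordered A, C, G, T; the six exchangeabilities follow the usual
order AC, AG, AT, CG, CT, GT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

_EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class ModelParameterError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    gamma_shape: float | None = None
    n_categories: int = 4
    p_invariant: float | None = None

    def __post_init__(self) -> None:
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.base_frequencies.shape != (4,):
            raise ModelParameterError("need 4 base frequencies")
        if np.any(self.base_frequencies <= 0):
            raise ModelParameterError("base frequencies must be positive")
        if abs(self.base_frequencies.sum() - 1.0) > 1e-8:
            raise ModelParameterError("base frequencies must sum to 1")
        if self.exchangeabilities.shape != (6,):
            raise ModelParameterError("need 6 exchangeabilities")
        if np.any(self.exchangeabilities < 0):
            raise ModelParameterError("exchangeabilities must be nonnegative")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelParameterError("gamma shape must be positive")
        if self.p_invariant is not None and not 0 <= self.p_invariant < 1:
            raise ModelParameterError("p_invariant must lie in [0, 1)")
        self._decomp = None

    # -- constructors -------------------------------------------------------
    @classmethod
    def jc(cls, **kw) -> "SubstitutionModel":
        return cls(**kw)

    @classmethod
    def k80(cls, kappa: float = 2.0, **kw) -> "SubstitutionModel":
        return cls(exchangeabilities=_kappa_exch(kappa), **kw)

    @classmethod
    def hky(cls, freqs, kappa: float = 2.0, **kw) -> "SubstitutionModel":
        return cls(base_frequencies=np.asarray(freqs),
                   exchangeabilities=_kappa_exch(kappa), **kw)

    @classmethod
    def gtr(cls, freqs, rates, **kw) -> "SubstitutionModel":
        return cls(base_frequencies=np.asarray(freqs),
                   exchangeabilities=np.asarray(rates), **kw)

    @classmethod
    def from_config(cls, cfg: dict) -> "SubstitutionModel":
        """Build from a JSON-style config, e.g.
        {"model": "GTR", "freqs": [...], "rates": [...], "gamma_shape": 0.5}.
        """
        name = cfg.get("model", "GTR").upper()
        kw = dict(gamma_shape=cfg.get("gamma_shape"),
                  n_categories=cfg.get("ncat", 4),
                  p_invariant=cfg.get("p_invariant"))
        freqs = cfg.get("freqs")
        if name in ("JC", "JC69"):
            return cls.jc(**kw)
        if name == "K80":
            return cls.k80(cfg.get("kappa", 2.0), **kw)
        if name == "F81":
            return cls(base_frequencies=np.asarray(freqs), **kw)
        if name == "HKY":
            return cls.hky(freqs, cfg.get("kappa", 2.0), **kw)
        if name == "SYM":
            return cls(exchangeabilities=np.asarray(cfg["rates"]), **kw)
        if name == "GTR":
            return cls.gtr(freqs, cfg["rates"], **kw)
        raise ModelParameterError(f"unknown model {name!r}")

    def with_frequencies(self, freqs) -> "SubstitutionModel":
        return SubstitutionModel(np.asarray(freqs), self.exchangeabilities.copy(),
                                 self.gamma_shape, self.n_categories,
                                 self.p_invariant)


def _kappa_exch(kappa: float) -> np.ndarray:
    # transitions AG and CT get kappa
    e = np.ones(6)
    e[1] = kappa
    e[4] = kappa
    return e


def build_generator(model: SubstitutionModel) -> np.ndarray:
    """Reversible generator Q with detailed balance pi_i Q_ij = pi_j Q_ji,
    normalized to one expected substitution per unit distance."""
    pi = model.base_frequencies
    Q = np.zeros((4, 4))
    for k, (i, j) in enumerate(_EXCH_PAIRS):
        s = model.exchangeabilities[k]
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ModelParameterError("degenerate generator (all rates zero)")
    return Q / mu


def _eig_decomposition(model: SubstitutionModel):
    """Eigendecomposition of Q via the pi-symmetrized form; cached on model."""
    if model._decomp is not None:
        return model._decomp
    Q = build_generator(model)
    pi = model.base_frequencies
    d = np.sqrt(pi)
    S = (Q * d[:, None]) / d[None, :]  # symmetric similarity transform
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    U = V / d[:, None] * 1.0  # right eigenvectors of Q: D^-1 V
    U = V / d[:, None]
    Uinv = (V * d[:, None]).T  # V^T D
    model._decomp = (w, U, Uinv, Q)
    return model._decomp


def transition_probabilities(model: SubstitutionModel,
                             distance: float) -> np.ndarray:
    """P(d) = exp(Q d) for an evolutionary distance in expected subs/site."""
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    w, U, Uinv, Q = _eig_decomposition(model)
    P = (U * np.exp(w * distance)) @ Uinv
    if not np.all(np.isfinite(P)):
        P = expm(Q * distance)  # conditioning fallback
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_probabilities_batch(model: SubstitutionModel,
                                   distances: np.ndarray) -> np.ndarray:
    """Vectorized P(d) for an array of distances; returns shape (..., 4, 4)."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    w, U, Uinv, _ = _eig_decomposition(model)
    E = np.exp(np.multiply.outer(d, w))  # (..., 4)
    P = np.einsum("im,...m,mj->...ij", U, E, Uinv)
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=-1, keepdims=True)
    return P


def discrete_gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of equal-probability discrete-Γ categories (overall mean 1)."""
    if shape <= 0:
        raise ModelParameterError("gamma shape must be positive")
    if n_categories < 1:
        raise ModelParameterError("need at least one category")
    edges = gamma_dist.ppf(np.linspace(0, 1, n_categories + 1), a=shape,
                           scale=1.0 / shape)
    # mean of Gamma(shape, 1/shape) truncated to [a, b], via the identity
    # E[X; a<X<b] = F_{shape+1}(b) - F_{shape+1}(a) (mean-1 gamma)
    cdf_up = gamma_dist.cdf(edges, a=shape + 1, scale=1.0 / shape)
    rates = (cdf_up[1:] - cdf_up[:-1]) * n_categories
    return rates / rates.mean()


def category_rates_and_weights(model: SubstitutionModel):
    """Site-rate mixture implied by +Γ/+I settings: (rates, weights).

    +I is a point mass at rate 0; the remaining mass is discrete Γ (or a
    single rate-1 class without Γ), rescaled so the mixture mean is 1.
    """
    if model.gamma_shape is None:
        rates = np.array([1.0])
        weights = np.array([1.0])
    else:
        rates = discrete_gamma_rates(model.gamma_shape, model.n_categories)
        weights = np.full(model.n_categories, 1.0 / model.n_categories)
    if model.p_invariant:
        p = model.p_invariant
        rates = np.concatenate([[0.0], rates / (1.0 - p)])
        weights = np.concatenate([[p], weights * (1.0 - p)])
    return rates, weights
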