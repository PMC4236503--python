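"""Phylogenetic informativeness (PI) profiles through time.

A site evolving at rate λ contributes an informativeness density
16·λ²·T·e^(−4λT) at historical time T (four-state symmetric form).  A
subset's profile is the per-site mean over its informative sites.  Screening
uses only ratios to the profile peak, so any positive rescaling of the
density leaves every decision unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import PartitionScheme
from .site_rates import SiteRates

__all__ = ["PIProfile", "pi_site", "profile_for_subset", "profiles_for_scheme",
           "decay_fraction", "profile_slope", "default_grid"]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def pi_site(T, lam) -> np.ndarray | float:
    """Informativeness density of a site with rate ``lam`` at time ``T`` Ma.

    Maximal at T = 1/(4λ); decays exponentially beyond it (the "rain shadow
    of noise" where homoplasy accumulates).
    """
    T = np.asarray(T, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(T < 0) or np.any(lam < 0):
        raise ValueError("time and rate must be nonnegative")
    out = 16.0 * lam ** 2 * T * np.exp(-4.0 * lam * T)
    return float(out) if out.ndim == 0 else out


def default_grid(root_age: float, n: int = 2048) -> np.ndarray:
    """Equally spaced times on (0, root_age]."""
    if root_age <= 0:
        raise ValueError("root age must be positive")
    return np.linspace(root_age / n, root_age, n)


@dataclass
class PIProfile:
    """Per-subset informativeness curve with its summary statistics."""

    name: str
    time_grid: np.ndarray
    values: np.ndarray
    peak_time: float
    peak_value: float
    n_sites: int
    rates: np.ndarray = field(repr=False, default=None)
    empty: bool = False

    def value_at(self, T: float) -> float:
        """Exact profile value (mean site density), not an interpolation."""
        if self.empty:
            return 0.0
        return float(np.mean(pi_site(T, self.rates)))


def _refine_peak(rates: np.ndarray, a: float, b: float,
                 rel_tol: float = 1e-6) -> tuple[float, float]:
    """Golden-section refinement of the profile maximum inside [a, b]."""
    def f(T):
        return float(np.mean(pi_site(T, rates)))

    while (b - a) > rel_tol * max(b, 1.0):
        x1 = b - _GOLDEN * (b - a)
        x2 = a + _GOLDEN * (b - a)
        if f(x1) >= f(x2):
            b = x2
        else:
            a = x1
    t = (a + b) / 2.0
    return t, f(t)


def profile_for_subset(name: str, rates: np.ndarray,
                       grid: np.ndarray) -> PIProfile:
    """Profile from the informative-site rates of one subset.

    ``rates`` must already be restricted to the subset's informative sites
    (use SiteRates.informative_mask with the scheme's site sets).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        return PIProfile(name, grid, np.zeros_like(grid), np.nan, 0.0, 0,
                         rates, empty=True)
    values = pi_site(grid[:, None], rates[None, :]).mean(axis=1)
    i = int(values.argmax())
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    peak_time, peak_value = _refine_peak(rates, a, b)
    if peak_value < values[i]:  # grid point was already the max
        peak_time, peak_value = float(grid[i]), float(values[i])
    return PIProfile(name, grid, values, peak_time, peak_value,
                     rates.size, rates)


def profiles_for_scheme(site_rates: SiteRates, scheme: PartitionScheme,
                        root_age: float,
                        grid: np.ndarray | None = None) -> list[PIProfile]:
    """One profile per subset, excluding uninformative/at-lower-bound sites."""
    if grid is None:
        grid = default_grid(root_age)
    mask = site_rates.informative_mask()
    out = []
    for name in scheme.subsets:
        sites = np.asarray(sorted(scheme.sites(name))) - 1
        ok = sites[mask[sites]]
        out.append(profile_for_subset(name, site_rates.rates[ok], grid))
    return out


def _check_boundary(profile: PIProfile, boundary: float) -> None:
    root = float(profile.time_grid[-1])
    if not 0 < boundary <= root + 1e-9:
        raise ValueError(
            f"boundary {boundary} Ma outside (0, root age {root} Ma]")


def decay_fraction(profile: PIProfile, boundary: float) -> float:
    """Fractional decline from the profile peak at the time boundary.

    Zero whenever the profile is still rising at the boundary
    (peak_time >= boundary).
    """
    _check_boundary(profile, boundary)
    if profile.empty or profile.peak_time >= boundary:
        return 0.0
    return 1.0 - profile.value_at(boundary) / profile.peak_value


def profile_slope(profile: PIProfile, boundary: float) -> float:
    """Per-Ma slope of the peak-normalized profile between the peak and the
    boundary (or the root, if the peak lies at/after the boundary)."""
    _check_boundary(profile, boundary)
    if profile.empty:
        return 0.0
    root = float(profile.time_grid[-1])
    ref = boundary if profile.peak_time < boundary else root
    if ref <= profile.peak_time:
        return 0.0
    norm = profile.value_at(ref) / profile.peak_value
    return (norm - 1.0) / (ref - profile.peak_time)


def profiles_to_frame(profiles: list[PIProfile],
                      boundary: float = 145.0) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "subset": p.name,
            "n_sites": p.n_sites,
            "peak_time": p.peak_time,
            "peak_value": p.peak_value,
            "slope": profile_slope(p, boundary) if not p.empty else np.nan,
            "decay_at_boundary": decay_fraction(p, boundary),
        })
    return pd.DataFrame(rows)
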