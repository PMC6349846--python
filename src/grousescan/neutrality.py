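"""SFS-based diversity and neutrality statistics.

All estimators consume an unfolded spectrum ``xi`` (length m+1; bins 0 and m
are monomorphic and contribute nothing except to site totals) and operate on
the last axis, so a stack of per-window spectra is processed in one call.
Window values are *sums* over the window's sites, not per-site averages —
the convention of the windowed theta tools this pipeline mirrors; divide by
window span for plotting if per-site values are wanted.

Undefined statistics (S = 0 windows) are returned as NaN and must be excluded
from genome-wide summaries rather than treated as zeros.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "theta_pi",
    "theta_watterson",
    "theta_h",
    "theta_l",
    "tajimas_d",
    "fay_wu_h",
    "segregating_sites",
    "window_stats",
]


def _prep(xi) -> tuple[np.ndarray, int, np.ndarray]:
    xi = np.asarray(xi, dtype=np.float64)
    m = xi.shape[-1] - 1
    if m < 2:
        raise ValueError("need at least m=2 chromosomes")
    i = np.arange(m + 1, dtype=np.float64)
    return xi, m, i


def segregating_sites(xi) -> np.ndarray | float:
    xi = np.asarray(xi)
    return xi[..., 1:-1].sum(axis=-1)


def theta_pi(xi):
    """Pairwise theta: mean pairwise differences, sum over sites.

    theta_pi = sum_i xi_i * i*(m-i) / C(m,2).
    """
    xi, m, i = _prep(xi)
    w = i * (m - i)
    return xi @ w / (m * (m - 1) / 2)


def theta_watterson(xi):
    """Watterson's theta: S / a1 with a1 the (m-1)-th harmonic number."""
    xi, m, _ = _prep(xi)
    a1 = (1.0 / np.arange(1, m)).sum()
    return segregating_sites(xi) / a1


def theta_h(xi, *, folded: bool = False):
    """Fay & Wu's homozygosity-weighted theta: sum_{0<i<m} xi_i i^2 / C(m,2).

    Weights square the derived count, so high-frequency derived alleles
    dominate; meaningless without polarization, hence the folded guard.
    """
    if folded:
        raise ValueError("theta_H requires an unfolded (polarized) spectrum")
    xi, m, i = _prep(xi)
    w = i**2
    w[m] = 0.0  # fixed-derived class carries no polymorphism signal
    return xi @ w / (m * (m - 1) / 2)


def theta_l(xi):
    """Zeng et al.'s linear-weighted theta: sum_{0<i<m} xi_i * i / (m-1)."""
    xi, m, i = _prep(xi)
    w = i.copy()
    w[m] = 0.0
    return xi @ w / (m - 1)


def _tajima_constants(m: int) -> tuple[float, float]:
    """(e1, e2) of Tajima's variance formula for sample size m."""
    k = np.arange(1, m)
    a1 = (1.0 / k).sum()
    a2 = (1.0 / k**2).sum()
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(xi):
    """Tajima's D: (theta_pi - theta_W) / sqrt(e1*S + e2*S*(S-1)).

    NaN where S = 0 (no information).  Negative values indicate an excess of
    rare variants (expansion, sweeps); positive values an excess of
    intermediate frequencies.
    """
    xi_arr, m, _ = _prep(xi)
    e1, e2 = _tajima_constants(m)
    s = segregating_sites(xi_arr)
    var = e1 * s + e2 * s * (s - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (theta_pi(xi_arr) - theta_watterson(xi_arr)) / np.sqrt(var)
    return np.where(s > 0, d, np.nan) if np.ndim(d) else (float(d) if s > 0 else np.nan)


def fay_wu_h(xi, normalized: bool = False):
    """Fay & Wu's H.

    Default (raw) form: H = theta_pi - theta_H.  Negative H flags an excess of
    high-frequency derived alleles (the hitchhiking signature); positive H an
    excess of rare derived alleles.  ``normalized=True`` returns Zeng et al.'s
    variance-standardized version (theta_pi - theta_L over its estimated
    standard deviation).  NaN where S = 0.
    """
    xi_arr, m, _ = _prep(xi)
    s = segregating_sites(xi_arr)
    if not normalized:
        h = theta_pi(xi_arr) - theta_h(xi_arr)
    else:
        k = np.arange(1, m)
        a1 = (1.0 / k).sum()
        a2 = (1.0 / k**2).sum()
        bn1 = a2 + 1.0 / m**2  # sum_{i<=m} 1/i^2
        theta = s / a1
        theta_sq = s * (s - 1) / (a1**2 + a2)
        var = theta * (m - 2) / (6.0 * (m - 1)) + theta_sq * (
            18.0 * m**2 * (3.0 * m + 2.0) * bn1
            - (88.0 * m**3 + 9.0 * m**2 - 13.0 * m + 6.0)
        ) / (9.0 * m * (m - 1) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            h = (theta_pi(xi_arr) - theta_l(xi_arr)) / np.sqrt(var)
    return np.where(s > 0, h, np.nan) if np.ndim(h) else (float(h) if s > 0 else np.nan)


def window_stats(xi_windows: np.ndarray) -> dict[str, np.ndarray]:
    """All per-window statistics from a stack of spectra (n_windows, m+1)."""
    s = segregating_sites(xi_windows).astype(np.float64)
    return {
        "S": s,
        "theta_pi": theta_pi(xi_windows),
        "theta_w": theta_watterson(xi_windows),
        "theta_h": theta_h(xi_windows),
        "tajima_d": tajimas_d(xi_windows),
        "fay_wu_h": fay_wu_h(xi_windows),
    }
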