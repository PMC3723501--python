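"""Numerics for sums of i.i.d. lognormal random variables.

The distribution of the summed signal from multiple proximal TCR-pMHC
contacts is the m-fold convolution of a lognormal.  No closed form exists,
so this module provides three evaluation routes for the survival function
P(S_m > x):

``convolution``
    Recursive numerical convolution of the survival function on a log-scale
    grid: S_m(x) = S_1(x) + \\int_0^1 phi((ln x + ln v)/sigma)
    S_{m-1}(x(1-v)) dv / (sigma v).  The split makes the integrand smooth on
    a shared v-grid, and working on log-survival preserves relative accuracy
    deep into the upper tail (which is magnified n-fold when fate
    probabilities are powers of encounter probabilities).  Validated against
    Monte Carlo to ~1e-3 absolute CDF error for m <= 10 at sigma = 1.

``shifted_lognormal``
    Three-moment (mean/variance/skewness) match to a shifted lognormal.
    Cheap and accurate for large m (abs error < 0.008 for m >= 30); used
    automatically beyond the convolution table depth.

``fenton_wilkinson``
    Classical two-moment lognormal match.  Retained for comparison; its body
    error reaches ~0.02 at sigma = 1, so it is not the default.

Tables are cached per (sigma, table depth); the lognormal scale parameter
mu only shifts the distribution multiplicatively, so it is factored out
before the cache lookup.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

# depth of the exact convolution tables; beyond this the 3-moment match is
# already well inside the oracle tolerance
CONV_TABLE_DEPTH = 25

_N_U = 2000  # log-x grid nodes
_N_V = 1000  # quadrature nodes on (0, 1)


class _SumTables:
    """Log-survival tables for S_m, m = 1..depth, for one sigma."""

    def __init__(self, sigma: float, depth: int):
        self.sigma = sigma
        self.depth = depth
        u = np.linspace(-9.0 * sigma, 11.0 * sigma + np.log(max(depth, 2)), _N_U)
        self.u = u
        x = np.exp(u)
        half = _N_V // 2
        a = np.geomspace(1e-13, 0.5, half)
        v = np.unique(np.concatenate([a, 1.0 - a[::-1]]))
        s1_log = stats.norm.logsf(u / sigma)
        logs = {1: s1_log}
        X = x[:, None]
        V = v[None, :]
        z = (np.log(X) + np.log(V)) / sigma
        w = stats.norm.pdf(z) / (sigma * V)
        uq = np.log(X * (1.0 - V))
        S1 = stats.norm.sf(u / sigma)
        for m in range(2, depth + 1):
            interp = PchipInterpolator(u, logs[m - 1], extrapolate=False)
            lv = interp(uq)
            Sprev = np.exp(np.where(np.isnan(lv), -np.inf, lv))
            Sprev = np.where(uq < u[0], 1.0, Sprev)
            Sprev = np.where(uq > u[-1], 0.0, Sprev)
            integral = np.trapezoid(w * Sprev, v, axis=1)
            S = np.clip(S1 + integral, 1e-300, 1.0)
            logs[m] = np.log(S)
        self._interp = {m: PchipInterpolator(u, t, extrapolate=False) for m, t in logs.items()}

    def sf(self, x: np.ndarray, m: int) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        below = x <= np.exp(self.u[0])
        above = x >= np.exp(self.u[-1])
        mid = ~(below | above)
        out[below] = 1.0
        out[above] = 0.0
        if np.any(mid):
            out[mid] = np.exp(self._interp[m](np.log(x[mid])))
        return out


_TABLE_CACHE: dict[tuple[float, int], _SumTables] = {}


def _get_tables(sigma: float, depth: int) -> _SumTables:
    key = (round(float(sigma), 12), depth)
    tab = _TABLE_CACHE.get(key)
    if tab is None:
        tab = _SumTables(sigma, depth)
        _TABLE_CACHE[key] = tab
    return tab


def _moments(mu: float, sigma: float) -> tuple[float, float, float]:
    """Mean, variance and third central moment of one lognormal."""
    w = np.exp(sigma**2)
    e1 = np.exp(mu + sigma**2 / 2.0)
    var = (w - 1.0) * e1**2
    k3 = (w + 2.0) * np.sqrt(w - 1.0) ** 3 * e1**3
    return e1, var, k3


def fenton_wilkinson_sf(x, m: int, mu: float = 0.0, sigma: float = 1.0):
    """Two-moment lognormal match to the m-fold sum."""
    e1, var, _ = _moments(mu, sigma)
    s2 = np.log1p(var / (m * e1 * e1))
    mufw = np.log(m * e1) - s2 / 2.0
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        z = (np.log(np.maximum(x, 1e-300)) - mufw) / np.sqrt(s2)
    return np.where(x <= 0, 1.0, stats.norm.sf(z))


def shifted_lognormal_sf(x, m: int, mu: float = 0.0, sigma: float = 1.0):
    """Three-moment shifted-lognormal match to the m-fold sum."""
    e1, var1, k3_1 = _moments(mu, sigma)
    mean, var, k3 = m * e1, m * var1, m * k3_1
    gamma = k3 / var**1.5
    w = brentq(lambda w_: (w_ + 2.0) ** 2 * (w_ - 1.0) - gamma**2, 1.0 + 1e-12, 1e9)
    s2 = np.log(w)
    emu = np.sqrt(var / ((w - 1.0) * w))
    shift = mean - emu * np.sqrt(w)
    x = np.asarray(x, dtype=float)
    y = x - shift
    with np.errstate(divide="ignore"):
        z = (np.log(np.maximum(y, 1e-300)) - np.log(emu)) / np.sqrt(s2)
    return np.where(y <= 0, 1.0, stats.norm.sf(z))


def lognormal_sum_sf(x, m: int, mu: float = 0.0, sigma: float = 1.0,
                     method: str = "auto"):
    """Survival function P(S_m > x) for a sum of m i.i.d. lognormals.

    Parameters
    ----------
    x : array-like
        Evaluation points (any real; the sum is positive).
    m : int
        Number of summands, m >= 0.  m = 0 gives a point mass at zero.
    mu, sigma : float
        Log-scale location and spread of a single summand.
    method : {"auto", "convolution", "shifted_lognormal", "fenton_wilkinson"}
        "auto" uses the convolution tables up to their depth and the
        three-moment match beyond.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if m == 0:
        out = np.where(x < 0.0, 1.0, 0.0)
        return float(out[0]) if scalar else out
    # factor out mu: S_m(x; mu, sigma) = S_m(x * exp(-mu); 0, sigma)
    xs = x * np.exp(-mu)
    if method == "auto":
        method = "convolution" if m <= CONV_TABLE_DEPTH else "shifted_lognormal"
    if method == "convolution":
        if m > CONV_TABLE_DEPTH:
            out = shifted_lognormal_sf(xs, m, 0.0, sigma)
        elif m == 1:
            with np.errstate(divide="ignore"):
                out = np.where(
                    xs <= 0, 1.0,
                    stats.norm.sf(np.log(np.maximum(xs, 1e-300)) / sigma))
        else:
            out = _get_tables(sigma, CONV_TABLE_DEPTH).sf(xs, m)
    elif method == "shifted_lognormal":
        out = shifted_lognormal_sf(xs, m, 0.0, sigma)
    elif method == "fenton_wilkinson":
        out = fenton_wilkinson_sf(xs, m, 0.0, sigma)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(out[0]) if scalar else out


def lognormal_sum_cdf(x, m: int, mu: float = 0.0, sigma: float = 1.0,
                      method: str = "auto"):
    """CDF counterpart of :func:`lognormal_sum_sf`."""
    return 1.0 - lognormal_sum_sf(x, m, mu, sigma, method)


def mc_sum_cdf(x, m: int, mu: float = 0.0, sigma: float = 1.0,
               n_samples: int = 10**6, seed: int = 0):
    """Monte-Carlo estimate of the m-sum CDF; the independent oracle."""
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    counts = np.zeros(x.shape, dtype=np.int64)
    chunk = max(1, min(n_samples, 10**7 // max(m, 1)))
    done = 0
    while done < n_samples:
        k = min(chunk, n_samples - done)
        s = np.exp(rng.normal(mu, sigma, size=(k, m))).sum(axis=1)
        counts += (s[None, :] <= x[:, None]).sum(axis=1)
        done += k
    return counts / n_samples
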