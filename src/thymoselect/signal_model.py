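"""Single-contact and encounter-level TCR signal-strength distributions.

A developing thymocyte surveys self pMHC in *encounters*, each the
simultaneous (or temporally proximal) binding of N TCRs to N pMHC ligands
on an antigen-presenting cell.  A single contact yields

* the agonist signal ``s_tim`` with probability g (the fraction of
  peptides replaced by the inducible agonist),
* no signal (a null peptide) with probability f * (1 - g),
* a lognormal(mu_log, sigma_log) endogenous signal otherwise.

The encounter strength is the sum of the N contact signals.  Its CDF is a
binomial mixture over (k agonist contacts, j null contacts) of m-fold
lognormal-sum CDFs, evaluated numerically (see
:mod:`thymoselect.lognormal_sum`).  Fate-relevant thresholds a <= b <= c
partition encounter strength into four zones; zones are half-open
[lower, upper), so a boundary value belongs to the higher zone.

Only relative signal strengths matter for fate decisions, so the
endogenous distribution is normalised to median 1 (mu_log = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .lognormal_sum import lognormal_sum_sf

ZONES = ("sub_positive", "conv", "reg", "deletion")


@dataclass(frozen=True)
class EncounterModel:
    """Parameters of the per-contact / per-encounter signal distribution.

    Attributes
    ----------
    N : int
        TCR-pMHC contacts integrated per encounter (>= 1).
    g : float
        Fraction of peptides replaced by agonist, in [0, 1].
    f : float
        Fraction of endogenous peptides that are null, in [0, 1).
    s_tim : float
        Signal strength of a single agonist contact (> 0).
    mu_log, sigma_log : float
        Log-scale location and spread of one endogenous contact signal;
        mu_log = 0 fixes the median endogenous strength to 1.
    """

    N: int = 1
    g: float = 0.0
    f: float = 0.0
    s_tim: float = 1.0
    mu_log: float = 0.0
    sigma_log: float = 1.0

    def __post_init__(self):
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError(f"g must lie in [0, 1], got {self.g}")
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"f must lie in [0, 1), got {self.f}")
        if not self.s_tim > 0.0:
            raise ValueError(f"s_tim must be positive, got {self.s_tim}")
        if not self.sigma_log > 0.0:
            raise ValueError(f"sigma_log must be positive, got {self.sigma_log}")

    def with_g(self, g: float) -> "EncounterModel":
        return replace(self, g=float(g))

    @property
    def contact_probs(self) -> tuple[float, float, float]:
        """(agonist, null, productive endogenous) per-contact probabilities."""
        return (self.g, self.f * (1.0 - self.g), (1.0 - self.f) * (1.0 - self.g))


@dataclass(frozen=True)
class Thresholds:
    """Fate-zone boundaries on encounter strength, a <= b <= c.

    a: positive selection, b: T_reg commitment, c: negative selection.
    a = -inf encodes the regime in which failing positive selection is
    negligible (p0 set to 0).
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        if math.isnan(self.a) or math.isnan(self.b) or math.isnan(self.c):
            raise ValueError("thresholds must not be NaN")
        if not (self.a <= self.b <= self.c):
            raise ValueError(f"need a <= b <= c, got {(self.a, self.b, self.c)}")

    def zone_of(self, s: float) -> str:
        """Fate zone of a single signal of strength s (half-open zones)."""
        if s < self.a:
            return "sub_positive"
        if s < self.b:
            return "conv"
        if s < self.c:
            return "reg"
        return "deletion"

    def scaled(self, factor: float) -> "Thresholds":
        return Thresholds(self.a * factor, self.b * factor, self.c * factor)


@dataclass(frozen=True)
class CategoryProbs:
    """Per-encounter probabilities of the four fate zones; sums to 1."""

    p0: float
    p1: float
    p2: float
    p3: float

    def __post_init__(self):
        for name, p in zip(("p0", "p1", "p2", "p3"), self.as_array()):
            if not -1e-12 <= p <= 1.0 + 1e-12:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if abs(sum(self.as_array()) - 1.0) > 1e-9:
            raise ValueError(f"category probabilities must sum to 1, got {self.as_array()}")

    def as_array(self) -> tuple[float, float, float, float]:
        return (self.p0, self.p1, self.p2, self.p3)


def sample_contact(model: EncounterModel, seed: int, count: int) -> np.ndarray:
    """Draw single-contact signal strengths (agonist / null / endogenous mixture)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=count)
    # draw the lognormal stream unconditionally so the mixture branches do
    # not perturb each other's stream positions
    ln = np.exp(rng.normal(model.mu_log, model.sigma_log, size=count))
    g, fn, _ = model.contact_probs
    out = np.where(u < g, model.s_tim, np.where(u < g + fn, 0.0, ln))
    return out


def _binom_support(n: int, p: float, tol: float = 1e-14) -> np.ndarray:
    """Indices of a Binomial(n, p) carrying all but ~tol of the mass."""
    if n == 0 or p == 0.0:
        return np.array([0])
    if p == 1.0:
        return np.array([n])
    lo = int(stats.binom.ppf(tol, n, p))
    hi = int(stats.binom.isf(tol, n, p))
    return np.arange(lo, hi + 1)


def _mixture_cdf(model: EncounterModel, x: np.ndarray, strict: bool,
                 method: str) -> np.ndarray:
    """P(encounter sum <= x) (or < x if strict) via the binomial mixture."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape)
    N, g, f = model.N, model.g, model.f
    ks = _binom_support(N, g)
    pk = stats.binom.pmf(ks, N, g)
    for k, pkv in zip(ks, pk):
        if pkv < 1e-300:
            continue
        rest = N - k
        js = _binom_support(rest, f)
        pj = stats.binom.pmf(js, rest, f)
        y = x - k * model.s_tim
        acc = np.zeros(x.shape)
        for j, pjv in zip(js, pj):
            m = rest - j
            if m == 0:
                term = (y > 0.0) if strict else (y >= 0.0)
                acc += pjv * term.astype(float)
            else:
                acc += pjv * (1.0 - lognormal_sum_sf(
                    y, m, model.mu_log, model.sigma_log, method=method))
        out += pkv * acc
    return np.clip(out, 0.0, 1.0)


def encounter_cdf(model: EncounterModel, x, strict: bool = False,
                  method: str = "auto", mc_samples: int = 10**6,
                  mc_seed: int = 0):
    """P(sum of N contact strengths <= x)  (strict=True gives P(< x)).

    ``method="mc"`` evaluates by Monte Carlo with ``mc_samples`` draws and
    fixed ``mc_seed``; this mode serves as the independent oracle for the
    numerical mixture evaluation.
    """
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    if method == "mc":
        out = _mc_encounter_cdf(model, xa, strict, mc_samples, mc_seed)
    else:
        out = _mixture_cdf(model, xa, strict, method)
    return float(out[0]) if np.ndim(x) == 0 else out


def _mc_encounter_cdf(model, x, strict, n_samples, seed):
    rng = np.random.default_rng(seed)
    counts = np.zeros(x.shape, dtype=np.int64)
    chunk = max(1, 10**7 // max(model.N, 1))
    done = 0
    g, fn, _ = model.contact_probs
    while done < n_samples:
        k = min(chunk, n_samples - done)
        u = rng.uniform(size=(k, model.N))
        ln = np.exp(rng.normal(model.mu_log, model.sigma_log, size=(k, model.N)))
        contacts = np.where(u < g, model.s_tim, np.where(u < g + fn, 0.0, ln))
        s = contacts.sum(axis=1)
        if strict:
            counts += (s[None, :] < x[:, None]).sum(axis=1)
        else:
            counts += (s[None, :] <= x[:, None]).sum(axis=1)
        done += k
    return counts / n_samples


def encounter_quantile(model: EncounterModel, q: float, method: str = "auto",
                       xtol: float = 1e-9) -> float:
    """Inverse of :func:`encounter_cdf`: x with CDF(x) = q, by bracketed root-finding."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie strictly in (0, 1), got {q}")

    def fun(x):
        return encounter_cdf(model, x, method=method) - q

    lo, hi = 1e-12, max(4.0 * model.N, 4.0 * model.N * model.s_tim)
    while fun(hi) < 0.0:
        hi *= 4.0
        if hi > 1e30:
            raise RuntimeError("failed to bracket quantile from above")
    while fun(lo) > 0.0:
        lo /= 4.0
        if lo < 1e-300:
            raise RuntimeError("failed to bracket quantile from below")
    return brentq(fun, lo, hi, xtol=xtol, rtol=1e-14)


def _strict_cdf_at(model, th_value, method):
    if math.isinf(th_value):
        return 0.0 if th_value < 0 else 1.0
    return float(encounter_cdf(model, th_value, strict=True, method=method))


def category_probs(model: EncounterModel, th: Thresholds,
                   method: str = "auto") -> CategoryProbs:
    """Per-encounter fate-zone probabilities (p0, p1, p2, p3).

    Zones are half-open [lower, upper): p0 = P(X < a), p1 = P(a <= X < b),
    p2 = P(b <= X < c), p3 = P(X >= c).
    """
    Fa = _strict_cdf_at(model, th.a, method)
    Fb = _strict_cdf_at(model, th.b, method)
    Fc = _strict_cdf_at(model, th.c, method)
    return CategoryProbs(Fa, Fb - Fa, Fc - Fb, 1.0 - Fc)


def category_probs_grid(model: EncounterModel, th: Thresholds, g_values,
                        method: str = "auto") -> np.ndarray:
    """Vectorised :func:`category_probs` over a grid of agonist fractions.

    Exploits that the mixture term for k agonist contacts,
    T_k(x) = sum_j Binom(N-k, f)(j) F_{N-k-j}(x - k s_tim),
    does not depend on g; only the binomial weights over k do.

    Returns an array of shape (len(g_values), 4).
    """
    g_values = np.asarray(g_values, dtype=float)
    N, f = model.N, model.f
    xs = np.array([th.a, th.b, th.c])
    finite = np.isfinite(xs)
    T = np.zeros((N + 1, 3))
    T[:, ~finite & (xs < 0)] = 0.0
    T[:, ~finite & (xs > 0)] = 1.0
    for k in range(N + 1):
        rest = N - k
        js = _binom_support(rest, f)
        pj = stats.binom.pmf(js, rest, f)
        for col in np.nonzero(finite)[0]:
            y = xs[col] - k * model.s_tim
            acc = 0.0
            for j, pjv in zip(js, pj):
                m = rest - j
                if m == 0:
                    acc += pjv * (1.0 if y > 0 else 0.0)  # strict: P(X < x)
                else:
                    acc += pjv * (1.0 - float(lognormal_sum_sf(
                        y, m, model.mu_log, model.sigma_log, method=method)))
            T[k, col] = acc
    ks = np.arange(N + 1)
    logC = stats.binom.logpmf(ks, N, 0.5) + N * np.log(2.0)  # log C(N, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        logg = np.where(g_values[:, None] > 0, np.log(g_values[:, None]), -np.inf)
        log1g = np.where(g_values[:, None] < 1, np.log1p(-g_values[:, None]), -np.inf)
        logw = logC[None, :] + ks[None, :] * logg + (N - ks)[None, :] * log1g
        logw = np.where((ks[None, :] == 0) & (g_values[:, None] == 0.0), 0.0, logw)
        logw = np.where((ks[None, :] == N) & (g_values[:, None] == 1.0), 0.0, logw)
    w = np.exp(logw)
    F = w @ T  # shape (n_g, 3): strict CDF at a, b, c
    p0 = F[:, 0]
    p1 = F[:, 1] - F[:, 0]
    p2 = F[:, 2] - F[:, 1]
    p3 = 1.0 - F[:, 2]
    return np.clip(np.stack([p0, p1, p2, p3], axis=1), 0.0, 1.0)


def agonist_strength_from_percentile(model: EncounterModel, pct: float) -> float:
    """Agonist contact strength expressed as a quantile of the productive
    endogenous single-contact (lognormal) distribution."""
    if not 0.0 < pct < 1.0:
        raise ValueError(f"pct must lie strictly in (0, 1), got {pct}")
    return float(np.exp(model.mu_log + model.sigma_log * stats.norm.ppf(pct)))
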