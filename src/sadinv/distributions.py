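"""Concrete species-abundance distribution families.

Three families, each available on the abundance scale n and on the process
scale r = log n (n = e^r, with n0 = 1 so that r is the accumulated total of
proportional demographic processes):

* the log series, q_n ∝ p^n / n with p = e^{-lam} (discrete, n = 1, 2, ...);
* its generalization q_n ∝ n^{-1} e^{-lam (n^beta - 1)/beta}, where the
  curvature beta measures the bending of the abundance scale relative to the
  process scale (beta = 1 recovers the log series, beta -> 0 a power law);
* the gamma-lognormal q_r ∝ e^{-lam e^r + a r - alpha r^2}, equivalently
  q_n ∝ n^{a_tilde - 1} e^{-lam n} e^{-alpha (log n - mu)^2}: a product of
  gamma and lognormal forms that matches the local-community pattern of
  neutral theory.

Continuous forms use support n in [1, inf) (r >= 0) by default: abundances of
observed species are at least one individual, and the continuous log series is
not normalizable down to n = 0.  The gamma-lognormal lives on all of r, where
its extra terms make it normalizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import exp1, gammaln
from scipy.optimize import brentq

from ._quad import gauss_legendre_panels, integrate_logf, truncated_support
from .errors import NumericalError, ValidationError

_LOG_TINY = -745.0  # below exp() underflow


# ---------------------------------------------------------------------------
# log series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogSeriesParams:
    """Log-series parameter in both conventions: p = e^{-lam}."""

    p: float
    lam: float

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValidationError(f"p must be in (0,1), got {self.p}")
        if abs(self.p * np.exp(self.lam) - 1.0) > 1e-12:
            raise ValidationError("inconsistent (p, lam): need p e^lam = 1")

    @classmethod
    def from_p(cls, p: float) -> "LogSeriesParams":
        return cls(p=p, lam=-np.log(p))

    @classmethod
    def from_lam(cls, lam: float) -> "LogSeriesParams":
        if not lam > 0:
            raise ValidationError("lam must be positive")
        return cls(p=np.exp(-lam), lam=lam)


def logseries_pmf(n, params: LogSeriesParams):
    """P(n) = p^n / (n L) with L = -log(1-p), for n = 1, 2, ..."""
    nn = np.asarray(n)
    if np.any(nn < 1) or not np.issubdtype(nn.dtype, np.integer) and np.any(
            nn != np.floor(nn)):
        raise ValidationError("abundances must be integers >= 1")
    nn = nn.astype(float)
    L = -np.log1p(-params.p)
    out = np.exp(nn * np.log(params.p) - np.log(nn) - np.log(L))
    return out if np.ndim(n) else float(out)


def logseries_mean(params: LogSeriesParams) -> float:
    """Mean abundance p / ((1-p) L)."""
    p = params.p
    return p / ((1.0 - p) * (-np.log1p(-p)))


@lru_cache(maxsize=128)
def _logseries_k_r(lam: float) -> float:
    # normalization of e^{-lam e^r} on r >= 0: substitute n = e^r ->
    # integral_1^inf e^{-lam n}/n dn = E1(lam)
    return 1.0 / float(exp1(lam))


def logseries_density_r(r, lam: float):
    """Continuous log series on the process scale: k e^{-lam e^r}, r >= 0.

    The same pattern as q_n = k n^{-1} e^{-lam n} on n >= 1 under r = log n;
    k = 1/E1(lam).  The shape is invariant to a shift r -> r + a (absorbed by
    refitting lam), but not to a stretch r -> b r.
    """
    if not lam > 0:
        raise ValidationError("lam must be positive")
    rr = np.asarray(r, dtype=float)
    k = _logseries_k_r(lam)
    with np.errstate(over="ignore"):
        out = np.where(rr >= 0.0, k * np.exp(-lam * np.exp(np.minimum(rr, 700.0))), 0.0)
    return out if np.ndim(r) else float(out)


def logseries_density_n(n, lam: float):
    """Continuous log series on the abundance scale: k n^{-1} e^{-lam n}, n >= 1."""
    if not lam > 0:
        raise ValidationError("lam must be positive")
    nn = np.asarray(n, dtype=float)
    k = _logseries_k_r(lam)
    out = np.where(nn >= 1.0, k * np.exp(-lam * nn) / np.maximum(nn, 1e-300), 0.0)
    return out if np.ndim(n) else float(out)


def logseries_T_n(n, lam: float):
    """Canonical scale of the log series in abundance terms: (1/lam) log n + n.

    Logarithmic (stretch-invariant) at small n, linear (shift- and
    stretch-invariant) at large n.
    """
    if not lam > 0:
        raise ValidationError("lam must be positive")
    nn = np.asarray(n, dtype=float)
    if np.any(nn <= 0):
        raise ValidationError("n must be positive")
    out = np.log(nn) / lam + nn
    return out if np.ndim(n) else float(out)


# ---------------------------------------------------------------------------
# generalized two-parameter family
# ---------------------------------------------------------------------------

def _genbeta_exponent(n, lam: float, beta: float):
    """-lam (n^beta - 1)/beta - log n, the log of the unnormalized density."""
    nn = np.asarray(n, dtype=float)
    logn = np.log(nn)
    if abs(beta) <= 1e-12:
        t = logn
    else:
        t = np.expm1(beta * logn) / beta
    return -lam * t - logn


@dataclass(frozen=True)
class GeneralizedSADParams:
    """(lam, beta) of q_n ∝ n^{-1} e^{-lam (n^beta - 1)/beta} on n >= 1.

    Integrability on [1, inf) requires lam > 0 and beta >= 0 (for beta < 0 the
    exponent tends to a constant and the n^{-1} tail diverges); the support
    (0, inf) is never integrable for this family, so [1, inf) is fixed.
    """

    lam: float
    beta: float

    def __post_init__(self):
        if not self.lam > 0:
            raise ValidationError("lam must be positive")
        if self.beta < 0:
            raise ValidationError(
                f"density not integrable on [1, inf) for beta = {self.beta} < 0"
            )


@lru_cache(maxsize=128)
def _genbeta_norm(lam: float, beta: float) -> float:
    # integral over n in [1, inf); in r = log n this is
    # integral_0^inf e^{-lam (e^{beta r}-1)/beta} dr
    def logf(r):
        r = np.asarray(r, dtype=float)
        if abs(beta) <= 1e-12:
            t = r
        else:
            t = np.expm1(beta * r) / beta
        return -lam * t

    lo, hi = truncated_support(lambda r: float(logf(r)), 0.0, 0.0, np.inf)
    if hi <= lo:
        hi = lo + 1.0
    return integrate_logf(logf, lo, hi, n_panels=200, n_nodes=10)


def generalized_sad_density(n, params: GeneralizedSADParams):
    """Normalized density of the generalized family on n >= 1."""
    nn = np.asarray(n, dtype=float)
    if np.any(nn <= 0):
        raise ValidationError("n must be positive")
    Z = _genbeta_norm(params.lam, params.beta)
    out = np.where(
        nn >= 1.0,
        np.exp(_genbeta_exponent(np.maximum(nn, 1e-300), params.lam, params.beta)) / Z,
        0.0,
    )
    return out if np.ndim(n) else float(out)


# ---------------------------------------------------------------------------
# gamma-lognormal
# ---------------------------------------------------------------------------

def _gln_logq_unnorm(r, lam: float, a: float, alpha: float):
    rr = np.asarray(r, dtype=float)
    with np.errstate(over="ignore"):
        er = np.exp(np.minimum(rr, 700.0))
    return -lam * er + a * rr - alpha * rr * rr


def _gln_mode(lam: float, a: float, alpha: float) -> float:
    """Root of d/dr (-lam e^r + a r - alpha r^2) = 0 (unique: decreasing)."""
    if alpha == 0.0:
        return float(np.log(a / lam))
    if lam == 0.0:
        return a / (2.0 * alpha)

    def g(r):
        return a - 2.0 * alpha * r - lam * np.exp(np.minimum(r, 700.0))

    lo, hi = -1.0, 1.0
    while g(lo) <= 0:
        lo *= 2.0
        if lo < -1e9:
            raise NumericalError("failed to bracket the gamma-lognormal mode")
    while g(hi) >= 0:
        hi *= 2.0
        if hi > 1e9:
            raise NumericalError("failed to bracket the gamma-lognormal mode")
    return float(brentq(g, lo, hi, xtol=1e-12))


def gln_log_norm(lam: float, a: float, alpha: float) -> float:
    """log of the integral of e^{-lam e^r + a r - alpha r^2} over r in R.

    Closed forms for the pure-gamma (alpha = 0) and pure-normal (lam = 0)
    branches; composite Gauss-Legendre after tail truncation otherwise.
    """
    if alpha < 0 or lam < 0:
        raise ValidationError("lam and alpha must be nonnegative")
    if alpha == 0.0:
        if lam == 0.0:
            raise ValidationError("lam = alpha = 0 is not normalizable")
        if a <= 0:
            raise ValidationError(
                "alpha = 0 requires a > 0 for a normalizable lower tail")
        # gamma: integral = Gamma(a) / lam^a
        return float(gammaln(a) - a * np.log(lam))
    if lam == 0.0:
        # normal in r: sqrt(pi/alpha) e^{a^2/(4 alpha)}
        return float(0.5 * np.log(np.pi / alpha) + a * a / (4.0 * alpha))
    mode = _gln_mode(lam, a, alpha)

    def logf(r):
        return _gln_logq_unnorm(r, lam, a, alpha)

    lo, hi = truncated_support(lambda r: float(logf(r)), mode)
    Z = integrate_logf(logf, lo, hi, n_panels=120, n_nodes=10)
    return float(np.log(Z))


@lru_cache(maxsize=256)
def _gln_cached_norm(lam: float, a: float, alpha: float) -> float:
    return gln_log_norm(lam, a, alpha)


def _gln_mean_r(lam: float, a: float, alpha: float) -> float:
    """Numerical mean of r under the normalized gamma-lognormal."""
    if lam == 0.0:
        return a / (2.0 * alpha)
    mode = _gln_mode(lam, a, alpha)

    def logf(r):
        return _gln_logq_unnorm(r, lam, a, alpha)

    lo, hi = truncated_support(lambda r: float(logf(r)), mode)
    nodes, weights = gauss_legendre_panels(lo, hi, 120, 10)
    lq = logf(nodes) - _gln_cached_norm(lam, a, alpha)
    q = np.exp(np.maximum(lq, _LOG_TINY))
    return float(np.sum(weights * nodes * q))


@dataclass(frozen=True)
class GammaLognormalParams:
    """(lam, a, alpha) of q_r = k e^{-lam e^r + a r - alpha r^2}.

    Derived views: mu (by default the mean of r, computed numerically; may be
    supplied), a_tilde = a - 2 alpha mu, and sigma2 = 1/(2 alpha) — the
    parameters of the lognormal factor in the abundance-scale form
    q_n = k n^{a_tilde - 1} e^{-lam n} e^{-alpha (log n - mu)^2}.
    """

    lam: float
    a: float
    alpha: float
    mu: float | None = None
    a_tilde: float = field(init=False)
    sigma2: float = field(init=False)
    log_k: float = field(init=False)

    def __post_init__(self):
        if self.lam < 0 or self.alpha < 0:
            raise ValidationError("lam and alpha must be nonnegative")
        if self.lam == 0.0 and self.alpha == 0.0:
            raise ValidationError(
                "not normalizable on r in R: need lam > 0 or alpha > 0")
        log_k = -_gln_cached_norm(self.lam, self.a, self.alpha)
        if self.alpha > 0:
            mu = self.mu
            if mu is None:
                mu = _gln_mean_r(self.lam, self.a, self.alpha)
            object.__setattr__(self, "mu", float(mu))
            object.__setattr__(self, "a_tilde", self.a - 2.0 * self.alpha * self.mu)
            object.__setattr__(self, "sigma2", 1.0 / (2.0 * self.alpha))
        else:
            object.__setattr__(self, "mu", 0.0 if self.mu is None else float(self.mu))
            object.__setattr__(self, "a_tilde", self.a)
            object.__setattr__(self, "sigma2", np.inf)
        object.__setattr__(self, "log_k", float(log_k))


def convert_params(a: float, alpha: float, mu: float) -> float:
    """a_tilde = a - 2 alpha mu (inverse: a = a_tilde + 2 alpha mu)."""
    if not alpha > 0:
        raise ValidationError("alpha must be positive: mu is undefined at alpha = 0")
    return a - 2.0 * alpha * mu


def gammalognormal_density_r(r, params: GammaLognormalParams):
    """Normalized process-scale density k e^{-lam e^r + a r - alpha r^2}."""
    lq = _gln_logq_unnorm(r, params.lam, params.a, params.alpha) + params.log_k
    out = np.exp(np.maximum(lq, _LOG_TINY))
    return out if np.ndim(r) else float(out)


def gammalognormal_density_n(n, params: GammaLognormalParams):
    """Abundance-scale form k_n n^{a_tilde-1} e^{-lam n} e^{-alpha (log n - mu)^2}.

    Identical to gammalognormal_density_r(log n)/n; k_n = k e^{alpha mu^2}.
    """
    nn = np.asarray(n, dtype=float)
    if np.any(nn <= 0):
        raise ValidationError("n must be positive")
    logn = np.log(nn)
    dev = logn - params.mu
    lq = (
        params.log_k + params.alpha * params.mu ** 2
        + (params.a_tilde - 1.0) * logn
        - params.lam * nn
        - params.alpha * dev * dev
    )
    out = np.exp(np.maximum(lq, _LOG_TINY))
    return out if np.ndim(n) else float(out)


def affine_scale_T_r(r, params: GammaLognormalParams):
    """Affine-invariant scale of the gamma-lognormal:

    T_r = e^r - (a_tilde/lam) r + (alpha/lam) (r - mu)^2,
    so that q_r ∝ e^{-lam T_r} (the proportionality constant absorbs
    e^{-alpha mu^2}, an affine shift of T).
    """
    if not params.lam > 0:
        raise ValidationError("T_r is defined relative to lam > 0")
    rr = np.asarray(r, dtype=float)
    dev2 = (rr - params.mu) ** 2 if params.alpha > 0 else 0.0
    out = (np.exp(rr) - (params.a_tilde / params.lam) * rr
           + (params.alpha / params.lam) * dev2)
    return out if np.ndim(r) else float(out)


# ---------------------------------------------------------------------------
# discrete gamma-lognormal (data-facing form on n = 1, 2, ...)
# ---------------------------------------------------------------------------

def gammalognormal_log_weights(n, lam: float, a: float, alpha: float):
    """log of the unnormalized abundance-scale weight at integer n."""
    nn = np.asarray(n, dtype=float)
    logn = np.log(nn)
    return (a - 1.0) * logn - lam * nn - alpha * logn * logn


def gammalognormal_pmf_table(lam: float, a: float, alpha: float,
                             n_max: int | None = None) -> np.ndarray:
    """Normalized pmf over n = 1..N for the discretized gamma-lognormal.

    N grows until the remaining tail (completed by quadrature over the
    continuous envelope) is below 1e-12 of the total, capped at 2^21.
    """
    if lam < 0 or alpha < 0 or (lam == 0.0 and alpha == 0.0):
        raise ValidationError("need lam > 0 or alpha > 0, both nonnegative")
    if lam == 0.0 and alpha == 0.0:
        raise ValidationError("not normalizable")
    N = 1024 if n_max is None else int(n_max)
    while True:
        n = np.arange(1, N + 1)
        lw = gammalognormal_log_weights(n, lam, a, alpha)
        m = lw.max()
        w = np.exp(lw - m)
        total = w.sum()
        # tail estimate from the continuous envelope beyond N
        tail = integrate_logf(
            lambda x: gammalognormal_log_weights(x, lam, a, alpha) - m,
            N + 0.5, N + 0.5 + max(10.0, 20.0 / max(lam, 1e-9)),
            n_panels=40, n_nodes=8,
        )
        if n_max is not None or tail < 1e-12 * total or N >= 2 ** 21:
            return w / (total if n_max is not None else (total + tail))
        N *= 2
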