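"""Canonical affine-invariant representation of probability patterns.

Almost any continuous probability pattern can be written q(z) = k e^{-lam T(z)}
where T is an affine-invariant measurement scale built from a shift-invariant
base scale w(z) and a curvature parameter beta:

    T(z) = (e^{beta w(z)} - 1) / beta,   with  T -> w  as  beta -> 0.

Shifting T by a is absorbed by the normalization constant k; stretching T by b
is absorbed by lam.  The information content I(z) = -log q(z) then changes at
the constant rate dI/dT = lam at every magnitude, which is what makes T the
natural scale of the pattern.  This module provides the representation itself
plus diagnostic checks of the invariances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from ._quad import grid_peak, integrate_logf, truncated_support
from .errors import ValidationError

#: branch tolerance below which canonical_T switches to its series limit
EPS_BRANCH = 1e-8


def canonical_T(w_value, beta: float, clip: bool = False):
    """Affine-invariant scale T = (e^{beta w} - 1)/beta, continuous at beta=0.

    For |beta| <= EPS_BRANCH the second-order series w + beta w^2/2 is used,
    avoiding the 0/0 branch.  Raises OverflowError when e^{beta w} overflows,
    unless clip=True, in which case T saturates to +-inf (internal use, where
    an overflowing T simply means zero density).
    """
    w = np.asarray(w_value, dtype=float)
    if abs(beta) <= EPS_BRANCH:
        out = w + 0.5 * beta * w * w
    else:
        arg = beta * w
        big = np.max(arg) if arg.size else -np.inf
        if big > 700.0 and not clip:
            raise OverflowError(
                f"e^(beta*w) overflows: beta = {beta:g}, max beta*w = {big:g}"
            )
        with np.errstate(over="ignore", invalid="ignore"):
            out = np.expm1(np.minimum(arg, 709.0)) / beta
            out = np.where(arg > 709.0, np.inf / beta, out)
    return out if np.ndim(w_value) else float(out)


def relative_curvature(T: Callable[[float], float], z: float,
                       h: float = 1e-4) -> float:
    """Diagnostic beta = T''(z)/T'(z) by central differences."""
    d1 = (T(z + h) - T(z - h)) / (2.0 * h)
    d2 = (T(z + h) - 2.0 * T(z) + T(z - h)) / (h * h)
    return d2 / d1


@dataclass(frozen=True)
class ShiftInvariantScale:
    """Base scale w(z): the purely shift-invariant part of a pattern."""

    w: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self):
        lo, hi = self.domain
        if not hi > lo:
            raise ValidationError(f"empty domain {self.domain}")


@dataclass(frozen=True)
class CanonicalDistribution:
    """q(z) = k e^{-lam T(z)} with T built from (w, beta).

    `k` is None until :func:`normalize` has been applied.  `T_fn`, when given,
    evaluates T directly; this matters when the formal w = (1/beta) log(...)
    has a negative log-argument in part of the domain even though
    e^{beta w}, and hence T and the density, stay real there.
    """

    scale: ShiftInvariantScale
    beta: float
    lam: float
    k: float | None = None
    T_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if not self.lam > 0:
            raise ValidationError(f"lam must be positive, got {self.lam}")

    def T(self, z, clip: bool = False):
        if self.T_fn is not None:
            return self.T_fn(np.asarray(z, dtype=float))
        return canonical_T(self.scale.w(np.asarray(z, dtype=float)),
                           self.beta, clip=clip)

    def log_density_unnorm(self, z):
        with np.errstate(invalid="ignore"):
            return -self.lam * np.asarray(self.T(z, clip=True), dtype=float)

    @property
    def domain(self) -> tuple[float, float]:
        return self.scale.domain


def normalize(dist: CanonicalDistribution) -> CanonicalDistribution:
    """Return `dist` with k = 1 / integral of e^{-lam T} over the domain.

    Idempotent.  Raises DivergentIntegralError naming the divergent tail when
    the integral does not exist.
    """
    lo, hi = dist.domain

    def logf(z):
        return dist.log_density_unnorm(z)

    peak = grid_peak(logf, lo, hi)
    a, b = truncated_support(lambda z: float(logf(np.asarray(z))), peak, lo, hi)
    Z = integrate_logf(logf, a, b, n_panels=200, n_nodes=10)
    return replace(dist, k=1.0 / Z)


def canonical_density(z, dist: CanonicalDistribution):
    """Density k e^{-lam T(z)}; requires a normalized distribution."""
    if dist.k is None:
        raise ValidationError(
            "distribution is not normalized: call normalize() first"
        )
    zz = np.asarray(z, dtype=float)
    lo, hi = dist.domain
    inside = (zz >= lo) & (zz <= hi)
    out = np.where(inside, dist.k * np.exp(dist.log_density_unnorm(zz)), 0.0)
    return out if np.ndim(z) else float(out)


def _support_grid(dist: CanonicalDistribution, n: int) -> np.ndarray:
    lo, hi = dist.domain

    def logf(z):
        return dist.log_density_unnorm(z)

    peak = grid_peak(logf, lo, hi)
    a, b = truncated_support(lambda z: float(logf(np.asarray(z))), peak, lo, hi)
    return np.linspace(a, b, n)


def affine_invariance_check(dist: CanonicalDistribution, shift: float,
                            stretch: float, n_grid: int = 1000) -> dict:
    """Verify that T -> shift + stretch*T leaves the density unchanged.

    The compensations are lam' = lam/stretch (conserved average value) and
    k' = k e^{lam' shift} (conserved total probability).  Returns a report
    with the maximum absolute density difference over a grid.
    """
    if dist.k is None:
        raise ValidationError("normalize the distribution first")
    if not stretch > 0:
        raise ValidationError("stretch must be positive")
    grid = _support_grid(dist, n_grid)
    q0 = canonical_density(grid, dist)
    lam2 = dist.lam / stretch
    k2 = dist.k * np.exp(lam2 * shift)
    T = np.asarray(dist.T(grid), dtype=float)
    q1 = k2 * np.exp(-lam2 * (shift + stretch * T))
    diff = float(np.max(np.abs(q1 - q0)))
    return {
        "max_abs_diff": diff,
        "lam_transformed": lam2,
        "k_transformed": k2,
        "n_grid": n_grid,
    }


def information(q_value):
    """Information content I = -log q of an observation with probability q.

    Additive over independent measurements: I(q1 q2) = I(q1) + I(q2).
    """
    q = np.asarray(q_value, dtype=float)
    if np.any(q <= 0):
        raise ValidationError("information requires q > 0")
    out = -np.log(q)
    return out if np.ndim(q_value) else float(out)


def information_increment_check(dist: CanonicalDistribution,
                                n_grid: int = 4001) -> dict:
    """Check dI/dT = lam numerically over the interior of the support.

    Differentiates I(z) = -log q(z) against T(z) by central differences,
    skipping points where T is locally flat.
    """
    if dist.k is None:
        raise ValidationError("normalize the distribution first")
    grid = _support_grid(dist, n_grid)
    T = np.asarray(dist.T(grid), dtype=float)
    I = -np.log(canonical_density(grid, dist))
    dI = I[2:] - I[:-2]
    dT = T[2:] - T[:-2]
    ok = np.abs(dT) > 1e-9 * (1.0 + np.abs(T[1:-1]))
    slope = dI[ok] / dT[ok]
    dev = float(np.max(np.abs(slope - dist.lam)))
    return {"max_abs_dev": dev, "lam": dist.lam, "n_used": int(ok.sum())}


def exponential_canonical(lam: float = 1.0) -> CanonicalDistribution:
    """Exponential pattern: w(z) = z on [0, inf), beta = 0."""
    scale = ShiftInvariantScale(w=lambda z: z, domain=(0.0, np.inf))
    return normalize(CanonicalDistribution(scale=scale, beta=0.0, lam=lam))


def logseries_canonical(lam: float = 1.0) -> CanonicalDistribution:
    """Log series on the process scale: w(r) = r on r >= 0, beta = 1."""
    scale = ShiftInvariantScale(w=lambda r: r, domain=(0.0, np.inf))
    return normalize(CanonicalDistribution(scale=scale, beta=1.0, lam=lam))


def gamma_lognormal_canonical(lam: float, a: float,
                              alpha: float) -> CanonicalDistribution:
    """Gamma-lognormal via its shift-invariant scale.

    w(r) = log(e^r - (a/lam) r + (alpha/lam) r^2) with beta = 1, so that
    k e^{-lam T} is proportional to e^{-lam e^r + a r - alpha r^2}.  The
    density uses T = e^w - 1 directly, which stays real even where the
    argument of the log in w is negative.
    """
    if not lam > 0:
        raise ValidationError("lam must be positive for this construction")

    def f(r):
        r = np.asarray(r, dtype=float)
        with np.errstate(over="ignore"):
            er = np.exp(np.minimum(r, 709.0))
        return er - (a / lam) * r + (alpha / lam) * r * r

    def w(r):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.log(f(r))

    scale = ShiftInvariantScale(w=w, domain=(-np.inf, np.inf))
    dist = CanonicalDistribution(scale=scale, beta=1.0, lam=lam,
                                 T_fn=lambda r: f(r) - 1.0)
    return normalize(dist)
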