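"""Synthetic data and stochastic oracles.

* proportional-process sums: r = sum of i.i.d. per-capita increments, with
  n = e^r — the aggregation that drives r toward the (asymptotically
  invariant) normal and n toward the lognormal;
* an individual-based Moran model of a dispersal-limited local community:
  each event kills one uniformly chosen individual and replaces it either by
  an immigrant from a fixed metacommunity pool (probability m) or by the
  offspring of a uniformly chosen survivor — preserving the zero-sum
  constraint exactly at every event;
* a Hoppe-urn metacommunity whose expected SAD is the Fisher log series with
  diversity theta;
* i.i.d. log-series abundance samples by inverse CDF.

All generators are seeded explicitly and reproducible (numpy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import LogSeriesParams
from .errors import ValidationError
from .neutral_theory import NeutralParams, expected_sad, octave_index, preston_octaves

_INCREMENTS = {
    "uniform": lambda rng, size, kw: rng.uniform(
        kw.get("low", -0.5), kw.get("high", 0.5), size),
    "normal": lambda rng, size, kw: rng.normal(
        kw.get("loc", 0.0), kw.get("scale", 1.0), size),
    "two-point": lambda rng, size, kw: np.where(
        rng.random(size) < kw.get("p", 0.5),
        kw.get("hi", 1.0), kw.get("lo", -1.0)),
    "degenerate": lambda rng, size, kw: np.full(size, kw.get("c", 1.0)),
}


@dataclass(frozen=True)
class AbundanceSample:
    """Vector of positive integer species abundances plus its provenance."""

    abundances: np.ndarray
    seed: int
    provenance: str = ""

    def __post_init__(self):
        a = np.asarray(self.abundances, dtype=int)
        if a.size and a.min() < 1:
            raise ValidationError("abundances must all be >= 1")
        object.__setattr__(self, "abundances", a)


@dataclass
class SimulationConfig:
    """Neutral local-community run: sizes in individuals, times in generations
    (one generation = J replacement events)."""

    J: int
    m: float
    theta: float | None = None
    metacommunity: np.ndarray | None = None
    J_M: int = 10_000
    burn_in: int = 200
    n_snapshots: int = 50
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in < 0 or self.thin < 1 or self.n_snapshots < 1:
            raise ValidationError("burn_in >= 0, thin >= 1, n_snapshots >= 1")
        if self.theta is None and self.metacommunity is None:
            raise ValidationError("provide theta or an explicit metacommunity")
        if not 0.0 < self.m <= 1.0:
            raise ValidationError("m must be in (0, 1]")


def simulate_proportional_process(steps: int, reps: int,
                                  increment: str = "uniform",
                                  seed: int = 0, **kwargs):
    """r = sum_{t=1}^{steps} m_t for i.i.d. increments; returns (r, n = e^r)."""
    if steps < 1 or reps < 1:
        raise ValidationError("steps and reps must be >= 1")
    if increment not in _INCREMENTS:
        raise ValidationError(
            f"unknown increment spec {increment!r}; supported: "
            f"{sorted(_INCREMENTS)}")
    rng = np.random.default_rng(seed)
    draws = _INCREMENTS[increment](rng, (reps, steps), kwargs)
    r = draws.sum(axis=1)
    return r, np.exp(r)


def metacommunity_draw(theta: float, J_M: int, seed: int = 0) -> np.ndarray:
    """Relative abundances of a Hoppe-urn metacommunity of J_M individuals.

    Individual i (1-based) founds a new species with probability
    theta/(theta + i - 1), else copies a uniformly chosen earlier individual;
    the expected species count is sum_i theta/(theta+i-1) ~ theta log(1+J_M/theta)
    (the Ewens expectation) and the expected SAD is the Fisher log series.
    """
    if not theta > 0:
        raise ValidationError("theta must be positive")
    rng = np.random.default_rng(seed)
    labels = np.empty(J_M, dtype=np.int64)
    u_new = rng.random(J_M)
    n_species = 0
    for i in range(J_M):
        if u_new[i] < theta / (theta + i):
            labels[i] = n_species
            n_species += 1
        else:
            labels[i] = labels[rng.integers(0, i)]
    counts = np.bincount(labels, minlength=n_species).astype(float)
    return counts / counts.sum()


@dataclass
class NeutralSimResult:
    snapshots: list[AbundanceSample]
    mean_sad: np.ndarray  # phi_n averaged over snapshots, n = 1..J
    metacommunity: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)


def _run_events(community: list, x_cum: np.ndarray, m: float,
                n_events: int, rng: np.random.Generator, J: int) -> None:
    """Advance the Moran dynamics by n_events zero-sum replacement events."""
    chunk = 1 << 16
    done = 0
    xc = x_cum.tolist()
    import bisect
    while done < n_events:
        k = min(chunk, n_events - done)
        kills = rng.integers(0, J, k).tolist()
        migr = (rng.random(k) < m).tolist()
        imm_u = rng.random(k).tolist()
        parents = rng.integers(0, J - 1, k).tolist() if J > 1 else [0] * k
        for i in range(k):
            kill = kills[i]
            if migr[i]:
                community[kill] = bisect.bisect_right(xc, imm_u[i])
            else:
                p = parents[i]
                if p >= kill:
                    p += 1
                community[kill] = community[p]
        done += k


def simulate_neutral_local(config: SimulationConfig) -> NeutralSimResult:
    """Zero-sum Moran dynamics of one local community.

    The immigrant pool is a fixed relative-abundance vector, drawn once from
    the Hoppe-urn metacommunity when only theta is given.  Snapshots are taken
    every `thin` generations after `burn_in` generations; every snapshot sums
    to exactly J individuals.
    """
    rng = np.random.default_rng(config.seed)
    if config.metacommunity is not None:
        x = np.asarray(config.metacommunity, dtype=float)
        x = x / x.sum()
    else:
        x = metacommunity_draw(config.theta, config.J_M,
                               seed=int(rng.integers(0, 2**31 - 1)))
    x_cum = np.cumsum(x)
    x_cum[-1] = 1.0
    J = config.J
    # initial community: i.i.d. draws from the metacommunity
    community = list(np.searchsorted(x_cum, rng.random(J), side="right"))

    _run_events(community, x_cum, config.m, config.burn_in * J, rng, J)
    snapshots = []
    mean_sad = np.zeros(J)
    for s in range(config.n_snapshots):
        if s > 0:
            _run_events(community, x_cum, config.m, config.thin * J, rng, J)
        counts = np.bincount(np.asarray(community))
        ab = counts[counts > 0]
        snapshots.append(AbundanceSample(abundances=np.sort(ab)[::-1],
                                         seed=config.seed,
                                         provenance=f"neutral snapshot {s}"))
        mean_sad += np.bincount(ab - 1, minlength=J)
    mean_sad /= config.n_snapshots
    return NeutralSimResult(snapshots=snapshots, mean_sad=mean_sad,
                            metacommunity=x, config=config)


def ensemble_neutral_octaves(J: int, m: float, theta: float, n_runs: int,
                             burn_in: int = 200, n_snapshots: int = 20,
                             thin: int = 10, J_M: int = 10_000,
                             seed: int = 0):
    """Octave SAD averaged over independent runs with fresh metacommunities.

    The quadrature formula averages over the log-series metacommunity
    ensemble, so the matching Monte-Carlo estimate must redraw the immigrant
    pool per run; the run-to-run spread then yields an honest standard error
    per octave.  Returns (mean_octaves, se_octaves).
    """
    n_oct = int(np.floor(np.log2(J))) + 1
    per_run = np.zeros((n_runs, n_oct))
    root = np.random.default_rng(seed)
    for k in range(n_runs):
        cfg = SimulationConfig(J=J, m=m, theta=theta, J_M=J_M,
                               burn_in=burn_in, n_snapshots=n_snapshots,
                               thin=thin,
                               seed=int(root.integers(0, 2**31 - 1)))
        res = simulate_neutral_local(cfg)
        j = octave_index(np.arange(1, J + 1))
        per_run[k] = np.bincount(j, weights=res.mean_sad, minlength=n_oct)
    mean = per_run.mean(axis=0)
    se = per_run.std(axis=0, ddof=1) / np.sqrt(n_runs)
    return mean, se


def expected_octaves(J: int, m: float, theta: float) -> np.ndarray:
    """Quadrature (or closed-form, m=1) expected octave SAD — the oracle's
    deterministic counterpart."""
    sad = expected_sad(NeutralParams(J=J, m=m, theta=theta))
    return preston_octaves(sad).octaves


def sample_logseries(p: float, n_species: int, seed: int = 0) -> AbundanceSample:
    """n_species i.i.d. log-series abundances by inverse CDF.

    The CDF table is built out to a cumulative tail below 1e-15 and cached for
    the duration of the call; draws falling beyond the table (probability
    < 1e-15) are clipped to its last entry.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError("p must be in (0,1)")
    params = LogSeriesParams.from_p(p)
    L = -np.log1p(-p)
    N = 64
    while True:
        n = np.arange(1, N + 1, dtype=float)
        pmf = np.exp(n * np.log(p) - np.log(n) - np.log(L))
        cdf = np.cumsum(pmf)
        if 1.0 - cdf[-1] < 1e-15 or N >= 1 << 26:
            break
        N *= 2
    rng = np.random.default_rng(seed)
    u = rng.random(n_species)
    draws = np.searchsorted(cdf, u, side="right") + 1
    draws = np.minimum(draws, N)
    return AbundanceSample(abundances=draws, seed=seed,
                           provenance=f"logseries p={p}")
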