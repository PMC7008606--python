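"""Curve fitting, maximum likelihood, maximum entropy, and the joint
abundance-energy marginalization."""

import numpy as np
import pytest

from sadinv import distributions as d
from sadinv import fitting as ft
from sadinv import neutral_theory as nt
from sadinv import simulate as sim
from sadinv.errors import InfeasibleConstraintsError, ValidationError


class TestCurveFit:
    def test_self_recovery_on_noiseless_octaves(self):
        lam, a, alpha, A = 0.002, 0.5, 0.05, 300.0
        octaves = A * ft.gln_octave_fractions(lam, a, alpha, 16)
        res = ft.fit_gamma_lognormal_curve(nt.OctaveSAD(octaves=octaves))
        assert res.params.lam == pytest.approx(lam, rel=5e-3)
        assert res.params.a == pytest.approx(a, rel=5e-3)
        assert res.params.alpha == pytest.approx(alpha, rel=5e-3)
        assert res.amplitude == pytest.approx(A, rel=5e-3)

    def test_sse_is_minimum_over_recorded_starts(self):
        octaves = 300.0 * ft.gln_octave_fractions(0.002, 0.5, 0.05, 16)
        res = ft.fit_gamma_lognormal_curve(nt.OctaveSAD(octaves=octaves))
        assert len(res.starts) == 27
        assert all(res.sse <= s["sse"] + 1e-12 for s in res.starts)

    def test_pure_gamma_curve_clamps_alpha_at_zero(self):
        octaves = 200.0 * ft.gln_octave_fractions(0.01, 0.8, 0.0, 14)
        res = ft.fit_gamma_lognormal_curve(nt.OctaveSAD(octaves=octaves))
        assert res.params.alpha == pytest.approx(0.0, abs=1e-4)
        assert res.params.lam == pytest.approx(0.01, rel=5e-3)
        assert res.params.a == pytest.approx(0.8, rel=5e-3)

    def test_requires_enough_octaves(self):
        with pytest.raises(ValidationError):
            ft.fit_gamma_lognormal_curve(
                nt.OctaveSAD(octaves=np.array([3.0, 2.0, 1.0, 0.0])))

    def test_point_sampled_fit_recovers_generator(self):
        # species-per-unit-r curve evaluated at n = 2^j for a community whose
        # expected SAD is itself (close to) a gamma-lognormal
        sad = nt.expected_sad(nt.NeutralParams(J=2_000, m=0.05, theta=20.0))
        res = ft.fit_gamma_lognormal_sad_points(sad)
        y = sad.n * sad.counts
        j = np.arange(int(np.floor(np.log2(2_000))) + 1)
        fitted = res.amplitude * ft._gln_pdf_r(
            j * np.log(2.0), res.params.lam, res.params.a, res.params.alpha)
        resid = fitted - y[2 ** j - 1]
        assert np.max(np.abs(resid)) < 0.05 * y.max()


class TestLogSeriesMLE:
    def test_recovery_from_large_sample(self):
        sample = sim.sample_logseries(0.9, 100_000, seed=3)
        fit = ft.fit_logseries_mle(sample.abundances)
        assert abs(fit.p - 0.9) < 0.01

    def test_all_singletons_is_boundary(self):
        fit = ft.fit_logseries_mle(np.ones(50, dtype=int))
        assert fit.p < 1e-6

    def test_permutation_invariant(self):
        x = np.array([1, 1, 2, 5, 9, 1, 3])
        a = ft.fit_logseries_mle(x)
        b = ft.fit_logseries_mle(x[::-1])
        assert a.p == b.p


def _discrete_gln_sample(lam, a, alpha, size, seed):
    pmf = d.gammalognormal_pmf_table(lam, a, alpha)
    cdf = np.cumsum(pmf)
    rng = np.random.default_rng(seed)
    draws = np.searchsorted(cdf, rng.random(size), side="right") + 1
    return np.minimum(draws, len(pmf))


class TestGammaLognormalMLE:
    def test_gamma_limit_matches_dedicated_gamma_fit(self):
        # data generated with alpha = 0 (discretized gamma): restricting the
        # likelihood to the alpha = 0 boundary must agree with an
        # independently coded two-parameter discrete-gamma MLE, and the full
        # three-parameter fit cannot do worse in likelihood
        from scipy.optimize import minimize

        draws = _discrete_gln_sample(0.05, 2.0, 0.0, 20_000, seed=4)
        vals, cnts = np.unique(draws, return_counts=True)
        n_total = cnts.sum()

        def oracle_nll(p):
            # brute-force discrete gamma: weights n^{a-1} e^{-lam n} summed
            # to an explicit cap, computed without the package's machinery
            lam, a = p
            if lam <= 1e-6:
                return 1e15
            n = np.arange(1, 5001, dtype=float)
            lw = (a - 1.0) * np.log(n) - lam * n
            logZ = np.log(np.sum(np.exp(lw - lw.max()))) + lw.max()
            lp = (a - 1.0) * np.log(vals) - lam * vals - logZ
            return -float(cnts @ lp) / n_total

        def restricted_nll(p):
            lam, a = p
            if lam <= 1e-6:
                return 1e15
            tab = d.gammalognormal_pmf_table(lam, a, 0.0)
            if len(tab) < vals[-1]:
                return 1e15
            lp = np.log(np.maximum(tab[vals - 1], 1e-300))
            return -float(cnts @ lp) / n_total

        oracle = minimize(oracle_nll, np.array([0.03, 1.5]),
                          method="Nelder-Mead").x
        restricted = minimize(restricted_nll, np.array([0.03, 1.5]),
                              method="Nelder-Mead").x
        assert restricted[0] == pytest.approx(oracle[0], rel=1e-3)
        assert restricted[1] == pytest.approx(oracle[1], rel=1e-3)
        # both near the generating parameters at this sample size
        assert oracle[0] == pytest.approx(0.05, rel=0.10)
        assert oracle[1] == pytest.approx(2.0, rel=0.10)

        full = ft.fit_gamma_lognormal_mle(draws)
        tab = d.gammalognormal_pmf_table(full.lam, full.a, full.alpha)
        lp = np.log(np.maximum(tab[vals - 1], 1e-300))
        full_nll = -float(cnts @ lp) / n_total
        assert full_nll <= restricted_nll(restricted) + 1e-9

    def test_duplicating_observations_leaves_estimate_unchanged(self):
        draws = _discrete_gln_sample(0.01, 0.5, 0.05, 500, seed=5)
        once = ft.fit_gamma_lognormal_mle(draws)
        twice = ft.fit_gamma_lognormal_mle(np.concatenate([draws, draws]))
        assert once.lam == pytest.approx(twice.lam, rel=1e-6)
        assert once.a == pytest.approx(twice.a, rel=1e-6)
        assert once.alpha == pytest.approx(twice.alpha, abs=1e-6)

    def test_rejects_tiny_or_invalid_samples(self):
        with pytest.raises(ValidationError):
            ft.fit_gamma_lognormal_mle(np.array([1, 2, 3]))
        with pytest.raises(ValidationError):
            ft.fit_gamma_lognormal_mle(np.array([0] * 20))


class TestMaxEnt:
    def test_mean_constraint_on_abundance_grid_gives_exponential(self):
        grid = np.linspace(0.0, 20.0, 2000)
        problem = ft.MaxEntProblem(grid=grid, features=[lambda n: n],
                                   targets=np.array([0.5]))
        res = ft.maxent_solve(problem)
        lam = res.multipliers[0]
        assert lam == pytest.approx(2.0, rel=1e-3)
        ref = lam * np.exp(-lam * grid)
        ref /= np.sum(ref * problem.measure_weights())
        density = res.masses / problem.measure_weights()
        assert np.max(np.abs(density - ref)) < 1e-6

    def test_mean_abundance_constraint_on_process_grid_gives_logseries(self):
        grid = np.linspace(0.0, 12.0, 3000)
        target = np.sum(np.exp(grid) * d.logseries_density_r(grid, 0.5)
                        * np.gradient(grid))
        problem = ft.MaxEntProblem(grid=grid, features=[np.exp(grid)],
                                   targets=np.array([target]))
        res = ft.maxent_solve(problem)
        density = res.masses / problem.measure_weights()
        ref = np.exp(-res.multipliers[0] * np.exp(grid))
        ref /= np.sum(ref * problem.measure_weights())
        assert np.max(np.abs(density - ref)) < 1e-6

    def test_three_constraints_round_trip_gamma_lognormal(self):
        params = d.GammaLognormalParams(lam=0.01, a=0.5, alpha=0.05)
        grid = np.linspace(-15.0, 12.0, 3000)
        w = np.gradient(grid)
        q = d.gammalognormal_density_r(grid, params)
        q = q / np.sum(q * w)
        mu = params.mu
        feats = [np.exp(grid), grid, (grid - mu) ** 2]
        targets = np.array([np.sum(f * q * w) for f in feats])
        problem = ft.MaxEntProblem(grid=grid, features=feats, targets=targets)
        res = ft.maxent_solve(problem)
        density = res.masses / problem.measure_weights()
        assert np.max(np.abs(density - q)) < 1e-6

    def test_scale_contrast_abundance_grid_is_not_logseries(self):
        # randomness on dn with an <n> constraint gives an exponential in n,
        # which is NOT the log-series shape n^{-1} e^{-lam n} for any lam
        # matched by mean
        grid = np.linspace(1.0, 60.0, 3000)
        w = np.gradient(grid)
        ls = d.logseries_density_n(grid, 0.2)
        ls = ls / np.sum(ls * w)
        target = np.sum(grid * ls * w)
        problem = ft.MaxEntProblem(grid=grid, features=[lambda n: n],
                                   targets=np.array([target]))
        res = ft.maxent_solve(problem)
        density = res.masses / problem.measure_weights()
        assert np.max(np.abs(density - ls)) > 0.01

    def test_unattainable_target_raises(self):
        grid = np.linspace(0.0, 1.0, 100)
        problem = ft.MaxEntProblem(grid=grid, features=[lambda z: z],
                                   targets=np.array([2.0]))
        with pytest.raises(InfeasibleConstraintsError):
            ft.maxent_solve(problem)


class TestHarteJointReduction:
    def test_marginal_is_logseries_shape(self):
        n = np.arange(1, 101, dtype=float)
        marg = ft.harte_joint_reduction(0.1, 1.0, n)
        ref = np.exp(-0.1 * n) / n
        ratio = marg / ref
        assert np.ptp(ratio) / ratio.mean() < 1e-8

    def test_independent_of_energy_multiplier(self):
        n = np.arange(1, 51, dtype=float)
        a = ft.harte_joint_reduction(0.2, 0.5, n)
        b = ft.harte_joint_reduction(0.2, 7.0, n)
        assert np.max(np.abs(a - b)) < 1e-10

    def test_matches_logseries_pmf_shape(self):
        n = np.arange(1, 81)
        marg = ft.harte_joint_reduction(0.3, 1.0, n.astype(float))
        pmf = d.logseries_pmf(n, d.LogSeriesParams.from_lam(0.3))
        ratio = marg / pmf
        assert np.ptp(ratio) / ratio.mean() < 1e-8
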