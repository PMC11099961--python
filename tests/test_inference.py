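"""Survival curves, the two MFPT estimators, bootstrap, and speedup."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy import optimize

import stimetad as st
from stimetad.errors import (
    DegenerateSampleError,
    InsufficientDataError,
)
from stimetad.inference import (
    bootstrap_mfpt,
    empirical_survival,
    fit_exponential_imetad,
    ks_exponentiality,
    speedup,
    st_fit,
)
from stimetad.synthetic import ContaminationModel, sample_contaminated_fpts


def exact_exp_quantiles(n, mean=1.0):
    """The n plotting-position quantiles of an exponential distribution."""
    i = np.arange(1, n + 1)
    return -mean * np.log(1.0 - i / (n + 1.0))


class TestEmpiricalSurvival:
    def test_plotting_positions_for_four_points(self):
        curve = empirical_survival(np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.allclose(np.exp(curve.log_survival), [4 / 5, 3 / 5, 2 / 5, 1 / 5])
        assert np.array_equal(curve.times, [1.0, 2.0, 3.0, 4.0])

    def test_duplicates_each_get_a_rank(self):
        curve = empirical_survival(np.array([2.0, 1.0, 2.0, 5.0]))
        assert curve.times.tolist() == [1.0, 2.0, 2.0, 5.0]
        assert np.all(np.diff(curve.log_survival) < 0)

    @given(
        values=hst.lists(
            hst.floats(1e-3, 1e3), min_size=2, max_size=200, unique=True
        )
    )
    def test_log_survival_strictly_decreasing(self, values):
        curve = empirical_survival(np.asarray(values))
        assert np.all(np.diff(curve.log_survival) < 0)
        assert np.all(np.isfinite(curve.log_survival))

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            empirical_survival(np.array([1.0]))


class TestExponentialFit:
    def test_recovers_mean_from_exact_quantiles(self):
        fit = fit_exponential_imetad(exact_exp_quantiles(100))
        assert fit.mfpt == pytest.approx(1.0, rel=0.02)
        assert fit.p_value > 0.99

    def test_scale_equivariance(self):
        v = exact_exp_quantiles(80, mean=2.0)
        a = fit_exponential_imetad(v).mfpt
        b = fit_exponential_imetad(10.0 * v).mfpt
        assert b == pytest.approx(10.0 * a, rel=1e-6)

    def test_mle_option_is_the_sample_mean(self):
        v = exact_exp_quantiles(50, mean=3.0)
        assert fit_exponential_imetad(v, method="mle").mfpt == pytest.approx(
            float(v.mean())
        )

    def test_inflated_tail_drags_estimate_above_short_time_scale(self):
        """A broader-than-exponential sample (contaminated tail) yields an
        MFPT estimate strictly above the true short-time scale 1/k."""
        model = ContaminationModel(true_rate_k=1.0, breakpoint_tstar=0.2)
        sample = sample_contaminated_fpts(model, 2000, seed=0)
        fit = fit_exponential_imetad(sample)
        assert fit.mfpt > 1.5  # truth is 1/k = 1


class TestShortTimeFit:
    def test_exact_exponential_selects_full_range(self):
        """On perfectly exponential plotting positions the log-survival is an
        exact line: rate 1 recovered and the tie-break takes the largest t*."""
        v = exact_exp_quantiles(100)
        fit = st_fit(v)
        assert fit.rate_k == pytest.approx(1.0, rel=0.05)
        assert fit.t_star == v.max()
        assert fit.n_points == 100
        assert fit.mfpt == pytest.approx(1.0 / fit.rate_k)

    def test_two_slope_curve_recovers_breakpoint_and_rate(self):
        """Points placed exactly on a two-slope log-survival (slope -1 below
        the breakpoint, -0.1 above) make the fit select the breakpoint as t*
        and return the short-time rate."""
        n = 1000
        y = np.log(1.0 - np.arange(1, n + 1) / (n + 1.0))
        i0 = 950
        t_break = -y[i0 - 1]
        t = np.where(-y <= t_break, -y, t_break + (-y - t_break) / 0.1)
        fit = st_fit(t)
        assert fit.t_star == t_break
        assert fit.rate_k == pytest.approx(1.0, rel=1e-12)
        assert fit.n_points == i0

    def test_scale_equivariance(self):
        v = exact_exp_quantiles(60, mean=5.0)
        a = st_fit(v)
        b = st_fit(4.0 * v)
        assert b.t_star == pytest.approx(4.0 * a.t_star, rel=1e-12)
        assert b.rate_k == pytest.approx(a.rate_k / 4.0, rel=1e-12)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            st_fit(np.full(10, 3.0))

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            st_fit(np.array([1.0, 2.0, 3.0]), min_points=5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_slope_matches_brute_force_minimizer(self, seed):
        """The closed-form through-origin slope at the selected cutoff equals
        a brute-force 1-D minimization of sum (y_i + k t_i)^2."""
        rng = np.random.default_rng(seed)
        v = rng.exponential(10.0, size=200)
        fit = st_fit(v)
        curve = empirical_survival(v)
        mask = curve.times <= fit.t_star
        tt, yy = curve.times[mask], curve.log_survival[mask]
        res = optimize.minimize_scalar(
            lambda k: float(np.sum((yy + k * tt) ** 2)),
            bounds=(1e-6, 10.0),
            method="bounded",
            options={"xatol": 1e-14},
        )
        assert fit.rate_k == pytest.approx(res.x, rel=1e-6)
        # and against the exact normal-equation solution, much tighter:
        assert fit.rate_k == pytest.approx(
            -float(tt @ yy) / float(tt @ tt), rel=1e-10
        )


class TestKsExponentiality:
    def test_exact_quantiles_pass(self):
        assert ks_exponentiality(exact_exp_quantiles(100)) > 0.99

    def test_gross_mixture_fails(self):
        """Half Exp(mean 1), half Exp(mean 50): far from any single
        exponential."""
        a = exact_exp_quantiles(100, mean=1.0)
        b = exact_exp_quantiles(100, mean=50.0)
        assert ks_exponentiality(np.concatenate([a, b])) < 0.05

    @given(seed=hst.integers(0, 50))
    def test_p_value_in_unit_interval(self, seed):
        v = np.random.default_rng(seed).exponential(1.0, size=30)
        assert 0.0 <= ks_exponentiality(v) <= 1.0


class TestBootstrap:
    def test_constant_estimator_collapses_summary(self):
        bs = bootstrap_mfpt(
            np.ones(50) + np.arange(50) * 0.01,
            estimator=lambda v: 7.0,
            n_batches=100,
            batch_size=20,
            seed=0,
        )
        assert bs.median == bs.q1 == bs.q3 == 7.0

    def test_same_seed_reproduces_summary(self):
        v = exact_exp_quantiles(300, mean=2.0)
        a = bootstrap_mfpt(v, "short_time", 50, 100, seed=9)
        b = bootstrap_mfpt(v, "short_time", 50, 100, seed=9)
        assert np.array_equal(a.estimates, b.estimates)
        assert a.median == b.median

    def test_iqr_matches_clt_closed_form(self):
        """Batch means of 200 exponential(1) draws have IQR ~ 1.349/sqrt(200)
        (CLT); the maximum-likelihood exponential fit is exactly the batch
        mean, so its bootstrap IQR must match the closed form."""
        rng = np.random.default_rng(4)
        v = rng.exponential(1.0, size=1000)
        bs = bootstrap_mfpt(
            v,
            estimator=lambda b: fit_exponential_imetad(b, method="mle").mfpt,
            n_batches=1000,
            batch_size=200,
            seed=5,
        )
        assert bs.iqr == pytest.approx(1.349 / np.sqrt(200), rel=0.15)

    def test_whiskers_are_data_points_within_fences(self):
        v = exact_exp_quantiles(500, mean=1.0)
        bs = bootstrap_mfpt(v, "standard", 200, 100, seed=2)
        assert bs.whisker_lo >= bs.q1 - 1.5 * bs.iqr
        assert bs.whisker_hi <= bs.q3 + 1.5 * bs.iqr
        assert bs.whisker_lo in bs.estimates
        assert bs.whisker_hi in bs.estimates


class TestSpeedup:
    def test_equal_means_give_unity(self):
        assert speedup(5.0, [5.0, 5.0]) == pytest.approx(1.0)

    def test_hundredfold(self):
        assert speedup(110.0, [1.1]) == pytest.approx(100.0)

    def test_inverse_scaling_with_biased_mean(self):
        s1 = speedup(10.0, [1.0, 2.0])
        s2 = speedup(10.0, [2.0, 4.0])
        assert s1 == pytest.approx(2.0 * s2)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            speedup(1.0, [])


class TestEstimatorConsistency:
    def test_estimators_agree_on_clean_exponential_data(self):
        """When the data really are exponential the short-time fit and the
        whole-sample fit give the same MFPT within sampling error."""
        rng = np.random.default_rng(11)
        v = rng.exponential(110.0, size=1000)
        a = fit_exponential_imetad(v).mfpt
        b = st_fit(v).mfpt
        assert abs(a - b) / a < 0.15

    def test_short_time_beats_standard_on_contaminated_tails(self):
        """On breakpoint-inflated samples the short-time estimator's error is
        smaller than the standard estimator's in nearly every replicate."""
        model = ContaminationModel()
        truth = model.true_mfpt
        wins = 0
        for seed in range(100):
            s = sample_contaminated_fpts(model, 1000, seed=seed)
            err_std = abs(fit_exponential_imetad(s).mfpt - truth)
            err_st = abs(st_fit(s).mfpt - truth)
            wins += err_st < err_std
        assert wins >= 95
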