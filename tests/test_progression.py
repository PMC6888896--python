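import numpy as np
import pytest
from scipy import stats

from vflatent import (LatentSeries, bootstrap_ci, global_rate_test_linear,
                      global_rate_test_nonlinear, hit_rate, md_slope_test,
                      null_cohort, PatientSeries, VisualField)
from vflatent.progression import _stacked_design


def _series(times, z):
    return LatentSeries(np.asarray(times, float), np.asarray(z, float))


class TestLinearGlobalRate:
    def test_single_feature_equals_ordinary_ols(self):
        """With L=1 the stacked zero-sum fit is plain simple regression."""
        t = np.array([0.0, 0.8, 1.7, 2.9, 4.1])
        z = np.array([0.2, -0.1, -0.6, -0.7, -1.4])[:, None]
        res = global_rate_test_linear(_series(t, z))
        ols = stats.linregress(t, z[:, 0])
        assert res.global_rate == pytest.approx(ols.slope, abs=1e-9)
        assert res.p_value == pytest.approx(ols.pvalue, abs=1e-9)

    def test_shared_grid_beta_is_mean_of_per_feature_slopes(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 5, 7))
        z = rng.normal(size=(7, 4)) + np.outer(t, rng.normal(size=4))
        res = global_rate_test_linear(_series(t, z))
        slopes = [stats.linregress(t, z[:, l]).slope for l in range(4)]
        assert res.global_rate == pytest.approx(np.mean(slopes), abs=1e-9)

    def test_matches_statsmodels_stacked_fit(self):
        """Independent route: same design matrix fitted by statsmodels OLS."""
        import statsmodels.api as sm
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, 5, 8))
        z = rng.normal(size=(8, 3)) - 0.3 * np.outer(t, np.ones(3))
        res = global_rate_test_linear(_series(t, z))
        X = _stacked_design(t, 3, quadratic=False)
        fit = sm.OLS(z.T.ravel(), X).fit()
        assert res.global_rate == pytest.approx(fit.params[3], abs=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues[3], abs=1e-10)

    def test_perfect_common_trend_recovers_rate_without_flagging(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        z = 1.0 + 2.0 * t[:, None] * np.ones((1, 3))
        with pytest.warns(UserWarning):
            res = global_rate_test_linear(_series(t, z))
        assert res.global_rate == pytest.approx(2.0, abs=1e-9)
        assert not res.flagged  # degenerate (zero-residual) fit yields no test

    def test_too_few_visits_is_no_test(self):
        with pytest.warns(UserWarning):
            res = global_rate_test_linear(_series([0.0, 1.0], [[0.0], [1.0]]))
        assert np.isnan(res.p_value) and not res.flagged


class TestNonlinearGlobalRate:
    def test_exact_quadratic_recovered(self):
        t = np.linspace(0, 3, 6)
        z = (1.0 + 2.0 * t + 3.0 * t ** 2)[:, None] * np.ones((1, 2))
        X = _stacked_design(t, 2, quadratic=True)
        y = z.T.ravel()
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert coef[2] == pytest.approx(2.0, abs=1e-8)   # global linear
        assert coef[3] == pytest.approx(3.0, abs=1e-8)   # global quadratic

    def test_f_statistic_equals_explicit_nested_rss(self):
        rng = np.random.default_rng(10)
        t = np.sort(rng.uniform(0, 5, 9))
        z = rng.normal(size=(9, 3)) - 0.2 * np.outer(t, np.ones(3))
        res = global_rate_test_nonlinear(_series(t, z))
        # brute-force nested fits
        X1 = _stacked_design(t, 3, quadratic=True)
        y = z.T.ravel()
        b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss1 = np.sum((y - X1 @ b1) ** 2)
        keep = [i for i in range(X1.shape[1]) if i not in (3, 4)]
        b0, *_ = np.linalg.lstsq(X1[:, keep], y, rcond=None)
        rss0 = np.sum((y - X1[:, keep] @ b0) ** 2)
        df1 = 27 - X1.shape[1]
        F = ((rss0 - rss1) / 2) / (rss1 / df1)
        assert res.p_value == pytest.approx(stats.f.sf(F, 2, df1), abs=1e-10)

    def test_needs_four_visits(self):
        with pytest.warns(UserWarning):
            res = global_rate_test_nonlinear(
                _series([0, 1, 2], np.zeros((3, 2))))
        assert np.isnan(res.p_value)


class TestNullCalibration:
    """Type-I error of both tests on iid standard-normal latent series."""

    @pytest.mark.parametrize("test_fn", [global_rate_test_linear,
                                         global_rate_test_nonlinear])
    def test_flag_rate_near_alpha(self, test_fn):
        rng = np.random.default_rng(15)
        times = np.linspace(0, 5, 8)
        n = 600
        flags = sum(test_fn(_series(times, rng.standard_normal((8, 8)))).flagged
                    for _ in range(n))
        tol = 3 * np.sqrt(0.05 * 0.95 / n)
        assert abs(flags / n - 0.05) < tol

    def test_p_values_uniform_under_null(self):
        rng = np.random.default_rng(16)
        times = np.linspace(0, 5, 8)
        ps = [global_rate_test_linear(_series(times, rng.standard_normal((8, 4)))).p_value
              for _ in range(5000)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestMDSlope:
    def test_strong_decline_is_flagged(self):
        t = np.linspace(0, 5, 10)
        md = -1.0 * t + 0.01 * np.random.default_rng(0).normal(size=10)
        res = md_slope_test(md, t)
        assert res.flagged and res.global_rate < 0
        # oracle: one-sided p from the two-sided linregress p
        lr = stats.linregress(t, md)
        assert res.p_value == pytest.approx(lr.pvalue / 2, abs=1e-12)

    def test_improving_series_never_flagged(self):
        t = np.linspace(0, 5, 10)
        md = 1.0 * t
        res = md_slope_test(md + np.random.default_rng(1).normal(size=10) * 0.01, t)
        assert not res.flagged and res.p_value > 0.5

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(17)
        t = np.linspace(0, 5, 8)
        n = 800
        flags = sum(md_slope_test(rng.normal(size=8), t).flagged for _ in range(n))
        tol = 3 * np.sqrt(0.05 * 0.95 / n)
        assert abs(flags / n - 0.05) < tol


class TestHitRate:
    @staticmethod
    def _cohort_with_trend(rate, n=12, visits=6):
        out = []
        for i in range(n):
            t = np.linspace(0, 5, visits)
            fields = [VisualField(np.full(52, rate * tt)) for tt in t]
            out.append(PatientSeries(f"g{i}", "glaucoma", t, fields))
        return out

    def test_strong_deterministic_trend_gives_hit_rate_one(self):
        cohort = self._cohort_with_trend(-2.0)
        res = hit_rate(cohort, None, method="md", cutoff_years=np.inf)
        assert res.rate == 1.0 and res.n_evaluated == 12

    def test_cutoff_uses_visits_on_or_before(self):
        t = np.array([0.0, 1.0, 3.0, 5.0])
        fields = [VisualField(np.zeros(52)) for _ in t]
        s = PatientSeries("p", "glaucoma", t, fields)
        trunc = s.truncated(4.0)
        np.testing.assert_array_equal(trunc.times, [0.0, 1.0, 3.0])
        assert s.truncated(5.0).n_visits == 4  # boundary included

    def test_truncation_is_monotone(self):
        t = np.array([0.0, 0.5, 1.5, 2.5, 4.5])
        s = PatientSeries("p", "normal", t,
                          [VisualField(np.zeros(52)) for _ in t])
        sets = [set(s.truncated(c).times) for c in (1.0, 2.0, 5.0)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_patients_with_too_few_visits_are_excluded(self):
        cohort = self._cohort_with_trend(-2.0, n=3, visits=6)
        short = PatientSeries("s", "glaucoma", [0.0, 0.4],
                              [VisualField(np.zeros(52))] * 2)
        res = hit_rate(cohort + [short], None, method="md")
        assert res.n_evaluated == 3 and res.n_excluded == 1

    def test_null_cohort_specificity_near_95(self):
        cohort = null_cohort(400, seed=18)
        res = hit_rate(cohort, None, method="md", cutoff_years=np.inf,
                       statuses=("normal", "suspect", "glaucoma"))
        tol = 3 * np.sqrt(0.05 * 0.95 / res.n_evaluated)
        assert abs(res.rate - 0.05) < tol

    def test_encode_fn_injection_runs_latent_tests(self):
        """A synthetic encoder with a strong latent trend flags everyone."""
        cohort = self._cohort_with_trend(-1.0, n=5)
        rng = np.random.default_rng(0)
        encode_fn = lambda s: LatentSeries(
            s.times, np.outer(s.times, np.ones(4)) + 1e-3 * rng.normal(size=(len(s.times), 4)))
        res = hit_rate(cohort, None, method="vae_linear", encode_fn=encode_fn)
        assert res.rate == 1.0


class TestBootstrap:
    def test_constant_flags_give_zero_width_interval(self):
        lo, hi = bootstrap_ci(np.ones(30, dtype=bool), seed=0)
        assert lo == hi == 1.0

    def test_same_seed_reproduces_interval(self):
        flags = np.random.default_rng(3).random(100) < 0.3
        assert bootstrap_ci(flags, seed=5) == bootstrap_ci(flags, seed=5)

    def test_coverage_of_true_proportion(self):
        rng = np.random.default_rng(21)
        covered = 0
        reps = 150
        for _ in range(reps):
            flags = rng.random(200) < 0.3
            lo, hi = bootstrap_ci(flags, n_boot=500, seed=int(rng.integers(2**31)))
            covered += lo <= 0.3 <= hi
        assert 0.90 <= covered / reps <= 0.99
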