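"""Downsampling, parameter optimisation, and irreversibility manipulation."""

import numpy as np
import pytest
from scipy import stats

import irrev
from irrev.core import SeriesError
from irrev.toolkit import _chi2_logsf, _combine_pvalues, downsample, manipulate, optimise_parameters


class TestDownsample:
    def test_average_hand_means(self):
        assert downsample([1.0, 3.0, 2.0, 4.0], "average", 2).tolist() == [2.0, 3.0]

    def test_skip_keeps_block_starts(self):
        assert downsample([1.0, 3.0, 2.0, 4.0], "skip", 2).tolist() == [1.0, 2.0]

    @pytest.mark.parametrize("method", ["skip", "average", "decimate"])
    def test_tau_one_is_identity(self, method, rng):
        x = rng.normal(size=64)
        assert np.array_equal(downsample(x, method, 1), x)

    def test_average_drops_incomplete_block(self):
        assert downsample([1.0, 3.0, 2.0, 4.0, 9.0], "average", 2).tolist() == [2.0, 3.0]

    def test_decimate_removes_high_frequencies(self, rng):
        t = np.arange(4096)
        slow = np.sin(2 * np.pi * t / 256)
        fast = np.sin(2 * np.pi * t * 0.47)  # above the post-decimation Nyquist
        y = downsample(slow + fast, "decimate", 4)
        resid = y - np.sin(2 * np.pi * np.arange(y.size) * 4 / 256)
        assert np.abs(resid[50:-50]).max() < 0.05

    def test_tau_bounds(self):
        with pytest.raises(SeriesError):
            downsample([1.0, 2.0], "average", 3)
        with pytest.raises(SeriesError):
            downsample([1.0, 2.0], "average", 0)

    def test_unknown_method(self):
        with pytest.raises(SeriesError):
            downsample([1.0, 2.0], "mean", 1)


class TestCombination:
    def test_fisher_closed_form(self):
        # k identical p0: chi-square tail of -2k ln p0 at 2k dof
        for p0, k in [(0.2, 5), (0.01, 3)]:
            expected = stats.chi2.sf(-2 * k * np.log(p0), 2 * k)
            assert np.exp(_combine_pvalues([p0] * k, "fisher")) == pytest.approx(expected)

    def test_logsf_matches_scipy_in_normal_range(self):
        for x, df in [(3.0, 2), (40.0, 8), (250.0, 200)]:
            assert _chi2_logsf(x, df) == pytest.approx(float(stats.chi2.logsf(x, df)))

    def test_logsf_finite_beyond_underflow(self):
        v = _chi2_logsf(1e5, 200)
        assert np.isfinite(v) and v < -2000


@pytest.fixture(scope="module")
def ensemble():
    return [irrev.generators.logistic(2000, seed=i) for i in range(8)]


@pytest.fixture(scope="module")
def uniform_2k():
    return np.random.default_rng(0).uniform(size=2000)


class TestOptimisation:
    def test_single_combination_grid(self, ensemble):
        res = optimise_parameters("COP", ensemble, grid={"pSize": [4]}, seed=0)
        assert res.best_params == {"pSize": 4}
        assert res.best_pvalue == pytest.approx(np.exp(res.best_log_pvalue))

    def test_best_is_minimum_of_report(self, ensemble):
        res = optimise_parameters("COP", ensemble, grid={"pSize": [3, 5]}, seed=0)
        assert res.best_log_pvalue == min(r["log_pvalue"] for r in res.grid_report)
        assert res.best_params["pSize"] in (3, 5)

    def test_superset_grid_never_worse(self, ensemble):
        small = optimise_parameters("COP", ensemble, grid={"pSize": [4]}, seed=1)
        large = optimise_parameters("COP", ensemble, grid={"pSize": [4, 3]}, seed=1)
        assert large.best_log_pvalue <= small.best_log_pvalue

    def test_failing_combination_recorded_and_skipped(self, ensemble):
        res = optimise_parameters(
            "MSTrends", ensemble, grid={"window": [4, 100_000]}
        )
        errors = [r for r in res.grid_report if "error" in r]
        assert len(errors) == 1
        assert res.best_params == {"window": 4}

    def test_empty_inputs_rejected(self, ensemble):
        with pytest.raises(ValueError):
            optimise_parameters("COP", [], grid={"pSize": [3]})
        with pytest.raises(ValueError):
            optimise_parameters("Costa Index", ensemble)  # no grid declared

    def test_median_combination(self, ensemble):
        res = optimise_parameters("COP", ensemble, grid={"pSize": [3]}, combine="median", seed=2)
        assert 0.0 <= res.best_pvalue <= 1.0


class TestManipulation:
    @pytest.fixture()
    def x(self, uniform_2k):
        return uniform_2k

    def test_single_iteration_deterministic(self, x):
        a = manipulate(x, numIterations=1, seed=5)
        b = manipulate(x, numIterations=1, seed=5)
        assert np.array_equal(a.series, b.series)
        assert a.pvalue == b.pvalue and a.correlation == b.correlation

    def test_series_support_and_correlation_bounds(self, x):
        res = manipulate(x, numIterations=20, pSize=4, seed=1)
        assert res.series.size == x.size - 4 + 1
        assert -1.0 <= res.correlation <= 1.0
        assert res.pattern.size == 4

    def test_increase_success_respects_threshold(self, x):
        res = manipulate(x, increase=True, numIterations=150, pSize=4, pvThreshold=0.05, seed=2)
        assert res.success
        assert res.pvalue <= 0.05

    def test_impossible_threshold_reports_failure(self, x):
        res = manipulate(x, increase=True, numIterations=5, pvThreshold=0.0, seed=3)
        assert not res.success
        assert res.pvalue > 0.0

    def test_decrease_mode(self, logistic_10k):
        res = manipulate(
            logistic_10k[:2000], increase=False, numIterations=50, pvThreshold=0.01, seed=4
        )
        assert res.success
        assert res.pvalue >= 0.01
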