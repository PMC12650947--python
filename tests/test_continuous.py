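"""Unit and property tests for the sixteen real-valued tests."""

import numpy as np
import pytest
from scipy import stats

import irrev
from irrev.core import SeriesError, reverse
from irrev.tests_continuous import (
    _costa_stat,
    _pomeau_stat,
    _reversal_partner_map,
    _run_lengths,
    _sample_skew,
    bicovariance_difference,
    correlation_integral,
    ordinal_pattern_counts,
    ternary_symbols,
    window_slopes,
)
from irrev import hvg


class TestWorkedExamples:
    """Hand-computed values frozen from the definitions."""

    def test_casali_skew_of_geometric_diffs(self):
        # diffs of [1,2,4,8] are [1,2,4]; g1 = (20/27)/(14/9)^1.5
        expected = (20 / 27) / (14 / 9) ** 1.5
        assert _sample_skew(np.diff([1.0, 2.0, 4.0, 8.0])) == pytest.approx(expected)
        assert expected == pytest.approx(0.3818017741, abs=1e-9)

    def test_costa_count_asymmetry(self):
        assert _costa_stat(np.array([1.0, 2.0, 3.0, 2.0])) == pytest.approx(1 / 3)

    def test_costa_monotone_extreme(self):
        assert _costa_stat(np.arange(10.0)) == 1.0
        assert _costa_stat(np.arange(10.0)[::-1]) == -1.0

    def test_pomeau_polynomial(self):
        assert _pomeau_stat(np.array([1.0, 2.0, 1.0, 2.0])) == pytest.approx(2 / 3)

    def test_ramsey_bicovariances(self):
        # B21 = 10/3, B12 = 8/3 for [1,2,1,2] at lag 1
        assert bicovariance_difference([1.0, 2.0, 1.0, 2.0], k=1) == pytest.approx(2 / 3)

    def test_correlation_integral_hand_count(self):
        # pairs of [0,1,2] within radius 1.5: (0,1) and (1,2), not (0,2)
        assert correlation_integral([0.0, 1.0, 2.0], epsilon=1.5, m=1) == pytest.approx(2 / 3)

    def test_dfk_median_split(self):
        from irrev.tests_continuous import _symbolize

        sym = _symbolize(np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0]), 2, "quantile")
        assert sym.tolist() == [0, 1, 0, 1, 0, 1]

    def test_ternary_thresholding(self):
        x = np.concatenate([[0.0], np.cumsum([1.0, 0.2, -0.9])])
        assert ternary_symbols(x, threshold=0.5).tolist() == [1, 0, -1]

    def test_run_length_decomposition(self):
        up, down = _run_lengths(np.array([1.0, 2.0, 3.0, 2.0, 1.0, 2.0]))
        assert sorted(up.tolist()) == [1, 2]
        assert down.tolist() == [2]

    def test_window_slope_exact_line(self):
        assert window_slopes([1.0, 2.0, 3.0], window=3)[0] == pytest.approx(1.0)

    def test_ordinal_counts_stride1(self):
        counts = ordinal_pattern_counts([1.0, 3.0, 2.0, 4.0], pSize=2, stride=1)
        # code 1 = ascending pair, code 2 = descending pair
        assert sorted(counts.values()) == [1, 2]

    def test_hvg_hand_construction(self):
        edges = hvg.horizontal_visibility_edges([3.0, 1.0, 2.0])
        assert set(edges) == {(0, 1), (1, 2), (0, 2)}
        indeg, outdeg = hvg.degrees(3, edges)
        assert outdeg.tolist() == [2, 1, 0]
        assert indeg.tolist() == [0, 1, 2]
        ret, adv = hvg.local_clustering_coefficients(3, edges)
        assert adv[0] == pytest.approx(1.0)  # future neighbours {1,2} are linked

    def test_hvg_monotone_is_path(self):
        edges = hvg.horizontal_visibility_edges([1.0, 2.0, 3.0, 4.0, 5.0])
        _, outdeg = hvg.degrees(5, edges)
        assert outdeg.tolist() == [1, 1, 1, 1, 0]


class TestReversalAntisymmetry:
    """Signed statistics flip sign under time reversal."""

    @pytest.fixture()
    def x(self, logistic_10k):
        return logistic_10k[:1500]

    def test_casali(self, x):
        d = np.diff(x)
        assert _sample_skew(-d[::-1]) == pytest.approx(-_sample_skew(d))

    def test_costa(self, x):
        assert _costa_stat(reverse(x)) == pytest.approx(-_costa_stat(x))

    def test_pomeau(self, x):
        assert _pomeau_stat(reverse(x)) == pytest.approx(-_pomeau_stat(x))

    def test_ramsey(self, x):
        assert bicovariance_difference(reverse(x)) == pytest.approx(-bicovariance_difference(x))

    def test_skewness_statistic(self, x):
        assert _sample_skew(np.diff(reverse(x))) == pytest.approx(-_sample_skew(np.diff(x)))

    def test_ternary_symbols_reverse_to_negated(self, x):
        s = ternary_symbols(x)
        s_rev = ternary_symbols(reverse(x))
        assert np.array_equal(s_rev, -s[::-1])

    def test_mstrends_slopes_negate(self, rng):
        x = rng.normal(size=20)
        fwd = window_slopes(x, window=4)
        rev = window_slopes(reverse(x), window=4)
        assert np.allclose(rev, -fwd[::-1])

    def test_zumbach_statistic_negates(self):
        x = irrev.generators.srgbm(500, seed=4)
        a = irrev.zumbach(x).statistic
        b = irrev.zumbach(reverse(x)).statistic
        assert b == pytest.approx(-a, rel=1e-9)

    def test_run_lengths_swap(self, x):
        up, down = _run_lengths(np.asarray(x))
        up_r, down_r = _run_lengths(reverse(x))
        assert sorted(up.tolist()) == sorted(down_r.tolist())
        assert sorted(down.tolist()) == sorted(up_r.tolist())


class TestPatternCombinatorics:
    @pytest.mark.parametrize("pSize", [2, 3, 4])
    def test_reversal_partner_is_involution(self, pSize):
        partner = _reversal_partner_map(pSize)
        import math

        assert len(partner) == math.factorial(pSize)
        for code, mate in partner.items():
            assert partner[mate] == code


class TestDegenerateInputs:
    def test_monotone_series_yields_no_hvg_asymmetry(self):
        res = irrev.local_clustering(np.arange(100.0))
        assert res.pvalue == 1.0 and res.statistic == 0.0

    def test_alternating_series_has_symmetric_runs(self):
        x = np.tile([0.0, 1.0], 50)
        res = irrev.tplength(x)
        assert res.pvalue == 1.0

    def test_bds_epsilon_too_small(self, gaussian_1k):
        with pytest.raises(SeriesError):
            irrev.bds(gaussian_1k, epsilon=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(SeriesError):
            irrev.bds(np.random.default_rng(0).normal(size=100))
        with pytest.raises(SeriesError):
            irrev.cop([1.0, 2.0, 3.0])

    def test_constant_series_rejected(self):
        with pytest.raises(SeriesError):
            irrev.casali(np.ones(100))

    def test_ternary_all_maintain_rejected(self):
        x = np.concatenate([[0.0], np.cumsum(np.full(99, 1e-12))])
        with pytest.raises(SeriesError):
            irrev.ternary(x, threshold=1.0)


class TestSymmetricInputs:
    def test_casali_statistic_near_zero_for_sine(self):
        # 2001 samples -> 2000 increments spanning whole periods exactly
        t = np.linspace(0, 20 * np.pi, 2001)
        assert _sample_skew(np.diff(np.sin(t))) == pytest.approx(0.0, abs=1e-10)

    def test_dfk_reversal_symmetric_histogram(self):
        # every counted word is a palindrome: histogram reversal-symmetric
        x = np.tile([0.0, 1.0, 0.0], 40)
        res = irrev.dfk(x, nSymbols=2, wordLength=3)
        assert res.statistic == 0.0 and res.pvalue == 1.0


class TestShuffleNullity:
    """Shuffling destroys irreversibility: p-values become unremarkable."""

    @pytest.mark.parametrize("name", ["COP", "Permutation Patterns", "Ternary Coding"])
    def test_shuffled_logistic_not_flagged(self, name, logistic_10k, rng):
        import inspect

        desc = irrev.get_test(name)
        hits = 0
        for _ in range(20):
            y = rng.permutation(logistic_10k[:1000])
            kw = {}
            if "seed" in inspect.signature(desc.function).parameters:
                kw["seed"] = int(rng.integers(2**31))
            if desc(y, **kw).pvalue < 0.01:
                hits += 1
        assert hits <= 2
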