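"""The sixteen irreversibility tests for real-valued series.

Every public function takes the series as first argument plus keyword
parameters and returns a :class:`~irrev.core.TestResult`.  Thirteen tests
carry a *native* p-value (a distributional null of their own); Casali,
Costa and Pomeau are bare measures and obtain their p-value from shuffled
surrogates (see :mod:`irrev.significance`).

Calibration note
----------------
Several tests are defined by comparing a sample of window-derived
quantities from the series against the corresponding sample from its
time-reversed copy.  Overlapping windows make those samples autocorrelated
and the two samples mutually dependent, which would distort a two-sample
p-value computed naively.  Where this matters (COP, MSTrends) the p-value
is therefore computed from interleaved, non-overlapping window blocks —
independent under the iid null — and count-based tests (DFK, Permutation
Patterns) count non-overlapping words so their chi-square null holds.
Moment-based z statistics (Ramsey, Ternary, Zumbach) use autocorrelation-
robust (HAC) standard errors instead.  Full overlapping-window samples
remain available through the module-level helper functions.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import stats

from . import hvg
from .cop import distance_profile, normalized_windows, random_pattern
from .core import SeriesError, TestDescriptor, TestResult, as_real_series, register, reverse
from .significance import SurrogatePlan, surrogate_test

__all__ = [
    "bds",
    "casali",
    "cop",
    "costa",
    "dfk",
    "diks",
    "local_clustering",
    "mstrends",
    "permutation_patterns",
    "pomeau",
    "ramsey",
    "skewness_index",
    "ternary",
    "tplength",
    "visibility_graph",
    "zumbach",
    "correlation_integral",
    "ordinal_pattern_counts",
    "window_slopes",
    "bicovariance_difference",
    "ternary_symbols",
]


def _plan(method: str, surrogates: int | None, seed) -> SurrogatePlan:
    return SurrogatePlan(method=method, S=surrogates, seed=seed)


def _sample_skew(d: np.ndarray) -> float:
    # moment-ratio skewness g1 = m3 / m2^(3/2), no bias correction
    return float(stats.skew(d, bias=True))


# ---------------------------------------------------------------------------
# BDS


def correlation_integral(x, epsilon: float, m: int = 1) -> float:
    """Fraction of distinct delay-vector pairs within max-norm ``epsilon``.

    Vectors are ``(x_t, ..., x_{t+m-1})`` at unit lag; the pair indicator
    uses a strict inequality.
    """
    arr = as_real_series(x, min_length=m + 1)
    A = _pair_indicator(arr, epsilon)
    B = _embed_indicator(A, m)
    n = B.shape[0]
    return float((B.sum() - n) / (n * (n - 1)))


def _pair_indicator(arr: np.ndarray, epsilon: float) -> np.ndarray:
    return np.abs(arr[:, None] - arr[None, :]) < epsilon


def _embed_indicator(A: np.ndarray, m: int) -> np.ndarray:
    n = A.shape[0] - m + 1
    B = A[:n, :n].copy()
    for d in range(1, m):
        B &= A[d : d + n, d : d + n]
    return B


def bds(x, m: int = 2, epsilon: float | None = None) -> TestResult:
    """Brock–Dechert–Scheinkman test on correlation-integral scaling.

    Compares the sample correlation integral at embedding dimension ``m``
    with the ``m``-th power of the one at dimension 1; under an iid null
    the standardised difference is asymptotically N(0, 1).  A rejection
    signals temporal dependence (e.g. low-dimensional chaos), which
    includes — but is not limited to — time asymmetry.
    """
    arr = as_real_series(x, min_length=200, require_variance=True)
    if m < 2:
        raise SeriesError("bds requires embedding dimension m >= 2")
    if epsilon is None:
        epsilon = 0.5 * float(arr.std())
    if epsilon <= 0:
        raise SeriesError("epsilon must be positive")

    A = _pair_indicator(arr, epsilon)
    n = arr.size - m + 1
    # restrict to the pair sample shared by all embedding dimensions
    A1 = A[:n, :n]
    s = A1.sum(axis=1) - 1  # row sums without the diagonal
    pairs = n * (n - 1)
    c = s.sum() / pairs
    if c == 0.0:
        raise SeriesError("epsilon too small: no pairs within radius")
    k = float(((s * s) - s).sum()) / (n * (n - 1) * (n - 2))

    B = _embed_indicator(A, m)
    cm = float((B.sum() - n) / pairs)

    # asymptotic variance of sqrt(n) (C_m - C_1^m), Brock et al. (1996)
    sigma2 = 4.0 * (
        k**m
        + 2.0 * sum(k ** (m - j) * c ** (2 * j) for j in range(1, m))
        + (m - 1) ** 2 * c ** (2 * m)
        - m**2 * k * c ** (2 * m - 2)
    )
    if sigma2 <= 0:
        raise SeriesError("degenerate BDS variance (epsilon ill-chosen)")
    w = np.sqrt(n) * (cm - c**m) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(w))
    return TestResult(pvalue=float(p), statistic=float(w))


# ---------------------------------------------------------------------------
# Casali (surrogate-based)


def casali(
    x,
    m: int = 1,
    method: str = "proportional",
    surrogates: int | None = None,
    seed=None,
) -> TestResult:
    """Skewness of the lag-``m`` increment distribution, surrogate p-value.

    The statistic is the sample skewness of ``x_{i+m} - x_i``; a value
    significantly different from zero marks the series as irreversible.
    """
    arr = as_real_series(x, min_length=50, require_variance=True)
    if not 1 <= m < arr.size:
        raise SeriesError("lag m out of range")
    if np.ptp(arr[m:] - arr[:-m]) == 0:
        raise SeriesError("zero variance of lag-m differences")

    def measure(y: np.ndarray) -> float:
        return abs(_sample_skew(y[m:] - y[:-m]))

    stat = _sample_skew(arr[m:] - arr[:-m])
    return surrogate_test(measure, arr, _plan(method, surrogates, seed), statistic=stat)


# ---------------------------------------------------------------------------
# COP


def cop(x, pSize: int = 3, nPatterns: int = 100, seed=None) -> TestResult:
    """Continuous-Ordinal-Pattern test.

    For each of ``nPatterns`` random reference shapes, the series and its
    time-reversed copy are transcribed into sequences of shape-to-window
    distances, and the two distance distributions are compared with a
    two-sample KS test on interleaved non-overlapping window blocks
    (independent under the null).  To keep the pattern search honest, the
    first half of the series *selects* the most discriminating pattern
    (largest KS distance) and the second half provides the reported KS
    test: selection and inference never share data, so the p-value is a
    true p-value with no multiplicity correction.
    """
    arr = as_real_series(x, min_length=max(50, pSize + 10), require_variance=True)
    if nPatterns < 1:
        raise SeriesError("nPatterns must be >= 1")
    rng = np.random.default_rng(seed)
    W, valid = normalized_windows(arr, pSize)
    idx = np.arange(W.shape[0])
    # disjoint blocks: forward sample from even blocks, reversed from odd
    in_a = valid & (idx % (2 * pSize) == 0)
    in_b = valid & (idx % (2 * pSize) == pSize)
    half = W.shape[0] // 2
    sel = idx < half
    a_sel, b_sel = W[in_a & sel], W[in_b & sel, ::-1]
    a_inf, b_inf = W[in_a & ~sel], W[in_b & ~sel, ::-1]
    if min(a_sel.shape[0], b_sel.shape[0], a_inf.shape[0], b_inf.shape[0]) < 5:
        raise SeriesError("series too short for COP comparison")

    best_d, best_pattern = -1.0, None
    for _ in range(nPatterns):
        pattern = random_pattern(pSize, rng)
        d, _ = stats.ks_2samp(
            distance_profile(pattern, a_sel), distance_profile(pattern, b_sel), method="asymp"
        )
        if d > best_d:
            best_d, best_pattern = float(d), pattern
    d, p = stats.ks_2samp(
        distance_profile(best_pattern, a_inf),
        distance_profile(best_pattern, b_inf),
        method="asymp",
    )
    return TestResult(pvalue=float(p), statistic=float(d))


# ---------------------------------------------------------------------------
# Costa index (surrogate-based)


def _costa_stat(y: np.ndarray) -> float:
    d = np.diff(y)
    n_up = int(np.count_nonzero(d > 0))
    n_down = int(np.count_nonzero(d < 0))
    if n_up + n_down == 0:
        raise SeriesError("constant series: no increments to compare")
    return (n_up - n_down) / (n_up + n_down)


def costa(
    x,
    method: str = "proportional",
    surrogates: int | None = None,
    seed=None,
) -> TestResult:
    """Costa index for real-valued series: up/down count asymmetry.

    statistic = (N_up - N_down) / (N_up + N_down), amplitudes disregarded;
    p-value from shuffled surrogates.
    """
    arr = as_real_series(x, min_length=50)
    stat = _costa_stat(arr)
    return surrogate_test(
        lambda y: abs(_costa_stat(y)), arr, _plan(method, surrogates, seed), statistic=stat
    )


# ---------------------------------------------------------------------------
# DFK


def _symbolize(arr: np.ndarray, nSymbols: int, binning: str) -> np.ndarray:
    if binning == "quantile":
        edges = np.quantile(arr, np.linspace(0, 1, nSymbols + 1)[1:-1])
    elif binning == "width":
        edges = np.linspace(arr.min(), arr.max(), nSymbols + 1)[1:-1]
    else:
        raise SeriesError(f"unknown binning {binning!r}")
    return np.searchsorted(edges, arr, side="left")


def dfk(
    x,
    nSymbols: int = 2,
    wordLength: int = 3,
    binning: str = "quantile",
) -> TestResult:
    """Daw–Finney–Kennel symbolic word-frequency test.

    Values are symbolised into ``nSymbols`` equal-probability bins, merged
    into non-overlapping words of ``wordLength`` symbols, and the frequency
    of each word is compared with that of its time-reversed partner via a
    chi-square statistic over reversal-asymmetric word pairs.
    """
    arr = as_real_series(x, min_length=50, require_variance=True)
    if nSymbols < 2 or wordLength < 2:
        raise SeriesError("need nSymbols >= 2 and wordLength >= 2")
    sym = _symbolize(arr, nSymbols, binning)
    n_words = sym.size // wordLength
    if n_words < 5 * nSymbols**wordLength:
        warnings.warn(
            "few words per word type: chi-square approximation may be poor",
            stacklevel=2,
        )
    if n_words < 2:
        raise SeriesError("series too short for word counting")
    words = sym[: n_words * wordLength].reshape(n_words, wordLength)
    base = nSymbols ** np.arange(wordLength)
    codes = words @ base
    codes_rev = words[:, ::-1] @ base
    counts = np.bincount(codes, minlength=nSymbols**wordLength)

    chi2, df = 0.0, 0
    seen = set()
    for c, cr in zip(codes, codes_rev):
        pair = (min(c, cr), max(c, cr))
        if c == cr or pair in seen:
            continue
        seen.add(pair)
        f1, f2 = counts[pair[0]], counts[pair[1]]
        chi2 += (f1 - f2) ** 2 / (f1 + f2)
        df += 1
    if df == 0:
        return TestResult(pvalue=1.0, statistic=0.0)
    return TestResult(pvalue=float(stats.chi2.sf(chi2, df)), statistic=float(chi2))


# ---------------------------------------------------------------------------
# Diks


def diks(x, m: int = 3, bandwidth: float | None = None) -> TestResult:
    """Diks-style kernel two-sample test between delay-vector clouds.

    Non-overlapping ``m``-dimensional delay vectors are drawn from the
    series and from its time-reversed copy; the squared kernel discrepancy
    between the two clouds is estimated by a linear-time U-statistic whose
    terms are iid under the null, giving a native upper-tail normal
    p-value.  ``bandwidth`` defaults to the series standard deviation.
    """
    arr = as_real_series(x, min_length=max(200, 10 * m), require_variance=True)
    if m < 2:
        raise SeriesError("diks requires m >= 2")
    if bandwidth is None:
        bandwidth = float(arr.std())
    if bandwidth <= 0:
        raise SeriesError("bandwidth must be positive")
    n_vec = arr.size // m
    V = arr[: n_vec * m].reshape(n_vec, m)
    R = V[:, ::-1]  # time-reversed delay vectors
    n_pairs = n_vec // 2
    v1, v2 = V[0 : 2 * n_pairs : 2], V[1 : 2 * n_pairs : 2]
    r1, r2 = R[0 : 2 * n_pairs : 2], R[1 : 2 * n_pairs : 2]

    def kern(a, b):
        return np.exp(-np.sum((a - b) ** 2, axis=1) / (4.0 * bandwidth**2))

    h = kern(v1, v2) + kern(r1, r2) - kern(v1, r2) - kern(v2, r1)
    sd = h.std(ddof=1)
    if sd == 0.0:
        return TestResult(pvalue=1.0, statistic=0.0)
    z = h.mean() / (sd / np.sqrt(n_pairs))
    return TestResult(pvalue=float(stats.norm.sf(z)), statistic=float(z))


# ---------------------------------------------------------------------------
# dHVG-based tests


def _es_or_degenerate(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Epps–Singleton two-sample comparison, p=1 on degenerate input."""
    if a.size < 5 or b.size < 5 or (np.ptp(a) == 0 and np.ptp(b) == 0):
        return TestResult(pvalue=1.0, statistic=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = stats.epps_singleton_2samp(a, b)
    except np.linalg.LinAlgError:
        return TestResult(pvalue=1.0, statistic=0.0)
    if not np.isfinite(w):
        return TestResult(pvalue=1.0, statistic=0.0)
    return TestResult(pvalue=float(p), statistic=float(w))


def local_clustering(x) -> TestResult:
    """Retarded vs advanced local clustering in the dHVG.

    The clustering coefficient of each node is computed separately over its
    past and its future neighbours; the two coefficient samples (taken from
    interleaved node subsets to keep them independent under the null) are
    compared with an Epps–Singleton test.
    """
    arr = as_real_series(x, min_length=50)
    edges = hvg.horizontal_visibility_edges(arr)
    ret, adv = hvg.local_clustering_coefficients(arr.size, edges)
    ret, adv = ret[1:-1], adv[1:-1]  # boundary nodes are truncated
    # interleaved, well-separated node subsets: near-independent under the null
    return _es_or_degenerate(ret[0::4], adv[2::4])


def visibility_graph(x) -> TestResult:
    """dHVG in-degree vs out-degree distribution comparison.

    Arcs point forward in time, so in-degrees look at the past and
    out-degrees at the future; under reversibility the two distributions
    coincide.  Compared with an Epps–Singleton test on interleaved node
    subsets, dropping the first and last node (boundary truncation bias).
    """
    arr = as_real_series(x, min_length=50)
    edges = hvg.horizontal_visibility_edges(arr)
    indeg, outdeg = hvg.degrees(arr.size, edges)
    indeg, outdeg = indeg[1:-1], outdeg[1:-1]
    # interleaved, well-separated node subsets: near-independent under the null
    return _es_or_degenerate(outdeg[0::4].astype(float), indeg[2::4].astype(float))


# ---------------------------------------------------------------------------
# MSTrends


def window_slopes(x, window: int = 10, degree: int = 1) -> np.ndarray:
    """Leading polynomial coefficient of every stride-1 window fit."""
    arr = as_real_series(x, min_length=window)
    from numpy.lib.stride_tricks import sliding_window_view

    W = sliding_window_view(arr, window)
    t = np.arange(window, dtype=float)
    if degree == 1:
        tc = t - t.mean()
        return (W @ tc) / (tc @ tc)
    coeffs = np.polyfit(t, W.T, degree)
    return coeffs[0]


def mstrends(x, window: int = 4, degree: int = 1) -> TestResult:
    """Sub-window trend (leading-coefficient) distribution asymmetry.

    Fits a degree-``degree`` polynomial to every stride-1 sub-window of the
    series and of its reversed copy; reversing a window multiplies the
    leading coefficient by ``(-1)^degree``.  The two coefficient samples,
    restricted to interleaved non-overlapping window blocks, are compared
    with a two-sample KS test.
    """
    arr = as_real_series(x, min_length=max(50, 4 * window), require_variance=True)
    if window < degree + 2:
        raise SeriesError("window too small for the requested degree")
    slopes = window_slopes(arr, window, degree)
    fwd = slopes[0 :: 2 * window]
    rev = ((-1.0) ** degree) * slopes[window :: 2 * window]
    if fwd.size < 5 or rev.size < 5:
        raise SeriesError("series too short for MSTrends comparison")
    d, p = stats.ks_2samp(fwd, rev, method="asymp")
    return TestResult(pvalue=float(p), statistic=float(d))


# ---------------------------------------------------------------------------
# Permutation patterns


def _pattern_codes(W: np.ndarray) -> np.ndarray:
    """Ordinal code of each window row (stable argsort; ties earlier-first)."""
    p = W.shape[1]
    order = np.argsort(W, axis=1, kind="stable")
    # encode the sorting permutation as a base-p integer (injective for fixed p)
    weights = p ** np.arange(p - 1, -1, -1)
    return order @ weights


def _reversal_partner_map(pSize: int) -> dict[int, int]:
    weights = pSize ** np.arange(pSize - 1, -1, -1)
    partner: dict[int, int] = {}
    for perm in itertools.permutations(range(pSize)):
        w = np.array(perm, dtype=float)
        code = int(np.argsort(w, kind="stable") @ weights)
        code_rev = int(np.argsort(w[::-1], kind="stable") @ weights)
        partner[code] = code_rev
    return partner


def ordinal_pattern_counts(x, pSize: int = 3, stride: int = 1) -> dict[int, int]:
    """Counts of ordinal-pattern codes over windows at the given stride."""
    arr = as_real_series(x, min_length=pSize)
    from numpy.lib.stride_tricks import sliding_window_view

    W = sliding_window_view(arr, pSize)[::stride]
    codes = _pattern_codes(W)
    vals, cnts = np.unique(codes, return_counts=True)
    return dict(zip(vals.tolist(), cnts.tolist()))


def permutation_patterns(x, pSize: int = 3) -> TestResult:
    """Ordinal-pattern frequency asymmetry under time reversal.

    Counts ordinal patterns over non-overlapping windows and compares the
    frequency of each pattern with that of its time-reversed partner
    through a chi-square over asymmetric pattern pairs.
    """
    arr = as_real_series(x, min_length=max(50, 4 * pSize), require_variance=True)
    if pSize < 2:
        raise SeriesError("pSize must be >= 2")
    counts = ordinal_pattern_counts(arr, pSize, stride=pSize)
    partner = _reversal_partner_map(pSize)
    chi2, df = 0.0, 0
    done = set()
    for code, mate in partner.items():
        if code == mate or (mate, code) in done:
            continue
        done.add((code, mate))
        f1, f2 = counts.get(code, 0), counts.get(mate, 0)
        if f1 + f2 == 0:
            continue
        chi2 += (f1 - f2) ** 2 / (f1 + f2)
        df += 1
    if df == 0:
        return TestResult(pvalue=1.0, statistic=0.0)
    return TestResult(pvalue=float(stats.chi2.sf(chi2, df)), statistic=float(chi2))


# ---------------------------------------------------------------------------
# Pomeau (surrogate-based)


def _pomeau_stat(y: np.ndarray) -> float:
    return float(np.mean(y[:-1] * y[1:] ** 2 - y[:-1] ** 2 * y[1:]))


def pomeau(
    x,
    method: str = "proportional",
    surrogates: int | None = None,
    seed=None,
) -> TestResult:
    """Time-asymmetric third-order polynomial ⟨x_t x_{t+1}² − x_t² x_{t+1}⟩.

    The statistic changes sign under time reversal and vanishes in
    expectation for any exchangeable series; p-value via surrogates on its
    magnitude.
    """
    arr = as_real_series(x, min_length=50, require_variance=True)
    stat = _pomeau_stat(arr)
    return surrogate_test(
        lambda y: abs(_pomeau_stat(y)), arr, _plan(method, surrogates, seed), statistic=stat
    )


# ---------------------------------------------------------------------------
# Ramsey


def bicovariance_difference(x, k: int = 1) -> float:
    """⟨x_t² x_{t−k}⟩ − ⟨x_t x_{t−k}²⟩, the raw Ramsey asymmetry."""
    arr = as_real_series(x, min_length=k + 2)
    a, b = arr[k:], arr[:-k]
    return float(np.mean(a**2 * b) - np.mean(a * b**2))


def ramsey(x, k: int = 1) -> TestResult:
    """Bicovariance (TR) test: ⟨x_t² x_{t−k}⟩ vs ⟨x_t x_{t−k}²⟩.

    The method-of-moments difference of the two sample bicovariances is
    standardised with an autocorrelation-robust (lag-``k`` truncated HAC)
    standard error; two-sided normal p-value.
    """
    arr = as_real_series(x, min_length=50, require_variance=True)
    if not 1 <= k < arr.size:
        raise SeriesError("lag k out of range")
    a, b = arr[k:], arr[:-k]
    d = a**2 * b - a * b**2
    n = d.size
    dc = d - d.mean()
    gamma0 = float(dc @ dc) / n
    var = gamma0
    for j in range(1, k + 1):
        var += 2.0 * float(dc[:-j] @ dc[j:]) / n
    if var <= 0:
        var = gamma0
    if var == 0:
        return TestResult(pvalue=1.0, statistic=0.0)
    z = d.mean() / np.sqrt(var / n)
    return TestResult(pvalue=float(2.0 * stats.norm.sf(abs(z))), statistic=float(z))


# ---------------------------------------------------------------------------
# Skewness index


def skewness_index(x) -> TestResult:
    """Koutsoyiannis-style skewness index of the differenced series.

    statistic = skew(Δx) / skew(x) (the relation between differenced and
    raw skewness); the p-value is the D'Agostino skewness test applied to
    the differenced series, whose symmetry is what time reversal preserves.
    """
    arr = as_real_series(x, min_length=50, require_variance=True)
    d = np.diff(arr)
    if np.ptp(d) == 0:
        raise SeriesError("zero variance of the differenced series")
    sk_x = _sample_skew(arr)
    sk_d = _sample_skew(d)
    if sk_x == 0.0:
        raise SeriesError("raw-series skewness exactly zero: index undefined")
    _, p = stats.skewtest(d)
    return TestResult(pvalue=float(p), statistic=float(sk_d / sk_x))


# ---------------------------------------------------------------------------
# Ternary coding


def ternary_symbols(x, q: float = 0.33, threshold: float | None = None) -> np.ndarray:
    """Map increments to {+1, 0, −1}: strong rise / maintain / strong fall.

    The "maintain" band holds increments with magnitude at or below the
    threshold — by default the ``q`` quantile of |Δx|, so it adapts to the
    scale of the series; an absolute ``threshold`` overrides it.
    """
    arr = as_real_series(x, min_length=2)
    d = np.diff(arr)
    if threshold is None:
        if not 0.0 <= q < 1.0:
            raise SeriesError("quantile q must be in [0, 1)")
        threshold = float(np.quantile(np.abs(d), q))
    return np.where(np.abs(d) > threshold, np.sign(d), 0.0).astype(int)


def ternary(x, q: float = 0.33, threshold: float | None = None) -> TestResult:
    """Ternary symbolisation of increments: rise / fall / maintain.

    Increments with magnitude below the threshold (by default the ``q``
    quantile of |Δx|, so the threshold adapts to scale) map to 0, the rest
    to ±1.  Under reversal the +1 and −1 frequencies swap; the count
    difference is standardised with a lag-1 HAC variance (increment signs
    are 1-dependent even under the iid null).
    """
    arr = as_real_series(x, min_length=50, require_variance=True)
    s = ternary_symbols(arr, q=q, threshold=threshold).astype(float)
    n_plus = int(np.count_nonzero(s > 0))
    n_minus = int(np.count_nonzero(s < 0))
    if n_plus + n_minus == 0:
        raise SeriesError("all increments fall in the 'maintain' class")
    sc = s - s.mean()
    n = s.size
    gamma0 = float(sc @ sc) / n
    gamma1 = float(sc[:-1] @ sc[1:]) / n
    var = gamma0 + 2.0 * gamma1
    if var <= 0:
        var = gamma0
    z = (n_plus - n_minus) / np.sqrt(n * var)
    stat = (n_plus - n_minus) / (n_plus + n_minus)
    return TestResult(pvalue=float(2.0 * stats.norm.sf(abs(z))), statistic=float(stat))


# ---------------------------------------------------------------------------
# TPLength


def _run_lengths(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(arr)
    signs = np.sign(d)
    signs = signs[signs != 0]  # flat steps carry no trend information
    if signs.size == 0:
        return np.array([]), np.array([])
    change = np.flatnonzero(np.diff(signs) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [signs.size]))
    lengths = ends - starts
    run_sign = signs[starts]
    return lengths[run_sign > 0], lengths[run_sign < 0]


def tplength(x) -> TestResult:
    """Trend-pattern length asymmetry.

    Decomposes the series into maximal increasing and decreasing runs; time
    reversal turns up-runs into down-runs, so the two run-length
    distributions are compared (Epps–Singleton, lengths being small
    integers).
    """
    arr = as_real_series(x, min_length=50)
    up, down = _run_lengths(arr)
    if up.size < 2 or down.size < 2:
        raise SeriesError("fewer than 2 runs of each sign")
    return _es_or_degenerate(up.astype(float), down.astype(float))


# ---------------------------------------------------------------------------
# Zumbach


def zumbach(x, window: int = 20) -> TestResult:
    """Zumbach volatility-asymmetry (time-reversal) test.

    Values are turned into returns (log-returns when the series is strictly
    positive, simple differences otherwise).  At each time two *historical*
    volatilities are computed over the past ``window`` returns — a fine-
    grained one (RMS of the returns) and a coarse-grained one (magnitude of
    the net change) — and likewise two *realised* ones over the next
    ``window``.  In a time-reversible process the correlation of coarse
    past with fine future equals that of coarse future with fine past;
    their difference is the statistic (the classic "mug-shot" asymmetry of
    financial series).  The p-value comes from a HAC-standardised mean of
    the corresponding cross products (Bartlett weights, lag ``2 window``),
    robust to the overlap-induced autocorrelation.
    """
    arr = as_real_series(x, min_length=3 * window, require_variance=True)
    if window < 2:
        raise SeriesError("window must be >= 2")
    r = np.diff(np.log(arr)) if np.all(arr > 0) else np.diff(arr)
    n = r.size
    if np.ptp(r) == 0:
        return TestResult(pvalue=1.0, statistic=0.0)
    w = window
    csum2 = np.concatenate(([0.0], np.cumsum(r**2)))
    csum1 = np.concatenate(([0.0], np.cumsum(r)))
    t = np.arange(w, n - w + 1)
    fine_p = np.sqrt((csum2[t] - csum2[t - w]) / w)
    fine_f = np.sqrt((csum2[t + w] - csum2[t]) / w)
    coarse_p = np.abs(csum1[t] - csum1[t - w]) / w
    coarse_f = np.abs(csum1[t + w] - csum1[t]) / w
    if min(np.ptp(fine_p), np.ptp(fine_f), np.ptp(coarse_p), np.ptp(coarse_f)) == 0:
        return TestResult(pvalue=1.0, statistic=0.0)
    stat = float(
        np.corrcoef(coarse_p, fine_f)[0, 1] - np.corrcoef(coarse_f, fine_p)[0, 1]
    )
    u = (coarse_p - coarse_p.mean()) * (fine_f - fine_f.mean()) - (
        coarse_f - coarse_f.mean()
    ) * (fine_p - fine_p.mean())
    m = u.size
    uc = u - u.mean()
    L = 2 * w
    var = float(uc @ uc) / m
    for j in range(1, min(L, m - 1) + 1):
        var += 2.0 * (1.0 - j / (L + 1)) * float(uc[:-j] @ uc[j:]) / m
    if var <= 0:
        return TestResult(pvalue=1.0, statistic=stat)
    z = u.mean() / np.sqrt(var / m)
    return TestResult(pvalue=float(2.0 * stats.norm.sf(abs(z))), statistic=stat)


# ---------------------------------------------------------------------------
# Registry entries (Table-driven: name, modes, defaults, grids)

_CONTINUOUS = [
    ("BDS", bds, {"native"}, {"m": 2, "epsilon": None}, {"m": [2, 3, 4]}, "Correlations between data points", 200),
    ("Casali", casali, {"proportional", "zscore"}, {"m": 1}, {"m": [1, 2, 3]}, "Correlations between data points", 50),
    ("COP", cop, {"native"}, {"pSize": 3, "nPatterns": 100}, {"pSize": [3, 4, 5, 6]}, "Ranking between successive values", 50),
    ("Costa Index", costa, {"proportional", "zscore"}, {}, {}, "Ranking between successive values", 50),
    ("DFK", dfk, {"native"}, {"nSymbols": 2, "wordLength": 3}, {"nSymbols": [2, 3, 4], "wordLength": [2, 3, 4]}, "Symbolisation of individual values", 50),
    ("Diks", diks, {"native"}, {"m": 3}, {"m": [2, 3, 4]}, "Correlations between data points", 200),
    ("Local CC", local_clustering, {"native"}, {}, {}, "Network embedding", 50),
    ("MSTrends", mstrends, {"native"}, {"window": 4, "degree": 1}, {"window": [3, 4, 5, 10, 20]}, "Linear and non-linear trends", 50),
    ("Permutation Patterns", permutation_patterns, {"native"}, {"pSize": 3}, {"pSize": [3, 4, 5]}, "Ranking between successive values", 50),
    ("Pomeau", pomeau, {"proportional", "zscore"}, {}, {}, "Asymmetric function", 50),
    ("Ramsey", ramsey, {"native"}, {"k": 1}, {"k": [1, 2, 3]}, "Statistics on data", 50),
    ("Skewness", skewness_index, {"native"}, {}, {}, "Statistics on data", 50),
    ("Ternary Coding", ternary, {"native"}, {"q": 0.33}, {"q": [0.2, 0.33, 0.5]}, "Symbolisation of individual values", 50),
    ("TPLength", tplength, {"native"}, {}, {}, "Linear and non-linear trends", 50),
    ("Visibility Graph", visibility_graph, {"native"}, {}, {}, "Network embedding", 50),
    ("Zumbach", zumbach, {"native"}, {"window": 20}, {"window": [10, 20, 50]}, "Statistics on data", 60),
]

# Diks' kernel discrepancy is positive under the alternative (upper tail);
# surrogate-based tests compare magnitudes against the null (upper tail too).
_ONE_SIDED = {"Casali", "Costa Index", "Diks", "Pomeau"}

for _name, _fn, _modes, _defaults, _grid, _cls, _minn in _CONTINUOUS:
    register(
        TestDescriptor(
            name=_name,
            function=_fn,
            value_kind="continuous",
            significance_modes=frozenset(_modes),
            default_params=_defaults,
            param_grid=_grid,
            analysis_class=_cls,
            sided="one-sided" if _name in _ONE_SIDED else "two-sided",
            min_length=_minn,
        )
    )
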