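"""Naive, loop-based reference implementations of every test statistic.

Each oracle follows the definition of its statistic as directly as
possible (explicit loops, no shared code with the package beyond scipy's
two-sample tests where the statistic *is* the scipy output applied to
samples assembled here by brute force).  They exist to pin down the
optimised implementations, so clarity beats speed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def sample_skew(d) -> float:
    d = list(map(float, d))
    n = len(d)
    mean = sum(d) / n
    m2 = sum((v - mean) ** 2 for v in d) / n
    m3 = sum((v - mean) ** 3 for v in d) / n
    return m3 / m2**1.5


# -- BDS ---------------------------------------------------------------------


def correlation_integral(x, epsilon, m=1) -> float:
    x = list(map(float, x))
    n = len(x) - m + 1
    vecs = [x[t : t + m] for t in range(n)]
    close = 0
    for i in range(n):
        for j in range(n):
            if i != j and all(abs(vecs[i][d] - vecs[j][d]) < epsilon for d in range(m)):
                close += 1
    return close / (n * (n - 1))


def bds_statistic(x, m=2, epsilon=None) -> float:
    x = list(map(float, x))
    if epsilon is None:
        epsilon = 0.5 * float(np.std(x))
    n = len(x) - m + 1
    sub = x[:n]
    # c and k over the common n-point sample
    s = [sum(1 for j in range(n) if j != i and abs(sub[i] - sub[j]) < epsilon) for i in range(n)]
    c = sum(s) / (n * (n - 1))
    k = sum(si * (si - 1) for si in s) / (n * (n - 1) * (n - 2))
    cm = correlation_integral(x, epsilon, m)
    sigma2 = 4.0 * (
        k**m
        + 2.0 * sum(k ** (m - j) * c ** (2 * j) for j in range(1, m))
        + (m - 1) ** 2 * c ** (2 * m)
        - m**2 * k * c ** (2 * m - 2)
    )
    return math.sqrt(n) * (cm - c**m) / math.sqrt(sigma2)


# -- simple moment statistics ------------------------------------------------


def casali_statistic(x, m=1) -> float:
    x = list(map(float, x))
    return sample_skew([x[i + m] - x[i] for i in range(len(x) - m)])


def costa_statistic(x) -> float:
    x = list(map(float, x))
    up = sum(1 for i in range(len(x) - 1) if x[i + 1] > x[i])
    down = sum(1 for i in range(len(x) - 1) if x[i + 1] < x[i])
    return (up - down) / (up + down)


def pomeau_statistic(x) -> float:
    x = list(map(float, x))
    terms = [x[i] * x[i + 1] ** 2 - x[i] ** 2 * x[i + 1] for i in range(len(x) - 1)]
    return sum(terms) / len(terms)


def bicovariance_difference(x, k=1) -> float:
    x = list(map(float, x))
    terms21 = [x[i] ** 2 * x[i - k] for i in range(k, len(x))]
    terms12 = [x[i] * x[i - k] ** 2 for i in range(k, len(x))]
    return sum(terms21) / len(terms21) - sum(terms12) / len(terms12)


def ramsey_statistic(x, k=1) -> float:
    x = list(map(float, x))
    d = [x[i] ** 2 * x[i - k] - x[i] * x[i - k] ** 2 for i in range(k, len(x))]
    n = len(d)
    mean = sum(d) / n
    dc = [v - mean for v in d]
    gamma0 = sum(v * v for v in dc) / n
    var = gamma0
    for j in range(1, k + 1):
        var += 2.0 * sum(dc[i] * dc[i + j] for i in range(n - j)) / n
    if var <= 0:
        var = gamma0
    return mean / math.sqrt(var / n)


def skewness_index_statistic(x) -> float:
    x = list(map(float, x))
    diffs = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return sample_skew(diffs) / sample_skew(x)


# -- dHVG --------------------------------------------------------------------


def hvg_edges(x) -> set[tuple[int, int]]:
    """All (i, j), i<j, with every intermediate strictly below min(xi, xj)."""
    x = list(map(float, x))
    edges = set()
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if all(x[k] < min(x[i], x[j]) for k in range(i + 1, j)):
                edges.add((i, j))
    return edges


def hvg_degrees(x) -> tuple[list[int], list[int]]:
    edges = hvg_edges(x)
    n = len(x)
    indeg = [sum(1 for (a, b) in edges if b == v) for v in range(n)]
    outdeg = [sum(1 for (a, b) in edges if a == v) for v in range(n)]
    return indeg, outdeg


def hvg_clustering(x) -> tuple[list[float], list[float]]:
    edges = hvg_edges(x)
    n = len(x)

    def cc(neigh):
        k = len(neigh)
        if k < 2:
            return 0.0
        links = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if (min(neigh[a], neigh[b]), max(neigh[a], neigh[b])) in edges
        )
        return 2.0 * links / (k * (k - 1))

    ret = [cc([a for (a, b) in edges if b == v]) for v in range(n)]
    adv = [cc([b for (a, b) in edges if a == v]) for v in range(n)]
    return ret, adv


def visibility_graph_statistic(x) -> float:
    indeg, outdeg = hvg_degrees(x)
    a = np.array(outdeg[1:-1], dtype=float)[0::4]
    b = np.array(indeg[1:-1], dtype=float)[2::4]
    w, _ = stats.epps_singleton_2samp(a, b)
    return float(w)


def local_clustering_statistic(x) -> float:
    ret, adv = hvg_clustering(x)
    a = np.array(ret[1:-1])[0::4]
    b = np.array(adv[1:-1])[2::4]
    w, _ = stats.epps_singleton_2samp(a, b)
    return float(w)


# -- window statistics -------------------------------------------------------


def window_slopes(x, window=4, degree=1) -> list[float]:
    x = list(map(float, x))
    out = []
    t = np.arange(window, dtype=float)
    for i in range(len(x) - window + 1):
        out.append(float(np.polyfit(t, x[i : i + window], degree)[0]))
    return out


def mstrends_statistic(x, window=4, degree=1) -> float:
    fwd_all = window_slopes(x, window, degree)
    rev_all = [((-1.0) ** degree) * s for s in fwd_all]
    fwd = fwd_all[0 :: 2 * window]
    rev = rev_all[window :: 2 * window]
    d, _ = stats.ks_2samp(fwd, rev, method="asymp")
    return float(d)


def ordinal_pattern_counts(x, pSize=3, stride=1) -> dict[tuple, int]:
    x = list(map(float, x))
    counts: dict[tuple, int] = {}
    for i in range(0, len(x) - pSize + 1, stride):
        w = x[i : i + pSize]
        order = tuple(sorted(range(pSize), key=lambda k: (w[k], k)))
        counts[order] = counts.get(order, 0) + 1
    return counts


def permutation_patterns_statistic(x, pSize=3) -> float:
    counts = ordinal_pattern_counts(x, pSize, stride=pSize)
    import itertools

    chi2 = 0.0
    done = set()
    for perm in itertools.permutations(range(pSize)):
        w = [float(v) for v in perm]
        code = tuple(sorted(range(pSize), key=lambda k: (w[k], k)))
        wr = w[::-1]
        mate = tuple(sorted(range(pSize), key=lambda k: (wr[k], k)))
        pair = tuple(sorted([code, mate]))
        if code == mate or pair in done:
            continue
        done.add(pair)
        f1, f2 = counts.get(code, 0), counts.get(mate, 0)
        if f1 + f2:
            chi2 += (f1 - f2) ** 2 / (f1 + f2)
    return chi2


# -- symbolisation tests -----------------------------------------------------


def dfk_statistic(x, nSymbols=2, wordLength=3) -> float:
    x = list(map(float, x))
    edges = [float(np.quantile(x, (q + 1) / nSymbols)) for q in range(nSymbols - 1)]

    def sym(v):
        # bin index = number of quantile edges strictly below the value
        return sum(1 for e in edges if e < v)

    syms = [sym(v) for v in x]
    words = []
    for i in range(0, len(syms) - wordLength + 1, wordLength):
        words.append(tuple(syms[i : i + wordLength]))
    counts: dict[tuple, int] = {}
    for w in words:
        counts[w] = counts.get(w, 0) + 1
    chi2 = 0.0
    done = set()
    for w in list(counts):
        wr = w[::-1]
        pair = tuple(sorted([w, wr]))
        if w == wr or pair in done:
            continue
        done.add(pair)
        f1, f2 = counts.get(w, 0), counts.get(wr, 0)
        chi2 += (f1 - f2) ** 2 / (f1 + f2)
    return chi2


def ternary_statistic(x, q=0.33) -> float:
    x = list(map(float, x))
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    thr = float(np.quantile([abs(v) for v in d], q))
    s = [(1 if v > 0 else -1) if abs(v) > thr else 0 for v in d]
    n_plus = sum(1 for v in s if v > 0)
    n_minus = sum(1 for v in s if v < 0)
    return (n_plus - n_minus) / (n_plus + n_minus)


def run_lengths(x) -> tuple[list[int], list[int]]:
    x = list(map(float, x))
    signs = []
    for i in range(len(x) - 1):
        d = x[i + 1] - x[i]
        if d != 0:
            signs.append(1 if d > 0 else -1)
    up, down = [], []
    i = 0
    while i < len(signs):
        j = i
        while j < len(signs) and signs[j] == signs[i]:
            j += 1
        (up if signs[i] > 0 else down).append(j - i)
        i = j
    return up, down


def tplength_statistic(x) -> float:
    up, down = run_lengths(x)
    w, _ = stats.epps_singleton_2samp(np.array(up, float), np.array(down, float))
    return float(w)


# -- kernel and volatility tests ---------------------------------------------


def diks_statistic(x, m=3, bandwidth=None) -> float:
    x = list(map(float, x))
    if bandwidth is None:
        bandwidth = float(np.std(x))
    n_vec = len(x) // m
    V = [x[t * m : (t + 1) * m] for t in range(n_vec)]
    R = [v[::-1] for v in V]

    def kern(a, b):
        return math.exp(-sum((ai - bi) ** 2 for ai, bi in zip(a, b)) / (4 * bandwidth**2))

    h = []
    for i in range(n_vec // 2):
        v1, v2, r1, r2 = V[2 * i], V[2 * i + 1], R[2 * i], R[2 * i + 1]
        h.append(kern(v1, v2) + kern(r1, r2) - kern(v1, r2) - kern(v2, r1))
    mean = sum(h) / len(h)
    sd = math.sqrt(sum((v - mean) ** 2 for v in h) / (len(h) - 1))
    return mean / (sd / math.sqrt(len(h)))


def zumbach_statistic(x, window=20) -> float:
    x = list(map(float, x))
    if all(v > 0 for v in x):
        r = [math.log(x[i + 1]) - math.log(x[i]) for i in range(len(x) - 1)]
    else:
        r = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    w, n = window, len(r)
    cp, cf, fp, ff = [], [], [], []
    for t in range(w, n - w + 1):
        past, fut = r[t - w : t], r[t : t + w]
        cp.append(abs(sum(past)) / w)
        cf.append(abs(sum(fut)) / w)
        fp.append(math.sqrt(sum(v * v for v in past) / w))
        ff.append(math.sqrt(sum(v * v for v in fut) / w))
    rho1 = np.corrcoef(cp, ff)[0, 1]
    rho2 = np.corrcoef(cf, fp)[0, 1]
    return float(rho1 - rho2)


def cop_statistic(x, pSize=3, nPatterns=100, seed=None) -> float:
    """Loop-based replay of the COP select-then-test statistic."""
    x = list(map(float, x))
    rng = np.random.default_rng(seed)

    def norm(w):
        mean = sum(w) / len(w)
        c = [v - mean for v in w]
        scale = max(abs(v) for v in c)
        return [v / scale for v in c]

    n_win = len(x) - pSize + 1
    windows = [norm(x[i : i + pSize]) for i in range(n_win)]
    half = n_win // 2
    a_sel = [windows[i] for i in range(n_win) if i % (2 * pSize) == 0 and i < half]
    b_sel = [windows[i][::-1] for i in range(n_win) if i % (2 * pSize) == pSize and i < half]
    a_inf = [windows[i] for i in range(n_win) if i % (2 * pSize) == 0 and i >= half]
    b_inf = [windows[i][::-1] for i in range(n_win) if i % (2 * pSize) == pSize and i >= half]

    def dist(p, w):
        return sum(abs(pi - wi) for pi, wi in zip(p, w)) / len(p)

    best_d, best_pattern = -1.0, None
    for _ in range(nPatterns):
        while True:
            raw = rng.uniform(-1.0, 1.0, size=pSize)
            if max(raw) > min(raw):
                break
        pattern = norm(list(raw))
        d, _ = stats.ks_2samp(
            [dist(pattern, w) for w in a_sel], [dist(pattern, w) for w in b_sel], method="asymp"
        )
        if d > best_d:
            best_d, best_pattern = float(d), pattern
    d, _ = stats.ks_2samp(
        [dist(best_pattern, w) for w in a_inf],
        [dist(best_pattern, w) for w in b_inf],
        method="asymp",
    )
    return float(d)


# -- discrete ----------------------------------------------------------------


def entropy_production(symbols) -> float:
    """KL of the bigram frequency distribution from its transpose."""
    symbols = list(symbols)
    big = {}
    for a, b in zip(symbols[:-1], symbols[1:]):
        big[(a, b)] = big.get((a, b), 0) + 1
    total = sum(big.values())
    ep = 0.0
    for (a, b), c in big.items():
        c_rev = big.get((b, a), 0)
        if c_rev == 0:
            raise ValueError("unmatched reverse transition")
        ep += (c / total) * math.log(c / c_rev)
    return ep


def costa_discrete_statistic(symbols) -> float:
    v = list(map(float, symbols))
    d = [v[i + 1] - v[i] for i in range(len(v) - 1)]
    d = [x for x in d if x != 0]
    num = sum(x * abs(x) for x in d)
    den = sum(x * x for x in d)
    return num / den
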