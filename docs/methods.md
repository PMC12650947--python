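# Methods

## The problem

A stationary time series is *time-reversible* when every finite-dimensional
statistic is invariant under the transformation t → −t: the series read
backwards is statistically indistinguishable from the series read forwards.
Linear Gaussian processes (and static transformations of them) are
reversible; irreversibility is therefore a fingerprint of nonlinearity,
non-Gaussianity, or out-of-equilibrium dynamics, and has been used to
characterise heartbeat, brain-activity and financial series. Because the
definition does not say *which* statistic breaks the symmetry, tests built
on different features (increments, ordinal structure, visibility graphs,
correlation integrals, entropy rates, volatilities) can disagree; `irrev`
collects 18 of them behind a single contract — series in, `(p-value,
statistic)` out — so that several can be run and compared at once.

## Tests and their nulls

Thirteen continuous-series tests carry a **native** p-value; three (Casali,
Costa, Pomeau) and both discrete tests are bare measures wrapped by the
**surrogate** machinery described below.

- **BDS** — compares the correlation integral at embedding dimension m with
  the m-th power of the dimension-1 integral; the standardised difference
  is asymptotically N(0,1) under an iid null (Brock–Dechert–Scheinkman
  variance). Note that BDS rejects for *any* temporal dependence, linear or
  not: it detects chaos and memory, not specifically time asymmetry, so a
  correlated but reversible process (e.g. an AR(1)) is legitimately
  flagged. Defaults: m = 2, ε = 0.5·sd(x).
- **Casali** — sample skewness of the lag-m increments x_{i+m} − x_i
  (moment-ratio g1, no bias correction); antisymmetric under reversal.
- **COP** — Continuous Ordinal Patterns: random normalised shapes of length
  `pSize` (zero mean, max-abs 1); the series and its reversal are
  transcribed into shape-to-window mean-absolute distances and the two
  distance distributions compared by a two-sample KS test. See
  "calibration" below for how the pattern search is kept honest.
- **Costa index** — (N↑ − N↓)/(N↑ + N↓) over increments, amplitudes
  disregarded (the continuous form); the discrete form (below) restores
  amplitudes.
- **DFK** — equal-probability symbolisation into `nSymbols` bins, words of
  `wordLength` symbols counted without overlap, chi-square over
  reversal-asymmetric word pairs. Default `nSymbols = 2`: for the fully
  chaotic logistic map the binary median partition is the generating
  partition (the symbol stream is an iid coin), which is why DFK at
  defaults famously misses that map's irreversibility — more bins or an
  optimised parameter set recover power.
- **Diks** — kernel (Gaussian, bandwidth = sd(x)) two-sample discrepancy
  between non-overlapping m-dimensional delay vectors of the series and of
  its reversal, estimated by a linear-time U-statistic whose terms are iid
  under the null; upper-tail normal p.
- **Local CC / Visibility Graph** — the directed horizontal visibility
  graph links i → j (i < j) when all intermediate values lie strictly below
  min(x_i, x_j). The degree test compares out-degrees (future) with
  in-degrees (past); the clustering test compares triangle densities among
  past vs future neighbours. Both use the Epps–Singleton two-sample test
  (degrees and clustering values are heavily tied, which ES tolerates),
  dropping the first/last node and using interleaved node subsets four
  apart so the two samples are near-independent under the null.
- **MSTrends** — least-squares leading coefficients of degree-`degree` fits
  on all stride-1 windows; reversing a window multiplies the coefficient by
  (−1)^degree. Two-sample KS on interleaved non-overlapping window blocks.
  Default window = 4: trend asymmetry in chaotic maps lives at short
  scales, and windows ≳10 average it away.
- **Permutation patterns** — ordinal patterns (stable ranks, earlier index
  first on ties) counted over non-overlapping windows; chi-square over
  pattern/reversed-pattern pairs. Overlap-free counting keeps the
  multinomial chi-square null exact; stride-1 counts remain available via
  `ordinal_pattern_counts`.
- **Pomeau** — the canonical third-order time-asymmetric polynomial
  ⟨x_t x_{t+1}² − x_t² x_{t+1}⟩, antisymmetric under reversal and zero in
  expectation for any exchangeable series.
- **Ramsey** — method-of-moments bicovariance difference ⟨x_t² x_{t−k}⟩ −
  ⟨x_t x_{t−k}²⟩, standardised with a lag-k truncated HAC variance (the
  product terms are k-dependent even under an iid null); two-sided normal p.
- **Skewness index** — statistic skew(Δx)/skew(x); p-value from the
  D'Agostino skewness test on the differenced series (slightly conservative
  there, as differencing induces 1-dependence).
- **Ternary coding** — increments mapped to {+1, 0, −1} with a "maintain"
  band at |Δx| below the q-quantile of |Δx| (scale-adaptive; an absolute
  threshold is available). The +1/−1 count difference is standardised with
  a lag-1 HAC variance: consecutive increment signs are negatively
  correlated (ρ = −1/3 for iid input) and ignoring that would make the
  naive chi-square severely conservative.
- **TPLength** — lengths of maximal increasing vs decreasing runs (zero
  steps carry no trend information and are dropped), compared by
  Epps–Singleton.
- **Zumbach** — returns (log-returns for strictly positive series,
  differences otherwise); per time point a fine (RMS) and a coarse (net
  change magnitude) volatility over the past `window` returns and likewise
  over the future. The statistic ρ(coarse past, fine future) − ρ(coarse
  future, fine past) is the classic time-reversal asymmetry of financial
  volatility; p from a HAC-standardised (Bartlett, lag 2·window) mean of
  the cross products.
- **Gaspard** — entropy production of the symbol stream: forward minus
  time-reversed entropy rate of the fitted Markov chain. Estimated through
  the joint bigram frequencies as Σ f_ij ln(f_ij/f_ji) — the KL divergence
  of the bigram distribution from its transpose. This coincides with the
  textbook Σ π_i P_ij ln(P_ij/P_ji) in population but, unlike the plug-in
  with the empirical marginal, is exactly non-negative in finite samples
  and zero iff the observed bigram counts are symmetric. A transition with
  no observed reverse makes the estimate infinite: this is reported as an
  error rather than silently regularised; a user-set pseudocount (default
  0) restores finiteness. Higher orders recode overlapping k-grams.
- **Costa index, discrete** — amplitude-aware asymmetry for ordered
  alphabets: (Σ_{Δ>0} Δ² − Σ_{Δ<0} Δ²) / Σ Δ² over non-zero increments, the
  squared-amplitude generalisation of the count index (to which it reduces
  when all increments have unit magnitude); antisymmetric under reversal.

## Surrogate significance

Measures without a native null are compared against ensembles of randomly
shuffled copies of the series. Shuffling conserves the value multiset
exactly while destroying all temporal relations — and with them any
irreversibility — so it samples the reversible null. Two schemes:

- **proportional** (default S = 100): p = max(c, 1)/S with c the number of
  surrogates whose statistic is ≥ the observed one. A true p-value with
  floor 1/S (0.01 at S = 100). The lower clamp is chosen so the floor is
  exactly 1/S rather than the (c+1)/(S+1) variant's 1/(S+1).
- **zscore** (default S = 20): the observed statistic standardised against
  the surrogate mean/sd, referred to a standard normal (upper tail by
  default). Cheap but approximate — the surrogate distribution need not be
  normal, so this is not a true p-value.

Wrapped statistics are oriented "larger = more irreversible" (absolute
values of signed statistics); the signed value is still reported. One
seeded generator drives the whole ensemble, so a fixed seed reproduces the
p-value bit-for-bit.

## Calibration choices

Tests defined by comparing window-derived samples of x against those of
rev(x) face two sources of miscalibration under the iid null: overlapping
windows autocorrelate each sample, and the two samples are built from the
same data. Naive two-sample p-values are then wrong in either direction.
The package's policy, applied uniformly:

- *Interleaved disjoint blocks* (COP, MSTrends): the forward sample is
  taken from even non-overlapping window blocks and the reversed sample
  from odd ones, making the two samples independent and internally iid
  under the null.
- *Overlap-free counting* (DFK, Permutation Patterns): words/patterns are
  counted at stride = word length, so counts are multinomial and the
  pair-difference chi-square has its nominal distribution.
- *HAC standardisation* (Ramsey, Ternary, Zumbach): moment statistics keep
  their full overlapping samples but the variance estimate absorbs the
  induced autocorrelation.
- *Selection/inference split* (COP): many random patterns are tried, which
  is a multiple-comparison problem; Bonferroni over patterns is hopeless
  here because the per-pattern tests are strongly dependent (rejection rate
  ≈ 0 instead of α). Instead the first half of the series selects the most
  discriminating pattern (largest KS distance) and the second half alone
  produces the reported KS p — a clean true p-value at the cost of halving
  the sample.

With these choices every native test's rejection rate on iid Gaussian
series (N = 1000) sits inside the 99% binomial envelope of α = 0.05 over
hundreds of replicates, which the test suite verifies. On dependent but
reversible input (a stationary Ornstein–Uhlenbeck path) several tests
become conservative — the HAC/blocking corrections are sized for the iid
null — which errs on the safe side: a reversible process is not flagged.

## Utilities

- **Downsampling** to scale τ: `skip` (first observation of each block,
  length ⌈N/τ⌉), `average` (block means over complete blocks, length
  ⌊N/τ⌋), `decimate` (order-8 Chebyshev-I low-pass at 0.8 of the new
  Nyquist applied zero-phase, then every τ-th sample — scipy's standard
  decimation). τ = 1 is the identity.
- **Parameter optimisation**: exhaustive grid search; per-series p-values
  are combined by Fisher's method (a median-p alternative is exposed for
  robustness) and the arg-min combination returned. The Fisher tail is
  evaluated in log space with an asymptotic upper-incomplete-gamma
  expansion, because ensembles of strongly irreversible series produce
  combined p-values far below double-precision underflow and comparing
  underflowed zeros would turn the arg-min into a tie-break. Failing grid
  points are recorded and skipped. To avoid overfitting, tune on one part
  of the data and evaluate on the rest — the optimiser itself takes
  whatever ensemble it is given.
- **Manipulation**: `numIterations` random COPs are tried; each candidate
  series is the distance transcription of the input (length N − pSize + 1,
  aligned to window starts, which is also the support used for the Pearson
  correlation with the original). In increase mode the candidate with the
  highest correlation among those with p ≤ `pvThreshold` wins (decrease
  mode: p ≥ threshold); if none qualifies, the best-achieved candidate is
  returned with `success=False` rather than raising. On iid uniform input
  with the defaults (1000 iterations, pSize 4, threshold 0.01) the winner
  typically keeps a correlation of ≈ 0.6–0.7 with the original — the
  distance transform is level-free, so the correlation is mediated by each
  point's excursion relative to its window, which caps it near 0.7.

## Synthetic generators

The generator zoo provides series of *known* irreversibility status, used
throughout the tests: the fully chaotic logistic map (r = 4; strongly
irreversible), Hénon (a = 1.4, b = 0.3), a linear congruential generator,
the Lorenz system (σ = 10, ρ = 28, β = 8/3, RK4 at dt = 0.01), a stationary
Ornstein–Uhlenbeck path (exact AR(1) discretisation, default θ = 1, σ = 1,
dt = 0.5 giving lag-1 correlation e^{−0.5} ≈ 0.61; reversible by
construction), geometric Brownian motion with Poissonian resetting
(μ = 0.05, σ = 0.2, reset rate 0.05 per unit time; the resets produce a
sawtooth and strong irreversibility), an asymmetric Weierstrass-type
fractal (geometric harmonics with phase coupling across scales; the
phase-coupling parameter breaks time symmetry), a scale-specific model (a
chaotic skeleton at one sample every `scale`, joined by reversible
Brownian-bridge in-fill: skip-downsampling at τ = scale exposes the
irreversibility, much coarser averaging destroys it), and a biased symbolic
ring walk (p_up ≠ 0.5 circulates a probability current, breaking detailed
balance).

These emulate the *mechanisms* of irreversibility, not the messiness of
real recordings: no measurement noise, artefacts, missing samples or
nonstationarity. Passing the suite shows the statistics behave correctly on
clean realisations of known processes; on real data, parameter optimisation
on a held-out subset and comparison across several tests remain essential.

## Numerical conventions

- NaN/inf values are rejected, never imputed; constant series (or constant
  derived samples) raise a series error where a statistic is undefined.
- Rank ties break earlier-index-first (stable sort) everywhere ordinal
  structure is used; COP windows with zero spread are skipped with a
  warning; equal-value bars block horizontal visibility.
- Per-test minimum lengths: 200 for BDS and Diks, 3·window for Zumbach, 50
  for the other continuous tests.
- Problem sizes in the test suite (series of 10^3–10^4 points, ensembles of
  100 series, 200-replicate calibration batteries) are chosen to make every
  check decisive on a single CPU in minutes.

## Known limitations

- Univariate, evenly sampled, stationary series only.
- Shuffle surrogates test against the *iid* reversible null; on
  non-stationary input (e.g. an unbounded random walk) a surrogate-based
  test can reject even though the generating process is reversible.
- The z-score surrogate scheme is an approximation by design.
- The COP selection/inference split halves the effective sample; on very
  short series (N ≲ 100) the COP test is underpowered.
- BDS should be read as a test of temporal dependence, not of
  irreversibility proper (see above).
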