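# irrev

Time-irreversibility analysis of univariate time series.

A stationary series is *time-reversible* when it is statistically
indistinguishable from its time-reversed copy (the transformation t → −t).
Reversibility is the hallmark of linear Gaussian dynamics; broken time
symmetry signals nonlinearity, non-Gaussian driving, memory, or
out-of-equilibrium behaviour, and has become a working tool for heartbeat,
brain-activity and financial series. Because "statistically different
backwards" does not say *which* statistic differs, many tests coexist —
built on increments, ordinal patterns, visibility graphs, correlation
integrals, entropy production, volatilities — and they can disagree on the
same data.

`irrev` packages **18 irreversibility tests** (16 for real-valued series,
2 for symbolic ones) behind one contract:

```
result = test(x)          # -> TestResult(pvalue, statistic)
```

plus the machinery around them:

- **surrogate significance** — measures without a native null are compared
  against ensembles of shuffled copies of the series, with a proportional
  scheme (true p-value, floor 1/S) or a z-score scheme (cheap
  approximation);
- **multiscale downsampling** — skip / block-average / anti-aliased
  decimation;
- **parameter optimisation** — grid search minimising the Fisher-combined
  p-value over an ensemble of series;
- **irreversibility manipulation** — Continuous-Ordinal-Pattern transforms
  that increase or decrease a series' irreversibility while staying
  correlated with the original;
- **generators** of series with known status: logistic/Hénon/LCG maps,
  Lorenz, Ornstein–Uhlenbeck (reversible), srGBM (irreversible),
  asymmetric Weierstrass, a scale-specific irreversible model, and a
  biased symbolic walk.

See `docs/methods.md` for the statistics, their null distributions, and
the calibration design.

## Worked example

```python
import irrev
from irrev.generators import logistic
from irrev.toolkit import downsample

x = logistic(10_000, r=4.0, seed=7)        # fully chaotic: irreversible

p, s = irrev.cop(x, pSize=3, seed=7)       # Continuous Ordinal Patterns
print(f"COP: p = {p:.3e}, KS distance = {s:.3f}")

p, s = irrev.pomeau(x, seed=7)             # surrogate-based measure
print(f"Pomeau: p = {p}, statistic = {s:.4f}")

y = downsample(x, "average", 2)            # coarse-grain to scale 2
print(f"COP after tau=2 averaging: p = {irrev.cop(y, seed=7).pvalue:.4f}")
```

prints

```
COP: p = 3.683e-49, KS distance = 0.361
Pomeau: p = 0.01, statistic = 0.0315
COP after tau=2 averaging: p = 0.0300
```

The chaotic orbit is overwhelmingly irreversible (COP p ≈ 10⁻⁴⁹). The
Pomeau statistic 0.0315 beats all 100 shuffled surrogates, so its
proportional p-value saturates the 1/S floor of 0.01. After averaging
pairs of observations the COP p-value rises above 0.01: the logistic map
has no multiscale structure, and one step of coarse-graining already
destroys the asymmetry its chaos creates.

Every test is also reachable through the registry, which makes sweeps
one-liners:

```python
for name, test in irrev.allTests:        # 18 (name, descriptor) pairs
    print(name, test(series_for(test)))
```

A command-line interface mirrors the library:

```sh
irrev generate --model logistic --n 10000 --seed 1 --output x.txt
irrev test --test COP --input x.txt --seed 7
irrev battery --input x.txt --surrogates 100 --method proportional
irrev downsample --method average --tau 2 --input x.txt --output y.txt
irrev optimise --test COP --inputs series_dir/ --grid pSize=3:6
irrev manipulate --increase --numIterations 1000 --pSize 4 \
      --pvThreshold 0.01 --input x.txt --seed 1
```

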