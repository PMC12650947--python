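"""Surrogate-based significance: turning a bare measure into a p-value.

Several asymmetry statistics (Casali, Costa, Pomeau, Gaspard) quantify the
magnitude of irreversibility without carrying a null distribution of their
own.  The package converts them into tests by comparing the observed value
against an ensemble of randomly *shuffled* copies of the same series.
Shuffling destroys all temporal relations — and with them, by definition,
any time irreversibility — while conserving the value multiset exactly, so
the ensemble samples the reversible null.

Two schemes are offered:

``proportional``
    The fraction of surrogates whose statistic equals or exceeds the
    observed one.  A true p-value, but granular: with ``S`` surrogates the
    smallest attainable p is ``1/S`` (0.01 at the default ``S=100``).

``zscore``
    The observed statistic is standardised against the surrogate mean and
    standard deviation and referred to a standard normal.  Cheap (``S=20``
    suffices in practice) but only an approximation — the surrogate
    distribution need not be normal, so the result is not a true p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .core import TestResult, as_real_series

__all__ = [
    "SurrogatePlan",
    "shuffle_surrogates",
    "proportional_pvalue",
    "zscore_pvalue",
    "surrogate_test",
]

DEFAULT_S = {"proportional": 100, "zscore": 20}


@dataclass(frozen=True)
class SurrogatePlan:
    """How a measure is converted into a p-value.

    Parameters
    ----------
    method:
        ``"proportional"`` or ``"zscore"``.
    S:
        Ensemble size (number of shuffled series).  Defaults to 100 for the
        proportional scheme and 20 for the z-score one.
    seed:
        Seed for the shuffling RNG; fixing it makes the p-value reproducible
        bit-for-bit.
    tail:
        ``"upper"`` (statistics are oriented so larger means more
        irreversible) or ``"two_sided"`` for the z-score scheme.
    """

    method: str = "proportional"
    S: int | None = None
    seed: int | None = None
    tail: str = "upper"

    def __post_init__(self):
        if self.method not in ("proportional", "zscore"):
            raise ValueError(f"unknown surrogate method {self.method!r}")
        if self.tail not in ("upper", "two_sided"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.S is not None and self.S < 1:
            raise ValueError("surrogate ensemble size S must be >= 1")

    @property
    def size(self) -> int:
        return self.S if self.S is not None else DEFAULT_S[self.method]


def shuffle_surrogates(x, S: int, seed=None) -> list[np.ndarray]:
    """Return ``S`` independent uniform random permutations of ``x``.

    Each surrogate has exactly the same value multiset (hence mean,
    variance, and marginal distribution) as the original series.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    arr = as_real_series(x)
    rng = np.random.default_rng(seed)
    return [rng.permutation(arr) for _ in range(S)]


def proportional_pvalue(stat_obs: float, stat_null: Sequence[float], S: int | None = None) -> float:
    """p = max(c, 1)/S with c = #{null statistics >= observed}.

    The lower clamp makes the minimum attainable p exactly ``1/S``; ties
    count ("equal to or higher").
    """
    null = np.asarray(stat_null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null ensemble")
    if S is None:
        S = null.size
    elif S != null.size:
        raise ValueError(f"null ensemble has {null.size} entries, expected S={S}")
    c = int(np.count_nonzero(null >= stat_obs))
    return max(c, 1) / S


def zscore_pvalue(stat_obs: float, stat_null: Sequence[float], tail: str = "upper") -> float:
    """Normal-approximation p from the surrogate z-score.

    Not a true p-value (the null distribution is only approximated as
    normal), but usable with ensembles as small as 20.
    """
    null = np.asarray(stat_null, dtype=float)
    if null.size < 2:
        raise ValueError("z-score scheme needs >= 2 surrogates")
    sd = null.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate null: zero spread across surrogates")
    z = (stat_obs - null.mean()) / sd
    if tail == "upper":
        return float(stats.norm.sf(z))
    return float(2.0 * stats.norm.sf(abs(z)))


def surrogate_test(
    measure: Callable[[np.ndarray], float],
    x,
    plan: SurrogatePlan | None = None,
    *,
    statistic: float | None = None,
) -> TestResult:
    """Wrap a bare measure into a TestResult via shuffled surrogates.

    ``measure`` must be oriented so that larger values mean more
    irreversible (wrappers take absolute values of signed statistics).
    ``statistic``, if given, is reported in place of ``measure(x)`` — used
    by tests whose displayed statistic is signed while the comparison runs
    on its magnitude.
    """
    if plan is None:
        plan = SurrogatePlan()
    arr = as_real_series(x)
    stat_obs = float(measure(arr))
    rng = np.random.default_rng(plan.seed)
    null = np.empty(plan.size)
    for j in range(plan.size):
        null[j] = measure(rng.permutation(arr))
    if plan.method == "proportional":
        p = proportional_pvalue(stat_obs, null)
    else:
        p = zscore_pvalue(stat_obs, null, tail=plan.tail)
    reported = stat_obs if statistic is None else float(statistic)
    return TestResult(pvalue=float(p), statistic=reported)
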