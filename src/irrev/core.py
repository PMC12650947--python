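"""Shared domain types, the uniform test contract, and the test registry.

A time series is *irreversible* when its statistical properties change under
the transformation ``t -> -t``, i.e. when the series read backwards is
distinguishable from the series read forwards.  Every test in this package,
whatever its internal machinery, answers that single question through a
common contract: it receives a univariate series and returns a
:class:`TestResult` holding a p-value and a test statistic.

Real-valued series are plain 1-D float arrays; symbolic series are 1-D
arrays of hashable tokens (integers or strings).  Both are validated, never
imputed: a NaN or infinite entry is an error, because silently repairing a
value would corrupt the very temporal structure under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "TestResult",
    "TestDescriptor",
    "SeriesError",
    "as_real_series",
    "as_symbol_series",
    "reverse",
    "register",
    "get_test",
    "all_tests",
    "continuous_tests",
    "discrete_tests",
]


class SeriesError(ValueError):
    """Raised when an input series violates a test's preconditions."""


class TestResult(NamedTuple):
    """Uniform output of every irreversibility test.

    Attributes
    ----------
    pvalue:
        Significance of the observed asymmetry, in ``[0, 1]``.
    statistic:
        Test-specific magnitude of the asymmetry (finite real; signed where
        the underlying quantity has a natural orientation).
    """

    pvalue: float
    statistic: float


@dataclass(frozen=True)
class TestDescriptor:
    """Registry entry making every test interchangeable.

    ``function`` accepts a series as first argument plus keyword parameters
    and returns a :class:`TestResult`.  ``significance_modes`` records how a
    p-value can be obtained: ``native`` (the test has its own distributional
    p-value), ``proportional`` and/or ``zscore`` (surrogate ensembles).
    ``sided`` records the orientation of the native p-value.
    """

    name: str
    function: Callable[..., TestResult]
    value_kind: str  # "continuous" | "discrete"
    significance_modes: frozenset[str]
    default_params: Mapping[str, Any] = field(default_factory=dict)
    param_grid: Mapping[str, Sequence[Any]] = field(default_factory=dict)
    analysis_class: str = ""
    sided: str = "two-sided"
    min_length: int = 50

    def __call__(self, x, **params) -> TestResult:
        merged = {**self.default_params, **params}
        return self.function(x, **merged)


# ---------------------------------------------------------------------------
# Series validation and reversal


def as_real_series(x, min_length: int = 2, require_variance: bool = False) -> np.ndarray:
    """Validate and return ``x`` as a 1-D float64 array.

    Raises :class:`SeriesError` if the series is shorter than ``min_length``,
    contains non-finite entries, or (when ``require_variance``) is constant.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SeriesError(f"expected a univariate series, got shape {arr.shape}")
    if arr.size < min_length:
        raise SeriesError(f"series too short: N={arr.size} < {min_length}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise SeriesError(f"non-finite value at index {bad}; missing data are not imputed")
    if require_variance and np.ptp(arr) == 0.0:
        raise SeriesError("series has zero variance")
    return arr


def as_symbol_series(s, min_length: int = 2, alphabet: Sequence | None = None) -> np.ndarray:
    """Validate a symbolic series (1-D array of tokens).

    If ``alphabet`` is given, every symbol must belong to it; otherwise the
    alphabet is inferred from the data.
    """
    arr = np.asarray(s)
    if arr.ndim != 1:
        raise SeriesError(f"expected a univariate symbol series, got shape {arr.shape}")
    if arr.size < min_length:
        raise SeriesError(f"series too short: N={arr.size} < {min_length}")
    if arr.dtype.kind == "f" and not np.all(np.isfinite(arr)):
        raise SeriesError("non-finite symbol")
    if alphabet is not None:
        extra = set(arr.tolist()) - set(alphabet)
        if extra:
            raise SeriesError(f"symbols outside alphabet: {sorted(map(str, extra))}")
    return arr


def reverse(x):
    """Time-reverse a series: ``rev(x)_i = x_{N+1-i}``.  An involution."""
    return np.asarray(x)[::-1]


# ---------------------------------------------------------------------------
# Registry

_REGISTRY: dict[str, TestDescriptor] = {}


def register(descriptor: TestDescriptor) -> TestDescriptor:
    if descriptor.name in _REGISTRY:
        raise ValueError(f"duplicate test name: {descriptor.name}")
    if not descriptor.significance_modes:
        raise ValueError(f"{descriptor.name}: empty significance_modes")
    _REGISTRY[descriptor.name] = descriptor
    return descriptor


def get_test(name: str) -> TestDescriptor:
    """Look a test up by its registry name (case-insensitive)."""
    _ensure_loaded()
    try:
        return _REGISTRY[name]
    except KeyError:
        for key, desc in _REGISTRY.items():
            if key.lower() == name.lower():
                return desc
        raise KeyError(
            f"unknown test {name!r}; available: {', '.join(sorted(_REGISTRY))}"
        ) from None


def all_tests() -> list[TestDescriptor]:
    """All registered tests (continuous first, then discrete), fixed order."""
    _ensure_loaded()
    return sorted(
        _REGISTRY.values(), key=lambda d: (d.value_kind != "continuous", d.name.lower())
    )


def continuous_tests() -> list[TestDescriptor]:
    return [d for d in all_tests() if d.value_kind == "continuous"]


def discrete_tests() -> list[TestDescriptor]:
    return [d for d in all_tests() if d.value_kind == "discrete"]


def _ensure_loaded() -> None:
    # Test modules self-register on import; import lazily to avoid cycles.
    if len(_REGISTRY) < 18:
        from . import tests_continuous, tests_discrete  # noqa: F401
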