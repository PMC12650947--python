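"""Continuous Ordinal Patterns (COPs).

A COP generalises the ordinal (permutation) pattern: instead of a rank
sequence, the reference is an arbitrary real-valued shape of length
``pSize``, normalised to zero mean and unit maximum absolute deviation.  A
series is transcribed into the sequence of distances between the shape and
every (identically normalised) sliding window, so similar window shapes map
to small distances.  The same machinery drives both the COP irreversibility
test and the irreversibility-manipulation algorithm.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import SeriesError, as_real_series

__all__ = ["normalize_pattern", "random_pattern", "normalized_windows", "distance_profile"]


def normalize_pattern(values) -> np.ndarray:
    """Zero-mean, max-abs-one normalisation (idempotent)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise SeriesError("a pattern needs at least 2 values")
    v = v - v.mean()
    scale = np.max(np.abs(v))
    if scale == 0.0:
        raise SeriesError("constant pattern cannot be normalised")
    return v / scale


def random_pattern(pSize: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a random COP: iid uniform(-1, 1) values, then normalised."""
    if pSize < 2:
        raise SeriesError("pSize must be >= 2")
    while True:
        raw = rng.uniform(-1.0, 1.0, size=pSize)
        if np.ptp(raw) > 0:
            return normalize_pattern(raw)


def normalized_windows(x, pSize: int) -> tuple[np.ndarray, np.ndarray]:
    """All stride-1 windows of ``x``, each normalised like a pattern.

    Returns ``(W, valid)`` where ``W`` has shape ``(N - pSize + 1, pSize)``
    and ``valid`` flags windows with non-zero spread; constant windows are
    undefined under the normalisation and are excluded (with a warning).
    """
    arr = as_real_series(x, min_length=pSize)
    W = sliding_window_view(arr, pSize).astype(float)
    W = W - W.mean(axis=1, keepdims=True)
    scale = np.max(np.abs(W), axis=1)
    valid = scale > 0.0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} constant window(s) skipped in COP transcription",
            stacklevel=2,
        )
    out = np.zeros_like(W)
    out[valid] = W[valid] / scale[valid, None]
    return out, valid


def distance_profile(pattern: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Mean absolute difference between the pattern and each window row."""
    return np.abs(W - pattern).mean(axis=1)
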