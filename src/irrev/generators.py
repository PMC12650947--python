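"""Generators of synthetic series with known (ir)reversibility.

These serve two purposes: validating the tests (a chaotic logistic orbit is
strongly irreversible; a stationary Ornstein–Uhlenbeck path is a linear
Gaussian process and hence reversible) and exercising full analysis
pipelines without external data.  All stochastic generators are seedable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "logistic",
    "henon",
    "lcg",
    "lorenz",
    "ornstein_uhlenbeck",
    "srgbm",
    "weierstrass_asym",
    "multiscale_irreversible",
    "symbolic_walk",
]


def logistic(n: int, r: float = 4.0, x0: float | None = None, burn_in: int = 1000, seed=None) -> np.ndarray:
    """Logistic map ``x_{k+1} = r x_k (1 - x_k)``; chaotic and irreversible at r=4.

    ``x0`` defaults to a random point in (0, 1); x0 = 0.5 is rejected (it
    maps to the degenerate orbit 1, 0, 0, ... at r = 4).
    """
    if not 0.0 < r <= 4.0:
        raise ValueError("r must be in (0, 4]")
    if x0 is None:
        x0 = float(np.random.default_rng(seed).uniform(0.05, 0.95))
    if not 0.0 < x0 < 1.0 or x0 == 0.5:
        raise ValueError("x0 must lie in (0, 1), excluding 0.5")
    total = n + burn_in
    out = np.empty(total)
    x = x0
    for k in range(total):
        x = r * x * (1.0 - x)
        out[k] = x
    return out[burn_in:]


def henon(n: int, a: float = 1.4, b: float = 0.3, burn_in: int = 1000, seed=None) -> np.ndarray:
    """x-coordinate of the Hénon map with the classic chaotic parameters."""
    rng = np.random.default_rng(seed)
    x, y = rng.uniform(-0.1, 0.1, size=2)
    out = np.empty(n + burn_in)
    for k in range(n + burn_in):
        x, y = 1.0 - a * x * x + y, b * x
        out[k] = x
    return out[burn_in:]


def lcg(n: int, a: int = 1664525, c: int = 1013904223, mod: int = 2**32, seed: int = 12345) -> np.ndarray:
    """Linear congruential generator orbit, scaled to [0, 1)."""
    out = np.empty(n)
    state = int(seed) % mod
    for k in range(n):
        state = (a * state + c) % mod
        out[k] = state / mod
    return out


def lorenz(
    n: int,
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    dt: float = 0.01,
    burn_in: int = 1000,
    seed=None,
) -> np.ndarray:
    """First coordinate of the Lorenz system, fixed-step RK4 integration."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    state = np.array([1.0, 1.0, 1.0]) + rng.normal(0, 0.1, size=3)

    def deriv(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    out = np.empty(n + burn_in)
    for k in range(n + burn_in):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k] = state[0]
    return out[burn_in:]


def ornstein_uhlenbeck(
    n: int, theta: float = 1.0, sigma: float = 1.0, dt: float = 0.5, x0: float | None = None, seed=None
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path (exact AR(1) discretisation).

    A linear Gaussian process: reversible, so no test should flag it beyond
    its nominal rate.  ``x0`` defaults to a draw from the stationary law.
    """
    if theta <= 0 or sigma <= 0 or dt <= 0:
        raise ValueError("theta, sigma and dt must be positive")
    rng = np.random.default_rng(seed)
    phi = np.exp(-theta * dt)
    sd_stat = sigma / np.sqrt(2.0 * theta)
    sd_step = sd_stat * np.sqrt(1.0 - phi * phi)
    x = float(rng.normal(0.0, sd_stat)) if x0 is None else float(x0)
    out = np.empty(n)
    noise = rng.normal(0.0, sd_step, size=n)
    for k in range(n):
        x = phi * x + noise[k]
        out[k] = x
    return out


def srgbm(
    n: int,
    mu: float = 0.05,
    sigma: float = 0.2,
    reset_rate: float = 0.05,
    dt: float = 0.1,
    x0: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Geometric Brownian motion with Poissonian stochastic resetting.

    Multiplicative growth punctuated by resets to ``x0`` at rate
    ``reset_rate`` produces a sawtooth-like, strongly irreversible
    stationary process.
    """
    if sigma <= 0 or dt <= 0 or reset_rate < 0 or x0 <= 0:
        raise ValueError("invalid srGBM parameters")
    rng = np.random.default_rng(seed)
    steps = np.exp((mu - 0.5 * sigma**2) * dt + sigma * np.sqrt(dt) * rng.normal(size=n))
    resets = rng.random(n) < -np.expm1(-reset_rate * dt)
    out = np.empty(n)
    x = x0
    for k in range(n):
        x = x0 if resets[k] else x * steps[k]
        out[k] = x
    return out


def weierstrass_asym(
    n: int,
    a: float = 0.6,
    b: float = 3.0,
    k_max: int = 12,
    phase: float = 0.7,
    dt: float = 1e-3,
    t0: float = 0.0,
) -> np.ndarray:
    """Asymmetric Weierstrass-type fractal signal.

    Sum of geometrically scaled harmonics ``sum_k a^k sin(2 pi b^k t +
    phase * k)``; the phase coupling across scales breaks the time symmetry
    that a pure cosine Weierstrass function would have.  Deterministic.
    """
    if not 0 < a < 1 or b <= 1:
        raise ValueError("need 0 < a < 1 and b > 1")
    t = t0 + dt * np.arange(n)
    out = np.zeros(n)
    for k in range(k_max + 1):
        out += a**k * np.sin(2.0 * np.pi * b**k * t + phase * k)
    return out


def multiscale_irreversible(n: int, scale: int = 8, noise: float = 0.2, seed=None) -> np.ndarray:
    """Series irreversible at one specific time scale.

    A strongly irreversible coarse skeleton (a chaotic logistic orbit, one
    point every ``scale`` samples) is joined by linear interpolation plus a
    Brownian-bridge filler — a time-reversible in-fill.  Skip-downsampling
    at tau = ``scale`` recovers the skeleton (irreversibility detectable);
    averaging at tau much larger than ``scale`` mixes skeleton points and
    washes it out.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    rng = np.random.default_rng(seed)
    n_coarse = int(np.ceil(n / scale)) + 1
    coarse = logistic(n_coarse, seed=rng.integers(2**31))
    if scale == 1:
        return coarse[:n]
    sd_bridge = noise * coarse.std()
    out = np.empty((n_coarse - 1) * scale)
    frac = np.arange(scale) / scale
    for j in range(n_coarse - 1):
        seg = coarse[j] + (coarse[j + 1] - coarse[j]) * frac
        w = np.concatenate(([0.0], np.cumsum(rng.normal(0, 1, scale - 1))))
        bridge = w - frac * w[-1] if scale > 1 else w
        out[j * scale : (j + 1) * scale] = seg + sd_bridge * bridge / np.sqrt(scale)
    return out[:n]


def symbolic_walk(n: int, n_states: int = 6, p_up: float = 0.5, seed=None, alphabet=None) -> np.ndarray:
    """Biased random walk on a ring of ``n_states`` symbols.

    With ``p_up != 0.5`` a net probability current circulates around the
    ring, breaking detailed balance: the symbol stream is irreversible.
    ``alphabet`` optionally maps states to tokens.
    """
    if n_states < 2 or not 0.0 < p_up < 1.0:
        raise ValueError("need n_states >= 2 and 0 < p_up < 1")
    rng = np.random.default_rng(seed)
    steps = np.where(rng.random(n) < p_up, 1, -1)
    states = np.mod(rng.integers(n_states) + np.cumsum(steps), n_states)
    if alphabet is not None:
        if len(alphabet) != n_states:
            raise ValueError("alphabet size must equal n_states")
        return np.asarray(alphabet)[states]
    return states
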