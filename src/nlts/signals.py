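"""Deterministic, seedable benchmark-signal generators.

Every validation signal used by the test-suite and the examples is generated
here: the chaotic Lorenz system, the logistic map, correlated Gaussian pairs
and compound (sine / sawtooth / square) oscillations.  All generators are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .embedding import TimeSeries

__all__ = [
    "LorenzParams",
    "LogisticParams",
    "GaussianPairParams",
    "generate_lorenz",
    "generate_logistic",
    "generate_gaussian_pair",
    "generate_compound_oscillation",
    "lorenz_derivative",
]


@dataclass
class LorenzParams:
    """Parameters of the Lorenz convection model.

    ``a`` is the Prandtl-like rate, ``b`` the Rayleigh-like forcing and ``c``
    the geometric damping; the canonical chaotic regime is (10, 28, 8/3).
    """

    a: float = 10.0
    b: float = 28.0
    c: float = 8.0 / 3.0
    fs: float = 40.0
    duration: float = 250.0
    initial_state: np.ndarray | None = None
    seed: int = 0
    transient: float = 10.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")


@dataclass
class LogisticParams:
    """Parameters of the logistic map x_{n+1} = a x_n (1 - x_n)."""

    a: float = 3.92
    x0: float = 0.5
    n: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.x0 < 1.0:
            raise ValueError("x0 must lie strictly inside (0, 1)")
        if not 0.0 < self.a <= 4.0:
            raise ValueError("a must lie in (0, 4] to keep the orbit in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be at least 1")


@dataclass
class GaussianPairParams:
    """Parameters of a bivariate Gaussian sample."""

    n: int = 10_000
    sigma_x: float = 1.0
    sigma_y: float = 1.0
    cov: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.cov) > self.sigma_x * self.sigma_y + 1e-12:
            raise ValueError("|cov| may not exceed sigma_x * sigma_y")


def lorenz_derivative(state: np.ndarray, a: float = 10.0, b: float = 28.0,
                      c: float = 8.0 / 3.0) -> np.ndarray:
    """Vector field of the Lorenz system at ``state`` = (X, Y, Z)."""
    x, y, z = state
    return np.array([a * (y - x), x * (b - z) - y, x * y - c * z])


def _rk4(state: np.ndarray, dt: float, a: float, b: float, c: float) -> np.ndarray:
    k1 = lorenz_derivative(state, a, b, c)
    k2 = lorenz_derivative(state + 0.5 * dt * k1, a, b, c)
    k3 = lorenz_derivative(state + 0.5 * dt * k2, a, b, c)
    k4 = lorenz_derivative(state + dt * k3, a, b, c)
    return state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def generate_lorenz(params: LorenzParams | None = None, *,
                    substeps: int = 10) -> tuple[TimeSeries, np.ndarray]:
    """Integrate the Lorenz system and return its X component.

    Fixed-step RK4 with ``substeps`` internal steps per output sample keeps
    the trajectory reproducible; an initial transient of ``params.transient``
    seconds is discarded so the recorded orbit lies on the attractor.  If no
    initial state is supplied, one is drawn uniformly in [-10, 10]^3 from the
    seeded generator.

    Returns
    -------
    (x, trajectory)
        ``x`` is the X component as a :class:`TimeSeries` with
        ``duration * fs`` samples, ``trajectory`` the full (n, 3) orbit.
    """
    if params is None:
        params = LorenzParams()
    rng = np.random.default_rng(params.seed)
    if params.initial_state is None:
        state = rng.uniform(-10.0, 10.0, size=3)
    else:
        state = np.asarray(params.initial_state, dtype=float).copy()
    dt = 1.0 / (substeps * params.fs)

    n_transient = int(round(params.transient * params.fs))
    n_out = int(round(params.duration * params.fs))
    traj = np.empty((n_out, 3))
    for i in range(n_transient + n_out):
        for _ in range(substeps):
            state = _rk4(state, dt, params.a, params.b, params.c)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(
                f"Lorenz integration diverged at output sample {i}")
        if i >= n_transient:
            traj[i - n_transient] = state
    ts = TimeSeries(traj[:, 0].copy(), fs=params.fs, label="lorenz_x")
    return ts, traj


def generate_logistic(params: LogisticParams | None = None) -> TimeSeries:
    """Iterate the logistic map x_{n+1} = a x_n (1 - x_n)."""
    if params is None:
        params = LogisticParams()
    x = np.empty(params.n)
    x[0] = params.x0
    for i in range(1, params.n):
        x[i] = params.a * x[i - 1] * (1.0 - x[i - 1])
    return TimeSeries(x, fs=None, label="logistic")


def generate_gaussian_pair(params: GaussianPairParams | None = None
                           ) -> tuple[TimeSeries, TimeSeries]:
    """Draw a correlated bivariate Gaussian sample as two series."""
    if params is None:
        params = GaussianPairParams()
    rng = np.random.default_rng(params.seed)
    cov = np.array([[params.sigma_x ** 2, params.cov],
                    [params.cov, params.sigma_y ** 2]])
    # Cholesky-style construction keeps the cov=sigma_x*sigma_y case exact.
    z = rng.standard_normal((params.n, 2))
    x = params.sigma_x * z[:, 0]
    rho = params.cov / (params.sigma_x * params.sigma_y)
    y = params.sigma_y * (rho * z[:, 0] + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z[:, 1])
    del cov
    return (TimeSeries(x, fs=None, label="gauss_x"),
            TimeSeries(y, fs=None, label="gauss_y"))


_WAVEFORMS = ("sine", "sawtooth", "square")


def generate_compound_oscillation(freq: float, fs: float, segment_duration: float,
                                  shapes: list[str] | tuple[str, ...] = _WAVEFORMS,
                                  noise_frac: float = 0.0, seed: int = 0,
                                  amplitude: float = 1.0) -> TimeSeries:
    """Concatenate constant-frequency segments of different waveform shapes.

    Each entry of ``shapes`` ("sine", "sawtooth", "square") produces one
    segment of ``segment_duration`` seconds at ``freq`` Hz.  Optional white
    Gaussian noise is added with standard deviation ``noise_frac`` times the
    SD of the raw (noise-free) signal.
    """
    if fs <= 2 * freq:
        raise ValueError("fs must exceed twice the oscillation frequency")
    n_seg = int(round(segment_duration * fs))
    t = np.arange(n_seg) / fs
    phase = 2 * np.pi * freq * t
    parts = []
    for shape in shapes:
        if shape == "sine":
            parts.append(amplitude * np.sin(phase))
        elif shape == "sawtooth":
            parts.append(amplitude * _sig.sawtooth(phase))
        elif shape == "square":
            parts.append(amplitude * _sig.square(phase))
        else:
            raise ValueError(f"unknown waveform shape: {shape!r}")
    x = np.concatenate(parts)
    if noise_frac:
        rng = np.random.default_rng(seed)
        x = x + noise_frac * np.std(x) * rng.standard_normal(x.size)
    return TimeSeries(x, fs=fs, label="compound")
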