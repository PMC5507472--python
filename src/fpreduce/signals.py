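"""Uniformly sampled time series and synthetic input generation.

The external drive of the population is described by two time-varying
moments, the mean input mu_ext(t) (mV/ms) and the noise intensity
sigma_ext^2(t) (mV^2/ms).  Both are modelled as Ornstein-Uhlenbeck (OU)
processes smoothed with a narrow Gaussian kernel so that the second-order
reduced models, which see the first two time derivatives of the input,
receive a twice-differentiable signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .params import OUParams

log = logging.getLogger(__name__)

__all__ = ["Signal", "ou_process", "gaussian_smooth", "clamp_variance_floor"]


@dataclass
class Signal:
    """A uniformly sampled real-valued time series starting at ``t0`` (ms)."""

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-d sequence")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    def resample(self, dt: float, n: int | None = None) -> "Signal":
        """Linear interpolation onto a new grid with spacing ``dt``."""
        if n is None:
            n = int(np.floor(self.duration / dt)) + 1
        t_new = self.t0 + dt * np.arange(n)
        vals = np.interp(t_new, self.times, self.values)
        return Signal(self.t0, dt, vals)

    def derivative(self) -> "Signal":
        """Central-difference time derivative (one-sided at the ends)."""
        return Signal(self.t0, self.dt,
                      np.gradient(self.values, self.dt, edge_order=2))

    def to_csv(self, path, units: str = "") -> None:
        header = f"t_ms,value{',' + units if units else ''}"
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "Signal":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        t, v = data[:, 0], data[:, 1]
        dt = t[1] - t[0]
        if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform time grid in CSV")
        return cls(float(t[0]), float(dt), v)

    @classmethod
    def constant(cls, value: float, dt: float, T: float,
                 t0: float = 0.0) -> "Signal":
        n = int(round(T / dt)) + 1
        return cls(t0, dt, np.full(n, float(value)))


def ou_process(params: OUParams, dt: float, T: float, seed: int) -> Signal:
    """Exact-discretization Ornstein-Uhlenbeck sample path on [0, T].

    Uses the exact transition x_{n+1} = mean + (x_n - mean) e^{-dt/tau}
    + theta sqrt(1 - e^{-2 dt/tau}) z_n, initialized from the stationary law
    Normal(mean, theta^2), so the marginal statistics are unbiased at any dt.
    """
    if dt <= 0 or T <= 0:
        raise ValueError("dt and T must be positive")
    if dt >= params.tau_ou / 2:
        raise ValueError("dt must resolve the OU correlation time (dt < tau_ou/2)")
    n = int(round(T / dt)) + 1
    rng = np.random.default_rng(seed)
    if params.theta == 0.0:
        return Signal(0.0, dt, np.full(n, params.mean))
    rho = np.exp(-dt / params.tau_ou)
    innov = params.theta * np.sqrt(1.0 - rho * rho)
    z = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = params.mean + params.theta * z[0]
    for k in range(1, n):
        x[k] = params.mean + rho * (x[k - 1] - params.mean) + innov * z[k]
    return Signal(0.0, dt, x)


def gaussian_smooth(x: Signal, sigma_t: float) -> Signal:
    """Convolution with a normalized Gaussian kernel of width sigma_t (ms).

    The kernel is truncated at +-4 sigma_t and the boundary is handled by
    edge replication; sigma_t = 0 returns the input unchanged.  Benchmarks
    discard an initial transient, which makes the edge policy immaterial.
    """
    if sigma_t < 0:
        raise ValueError("sigma_t must be nonnegative")
    if sigma_t == 0.0:
        return Signal(x.t0, x.dt, x.values.copy())
    half = max(1, int(np.ceil(4.0 * sigma_t / x.dt)))
    u = np.arange(-half, half + 1) * x.dt
    kern = np.exp(-0.5 * (u / sigma_t) ** 2)
    kern /= kern.sum()
    padded = np.concatenate([
        np.full(half, x.values[0]), x.values, np.full(half, x.values[-1])
    ])
    vals = np.convolve(padded, kern, mode="valid")
    return Signal(x.t0, x.dt, vals)


def clamp_variance_floor(x: Signal, floor_sq: float = 0.25) -> Signal:
    """Clamp rare negative/low excursions of a sigma^2 process at the floor.

    An OU model for sigma_ext^2(t) is unbounded below; parametrizations for
    which P(sigma^2 < floor) is non-negligible (> 1%) are rejected, and rare
    samples below the floor are clamped with a warning.
    """
    frac = np.mean(x.values < floor_sq)
    if frac > 0.01:
        raise ValueError(
            f"{100 * frac:.1f}% of sigma^2 samples below the floor "
            f"{floor_sq}; choose a larger baseline or smaller variation"
        )
    if frac > 0:
        warnings.warn(
            f"clamping {100 * frac:.3f}% of sigma^2 samples at {floor_sq}",
            stacklevel=2,
        )
    return Signal(x.t0, x.dt, np.maximum(x.values, floor_sq))
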