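"""Noise schedule and the forward / large-step reverse diffusion algebra.

The forward process corrupts a clean image ``x0`` with Gaussian noise of
per-step variance ``theta_t`` (an increasing sequence):

    x_t = sqrt(1 - theta_t) * x_{t-1} + sqrt(theta_t) * eps,  eps ~ N(0, I)

Writing ``gamma_t = 1 - theta_t`` and ``gamma_bar_t = prod_{s<=t} gamma_s``,
the marginal is ``x_t = sqrt(gamma_bar_t) x0 + sqrt(1 - gamma_bar_t) eps``.
Sampling runs in strides of ``k`` time units: the reverse transition from
``t`` to ``t - k`` is the exact Gaussian posterior of the forward marginals
with effective one-step retention ``gamma_bar_t / gamma_bar_{t-k}``, so a
full trajectory costs only ``T / k`` generator calls.

Time convention: ``t = 0`` is the clean image and ``gamma_bar_0 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ContractError

__all__ = [
    "NoiseSchedule",
    "build_linear_schedule",
    "forward_step",
    "forward_marginal",
    "sampling_times",
    "posterior_coefficients",
    "posterior_step",
    "epsilon_update",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step noise variances and their cumulative products.

    ``theta[i]`` is the variance added at time ``t = i + 1`` (1-based times);
    ``gamma = 1 - theta``; ``gamma_bar[i] = prod(gamma[:i+1])``.
    """

    T: int
    k: int
    theta: np.ndarray
    gamma: np.ndarray = field(init=False)
    gamma_bar: np.ndarray = field(init=False)

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=np.float64)
        if theta.shape != (self.T,):
            raise ConfigurationError("theta must have length T")
        if np.any(theta <= 0) or np.any(theta >= 1):
            raise ConfigurationError("theta values must lie in (0, 1)")
        if self.T % self.k != 0:
            raise ConfigurationError("T must be divisible by the stride k")
        if self.k <= 0:
            raise ConfigurationError("k must be positive")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "gamma", 1.0 - theta)
        object.__setattr__(self, "gamma_bar", np.cumprod(1.0 - theta))

    def gamma_bar_at(self, t: int) -> float:
        """gamma_bar at integer time t, with the t = 0 convention of 1."""
        if not 0 <= t <= self.T:
            raise ContractError(f"time {t} outside [0, {self.T}]")
        return 1.0 if t == 0 else float(self.gamma_bar[t - 1])

    def theta_at(self, t: int) -> float:
        if not 1 <= t <= self.T:
            raise ContractError(f"time {t} outside [1, {self.T}]")
        return float(self.theta[t - 1])

    @property
    def num_sampling_steps(self) -> int:
        return self.T // self.k

    def config(self) -> dict:
        return {"T": self.T, "k": self.k}


def build_linear_schedule(T: int, theta_min: float = 1e-4,
                          theta_max: float = 0.02, k: int = 1) -> NoiseSchedule:
    """Linearly increasing theta from ``theta_min`` to ``theta_max``."""
    if not (0.0 < theta_min < theta_max < 1.0):
        raise ConfigurationError("need 0 < theta_min < theta_max < 1")
    if T <= 0 or T % k != 0:
        raise ConfigurationError("T must be a positive multiple of k")
    theta = np.linspace(theta_min, theta_max, T)
    return NoiseSchedule(T=T, k=k, theta=theta)


def _check_shapes(*arrays):
    shapes = {np.shape(a) for a in arrays}
    if len(shapes) > 1:
        raise ContractError(f"shape mismatch: {sorted(shapes)}")


def forward_step(x_prev, t: int, schedule: NoiseSchedule, eps):
    """One forward corruption step from ``x_{t-1}`` to ``x_t``."""
    x_prev = np.asarray(x_prev, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    _check_shapes(x_prev, eps)
    th = schedule.theta_at(t)
    return np.sqrt(1.0 - th) * x_prev + np.sqrt(th) * eps


def forward_marginal(x0, t: int, schedule: NoiseSchedule, eps):
    """Closed-form corruption of ``x0`` straight to time ``t``."""
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    _check_shapes(x0, eps)
    gb = schedule.gamma_bar_at(t)
    return np.sqrt(gb) * x0 + np.sqrt(1.0 - gb) * eps


def sampling_times(schedule: NoiseSchedule) -> list[int]:
    """Reverse-trajectory times [T, T-k, ..., k]; the output lands at 0."""
    return list(range(schedule.T, 0, -schedule.k))


def posterior_coefficients(t: int, schedule: NoiseSchedule):
    """(coef_x0, coef_xt, sigma) of the k-step Gaussian posterior at time t."""
    if t not in sampling_times(schedule):
        raise ContractError(f"t={t} is not on the k-stride sampling grid")
    s = t - schedule.k
    gb_t = schedule.gamma_bar_at(t)
    gb_s = schedule.gamma_bar_at(s)
    alpha = gb_t / gb_s
    theta_tilde = 1.0 - alpha
    coef_x0 = np.sqrt(gb_s) * theta_tilde / (1.0 - gb_t)
    coef_xt = np.sqrt(alpha) * (1.0 - gb_s) / (1.0 - gb_t)
    sigma = 0.0 if s == 0 else np.sqrt(theta_tilde * (1.0 - gb_s) / (1.0 - gb_t))
    return float(coef_x0), float(coef_xt), float(sigma)


def posterior_step(x_t, x0_hat, t: int, schedule: NoiseSchedule, noise):
    """Sample ``x_{t-k} ~ q(x_{t-k} | x_t, x0_hat)``.

    Uses the exact Gaussian posterior of the forward marginals with the
    effective one-step retention ``alpha = gamma_bar_t / gamma_bar_{t-k}``.
    The terminal step (``t - k == 0``) is deterministic (returns the mean,
    which there collapses to ``x0_hat``).
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    x0_hat = np.asarray(x0_hat, dtype=np.float64)
    _check_shapes(x_t, x0_hat)
    coef_x0, coef_xt, sigma = posterior_coefficients(t, schedule)
    mean = coef_x0 * x0_hat + coef_xt * x_t
    if sigma == 0.0:
        return mean
    noise = np.asarray(noise, dtype=np.float64)
    _check_shapes(x_t, noise)
    return mean + sigma * noise


def epsilon_update(x_t, eps_hat, t: int, schedule: NoiseSchedule):
    """Single-step deterministic reverse update in epsilon parameterization.

    Provided as an independent cross-check of :func:`posterior_step` (the
    sampler itself predicts the clean image, not the noise).
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    _check_shapes(x_t, eps_hat)
    th = schedule.theta_at(t)
    gb = schedule.gamma_bar_at(t)
    return (x_t - th / np.sqrt(1.0 - gb) * eps_hat) / np.sqrt(1.0 - th)
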