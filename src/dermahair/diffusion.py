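"""Mathematical core of the conditional Gaussian diffusion, network-free.

Conventions
-----------
The forward chain is variance preserving:

    q(y_t | y_{t-1}) = N(y_t | sqrt(alpha_t) * y_{t-1}, (1 - alpha_t) I)

with per-step retention factors ``alpha_t`` tied to a cumulative noise
variance ``gamma_t`` through ``1 - gamma_t = prod_{s<=t} alpha_s``. The
closed-form marginal is then

    y_t = sqrt(1 - gamma_t) * y_0 + sqrt(gamma_t) * eps,   eps ~ N(0, I),

so the signal and noise variances always sum to one. ``gamma`` runs from
``gamma_min`` (nearly clean) to ``gamma_max`` (nearly pure noise) over T
steps; during training the noise level is drawn from the piecewise-uniform
density p(gamma) = (1/T) sum_t U(gamma_{t-1}, gamma_t).

The reverse step is the Gaussian posterior parameterization

    mu = (y_t - (1 - alpha_t) / sqrt(gamma_t) * eps_hat) / sqrt(alpha_t),
    sigma^2_t = 1 - alpha_t,

with ``eps_hat`` the network's noise estimate; the training objective is the
mean squared error between ``eps_hat`` and the true ``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures_io import ContractError


@dataclass(frozen=True)
class DiffusionConfig:
    """Schedule hyperparameters: step count and gamma endpoints."""

    T: int = 2000
    gamma_min: float = 1e-4
    gamma_max: float = 0.98

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ContractError("T must be >= 1")
        if not (0.0 <= self.gamma_min < self.gamma_max <= 1.0):
            raise ContractError(
                "gamma endpoints must satisfy 0 <= gamma_min < gamma_max <= 1"
            )


@dataclass(frozen=True)
class NoiseSchedule:
    """T+1 ordered noise levels gamma_0..gamma_T and the implied alpha_1..alpha_T."""

    gamma: np.ndarray
    alpha: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=np.float64)
        if gamma.ndim != 1 or len(gamma) < 2:
            raise ContractError("gamma must be a 1-D array of at least 2 levels")
        if gamma[0] < 0 or gamma[-1] > 1 or np.any(np.diff(gamma) <= 0):
            raise ContractError("gamma must be strictly increasing within [0, 1]")
        # 1 - gamma_t = prod_{s<=t} alpha_s, with the product anchored at the
        # clean image: alpha_1 = 1 - gamma_1 and
        # alpha_t = (1-gamma_t)/(1-gamma_{t-1}) for t >= 2. gamma_0 only
        # floors the training noise-level density; it is not a chain state.
        alpha = np.empty(len(gamma) - 1)
        alpha[0] = 1.0 - gamma[1]
        alpha[1:] = (1.0 - gamma[2:]) / (1.0 - gamma[1:-1])
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "alpha", alpha)

    @property
    def T(self) -> int:
        return len(self.gamma) - 1


def make_schedule(config: DiffusionConfig) -> NoiseSchedule:
    """Linearly spaced gamma levels over [gamma_min, gamma_max] (T+1 knots)."""
    gamma = np.linspace(config.gamma_min, config.gamma_max, config.T + 1)
    return NoiseSchedule(gamma=gamma)


def sample_gamma(schedule: NoiseSchedule,
                 rng: np.random.Generator) -> tuple[int, float]:
    """Draw (t, gamma) from the piecewise-uniform training density.

    t is uniform on {1..T}; gamma is uniform on the half-open interval
    (gamma_{t-1}, gamma_t].
    """
    t = int(rng.integers(1, schedule.T + 1))
    lo, hi = schedule.gamma[t - 1], schedule.gamma[t]
    gamma = hi - float(rng.uniform(0.0, hi - lo))  # in (lo, hi]
    return t, gamma


def piecewise_uniform_cdf(schedule: NoiseSchedule, g: np.ndarray) -> np.ndarray:
    """Closed-form CDF of the training noise-level density (test oracle)."""
    g = np.asarray(g, dtype=np.float64)
    gamma = schedule.gamma
    T = schedule.T
    cdf = np.zeros_like(g)
    for t in range(1, T + 1):
        lo, hi = gamma[t - 1], gamma[t]
        frac = np.clip((g - lo) / (hi - lo), 0.0, 1.0)
        cdf += frac / T
    return cdf


def forward_step(y_prev: np.ndarray, alpha_t: float,
                 rng: np.random.Generator) -> np.ndarray:
    """One forward Markov step: sqrt(alpha)*y + sqrt(1-alpha)*eps."""
    if not (0.0 < alpha_t <= 1.0):
        raise ContractError("alpha_t must be in (0, 1]")
    y_prev = np.asarray(y_prev, dtype=np.float64)
    eps = rng.standard_normal(y_prev.shape)
    return np.sqrt(alpha_t) * y_prev + np.sqrt(1.0 - alpha_t) * eps


def noised_image(y0: np.ndarray, gamma_t: float, eps: np.ndarray) -> np.ndarray:
    """Closed-form noising: sqrt(1-gamma)*y0 + sqrt(gamma)*eps."""
    if not (0.0 <= gamma_t <= 1.0):
        raise ContractError("gamma_t must be in [0, 1]")
    y0 = np.asarray(y0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if y0.shape != eps.shape:
        raise ContractError(f"shape mismatch: y0 {y0.shape} vs eps {eps.shape}")
    return np.sqrt(1.0 - gamma_t) * y0 + np.sqrt(gamma_t) * eps


def training_loss(predicted_noise: np.ndarray, eps: np.ndarray) -> float:
    """Mean squared error between predicted and true noise fields."""
    predicted_noise = np.asarray(predicted_noise, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if predicted_noise.shape != eps.shape:
        raise ContractError(
            f"shape mismatch: prediction {predicted_noise.shape} vs eps {eps.shape}"
        )
    return float(np.mean((predicted_noise - eps) ** 2))


def posterior_step_params(y_t: np.ndarray, predicted_noise: np.ndarray,
                          schedule: NoiseSchedule,
                          t: int) -> tuple[np.ndarray, float]:
    """Gaussian reverse-step parameters (mu, sigma^2) at step t.

    mu = (y_t - (1-alpha_t)/sqrt(gamma_t) * eps_hat) / sqrt(alpha_t);
    the fixed variance choice is sigma^2_t = 1 - alpha_t.
    """
    if not (1 <= t <= schedule.T):
        raise ContractError(f"t must be in [1, {schedule.T}], got {t}")
    y_t = np.asarray(y_t, dtype=np.float64)
    predicted_noise = np.asarray(predicted_noise, dtype=np.float64)
    alpha_t = schedule.alpha[t - 1]
    gamma_t = schedule.gamma[t]
    mu = (y_t - (1.0 - alpha_t) / np.sqrt(gamma_t) * predicted_noise) / np.sqrt(alpha_t)
    sigma2 = float(1.0 - alpha_t)
    return mu, sigma2


# range conversions between the external [0,1] and internal [-1,1] conventions

def to_internal(px: np.ndarray) -> np.ndarray:
    """Map [0, 1] pixels to the internal [-1, 1] range."""
    return 2.0 * np.asarray(px, dtype=np.float64) - 1.0


def to_external(px: np.ndarray) -> np.ndarray:
    """Map internal [-1, 1] values back to [0, 1], clipping."""
    return np.clip((np.asarray(px, dtype=np.float64) + 1.0) / 2.0, 0.0, 1.0)
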