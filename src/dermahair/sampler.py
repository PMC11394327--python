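"""Inference: iterative refinement of a noise field into a hair-free image.

Two sampling modes are first class:

* ``residual`` — the plain additive update ``y_{t-1} = f(y_t, x, t) + y_t``:
  each step adds the network output to the current iterate. The final image
  telescopes exactly to ``y_T + sum_t f(y_t, x, t)``.
* ``ancestral`` (default) — the standard Gaussian ancestral sampler: the
  network's noise estimate parameterizes the reverse posterior
  ``N(mu, sigma^2 I)`` and ``y_{t-1}`` is drawn from it, with no noise added
  at the final step. Optionally the implied denoised estimate
  ``y0_hat = (y_t - sqrt(gamma) eps_hat) / sqrt(1-gamma)`` is clipped to
  [-1, 1] before forming mu, a numerical guard for lightly trained models.

The two modes differ because an additive update and a posterior draw are
different readings of "apply the denoiser"; both are kept so either
behaviour can be reproduced and compared. The denoiser argument may be
trained :class:`~dermahair.denoiser.DenoiserParams` or any callable
``(x, y_t, gamma) -> noise field`` (oracle denoisers in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoiser import DenoiserParams, predict_noise
from .diffusion import (NoiseSchedule, posterior_step_params, to_external,
                        to_internal)
from .fixtures_io import ContractError, RasterImage, UNIT_RANGE


@dataclass(frozen=True)
class SamplerConfig:
    """Inference settings: mode, step count, seed, numerical guard."""

    mode: str = "ancestral"
    T_infer: int | None = None      # None: use the schedule's T
    seed: int = 0
    clip_denoised: bool = True
    keep_trajectory: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("residual", "ancestral"):
            raise ContractError("mode must be 'residual' or 'ancestral'")
        if self.T_infer is not None and self.T_infer < 0:
            raise ContractError("T_infer must be >= 0")


def _eval_denoiser(model, x: np.ndarray, y_t: np.ndarray,
                   gamma: float) -> np.ndarray:
    if isinstance(model, DenoiserParams):
        return predict_noise(model, x, y_t, gamma)
    return np.asarray(model(x, y_t, gamma), dtype=np.float64)


def refine_step(model, y_t: np.ndarray, x: np.ndarray, t: int,
                gamma: float) -> np.ndarray:
    """Additive refinement: y_{t-1} = f(y_t, x, t) + y_t (exactly)."""
    if t < 1:
        raise ContractError("t must be >= 1")
    return _eval_denoiser(model, x, y_t, gamma) + y_t


def ancestral_step(model, y_t: np.ndarray, x: np.ndarray,
                   schedule: NoiseSchedule, t: int,
                   rng: np.random.Generator,
                   clip_denoised: bool = True) -> np.ndarray:
    """Draw y_{t-1} from the reverse Gaussian posterior at step t.

    At t = 1 the posterior mean is returned without added noise.
    """
    gamma_t = float(schedule.gamma[t])
    eps_hat = _eval_denoiser(model, x, y_t, gamma_t)
    if clip_denoised and gamma_t < 1.0:
        y0_hat = (y_t - np.sqrt(gamma_t) * eps_hat) / np.sqrt(1.0 - gamma_t)
        y0_hat = np.clip(y0_hat, -1.0, 1.0)
        eps_hat = (y_t - np.sqrt(1.0 - gamma_t) * y0_hat) / np.sqrt(gamma_t)
    mu, sigma2 = posterior_step_params(y_t, eps_hat, schedule, t)
    if t == 1 or sigma2 == 0.0:
        return mu
    return mu + np.sqrt(sigma2) * rng.standard_normal(mu.shape)


def _subschedule(schedule: NoiseSchedule, T_infer: int) -> NoiseSchedule:
    """Pick T_infer+1 gamma knots from the training schedule (inclusive ends)."""
    if T_infer == schedule.T:
        return schedule
    idx = np.unique(np.round(
        np.linspace(0, schedule.T, T_infer + 1)).astype(int))
    if len(idx) != T_infer + 1:   # degenerate for T_infer > T: rebuild linearly
        gamma = np.linspace(schedule.gamma[0], schedule.gamma[-1], T_infer + 1)
        return NoiseSchedule(gamma=gamma)
    return NoiseSchedule(gamma=schedule.gamma[idx])


def dehair(model, x: RasterImage, schedule: NoiseSchedule,
           config: SamplerConfig = SamplerConfig()
           ) -> tuple[RasterImage, list[np.ndarray] | None]:
    """Generate the hair-free image conditioned on the hairy input ``x``.

    Starts from y_T ~ N(0, I), applies ``T_infer`` steps in the configured
    mode (internal [-1, 1] range), and maps the result back to a clipped
    [0, 1] image. Returns ``(image, trajectory)``; the trajectory (internal
    range, length T_infer + 1 including the initialization) is kept only
    when ``config.keep_trajectory``.
    """
    if x.value_range != UNIT_RANGE:
        raise ContractError("dehair expects a [0, 1] conditioning image")
    T_infer = schedule.T if config.T_infer is None else config.T_infer
    sched = _subschedule(schedule, T_infer) if T_infer > 0 else schedule
    rng = np.random.default_rng(config.seed)
    x_int = to_internal(x.pixels)
    y = rng.standard_normal(x_int.shape)
    trajectory = [y.copy()] if config.keep_trajectory else None
    for t in range(T_infer, 0, -1):
        if config.mode == "residual":
            y = refine_step(model, y, x_int, t, gamma=float(sched.gamma[t]))
        else:
            y = ancestral_step(model, y, x_int, sched, t, rng,
                               clip_denoised=config.clip_denoised)
        if trajectory is not None:
            trajectory.append(y.copy())
    out = RasterImage(to_external(y), value_range=UNIT_RANGE)
    return out, trajectory
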