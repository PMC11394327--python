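"""Conditional U-Net noise estimator f(x, y_t, gamma) and its training loop.

The network receives the noisy image y_t channel-concatenated with the hairy
conditioning image x (resized to match y_t if needed) at every denoising
step, plus a sinusoidal embedding of the noise level gamma injected into
each residual block as a per-channel shift. The architecture is a small
multi-scale U-Net: per-stage channel widths ``base_channels * multiplier``,
ResNet blocks with ReLU activations at every stage, 2x average-pool
downsampling and nearest-neighbour upsampling with skip concatenation.

Training follows the standard conditional-diffusion recipe: sample a pair
(x, y0), a noise level gamma from the piecewise-uniform schedule density,
Gaussian noise eps, form y_t = sqrt(1-gamma) y0 + sqrt(gamma) eps, and take
an Adam step on the MSE between the network output and eps. All images are
mapped to the internal [-1, 1] range before entering the diffusion.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .diffusion import (DiffusionConfig, NoiseSchedule, make_schedule,
                        noised_image, sample_gamma, to_internal)
from .fixtures_io import ContractError, DatasetManifest, PairedSample, load_pairs

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters; parameter shapes follow from these."""

    image_channels: int = 1
    base_channels: int = 16
    depth_multipliers: tuple[int, ...] = (1, 2)
    n_res_blocks: int = 1
    time_embed_dim: int = 16

    def __post_init__(self) -> None:
        if len(self.depth_multipliers) < 1:
            raise ContractError("need at least one resolution stage")
        if any(m < 1 for m in self.depth_multipliers):
            raise ContractError("depth multipliers must be positive integers")
        if self.image_channels not in (1, 3):
            raise ContractError("image_channels must be 1 or 3")
        if self.time_embed_dim % 2 or self.time_embed_dim < 2:
            raise ContractError("time_embed_dim must be a positive even integer")

    @property
    def n_stages(self) -> int:
        return len(self.depth_multipliers)

    @property
    def size_divisor(self) -> int:
        return 2 ** (self.n_stages - 1)


@dataclass
class DenoiserParams:
    """All trainable parameters plus the architecture that shaped them."""

    theta: dict[str, np.ndarray]
    config: DenoiserConfig
    step: int = 0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.theta.values())


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. Defaults follow the full-scale recipe
    (Adam, learning rate 1e-4); iterations/batch are sized by the caller."""

    learning_rate: float = 1e-4
    iterations: int = 20000
    batch_size: int = 8
    seed: int = 0
    checkpoint_every: int = 0   # 0 disables periodic checkpoints
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ContractError("learning rate must be >= 0")
        if self.iterations < 1:
            raise ContractError("iterations must be >= 1")


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _stage_widths(config: DenoiserConfig) -> list[int]:
    return [config.base_channels * m for m in config.depth_multipliers]


def _resblock_shapes(name: str, c_in: int, c_out: int,
                     tdim: int) -> dict[str, tuple[int, ...]]:
    shapes = {
        f"{name}.conv1.W": (c_out, c_in, 3, 3),
        f"{name}.conv1.b": (c_out,),
        f"{name}.conv2.W": (c_out, c_out, 3, 3),
        f"{name}.conv2.b": (c_out,),
        f"{name}.tproj.W": (c_out, tdim),
        f"{name}.tproj.b": (c_out,),
    }
    if c_in != c_out:
        shapes[f"{name}.skip.W"] = (c_out, c_in, 1, 1)
        shapes[f"{name}.skip.b"] = (c_out,)
    return shapes


def _parameter_shapes(config: DenoiserConfig) -> dict[str, tuple[int, ...]]:
    widths = _stage_widths(config)
    tdim = config.time_embed_dim
    shapes: dict[str, tuple[int, ...]] = {
        "conv_in.W": (widths[0], 2 * config.image_channels, 3, 3),
        "conv_in.b": (widths[0],),
        "temb.fc1.W": (tdim, tdim),
        "temb.fc1.b": (tdim,),
        "temb.fc2.W": (tdim, tdim),
        "temb.fc2.b": (tdim,),
        "conv_out.W": (config.image_channels, widths[0], 3, 3),
        "conv_out.b": (config.image_channels,),
    }
    c = widths[0]
    for s, w in enumerate(widths):
        for i in range(config.n_res_blocks):
            shapes.update(_resblock_shapes(f"down{s}.b{i}", c, w, tdim))
            c = w
    shapes.update(_resblock_shapes("mid", c, c, tdim))
    for s in range(config.n_stages - 2, -1, -1):
        w = widths[s]
        c_in = c + widths[s]  # upsampled features + skip concat
        for i in range(config.n_res_blocks):
            shapes.update(_resblock_shapes(f"up{s}.b{i}", c_in, w, tdim))
            c_in = w
        c = w
    return shapes


def init_denoiser(config: DenoiserConfig, seed: int) -> DenoiserParams:
    """He-normal initialization for all weights, zero biases; pure in seed."""
    rng = np.random.default_rng(seed)
    theta: dict[str, np.ndarray] = {}
    for name, shape in _parameter_shapes(config).items():
        if name.endswith(".b"):
            theta[name] = np.zeros(shape)
        else:
            fan_in = int(np.prod(shape[1:]))
            theta[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
    return DenoiserParams(theta=theta, config=config, step=0)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def sinusoidal_embedding(gamma: np.ndarray, dim: int,
                         max_freq: float = 1000.0) -> np.ndarray:
    """(B,) gamma levels -> (B, dim) sin/cos features on log-spaced frequencies."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(max_freq), half))
    angles = gamma[:, None] * freqs[None, :]
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)


def _resblock(theta: dict[str, nn.Tensor], name: str, h: nn.Tensor,
              temb: nn.Tensor) -> nn.Tensor:
    a = nn.relu(h)
    h1 = nn.conv2d(a, theta[f"{name}.conv1.W"], theta[f"{name}.conv1.b"])
    shift = nn.linear(temb, theta[f"{name}.tproj.W"], theta[f"{name}.tproj.b"])
    shift = nn.reshape(shift, shift.shape + (1, 1))
    h1 = nn.add_broadcast(h1, shift)
    h2 = nn.conv2d(nn.relu(h1), theta[f"{name}.conv2.W"], theta[f"{name}.conv2.b"])
    if f"{name}.skip.W" in theta:
        skip = nn.conv2d(h, theta[f"{name}.skip.W"], theta[f"{name}.skip.b"])
    else:
        skip = h
    return nn.add(h2, skip)


def _forward_graph(theta_arrays: dict[str, np.ndarray], config: DenoiserConfig,
                   x: np.ndarray, y_t: np.ndarray,
                   gamma: np.ndarray,
                   requires_grad: bool) -> tuple[nn.Tensor, dict[str, nn.Tensor]]:
    """Build the U-Net tape on NCHW inputs; returns (output, wrapped params)."""
    theta = {k: nn.Tensor(v, requires_grad=requires_grad)
             for k, v in theta_arrays.items()}
    emb = nn.Tensor(sinusoidal_embedding(gamma, config.time_embed_dim))
    temb = nn.linear(emb, theta["temb.fc1.W"], theta["temb.fc1.b"])
    temb = nn.linear(nn.relu(temb), theta["temb.fc2.W"], theta["temb.fc2.b"])

    inp = nn.concat_channels(nn.Tensor(y_t), nn.Tensor(x))
    h = nn.conv2d(inp, theta["conv_in.W"], theta["conv_in.b"])
    skips: list[nn.Tensor] = []
    for s in range(config.n_stages):
        for i in range(config.n_res_blocks):
            h = _resblock(theta, f"down{s}.b{i}", h, temb)
        skips.append(h)
        if s < config.n_stages - 1:
            h = nn.avg_pool2(h)
    h = _resblock(theta, "mid", h, temb)
    for s in range(config.n_stages - 2, -1, -1):
        h = nn.upsample_nearest2(h)
        h = nn.concat_channels(h, skips[s])
        for i in range(config.n_res_blocks):
            h = _resblock(theta, f"up{s}.b{i}", h, temb)
    out = nn.conv2d(nn.relu(h), theta["conv_out.W"], theta["conv_out.b"])
    return out, theta


def _as_nchw(img: np.ndarray, channels: int) -> np.ndarray:
    """Accept (H,W), (H,W,C), (B,C,H,W); return (B,C,H,W)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        img = img[None, None]
    elif img.ndim == 3:           # (H,W,C) channel-last single image
        img = img.transpose(2, 0, 1)[None]
    elif img.ndim != 4:
        raise ContractError(f"cannot interpret image array of shape {img.shape}")
    if img.shape[1] != channels:
        raise ContractError(
            f"expected {channels} channels, got {img.shape[1]}")
    return img


def _pad_to_divisor(arr: np.ndarray, d: int) -> tuple[np.ndarray, tuple[int, int]]:
    B, C, H, W = arr.shape
    ph = (-H) % d
    pw = (-W) % d
    if ph or pw:
        arr = np.pad(arr, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    return arr, (ph, pw)


def predict_noise(params: DenoiserParams, x: np.ndarray, y_t: np.ndarray,
                  gamma: float | np.ndarray) -> np.ndarray:
    """Estimate the noise field from (conditioning, noisy image, noise level).

    ``x`` is resized (bilinear) to the spatial size of ``y_t`` when they
    differ; both are reflect-padded to a multiple of ``2**(stages-1)`` and
    the output is cropped back. Deterministic given (params, inputs).
    """
    config = params.config
    y = _as_nchw(y_t, config.image_channels)
    xc = _as_nchw(x, config.image_channels)
    if xc.shape[2:] != y.shape[2:]:
        xc = np.stack([
            np.stack([_sk_resize(xc[b, c], y.shape[2:], order=1,
                                 mode="reflect", anti_aliasing=False)
                      for c in range(xc.shape[1])])
            for b in range(xc.shape[0])])
    B, _, H, W = y.shape
    gamma = np.broadcast_to(np.atleast_1d(np.asarray(gamma, dtype=np.float64)),
                            (B,))
    d = config.size_divisor
    yp, (ph, pw) = _pad_to_divisor(y, d)
    xp, _ = _pad_to_divisor(xc, d)
    out, _ = _forward_graph(params.theta, config, xp, yp, gamma,
                            requires_grad=False)
    res = out.data[:, :, :H, :W]
    if np.asarray(y_t).ndim == 2:
        return res[0, 0]
    if np.asarray(y_t).ndim == 3:
        return res[0].transpose(1, 2, 0)
    return res


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def denoiser_loss_and_grads(theta_arrays: dict[str, np.ndarray],
                            config: DenoiserConfig, x: np.ndarray,
                            y_t: np.ndarray, gamma: np.ndarray,
                            eps: np.ndarray,
                            want_grads: bool = True
                            ) -> tuple[float, dict[str, np.ndarray] | None]:
    """MSE between the network output and the true noise, with gradients."""
    out, theta = _forward_graph(theta_arrays, config, x, y_t, gamma,
                                requires_grad=want_grads)
    loss = nn.mse_loss(out, eps)
    if not want_grads:
        return float(loss.data), None
    loss.backward()
    grads = {k: t.grad for k, t in theta.items()}
    return float(loss.data), grads


def _batch_arrays(batch: list[PairedSample],
                  channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack a batch of pairs into internal-range NCHW (x, y0) arrays."""
    xs, ys = [], []
    for pair in batch:
        xs.append(to_internal(pair.hairy.pixels).transpose(2, 0, 1))
        ys.append(to_internal(pair.clean.pixels).transpose(2, 0, 1))
    x = np.stack(xs)
    y0 = np.stack(ys)
    if x.shape[1] != channels:
        raise ContractError(
            f"batch has {x.shape[1]} channels, model expects {channels}")
    return x, y0


def train_step(params: DenoiserParams, batch: list[PairedSample],
               schedule: NoiseSchedule, opt: nn.Adam,
               rng: np.random.Generator) -> float:
    """One training iteration: noise the batch, fit eps, Adam-update theta."""
    if not batch:
        raise ContractError("batch must be non-empty")
    config = params.config
    x, y0 = _batch_arrays(batch, config.image_channels)
    B = x.shape[0]
    gammas = np.empty(B)
    y_t = np.empty_like(y0)
    eps = np.empty_like(y0)
    for b in range(B):
        _, g = sample_gamma(schedule, rng)
        gammas[b] = g
        eps[b] = rng.standard_normal(y0[b].shape)
        y_t[b] = noised_image(y0[b], g, eps[b])
    d = config.size_divisor
    xp, _ = _pad_to_divisor(x, d)
    yp, _ = _pad_to_divisor(y_t, d)
    ep, _ = _pad_to_divisor(eps, d)
    loss, grads = denoiser_loss_and_grads(params.theta, config, xp, yp,
                                          gammas, ep)
    if not np.isfinite(loss):
        raise RuntimeError(
            f"non-finite training loss at step {params.step}: {loss}")
    opt.step(params.theta, grads)
    params.step += 1
    return loss


def train(dataset: DatasetManifest | list[PairedSample],
          train_config: TrainConfig,
          diffusion_config: DiffusionConfig,
          denoiser_config: DenoiserConfig,
          log_path: str | Path | None = None,
          resume_from: str | Path | None = None,
          ) -> tuple[DenoiserParams, list[float]]:
    """Run the training loop; returns (params, per-iteration loss history).

    ``dataset`` is either a manifest (train split loaded from disk) or an
    in-memory list of pairs. Fully seeded: initialization, noise-level and
    noise draws, and batch order all derive from ``train_config.seed``; a
    run resumed from a periodic checkpoint reproduces the uninterrupted run
    bit for bit because the RNG state is stored in the checkpoint.
    """
    if isinstance(dataset, DatasetManifest):
        pairs = load_pairs(dataset, split="train")
    else:
        pairs = list(dataset)
    if not pairs:
        raise ContractError("training dataset is empty")

    schedule = make_schedule(diffusion_config)
    if resume_from is not None:
        params, opt, rng, history = _load_training_state(
            resume_from, denoiser_config, train_config)
        start = params.step
    else:
        params = init_denoiser(denoiser_config, seed=train_config.seed)
        opt = nn.Adam(lr=train_config.learning_rate)
        rng = np.random.default_rng(train_config.seed + 1)
        history = []
        start = 0

    for it in range(start, train_config.iterations):
        idx = rng.integers(0, len(pairs), size=train_config.batch_size)
        batch = [pairs[i] for i in idx]
        loss = train_step(params, batch, schedule, opt, rng)
        history.append(loss)
        if (train_config.checkpoint_every
                and train_config.checkpoint_dir
                and (it + 1) % train_config.checkpoint_every == 0):
            path = Path(train_config.checkpoint_dir) / f"ckpt_{it + 1:06d}.npz"
            save_checkpoint(params, opt, path, schedule=schedule,
                            rng=rng, history=history)
    if log_path is not None:
        lines = ["iteration,loss"] + [f"{i},{l:.10g}" for i, l in enumerate(history)]
        Path(log_path).write_text("\n".join(lines) + "\n")
    return params, history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(params: DenoiserParams, opt: nn.Adam | None,
                    path: str | Path, schedule: NoiseSchedule | None = None,
                    rng: np.random.Generator | None = None,
                    history: list[float] | None = None) -> Path:
    """Single-archive checkpoint: parameters, optimizer, configs, RNG state."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"theta/{k}": v for k, v in params.theta.items()}
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(params.config),
        "step": params.step,
    }
    if opt is not None:
        state = opt.state_dict()
        for k, v in state.pop("m").items():
            arrays[f"opt_m/{k}"] = v
        for k, v in state.pop("v").items():
            arrays[f"opt_v/{k}"] = v
        meta["opt"] = state
    if schedule is not None:
        arrays["schedule/gamma"] = schedule.gamma
    if rng is not None:
        meta["rng_state"] = rng.bit_generator.state
    if history is not None:
        arrays["history"] = np.asarray(history)
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(
        json.dumps(meta, default=int).encode(), dtype=np.uint8), **arrays)
    path.write_bytes(buf.getvalue())
    return path


def load_checkpoint(path: str | Path
                    ) -> tuple[DenoiserParams, dict, NoiseSchedule | None]:
    """Load a checkpoint; returns (params, extras, schedule).

    ``extras`` carries the optimizer state dict, RNG state and loss history
    when present. Corrupt archives or unknown versions raise.
    """
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise OSError(f"cannot read checkpoint {path}: {exc}") from exc
    if "__meta__" not in data:
        raise OSError(f"not a recognizable checkpoint: {path}")
    meta = json.loads(bytes(data.pop("__meta__")).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise OSError(
            f"checkpoint version {meta.get('version')} unsupported "
            f"(expected {CHECKPOINT_VERSION})")
    cfg = meta["config"]
    cfg["depth_multipliers"] = tuple(cfg["depth_multipliers"])
    config = DenoiserConfig(**cfg)
    theta = {k[len("theta/"):]: v for k, v in data.items()
             if k.startswith("theta/")}
    expected = _parameter_shapes(config)
    if set(theta) != set(expected) or any(
            theta[k].shape != expected[k] for k in expected):
        raise OSError(f"checkpoint parameters do not match config: {path}")
    params = DenoiserParams(theta=theta, config=config, step=meta["step"])
    extras: dict = {}
    if "opt" in meta:
        opt_state = dict(meta["opt"])
        opt_state["m"] = {k[len("opt_m/"):]: v for k, v in data.items()
                          if k.startswith("opt_m/")}
        opt_state["v"] = {k[len("opt_v/"):]: v for k, v in data.items()
                          if k.startswith("opt_v/")}
        extras["opt_state"] = opt_state
    if "rng_state" in meta:
        extras["rng_state"] = meta["rng_state"]
    if "history" in data:
        extras["history"] = data["history"].tolist()
    schedule = None
    if "schedule/gamma" in data:
        schedule = NoiseSchedule(gamma=data["schedule/gamma"])
    return params, extras, schedule


def _load_training_state(path: str | Path, denoiser_config: DenoiserConfig,
                         train_config: TrainConfig):
    params, extras, _ = load_checkpoint(path)
    if params.config != denoiser_config:
        raise OSError("checkpoint config does not match requested config")
    opt = nn.Adam.from_state_dict(extras["opt_state"])
    opt.lr = train_config.learning_rate
    rng = np.random.default_rng()
    rng.bit_generator.state = extras["rng_state"]
    return params, opt, rng, extras.get("history", [])
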