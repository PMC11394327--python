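"""Image-quality and classification metrics, plus per-class report tables.

Image quality is scored with PSNR (log mean-squared-error fidelity), SSIM
(windowed structural similarity) and LPIPS (feature-space patch distance
with an injectable feature extractor — by default a fixed-seed random
convolution stack so no pretrained weights are needed). Classification is
scored one-vs-rest per class from confusion counts with the usual accuracy,
precision, recall, specificity and F1 definitions, and cross-entropy loss.

Reports aggregate per-class means over the seven diagnostic classes and an
``Average`` row equal to their arithmetic mean, mirroring the layout of
per-class dehairing benchmark tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures_io import CLASSES, ContractError, RasterImage

_EPS_FLOOR = 1e-12


def _pixels(img) -> np.ndarray:
    if isinstance(img, RasterImage):
        return img.pixels
    px = np.asarray(img, dtype=np.float64)
    return px[:, :, None] if px.ndim == 2 else px


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------

def psnr(reference, test, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(MAX^2 / MSE), in dB.

    Identical images have zero MSE; +inf is returned as the sentinel.
    """
    ref = _pixels(reference)
    tst = _pixels(test)
    if ref.shape != tst.shape:
        raise ContractError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value ** 2 / mse))


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

def _window_stats(x: np.ndarray, win: int) -> tuple[np.ndarray, ...]:
    """Per-window population mean/second-moment via sliding windows."""
    v = np.lib.stride_tricks.sliding_window_view(x, (win, win))
    return v.mean(axis=(2, 3)), (v * v).mean(axis=(2, 3)), v


def ssim(x, y, C1: float | None = None, C2: float | None = None,
         window: int = 8, max_value: float = 1.0) -> float:
    """Structural similarity index averaged over sliding windows.

    Per window w: SSIM_w = (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
    ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)) with population
    (1/N) variance/covariance; the score is the mean over all fully valid
    windows and channels. Defaults C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2.
    """
    xa = _pixels(x)
    ya = _pixels(y)
    if xa.shape != ya.shape:
        raise ContractError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    H, W = xa.shape[:2]
    win = min(window, H, W)
    if C1 is None:
        C1 = (0.01 * max_value) ** 2
    if C2 is None:
        C2 = (0.03 * max_value) ** 2
    vals = []
    for c in range(xa.shape[2]):
        xc, yc = xa[:, :, c], ya[:, :, c]
        mx, mx2, vx = _window_stats(xc, win)
        my, my2, vy = _window_stats(yc, win)
        mxy = (vx * vy).mean(axis=(2, 3))
        var_x = mx2 - mx ** 2
        var_y = my2 - my ** 2
        cov = mxy - mx * my
        s = ((2 * mx * my + C1) * (2 * cov + C2)
             / ((mx ** 2 + my ** 2 + C1) * (var_x + var_y + C2)))
        vals.append(s.mean())
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# LPIPS
# ---------------------------------------------------------------------------

class IdentityExtractor:
    """Trivial extractor: the image itself is the single feature layer."""

    weights = (1.0,)

    def __call__(self, img) -> list[np.ndarray]:
        px = _pixels(img)
        return [px.transpose(2, 0, 1)]


class RandomConvExtractor:
    """Fixed-seed stack of random 3x3 convolutions with ReLU between layers.

    A deterministic stand-in for a pretrained perceptual backbone: feature
    maps at each depth are returned with uniform layer weights. Not a
    calibrated perceptual metric — it gives a reproducible feature-space
    distance for tests and desk-scale reports.
    """

    def __init__(self, seed: int = 0, n_layers: int = 3, channels: int = 8,
                 in_channels: int = 1) -> None:
        rng = np.random.default_rng(seed)
        self.kernels = []
        c_in = in_channels
        for _ in range(n_layers):
            k = rng.normal(0.0, np.sqrt(2.0 / (c_in * 9)), (channels, c_in, 3, 3))
            self.kernels.append(k)
            c_in = channels
        self.weights = tuple(1.0 / n_layers for _ in range(n_layers))

    def __call__(self, img) -> list[np.ndarray]:
        from .nn import Tensor, conv2d
        px = _pixels(img).transpose(2, 0, 1)[None]
        feats = []
        h = px
        for k in self.kernels:
            out = conv2d(Tensor(h), Tensor(k), Tensor(np.zeros(k.shape[0]))).data
            h = np.maximum(out, 0.0)
            feats.append(out[0])
            # downsample between layers to vary H_l, W_l
            if h.shape[2] >= 4 and h.shape[3] >= 4:
                h = h[:, :, ::2, ::2]
        return feats


def lpips(i1, i2, extractor=None) -> float:
    """Feature-space patch distance:

    sum_l omega_l / (H_l W_l) * sum_{h,w} ||F_l(I1)_{h,w} - F_l(I2)_{h,w}||_2^2

    where the squared norm runs over the channel axis. Zero iff all feature
    maps agree. The extractor must expose ``weights`` and return a list of
    (C_l, H_l, W_l) maps; default is the fixed-seed random-conv stack.
    """
    if extractor is None:
        extractor = RandomConvExtractor(in_channels=_pixels(i1).shape[2])
    f1 = extractor(i1)
    f2 = extractor(i2)
    total = 0.0
    for w, a, b in zip(extractor.weights, f1, f2):
        if a.shape != b.shape:
            raise ContractError("extractor returned mismatched feature shapes")
        _, Hl, Wl = a.shape
        sq = ((a - b) ** 2).sum(axis=0)   # ||.||^2 over channels, per (h, w)
        total += w * sq.sum() / (Hl * Wl)
    return float(total)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, specificity and F1 from confusion counts.

    Undefined ratios (zero denominator) are reported as NaN sentinels rather
    than raising; an all-zero table yields all-NaN.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    precision = ratio(counts.TP, counts.TP + counts.FP)
    recall = ratio(counts.TP, counts.TP + counts.FN)
    specificity = ratio(counts.TN, counts.TN + counts.FP)
    accuracy = ratio(counts.TP + counts.TN, counts.total)
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "specificity": specificity, "f1": f1}


def one_vs_rest_counts(y_true: list[str], y_pred: list[str],
                       classes: tuple[str, ...] = CLASSES
                       ) -> dict[str, ConfusionCounts]:
    """Reduce multiclass predictions to per-class one-vs-rest counts."""
    if len(y_true) != len(y_pred):
        raise ContractError("y_true and y_pred must have equal length")
    out = {}
    for cls in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        tn = len(y_true) - tp - fp - fn
        out[cls] = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
    return out


def cross_entropy(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mean cross-entropy -sum_i y_i log p_i over samples.

    ``labels`` are one-hot rows; probabilities are clamped below at 1e-12
    so a zero probability at the true label stays finite.
    """
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.ndim == 1:
        y, p = y[None], p[None]
    if y.shape != p.shape:
        raise ContractError("labels and probabilities must share shape")
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ContractError("probabilities must be non-negative and sum to 1")
    return float(np.mean(-np.sum(y * np.log(np.maximum(p, _EPS_FLOOR)), axis=1)))


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def evaluate_pairs(pairs, extractor=None, max_value: float = 1.0
                   ) -> pd.DataFrame:
    """Per-class PSNR/SSIM/LPIPS means plus an Average row.

    ``pairs`` is a sequence of (clean, restored, label) triples. Classes with
    no samples are omitted; the Average row is the arithmetic mean of the
    reported class rows (infinite PSNR rows propagate the sentinel).
    """
    pairs = list(pairs)
    if not pairs:
        raise ContractError("evaluate_pairs requires a non-empty list")
    by_class: dict[str, list[tuple[float, float, float]]] = {}
    for clean, restored, label in pairs:
        if label not in CLASSES:
            raise ContractError(f"unknown label {label!r}")
        row = (psnr(clean, restored, max_value=max_value),
               ssim(clean, restored, max_value=max_value),
               lpips(clean, restored, extractor=extractor))
        by_class.setdefault(label, []).append(row)
    records = {}
    for cls in CLASSES:
        if cls in by_class:
            arr = np.asarray(by_class[cls])
            records[cls] = arr.mean(axis=0)
    table = pd.DataFrame.from_dict(records, orient="index",
                                   columns=["PSNR", "SSIM", "LPIPS"])
    table.loc["Average"] = table.mean(axis=0)
    table.index.name = "class"
    return table
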