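"""Image I/O, the paired-dataset directory convention, and procedural fixtures.

The paired dataset convention mirrors the layout used for dermoscopic
hair-removal benchmarks: two root directories, ``Data_Skin_with_Hair`` and
``Data_Skin_without_Hair``, each containing one subdirectory per diagnostic
class (akiec, bcc, bkl, df, mel, nv, vasc), with matching basenames across
the two roots forming the (hairy, hair-free) pairs.

The procedural generators stand in for real dermoscopy data so the whole
pipeline is testable at desk scale: ``make_lesion_texture`` draws a smooth
skin-toned background with one darker elliptical blob (lesion surrogate);
``make_procedural_hair_mask`` draws thin curved strands as a binary mask.
Both are pure functions of their seed and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import line as _bresenham_line

CLASSES = ("akiec", "bcc", "bkl", "df", "mel", "nv", "vasc")

#: declared range for images handed to/returned by disk I/O
UNIT_RANGE = (0.0, 1.0)
#: internal range used by the diffusion core
SYMMETRIC_RANGE = (-1.0, 1.0)


class ContractError(ValueError):
    """An operation precondition was violated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RasterImage:
    """H x W x C grid of real-valued pixel intensities with a declared range.

    ``value_range`` is ``None`` for unbounded intermediates (e.g. the merged
    image of the mask-overlay arithmetic, which may exceed [0, 1]).
    """

    pixels: np.ndarray
    value_range: tuple[float, float] | None = UNIT_RANGE

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ContractError(
                f"pixels must be HxW or HxWxC with C in {{1,3}}, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ContractError("image must have H >= 1 and W >= 1")
        if not np.all(np.isfinite(px)):
            raise ContractError("image contains non-finite values")
        if self.value_range is not None:
            lo, hi = self.value_range
            if px.min() < lo - 1e-12 or px.max() > hi + 1e-12:
                raise ContractError(
                    f"pixels outside declared range [{lo}, {hi}]: "
                    f"[{px.min():.6g}, {px.max():.6g}]"
                )
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class HairMask:
    """H x W binary grid; 1 marks a hair pixel, 0 background."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ContractError(f"mask must be HxW, got shape {px.shape}")
        if not np.isin(px, (0.0, 1.0)).all():
            raise ContractError("mask entries must be exactly 0 or 1")
        self.pixels = px

    @classmethod
    def from_grayscale(cls, gray: np.ndarray, threshold: float = 0.5) -> "HairMask":
        """Binarize a grayscale mask image at ``threshold`` (default 0.5)."""
        gray = np.asarray(gray, dtype=np.float64)
        if gray.ndim == 3:
            gray = gray.mean(axis=2)
        return cls((gray >= threshold).astype(np.float64))


@dataclass
class PairedSample:
    """One (hairy, hair-free) training pair with its diagnostic label."""

    hairy: RasterImage
    clean: RasterImage
    label: str
    id: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ContractError(f"unknown label {self.label!r}; expected one of {CLASSES}")
        if self.hairy.pixels.shape != self.clean.pixels.shape:
            raise ContractError("hairy and clean images must share dimensions")


@dataclass
class DatasetManifest:
    """Index of a paired dataset: per-class sample ids and the train/test split."""

    root: str
    classes: dict[str, list[str]] = field(default_factory=dict)
    train_ids: dict[str, list[str]] = field(default_factory=dict)
    test_ids: dict[str, list[str]] = field(default_factory=dict)
    seed: int | None = None

    def n_samples(self) -> int:
        return sum(len(v) for v in self.classes.values())

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "root": self.root,
            "classes": self.classes,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "seed": self.seed,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def pair_paths(self, label: str, sample_id: str) -> tuple[Path, Path]:
        root = Path(self.root)
        return (
            root / "Data_Skin_with_Hair" / label / f"{sample_id}.png",
            root / "Data_Skin_without_Hair" / label / f"{sample_id}.png",
        )


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> RasterImage:
    """Read a PNG/JPEG file into a [0, 1]-scaled :class:`RasterImage`."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if im.mode not in ("1", "I", "F") else "L")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / undecodable
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    return RasterImage(arr, value_range=UNIT_RANGE)


def write_image(img: RasterImage, path: str | Path) -> Path:
    """Write an in-range [0, 1] image as 8-bit PNG.

    Quantization rounds half-up: ``floor(v * 255 + 0.5)``. Out-of-range or
    unbounded inputs raise; callers clip explicitly first (no silent clipping).
    """
    if img.value_range != UNIT_RANGE:
        raise ContractError(
            f"write_image requires declared range {UNIT_RANGE}, got {img.value_range}"
        )
    px = img.pixels
    if px.min() < 0.0 or px.max() > 1.0:
        raise ContractError("pixel values outside [0, 1]; clip before writing")
    quant = np.floor(px * 255.0 + 0.5).astype(np.uint8)
    if quant.shape[2] == 1:
        quant = quant[:, :, 0]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(quant).save(path, format="PNG")
    return path


# ---------------------------------------------------------------------------
# procedural fixtures
# ---------------------------------------------------------------------------

def make_lesion_texture(seed: int, size: tuple[int, int] = (64, 64),
                        channels: int = 1) -> RasterImage:
    """Procedural lesion-like texture: smooth skin background + darker blob.

    Deterministic in ``seed``. The background is a skin-toned base with
    low-frequency Gaussian-filtered noise; the lesion surrogate is one
    ellipse with a Gaussian-smoothed boundary, darker than the background.
    """
    H, W = size
    if H < 16 or W < 16:
        raise ContractError(f"size must be at least 16x16, got {size}")
    if channels not in (1, 3):
        raise ContractError("channels must be 1 or 3")
    rng = np.random.default_rng(seed)

    base = rng.uniform(0.55, 0.8)
    background = gaussian_filter(rng.normal(0.0, 1.0, size), sigma=max(H, W) / 12.0)
    bg_span = background.max() - background.min()
    if bg_span > 0:
        background = (background - background.min()) / bg_span  # [0,1]
    texture = base + 0.08 * (background - 0.5)

    # elliptical lesion surrogate, smoothed boundary
    cy = rng.uniform(0.35, 0.65) * H
    cx = rng.uniform(0.35, 0.65) * W
    ay = rng.uniform(0.15, 0.3) * H
    ax = rng.uniform(0.15, 0.3) * W
    theta = rng.uniform(0.0, np.pi)
    contrast = rng.uniform(0.2, 0.4)
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    ry = dy * np.cos(theta) - dx * np.sin(theta)
    rx = dy * np.sin(theta) + dx * np.cos(theta)
    inside = ((ry / ay) ** 2 + (rx / ax) ** 2 <= 1.0).astype(np.float64)
    blob = gaussian_filter(inside, sigma=min(H, W) / 24.0)
    texture = texture - contrast * blob

    texture = np.clip(texture, 0.0, 1.0)
    if channels == 3:
        # mild per-channel tint so RGB fixtures are not trivially gray
        tint = np.array([1.0, 0.92, 0.88]) + rng.uniform(-0.02, 0.02, 3)
        texture = np.clip(texture[:, :, None] * tint[None, None, :], 0.0, 1.0)
    return RasterImage(texture, value_range=UNIT_RANGE)


def _strand_points(rng: np.random.Generator, size: tuple[int, int],
                   curvature: float) -> tuple[np.ndarray, np.ndarray]:
    """Rasterized pixel coordinates of one curved polyline strand."""
    H, W = size
    n_seg = 6
    seg_len = max(3.0, 0.12 * min(H, W))
    r = float(rng.uniform(0, H - 1))
    c = float(rng.uniform(0, W - 1))
    angle = float(rng.uniform(0, 2 * np.pi))
    rows, cols = [], []
    for _ in range(n_seg):
        r2 = r + seg_len * np.sin(angle)
        c2 = c + seg_len * np.cos(angle)
        rr, cc = _bresenham_line(int(round(r)), int(round(c)),
                                 int(round(r2)), int(round(c2)))
        rows.append(rr)
        cols.append(cc)
        r, c = r2, c2
        angle += float(rng.normal(0.0, curvature))
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    return rr[keep], cc[keep]


def make_procedural_hair_mask(seed: int, size: tuple[int, int] = (64, 64),
                              n_strands: int = 5,
                              curvature: float = 0.3) -> HairMask:
    """Binary mask of ``n_strands`` thin curved strands; pure in (seed, params).

    Strand placement retries to keep strands disjoint (8-connectivity) so the
    connected-component count equals ``n_strands`` on a canvas large enough to
    hold them; if separation cannot be achieved the last draw is kept anyway.
    """
    if n_strands < 0:
        raise ContractError("n_strands must be >= 0")
    H, W = size
    rng = np.random.default_rng(seed)
    mask = np.zeros((H, W), dtype=np.float64)
    # occupancy dilated by one pixel keeps new strands non-adjacent
    blocked = np.zeros((H, W), dtype=bool)
    for _ in range(n_strands):
        for _attempt in range(50):
            rr, cc = _strand_points(rng, size, curvature)
            if len(rr) and not blocked[rr, cc].any():
                break
        mask[rr, cc] = 1.0
        r0 = np.clip(rr[:, None] + np.array([-1, 0, 1])[None, :], 0, H - 1)
        c0 = np.clip(cc[:, None] + np.array([-1, 0, 1])[None, :], 0, W - 1)
        for dr in range(3):
            for dc in range(3):
                blocked[r0[:, dr], c0[:, dc]] = True
    return HairMask(mask)


# ---------------------------------------------------------------------------
# dataset layout and split
# ---------------------------------------------------------------------------

def build_dermahair_layout(pairs: Sequence[PairedSample],
                           root: str | Path) -> DatasetManifest:
    """Write paired samples to the two-root/seven-class directory convention.

    Hairy images go under ``<root>/Data_Skin_with_Hair/<class>/<id>.png`` and
    the hair-free counterparts under ``Data_Skin_without_Hair`` with matching
    basenames. All 14 class directories are created even when empty.
    """
    root = Path(root)
    seen: set[str] = set()
    for cls in CLASSES:
        (root / "Data_Skin_with_Hair" / cls).mkdir(parents=True, exist_ok=True)
        (root / "Data_Skin_without_Hair" / cls).mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest(root=str(root),
                               classes={cls: [] for cls in CLASSES})
    for pair in pairs:
        if pair.id in seen:
            raise ContractError(f"duplicate sample id {pair.id!r}")
        seen.add(pair.id)
        hairy_path, clean_path = manifest.pair_paths(pair.label, pair.id)
        write_image(pair.hairy, hairy_path)
        write_image(pair.clean, clean_path)
        manifest.classes[pair.label].append(pair.id)
    return manifest


def split_per_class(manifest: DatasetManifest, n_test: int,
                    seed: int) -> DatasetManifest:
    """Reserve ``n_test`` samples per class for the test split, rest for train.

    Stratified and deterministic in ``seed``; the benchmark convention holds
    100 images per class out (700 test images over the seven classes).
    """
    rng = np.random.default_rng(seed)
    train_ids: dict[str, list[str]] = {}
    test_ids: dict[str, list[str]] = {}
    for cls in sorted(manifest.classes):
        ids = sorted(manifest.classes[cls])
        if len(ids) < n_test:
            raise ContractError(
                f"class {cls!r} has {len(ids)} samples, fewer than n_test={n_test}"
            )
        perm = rng.permutation(len(ids))
        test_ids[cls] = sorted(ids[i] for i in perm[:n_test])
        train_ids[cls] = sorted(ids[i] for i in perm[n_test:])
    return DatasetManifest(root=manifest.root, classes=dict(manifest.classes),
                           train_ids=train_ids, test_ids=test_ids, seed=seed)


def load_pairs(manifest: DatasetManifest, split: str = "train") -> list[PairedSample]:
    """Load the (hairy, clean) image pairs of one split from disk."""
    ids = manifest.train_ids if split == "train" else manifest.test_ids
    pairs = []
    for cls in sorted(ids):
        for sample_id in ids[cls]:
            hairy_path, clean_path = manifest.pair_paths(cls, sample_id)
            pairs.append(PairedSample(hairy=read_image(hairy_path),
                                      clean=read_image(clean_path),
                                      label=cls, id=sample_id))
    return pairs
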