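"""Synthetic hair degradation.

Two generators produce hairy/hair-free training pairs from clean images:

1. **Mask overlay arithmetic** — given a binary hair mask (1 = hair), the
   mask is complemented (``-1 * (mask - 1)``), added to the image, and the
   merged result is post-processed by subtracting 1. Algebraically the
   unclipped result is exactly ``img - mask``: background pixels are
   untouched and hair pixels are darkened by a full intensity unit (negative
   values are possible; the rendered variant clips to [0, 1]).

2. **Self-supervised line synthesis** — a fixed number of short diagonal
   segments (default 1000) is drawn at random positions: start coordinates
   uniform integers on [0, W] x [0, H], length a uniform integer in
   [10, 30], direction d uniform on {-1, +1}, endpoints
   ``x_end = x_start + d * length`` and ``y_end = y_start + length``.
   Segments are rasterized with Bresenham's algorithm, clipped to the
   canvas, and painted a constant color (default black).

Coordinates follow the raster convention: x = column, y = row, origin at
the top-left. All operations are pure given their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _bresenham_line

from .fixtures_io import ContractError, HairMask, RasterImage, UNIT_RANGE

DEFAULT_N_LINES = 1000
DEFAULT_LENGTH_RANGE = (10, 30)


# ---------------------------------------------------------------------------
# mask-overlay arithmetic
# ---------------------------------------------------------------------------

@dataclass
class OverlayResult:
    """All intermediates of the mask-overlay pipeline.

    ``merged`` and ``final_unclipped`` are unbounded grids (values can leave
    [0, 1]); ``final_clipped`` is the rendered [0, 1] image.
    """

    normalized_mask: np.ndarray
    merged: np.ndarray
    final_unclipped: np.ndarray
    final_clipped: RasterImage


def normalize_hair_mask(mask: HairMask | np.ndarray) -> np.ndarray:
    """Complement a binary hair mask: ``-1 * (mask - 1)``, i.e. 1 <-> 0."""
    px = mask.pixels if isinstance(mask, HairMask) else np.asarray(mask, dtype=np.float64)
    if not np.isin(px, (0.0, 1.0)).all():
        raise ContractError("hair mask must be binary {0, 1}")
    return -1.0 * (px - 1.0) + 0.0   # +0.0 normalizes -0.0


def merge_images(img: np.ndarray, normalized_mask: np.ndarray) -> np.ndarray:
    """Elementwise sum of image and complemented mask (range may exceed [0,1])."""
    img = np.asarray(img, dtype=np.float64)
    normalized_mask = np.asarray(normalized_mask, dtype=np.float64)
    if img.shape != normalized_mask.shape:
        raise ContractError(
            f"shape mismatch: image {img.shape} vs mask {normalized_mask.shape}"
        )
    return img + normalized_mask


def postprocess_merged(merged: np.ndarray) -> np.ndarray:
    """Subtract 1 from the merged image (unclipped)."""
    return np.asarray(merged, dtype=np.float64) - 1.0


def add_mask_hair(img: RasterImage, mask: HairMask, clip: bool = True) -> OverlayResult:
    """Superimpose a binary hair mask on a [0, 1] image.

    The mask is broadcast identically over every channel for RGB input.
    The unclipped output equals ``img - mask`` elementwise; pixels with
    mask = 0 are bit-identical to the input.
    """
    if img.value_range != UNIT_RANGE:
        raise ContractError("add_mask_hair expects a [0, 1] image")
    mpx = mask.pixels
    if mpx.shape != img.pixels.shape[:2]:
        raise ContractError(
            f"shape mismatch: image {img.pixels.shape[:2]} vs mask {mpx.shape}"
        )
    mask_b = np.broadcast_to(mpx[:, :, None], img.pixels.shape)
    normalized = normalize_hair_mask(mask)
    normalized_b = np.broadcast_to(normalized[:, :, None], img.pixels.shape)
    merged = merge_images(img.pixels, normalized_b)
    # the closed form img - mask is the authoritative result: it keeps
    # mask=0 pixels bit-identical to the input, which the staged
    # add-then-subtract arithmetic only matches to float rounding
    final = img.pixels - mask_b
    assert np.allclose(final, postprocess_merged(merged), atol=1e-12)
    clipped = RasterImage(np.clip(final, 0.0, 1.0), value_range=UNIT_RANGE)
    return OverlayResult(normalized_mask=normalized, merged=merged,
                         final_unclipped=final, final_clipped=clipped)


# ---------------------------------------------------------------------------
# self-supervised line synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineSpec:
    """One diagonal hair segment: start point, length, direction, endpoints."""

    x_start: int
    y_start: int
    length: int
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ContractError("direction must be -1 or +1")

    @property
    def x_end(self) -> int:
        return self.x_start + self.direction * self.length

    @property
    def y_end(self) -> int:
        return self.y_start + self.length


def sample_line(rng: np.random.Generator, W: int, H: int,
                length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE) -> LineSpec:
    """Draw one random segment spec.

    Draw order is fixed (x_start, y_start, length, direction) for
    reproducibility. Start coordinates are integers on the inclusive ranges
    [0, W] and [0, H]; overhanging endpoints are clipped at rasterization.
    """
    lo, hi = length_range
    if lo > hi:
        raise ContractError("length_range must satisfy lo <= hi")
    x_start = int(rng.integers(0, W + 1))
    y_start = int(rng.integers(0, H + 1))
    length = int(rng.integers(lo, hi + 1))
    direction = int(rng.choice((-1, 1)))
    return LineSpec(x_start=x_start, y_start=y_start, length=length,
                    direction=direction)


def _paint_line(px: np.ndarray, spec: LineSpec, color: float, width: int) -> None:
    """Paint one segment in place on an HxWxC pixel grid."""
    H, W = px.shape[:2]
    rr, cc = _bresenham_line(spec.y_start, spec.x_start, spec.y_end, spec.x_end)
    rows, cols = [rr], [cc]
    for off in range(1, width):
        shift = (off + 1) // 2 * (1 if off % 2 else -1)
        rows.append(rr)
        cols.append(cc + shift)
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    px[rr[keep], cc[keep], :] = color


def rasterize_line(img: RasterImage, spec: LineSpec, color: float = 0.0,
                   width: int = 1) -> RasterImage:
    """Paint one segment onto a copy of the image (input never mutated).

    Bresenham path from (x_start, y_start) to (x_end, y_end); pixels outside
    the canvas are dropped. ``width`` > 1 thickens the stroke by offsetting
    the path perpendicular to its dominant axis.
    """
    px = img.pixels.copy()
    _paint_line(px, spec, color, width)
    return RasterImage(px, value_range=img.value_range)


def synth_line_hair(img: RasterImage, n_lines: int = DEFAULT_N_LINES,
                    seed: int = 0,
                    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
                    color: float = 0.0, width: int = 1,
                    return_lines: bool = False):
    """Draw ``n_lines`` random diagonal segments simulating hair strands.

    Deterministic for a fixed seed; the input image is not mutated. With
    ``return_lines=True`` the sampled :class:`LineSpec` list is returned
    alongside the degraded image.
    """
    if img.value_range != UNIT_RANGE:
        raise ContractError("synth_line_hair expects a [0, 1] image")
    rng = np.random.default_rng(seed)
    px = img.pixels.copy()
    lines = []
    H, W = img.height, img.width
    for _ in range(n_lines):
        spec = sample_line(rng, W, H, length_range)
        lines.append(spec)
        _paint_line(px, spec, color, width)
    out = RasterImage(px, value_range=img.value_range)
    if return_lines:
        return out, lines
    return out
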