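"""Colour-based segmentation of top-view canopy images.

Projected leaf area is measured from overhead RGB frames of the cultivation
floor.  Vegetation is separated from the grey floor by the excess-green
index, ExG = 2G - R - B, thresholded on the 0-255 scale; speckle is removed
with a minimum-blob filter (8-connectivity).  A synthetic canopy renderer
provides images with exactly known foreground area for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .errors import ValidationError


@dataclass
class CanopyImage:
    """8-bit RGB raster (row-major, origin top-left) with its pixel scale."""

    pixels: np.ndarray  # (H, W, 3) uint8
    scale: float        # metres per pixel

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"expected an RGB (H, W, 3) image, got shape {self.pixels.shape}"
            )
        if self.scale <= 0:
            raise ValidationError("scale must be positive (metres per pixel)")


@dataclass
class SegmentationParams:
    exg_threshold: float = 20.0  # excess-green cutoff on the 0-255 scale
    min_blob_px: int = 16        # connected components smaller than this are dropped

    def __post_init__(self):
        if self.min_blob_px < 0:
            raise ValidationError("min_blob_px must be >= 0")


def excess_green_mask(
    image: CanopyImage, params: SegmentationParams | None = None
) -> np.ndarray:
    """Binary vegetation mask: pixels with 2G - R - B above the threshold.

    Components smaller than ``min_blob_px`` (8-connectivity) are removed.
    """
    params = params or SegmentationParams()
    px = image.pixels.astype(np.int32)
    exg = 2 * px[..., 1] - px[..., 0] - px[..., 2]
    mask = exg > params.exg_threshold
    if params.min_blob_px > 1:
        mask = morphology.remove_small_objects(
            mask, max_size=params.min_blob_px - 1, connectivity=2
        )
    return mask


def projected_area_from_mask(mask: np.ndarray, scale: float) -> float:
    """Foreground area in m^2: pixel count times the pixel area."""
    if scale <= 0:
        raise ValidationError("scale must be positive")
    return float(np.count_nonzero(mask)) * scale * scale


def segment_area(
    image: CanopyImage, params: SegmentationParams | None = None
) -> float:
    """Convenience: excess-green segmentation straight to projected area (m^2)."""
    return projected_area_from_mask(excess_green_mask(image, params), image.scale)


def render_canopy(
    n_plants: int,
    mean_radius: float,
    frame: tuple[float, float] = (1.2, 1.5),
    scale: float = 0.004,
    seed: int = 0,
) -> tuple[CanopyImage, float]:
    """Render a synthetic top-view canopy with exactly known foreground area.

    Plants are clusters of overlapping green ellipses (leaf-like hue jitter)
    on a grey floor, centred on a jittered grid.  Returns the image and the
    exact rendered foreground area (mask pixel count x pixel area), which is
    the ground truth for segmentation round-trips.  Deterministic per seed.
    """
    if n_plants < 0:
        raise ValidationError("n_plants must be >= 0")
    h = int(round(frame[0] / scale))
    w = int(round(frame[1] / scale))
    rng = np.random.default_rng(seed)
    img = np.full((h, w, 3), 110, np.uint8)
    # grey-level floor texture so a uniform-background shortcut cannot pass
    noise = rng.integers(-6, 7, size=(h, w, 1))
    img = np.clip(img.astype(np.int32) + noise, 0, 255).astype(np.uint8)
    fg = np.zeros((h, w), bool)
    if n_plants > 0:
        r_px = mean_radius / scale
        # jittered grid layout
        ncol = int(np.ceil(np.sqrt(n_plants * w / h)))
        nrow = int(np.ceil(n_plants / ncol))
        if (nrow * 2 * r_px > h) or (ncol * 2 * r_px > w):
            raise ValidationError(
                f"{n_plants} plants of radius {mean_radius} m do not fit the frame"
            )
        cell_h, cell_w = h / nrow, w / ncol
        centres = []
        for k in range(n_plants):
            i, j = divmod(k, ncol)
            cy = (i + 0.5) * cell_h + rng.uniform(-0.1, 0.1) * cell_h
            cx = (j + 0.5) * cell_w + rng.uniform(-0.1, 0.1) * cell_w
            centres.append((cy, cx))
        yy, xx = np.mgrid[0:h, 0:w]
        for cy, cx in centres:
            n_leaves = rng.integers(5, 9)
            for _ in range(n_leaves):
                ang = rng.uniform(0, 2 * np.pi)
                off = rng.uniform(0.15, 0.45) * r_px
                ly, lx = cy + off * np.sin(ang), cx + off * np.cos(ang)
                a = rng.uniform(0.45, 0.75) * r_px
                b = rng.uniform(0.30, 0.55) * r_px
                ca, sa = np.cos(ang), np.sin(ang)
                dy, dx = yy - ly, xx - lx
                u = ca * dx + sa * dy
                v = -sa * dx + ca * dy
                leaf = (u / a) ** 2 + (v / b) ** 2 <= 1.0
                g = int(rng.uniform(130, 190))
                r = int(rng.uniform(30, 70))
                bch = int(rng.uniform(30, 70))
                img[leaf] = (r, g, bch)
                fg |= leaf
    true_area = float(np.count_nonzero(fg)) * scale * scale
    return CanopyImage(pixels=img, scale=scale), true_area


def render_disk(
    radius_px: int, margin_px: int = 10, scale: float = 0.004
) -> tuple[CanopyImage, float]:
    """A single green disk on grey floor — analytic-area fixture."""
    side = 2 * (radius_px + margin_px)
    img = np.full((side, side, 3), 110, np.uint8)
    yy, xx = np.mgrid[0:side, 0:side]
    c = side / 2 - 0.5
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
    img[disk] = (40, 160, 40)
    return CanopyImage(pixels=img, scale=scale), float(disk.sum()) * scale * scale


def label_plants(mask: np.ndarray) -> int:
    """Number of connected canopy components (diagnostic only)."""
    return int(measure.label(mask, connectivity=2).max())
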