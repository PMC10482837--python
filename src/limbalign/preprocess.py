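"""Deterministic image operators applied ahead of detection/segmentation.

All operators work on single-channel images (8-bit grayscale or unit-interval
float) wrapped in :class:`ImageBuffer` and publish the exact coordinate
transform they induce, so landmark coordinates can be mapped between the
processed and original frames. Conventions: 0-based (row, col), half-open
boxes, pad fill 0 (radiograph background is black).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageBuffer",
    "RoiBox",
    "CoordTransform",
    "load_grayscale",
    "pad_to_square",
    "resize_fixed",
    "clahe",
    "normalize_unit",
    "crop_roi",
    "flip_right_to_left",
]

#: The ten full-image ROI classes (five anatomical classes per side).
FULL_ROI_CLASSES = tuple(
    f"{side}_{cls}" for side in ("left", "right")
    for cls in ("femoral_shaft", "tibial_shaft", "femoral_head", "knee", "ankle"))


@dataclass(frozen=True)
class ImageBuffer:
    """A 2-D intensity buffer plus its (row, col) origin offset in the
    full-image frame."""

    pixels: np.ndarray
    origin_offset: tuple = (0, 0)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("ImageBuffer requires a non-empty 2-D array")
        if self.origin_offset[0] < 0 or self.origin_offset[1] < 0:
            raise ValueError("origin offset components must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class RoiBox:
    """0-based half-open bounding box for one ROI class."""

    class_label: str
    bounds: tuple  # (row_min, col_min, row_max, col_max)

    def __post_init__(self):
        r0, c0, r1, c1 = self.bounds
        if not (r0 < r1 and c0 < c1):
            raise ValueError(f"degenerate box bounds {self.bounds}")


@dataclass(frozen=True)
class CoordTransform:
    """Axis-aligned affine map ``p_out = p_in * scale + shift`` on
    (row, col) coordinates; invertible exactly."""

    scale: tuple = (1.0, 1.0)
    shift: tuple = (0.0, 0.0)

    def apply(self, points):
        p = np.asarray(points, dtype=float)
        return p * np.asarray(self.scale) + np.asarray(self.shift)

    def invert(self, points):
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.shift)) / np.asarray(self.scale)

    def compose(self, inner: "CoordTransform") -> "CoordTransform":
        """Transform equivalent to applying ``inner`` first, then self."""
        s = (self.scale[0] * inner.scale[0], self.scale[1] * inner.scale[1])
        t = (self.scale[0] * inner.shift[0] + self.shift[0],
             self.scale[1] * inner.shift[1] + self.shift[1])
        return CoordTransform(s, t)


def load_grayscale(path) -> ImageBuffer:
    """Read a PNG/JPEG as single-channel; RGB inputs (gray-valued 24-bit
    radiographs) are collapsed by channel average."""
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2).round().astype(np.uint8)
    return ImageBuffer(img)


def pad_to_square(img: ImageBuffer, fill=0):
    """Pad to side = max(h, w) with content centred; remainder goes to the
    bottom/right. Returns ``(padded, transform)`` with the original -> padded
    coordinate map."""
    h, w = img.shape
    side = max(h, w)
    top = (side - h) // 2
    left = (side - w) // 2
    out = np.full((side, side), fill, dtype=img.pixels.dtype)
    out[top:top + h, left:left + w] = img.pixels
    return (ImageBuffer(out, img.origin_offset),
            CoordTransform(shift=(float(top), float(left))))


def resize_fixed(img: ImageBuffer, target):
    """Bilinear resize to a fixed (rows, cols) size. The returned transform
    maps input pixel-centre coordinates to output ones
    (``out = (in + 0.5) * s - 0.5``)."""
    tr, tc = int(target[0]), int(target[1])
    if tr <= 0 or tc <= 0:
        raise ValueError("target dimensions must be positive")
    h, w = img.shape
    out = _sk_resize(img.pixels.astype(float), (tr, tc), order=1,
                     preserve_range=True, anti_aliasing=False)
    if np.issubdtype(img.pixels.dtype, np.integer):
        out = np.clip(np.round(out), 0, np.iinfo(img.pixels.dtype).max
                      ).astype(img.pixels.dtype)
    sr, sc = tr / h, tc / w
    t = CoordTransform(scale=(sr, sc), shift=(0.5 * sr - 0.5, 0.5 * sc - 0.5))
    return ImageBuffer(out, img.origin_offset), t


def clahe(img: ImageBuffer, block=(8, 8), clip: float = 2.0) -> ImageBuffer:
    """Contrast-limited adaptive histogram equalisation for 8-bit grayscale.

    The image is divided into a ``block`` = (rows, cols) grid of tiles (edge
    tiles absorb the division remainder). Each tile's 256-bin histogram is
    clipped at ``clip`` times the uniform bin height, the excess is
    redistributed uniformly, and each pixel is mapped by bilinear
    interpolation between the transfer functions of the four nearest tile
    centres. ``clip`` <= 0 or a non-8-bit input is rejected.
    """
    px = img.pixels
    if px.dtype != np.uint8:
        raise ValueError("clahe requires an 8-bit grayscale image")
    gr, gc = int(block[0]), int(block[1])
    if gr < 1 or gc < 1 or clip <= 0:
        raise ValueError("block must be >= (1,1) and clip > 0")
    h, w = px.shape
    gr, gc = min(gr, h), min(gc, w)
    nbins = 256

    # tile edges: even division, remainder absorbed by the last tile
    redges = np.linspace(0, h, gr + 1).round().astype(int)
    cedges = np.linspace(0, w, gc + 1).round().astype(int)
    luts = np.empty((gr, gc, nbins), dtype=float)
    centers_r = np.empty(gr)
    centers_c = np.empty(gc)
    for i in range(gr):
        centers_r[i] = (redges[i] + redges[i + 1] - 1) / 2.0
        for j in range(gc):
            if i == 0:
                centers_c[j] = (cedges[j] + cedges[j + 1] - 1) / 2.0
            tile = px[redges[i]:redges[i + 1], cedges[j]:cedges[j + 1]]
            area = tile.size
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(float)
            if np.count_nonzero(hist) == 1:
                # a constant tile has no contrast to equalise: identity map
                luts[i, j] = np.arange(nbins)
                continue
            limit = max(clip * area / nbins, 1.0)
            excess = np.clip(hist - limit, 0, None).sum()
            hist = np.minimum(hist, limit) + excess / nbins
            cdf = np.cumsum(hist)
            luts[i, j] = np.round(cdf * (nbins - 1) / area)

    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    i1 = np.clip(np.searchsorted(centers_r, rows), 0, gr - 1)
    i0 = np.clip(i1 - 1, 0, gr - 1)
    j1 = np.clip(np.searchsorted(centers_c, cols), 0, gc - 1)
    j0 = np.clip(j1 - 1, 0, gc - 1)
    span_r = np.where(i1 > i0, centers_r[i1] - centers_r[i0], 1.0)
    wr = np.clip((rows - centers_r[i0]) / span_r, 0.0, 1.0)
    span_c = np.where(j1 > j0, centers_c[j1] - centers_c[j0], 1.0)
    wc = np.clip((cols - centers_c[j0]) / span_c, 0.0, 1.0)

    I0, I1 = i0[:, None], i1[:, None]
    J0, J1 = j0[None, :], j1[None, :]
    WR = wr[:, None]
    WC = wc[None, :]
    out = ((1 - WR) * (1 - WC) * luts[I0, J0, px]
           + (1 - WR) * WC * luts[I0, J1, px]
           + WR * (1 - WC) * luts[I1, J0, px]
           + WR * WC * luts[I1, J1, px])
    return ImageBuffer(np.clip(np.round(out), 0, 255).astype(np.uint8),
                       img.origin_offset)


def normalize_unit(img: ImageBuffer) -> ImageBuffer:
    """Map 8-bit intensities to [0, 1] floats (model-input normalisation;
    inert in the geometry path)."""
    return ImageBuffer(img.pixels.astype(float) / 255.0, img.origin_offset)


def crop_roi(img: ImageBuffer, box: RoiBox) -> ImageBuffer:
    """Copy the box contents into a new buffer whose origin offset is the
    box origin in the full-image frame."""
    r0, c0, r1, c1 = box.bounds
    h, w = img.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(f"ROI box {box.bounds} exceeds image bounds {h}x{w}")
    off = img.origin_offset
    return ImageBuffer(img.pixels[r0:r1, c0:c1].copy(),
                       (off[0] + r0, off[1] + c0))


def flip_right_to_left(img: ImageBuffer, side: str):
    """Mirror a right-side buffer horizontally so it matches the left-side
    convention; left-side input is returned unchanged. Returns
    ``(buffer, flipped)`` — when ``flipped`` a detected column ``c``
    un-mirrors to ``W - 1 - c``."""
    if side == "left":
        return img, False
    if side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return ImageBuffer(img.pixels[:, ::-1].copy(), img.origin_offset), True
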