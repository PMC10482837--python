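"""Per-class binary mask containers and their on-disk layout.

A :class:`MaskSet` holds one binary mask per anatomical ROI class for one
limb, each cropped to its bounding box with an integer ``(row, col)`` offset
into a common full-image coordinate frame, plus the pixel spacing (mm/px)
and laterality.

On disk a mask set is one directory: one 8-bit PNG per class named
``{side}_{class}.png`` (nonzero = foreground) and a ``rois.json`` sidecar
with the offsets (0-based half-open boxes in full-image coordinates), pixel
spacing, side and canvas size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["ROI_CLASSES", "MaskSet", "MissingStructureError"]

#: The five per-side ROI classes (the study's ten ROIs are these, per side).
ROI_CLASSES = ("femoral_shaft", "tibial_shaft", "femoral_head", "knee", "ankle")


class MissingStructureError(ValueError):
    """An expected anatomical structure or ROI class is absent."""


@dataclass
class MaskSet:
    side: str
    pixel_spacing: float
    canvas_shape: tuple
    masks: dict = field(default_factory=dict)
    offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")

    def validate(self, required=ROI_CLASSES) -> None:
        for cls in required:
            if cls not in self.masks:
                raise MissingStructureError(f"mask set is missing ROI class {cls!r}")
            if cls not in self.offsets:
                raise MissingStructureError(f"no offset recorded for ROI class {cls!r}")
            r0, c0 = self.offsets[cls]
            if r0 < 0 or c0 < 0:
                raise ValueError(f"negative offset for {cls!r}")
            if not self.masks[cls].any():
                raise MissingStructureError(f"mask for ROI class {cls!r} is empty")

    def full_mask(self, cls: str) -> np.ndarray:
        """Place the cropped class mask into a full-canvas boolean array."""
        out = np.zeros(self.canvas_shape, dtype=bool)
        m = self.masks[cls]
        r0, c0 = self.offsets[cls]
        out[r0:r0 + m.shape[0], c0:c0 + m.shape[1]] = m
        return out

    def box(self, cls: str) -> tuple:
        """0-based half-open bounding box (row_min, col_min, row_max, col_max)."""
        m = self.masks[cls]
        r0, c0 = self.offsets[cls]
        return (r0, c0, r0 + m.shape[0], c0 + m.shape[1])

    def copy(self) -> "MaskSet":
        return MaskSet(
            side=self.side,
            pixel_spacing=self.pixel_spacing,
            canvas_shape=tuple(self.canvas_shape),
            masks={k: v.copy() for k, v in self.masks.items()},
            offsets={k: tuple(v) for k, v in self.offsets.items()},
        )

    # ------------------------------------------------------------------ io

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rois = {}
        for cls, m in self.masks.items():
            iio.imwrite(directory / f"{self.side}_{cls}.png",
                        (m.astype(np.uint8) * 255))
            r0, c0 = self.offsets[cls]
            rois[cls] = [int(r0), int(c0), int(r0 + m.shape[0]), int(c0 + m.shape[1])]
        meta = {
            "side": self.side,
            "pixel_spacing": self.pixel_spacing,
            "canvas_shape": [int(x) for x in self.canvas_shape],
            "rois": rois,
        }
        (directory / "rois.json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load(directory, side: str | None = None) -> "MaskSet":
        directory = Path(directory)
        meta = json.loads((directory / "rois.json").read_text())
        side = side or meta["side"]
        ms = MaskSet(side=side,
                     pixel_spacing=float(meta["pixel_spacing"]),
                     canvas_shape=tuple(meta["canvas_shape"]))
        for cls, box in meta["rois"].items():
            path = directory / f"{side}_{cls}.png"
            if not path.exists():
                raise MissingStructureError(f"mask file not found: {path.name}")
            img = np.asarray(iio.imread(path))
            if img.ndim == 3:
                img = img[..., :3].mean(axis=2)
            ms.masks[cls] = img > 0
            ms.offsets[cls] = (int(box[0]), int(box[1]))
        return ms
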