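"""Planar geometry primitives shared across the measurement pipeline.

Coordinate convention (used everywhere in this package): 0-based
``(row, col)`` with row increasing downward, i.e. superior -> inferior on an
upright full-leg radiograph. Boxes are half-open. Direction *angles* are
measured from the straight-down unit vector ``(1, 0)``, positive toward
increasing column; :func:`dir_vec` converts such an angle to a unit vector.

For a left-side limb the lateral side is toward smaller column indices and
the medial side toward larger ones (mirrored for the right side). Medial /
lateral labelling is always derived from the side flag, never from image
content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Point",
    "AxisLine",
    "dir_vec",
    "unit",
    "rotate",
    "ray",
    "ray_angle",
    "acute_angle",
    "perp_distance",
    "signed_perp_distance",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction collapses (coincident points,
    collinear circle input, zero-length direction, ...)."""


@dataclass(frozen=True)
class Point:
    """A 2-D point in the full-image frame, in pixel units unless noted."""

    row: float
    col: float

    def as_array(self) -> np.ndarray:
        return np.array([self.row, self.col], dtype=float)

    @staticmethod
    def from_array(a) -> "Point":
        return Point(float(a[0]), float(a[1]))

    def distance_to(self, other: "Point") -> float:
        return float(np.hypot(self.row - other.row, self.col - other.col))

    def translated(self, drow: float, dcol: float) -> "Point":
        return Point(self.row + drow, self.col + dcol)

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.row) and np.isfinite(self.col))


@dataclass(frozen=True)
class AxisLine:
    """An oriented line: an anchor point plus a unit direction ``(drow, dcol)``.

    Orientation matters for clinically signed angles: shaft and mechanical
    axes are stored proximal -> distal, the femoral neck axis is stored
    pointing toward the head centre.
    """

    anchor: Point
    direction: tuple

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise DegenerateGeometryError("axis direction has zero length")
        object.__setattr__(self, "direction", (float(d[0] / n), float(d[1] / n)))

    @property
    def d(self) -> np.ndarray:
        return np.array(self.direction, dtype=float)

    def point_at(self, t: float) -> Point:
        return Point(self.anchor.row + t * self.direction[0],
                     self.anchor.col + t * self.direction[1])

    def reversed(self) -> "AxisLine":
        return AxisLine(self.anchor, (-self.direction[0], -self.direction[1]))


def dir_vec(angle_deg: float) -> np.ndarray:
    """Unit vector at ``angle_deg`` from straight-down, positive toward +col."""
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise DegenerateGeometryError("cannot normalise zero-length vector")
    return v / n


def rotate(v, angle_deg: float) -> np.ndarray:
    """Rotate a (row, col) vector; rotate(dir_vec(a), d) == dir_vec(a + d)."""
    v = np.asarray(v, dtype=float)
    c, s = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def ray(frm: Point, to: Point) -> np.ndarray:
    """Unit vector from one landmark toward another."""
    d = to.as_array() - frm.as_array()
    n = np.linalg.norm(d)
    if n == 0:
        raise DegenerateGeometryError(f"coincident landmarks: {frm} and {to}")
    return d / n


def ray_angle(u, v) -> float:
    """Angle in degrees between two oriented rays, in [0, 180]."""
    dot = float(np.clip(np.dot(unit(u), unit(v)), -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def acute_angle(u, v) -> float:
    """Angle in degrees between two *lines* (orientation ignored), in [0, 90]."""
    dot = float(np.clip(abs(np.dot(unit(u), unit(v))), 0.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def signed_perp_distance(p: Point, line: AxisLine) -> float:
    """Perpendicular distance of ``p`` from the line, signed by the cross
    product of the line direction with the anchor->p vector (positive toward
    the +90 deg rotation of the direction)."""
    d = line.d
    rel = p.as_array() - line.anchor.as_array()
    return float(d[0] * rel[1] - d[1] * rel[0])


def perp_distance(p: Point, line: AxisLine) -> float:
    return abs(signed_perp_distance(p, line))
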