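"""Synthetic full-leg phantom with closed-form ground truth.

The phantom models each bone as a union of piecewise-analytic primitives
(discs, rectangles, convex quads) in a continuous millimetre frame, so every
anatomical landmark and every alignment parameter has an exact closed-form
value *before* any rasterisation. Rasterisation error is therefore part of
the measured pipeline error, not of the ground truth.

Construction (left-side convention; the right side is an exact mirror):

* the tibial mechanical axis is vertical through the tibial knee centre;
* the tibial plateau line is tilted so that the medial proximal tibial angle
  equals ``mMPTA_true``; the femoral condylar line is the plateau line
  rotated by ``jlca_true``; the femoral mechanical axis is placed so that
  the lateral distal femoral angle equals ``mLDFA_true``;
* the femoral head is a disc on the mechanical axis; the femoral anatomical
  (shaft) axis is the mechanical axis tilted laterally by the
  anatomical-mechanical angle; the neck joins head centre to shaft at
  ``neck_shaft_angle``; the greater trochanter is a disc whose tip realises
  ``mLPFA_true``;
* joint surfaces (condyles, plateau, plafond) are pairs of disc lobes whose
  extremal points lie exactly on the joint-orientation lines, joined by a
  connecting quad that creates the intercondylar / interlobe notch.

Angle bookkeeping uses the direction-angle convention of
:mod:`limbalign.geometry` (0 deg = straight down, positive toward medial for
a left limb). With ``theta_c = mMPTA + jlca`` and
``phi = mLDFA - theta_c`` (the varus(+)/valgus(-) tilt of the femoral
mechanical axis from vertical), the implied mechanical tibiofemoral angle is
``|phi|``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import polygon2mask
from skimage.measure import find_contours

from .geometry import AxisLine, Point, dir_vec
from .landmarks import LandmarkSet
from .masks import ROI_CLASSES, MaskSet
from .measure import compute_report

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "PhantomSizeError",
    "sample_spec",
    "generate_phantom",
    "add_boundary_jitter",
    "POPULATIONS",
    "DEFAULT_CANVAS",
]

#: Default canvas (rows, cols) in px at the default 0.48 mm/px spacing —
#: roughly a 4x downsample of a ~3000x7000 px full-leg radiograph, tall
#: enough for legs at the upper end of the emulated population.
DEFAULT_CANVAS = (2000, 760)

POPULATIONS = ("normal", "varus", "valgus", "lld")


class PhantomSizeError(ValueError):
    """The requested limb does not fit the canvas at the given spacing."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic limb.

    All lengths in mm, angles in degrees. ``mLDFA_true``, ``mMPTA_true``,
    ``mLDTA_true``, ``jlca_true`` and ``neck_shaft_angle`` are realised
    exactly by the closed-form geometry; the remaining alignment parameters
    follow from the construction.
    """

    side: str = "left"
    pixel_spacing: float = 0.48
    femoral_length: float = 460.0
    tibial_length: float = 363.0
    neck_shaft_angle: float = 130.0
    neck_length: float = 55.0
    head_radius: float = 25.0
    mLDFA_true: float = 87.5
    mMPTA_true: float = 87.0
    mLDTA_true: float = 89.0
    jlca_true: float = 1.0
    shaft_width: float = 28.0
    condyle_width: float = 85.0
    plafond_width: float = 55.0
    boundary_jitter_sd: float = 0.0
    seed: int = 0
    # shape parameters of the analytic construction
    mLPFA_true: float = 90.0
    anat_mech_angle: float = 6.0
    neck_width: float = 24.0
    trochanter_offset: float = 55.0
    trochanter_radius: float = 16.0
    joint_gap: float = 8.0
    knee_lobe_radius: float = 14.0
    plateau_lobe_radius: float = 12.0
    ankle_lobe_radius: float = 8.0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in ("pixel_spacing", "femoral_length", "tibial_length",
                     "neck_length", "head_radius", "shaft_width",
                     "condyle_width", "plafond_width", "neck_width",
                     "trochanter_offset", "trochanter_radius", "joint_gap",
                     "knee_lobe_radius", "plateau_lobe_radius",
                     "ankle_lobe_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("neck_shaft_angle", "mLDFA_true", "mMPTA_true",
                     "mLDTA_true", "mLPFA_true"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"{name} must lie in (0, 180) deg, got {v}")
        if self.jlca_true < 0 or self.jlca_true >= 90:
            raise ValueError("jlca_true must lie in [0, 90) deg")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PhantomSpec":
        return PhantomSpec(**d)


@dataclass
class PhantomCase:
    """A rasterised phantom together with its closed-form truth."""

    mask_set: MaskSet
    truth_landmarks: LandmarkSet
    truth_report: object
    spec: PhantomSpec


# --------------------------------------------------------------------------
# population sampling

def sample_spec(rng_seed: int, population: str = "normal") -> PhantomSpec:
    """Draw one phantom spec emulating the stated study population.

    ``normal`` samples every parameterised angle inside its printed normal
    range (and the implied tibiofemoral angle near zero); ``varus`` /
    ``valgus`` push the femoral mechanical axis tilt beyond +-3 deg;
    ``lld`` keeps normal angles but shortens the limb.
    """
    if population not in POPULATIONS:
        raise ValueError(
            f"unknown population {population!r}; expected one of {POPULATIONS}")
    rng = np.random.default_rng(rng_seed)

    nsa = rng.uniform(125.0, 135.0)
    mldta = rng.uniform(86.5, 91.5)
    mlpfa = rng.uniform(86.0, 94.0)

    if population in ("normal", "lld"):
        mmpta = rng.uniform(85.5, 88.5)
        jlca = rng.uniform(0.0, 1.5)
        hi = min(0.5, 90.0 - (mmpta + jlca))
        phi = rng.uniform(-0.5, hi)
    elif population == "varus":
        mmpta = rng.uniform(81.0, 85.0)
        jlca = rng.uniform(1.0, 3.0)
        phi = rng.uniform(3.5, 8.0)
    else:  # valgus
        mmpta = rng.uniform(90.0, 93.0)
        jlca = rng.uniform(0.0, 2.0)
        phi = rng.uniform(-8.0, -3.5)
    mldfa = phi + mmpta + jlca

    if population == "lld":
        femoral = rng.uniform(385.0, 425.0)
        tibial = rng.uniform(305.0, 335.0)
    else:
        femoral = float(np.clip(rng.normal(460.0, 25.0), 405.0, 500.0))
        tibial = float(np.clip(rng.normal(363.0, 20.0), 315.0, 395.0))

    return PhantomSpec(
        side="left" if rng.random() < 0.5 else "right",
        femoral_length=femoral,
        tibial_length=tibial,
        neck_shaft_angle=float(nsa),
        head_radius=float(rng.uniform(22.0, 27.0)),
        mLDFA_true=float(mldfa),
        mMPTA_true=float(mmpta),
        mLDTA_true=float(mldta),
        jlca_true=float(jlca),
        mLPFA_true=float(mlpfa),
        shaft_width=float(rng.uniform(25.0, 31.0)),
        condyle_width=float(rng.uniform(78.0, 92.0)),
        plafond_width=float(rng.uniform(50.0, 60.0)),
        seed=int(rng_seed),
    )


# --------------------------------------------------------------------------
# analytic primitives

class _Disc:
    def __init__(self, center, radius):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def bbox(self):
        c, r = self.center, self.radius
        return (c[0] - r, c[1] - r, c[0] + r, c[1] + r)

    def contains(self, R, C):
        return (R - self.center[0]) ** 2 + (C - self.center[1]) ** 2 <= self.radius ** 2


class _ConvexPoly:
    def __init__(self, vertices):
        self.vertices = np.asarray(vertices, dtype=float)

    def bbox(self):
        v = self.vertices
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())

    def contains(self, R, C):
        v = self.vertices
        centroid = v.mean(axis=0)
        inside = np.ones(np.broadcast_shapes(np.shape(R), np.shape(C)), dtype=bool)
        n = len(v)
        for i in range(n):
            a, b = v[i], v[(i + 1) % n]
            e = b - a
            # signed side of edge; centroid fixes the orientation
            s_c = e[0] * (centroid[1] - a[1]) - e[1] * (centroid[0] - a[0])
            s = e[0] * (C - a[1]) - e[1] * (R - a[0])
            inside &= (s * np.sign(s_c)) >= 0
        return inside


def _rect(p0, p1, width):
    """Convex quad: rectangle of given width along the segment p0 -> p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0]]) * (width / 2.0)
    return _ConvexPoly([p0 + perp, p1 + perp, p1 - perp, p0 - perp])


# --------------------------------------------------------------------------
# closed-form geometry

def _build_geometry(spec: PhantomSpec):
    """Left-convention geometry in mm: landmark points, axis directions and
    the per-class primitive lists."""
    s = spec
    theta_c = s.mMPTA_true + s.jlca_true
    phi = s.mLDFA_true - theta_c
    delta = s.anat_mech_angle

    f_up = dir_vec(180.0 - phi)         # femoral mech axis, distal -> proximal
    a_dn = dir_vec(delta - phi)         # femoral anatomical axis, proximal -> distal
    n_dir = dir_vec(delta - phi + s.neck_shaft_angle)   # neck, toward head

    lm_mech = s.femoral_length - s.head_radius
    y_apex, x_knee = 15.0, 170.0
    head = np.array([y_apex + s.head_radius,
                     x_knee + lm_mech * math.sin(math.radians(phi))])
    kf = head - lm_mech * f_up          # femoral knee centre
    apex = head - np.array([s.head_radius, 0.0])

    cond_med = kf + (s.condyle_width / 2.0) * dir_vec(theta_c)
    cond_lat = kf - (s.condyle_width / 2.0) * dir_vec(theta_c)

    kt = kf + np.array([s.joint_gap, 0.0])   # tibial knee centre
    plat_w = 0.92 * s.condyle_width
    plat_med = kt + (plat_w / 2.0) * dir_vec(s.mMPTA_true)
    plat_lat = kt - (plat_w / 2.0) * dir_vec(s.mMPTA_true)

    ankle = kt + np.array([s.tibial_length, 0.0])
    plaf_med = ankle + (s.plafond_width / 2.0) * dir_vec(s.mLDTA_true)
    plaf_lat = ankle - (s.plafond_width / 2.0) * dir_vec(s.mLDTA_true)

    neck_base = head - s.neck_length * n_dir
    troch_tip = head + s.trochanter_offset * dir_vec(-phi - s.mLPFA_true)
    troch_c = troch_tip + np.array([s.trochanter_radius, 0.0])

    # --- primitives per ROI class -------------------------------------
    fs_top = neck_base + 6.0 * a_dn
    t_len = (kf[0] - 45.0 - fs_top[0]) / a_dn[0]
    fs_bot = fs_top + t_len * a_dn
    femoral_shaft = [_rect(fs_top, fs_bot, s.shaft_width)]

    tibial_shaft = [_rect(kt + np.array([40.0, 0.0]),
                          ankle - np.array([35.0, 0.0]),
                          0.85 * s.shaft_width)]

    femoral_head = [
        _Disc(head, s.head_radius),
        _rect(head, neck_base, s.neck_width),
        _Disc(troch_c, s.trochanter_radius),
        _rect(troch_c, neck_base, 18.0),
    ]

    def _lobed(pt_a, pt_b, r, toward_down):
        """Two disc lobes whose extremal points are exactly pt_a / pt_b,
        joined by a parallelogram that recedes away from the joint line."""
        sgn = 1.0 if toward_down else -1.0
        ca = pt_a - sgn * np.array([r, 0.0])
        cb = pt_b - sgn * np.array([r, 0.0])
        back = -sgn * np.array([1.6 * r, 0.0])
        return [_Disc(ca, r), _Disc(cb, r),
                _ConvexPoly([ca, cb, cb + back, ca + back])]

    knee = (_lobed(cond_med, cond_lat, s.knee_lobe_radius, toward_down=True)
            + _lobed(plat_med, plat_lat, s.plateau_lobe_radius, toward_down=False))
    ankle_prims = _lobed(plaf_med, plaf_lat, s.ankle_lobe_radius, toward_down=True)

    primitives = {
        "femoral_shaft": femoral_shaft,
        "tibial_shaft": tibial_shaft,
        "femoral_head": femoral_head,
        "knee": knee,
        "ankle": ankle_prims,
    }
    points = {
        "head_center": head, "head_apex": apex, "trochanter_tip": troch_tip,
        "neck_base": neck_base,
        "femoral_condyle_medial": cond_med, "femoral_condyle_lateral": cond_lat,
        "knee_center_femoral": kf,
        "plateau_medial": plat_med, "plateau_lateral": plat_lat,
        "knee_center_tibial": kt,
        "plafond_medial": plaf_med, "plafond_lateral": plaf_lat,
        "ankle_center": ankle,
    }
    dirs = {
        "neck": n_dir, "femoral_anat": a_dn, "tibial_anat": np.array([1.0, 0.0]),
    }
    return points, dirs, primitives


def _truth_landmarks(spec: PhantomSpec, points, dirs, canvas) -> LandmarkSet:
    """Convert the mm geometry to a pixel-frame LandmarkSet, mirroring for a
    right-side limb (col' = W - 1 - col, dcol' = -dcol)."""
    sp = spec.pixel_spacing
    w = canvas[1]
    mirror = spec.side == "right"

    def pt(a) -> Point:
        r, c = a[0] / sp, a[1] / sp
        if mirror:
            c = (w - 1) - c
        return Point(float(r), float(c))

    def dv(d):
        return (float(d[0]), float(-d[1]) if mirror else float(d[1]))

    return LandmarkSet(
        head_center=pt(points["head_center"]),
        head_radius=spec.head_radius / sp,
        head_apex=pt(points["head_apex"]),
        trochanter_tip=pt(points["trochanter_tip"]),
        neck_axis=AxisLine(pt(points["neck_base"]), dv(dirs["neck"])),
        femoral_anat_axis=AxisLine(pt(points["neck_base"]), dv(dirs["femoral_anat"])),
        femoral_condyle_medial=pt(points["femoral_condyle_medial"]),
        femoral_condyle_lateral=pt(points["femoral_condyle_lateral"]),
        knee_center_femoral=pt(points["knee_center_femoral"]),
        plateau_medial=pt(points["plateau_medial"]),
        plateau_lateral=pt(points["plateau_lateral"]),
        knee_center_tibial=pt(points["knee_center_tibial"]),
        tibial_anat_axis=AxisLine(pt(points["knee_center_tibial"]), dv(dirs["tibial_anat"])),
        plafond_medial=pt(points["plafond_medial"]),
        plafond_lateral=pt(points["plafond_lateral"]),
        ankle_center=pt(points["ankle_center"]),
        side=spec.side,
    )


# --------------------------------------------------------------------------
# rasterisation

def _rasterise(primitives, canvas, spacing, mirror):
    """Sample pixel centres against the union of primitives; return the
    cropped boolean mask and its (row, col) offset in the canvas frame."""
    full = np.zeros(canvas, dtype=bool)
    for prim in primitives:
        r0m, c0m, r1m, c1m = prim.bbox()
        i0 = max(int(math.floor(r0m / spacing)) - 2, 0)
        j0 = max(int(math.floor(c0m / spacing)) - 2, 0)
        i1 = min(int(math.ceil(r1m / spacing)) + 3, canvas[0])
        j1 = min(int(math.ceil(c1m / spacing)) + 3, canvas[1])
        if i1 <= i0 or j1 <= j0:
            continue
        R = (np.arange(i0, i1, dtype=float) * spacing)[:, None]
        C = (np.arange(j0, j1, dtype=float) * spacing)[None, :]
        full[i0:i1, j0:j1] |= prim.contains(R, C)
    if mirror:
        full = full[:, ::-1]
    rows = np.flatnonzero(full.any(axis=1))
    cols = np.flatnonzero(full.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    return full[r0:r1, c0:c1].copy(), (r0, c0)


def generate_phantom(spec: PhantomSpec, canvas=DEFAULT_CANVAS) -> PhantomCase:
    """Rasterise one phantom and attach its closed-form truth.

    Raises :class:`PhantomSizeError` when the limb (with drawing margins)
    exceeds the canvas at the spec's pixel spacing.
    """
    points, dirs, primitives = _build_geometry(spec)
    sp = spec.pixel_spacing

    extent_r = max(p.bbox()[2] for prims in primitives.values() for p in prims)
    extent_c = max(p.bbox()[3] for prims in primitives.values() for p in prims)
    min_r = min(p.bbox()[0] for prims in primitives.values() for p in prims)
    min_c = min(p.bbox()[1] for prims in primitives.values() for p in prims)
    if min_r < 0 or min_c < 0 or extent_r / sp >= canvas[0] - 2 or extent_c / sp >= canvas[1] - 2:
        raise PhantomSizeError(
            f"limb extent {extent_r:.0f}x{extent_c:.0f} mm does not fit "
            f"canvas {canvas[0]}x{canvas[1]} px at {sp} mm/px")

    ms = MaskSet(side=spec.side, pixel_spacing=sp, canvas_shape=tuple(canvas))
    for cls in ROI_CLASSES:
        mask, off = _rasterise(primitives[cls], canvas, sp, spec.side == "right")
        ms.masks[cls] = mask
        ms.offsets[cls] = off

    truth_lm = _truth_landmarks(spec, points, dirs, canvas)
    truth_report = compute_report(truth_lm, sp)
    case = PhantomCase(mask_set=ms, truth_landmarks=truth_lm,
                       truth_report=truth_report, spec=spec)
    if spec.boundary_jitter_sd > 0:
        case = add_boundary_jitter(case, spec.boundary_jitter_sd, spec.seed)
    return case


# --------------------------------------------------------------------------
# boundary jitter

def _jitter_mask(mask: np.ndarray, sd: float, rng, corr_len: float = 5.0):
    """Perturb the boundary polygon(s) of a mask by smooth zero-mean normal
    displacement and re-rasterise. The buffer is padded so displaced
    boundaries are not clipped; returns ``(jittered, pad)``."""
    pad = int(math.ceil(4 * sd)) + 2
    padded = np.pad(mask, pad)
    out = np.zeros_like(padded)
    for contour in find_contours(padded.astype(float), 0.5):
        n = len(contour)
        if n < 8:
            continue
        noise = gaussian_filter1d(rng.standard_normal(n), corr_len, mode="wrap")
        s = noise.std()
        if s > 0:
            noise *= sd / s
        tangent = np.gradient(contour, axis=0)
        norms = np.linalg.norm(tangent, axis=1)
        norms[norms == 0] = 1.0
        tangent /= norms[:, None]
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
        out |= polygon2mask(padded.shape, contour + noise[:, None] * normal)
    return out, pad


def add_boundary_jitter(case: PhantomCase, sd: float, seed: int) -> PhantomCase:
    """Return a new case whose mask boundaries are perturbed (segmentation
    noise model); the closed-form truth is unchanged by construction."""
    if sd < 0:
        raise ValueError("jitter sd must be >= 0")
    if sd == 0:
        return PhantomCase(mask_set=case.mask_set.copy(),
                           truth_landmarks=case.truth_landmarks,
                           truth_report=case.truth_report,
                           spec=case.spec)
    rng = np.random.default_rng(seed)
    ms = case.mask_set.copy()
    canvas = ms.canvas_shape
    for cls in ROI_CLASSES:
        jittered, pad = _jitter_mask(ms.masks[cls], sd, rng)
        r0, c0 = ms.offsets[cls]
        r0, c0 = r0 - pad, c0 - pad
        # clamp the expanded buffer to the canvas
        if r0 < 0:
            jittered = jittered[-r0:]
            r0 = 0
        if c0 < 0:
            jittered = jittered[:, -c0:]
            c0 = 0
        jittered = jittered[:canvas[0] - r0, :canvas[1] - c0]
        rows = np.flatnonzero(jittered.any(axis=1))
        cols = np.flatnonzero(jittered.any(axis=0))
        ra, rb = int(rows[0]), int(rows[-1]) + 1
        ca, cb = int(cols[0]), int(cols[-1]) + 1
        ms.masks[cls] = jittered[ra:rb, ca:cb].copy()
        ms.offsets[cls] = (r0 + ra, c0 + ca)
    return PhantomCase(mask_set=ms, truth_landmarks=case.truth_landmarks,
                       truth_report=case.truth_report,
                       spec=replace(case.spec, boundary_jitter_sd=sd))
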