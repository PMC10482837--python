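"""Anatomical landmark detection from per-class binary masks.

Every detector works on a boolean mask in its own (cropped) frame and
returns sub-pixel landmark coordinates in that frame; :func:`assemble` maps
them into the full-image frame via the recorded ROI offsets. Right-side
masks are horizontally flipped into the left-side convention before
detection and the resulting coordinates are un-mirrored, so a single set of
medial/lateral rules serves both sides.

Detectors implement the standard joint-orientation definitions: the femoral
head centre is an algebraic least-squares circle fit to the superior head
boundary arc, shaft (anatomical) axes are total-least-squares lines through
mid-diaphyseal run midpoints, and joint orientation lines join the two
articular extremal points of each joint surface (condyles, plateau,
plafond), located per lobe with sub-pixel quadratic refinement of the
extremal boundary profile.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter1d, label
from scipy.signal import find_peaks
from skimage.measure import find_contours

from .geometry import AxisLine, DegenerateGeometryError, Point
from .masks import ROI_CLASSES, MaskSet, MissingStructureError

__all__ = [
    "LandmarkSet",
    "FragmentedMaskError",
    "fit_circle",
    "head_landmarks",
    "shaft_axis",
    "joint_line",
    "assemble",
]

JOINT_BONES = ("femur_distal", "tibia_proximal", "tibia_distal")


class FragmentedMaskError(ValueError):
    """A mask is too fragmented for its detector's assumptions."""


@dataclass(frozen=True)
class LandmarkSet:
    """Named landmarks and joint-orientation data for one limb, in the
    full-image (row, col) pixel frame."""

    head_center: Point
    head_radius: float
    head_apex: Point
    trochanter_tip: Point
    neck_axis: AxisLine            # oriented toward the head centre
    femoral_anat_axis: AxisLine    # proximal -> distal
    femoral_condyle_medial: Point
    femoral_condyle_lateral: Point
    knee_center_femoral: Point
    plateau_medial: Point
    plateau_lateral: Point
    knee_center_tibial: Point
    tibial_anat_axis: AxisLine     # proximal -> distal
    plafond_medial: Point
    plafond_lateral: Point
    ankle_center: Point
    side: str

    def points(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Point):
                out[f.name] = v
        return out

    def validate(self) -> None:
        for name, p in self.points().items():
            if not p.is_finite():
                raise DegenerateGeometryError(f"landmark {name} is not finite")
        sgn = 1.0 if self.side == "left" else -1.0
        pairs = [
            ("femoral_condyle", self.femoral_condyle_medial, self.femoral_condyle_lateral),
            ("plateau", self.plateau_medial, self.plateau_lateral),
            ("plafond", self.plafond_medial, self.plafond_lateral),
        ]
        for name, med, lat in pairs:
            if med.distance_to(lat) < 1e-9:
                raise DegenerateGeometryError(f"{name} medial/lateral points coincide")
            if sgn * (med.col - lat.col) <= 0:
                raise DegenerateGeometryError(
                    f"{name}: medial/lateral ordering inconsistent with side={self.side}")


# --------------------------------------------------------------------------
# circle fitting

def fit_circle(points) -> tuple:
    """Algebraic least-squares (Kasa) circle fit.

    Minimises ``sum((x^2 + y^2 + D x + E y + F)^2)``; exact on noise-free
    circles. Raises :class:`~limbalign.geometry.DegenerateGeometryError` on
    fewer than three points or (near-)collinear input.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 points")
    r, c = pts[:, 0], pts[:, 1]
    A = np.column_stack([r, c, np.ones_like(r)])
    b = -(r ** 2 + c ** 2)
    # collinearity check on the centred coordinates
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[0] == 0 or sv[1] / sv[0] < 1e-9:
        raise DegenerateGeometryError("circle fit is degenerate: collinear points")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    D, E, F = sol
    cr, cc = -D / 2.0, -E / 2.0
    rad2 = cr ** 2 + cc ** 2 - F
    if rad2 <= 0:
        raise DegenerateGeometryError("circle fit produced non-positive radius")
    return Point(float(cr), float(cc)), float(np.sqrt(rad2))


# --------------------------------------------------------------------------
# helpers

def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel boundary samples (contours at the 0.5 level)."""
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise MissingStructureError("mask has no boundary")
    return np.vstack(contours)


def _flip_if_right(mask: np.ndarray, side: str) -> np.ndarray:
    return mask[:, ::-1] if side == "right" else mask


def _unmirror_point(p: Point, width: int, side: str) -> Point:
    if side == "right" and p is not None:
        return Point(p.row, (width - 1) - p.col)
    return p


def _unmirror_axis(a: AxisLine, width: int, side: str) -> AxisLine:
    if side == "right" and a is not None:
        return AxisLine(_unmirror_point(a.anchor, width, side),
                        (a.direction[0], -a.direction[1]))
    return a


def _subpixel_extremum(profile_cols, profile_vals, peak_col, window, maximize):
    """Quadratic refinement of an extremal (col -> extreme row) profile.

    Fits a parabola to the integer profile inside ``window`` columns of the
    detected peak and returns the sub-pixel ``(row, col)`` vertex; averaging
    over the window suppresses the rasterisation quantisation of individual
    columns. Falls back to the raw peak when the fit is not concave the
    right way or the vertex escapes the window.
    """
    sel = np.abs(profile_cols - peak_col) <= window
    x = profile_cols[sel].astype(float)
    y = profile_vals[sel].astype(float)
    if len(x) >= 5:
        coef = np.polyfit(x - peak_col, y, 2)
        a, b, c0 = coef
        ok = (a < 0) if maximize else (a > 0)
        if ok and abs(a) > 1e-12:
            dx = -b / (2 * a)
            if abs(dx) <= window:
                return float(a * dx * dx + b * dx + c0), float(peak_col + dx)
    i = int(np.argmax(y) if maximize else np.argmin(y))
    return float(y[i]), float(x[i])


# --------------------------------------------------------------------------
# detectors

def head_landmarks(head_mask: np.ndarray, side: str = "left"):
    """Detect femoral-head landmarks from the femoral-head-class mask.

    Returns ``(head_center, head_radius, head_apex, trochanter_tip,
    neck_axis)`` in the mask's own frame. The head centre/radius come from a
    Kasa circle fit to boundary points away from the neck attachment; the
    apex is the most superior point of the fitted disc; the trochanter tip
    is the most superior mask point outside the fitted disc on the lateral
    side of the neck axis; the neck axis joins the head centre to the
    centroid of the neck cross-section just beyond the head boundary.

    When the mask holds a bare head disc (no neck/trochanter), the
    trochanter tip and neck axis are reported as ``None``.
    """
    mask = np.asarray(head_mask, dtype=bool)
    if not mask.any():
        raise MissingStructureError("femoral head mask is empty")
    mask = _flip_if_right(mask, side)
    width = mask.shape[1]

    # rough centre/radius: the head is the largest inscribed disc
    dist = distance_transform_edt(mask)
    r0 = float(dist.max())
    if r0 < 3.0:
        raise MissingStructureError("no circular component found in head mask")
    cr0, cc0 = np.unravel_index(int(np.argmax(dist)), dist.shape)
    center = np.array([float(cr0), float(cc0)])

    bpts = _boundary_points(mask)
    rows, cols = np.nonzero(mask)
    pix = np.column_stack([rows, cols]).astype(float)

    radius = r0
    for _ in range(2):
        d_pix = np.linalg.norm(pix - center, axis=1)
        outside = pix[d_pix > 1.06 * radius]
        if len(outside):
            attach = outside.mean(axis=0) - center
            attach /= np.linalg.norm(attach)
        else:
            attach = None
        d_b = np.linalg.norm(bpts - center, axis=1)
        ring = np.abs(d_b - radius) < max(2.5, 0.05 * radius)
        keep = ring.copy()
        if attach is not None:
            v = (bpts - center) / np.maximum(d_b, 1e-9)[:, None]
            keep &= (v @ attach) < np.cos(np.deg2rad(70.0))
        if keep.sum() < 10:
            keep = ring
        if keep.sum() < 3:
            raise MissingStructureError("no circular component found in head mask")
        c_fit, radius = fit_circle(bpts[keep])
        center = c_fit.as_array()

    head_center = Point(float(center[0]), float(center[1]))
    head_apex = Point(float(center[0] - radius), float(center[1]))

    d_pix = np.linalg.norm(pix - center, axis=1)
    outside = pix[d_pix > 1.06 * radius]
    if len(outside) < 30:
        # bare disc: neck and trochanter are absent
        return (_unmirror_point(head_center, width, side), radius,
                _unmirror_point(head_apex, width, side), None, None)

    # initial neck direction from the thin band just beyond the head boundary
    d_out = np.linalg.norm(outside - center, axis=1)
    short = outside[d_out < 1.06 * radius + 6.0]
    if len(short) < 5:
        short = outside
    d0 = short.mean(axis=0) - center
    d0 /= np.linalg.norm(d0)
    perp0 = np.array([-d0[1], d0[0]])
    half_width = np.abs((short - center) @ perp0).max() + 2.0

    # refine along a longer corridor with cross-section midpoints; the
    # perpendicular cut and the bin-width guard exclude the trochanter
    corridor = outside[d_out < 1.06 * radius + 0.5 * radius]
    rel_b = corridor - center
    t = rel_b @ d0
    p = rel_b @ perp0
    keep = np.abs(p) <= half_width
    t, p = t[keep], p[keep]
    mids, tks, widths = [], [], []
    edges = np.arange(t.min(), t.max() + 3.0, 3.0)
    for k in range(len(edges) - 1):
        sel_k = (t >= edges[k]) & (t < edges[k + 1])
        if sel_k.sum() < 4:
            continue
        mids.append(0.5 * (p[sel_k].min() + p[sel_k].max()))
        tks.append(t[sel_k].mean())
        widths.append(p[sel_k].max() - p[sel_k].min())
    if len(widths) >= 3:
        widths = np.asarray(widths)
        good = np.abs(widths - np.median(widths)) <= 0.25 * np.median(widths) + 2.0
        tks = np.asarray(tks)[good]
        mids = np.asarray(mids)[good]
        den = float(np.sum(tks * tks))
        if den > 0 and len(tks) >= 2:
            slope = float(np.sum(tks * mids)) / den
            d0 = d0 + slope * perp0
            d0 /= np.linalg.norm(d0)
    iso = center + d0 * float(np.mean(t))
    neck_dir = -d0
    neck_axis = AxisLine(Point(float(iso[0]), float(iso[1])),
                         (float(neck_dir[0]), float(neck_dir[1])))

    # lateral half-plane of the neck line (left convention: lateral = -col)
    n_perp = np.array([-neck_dir[1], neck_dir[0]])
    if n_perp[1] > 0:
        n_perp = -n_perp
    rel = pix - center
    lateral = (rel @ n_perp) > 2.0
    # the trochanter sits well clear of the head disc; the stricter radial
    # cut keeps boundary noise on the head itself out of the candidate set
    cand = pix[lateral & (d_pix > max(1.3 * radius, 1.06 * radius + 4.0))]
    if len(cand) < 10:
        trochanter_tip = None
    else:
        cand_cols = cand[:, 1].astype(int)
        cand_rows = cand[:, 0].astype(int)
        ucols, inv = np.unique(cand_cols, return_inverse=True)
        top = np.full(len(ucols), np.inf)
        np.minimum.at(top, inv, cand_rows.astype(float))
        # centre of the quantised top plateau (contiguous run of min rows)
        min_row = top.min()
        flat = np.flatnonzero(top <= min_row + 0.5)
        runs = np.split(flat, np.flatnonzero(np.diff(flat) > 1) + 1)
        run = max(runs, key=len)
        tip_col = float(ucols[run].mean())
        row_t, col_t = _subpixel_extremum(ucols, top, tip_col, 9, maximize=False)
        trochanter_tip = Point(row_t, col_t)

    return (_unmirror_point(head_center, width, side), radius,
            _unmirror_point(head_apex, width, side),
            _unmirror_point(trochanter_tip, width, side),
            _unmirror_axis(neck_axis, width, side))


def shaft_axis(shaft_mask: np.ndarray, central_fraction: float = 0.6) -> AxisLine:
    """Mid-diaphyseal (anatomical) axis of a long-bone shaft mask.

    Takes the midpoint of the foreground run in every occupied row of the
    central ``central_fraction`` of the mask's vertical extent and fits a
    total-least-squares line. The direction is oriented proximal -> distal
    (increasing row).
    """
    mask = np.asarray(shaft_mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if len(rows) < 20:
        raise MissingStructureError("shaft mask has fewer than 20 foreground rows")
    cols = np.flatnonzero(mask.any(axis=0))
    if len(rows) <= len(cols):
        raise MissingStructureError("shaft mask must be taller than wide")
    r_lo = rows[0] + (1 - central_fraction) / 2 * (rows[-1] - rows[0])
    r_hi = rows[-1] - (1 - central_fraction) / 2 * (rows[-1] - rows[0])
    mids = []
    fragmented = 0
    total = 0
    for r in rows:
        if r < r_lo or r > r_hi:
            continue
        total += 1
        line = mask[r]
        padded = np.concatenate([[False], line, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        if len(starts) > 1:
            fragmented += 1
        mids.append((float(r), (starts[0] + ends[-1] - 1) / 2.0))
    if total == 0:
        raise MissingStructureError("shaft mask central section is empty")
    if fragmented > 0.2 * total:
        raise FragmentedMaskError(
            f"shaft mask fragmented: {fragmented}/{total} rows have multiple runs")
    pts = np.asarray(mids)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    d = vt[0]
    if d[0] < 0:
        d = -d
    if d[0] == 0:
        raise DegenerateGeometryError("shaft axis is horizontal")
    return AxisLine(Point(float(centroid[0]), float(centroid[1])),
                    (float(d[0]), float(d[1])))


def _component_profile(comp: np.ndarray, distal: bool):
    """Per-column extremal-row profile of a component (max row if distal)."""
    occ = comp.any(axis=0)
    cols = np.flatnonzero(occ)
    nrows = comp.shape[0]
    idx = np.arange(nrows)[:, None]
    if distal:
        vals = np.where(comp[:, cols], idx, -1).max(axis=0).astype(float)
    else:
        vals = np.where(comp[:, cols], idx, nrows + 1).min(axis=0).astype(float)
    return cols.astype(float), vals


def _two_lobes(comp: np.ndarray, distal: bool, bone: str):
    """Locate the two articular extremal points of a joint component."""
    cols, vals = _component_profile(comp, distal)
    if len(cols) < 12:
        raise DegenerateGeometryError(f"{bone}: articular contour too small")
    signal = vals if distal else -vals
    smooth = gaussian_filter1d(signal, 2.0, mode="nearest")
    peaks, props = find_peaks(smooth, prominence=3.0, distance=8)
    # profile endpoints can be extrema too; find_peaks misses plateau edges
    if len(peaks) < 2:
        peaks, props = find_peaks(smooth, prominence=1.5, distance=5)
    if len(peaks) < 2:
        raise DegenerateGeometryError(
            f"{bone}: expected two articular lobes, found {len(peaks)}")
    order = np.argsort(props["prominences"])[::-1][:2]
    picked = np.sort(peaks[order])
    out = []
    for pk in picked:
        row, col = _subpixel_extremum(cols, vals, cols[pk], 9, maximize=distal)
        out.append(Point(row, col))
    return out  # sorted by column: [smaller col, larger col]


def _split_knee(mask: np.ndarray, want: str) -> np.ndarray:
    """Isolate the femoral (upper) or tibial (lower) component of a knee
    mask. Falls back to a horizontal cut at the occupancy pinch when the
    joint space is bridged."""
    lab, n = label(mask)
    if n >= 2:
        sizes = np.bincount(lab.ravel())[1:]
        big = np.argsort(sizes)[::-1][:2] + 1
        crow = [np.nonzero(lab == i)[0].mean() for i in big]
        upper = big[int(np.argmin(crow))]
        lower = big[int(np.argmax(crow))]
        return lab == (upper if want == "upper" else lower)
    # bridged: cut at the thinnest row band in the middle half
    counts = mask.sum(axis=1)
    occ = np.flatnonzero(counts)
    lo = occ[0] + (occ[-1] - occ[0]) // 4
    hi = occ[-1] - (occ[-1] - occ[0]) // 4
    cut = lo + int(np.argmin(counts[lo:hi + 1]))
    out = mask.copy()
    if want == "upper":
        out[cut:] = False
    else:
        out[:cut] = False
    return out


def joint_line(joint_mask: np.ndarray, bone: str, side: str = "left"):
    """Joint-orientation line of a knee or ankle mask.

    Returns ``(medial, lateral, line, center)`` where the line joins the two
    articular extremal points (condyles / plateau edges / plafond corners)
    and ``center`` is their midpoint. Medial/lateral labels derive from the
    side flag.
    """
    if bone not in JOINT_BONES:
        raise ValueError(f"unknown bone {bone!r}; expected one of {JOINT_BONES}")
    mask = np.asarray(joint_mask, dtype=bool)
    if not mask.any():
        raise MissingStructureError(f"{bone}: joint mask is empty")
    mask = _flip_if_right(mask, side)
    width = mask.shape[1]

    if bone == "femur_distal":
        comp, distal = _split_knee(mask, "upper"), True
    elif bone == "tibia_proximal":
        comp, distal = _split_knee(mask, "lower"), False
    else:
        comp, distal = mask, True
    p_small, p_large = _two_lobes(comp, distal, bone)

    # left convention inside this frame: lateral = smaller col
    lateral, medial = p_small, p_large
    center = Point((medial.row + lateral.row) / 2.0,
                   (medial.col + lateral.col) / 2.0)
    d = medial.as_array() - lateral.as_array()
    line = AxisLine(center, (float(d[0]), float(d[1])))

    return (_unmirror_point(medial, width, side),
            _unmirror_point(lateral, width, side),
            _unmirror_axis(line, width, side),
            _unmirror_point(center, width, side))


# --------------------------------------------------------------------------
# assembly

def _offset_point(p: Point, off) -> Point:
    return None if p is None else Point(p.row + off[0], p.col + off[1])


def _offset_axis(a: AxisLine, off) -> AxisLine:
    return None if a is None else AxisLine(_offset_point(a.anchor, off), a.direction)


def assemble(mask_set: MaskSet) -> LandmarkSet:
    """Run all detectors on a complete five-class mask set and return the
    LandmarkSet in the full-image frame (offsets applied, right side
    un-mirrored), validated against the medial/lateral invariants."""
    mask_set.validate(required=ROI_CLASSES)
    side = mask_set.side
    off = mask_set.offsets

    center, radius, apex, troch, neck = head_landmarks(
        mask_set.masks["femoral_head"], side)
    if troch is None or neck is None:
        raise MissingStructureError(
            "femoral head mask lacks a neck/trochanter structure")
    o = off["femoral_head"]
    center, apex, troch = (_offset_point(p, o) for p in (center, apex, troch))
    neck = _offset_axis(neck, o)

    fem_anat = _offset_axis(shaft_axis(mask_set.masks["femoral_shaft"]),
                            off["femoral_shaft"])
    tib_anat = _offset_axis(shaft_axis(mask_set.masks["tibial_shaft"]),
                            off["tibial_shaft"])

    cm, cl, _, kf = joint_line(mask_set.masks["knee"], "femur_distal", side)
    pm, pl, _, kt = joint_line(mask_set.masks["knee"], "tibia_proximal", side)
    fm, fl, _, ac = joint_line(mask_set.masks["ankle"], "tibia_distal", side)
    ko = off["knee"]
    cm, cl, kf, pm, pl, kt = (_offset_point(p, ko) for p in (cm, cl, kf, pm, pl, kt))
    ao = off["ankle"]
    fm, fl, ac = (_offset_point(p, ao) for p in (fm, fl, ac))

    lm = LandmarkSet(
        head_center=center, head_radius=radius, head_apex=apex,
        trochanter_tip=troch, neck_axis=neck, femoral_anat_axis=fem_anat,
        femoral_condyle_medial=cm, femoral_condyle_lateral=cl,
        knee_center_femoral=kf,
        plateau_medial=pm, plateau_lateral=pl, knee_center_tibial=kt,
        tibial_anat_axis=tib_anat,
        plafond_medial=fm, plafond_lateral=fl, ankle_center=ac,
        side=side,
    )
    lm.validate()
    return lm
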