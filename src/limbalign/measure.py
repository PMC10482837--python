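"""Lower-limb alignment parameters from a landmark set.

Computes the 16 standard frontal-plane alignment parameters — the
mechanical-axis family (mLPFA, mLDFA, mMPTA, mLDTA, mJLCA, mTFA, MAD), the
anatomical-axis family (aMPFA, aLDFA, NSA, aMPTA, aLDTA, aTFA) and the three
lengths (full leg, femur, tibia) — and classifies each angle/deviation
against its published normal range (closed intervals; lengths carry no
range).

Angle-side conventions (Paley): each named angle is the angle between an
*oriented* axis ray and the joint-line ray on the named side, so values live
in [0, 180] degrees and are invariant under left/right mirroring:

* mLPFA: femoral mechanical axis (hip -> knee) vs head-centre -> trochanter
  tip ray; mLDFA: femoral mechanical axis (knee -> hip) vs knee-centre ->
  lateral condyle ray; mMPTA: tibial mechanical axis (knee -> ankle) vs
  knee-centre -> medial plateau ray; mLDTA: tibial mechanical axis
  (ankle -> knee) vs ankle-centre -> lateral plafond ray;
* NSA: neck axis (toward head) vs femoral anatomical axis (proximal ->
  distal); the anatomical angles substitute the anatomical shaft axes.

MAD is reported as an unsigned perpendicular distance (mm) from the tibial
knee centre to the hip-to-ankle line; a signed medial(-)/lateral(+) variant
is available via ``signed_mad=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .geometry import (AxisLine, DegenerateGeometryError, acute_angle, ray,
                       ray_angle, signed_perp_distance)

__all__ = [
    "NORMAL_RANGES",
    "ANGLE_FIELDS",
    "LENGTH_FIELDS",
    "AxisBundle",
    "MeasurementReport",
    "angle_between",
    "build_axes",
    "compute_report",
    "classify_normality",
]

#: Published normal ranges (closed intervals). Angles in degrees, MAD in mm.
#: Lengths carry no normal range. The anatomical distal tibial angle shares
#: the mechanical LDTA range (tibial anatomical and mechanical axes
#: coincide); its own printed range is garbled in the source table.
NORMAL_RANGES = {
    "mLPFA": (85.0, 95.0, "deg"),
    "mLDFA": (85.0, 90.0, "deg"),
    "mMPTA": (85.0, 90.0, "deg"),
    "mLDTA": (86.0, 92.0, "deg"),
    "MAD": (0.0, 3.0, "mm"),
    "mJLCA": (0.0, 2.0, "deg"),
    "mTFA": (0.0, 3.0, "deg"),
    "aMPFA": (80.0, 89.0, "deg"),
    "aLDFA": (79.0, 83.0, "deg"),
    "NSA": (124.0, 136.0, "deg"),
    "aMPTA": (85.0, 90.0, "deg"),
    "aLDTA": (86.0, 92.0, "deg"),
    "aTFA": (0.0, 3.0, "deg"),
}

ANGLE_FIELDS = ("mLPFA", "mLDFA", "mMPTA", "mLDTA", "mJLCA", "mTFA",
                "aMPFA", "aLDFA", "NSA", "aMPTA", "aLDTA", "aTFA")
LENGTH_FIELDS = ("full_leg_length", "femoral_length", "tibial_length")
PARAMETER_FIELDS = ("mLPFA", "mLDFA", "mMPTA", "mLDTA", "MAD", "mJLCA",
                    "mTFA", "aMPFA", "aLDFA", "NSA", "aMPTA", "aLDTA",
                    "aTFA") + LENGTH_FIELDS


@dataclass(frozen=True)
class AxisBundle:
    """The mechanical and anatomical axes of one limb, oriented
    proximal -> distal."""

    femoral_mech: AxisLine   # head centre -> femoral knee centre
    tibial_mech: AxisLine    # tibial knee centre -> ankle centre
    hip_ankle: AxisLine      # head centre -> ankle centre
    femoral_anat: AxisLine
    tibial_anat: AxisLine


@dataclass
class MeasurementReport:
    """The 16 alignment parameters for one limb, with normality flags."""

    mLPFA: float
    mLDFA: float
    mMPTA: float
    mLDTA: float
    mJLCA: float
    mTFA: float
    aMPFA: float
    aLDFA: float
    NSA: float
    aMPTA: float
    aLDTA: float
    aTFA: float
    MAD: float
    full_leg_length: float
    femoral_length: float
    tibial_length: float
    side: str
    pixel_spacing: float
    mad_signed: float = 0.0
    normal_flags: dict = field(default_factory=dict)

    def value(self, name: str) -> float:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: parameter, value, units, normal_range, normal_flag."""
        rows = []
        for name in PARAMETER_FIELDS:
            if name in NORMAL_RANGES:
                lo, hi, units = NORMAL_RANGES[name]
                rng = f"{lo:g}-{hi:g}"
                flag = self.normal_flags.get(name)
            else:
                units, rng, flag = "mm", "-", None
            rows.append({
                "parameter": name,
                "value": round(float(getattr(self, name)), 2),
                "units": units,
                "normal_range": rng,
                "normal_flag": "" if flag is None else bool(flag),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        head = (f"Lower-limb alignment report (side={self.side}, "
                f"spacing={self.pixel_spacing:g} mm/px)\n")
        return head + df.to_string(index=False)


def angle_between(a, b, kind: str = "acute") -> float:
    """Angle between two axes in degrees.

    ``acute`` ignores orientation and returns arccos(|a.b|) in [0, 90];
    ``as_defined`` respects the stored orientations and returns
    arccos(a.b) in [0, 180] — the clinical side convention is then encoded
    in how each axis/ray was oriented.
    """
    da = a.d if isinstance(a, AxisLine) else np.asarray(a, dtype=float)
    db = b.d if isinstance(b, AxisLine) else np.asarray(b, dtype=float)
    if kind == "acute":
        return acute_angle(da, db)
    if kind == "as_defined":
        return ray_angle(da, db)
    raise ValueError(f"unknown angle kind {kind!r}")


def build_axes(lm) -> AxisBundle:
    """Construct the axis bundle from named landmark endpoints."""
    fm = AxisLine(lm.head_center, ray(lm.head_center, lm.knee_center_femoral))
    tm = AxisLine(lm.knee_center_tibial, ray(lm.knee_center_tibial, lm.ankle_center))
    ha = AxisLine(lm.head_center, ray(lm.head_center, lm.ankle_center))
    fa = lm.femoral_anat_axis if lm.femoral_anat_axis.direction[0] > 0 \
        else lm.femoral_anat_axis.reversed()
    ta = lm.tibial_anat_axis if lm.tibial_anat_axis.direction[0] > 0 \
        else lm.tibial_anat_axis.reversed()
    return AxisBundle(femoral_mech=fm, tibial_mech=tm, hip_ankle=ha,
                      femoral_anat=fa, tibial_anat=ta)


def compute_report(lm, spacing: float, signed_mad: bool = False) -> MeasurementReport:
    """Compute the 16 alignment parameters from a complete landmark set.

    ``spacing`` converts pixel distances to mm. Raises on non-positive
    spacing or degenerate landmark geometry.
    """
    if spacing <= 0:
        raise ValueError("pixel spacing must be > 0")
    axes = build_axes(lm)
    f_dn = axes.femoral_mech.d          # hip -> knee
    t_dn = axes.tibial_mech.d           # knee -> ankle
    a_dn = axes.femoral_anat.d
    ta_dn = axes.tibial_anat.d
    neck = lm.neck_axis.d               # toward head

    cond_lat = ray(lm.knee_center_femoral, lm.femoral_condyle_lateral)
    plat_med = ray(lm.knee_center_tibial, lm.plateau_medial)
    plaf_lat = ray(lm.ankle_center, lm.plafond_lateral)
    troch = ray(lm.head_center, lm.trochanter_tip)

    mLPFA = ray_angle(f_dn, troch)
    mLDFA = ray_angle(-f_dn, cond_lat)
    mMPTA = ray_angle(t_dn, plat_med)
    mLDTA = ray_angle(-t_dn, plaf_lat)
    cond_line = ray(lm.femoral_condyle_lateral, lm.femoral_condyle_medial)
    plat_line = ray(lm.plateau_lateral, lm.plateau_medial)
    mJLCA = acute_angle(cond_line, plat_line)
    mTFA = ray_angle(f_dn, t_dn)

    NSA = ray_angle(neck, a_dn)
    aMPFA = ray_angle(a_dn, -troch)
    aLDFA = ray_angle(-a_dn, cond_lat)
    aMPTA = ray_angle(ta_dn, plat_med)
    aLDTA = ray_angle(-ta_dn, plaf_lat)
    aTFA = ray_angle(a_dn, ta_dn)

    mad_px_signed = signed_perp_distance(lm.knee_center_tibial, axes.hip_ankle)
    # positive = knee centre lateral to the hip-ankle line (varus)
    lateral_sign = -1.0 if lm.side == "left" else 1.0
    mad_signed_mm = lateral_sign * mad_px_signed * spacing
    MAD = abs(mad_signed_mm)

    full_leg = lm.head_apex.distance_to(lm.ankle_center) * spacing
    femoral = lm.head_apex.distance_to(lm.knee_center_femoral) * spacing
    tibial = lm.knee_center_tibial.distance_to(lm.ankle_center) * spacing

    report = MeasurementReport(
        mLPFA=mLPFA, mLDFA=mLDFA, mMPTA=mMPTA, mLDTA=mLDTA, mJLCA=mJLCA,
        mTFA=mTFA, aMPFA=aMPFA, aLDFA=aLDFA, NSA=NSA, aMPTA=aMPTA,
        aLDTA=aLDTA, aTFA=aTFA,
        MAD=mad_signed_mm if signed_mad else MAD,
        full_leg_length=full_leg, femoral_length=femoral, tibial_length=tibial,
        side=lm.side, pixel_spacing=spacing, mad_signed=mad_signed_mm,
    )
    for name in ANGLE_FIELDS:
        v = getattr(report, name)
        if not (0.0 <= v <= 180.0) or not np.isfinite(v):
            raise DegenerateGeometryError(f"angle {name} out of range: {v}")
    report.normal_flags = classify_normality(report)
    return report


def classify_normality(report: MeasurementReport) -> dict:
    """Flag each parameter as inside (True) or outside (False) its closed
    normal interval; lengths have no printed range and map to ``None``."""
    flags = {}
    for name in PARAMETER_FIELDS:
        if name in NORMAL_RANGES:
            lo, hi, _ = NORMAL_RANGES[name]
            v = abs(report.value(name)) if name == "MAD" else report.value(name)
            flags[name] = bool(lo <= v <= hi)
        else:
            flags[name] = None
    return flags
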