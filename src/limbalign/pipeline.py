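"""Run configuration and the three-step measurement pipeline.

Step 1 (ROI detection) and step 2 (segmentation) of the full system are
satisfied here by user-supplied mask sets or by the phantom oracle; step 3
(landmark detection + parameter computation) is this package's core. The
pipeline is deterministic given the configuration and seed; outputs embed a
hash of the configuration for provenance, and per-step wall times are
logged at INFO level.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .landmarks import LandmarkSet, assemble
from .masks import MaskSet
from .measure import MeasurementReport, compute_report

__all__ = ["RunConfig", "run_pipeline", "write_report", "write_landmarks",
           "read_landmarks", "render_overlay"]

logger = logging.getLogger("limbalign")


@dataclass
class RunConfig:
    pixel_spacing: float = 0.48
    side: str = "left"               # 'left', 'right' or 'both'
    canvas: tuple = (2000, 760)
    clahe_block: tuple = (8, 8)
    clahe_clip: float = 2.0
    shaft_fraction: float = 0.6
    icc_form: str = "icc2"
    hd_variant: str = "max"          # 'max' or 'p95'
    seed: int = 0
    signed_mad: bool = False

    def __post_init__(self):
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.side not in ("left", "right", "both"):
            raise ValueError("side must be 'left', 'right' or 'both'")
        if not 0.0 < self.shaft_fraction < 1.0:
            raise ValueError("shaft_fraction must be in (0, 1)")
        if self.icc_form not in ("icc1", "icc2", "icc3"):
            raise ValueError("icc_form must be icc1/icc2/icc3")
        if self.hd_variant not in ("max", "p95"):
            raise ValueError("hd_variant must be 'max' or 'p95'")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["canvas"] = list(self.canvas)
        d["clahe_block"] = list(self.clahe_block)
        return json.dumps(d, indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "RunConfig":
        d = json.loads(text)
        d["canvas"] = tuple(d["canvas"])
        d["clahe_block"] = tuple(d["clahe_block"])
        return RunConfig(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# serialisation

def _point_json(p):
    return [round(p.row, 4), round(p.col, 4)]


def write_landmarks(lm: LandmarkSet, path) -> None:
    """Landmark JSON: named points as [row, col]; named lines as
    {point: [row, col], direction: [drow, dcol]} with unit direction."""
    data = {"side": lm.side, "head_radius_px": round(lm.head_radius, 4),
            "points": {}, "lines": {}}
    for name, p in lm.points().items():
        data["points"][name] = _point_json(p)
    for name in ("neck_axis", "femoral_anat_axis", "tibial_anat_axis"):
        a = getattr(lm, name)
        data["lines"][name] = {"point": _point_json(a.anchor),
                               "direction": [round(a.direction[0], 9),
                                             round(a.direction[1], 9)]}
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def read_landmarks(path) -> dict:
    return json.loads(Path(path).read_text())


def write_report(report: MeasurementReport, path, config: RunConfig | None = None) -> None:
    """Report CSV: parameter, value, units, normal_range, normal_flag.
    Values rounded to 0.01 (degrees / mm), period decimal separator."""
    df = report.to_frame()
    header = ""
    if config is not None:
        header = f"# config_hash={config.digest()}\n"
    csv = df.to_csv(index=False, float_format="%.2f")
    Path(path).write_text(header + csv)


# --------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig, masks: MaskSet | None = None,
                 phantom_seed: int | None = None,
                 population: str = "normal",
                 out_dir=None):
    """Measure one or two limbs from masks or from a generated phantom.

    Returns a list of ``(report, landmark_set)`` tuples (one per side).
    When ``out_dir`` is given, writes per-side ``report_{side}.csv``,
    ``landmarks_{side}.json`` and, for phantoms, the mask set directory.
    """
    from . import phantom as ph  # deferred: phantom imports measure

    t0 = time.perf_counter()
    cases = []
    if masks is not None:
        mask_sets = [masks]
    else:
        if phantom_seed is None:
            raise ValueError("provide either a mask set or a phantom seed")
        sides = ["left", "right"] if config.side == "both" else [config.side]
        mask_sets = []
        for side in sides:
            spec = ph.sample_spec(phantom_seed, population)
            spec = ph.PhantomSpec(**{**spec.to_dict(),
                                     "side": side,
                                     "pixel_spacing": config.pixel_spacing})
            case = ph.generate_phantom(spec, canvas=config.canvas)
            cases.append(case)
            mask_sets.append(case.mask_set)
    t1 = time.perf_counter()
    logger.info("step 1-2 (ROI masks ready): %.3f s", t1 - t0)

    results = []
    for i, ms in enumerate(mask_sets):
        ta = time.perf_counter()
        lm = assemble(ms)
        tb = time.perf_counter()
        report = compute_report(lm, ms.pixel_spacing, signed_mad=config.signed_mad)
        tc = time.perf_counter()
        logger.info("side=%s step 3 (landmarks %.3f s, measurement %.3f s)",
                    ms.side, tb - ta, tc - tb)
        results.append((report, lm))
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_report(report, out / f"report_{ms.side}.csv", config)
            write_landmarks(lm, out / f"landmarks_{ms.side}.json")
            if cases:
                ms.save(out / f"masks_{ms.side}")
                (out / f"spec_{ms.side}.json").write_text(
                    json.dumps(cases[i].spec.to_dict(), indent=2, sort_keys=True))
    return results


def render_overlay(mask_set: MaskSet, lm: LandmarkSet, path,
                   background=None) -> None:
    """Render the detected axes, joint lines and landmarks over the mask
    union (or a supplied grayscale background) and save as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    canvas = np.zeros(mask_set.canvas_shape, dtype=float)
    if background is not None:
        canvas = np.asarray(background, dtype=float)
    else:
        for cls in mask_set.masks:
            canvas = np.maximum(canvas, mask_set.full_mask(cls) * 255.0)
    fig, ax = plt.subplots(figsize=(6, 12))
    ax.imshow(canvas, cmap="gray")
    segs = [
        (lm.head_center, lm.knee_center_femoral, "tab:red"),
        (lm.knee_center_tibial, lm.ankle_center, "tab:red"),
        (lm.head_center, lm.ankle_center, "tab:orange"),
        (lm.femoral_condyle_lateral, lm.femoral_condyle_medial, "tab:cyan"),
        (lm.plateau_lateral, lm.plateau_medial, "tab:cyan"),
        (lm.plafond_lateral, lm.plafond_medial, "tab:cyan"),
        (lm.head_center, lm.trochanter_tip, "tab:green"),
    ]
    for a, b, color in segs:
        ax.plot([a.col, b.col], [a.row, b.row], color=color, lw=1.2)
    for p in lm.points().values():
        ax.plot(p.col, p.row, "y+", ms=6)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
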