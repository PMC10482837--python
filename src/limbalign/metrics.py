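"""Evaluation statistics: segmentation overlap, detection precision and
method-comparison agreement.

* :func:`dsc` / :func:`hausdorff` — Dice similarity coefficient and the
  undirected (maximum) Hausdorff distance between mask boundaries, in mm.
* :func:`mean_average_precision` — detection mAP averaged over IoU
  thresholds 0.50:0.05:0.95 with all-point precision-recall interpolation.
* :func:`agreement` — the paired method-comparison suite: Lin's concordance
  correlation (biased 1/n moments, per Lin's original estimator), Pearson
  correlation, intraclass correlation (two-way random effects, absolute
  agreement, single rater — ICC(2,1) — by default), MAE/MSE/RMSE,
  Bland-Altman bias and 1.96-SD limits of agreement, and the mean absolute
  deviation of the paired differences.

Terminology note: "MAD" as a report column is the *mechanical axis
deviation* in mm (``mad_mm`` contexts); the dispersion statistic here is
``mad_abs_dev``. The two are never conflated in outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "dsc",
    "hausdorff",
    "mask_boundary",
    "iou_box",
    "mean_average_precision",
    "agreement",
    "icc",
]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class PairedSeries:
    """Paired measurements of one parameter: reference (radiologist role)
    vs system."""

    reference: np.ndarray
    system: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        sys = np.asarray(self.system, dtype=float)
        if ref.ndim != 1 or ref.shape != sys.shape:
            raise ValueError("reference and system must be equal-length 1-D vectors")
        if len(ref) < 2:
            raise ValueError("paired series needs n >= 2")
        if not (np.isfinite(ref).all() and np.isfinite(sys).all()):
            raise ValueError("paired series must be finite")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "system", sys)


@dataclass(frozen=True)
class AgreementResult:
    ccc: float | None
    pcc: float | None
    icc: float | None
    mae: float
    mse: float
    rmse: float
    mean_diff: float
    loa_low: float
    loa_high: float
    mad_abs_dev: float
    label: str = ""
    units: str = ""


# --------------------------------------------------------------------------
# segmentation metrics

def dsc(a, b) -> float:
    """Dice similarity coefficient 2|A^B| / (|A| + |B|); 1.0 when both
    masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-neighbour background (or image edge)."""
    mask = np.asarray(mask, dtype=bool)
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(a, b, spacing: float = 1.0, percentile: float | None = None) -> float:
    """Undirected Hausdorff distance between mask boundary pixel sets, in mm.

    ``percentile`` switches to the robust percentile variant (e.g. 95) of
    the directed nearest-neighbour distances; default is the true maximum.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("hausdorff requires two non-empty masks")
    pa, pb = mask_boundary(a), mask_boundary(b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile is None:
        d = max(d_ab.max(), d_ba.max())
    else:
        d = max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))
    return float(d) * spacing


# --------------------------------------------------------------------------
# detection metric

def iou_box(a, b) -> float:
    """IoU of two 0-based half-open boxes (row_min, col_min, row_max, col_max)."""
    r0 = max(a[0], b[0])
    c0 = max(a[1], b[1])
    r1 = min(a[2], b[2])
    c1 = min(a[3], b[3])
    inter = max(0.0, r1 - r0) * max(0.0, c1 - c0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def _average_precision(dets, gts, thr: float) -> float:
    """All-point interpolated AP for one class at one IoU threshold.

    ``dets`` is a list of (box, score); ``gts`` a list of boxes. Greedy
    matching in descending score order, each truth matched at most once.
    """
    if not gts:
        raise ValueError("no ground truth")
    if not dets:
        return 0.0
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][1], i))
    matched = [False] * len(gts)
    tp = np.zeros(len(dets))
    for rank, i in enumerate(order):
        box = dets[i][0]
        ious = [0.0 if matched[j] else iou_box(box, g) for j, g in enumerate(gts)]
        best = int(np.argmax(ious)) if ious else -1
        if best >= 0 and ious[best] >= thr - 1e-9:
            matched[best] = True
            tp[rank] = 1.0
    ctp = np.cumsum(tp)
    recall = ctp / len(gts)
    precision = ctp / np.arange(1, len(dets) + 1)
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


def mean_average_precision(detections: dict, truths: dict,
                           thresholds=IOU_THRESHOLDS) -> float:
    """Detection mAP over classes and IoU thresholds 0.50:0.05:0.95.

    ``detections`` maps class -> list of (box, score); ``truths`` maps
    class -> list of boxes. A detected class without ground truth is
    excluded with a warning; classes with truth but no detections score 0.
    """
    classes = sorted(truths)
    extra = set(detections) - set(truths)
    for cls in sorted(extra):
        warnings.warn(f"class {cls!r} has detections but no ground truth; excluded",
                      stacklevel=2)
    if not classes:
        raise ValueError("no ground-truth classes to evaluate")
    aps = []
    for cls in classes:
        dets = detections.get(cls, [])
        for box, score in dets:
            if not np.isfinite(score):
                raise ValueError(f"non-finite detection score in class {cls!r}")
        aps.append(np.mean([_average_precision(dets, truths[cls], t)
                            for t in thresholds]))
    return float(np.mean(aps))


# --------------------------------------------------------------------------
# agreement suite

def icc(reference, system, form: str = "icc2") -> float | None:
    """Intraclass correlation for two raters via the two-way ANOVA mean
    squares. Forms: ``icc1`` one-way random; ``icc2`` two-way random,
    absolute agreement, single rater (the method-comparison default);
    ``icc3`` two-way mixed, consistency. Returns None when undefined."""
    x = np.asarray(reference, dtype=float)
    y = np.asarray(system, dtype=float)
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)
    if form == "icc1":
        msw = (sse + ssc) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        return None if denom == 0 else float((msr - msw) / denom)
    if form == "icc2":
        denom = msr + (k - 1) * mse + k / n * (msc - mse)
        return None if denom == 0 else float((msr - mse) / denom)
    if form == "icc3":
        denom = msr + (k - 1) * mse
        return None if denom == 0 else float((msr - mse) / denom)
    raise ValueError(f"unknown ICC form {form!r}")


def agreement(series: PairedSeries, icc_form: str = "icc2") -> AgreementResult:
    """Full method-comparison statistics for one paired series.

    Differences are ``system - reference``. With zero variance in either
    series the correlation coefficients are undefined and reported as None
    rather than NaN.
    """
    x, y = series.reference, series.system
    d = y - x
    n = len(d)
    mae = float(np.mean(np.abs(d)))
    mse = float(np.mean(d ** 2))
    rmse = float(np.sqrt(mse))
    mean_diff = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    loa_low = mean_diff - 1.96 * sd_d
    loa_high = mean_diff + 1.96 * sd_d
    mad_abs_dev = float(np.mean(np.abs(d - mean_diff)))

    sx2 = float(np.var(x))           # 1/n moments (Lin's estimator)
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    if sx2 == 0.0 or sy2 == 0.0:
        pcc = None
        ccc = None
    else:
        pcc = sxy / np.sqrt(sx2 * sy2)
        ccc = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)

    return AgreementResult(
        ccc=ccc, pcc=pcc, icc=icc(x, y, icc_form),
        mae=mae, mse=mse, rmse=rmse,
        mean_diff=mean_diff, loa_low=float(loa_low), loa_high=float(loa_high),
        mad_abs_dev=mad_abs_dev, label=series.label, units=series.units,
    )
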