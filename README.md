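# limbalign

Automated measurement of lower-limb alignment from full-leg radiograph
segmentation masks.

Clinicians assess frontal-plane lower-limb alignment — varus/valgus
deformity, leg-length discrepancy, joint-line orientation — on standing
anteroposterior radiographs by drawing mechanical and anatomical axes and
reading off a standard set of angles and lengths (Paley's deformity
parameters). Measuring them by hand is slow and observer-dependent.
`limbalign` implements the measurement core of an automated system: given
per-ROI binary bone masks (femoral shaft, tibial shaft, femoral head, knee,
ankle — the masks a segmentation model or a human annotator produces), it
detects the anatomical landmarks, constructs the axes, and computes the 16
standard alignment parameters with normal-range classification. It also
ships the evaluation toolkit used to validate such systems and a synthetic
leg phantom with closed-form ground truth, so the whole pipeline can be
tested end-to-end without patient data.

## What it computes

With the femoral mechanical axis **f** (femoral head centre → knee centre),
the tibial mechanical axis **t** (knee centre → ankle centre), the
anatomical (mid-diaphyseal) shaft axes, and the joint orientation lines
(femoral condyles, tibial plateau, tibial plafond), the report contains:

| group | parameters |
|---|---|
| mechanical | mLPFA, mLDFA, mMPTA, mLDTA, mJLCA, mTFA, MAD (mm) |
| anatomical | aMPFA, aLDFA, NSA, aMPTA, aLDTA, aTFA |
| lengths | full leg, femur, tibia (mm) |

Each angle is the angle between the oriented axis ray and the joint-line
ray on its clinically named side (e.g. mLDFA = femoral mechanical axis vs
the distal femoral joint line, measured laterally); MAD is the perpendicular
distance from the knee centre to the hip–ankle line. Every parameter is
flagged against its published normal range (closed intervals; e.g.
mLDFA 85°–90°, NSA 124°–136°, MAD 0–3 mm).

Landmark detection uses classical geometry on the masks: an algebraic
least-squares (Kåsa) circle fit to the superior femoral-head boundary arc,
total-least-squares lines through mid-diaphyseal run midpoints for the shaft
axes, and sub-pixel localisation of the two articular extremal points of
each joint surface.

The evaluation module implements the statistics used to compare such a
system against a human reader: Dice similarity coefficient, Hausdorff
distance, detection mAP (IoU 0.50:0.05:0.95), Lin's concordance correlation,
Pearson correlation, ICC(2,1), Bland–Altman bias and limits of agreement,
and MAE/MSE/RMSE/mean absolute deviation.

## Worked example

Generate a synthetic varus leg (masks + closed-form ground truth), then
measure it:

```sh
limbalign phantom-generate --seed 42 --population varus --out case42
limbalign measure-run --masks case42 --out report42.csv
```

prints

```
Lower-limb alignment report (side=left, spacing=0.48 mm/px)
      parameter  value units normal_range normal_flag
          mLPFA  92.62   deg        85-95        True
          mLDFA  92.99   deg        85-90       False
          mMPTA  83.78   deg        85-90       False
          mLDTA  88.56   deg        86-92        True
            MAD  26.88    mm          0-3       False
          mJLCA   1.30   deg          0-2        True
           mTFA   7.91   deg          0-3       False
          aMPFA  81.37   deg        80-89        True
          aLDFA  86.99   deg        79-83       False
            NSA 132.84   deg      124-136        True
          aMPTA  83.79   deg        85-90       False
          aLDTA  88.58   deg        86-92        True
           aTFA   1.89   deg          0-3        True
full_leg_length 825.62    mm            -            
 femoral_length 462.73    mm            -            
  tibial_length 356.22    mm            -            
```

The phantom was sampled from the varus population, and the report reads
exactly like a varus limb: the tibiofemoral angle (mTFA 7.91°) and
mechanical axis deviation (MAD 26.9 mm) are far outside their normal ranges,
driven by an abnormally high mLDFA and low mMPTA, while the hip and ankle
parameters stay normal. The phantom's own `truth_report.csv` (written next
to the masks) holds the closed-form values; the measured angles agree with
them to well under half a degree.

The same `measure-run` command works on any directory of PNG masks with a
`rois.json` sidecar (pixel spacing, laterality, per-class bounding boxes) —
the file layout a segmentation stage would emit. `limbalign evaluate-seg`
and `limbalign evaluate-agreement` produce the DSC/HD and
method-comparison tables; `limbalign selftest` runs a quick phantom
round-trip check.

## Layout

- `limbalign.phantom` — synthetic leg generator (`PhantomSpec`,
  `generate_phantom`, `add_boundary_jitter`); ground truth is closed-form,
  never derived from rasterised masks.
- `limbalign.preprocess` — deterministic image operators (pad-to-square,
  fixed resize, CLAHE, ROI crop, right→left flip) with exact coordinate
  transforms.
- `limbalign.landmarks` — the detectors and `assemble()`.
- `limbalign.measure` — axes, the 16 parameters, normal-range flags.
- `limbalign.metrics` — DSC, Hausdorff, mAP, agreement suite.
- `limbalign.pipeline` / `limbalign.cli` — configuration, IO, subcommands.

See `docs/methods.md` for the model, conventions and known limitations.
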