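# infantwear

Wear/non-wear discrimination for infant-worn triaxial accelerometers.

Identifying when an activity monitor is actually being worn is the first
data-cleaning step in any wearable study, and it is hardest in infants:
they sleep most of the day, move sporadically, and much of the recorded
movement is caregiver-generated. The standard heuristic — treating runs of
consecutive zero activity counts as non-wear — conflates quiet sleep with a
device left on a table. `infantwear` implements an alternative that works
from the raw 30 Hz signal of hip- and ankle-worn devices, combining device
*inclination* with *change in movement* so that a motionless worn device can
still be recognized as worn.

## Method

For each device axis a ∈ {X, Y, Z} and each 30 Hz sample, the package
computes the vector magnitude VM = √(X² + Y² + Z²) (milli-g) and the
per-axis inclination angle θₐ = arccos(a / VM) · 180/π, then averages these
into one-minute epochs (per-sample first, then averaged). Movement change is
captured by a sliding coefficient of variation: for window length
w ∈ {2, 3, 4, 5} minutes, the CV of every window of w consecutive minutes
containing the anchor minute is scale · sd/|mean| (sample sd), and the
anchor's CV is the **minimum** over those w placements. Anchors lacking any
placement (the first and last w − 1 minutes) are missing.

Minutes are classified wear/non-wear (non-wear is the positive class) by a
CART decision tree over six predictors per site — θX, θY, θZ and the
4-minute CVs of the X, Y, Z axes — either per site or with both sites'
twelve predictors combined. The cost-complexity penalty cp is tuned over 50
log-spaced values in [10⁻⁵, 10⁻¹] by inner 10-fold stratified CV maximizing
ROC AUC, and models are evaluated by leave-one-*participant*-out
cross-validation. The consecutive-zero-counts comparison labels every run of
≥ 2 zero-count minutes as non-wear, with an "any site wear → wear"
combined-site rule.

A synthetic study generator produces labeled raw recordings (device on a
table, worn sleep, waking movement, caregiver handling) plus pseudo-counts
so the whole pipeline is testable end to end.

## Worked example

```python
>>> from infantwear import sliding_cv, placement_cvs
>>> vm = [1020.73, 1021.07, 1021.28, 1021.30, 1021.48, 1021.12,
...       1036.18, 1024.44, 990.04, 974.24, 969.71]   # per-minute VM, milli-g
>>> placement_cvs(vm, 2, scale=1e4)[6]                 # anchor 10:36:00
array([103.52430977,  80.57219294])
>>> round(sliding_cv(vm, 2, scale=1e4)[6], 1)          # min over placements
80.6
```

The two placements of the 10:36 anchor have CVs 103.5 (backward window
10:35–10:36) and 80.6 (forward window 10:36–10:37); the retained sliding CV
is their minimum, 80.6 — a movement-change feature for that minute.

Full pipeline on synthetic data:

```python
>>> from infantwear import default_study_config, generate_feature_dataset, WearTreeModel
>>> feats, labels, counts = generate_feature_dataset(default_study_config(seed=0))
>>> cv = WearTreeModel(feats, site_mode="ankle", seed=0).loocv()
>>> cv.summary().round(3)
             mean  min  max  n_folds  n_excluded
metric
accuracy      1.0  1.0  1.0       15           0
sensitivity   1.0  1.0  1.0       15           0
specificity   1.0  1.0  1.0       15           0
ppv           1.0  1.0  1.0       15           0
npv           1.0  1.0  1.0       15           0
f1            1.0  1.0  1.0       15           0
```

Each row is the macro average over the 15 held-out participants with its
per-fold (min, max) range; on this well-separated synthetic study the ankle
model recovers wear status essentially perfectly, while the hip-only model
(whose sleeping-hip signal is deliberately generated to resemble a device on
a table) averages ≈ 0.71 accuracy.

The same workflow is available from the shell:

```
infantwear simulate --preset tiny --out demo --seed 5
infantwear features --raw demo/raw/P01_hip.csv --raw demo/raw/P01_ankle.csv \
    --raw demo/raw/P02_hip.csv --raw demo/raw/P02_ankle.csv \
    --labels demo/labels.csv --out demo/features.csv
infantwear loocv --features demo/features.csv --site ankle --out demo/cv
infantwear baseline --counts demo/counts.csv --combine --out demo/baseline.csv
```

## Layout

- `infantwear.features` — VM, inclination, minute aggregation, sliding CV,
  feature-table assembly
- `infantwear.tree` — CART fitting/tuning, LOOCV, `WearTreeModel` /
  `WearTreeResults` / `LOOCVResults`
- `infantwear.baseline` — consecutive-zero-counts method
- `infantwear.metrics` — confusion metrics, fold summaries, wear-minute tables
- `infantwear.synthetic` — labeled synthetic study generator
- `infantwear.io` / `infantwear.cli` — CSV dialects, model artifacts,
  pipeline, command line

See `docs/methods.md` for modeling assumptions, parameter choices and
limitations.
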