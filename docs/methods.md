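# Methods

## Problem and approach

A body-worn accelerometer that is not moving is not necessarily not worn.
In infants this ambiguity dominates: long sleep bouts produce the same
"no movement" count signature as a device sitting on a table. The package
classifies each minute of a recording as wear or non-wear from two kinds of
raw-signal features that a count-based rule cannot see: device *posture*
(per-axis inclination angles) and *relative change in movement* (a sliding
coefficient of variation), feeding a small, interpretable decision tree.

## Feature extraction

Raw input is a 30 Hz triaxial series in milli-g (±8 g dynamic range). Per
sample, VM = √(X²+Y²+Z²) and θₐ = arccos(a/VM)·180/π for each axis; θₐ is
undefined (missing) where VM = 0. These per-sample quantities are averaged
into one-minute epochs **before** any windowed statistics — computing the
angle of a mean vector instead of the mean of per-sample angles gives
materially different values under oscillating movement (an alternating
±1 g X-axis signal has mean X = 0 but mean θX = 90°, not undefined), and the
package enforces and tests this ordering. Epochs align to wall-clock minute
boundaries; partial leading/trailing minutes are dropped.

The sliding CV of an anchor minute at window length w ∈ {2,3,4,5} considers
all w contiguous placements of a w-minute window containing the anchor;
each placement's CV is scale·(sample sd / |mean|) and the anchor keeps the
*minimum*. The minimum makes the feature insensitive to a transition that
merely abuts the anchor: a quiet minute next to a burst still has one quiet
placement. Conventions:

- The anchor is defined only when **all** w placements exist, so the first
  and last w−1 minutes are missing. (A `min-over-available` fallback exists
  but is off by default.) Missing edge minutes are excluded from model
  training and scored as missing at prediction.
- `scale` defaults to 100 (a true percent). The worked-example regression
  values use scale 10⁴, which is the convention the printed example
  actually follows; both are honored, with the scale as an explicit
  parameter.
- A placement with sd = 0 and mean = 0 (an all-zero stationary window) has
  CV 0; sd > 0 with mean = 0 is undefined and that placement is dropped
  from the minimum. Using |mean| keeps CVs non-negative on signed axis
  channels.

## Classifier

CART with the Gini criterion, grown fully and cost-complexity pruned.
The pruning strength is expressed as an rpart-style *relative* complexity
parameter cp and mapped internally to scikit-learn's absolute `ccp_alpha`
as cp · gini(root); this keeps cp comparable across training sets with
different class balance, and leaf count is non-increasing in cp (tested).
Default predictors are the per-axis inclination angles and per-axis
4-minute CVs (six per site; twelve for the combined-site model), the
feature set that won the original model selection.

cp is tuned over 50 logarithmically spaced values in [10⁻⁵, 10⁻¹]
(log spacing is the natural choice for a positive scale parameter spanning
four decades) by inner stratified 10-fold cross-validation maximizing ROC
AUC with non-wear as the positive class. Ties — common when several cp
values leave the same pruned tree — break toward the **largest** cp, i.e.
the simplest tree. Plain maximum AUC is used (no one-standard-error rule).
Inner folds are seeded; the fold count drops below 10 only if the minority
class has fewer members than folds. Surrogate splits are not implemented:
rows with missing predictors are excluded from training and receive missing
predictions, with counts logged — a simpler, auditable contract.

Evaluation is leave-one-**participant**-out: each fold tunes and fits on
all other participants and predicts the held-out one, so no within-subject
correlation can leak into the estimate. Fold metrics (accuracy,
sensitivity, specificity, PPV, NPV, F1; non-wear positive) are
macro-averaged with per-fold (min, max) ranges; pooled-confusion metrics
are also available. Zero-denominator metrics are reported missing — never
coerced to 0 — and excluded from averages with a logged count.

## Zero-counts baseline

Every maximal run of ≥ `min_run` (default 2) consecutive zero-count 60-s
epochs is non-wear; isolated zeros in shorter runs stay wear; no special
casing at recording boundaries. The combined-site decision is wear iff at
least one site is wear. Counts are consumed from file; the proprietary
raw-to-count conversion is out of scope.

## Synthetic study generator

The generator exists so that feature extraction, tuning, LOOCV and the
baseline comparison can be exercised at realistic scale without any device
data. Per-sample model: 1000·orientation (unit gravity direction) +
isotropic Gaussian sensor noise + Poisson-arriving damped-sinusoid bursts
(0.5–3 s, 2–8 Hz, random direction, exponential decay) + a slow per-minute
orientation random walk in worn states. State defaults (noise sd in
milli-g, bursts/min, burst amplitude in milli-g, drift °/min):

| state              | noise | bursts/min | amplitude | drift |
|--------------------|------:|-----------:|----------:|------:|
| nonwear_table      |   2   |     0      |     —     |   0   |
| worn_sleep         |   3   |    0.08    |    120    |  0.4  |
| worn_awake         |   5   |    5       |    250    |  1.5  |
| caregiver_handling |   6   |    4       |    200    |  3    |

Site structure encodes the mechanism that made the ankle the better site in
practice: ankle bursts dominate while awake (hip rate scaled ×0.3), the
sleeping hip is motionless (burst/drift ×0) and oriented nearly flat
(tilt 0–10° from device-face-down), overlapping the on-table orientation
(tilt 0–6°), while the sleeping ankle points along −Y with 10–30° tilt.
Caregiver handling applies the *same* burst event times to both sites.

The study-scale default is 15 participants × 2 sites with, per participant,
451 non-wear minutes (two table blocks, emulating pre-visit initialization
and post-visit download) and 321 wear minutes (sleep 132, waking 101,
handling 88), jittered ±8 % per participant — reproducing the criterion
minute budget (≈ 6 770 non-wear / 4 810 wear in total, ≈ 451/321 per
participant) of the two-visit laboratory protocol the method was built for.
All randomness flows from one seed through per-participant spawned
generators, so output is bit-reproducible.

Pseudo-counts are a **synthetic stand-in** for ActiLife's proprietary
count conversion: per minute, `floor(12 · max(0, mean|VM−1000| − 3 mg))`.
The 3 mg dead band guarantees zero counts for stationary minutes (noiseless
or sensor-noise-only) and keeps quiet sleep mostly at zero — the property
the zero-counts comparison turns on. The gain (12 counts/mg) only sets a
plausible magnitude; the baseline uses only the zero pattern.

### What passing tests do and do not show

The generator's regimes are well separated by construction (distinct
orientations and burst statistics), so near-perfect ankle/combined LOOCV
recovery demonstrates that the pipeline — features, tuning, fold hygiene,
prediction — is correct, not that real infant data are this easy: the
published models sit near 90 % accuracy, not 100 %. The generator omits
device calibration error, temperature drift, idle-sleep-mode artifacts,
non-wear in worn-like orientations (diaper bag, car seat) and genuinely
ambiguous handling, all of which compress real-world performance. The
hip-vs-ankle gap on synthetic data reproduces the *direction* and mechanism
of the published result, not its magnitude.

## Numerical choices and degenerate inputs

- Sample sd uses ddof = 1 everywhere, matching the worked example.
- AUC ties in tuning use a 1e-12 tolerance before the largest-cp tie-break.
- Inner folds whose test split contains one class are skipped in the AUC
  mean; single-class training data is an error.
- A held-out participant with no labeled minutes is skipped with a warning.
- Duplicate participant×site×minute rows are an error naming the timestamp;
  label rows that match no feature minute are reported, not dropped
  silently.
- Percent differences in wear-minute tables are |method − criterion| /
  criterion × 100 computed from totals, rounded to 0.1; means/SDs to 0.1.
- Timestamps are timezone-naive ISO-8601; accelerations are normalized to
  milli-g at ingest (g inputs ×1000).

## Known limitations

- No surrogate splits, probability calibration, ensembles, or graphical
  tree rendering (a text rendering is provided).
- The tree-structure equivalence between a combined-site model with one
  constant site and the single-site model holds when the best split is
  unique; exact ties between equally separating features are broken by the
  library's seeded feature permutation.
- Native .gt3x binary ingestion is not included; ActiGraph RAW CSV and a
  headerless CSV dialect are the supported raw inputs.
- The zero-counts baseline is only as faithful as the counts supplied to
  it; with synthetic pseudo-counts it characterizes the *rule*, not
  ActiLife's filter.
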