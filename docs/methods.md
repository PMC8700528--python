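# Methods

## Problem and pipeline

Cervical vertebral maturation (CVM) staging estimates skeletal maturity from
the morphology of the second to fourth cervical vertebrae (C2–C4) on a
lateral cephalogram. `cvmstage` implements the full automatic pipeline:

1. **Annotation and calibration** — fifteen named landmarks per image in
   LabelMe JSON: two reference markers R1/R2 placed 10 mm apart on the
   film's calibration ruler, and thirteen anatomic points (`lp`/`la`
   posterior/anterior lower-border corners, `m` the deepest point of the
   lower-border concavity, `up`/`ua` upper-border corners of C3/C4; C2
   carries only its lower border). The per-image scale is
   `mm_per_pixel = 10 / |R1 − R2|`; calibration is per image because
   cephalostat magnification varies.
2. **Morphometrics** — five scalars: concavity depths `C2Conc`, `C3Conc`,
   `C4Conc` (mm) and base-to-anterior-height ratios `C3BAR`, `C4BAR`
   (dimensionless). Concavity is the perpendicular distance from `m` to the
   chord `lp–la`, signed and clamped: a flat or convex border scores 0,
   because the immature stages are defined by the *absence* of a concavity,
   never by a negative one. The sign is anchored on the vertebra's own
   upper-border midpoint (for C2, on the side opposite the C3 body), which
   makes the convention rotation-invariant rather than image-axis-dependent.
3. **Staging** — a thresholded decision tree (below).
4. **Evaluation** — one-vs-rest per-stage metrics, accuracy, Cohen's kappa,
   ICC and per-landmark mm error.
5. **Detection** — a small convolutional network regressing the 30 landmark
   coordinates from the 100 × 200 px C2–C4 region of interest.

## Staging rules and thresholds

Let k be the number of concave lower borders among C2, C3, C4
(`depth ≥ concavity_mm`). Then k = 0 → CS1, k = 1 → CS2, k = 2 → CS3. With
k = 3 the C3/C4 body shape decides the tier: any vertical rectangle
(`BAR ≤ vertical_upper_bar`) → CS6, else any square
(`BAR ≤ square_upper_bar`) → CS5, else CS4. The most mature shape wins;
boundary ties count on the mature side.

Defaults: `concavity_mm = 1.0` (the conventional visibility criterion for a
lower-border concavity), `square_upper_bar = 1.2`,
`vertical_upper_bar = 0.95`. The original clinical description of the
method does not commit to printed numeric thresholds, so these are this
package's engineering defaults, exposed as configuration
(`StageThresholds`) and as a JSON thresholds file in the CLI.

Two deliberate totality choices:

* staging counts concave borders rather than matching their identity, so an
  anatomically out-of-order pattern (e.g. C4 concave while C2 is flat —
  possible under annotation noise) still receives the stage implied by k,
  flagged `pattern_consistent = False`;
* the immature trapezoid and the horizontal rectangle are merged into one
  `horizontal` class: with only the five measurements above they are
  indistinguishable, and the early/late split is carried entirely by the
  concavity counts.

Stages are monotone along the maturation direction: deepening concavities
and falling BARs can never decrease the assigned stage (property-tested).

## Agreement statistics

From the 6 × 6 confusion matrix (rows gold, columns predicted), one-vs-rest
per stage: precision TP/(TP+FP), recall TP/(TP+FN), specificity
TN/(TN+FP), F1 the harmonic mean of precision and recall. Accuracy is the
trace over the total; kappa is unweighted Cohen's kappa. Metrics with a
zero denominator return an explicit `None` marker. Report display uses
half-up rounding to 2 decimals; full precision is kept internally.

The ICC treats the stages as equally spaced integer codes 1–6 (an explicit
assumption). The default variant is ICC(2,1) — two-way random effects,
absolute agreement, single rater — because agreement between an automatic
system and a gold standard is an absolute-agreement question; ICC(3,1) and
ICC(2,k) are selectable. The implementation is the standard mean-squares
decomposition and is cross-checked against `pingouin.intraclass_corr` in
the tests; kappa and the per-class metrics are cross-checked against
scikit-learn.

Landmark error is the per-landmark Euclidean distance in mm between paired
annotations, calibrated by the gold record's reference markers. The
summary row is the unweighted mean and sample SD (n − 1) across the 13
per-landmark means — the convention under which the published error-table
totals are reproduced exactly; image-weighted pooling is available behind
`pooled=True`.

A note on the published specificity formula: the printed formula
TN/(TP+FN) is internally inconsistent with the printed specificity values;
TN/(TN+FP) reproduces them exactly (e.g. CS5: 74/88 = 0.84) and is what
this package implements.

## Synthetic data generator

The generator emulates the *measurement geometry* of a lateral-cephalogram
ROI, not its photometric appearance. On a 100 × 200 px canvas at
0.25 mm/px it places R1/R2 exactly 10 mm apart, a C2 lower border with a
12 mm chord, and C3/C4 bodies as quadrilaterals whose anterior height is
drawn from 8–11 mm and whose base width realises the target BAR. The
concave lower border is the circular arc through `lp`, `m`, `la` — the
unique smooth curve consistent with `m` being the deepest point of the
concavity.

Stage-conditioned sampling draws depths and BARs uniformly from the region
of measurement space consistent with the requested stage *under the staging
module's own thresholds*, at a margin of 0.15 mm (concavity) and 0.05
(BAR) from every boundary, so the generator and classifier cannot drift
apart and zero-jitter recovery is exact by construction. Concavity depths
for concave borders span threshold + margin up to ≈2.5 mm, matching the
range seen across maturation. Annotation noise is isotropic Gaussian per
anatomic landmark (sigma in mm; R1/R2 fixed so calibration is untouched);
its displacement magnitudes are Rayleigh-distributed with mean
σ·√(π/2), which the tests verify in closed form. Rendering fills the body
polygons at a constant foreground intensity over background, with Gaussian
blur and additive Gaussian noise; default dataset proportions follow a
typical orthodontic cohort (CS1–CS6 ≈ 25/22/17/11/5/20 %).

What the generator does **not** emulate: soft tissue, bone texture,
overlapping anatomy, exposure variation, and inter-patient shape
correlation. Tests passing on synthetic data therefore validate the
geometry, the decision logic and the statistics — not clinical-grade
landmark detection on real radiographs.

## Detector

The landmark detector is a compact numpy-implemented convolutional network:
stride-2 3 × 3 convolutions (default channels 8-16-32-64, ReLU, 'same'
padding, He initialisation) followed by one fully connected layer emitting
30 values — the 15 landmark coordinates in canonical order, normalised by
image width/height. Training minimises mean squared error with Adam
(lr 1e-4, β 0.9/0.999, eps 1e-8, batch 32); every source of randomness
(initialisation, batch order) derives from the config seed, and checkpoints
(config + parameters + landmark order) reload bit-exactly.

Desk-scale defaults are 30 epochs on a few hundred synthetic images —
deliberately small so a full train/evaluate cycle runs in about a minute on
one CPU. At that scale the detector converges (loss falls by >99 % on a
200-image run and memorises a single case to <0.1 px) and localises unseen
synthetic cases to roughly 1 mm. That is sufficient to demonstrate the
pipeline but **not** to stage reliably: the stage-consistent sampling
margins are 0.15 mm, so thresholded staging from predicted landmarks stays
near chance until localisation error falls well below the decision
margins. Reaching the sub-0.4 mm regime reported for full-scale clinical
systems requires a much deeper backbone and a large real training set,
which is outside this package's scope; depth, channels and epochs are
configuration so such a variant can be plugged in.

## Numerical choices and degenerate inputs

* Anterior heights below 0.5 px raise a degeneracy error instead of
  producing unbounded BARs; coincident chord points raise rather than
  returning NaN.
* Concavity clamping means measurements are continuous but not
  differentiable at 0; staging is piecewise constant with inclusive
  boundaries on the mature side, and values ≥1e-6 away from a boundary are
  stable under 1e-9 perturbations (tested).
* ROI cropping uses a corner-anchored affine map (box corner → ROI corner,
  bilinear resampling); the recorded transform inverts to 1e-6 px.
* In the CNN, intensities are centred by subtracting 0.5; coordinate
  normalisation is x/width, y/height. Both are package conventions,
  documented as part of the checkpoint contract.
* Records whose predicted geometry cannot be measured (possible for an
  untrained detector) are assigned the least mature stage during
  evaluation rather than crashing a batch run.

## Problem sizes used in the checks

The self-checks (`scripts/acceptance.py`) use: 200 zero-jitter cases per
stage for exact recovery; 600 cases × jitter sigmas {0, 0.25, 0.5, 1.0} mm
for noise monotonicity; 13 000 displacements for the Rayleigh check; a
200-image, 30-epoch detector run for the loss-reduction check and a
single-case 150-epoch run for memorisation; and the published hold-out
composition (100 images) with its per-stage precision/recall for the metric
reconstruction. These sizes were chosen as the smallest at which each
property is measured stably.

## Known limitations

* The staging thresholds are defensible defaults, not fitted clinical
  values; real-data use should calibrate them.
* The synthetic image model is schematic; detector results on it do not
  transfer to radiographs.
* No bootstrap confidence intervals or paired classifier tests; the
  evaluation module scores one system against one gold standard.
* DICOM ingestion and automatic ruler detection are out of scope; input is
  LabelMe JSON plus PNG/JPEG.
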