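# Methods

This note documents the models, conventions and numerical choices behind
`osteomorph`, and what the synthetic-study generator does and does not
emulate.

## Study design

The canonical experiment lattice is 3 donor lots × 2 culture conditions
(osteogenic induction vs non-induction control) × 3 passages per lot × 3
replicate wells = 54 wells, imaged at 5 view fields per well. Imaging is
scheduled every 8 h; of 40 scheduled timepoints, three are excluded (cell
settling at the start and two medium changes), leaving 37 retained
timepoints and 54 × 5 × 37 = 9,990 acquisition slots. All counts are
configurable (`DesignConfig`); the retained-timepoint count reconciles the
666-column morphology design (9 × 2 × 37) with the image total.

Each well carries two terminal markers: the day-14 ALP activity rate
(early differentiation, absorbance ratio) and the day-21 calcium
deposition rate (late maturation, absorbance), both dimensionless.

## Synthetic-study generator

The generator replaces an undeposited microscopy dataset, so its role is
to reproduce the statistical structure the analysis depends on — not the
optics of phase contrast.

**Latent potential.** Each well's osteogenic potential is
`clip(mu_condition + a_lot + b_lot,passage + c_well, 0, 1)` with
`mu_induction = 0.70`, `mu_control = 0.25` and Gaussian effects of SD
0.12 (lot) > 0.06 (passage) > 0.03 (well). The ordering encodes that
donor-to-donor ("patient-derived") variance dominates processing-derived
variance; a nested method-of-moments ANOVA in the test suite recovers the
three components from generated data within 15%.

**Donor style and assay offset.** Each lot additionally draws a
morphological *style* (log cell-size scale, SD 0.15) and a standard-normal
*assay offset*. The style is visible in the images (all of the lot's cells
are scaled by `exp(style)`); the assay offset shifts the lot's marker
values (gain 0.08 for ALP, 0.15 for calcium) and is independent of
morphology **across** lots. Within a lot, however, the offset is
learnable: a model trained with some of the lot's own wells can attach the
residual to the lot's distinctive style signature. This is the mechanism
behind the ongoing-patient scheme's advantage — it mirrors the clinical
observation that a new patient's cells carry individual characteristics
that historical data cannot supply.

**Markers.** Noise-free means are monotone in the potential *p*:
`ALP = 0.25 + 0.90 p + 0.30 style + 0.08 offset` and
`Ca = 0.05 + 0.80 p² + 0.35 style + 0.15 offset`, each plus Gaussian noise
with SD proportional to the mean (CV 0.07 for ALP, 0.22 for calcium) and
clipped at zero. Calcium's quadratic response, larger CV and larger donor
offset make it the harder, higher-variance endpoint, matching the relative
behaviour of the two assays.

**Cells.** Cells are rasterized superellipses `|x/a|^m + |y/b|^m ≤ 1`.
A phenotype scalar `phi = potential × (0.15 + 0.85 t/T)` interpolates each
cell between the control morphology (aspect ratio drawn from 3–8, pointed
exponent m = 1.3 — a spindle) and the induced morphology (aspect 1–2,
boxy exponent m = 4, area grown by up to 2.2×, interior hole with
probability 0.5·phi) — so induction/control separation grows over culture
time, and per-timepoint mean form-factor curves diverge. Cell area is
lognormal around 150 px² with an 80 px² floor, keeping real cells well
above the 50 px² particle-deletion scale. Cells are placed by rejection
sampling with a 5 px minimum gap; in crowded fields the accepted area
shrinks by 1.5% per retry, imitating confluence, and a field that cannot
be packed raises an error. Per-field counts grow exponentially from 6 to
~15 cells across the run (desk scale).

**Image formation.** Background 40 plus a random planar illumination
gradient (amplitude 8), cells at +120 ± 12, Poisson-distributed sub-cell
bright specks (radius 1–2 px, the debris that particle deletion and
cleansing must remove), and white noise of SD 5, quantized to 8-bit.
Whole datasets are pure functions of (config, seed): per-field RNG streams
are derived from `SeedSequence((seed, crc32(well_id), timepoint))`.

**What is not emulated.** Phase-contrast halos and shading, cell motility
and tracking, touching/confluent cells, mitosis and death, focus drift.
Passing tests therefore demonstrate that the *pipeline* recovers the
structure the generator encodes; they cannot certify performance on real
phase-contrast data, where segmentation is the dominant risk.

## Segmentation

Commercial morphometry chains typically reduce background by optical
deconvolution; without point-spread data this package estimates background
by grayscale
opening with a 33 px square window (larger than any cell's minor
footprint, separable and fast) and subtracts it, which removes slow
illumination trends while preserving compact bright objects. Open–close
smoothing with radius-1 disks follows. One global threshold per dataset is
selected on a 5-intensity-step grid by minimizing the total absolute
difference between post-cleanup object counts and reference counts over 20
randomly chosen calibration images (ties to the lower threshold); the
reference counts are ground-truth in the synthetic setting and would be
manual counts on real data. Components are labeled with 8-connectivity;
objects under 50 px² are deleted; border-touching objects are retained
(at tens of cells per small field, discarding them would bias the pooled
statistics). Foreground is bright-on-dark; `invert` covers the opposite
polarity.

## Morphometrics

Definitions (A_f = hole-filled area, P = perimeter of the filled object):

| feature | definition |
|---|---|
| total_area | A_f (config switch selects foreground-only instead) |
| hole_area | A_f − foreground area |
| relative_hole_area | hole_area / A_f |
| breadth | minimum caliper (Feret) diameter |
| elliptical_form_factor | breadth / maximum caliper diameter (≤ 1) |
| shape_factor | 4πA_f / P² |
| fiber_length, fiber_breadth | L ≥ B solving P = 2(L+B), A_f = LB |
| inner_radius | max of the Euclidean distance transform inside A_f |

Calipers use rotating calipers on the convex hull of the boundary pixels'
corner points, so a w×h pixel block measures exactly w and h. The fiber
discriminant P² − 16A_f is clamped at zero (and flagged) for near-disk
objects where the rectangle model degenerates. Single-pixel objects are
measured with pixel-square conventions and flagged.

**Perimeter convention.** Shape factor and the fiber features inherit the
digital perimeter estimator, which is therefore configuration-pinned. The
default is the 4-direction Cauchy–Crofton intercept estimator
(`skimage.measure.perimeter_crofton`), chosen over the weighted edge-chain
estimator after benchmarking both against continuous polygon truth on
rasterized superellipse fixtures (Crofton: mean |error| ≈ 1%, max ≈ 3.7%;
weighted chain: ≈ 2% / 5.3%). Both families carry an orientation-dependent
residual bias — worst for long straight edges near 45° — that is inherent
to local digital perimeter estimation; consequently the test suite holds
perimeter-derived features to 3.5% against continuous truth (other
features are held to 2% against same-raster brute-force oracles, where
digitization cancels).

**Noise cleansing.** Commercial morphometry suites remove non-cell
objects with undisclosed proprietary algorithms; this package substitutes
a documented rule: an object is dropped when its robust z-score (median/MAD) on
log-total-area or on shape factor exceeds `z_cut` (default 3.5) within its
well/timepoint population. Log area separates sub-cell debris from cells
across the sizes the renderer produces; the shape-factor channel catches
round artifacts. The rule, its threshold and its removal log are exposed.

## Feature table

The modeling sample is the well. Per retained timepoint, all objects from
the well's fields are pooled; each feature contributes its pooled mean and
population SD, and the per-field cell count contributes its own mean/SD
across fields (the count block can be disabled to reproduce the pure
666-column morphology design). Column order is feature-major, statistic
next, timepoint-minor, recorded in a sidecar column dictionary. Wells with
zero objects at a timepoint get linear temporal interpolation with a
missing flag; wells missing more than 20% of timepoints are rejected. A
change-rate transform (successive differences divided by the 8 h interval)
is available for time-trend modeling and is exactly invertible up to each
series' first value.

## Ridge regression and transfer scenarios

The estimator minimizes ‖y − Zβ − c‖² + λ‖β‖² with Z the
column-standardized design (training means/SDs; constant columns dropped
and logged) and the intercept c unpenalized. With p ≫ n the solution uses
the dual form β = Zᵀ(ZZᵀ + λI)⁻¹y_c; λ = 0 falls back to the minimum-norm
least-squares solution. The penalty is selected by leave-one-out
cross-validation over a log-spaced grid (default 10⁻³…10⁴, 15 points) on
the training rows only, ties toward the larger λ; the LOOCV loop
standardizes once on the selection set and refits each fold through the
precomputed Gram matrix (an O(n³) shortcut; the outer evaluation split is
never touched, which a mutation test asserts). Each endpoint (D14_ALP,
D21_Ca) gets its own model.

Scenario evaluation holds out each lot in turn as the "patient":
new-patient trains on the remaining lots (36/18 at canonical counts);
ongoing-patient moves the held-out lot's first pilot passage (configurable
to 2) into training (42/12). λ is re-selected per training set, and
held-out predictions are pooled over all lots for the summary indices
(per-lot summaries are also reported, since the pooling convention is a
genuine choice).

## Evaluation indices

R is the Pearson correlation of pooled actual and predicted values; MAE
the mean absolute error; the standardized error divides the mean squared
prediction error by the *population* (n-divisor) variance of all
experimentally determined values of that endpoint — 0 for perfect
prediction, 1 for the grand-mean predictor, and legitimately above 1 for a
cold-start model that is worse than the mean on a hard transfer. The
per-feature elimination ablation drops each feature's entire
mean/SD/timepoint block and re-runs the scenario. Per-timepoint
induction-vs-control comparisons use Welch's t-test on well-level means
with a Bonferroni-adjusted column alongside raw p-values; at n = 3 wells
per group, Welch's small-sample df correction leaves a 5-SD separation
hovering around p ≈ 10⁻², which the tests assert as such rather than as a
uniform p < 0.01.

## Problem sizes

Structural checks (54 samples, 666 columns, 9,990 slots, 36/18 and 42/12
splits) run on the canonical lattice. Statistical end-to-end checks run on
a desk-scale configuration that keeps the complete 54-well structure —
which the transfer scenarios need — but images 2 fields/well at 10
retained timepoints on 192×192 fields with 6–15 cells each (1,080 images,
~10⁴ measured objects per study); one full image-to-prediction run takes
well under a minute on one core, so multi-seed replication stays cheap.
The directional finding (ongoing ≥ new-patient for both endpoints) is
asserted across 10 independent studies, and a permuted-label null checks
that pooled |R| collapses below 0.3.

## Known limitations

* The generator's cells are isolated convex-ish blobs; real cultures reach
  confluence, where counting and per-cell morphometry degrade.
* Digital perimeter estimators (all of them) are orientation-biased at the
  percent level; comparisons of shape factor / fiber features across
  software packages must pin the estimator.
* The standardized-error variance convention (population, all values of
  the endpoint) and the pooled-R convention are pinned in config; other
  conventions change the numbers.
* LOOCV-based λ selection with 36–48 training samples has high variance;
  the reported per-lot λ values make this auditable.
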