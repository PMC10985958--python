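# Methods

`nasoclear` analyzes dynamic PET time-activity curves (TACs) of a freely
diffusible, non-binding bolus tracer to quantify fluid transport from the
brain (lateral orbitofrontal cortex, LOF) to the nasal compartment
(superior/middle/inferior turbinates and cribriform plate), with the carotid
artery, jugular vein and temporalis muscle as vascular and extracranial
controls.  Because the human scans such a study rests on are not publicly
deposited, the package pairs the analysis pipeline with a synthetic-cohort
generator that reproduces the *statistical structure* of such data, so every
stage is testable end to end.

## Acquisition model

A 60-min dynamic scan is represented by a contiguous frame schedule; the
default is 45 frames (18 × 10 s, 4 × 30 s, 15 × 60 s, 8 × 300 s) spanning
exactly 3600 s.  Frame values are anchored at frame midpoints — the standard
convention for dynamic PET and the one consistent with trapezoid
integration.  Midpoint-anchored SUV curves are linearly resampled onto a
uniform 10-s grid (361 samples, 0–3600 s): exact at every midpoint, rising
linearly from (0, 0) before the first midpoint (no tracer before injection),
and held constant after the last midpoint (3450 s), which adds no invented
structure over the final half-frame.  All downstream metrics and statistics
operate on this grid so that densely sampled early frames are not
over-weighted.

SUV is computed as concentration (Bq/cc) divided by injected dose per body
weight, `SUV = C / (dose_Bq / weight_g)`, assuming 1 g/cc tissue density and
no residual-activity correction.  SUV conversion precedes interpolation;
the two operations commute, the order is fixed for clarity.

## Clearance metrics

* **AUC** — composite trapezoid rule on the 10-s grid.  Window endpoints
  must lie on the grid; nothing is snapped silently.
* **Influx/egress split** — tissue curves split at 300 s (early window in
  which blood delivery dominates) vs 300–3600 s; the carotid artery splits
  at 30 s because its peak falls inside the first minute; a 120-s variant
  supports the split-threshold sensitivity analysis.  The two windows share
  the boundary sample, so they sum to the total AUC to machine precision.
* **t75** — the time at which the cumulative integral of C(t) first reaches
  75% of the 0–3600 s integral.  The cumulative trapezoid integral is
  linearly interpolated between grid points, making the statistic unique and
  continuous in the data.  It is undefined (an error, never a silent NaN)
  for an all-zero curve.
* **Egress/influx ratio** — egress AUC divided by influx AUC; scale
  invariant; undefined when the influx AUC is zero.

## Generative model for synthetic cohorts

The arterial input is a gamma-variate bolus,
`A (t'/tp)^α exp(α(1 − t'/tp))` with onset 10 s and peak `tp = α/rate`
(15 s after onset at defaults, so the arterial peak falls within 30 s of
arrival), plus a recirculation term rising with the bolus to a plateau of
0.15·A and decaying slowly (3×10⁻⁴ /s).  The peak amplitude scales with
injected dose per body weight (≈20 kBq/cc for 480 MBq into 75 kg), so SUV
normalization behaves as it would in real data.

Each region follows a one-tissue compartment model
`C_T(t) = (1 − vb)·k1·[u ⊛ e^(−k2 t)](t) + vb·u(t)`, where the input `u` is
the AIF after a per-region delay and single-exponential dispersion.  The
convolution uses an exponential-integrator recursion that is exact for
piecewise-linear inputs, run as an IIR filter on a 1-s simulation grid.
Defaults: LOF k1 = 0.6 mL/cc/min, k2 = 0.7 /min (gray-matter flow-tracer
values); temporalis slower (0.10/0.15); carotid and jugular are
partial-volume-scaled blood pools (k1 = 0).  Turbinates and cribriform
plate are low-perfusion, *slow-draining* compartments (k1 ≈ 0.08–0.12
mL/cc/min, k2 ≈ 0.13–0.17 /min, e-fold washout ~7 min) fed by a mixture of
arterial input and the LOF curve (brain_mix 0.4–0.5).  The slow nasal k2 is
deliberate: with brain-like fast washout the nasal tissue tracks blood
equilibrium and a multiplicative k1/k2 reduction cannot move the clearance
time or the egress ratio, whereas slow mucosal drainage — the physiologic
picture the brain-to-nose hypothesis implies — makes "slowed egress"
expressible.  The brain_mix coupling makes brain and nose AUCs correlate
across subjects, as observed in the cohort this emulates.

**Amyloid effect.**  Amyloid-positive subjects receive (a) multiplicative
k1/k2 reductions (default 0.8 on both) in the LOF and all nasal regions —
reduced influx and slowed egress — and (b) a reduction of the recirculation
plateau (factor 0.8).  The systemic recirculation component is needed
because, in a one-tissue model, scaling k1 and k2 equally leaves both the
tissue/blood equilibrium and the long-run AUC invariant, so tissue-side
factors alone produce a <1% total-AUC group difference; reduced
recirculating tracer supplies the overall concentration reduction while
leaving the arterial bolus (carotid influx) untouched — reproducing the
observed dissociation of a carotid egress effect without a carotid influx
effect.  With all factors at 1.0 (`CohortConfig.null()`), the two groups
draw from identical distributions.

**Between-subject variability.**  Lognormal jitter on a subject-level flow
factor (σ = 0.12), per-region k1/k2 (σ = 0.08) and AIF amplitude
(σ = 0.10), plus ±2 s uniform onset jitter.  Group metadata (weight, age,
sex, ApoE ε4 carriage) are sampled from the per-group demographic
distributions of the emulated cohort (16 amyloid-negative / 8 positive;
weights 76.7 ± 15.8 vs 59.8 ± 8.5 kg; dose 480 ± 48 MBq).

**Noise.**  Frame noise is Gaussian with
`sd = noise_scale·sqrt(max(value, floor)/duration)` — a decay-corrected
count-statistics proxy making short early frames noisier — clipped at zero;
default `noise_scale = 20` (Bq/cc · s)^½ gives ~2–6% noise on tissue
frames.  Seeding is counter-based (`SeedSequence((master, subject_index))`),
so growing a cohort never reshuffles earlier subjects.

**What the generator does not emulate:** scanner physics (attenuation,
scatter, decay, reconstruction, partial volume), spatial anatomy (phantom
regions are abstract voxel sets), arterial sampling errors, or motion.
Tests passing on synthetic cohorts therefore validate the *pipeline
machinery and statistical calibration*, not the biological claims of any
real dataset.

## ROI segmentation

The semi-automatic turbinate procedure is: bounding box on a structural
volume → discard the lowest intensity quartile inside the box (air-like
voxels; nearest-rank percentile, strict `>` cut so ties at the cutoff are
excluded) → seeded region growing from 3D spherical seeds (default radius
1.5 mm, in physical units) restricted to the retained voxels,
6-connectivity, one voxel layer per cycle, up to 10,000 cycles.  At
convergence this equals the union of connected components touched by a
seed; the iteration count mirrors the interactive tool the procedure is
modeled on, whose exact update rule is not public — equivalence is by
analogy, not construction.  The cribriform plate uses a fixed-extent box
ROI (≤20 × 10 × 5 mm).  Voxel indices are 0-based and boxes half-open.
Vessel ROIs are expected as user-supplied masks; vessel tracking is out of
scope.

## Statistics

* Mann-Whitney / Wilcoxon rank-sum (one implementation, two names):
  midrank ties; exact enumeration of group assignments for combined n ≤ 10,
  otherwise normal approximation with tie and continuity corrections.
* Spearman: Pearson correlation of midranks; exact n! permutation p for
  n ≤ 8, t-approximation otherwise.  The switchpoints are fixed documented
  constants.
* Pearson chi-square on 2×2 tables, df = 1, continuity correction off by
  default (flag available).
* Two-way mixed repeated-measures ANOVA (between: amyloid group; within:
  time) using the classical weighted-means sums-of-squares decomposition
  for designs complete over time with unequal group sizes.  The group
  effect is tested against subjects-within-groups; time and group × time
  against the within-subject residual with Greenhouse-Geisser-corrected
  degrees of freedom.  Epsilon comes from the pooled within-group
  covariance, double-centered, clamped to [1/(k−1), 1]; it is exactly 1 at
  two timepoints, and at k = 2 the group F equals the squared two-sample t
  on subject means.
* Benjamini-Hochberg step-up FDR adjustment (via statsmodels).  For
  pointwise TAC comparisons the FDR family is all timepoints of one panel
  (361 for 0–60 min; configurable); timepoints with zero variance across
  subjects (e.g. t = 0) are trivially non-significant.
* Significance is two-sided at α = 0.05 throughout; subjects with undefined
  statistics would be excluded listwise from the affected test.
* The pipeline always uses the nonparametric branch for group comparisons;
  a normality-gated parametric branch is deliberately not implemented.
  Regression models predicting amyloid status from clearance measures are
  likewise out of scope: their covariate structure cannot be pinned down
  well enough to implement honestly.

## Design notes and numerical choices

* Split thresholds, the 0.75 fraction, α, and the 10-s grid are all named
  configuration keys with the defaults above.
* The sensitivity comparison (300-s vs 120-s split) checks that per-subject
  total AUCs are identical (they must be, by additivity) and that the
  influx- and egress-segment group effects keep their direction.  The
  egress/influx ratio is excluded from the direction check: it is defined
  at the 5-min split, and under the generative model its group effect
  genuinely reverses sign at a 2-min split (the influx reduction shrinks
  from ~23% to ~18% while the egress reduction stays ~20%).
* Problem sizes in the test and acceptance suites — 500 null cohorts for
  type-I calibration, 100 replicates for effect-direction recovery, 100
  random curves for the dense-grid oracles — were chosen to give stable
  Monte-Carlo estimates at interactive runtimes.
* Degenerate inputs fail loudly: all-zero TACs, empty masks, off-grid
  window endpoints, zero chi-square marginals and constant correlation
  inputs all raise typed errors rather than returning NaN.

## Known limitations

* The one-tissue model with a mixed brain/blood nasal input is a modeling
  convenience, not a physiological claim about whether turbinate signal is
  perfusion- or drainage-fed.
* Kinetic constants are literature-plausible, not fitted to any dataset;
  only directions and rough magnitudes of group effects are meaningful.
* The segmentation stage operates on synthetic structural phantoms; no
  registration, parcellation or atlas support is provided.
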