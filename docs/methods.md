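# Methods

This note documents the models, defaults and numerical choices behind
`wmhmap`, and what the synthetic validation does and does not establish.

## Data model

All volumetric inputs are binary lesion masks on one common grid (NIfTI).
Inputs are assumed co-registered; volumes are reoriented to canonical axis
order on load, float masks are binarized at |v| > 0.5 (masks may arrive as
interpolated floats after resampling), and any affine beyond axis
permutations/flips is rejected rather than resampled — registration is out of
scope, so non-congruent inputs fail loudly. Voxel-wise analyses operate on a
4D stack (3 spatial axes + subject axis) built only from grid-congruent
masks.

The cohort table carries, per subject: age, sex, diabetes / hypertension /
hyperlipidemia flags, 4-level smoking status, RSSI and lacune location codes
over a fixed 7-region x 2-hemisphere vocabulary (internal/external
capsule/lentiform nucleus, internal border zone, centrum semiovale, thalamus,
brainstem, cerebellum, optical radiation), lacune count, lesion volumes per
timepoint and tier, ICV, and follow-up availability. Location-code lists are
ordered primary-first (largest cluster first); the dual analysis path either
keeps the primary code or emits a composite code for multi-cluster subjects,
so every model can be run under both codings.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
fixture. Defaults reproduce the reference sample's marginals: n=118 with
follow-up probability 88/118; age ~ N(64.93, 11.75^2) years; ICV ~ N(1469.20,
139.82^2) ml; male fraction 67/118; diabetes 12/118, hypertension 82/118,
hyperlipidemia 73/118; smoking levels 46/5/31/35 of 117 reporters (the exact
counts, which sum to 1 as probabilities, rather than their rounded
percentages); RSSI in 79/118 subjects with per-location draw weights
proportional to the reported per-region feature counts; old lesions in
42/118.

**WMH spatial model.** A fixed probability template with a
periventricular-like gradient (Gaussian decay from the grid's
anterior-posterior center-line, sd 0.18 of the grid width, peak 0.5) is
scaled by a per-subject log-normal severity factor (median 0.10, log-sd 0.9,
truncated at 0.45), sampled voxel-wise by Bernoulli draws, and morphologically
closed (26-connectivity) so lesions are spatially clustered rather than
salt-and-pepper — the downstream statistics assume spatially coherent
lesions. With the default 32^3 grid at 3 mm isotropic this yields a median
total WMH of ~0.94 %ICV with IQR ~0.4–2.3, matching the reference marginals
(0.944, IQR 0.31–2.47). The severity truncation also keeps the extreme tail
of simulated loads within a clinically plausible range. The intense tier is
the lesion subset whose template value lies in the top 30% of template values
over the lesion — a deterministic, location-based stand-in for signal
intensity.

**Planted effects.**
* Lacune count ~ Poisson(0.3 + 0.37 x WMH %ICV): counts are small
  non-negative integers, and the expectation is linear in WMH load with the
  nominal slope 0.37, so an identity-scale regression recovers it.
* 1-year change: expected progression volume = 0.5 ml + 2.9 ml per ml of RSSI
  volume, realized as a Poisson number of voxels sampled from successive
  dilation rings of the baseline mask (confluent growth); if rings run out
  (tiny lesions) the remainder is drawn from the highest-template free voxels
  so the planted expectation is met without attenuation bias. Regression
  removes a Poisson(0.5 ml) number of mask-interior-boundary voxels,
  independent of RSSI.
* Optional spatial effects keyed to one location x risk-factor group: a
  designated voxel region where members' lesion probability is raised (0.60
  vs 0.15 for everyone else), and/or a designated progression region added at
  follow-up. `planted_balance=True` deterministically assigns the first half
  of subjects to the target condition, giving exact group sizes for power
  analyses; marginal prevalences are intentionally distorted under that flag.

Everything is drawn from a single seeded generator; fixed config + seed gives
bit-identical tables and masks.

**What the generator does not emulate:** MRI physics, partial-volume effects,
anatomically realistic lesion shapes or nonlinear anatomical variability,
spatial correlation between RSSI site and WMH topography (absent unless
planted), and attrition that depends on disease severity. Passing tests
therefore establish the *statistical machinery* (calibration, recovery,
conservation, oracle agreement) under known truth — not clinical validity on
real images.

## Segmentation

WMH segmentation is a simplified re-implementation of red-green color-fusion
thresholding: each channel is rescaled over its 1st–99th percentile window
(threshold transferability across subjects), the fusion scalar is the
channel-wise minimum (a voxel must be bright on both sequences), and two
thresholds split total WMH into intense (>= high) and less-intense tiers. The
tier partition (disjoint, union = total) is enforced by construction and
tested. This is deliberately a simplification of multispectral fusion tools,
not a port; numeric thresholds are free parameters (`--wmh-low`,
`--wmh-high`). Stroke-lesion delineation is seeded region growing: the
26-connected component of the suprathreshold set containing the seed (26 =
common neuroimaging practice; stated explicitly because conventions vary). A
seed below the floor returns an empty, flagged mask rather than an error.

## Volumetrics

Volume = voxel count x voxel volume / 1000 (ml); %ICV = 100 x ml / ICV. The
evolution map codes each voxel 0/1/2/3 = never / regressed / stable /
progressed; the conservation identities vol(stable)+vol(progressed) =
follow-up volume and vol(stable)+vol(regressed) = baseline volume are exact
in voxel counts. Change is computed only for followed-up subjects — no
imputation. All medians and IQRs use linear interpolation between order
statistics; per-location summaries are emitted in both ml and %ICV (models
use %ICV, printed tables ml), and groups below a configurable size floor
(default 5) are flagged "descriptive only" rather than suppressed.

## Subject-level statistics

Models are ordinary least squares on a design with intercept, continuous
terms as-is, and categorical terms expanded to indicators against a declared
reference level; ANCOVA is the same machinery with a change response and
covariates (age always; optionally risk factors, lacune count, old-lesion
volume, location). Missing rows are deleted listwise with the count reported.
Standard errors are HC3 (heteroscedasticity-consistent) by default: lesion
volumes and counts have variance growing with the mean, and classical OLS
errors demonstrably undercover the planted slopes in simulation (coverage
~75% nominal 95%); HC3 restores ~95% coverage. `cov_type="nonrobust"` gives
the classical errors. Smoking enters models as current-or-recent vs
ex-or-never by default, with the full 4-level coding available.

Kruskal-Wallis is implemented with the explicit tie correction and chi-square
reference, plus an exact enumeration option for total n <= 12 (all distinct
assignments of the observed values to the group sizes). The nonparametric
Levene test rank-transforms the pooled values and applies a Brown-Forsythe
style one-way F on absolute deviations from group medians of the ranks.

## Voxel-wise mapping

Per contrast, the target group (feature in a location, optionally restricted
to a risk-factor level) is compared with subjects carrying the feature
elsewhere (and, when conditioned, without the factor; carriers violating
either restriction are excluded so the two groups partition the analyzable
sample). On binary data the per-voxel Kruskal-Wallis reduces to a closed-form
function of the group lesion counts, vectorized over the grid, with the tie
term computed from the counts of ones and zeros. Voxels with fewer than
`min_overlap` (default 2) lesioned subjects are excluded from testing *and*
from the multiple-testing family — untestable voxels would inflate the family
size. BH-FDR is applied per contrast (each map is its own family), at both
0.05 and 0.01 by default; decisions at nested alphas are nested. Suprathreshold
counts convert to ml with the map's voxel volume; the reporting convention
pairs counts with ml at 1 mm isotropic. A k-group mode (more than two
location groups at once) is available through the same entry point.

## Evolution association model

Per-subject evolution maps become a sparse subject x voxel matrix with
entries +1 (progressed), -1 (regressed), 0 otherwise, columns ordered by
voxel coordinate; a baseline mode uses {0,1} WMH presence. The model
minimizes mean epsilon-insensitive loss + (lambda/2)||w||^2 over the voxel
weights by SGD — covariates (age) and the intercept are unpenalized. Defaults:
lambda = 1/47 exactly (treated as an opaque constant; a flag rescales by n
for the alternative normalization convention), epsilon = IQR(response)/13.49
(the dispersion convention common to SVR implementations), 50 epochs,
mini-batch 1, fixed per-seed shuffling, step eta0/(1 + decay t) with
eta0 auto-scaled to the data radius, and averaging of the iterates over the
second half of the run. Runs are fully deterministic given the seed.

A squared-loss mode exists solely for validation: with epsilon = 0 and no
intercept it converges to the closed-form ridge estimator
(X'X + n lambda I)^{-1} X'y; the auto step is 5x smaller there because the
averaged iterate's residual bias under per-epoch reshuffling is linear in the
step size (measured empirically), and the validation tolerance is 1e-3
relative.

Two conventions are genuinely ambiguous in this kind of analysis and both are
implemented behind flags, asserting neither as canonical: the model
orientation (location encoded as the response over voxel predictors — the
default, motivated by the high-dimensional sparse predictors — or per-voxel
responses regressed on location + age via a vectorized closed-form ridge),
and the numeric coding of location (raw proforma integer of the primary
cluster, or a one-vs-rest region indicator).

Display maps split the signed weights by sign and rescale each half to 50% of
its own maximum, clipped to [0,1]; this is visualization only and never feeds
back into statistics.

## Pipeline and reproducibility

Stages (simulate, volumes, stats, voxelmap, associate, report) communicate
through files in a run directory; a global seed expands to per-stage seeds by
hashing the stage name, so any stage can be rerun in isolation reproducibly.
Every run writes a manifest with the SHA-256 of each artifact and the config
hash; a failed stage aborts with its name, retaining and flagging completed
artifacts.

## Validation problem sizes

The test suite and acceptance script use 32^3 grids at 3 mm (the package's
default synthetic resolution), 200 null cohorts of n=60 for FDR calibration,
n=60/60 groups for the 2,000-voxel planted-region recovery, 20 cohorts of
n=500 for slope-recovery coverage, 10 instances of n=40, p=15 for the ridge
oracle, and 1,000 random voxels for Kruskal-Wallis oracle agreement — sizes
chosen so the whole validation runs in a few minutes on one CPU while keeping
Monte-Carlo error well below the tested margins.

## Known limitations

* The segmentation is a thresholding abstraction; it has no bias-field or
  skull-strip handling and is validated only on synthetic phantoms.
* Under the global null the per-contrast BH procedure is conservative on
  heavily tied binary data (realized false-discovery proportions near zero);
  the calibration test bounds, not pins, the error rate.
* The generator's planted change mechanism is additive and voxel-wise; it
  does not model cavitation or lesion disappearance categories from visual
  rating, which are out of scope.
* Reported clinical coefficients from the motivating study design are not
  reproducible without the clinical data; validation is by planted-effect
  recovery at matching magnitudes (0.37, 2.9) instead.
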