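# Methods

This note documents the models implemented in `wmhdti`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical decisions that affect results.

## Signal model and tensor estimation

Diffusion-weighted signals follow the mono-exponential tensor model
S(b, g) = S₀ exp(−b gᵀ D g) with D a symmetric positive 3×3 tensor per
voxel. Units are chosen so diffusivities are in µm²/ms and b-values in
ms/µm² (so the clinical b = 1000 s/mm² is stored as 1.0); this keeps MD
on the scale in which tract values are usually reported (≈ 0.7 µm²/ms in
healthy white matter).

Fitting linearizes the model: ln S = ln S₀ − b gᵀ D g is linear in the
7-vector (ln S₀, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) with the design row
[1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz]. Because the
log transform makes the noise variance approximately σ²/S², an ordinary
least-squares pass is followed by one weighted pass with weights equal to
the squared signals predicted by the first pass — the classical
heteroscedasticity-corrected WLLS estimator. The number of passes is
configurable (`n_passes`); two passes is the default because iterating
weights to convergence changes third-decimal digits at realistic SNR
while complicating the estimator's description. On noise-free data the
fit is exact (the log-linear system is consistent), which the test suite
verifies to 1e-8 over a full phantom.

Numerical guards: non-positive signals are clamped to a tiny positive
floor before the log, and a voxel is invalidated (never raised on) when
more than half its measurements needed clamping or the solution is
non-finite. Negative eigenvalues — a noise artifact — are clamped to zero
for MD/FA computation only; FA is therefore guaranteed in [0, 1] and is
defined as 0 when all eigenvalues vanish.

## Phantoms

Image-level phantoms are regular grids (default 40³ voxels at 2 mm
isotropic) with an isotropic background (0.7 µm²/ms), straight or arc
bundles carrying prolate tensors (1.5, 0.4, 0.3 µm²/ms, FA ≈ 0.73)
oriented along the local tangent, and a central "ventricular" slab.
Lesion voxels are sampled without replacement with probability
∝ exp(−d/τ) in the distance d to that slab (τ default 10 mm), emulating
periventricular predilection without anatomy; they keep the local fiber
orientation but carry higher-MD / lower-FA eigenvalues
(1.6, 0.9, 0.7 µm²/ms, MD ≈ 1.07, FA ≈ 0.42). Lesion FA was deliberately
kept above the 0.2 tracking threshold so streamlines traverse lesions and
the lesion voxels enter the tract average — the voxel-scale mechanism by
which lesion load inflates tract-mean MD. Lesions below that FA would
instead truncate streamlines, a known interference of severe lesions with
fiber tracking that this package reports but does not model further.

Rician noise is applied channel-wise as |S + n₁ + i n₂| with
n₁, n₂ ~ N(0, σ²) and σ = mean brain S₀ / SNR (default SNR 30 at b = 0).
The default encoding is one b = 0 volume plus 64 golden-spiral directions
at b = 1 ms/µm².

## Tractography

Deterministic fixed-step Euler integration of the principal eigenvector
field, seeded at the center of every voxel with FA ≥ 0.2 and propagated
in both directions with per-step sign alignment. Defaults: step 1 mm
(half a voxel), turn threshold 30° per step, length window 10–250 mm.
Direction lookup is nearest-voxel (the FACT convention, which is also
what common whole-brain trackers default to); trilinear interpolation of
the six tensor components — followed by eigendecomposition at the
interpolated point — is available via `TrackingParams(interpolation=
"trilinear")`. Nearest-voxel lookup is the default because it preserves
sharp interfaces: blending tensors across an abrupt 60° fiber kink
rotates the principal axis gradually enough that per-step turns can slip
under the 30° limit, letting streamlines cross a boundary that should
terminate them. Seed density, step size and length limits are exposed as
parameters; none of them is canonical.

## Tract segmentation and summaries

A tract is an inclusion mask (AND-ROI: the full atlas tract volume,
resampled to the subject grid by nearest neighbor) plus an exclusion
shell (NOT-ROI): the mask dilated by 5 iterations of 26-connected binary
dilation (a Chebyshev ball, so a single voxel dilates to an 11³ cube)
minus the mask itself. A streamline is retained when at least one vertex
(world → voxel by rounding at voxel centers, 0-based, half-open
ownership) lies in the AND-ROI and none in the shell; exclusion removes
the whole streamline rather than truncating it. Tract MD/FA are means
over the set of *unique voxels visited* by retained streamlines rather
than over vertices: voxel-set semantics make the summary invariant to
seed density and duplicate streamlines. Both choices (whole-streamline
exclusion, voxel-based averaging) are genuinely open in the literature;
the alternatives would change absolute values slightly but not the
lesion-load mechanism. Manual tract editing is replaced by a QC report
(streamline counts, ROI and visitation sizes); nothing is edited
automatically.

## Subject metrics

WMH and ventricle volumes (voxel count × voxel volume, ml) are expressed
as percentages of intracranial volume. Load classes use closed
thresholds: lower ≤ 0.5 % ICV, higher ≥ 1 % ICV, intermediate otherwise
(excluded from the subgroup contrast). The thresholds correspond
approximately to the familiar visual-rating extremes but are treated as
the authoritative quantitative definition; no visual scale is
implemented.

## Cohort simulation

Summary-level cohorts draw, per subject: age, sex, cardiovascular
disease, MMSE, ICV, ventricle load, and a right-skewed (gamma) WMH load —
controls 0.70 ± 0.91 % ICV, prodromal AD 1.17 ± 1.38 % ICV, with group
sizes 132/83. Per-tract MD/FA follow

  y = μ_t + γ s_t L + a_t AD + b_v (VV − 2.18) + ε,

with tract baselines equal to the lower-load subgroup summaries (e.g.
left SLF MD 0.73 ± 0.03 µm²/ms), susceptibility ordering s(SLF) = 1 >
s(DC) = 0.5 > s(CST) = 0.2 > s(VC) = 0, γ_MD = 0.04 µm²/ms per % ICV
(chosen so the lower/higher subgroup contrast reproduces the ≈ 0.06
µm²/ms SLF difference), γ_FA = −0.02, and small NAWM effects a_t
concentrated in the cingulum tracts. The susceptibility weights are
qualitative — anchored to the anatomical fact that the SLF and dorsal
cingulum traverse periventricular/deep white matter where lesions
concentrate while the ventral cingulum largely does not — because no
quantitative per-tract lesion overlap is available to calibrate them.

What the generator does *not* emulate: spatial correlation between
tracts, measurement error correlated across metrics, non-Gaussian
residuals, age trends in load, or any image-level provenance of the
summary metrics. Passing cohort-level tests therefore demonstrates the
statistical machinery and its calibration, not robustness to those
real-data features.

### The confound-recovery scenario

`confound_recovery_spec()` is a designed demonstration, not the default
calibration: the SLF-analog difference is purely WMH-mediated
(s = 1, a = 0) and the VC-analog purely NAWM-driven (s = 0, a = 0.05
µm²/ms), with a wider group separation in load (0.4 ± 0.4 vs 1.6 ± 0.8
% ICV) and γ_MD = 0.06. Under the default load distributions the
WMH-mediated marginal group effect is bounded by the group separation in
load itself (d ≈ 0.43), too small to detect reliably at n = 215, so a
scenario faithful to the adjustment logic needs the wider separation.
Effect magnitudes were fixed by an analytic power calculation targeting
≥ 0.99 detection per pattern component; the expected joint rate (~0.95)
is then dominated by the one true-null component — the adjusted SLF group
effect, non-significant by construction in 95 % of replicates. The
pattern is evaluated on MD; evaluating MD and FA jointly would stack two
independent true-null events and pin the expected rate at the boundary of
what a qualitative claim should tolerate.

## Statistics

* Mann-Whitney U: midrank U statistic; exact two-sided p by exhaustive
  enumeration of label assignments when both n ≤ 8 (valid under ties),
  otherwise the tie-corrected normal approximation with continuity
  correction. All-tied data return p = 1 with a warning.
* Student's t / Cohen's d: pooled-variance two-sided t; d = (m_high −
  m_low)/s_pooled. No correction for small-sample bias (Hedges g) — d is
  reported as defined.
* Matching: greedy 1:1 nearest-neighbor on standardized (age, MMSE,
  ventricle load) within exact sex and CVD strata, relaxing strata only
  if a load class is exhausted; balance is reported (Mann-Whitney for
  continuous covariates, two-proportion z for binary) rather than
  enforced.
* Standardized OLS: every variable — outcome, continuous, and 0/1
  predictors alike — is z-scored before an OLS fit with intercept; this
  matches what mainstream statistics packages report as standardized β,
  including for binary predictors. Collinear or constant predictors
  raise, naming the columns.
* Nested comparison: ΔR² = R²₂ − R²₁ (clamped at 0 against floating-point
  negatives for identical fits) tested with the F-change statistic. The
  F-change test was chosen as the significance test for ΔR² because it is
  the standard hierarchical-regression test; for a single added predictor
  it is equivalent to that predictor's t-test.
* Model 1 is metric ~ group + ventricle load; model 2 adds WMH load.
  MMSE and amyloid status are *excluded* by default even though they
  differ between groups: both are definitionally entangled with the
  diagnosis, so conditioning on them would absorb the group effect being
  estimated. They can be added via `extra_covariates` if a user wants
  the alternative specification.
* α = 0.05 two-sided throughout; no multiple-comparison correction by
  default (Holm available as an option on the subgroup table).

## Problem sizes and determinism

The shipped tests and the acceptance script use: a 40³ recovery phantom
(65 volumes), 10⁵ random SPD tensors, single-bundle tracking phantoms of
~640 seeds, 100-blob / 100-polyline morphology and segmentation oracles,
1000 null-calibration replicates and 200 confound-recovery replicates at
n = 215 each, and a two-bundle lesion phantom at 0.8 % lesion load. These
sizes put every Monte-Carlo estimate's standard error well below the
bands being checked. All randomness flows from explicit seeds
(`numpy.random.default_rng`; the acceptance script derives independent
child seeds via `SeedSequence`), so every run is reproducible.

## Known limitations

* No motion/eddy artifacts, no susceptibility distortion, no realistic
  brain geometry; registration is identity/affine by construction.
* Lesions are voxel sets with a single eigenvalue profile, not graded
  pathology, and lesion segmentation itself is out of scope (masks are
  inputs).
* Single-shell, single-tensor model only; crossing fibers are not
  represented, so tracking behavior in crossing regions is untested.
* The cohort generator's susceptibility weights and NAWM effects are
  plausible calibrations, not estimates from data.
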