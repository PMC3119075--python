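# Methods

`dtiplast` re-implements, as a tested pipeline, a longitudinal voxel-based
DTI analysis of learning-induced structural plasticity in the rat brain:
diffusion-weighted signal → tensor index maps → motion screening →
spatial normalization → voxelwise mixed-design ANOVA with FDR correction →
regional post-hoc quantification, together with the histology morphometry
stage (staining intensity and astrocyte geometry).  Because no in-vivo
data are redistributable, every stage is exercised on synthetic phantom
cohorts with known injected effects; this note records the models, the
parameters that matter, and what the synthetic studies do and do not show.

## Signal model and tensor fitting

Signals follow the single-tensor Stejskal–Tanner model
`S_i = S0 · exp(−b_i gᵢᵀ D gᵢ)` with a 15-direction b = 1000 s/mm² shell
plus one b0 (the directions are generated by electrostatic repulsion with
a fixed seed, since no published table is available).  Noise is Rician —
the magnitude of the complex signal plus i.i.d. Gaussian components —
with a Gaussian option for analytic tests whose null distributions must
be exact.

Fitting log-linearizes the model and solves per voxel by least squares;
the default is weighted least squares with weights equal to the squared
fitted signals from an ordinary first pass.  Nonpositive samples are
floored at half the voxel's smallest positive signal before the log
(voxel exclusion happens only when the whole series is nonpositive, and
is counted in the fit QC report).  Negative eigenvalues are clamped to
zero and counted rather than constrained away, keeping the fit linear.
From the sorted eigenvalues: FA (the standard normalized eigenvalue
dispersion), ADC ≡ mean diffusivity (λ₁+λ₂+λ₃)/3 — this package follows
the field's loose usage of "ADC" for the tensor trace/3 — axial
diffusivity λ₁ and radial diffusivity (λ₂+λ₃)/2.  FA of an exactly zero
tensor is defined as 0 so background voxels cannot poison statistics.

## The phantom

The phantom stands in for an atlas-registered brain: an in-plane
elliptical mask (radius 0.41 of the matrix, i.e. the brain fills ~80% of
the phase-encode FOV) over a 16×16×4 grid of 0.2×0.2×1.2 mm voxels, with
six box regions spanning the slab — DG, CG, PC, SC, CC, a no-effect
control region EC — embedded in background grey matter.  Baseline
eigenvalues are rat-brain-typical defaults (not literature-fit values):
cortical regions nearly isotropic with MD ≈ 0.7×10⁻³ mm²/s, corpus
callosum (1.4, 0.3, 0.3)×10⁻³ mm²/s (FA ≈ 0.75).  The CG region is
modelled as the cingulum fiber bundle adjacent to the cingulate cortex,
(1.3, 0.35, 0.3)×10⁻³ (FA ≈ 0.71): a *fractional* FA change on a
near-isotropic cortical tensor is smaller than the FA estimator's noise
floor at any realistic SNR, so the anisotropic bundle is the honest
carrier of the FA effect.  Regions that are analyzed on the same index
map are laid out with at least two voxels of separation so their
significance clusters remain distinct under 26-connectivity despite
smoothing spillover.

Effects are signed percent changes applied at the second scan to
matching (group, age) subjects.  ADC effects scale all three eigenvalues
together, which leaves FA exactly invariant; FA effects rescale the
eigenvalue spread about the mean, λ′ = m + s·(λ−m), where the scalar s
has a closed form for any target FA and the mean diffusivity is
preserved identically by construction.  Requests that would need
negative eigenvalues are rejected with the feasible range.  The default
effect pattern mirrors the study's findings: DG and PC ADC −2.5% and CG
FA −2.5% and CC FA +3% in the learning group; SC ADC −6% in the
swimming-only group; DG age-stable (attenuation 1.0 at 1/4/12 months),
CG/CC attenuation 1.3/1.0/0.5 across ages.

Cohorts give every subject two scans of three repeats; each subject
receives a small rigid head pose (≤2 in-plane voxels, ≤5°, mostly
in-plane; through-plane translation is kept under half a slice so the
brain stays in the 4-slice slab) plus a smaller per-scan jitter, so both
co-registration and normalization have real work.  Every random stream
derives from the design's master seed through named seed sequences, so a
cohort regenerates byte-identically.

Default noise is σ = S0/60 per complex channel (b0 SNR 60 per repeat,
~100 after averaging; the high-field, dedicated-surface-coil regime).
This level was chosen at design time so that the deliberately small
synthetic cohorts (8 subjects per group) have a per-voxel effect size of
≈2.4 for the weakest injected effects — comparable detection sensitivity
to what the original 46-animal design obtains at lower SNR — and it is
config-exposed, not hard-coded.  The FDR-calibration studies use the
more conservative σ = S0/40; error control does not depend on the noise
level.

## Motion screening and averaging

Respiratory motion during an EPI readout corrupts only the slices
excited at that moment, smearing brain signal along the phase-encode
axis; the simulator reproduces this as a half-FOV (N/2) ghost of the
in-mask signal on a single (slice, direction) image.  The screen
computes the mean-signal profile along the phase axis and the statistic
(mean profile at positions with no brain voxels − background floor) /
(mean in-mask signal), rejecting above τ = 0.05 (config).  The floor is
the median of out-of-mask voxels more than 10 voxels from the brain;
on small matrices without such voxels the 25th percentile of the whole
background is used, a low quantile being robust to the ghost itself
contaminating the near background.  Screening uses a mask derived from
the subject's own mean b0 (a displaced head must not be mistaken for a
ghost).  Surviving repeats are averaged per (slice, direction) cell, and
a cell losing all repeats is a hard error naming the cell.

## Spatial normalization

The chain mirrors the study protocol: (a) b0 bias correction — a
tri-quadratic polynomial fitted to in-mask intensities and divided out,
in-mask mean preserved — for the surface-coil gradient (<15%, simulated
as a smooth multiplicative field); (b) rigid (6-parameter) b0
co-registration to the b0 template; (c) 12-parameter affine
normalization estimated on FA, initialized from the rigid fit;
(d) transforms propagated unchanged to FA/ADC/AD/RD with
nearest-neighbour resampling (map values are never interpolated), then
0.3-mm Gaussian smoothing (NaN-aware, weight-renormalized, in mm so the
kernel respects the anisotropic voxels).  The phantom ground truth
serves as the template, standing in for the study's single
atlas-registered reference animal; genuinely nonlinear warping is out of
scope because synthetic subjects differ only rigidly/affinely.

Registration maximizes normalized cross-correlation (same-modality
matching; mutual information is unnecessary) by Powell search with a
0.2-mm FWHM pre-smoothing used for parameter estimation only, a coarse
translation multi-start, and cubic-spline resampling inside the metric
(trilinear interpolation biases the NCC optimum by a noticeable fraction
of a voxel).  Out-of-FOV voxels are zero-filled in the metric: the
background is air, and a NaN-masked metric would be blind to overlap
loss — a z-uniform slab could slide or stretch along z at constant NCC.
For the same reason parameters are bounded to plausible ranges
(translations ≤ FOV/4, rotations ≤ 20°, scales ±25%, shears ≤ 0.25) and
a small quadratic penalty (1e-4 at the bound scale) anchors directions
the image content does not constrain — the same role the regularized
affine priors play in standard normalization software.  Transforms are
stored as 4×4 world-coordinate (mm) matrices, fixed←moving, serialized
as plain text.

Normalization quality is summarized as voxelwise mean/SD/(SD/mean) maps
over the cohort and the ratio of 95th-percentile in-mask SD between two
pipelines (affine vs rigid-only), which reproduces on phantoms the
observation that full normalization flattens the SD landscape.

## Voxelwise statistics

The design is split-plot: one between-subject factor (group L/S/NL, or
age 1/4/12 months) and scan time (two levels, repeated).  Each effect is
tested against its own error stratum: the group effect against
subject-within-group variation of the subject means, the time and
interaction effects against the time×subject(group) residual.  With two
time points the within stratum reduces exactly to the per-subject
difference d = y₂−y₁: the interaction F equals the one-way ANOVA F of d
across groups, and the time effect tests the unweighted (Type III) grand
mean of d — so unbalanced groups (the study's 22/10/14) do not tilt the
inference toward the larger groups.  Both reductions are verified in the
tests against an independent projection-matrix GLM oracle and against
`pingouin.mixed_anova` on balanced designs, to 1e-8 relative in F.  The
reported sum-of-squares decomposition is the sequential one, which is
exactly additive (and coincides with the hypothesis SS when balanced).
Voxels with zero within-cell variance get p = 1 and a flag rather than
being dropped, keeping all maps aligned.  The voxelwise engine is the
same closed-form computation broadcast over all in-mask voxels.

Multiple comparisons use Benjamini–Hochberg FDR at q = 0.05 (via
statsmodels), applied separately per index map and per effect — the
per-map family definition; q-value maps are the monotone step-up
adjusted p-values.  Significant interaction voxels are grouped into
connected components (26-connectivity default, minimum 5 voxels, both
config), annotated with overlapping ROI labels, and each cluster gets a
regional post-hoc: per-(group, time) mean ± SE, percent change
100·(m₂−m₁)/m₁, a paired t-test per group, and the driving group — the
one with the largest standardized change |mean(d)|/SE(d).  The age
analysis reuses the same engine with age as the between factor and
additionally reports per-age regional changes with 95% CIs.  Volumetric
change of a labelled structure is voxel count × voxel volume compared
across time points with a paired t-test.

## Histology morphometry

Staining intensity is the mean of pixels strictly above one global
threshold shared by all images of a marker (raising the threshold can
never lower the mean — a property test).  Cells are the 8-connected
supra-threshold components with at least 5 px (both config); per object
the area is the pixel count × pixel area and the perimeter follows the
four-direction Crofton estimator (a pixel-boundary walk is available
behind a config switch; the convention is recorded in the output
metadata).  Pixel size is per-image metadata, never assumed, since
intensity and geometry are measured at different magnifications.  Group
comparisons use normalized histograms of perimeter/area plus a
two-sample t-test on the underlying per-object values.

The histology phantom renders non-overlapping discs or star-shaped cells
(k radial processes — the activated-astrocyte morphology: similar area,
much longer perimeter) with rejection-sampled placement, and reports
ground truth per object with the perimeter evaluated under the same
declared convention, making the threshold→label→measure round trip
exact up to the (9σ) intensity margins.

## Simulation studies and their scope

* **FDR calibration** (also what `scripts/acceptance.py` recomputes):
  200 null cohorts → the fraction with any corrected-significant
  interaction voxel sits at the Simes level q; 200 cohorts with ~5% of
  in-mask voxels truly affected (−5% ADC, learning group) → mean FDP
  ≤ q·m₀/m.  These cohorts are analyzed *without* smoothing so the
  voxelwise ground-truth set remains exactly the injected region
  (smoothing would smear true effects into neighbours that then count,
  spuriously, as false discoveries).
* **Localization**: 20 default-effect cohorts through the full chain
  (with smoothing); success means every injected region yields a
  surviving interaction cluster on the right index with the right
  driving group and the control region stays clean.
* **Age pattern**: learning-group cohorts at 1/4/12 months; the DG ADC
  change is age-stable (overlapping CIs) while the CC/CG FA changes
  shrink monotonically.
* **Motion screen**: 200 ghosted + 200 clean slice images at 10% ghost
  amplitude; sensitivity and specificity at default τ.
* **Registration recovery**: 50 random rigid perturbations (≤2 voxels,
  ≤5°) applied analytically to a smooth test pattern whose features are
  resolvable at the anisotropic voxel size; success is ≤0.1 voxel mean
  displacement error per axis.

Problem sizes (16×16×4 grids, 8 subjects per group, 200-cohort
calibration runs, 50 registration trials) are the package's scaled-down
study conditions; they keep each study to seconds–minutes while leaving
the statistical claims testable.

What passing these studies shows — and does not.  The phantoms have
piecewise-constant anatomy, box-shaped regions, stationary Rician noise,
no eddy-current or susceptibility effects, no physiological drift, and
subjects differing only rigidly (plus an optional synthetic bias field
and scheduled ghosts).  Passing therefore validates the *computational
chain* — forward model, estimators, error-rate control, localization
logic, geometry handling — under conditions where ground truth is
exact.  It does not certify performance on real tissue contrast,
real motion, or nonlinear anatomical variability, and the effect
magnitudes recovered here inherit the phantom's idealizations (e.g.
regional means are diluted a few tenths of a percent by smoothing at
region edges).

## Numerical choices and limitations

Tolerances: noise-free simulate→fit round trips are exact to ≲1e-8
relative (the fit inverts the forward model); FA injection achieves the
target ratio to well under 1e-6 and preserves MD to 1e-12 relative;
the ANOVA engine matches its oracle to 1e-8 relative in F.  Ties and
degenerate inputs: repeated eigenvalues are allowed (eigenvectors then
arbitrary within the eigenspace, irrelevant for the scalar indices);
zero-variance voxels get p = 1; empty regions, empty masks, rank-
deficient gradient schemes, single-subject groups, all-rejected repeat
cells and infeasible FA targets are hard, named errors.  Known
limitations: the single-tensor model only (no multi-shell or
non-Gaussian variants), no nonlinear registration, no permutation or
random-field inference, no covariate adjustment, and the tensor
orientation is resampled channelwise during the small rigid
perturbations (no eigenvector reorientation — immaterial for the scalar
maps analyzed here, at ≤5° unacceptable for tractography, which is out
of scope).
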