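# Methods

This note documents the models, parameter choices and numerical decisions
behind `vesicoloc`, and what the synthetic-data validations do and do not
demonstrate about real microscope data.

## Coordinate conventions

Axis order is `(z, y, x)` everywhere. Physical positions are nanometres
with the origin at the centre of voxel `(0, 0, 0)`; voxel index ↔ nm
conversion uses `(voxel_z_nm, voxel_xy_nm, voxel_xy_nm)`. All exported
positions and all distance thresholds (200 nm prefilter, 150 nm mask) are
in nm, so they are unit-safe under anisotropic voxels. The single
pixel-unit quantity is the duplicate-removal radius (2 px), which is
defined in pixels; its z component is scaled by the voxel anisotropy
(110/40 at the defaults).

## Synthetic stack generator

The generator emulates reconstructed 3D-SIM stacks of immunolabelled
dense-core vesicles:

- **Spots.** Each vesicle is far below the diffraction limit, so its image
  is the PSF: an anisotropic 3D Gaussian with `psf_sigma_xy_nm = 80`,
  `psf_sigma_z_nm = 150` (≈190/350 nm FWHM — SIM-class lateral resolution
  with the usual axial penalty). Peak amplitude 1 per labelled channel by
  default; channels not in the vesicle's label set receive exactly zero
  signal.
- **Geometry.** Defaults `voxel_xy_nm = 40` (ELYRA-class SIM
  reconstruction pixel), `voxel_z_nm = 110` (the acquisition z-spacing).
  Vesicle positions are uniform with a 3σ border margin and a
  rejection-sampled minimum pairwise separation (default in experiments:
  400 nm). Category counts (7 single/double/triple classes) are one
  multinomial draw — the first variate from `default_rng(seed)`, so tests
  can reproduce it independently.
- **Chromatic aberration.** A global per-channel translation (the model
  the correction step assumes); field-dependent distortion is out of
  scope.
- **Noise.** Optional Poisson stage (photon scaling) followed by additive
  Gaussian noise whose SD is a fraction of the maximum amplitude; default
  0.1 (peak SNR ≈ 10). Negative values are clipped to zero, as in
  reconstructed microscope exports.

What this does **not** emulate: SIM reconstruction artefacts (honeycomb
patterns, out-of-focus haze), structured cytoplasmic background,
heterogeneous vesicle brightness, bleed-through, or tissue morphology.
Passing the synthetic validations therefore demonstrates correctness of
the algorithmic chain under the stated forward model, not robustness to
every pathology of real stacks.

## Detection

Bright spots: three-class Otsu on the channel histogram; voxels in the top
class form the bright mask ("histogram splitting" made deterministic and
parameter-free; the strategy is a config tag so alternatives can be
swapped). Components use 26-connectivity. Components smaller than 5 voxels
are discarded: at these voxel sizes the PSF core spans well over five
voxels, so a 1–3-voxel supra-threshold cluster is a noise spike, not a
vesicle — without this floor, sparse fields produce hundreds of spurious
single-voxel candidates per channel whose downstream fits are wasted work
and whose positions pollute the registration means.

Dim spots: binary Otsu, then components kept iff `12 < np < 250` voxels,
both bounds strict. `np` counts voxels, not xy-pixels.

Merging: candidates from all channels and both modes are pooled and merged
greedily in descending peak intensity; a candidate within 2 px (z scaled
by anisotropy, "within" read as ≤) of an already-kept one is absorbed, so
the brighter duplicate survives and the output is duplicate-free under the
same rule.

## Localization

Each merged candidate is refined per channel over a 9×9×5 (x, y, z) voxel
window by least-squares (`scipy.optimize.least_squares`, trf, analytic
Jacobian): axis-aligned anisotropic Gaussian (σ_xy shared by x and y, σ_z
free) plus a constant offset. Seeds whose windows overlap are fitted as a
sum of Gaussians; to keep the joint problem bounded in dense fields, each
seed is fitted with its (up to 4 nearest) directly overlapping neighbours
as extra components and only the focal seed's parameters are kept.

Three guards define a *converged* localization:

- **Iteration/tolerance**: relative cost change < 1e-8 (ftol), up to 200
  evaluations; σ bounded to [0.5, 10] px.
- **Travel bound**: the fitted centre stays within ~2 px of its seed. The
  fit refines a detected centroid; with unbounded travel, a fit in a
  channel with no local signal latches onto a *neighbouring* vesicle at
  the window edge, which systematically drags single- and double-labelled
  vesicles out of the separation prefilter.
- **Amplitude vs noise floor**: the fitted amplitude must exceed 3× the
  residual SD. A "fit" to a signal-free window is a noise bump; its
  sub-pixel position is meaningless.

A seed failing any guard falls back to the intensity-weighted centroid of
its window (`converged = False`). Centroid positions still participate in
the prefilter — they are the best available location estimate for a
channel with no fit-worthy signal — but not in registration.

After refinement the 2-px coordinate-duplicate rule is applied once more,
on the fitted positions (brighter fit wins). Chromatic shift can push a
vesicle's per-channel detections just past the detection-stage dedupe
radius; after fitting they collapse onto one centre and are duplicates
under the same rule. Without this, multiply-detected (i.e. brighter,
multi-channel) vesicles are over-counted relative to singles.

## Registration

Channels 2 and 3 are translated so the three per-channel mean positions
coincide (to < 1e-9 nm). Means are computed over the spots converged in
**all three** channels: on a common vesicle set the spatial scatter of the
vesicles themselves is shared across channels and cancels in the
difference of means, leaving the chromatic offset; per-channel sets would
re-introduce that scatter (hundreds of nm at a few hundred spots).
Registration is a pure translation: intra-channel distances are untouched
and the operation is idempotent.

## Prefilter, intensity, classification

- Prefilter: pass iff all three pairwise inter-channel distances are
  strictly < 200 nm (nm coordinates absorb anisotropy). Failing vesicles
  are `excluded` and receive no intensity measurement.
- Normalization and background are computed once per channel per image:
  divide by the channel maximum, background = mean of the normalized full
  3D volume.
- Vesicle intensity: mean normalized intensity over voxels whose centres
  lie within 150 nm of the channel's vesicle centre (true physical sphere;
  voxel-centre membership keeps a brute-force oracle exact), minus
  background. May be negative.
- Calls: positive > 0.05, negative < 0.02, both strict; anything in the
  dead band [0.02, 0.05] (including exact threshold equality) is
  indeterminate, and any indeterminate channel makes the vesicle
  indeterminate. A vesicle with all three channels empty also ends up
  indeterminate (no content category applies). Indeterminate vesicles are
  excluded from percentage denominators; counts are always reported.
- Per-cell summaries: percentages over determinate prefilter-passing
  vesicles; with none, percentages are NaN (None in JSON). A per-true-
  category prefilter pass-rate diagnostic is available for bias checks; no
  significance test is attached.

## Sizing

Line profiles are sampled along x in the voxel row nearest the (y, z)
centre — no interpolation, matching "profiles in the microscope's x-axis"
— with half-length 7 px (15 samples). Fit: amplitude·Gaussian + offset;
R² on the profile; accepted iff R² > 0.75. Both σ and FWHM are reported:
size is defined as σ, but apparent sizes are conventionally compared with
FWHM-like resolution limits. The median's 95% CI uses a seeded percentile
bootstrap (10,000 resamples) since no analytic form is assumed.

Known limitation: near the noise floor two compressive effects bias σ
slightly low — zero-clipping of negative noise lifts the baseline more
than the peak, and off-row vesicles attenuate the nearest-row profile. At
peak SNR 10 the combined bias is ≈3–4% for σ ∈ {80, 100} nm and ≈6% at
σ = 60 nm (1.5 px), where sparse peak sampling amplifies it. The 1D
estimator itself is unbiased on unclipped profiles.

## Assay statistics

- **Fold change**: peak areas are divided by well protein content, then by
  the mean protein-normalized control well of the same culture (and
  hormone). Scale-invariant per culture by construction.
- **Dunn test**: all conditions pooled and ranked once (tie-corrected
  variance); two-sided z for each condition vs control; Holm adjustment by
  default (flag for Bonferroni/none). The paper-style "condition vs
  control" contrasts only — not all pairwise comparisons.
- **Correlations**: Pearson R on untransformed fold values matched by
  culture × condition × replicate (log option available).
- **Relative expression**: ΔCT = housekeeper CT − gene CT; expression
  2^ΔCT; undetermined CTs set to the 40-cycle ceiling before ΔCT. The
  ratio paired t-test is a paired t-test on log expression (the standard
  construction).
- **Calcium**: fold = max fluorescence during application over the mean of
  the pre-application and post-washout 30 s window maxima; cohort tested
  against 1 with a two-sided Wilcoxon signed-rank test. Cells failing both
  positive controls (fold ≤ 1.1, configurable) can be excluded via
  `responder_mask`.
- The synthetic secretion generator drives all three hormones with one
  latent per-well stimulus strength: 75% of the log-variance of the
  well noise is shared across hormones (a strongly responding well
  responds strongly for every peptide), 25% is independent per-hormone
  measurement noise; total CV equals `noise_cv`. Protein content varies
  per well (lognormal), exercising the normalization path.

## Validation experiment sizes

The test suite and acceptance script use desk-scale simulations chosen to
give stable statistics: the secondary-antibody control uses 5 cells × 300
vesicles (24×256×256 voxels, peak SNR 8, shifts ≤ 1 px); triple-fraction
recovery uses 200 vesicles × 5 seeds per mixture (p = 0.5 and 0.9), the
pooled estimate falling inside the exact binomial 95% interval of a
200-vesicle draw at p; the Dunn
null calibration uses 1000 replicates at n = 8 per group. Oracle checks
(flood-fill component labelling, brute-force sphere loops, closed-form
Gaussians, textbook correlation formulas) are exact.
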