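# Methods

## Segmentation model

EAT is defined purely by thresholds: a voxel belongs to the segmentation iff
it lies inside the pericardial mask **and** its attenuation `v` satisfies
`lower ≤ v ≤ upper` with both bounds inclusive. The inclusive convention is
a deliberate choice — it makes the integer bin count `upper − lower + 1`
(161 for [−190, −30] HU) internally consistent with the histogram grid — and
is applied uniformly; vendor workstations do not document their boundary
handling, so results at exactly −190/−30 HU may differ from a specific
workstation by single voxels. No connectivity or morphology filtering is
applied: the mask is trusted to delimit the pericardium, and everything
in-window inside it counts as fat.

Voxel volume is `dx·dy·dz` from the stored grid spacing. For
reconstructions with overlapping slices (e.g. 3.0 mm thickness at 1.5 mm
increment) this means the *increment* defines the voxel volume, which avoids
double-counting overlapped slabs; the nominal slice thickness never enters.

Metrics of a segmentation with voxel set S:

- volume `|S| · voxel_volume / 1000` mL (exact arithmetic; empty S → 0);
- mean attenuation = arithmetic mean of HU over S;
- noise = SD of HU over S, **sample convention** (n−1 denominator, the
  default of common statistics packages; switchable via `ddof`);
- histogram: bin `b` is centered on integer HU value `b` and covers
  `[b − 0.5, b + 0.5)`; counts always sum to `|S|`, and the normalized form
  divides by `|S|`. Values are binned as floats (no pre-rounding), which
  matters only for data that are not already integer HU.

An empty segmentation yields missing (NaN) mean/noise with a warning rather
than an error, and the patient drops out of affected paired analyses
pairwise — mirroring how a failed measurement is handled in practice.

## Histogram comparison

Two normalized histograms on a common bin grid are compared with the
Euclidean distance `‖q − p‖₂`. Only equal windows are comparable; the
widened CTA_0 measurement has a different bin grid and is excluded from all
distance computations by construction. Distances are computed per patient
and then summarised as mean ± SD across patients; the cohort-averaged
histogram (`average_histograms`) is produced for plotting, not for the
quantitative comparison. For normalized inputs the distance lies in
[0, √2], the upper bound attained by disjoint supports.

## Agreement statistics

For each metric and series pair, patient-aligned values (reference `x`,
comparator `y`) feed:

- differences: `mean(y − x)` and `median(y − x)` are both reported (tables
  in the literature are not always explicit about which they print), and
  percent differences under **two conventions** — per-patient
  `mean((y−x)/x)·100` (primary) and ratio-of-means `mean(y−x)/mean(x)·100` —
  because printed percentages are ambiguous between them; emitting both
  makes any discrepancy auditable. Note the per-patient convention flips
  sign for negative-valued metrics such as mean HU.
- regression: OLS with the **reference as response** (`x ≈ a·y + b`), so
  R² = 1 − SS_res/SS_tot reads as the accuracy with which a linear
  rescaling of the comparator predicts the reference. A constant reference
  is flagged degenerate (R² missing); a constant comparator is an error.
- testing: Shapiro-Wilk on the differences at α = 0.05 gates between the
  paired *t*-test (normal) and the Wilcoxon signed-rank test, both
  two-sided. Constant differences route to the distribution-free branch;
  all-zero differences report p = 1 with a degenerate flag. Bonferroni
  adjustment is `min(1, m·p)` with the family `m` = the number of
  comparisons within one metric's table (volume: all variant pairs;
  attenuation/noise: equal-window pairs) — the family definition is
  configurable because it is a reporting policy, not a mathematical fact.
- mean-difference (Bland-Altman) data: per-patient `( (x+y)/2, y−x )` with
  bias = mean difference and limits of agreement at bias ± 1.96·SD of the
  differences (the standard convention).

## Phantom simulator

Geometry is a nest of concentric spheres in physical mm coordinates — blood
pool, myocardial shell, epicardial fat shell, pericardial sac — voxelized on
a regular grid (spheres become ellipsoids in index space under anisotropic
spacing). The analysis depends only on the HU distribution inside the mask,
so anatomical realism buys nothing; what the concentric geometry buys is an
*exactly countable* ground truth: the fat shell predicate is evaluated per
voxel center, and `true_fat_volume_ml = count × voxel_volume / 1000`
exactly. Defaults: 84³ grid at 1.5 mm isotropic spacing, radii
30/40/48/52 mm — a ≈195 mL fat shell. Cohorts draw per-patient target
volumes uniformly from a configured range (default 100–300 mL, matching the
order of magnitude of adult EAT volumes) and scale all radii by the cube
root of the volume ratio.

Fat voxels draw i.i.d. from `Normal(fat_mu + shift_delta,
√(fat_sigma² + extra_noise_sigma²))` per series, with identical fat
*locations* across the series of a patient (the series are co-registered by
construction). Non-fat tissues are constant plates far outside the fat
window — blood 45 HU (350 HU on CTA, emulating iodine), myocardium 40 HU,
background −500 HU — chosen so they exercise the mask/window logic without
entering any segmentation. Noise is i.i.d. Gaussian per voxel; no CT
texture, beam hardening or reconstruction-kernel model is attempted, because
every downstream metric is a first-order histogram statistic that is blind
to spatial correlation. Optional Gaussian smoothing (FWHM in mm) emulates
partial-volume blur and is **off by default** so that exact-recovery
properties hold.

### Calibration of the default series models

Published per-series EAT attenuation statistics are measured *inside the
segmentation window*, i.e. they are moments of a truncated distribution.
Using them directly as generative parameters would systematically miss the
targets (a Gaussian with mean −81 and SD 32.5 truncated to [−190, −30] has
mean ≈ −85, not −81). The default models are therefore calibrated by
numerically inverting the truncated-normal mean/SD
(`calibrate_fat_model`): for each series, (μ, σ) of the untruncated normal
is solved so that the truncated moments equal the target in-window values

| series   | target mean (HU) | target SD (HU) | generative μ | generative σ |
|----------|-----------------:|---------------:|-------------:|-------------:|
| TNC      | −81.1 | 32.5 | −65.94 | 43.48 |
| VNC_Conv | −75.4 | 31.0 | −53.19 | 44.81 |
| VNC_PC   | −79.1 | 30.3 | −67.74 | 38.67 |
| CTA      | −83.1 | 32.3 | −71.74 | 41.20 |

The constants are frozen in `DEFAULT_SERIES_MODELS` (expressed as the TNC
base μ plus per-series shift) and a test re-derives them against the
truncated-normal closed form. A consequence worth knowing: only ~70–84% of
the generative fat distribution lies inside the window, so measured phantom
volumes sit 16–30% below ground truth, series-dependently — VNC_Conv loses
the most, which is why it shows the largest volume deficit and histogram
distance in phantom studies. The underlying full fat HU distribution of
real tissue is not observable from in-window statistics alone, so this
calibration reproduces the *measured* surface, not the (unknown) true
generative one; generative volume differences caused by the VNC
reconstruction algorithms themselves are out of scope and not emulated.

### Randomness

One master seed drives everything. Per-patient and per-series substreams
derive via `numpy.random.SeedSequence(master, spawn_key=...)`, so geometry
and truth counts are seed-invariant, regenerating a cohort with the same
seed is bit-identical, and changing the seed changes only the noise.

## What passing tests do and do not show

The phantom shares one fat geometry across series and draws independent
i.i.d. values per voxel. Passing recovery and agreement tests therefore
demonstrates the correctness of the *measurement and statistics machinery*
— windowing, binning, distances, paired inference — under known truth. They
do not validate VNC reconstruction quality on real scanners, partial-volume
behaviour at the pericardium, registration error between series (assumed
perfectly co-registered), or the transferability of the calibrated
attenuation models to other scanners and kernels.

## Problem sizes and numerics

The test suite runs phantoms at 32³–72³ voxels and cohorts of 3–8 patients;
statistical-recovery checks use 100 seeded 42-patient cohorts (matching a
realistic single-center cohort size) and 1000 null replicates for type-I
control. The acceptance script runs the full default geometry (84³, 42
patients). Grid-spacing equality uses a 1e-3 mm per-axis tolerance (header
float noise); histogram normalization is checked to 1e-9; brute-force
equivalence of floating-point metrics to 1e-10. Degenerate inputs (empty
masks or segmentations, constant samples, zero-variance differences) are
handled by explicit flags and warnings rather than exceptions wherever a
real cohort could plausibly produce them.
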