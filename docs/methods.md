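# Methods

`marginspec` models the site-level optical interrogation of breast surgical
margins with a multi-channel fiber-optic diffuse reflectance probe in the
visible range (450–600 nm), and the statistical analysis of the extracted
optical parameters across tissue types, disease depth and menopausal status.
This note documents the model, its assumptions, the tunable parameters, the
synthetic-data generator, and the numerical choices.

## Optical model

**Absorption.** The tissue absorption coefficient is a Beer–Lambert
superposition of oxyhemoglobin, deoxyhemoglobin, β-carotene and Lymphazurin
(isosulfan blue, an extrinsic surgical dye), plus an arbitrary Gaussian
absorber centered at 515 nm with σ = 10 nm that soaks up the known shape
difference between tabulated and in-tissue β-carotene absorption:

    μa(λ) = Σᵢ εᵢ(λ)·Cᵢ + A_g·exp(−(λ−515)²/(2·10²))   [cm⁻¹]

Concentrations are in μM and the packaged extinction curves fold in the
decadic factor (μa = ε·C directly). The packaged curves are *synthetic*
parametric approximations with the standard landmark features (oxyhemoglobin
Q-bands at 542/577 nm, deoxyhemoglobin band at 556 nm, Soret tails, the broad
carotenoid band, the rising flank of the dye's ~640 nm band); see
`src/marginspec/data/README.md`. All validation in this package is
self-consistent — forward simulation and inversion share the basis — so none
of the recovery results depend on curve fidelity to a particular published
compilation. Real-instrument users should load their own calibrated tables.

**Scattering.** Reduced scattering follows the Mie-type power law
μs′(λ) = a·(λ/λ₀)^(−b) with λ₀ = 500 nm. The scalar summary ⟨μs′⟩ is the
unweighted mean of μs′(λ) over the analysis grid (the study reports a
wavelength-averaged value without defining the weighting; unweighted is
assumed). Saturation SO2 = C_HbO2/THb is reported as a flagged missing value
when THb = 0, never as NaN.

## Forward model: scaled Monte Carlo

The probe-measured reflectance for arbitrary (μa, μs′) comes from baseline
weighted-photon Monte Carlo simulations run once at μa = 0 over a μs′ grid of
{2, 4.5, 7.5, 11, 16.5, 25} cm⁻¹. Each baseline stores per-collected-photon
exit weights and path lengths; reflectance at arbitrary absorption is the
Beer–Lambert re-weighting R(μa) = Σᵢ wᵢ·exp(−μa·Lᵢ), with linear
interpolation in μs′ between baselines. For speed inside the inversion loop,
path lengths are pooled into 160 geometric bins re-centered at their
weighted-mean path; the binned and per-photon evaluations agree far below the
Monte Carlo noise floor, and R(0) is preserved exactly.

Geometry and transport parameters (one channel of the 4×2 probe array; the
10 mm channel pitch prevents cross-talk, so one channel is simulated and
reused):

| parameter | value | rationale |
|---|---|---|
| illumination core | 19 × 200 μm fibers, hex-packed, radius 0.5 mm | probe as built |
| collection | 4 × 200 μm fibers at the core corners (0.6 mm radius) | probe as built |
| NA | 0.22 (acceptance sin θ ≤ NA/n_tissue in tissue) | probe as built |
| anisotropy g | 0.9 | typical soft tissue |
| n_tissue / n_window | 1.37 / 1.49 | soft tissue against an acrylic imaging box |
| photons per baseline | 4×10⁵ | noise cancels between forward and inverse (shared lookup); see below |
| path cutoff / depth kill | 3 cm / 0.8 cm | captures essentially all collected weight at sub-mm separations |
| Russian roulette | below weight 10⁻⁴, survival 0.1 | standard |

Variance reduction: the four discrete collection fibers are represented as an
annulus at the corner radius with an area-fraction weight (azimuthal
symmetry of the launch distribution makes this exact in expectation).
Photons exiting within the annulus and the NA cone are recorded with weight
w·(1−R_Fresnel); the remainder re-enters with weight w·R_Fresnel.

Because the forward simulator and the inverse model evaluate the *same*
lookup surface, Monte Carlo noise in the baselines cancels out of every
recovery experiment; the photon budget only needs to keep the surface smooth
and monotone, which 4×10⁵ photons per baseline achieves with margin. Two
closed-form diffusion oracles (total semi-infinite reflectance, and the
extrapolated-boundary dipole at the collection radius) provide independent
physics checks; the dipole matches the Monte Carlo μa-dependence within 15%
in the high-albedo regime. Larger deviations at lower albedo are expected —
diffusion theory degrades at sub-transport-length source–detector
separations.

## Inverse extraction

`SpectralInversion.fit` minimizes the sum of squared relative residuals
(model/data − 1) over the seven free parameters {C_HbO2, C_dHb, C_bcar,
C_lymph, A_g, a, b} with trust-region reflective least squares, bounds
C ∈ [0, 200] μM, A_g ∈ [0, 5] cm⁻¹, b ∈ [0, 2], and a bounded so the power
law stays inside the lookup's μs′ hull for every admissible b (a ∈ [2.9, 20]
cm⁻¹ for the default hull — physiologic breast values sit well inside).
A heuristic center start plus Latin-hypercube restarts (deterministic under
the seed; 4 restarts by default, early exit once an exact fit is found) guard
against local minima. Approximate standard errors come from the Gauss–Newton
covariance at the optimum. Zero-noise forward–inverse round trips recover
all free parameters to ~10⁻⁶ relative for every tissue preset; the
acceptance criterion is 0.5%.

The Lymphazurin concentration is always a free parameter; sites failing the
dye-dominance QC rule are excluded upstream rather than refit.

## QC and cohort bookkeeping

* **Dye dominance:** a site is excluded when R(600 nm) < R(450 nm), strictly
  (heavy dye inverts the usual hemoglobin-dominated slope; ties retain).
* **Extreme outliers:** values beyond 3·IQR outside the quartiles
  (type-7/linear-interpolation quartiles; strict inequalities, so constant
  vectors have no outliers). Which extracted parameter(s) the rule applies to
  is configurable; the default applies it per parameter and excludes a site
  flagged on any.
* **Retention stages:** stage 1 removes undiagnosed and QC-flagged sites;
  stage 2 keeps predominant tissue types (FG/FA/A among normals, IDC/DCIS
  among malignants) and drops the heterogeneous margin; stage 3 keeps stage-1
  *normal* sites from patients with known pre/post menopausal status.
  `make_reference_cohort()` transcribes the study's site flow
  (854 → 595 + 38 → 408 + 32 → 553) with synthesized ids; retention on it
  reproduces every printed stage count except the stage-3 patient count,
  which is printed as 93 but is arithmetically forced to 94 by the other
  printed counts (margins and site totals are reproduced exactly).
* **Probe coverage:** the 4×2 channel array at 10 mm pitch samples 8 holes of
  the 5 mm hole grid per placement; 2×2 interleaved sub-shifts cover a
  40×20 mm block exactly once, so the average 64-hole margin takes 8
  placements.

## Statistics

Group summaries are median, unscaled MAD (no 1.4826 consistency factor —
the study pairs MAD with medians descriptively), type-7 quartiles and Tukey
whiskers at 1.5·IQR. Pairwise contrasts are two-sided Wilcoxon rank-sum
tests: exact enumeration for tie-free samples with combined n ≤ 12,
otherwise the normal approximation with midranks, tie variance correction
and continuity correction (scipy's Mann–Whitney implementation; an
independent exhaustive-permutation oracle verifies it in the tests).
Bonferroni factors are fixed by the comparison scheme: m = 1 (malignant vs
normal; pre vs post), 3 (normal types), 6 (disease × normal-type variants),
9 (depth × normal type). Strata below a minimum size are skipped with a
logged warning rather than tested. Null calibration over 500 same-
distribution cohorts keeps the adjusted type-I error at or below 5%.

## Synthetic cohorts

Per-site parameters are drawn from log-normals matched to each preset's
(median, MAD) by solving Φ(ln(1+r)/σ) − Φ(ln(1−r)/σ) = ½ for σ, r = MAD/median.
Ratios r ≥ 1 are unachievable for a log-normal and raise an error — this
occurs for exactly one printed group (the pre-menopausal normal
[β-carotene], whose printed MAD exceeds its median and is internally
inconsistent with the same section's adipose values). Presets carry the
printed group medians/MADs for ⟨μs′⟩, [THb] and [β-carotene]; quantities the
study does not print carry documented defaults: SO2 0.6 (normal) / 0.5
(malignant) with 0.05 SD, scattering power b ~ U(0.6, 1.4) (typical breast
range), Gaussian-absorber magnitude A_g = 0.012·[β-carotene] with 20%
log-normal jitter (the two are known to be strongly correlated in this
basis), and pooled-group β-carotene medians near the adipose value.
Menopausal composition of normal sites follows the printed histograms
(pre: 66/14/20 A/FA/FG, post: 84/15/1); malignant depth mix is 10/17/11.
Contaminated sites receive a dye load drawn 1.4–2.5× above the per-site
critical load that inverts the 450/600 nm ordering, so the contamination
rate maps directly onto the QC flag rate.

Cohort generation uses iid draws. The *group-median recovery* validations
(`validation.group_median_recovery`) instead draw group parameters with
Latin-hypercube stratification — marginally still exact samples of the same
log-normals, declared via `sample_parameters(..., stratified=True)`. At the
study's smallest group size (n = 10) the iid sample median has a standard
error of ~8% of the target, which would make the recovered median a readout
of seed luck rather than of extraction fidelity; stratification collapses
that sampling noise while leaving the population being sampled unchanged.
Null-calibration and power simulations keep iid draws (rank-based tests
assume exchangeable iid samples).

What the generator does *not* emulate: within-site tissue heterogeneity
(each synthetic site is a homogeneous semi-infinite medium), intervening
normal tissue above close malignant foci (depth presets shift the group
medians instead), spatial correlation across a margin, patient-level
clustering of optical properties, and instrument artifacts beyond
multiplicative Gaussian noise with a small additive floor. Passing recovery
tests therefore demonstrates the *inverse model and statistics* are correct
and well calibrated under the stated generating assumptions — not that the
pipeline is robust to layered tissue or model mismatch.

## Sensing depth

The depth-resolved weighted visiting frequency of collected photons
(exit weight × Beer–Lambert attenuation × path length per 0.1 mm depth bin)
is accumulated in a depth-tracked transport run at the requested (μa, μs′);
the scalar sensing depth is the 0.90 quantile of the cumulative profile
(the quantile is configurable — the summary statistic used by the original
simulations is not printed — and only collected photons contribute, also a
documented choice). Across the positive/adipose/fibro-glandular presets at
450 and 600 nm the depths fall in the 0.5–2.2 mm range reported for this
probe, with adipose tissue sensed deepest at the red end.

## Problem sizes

The shipped defaults reflect what the validation experiments need: 4×10⁵
photons per baseline (six baselines, ~1 minute total), 20 replicates per
phantom cell, 10 repeatability replicates, group sizes 38/595/10 matching the
study's retained groups, 500 null cohorts for calibration, 2.5×10⁵ photons
per sensing-depth run. Every reported number is recomputed at run time by
`scripts/acceptance.py` (see the README).

## Known limitations

* Homogeneous semi-infinite medium only; no layered or laterally
  heterogeneous tissue, polarization, or fluorescence.
* The packaged extinction curves are synthetic approximations (above).
* The diffusion oracles are approximate at the probe's sub-transport-length
  separations; they check shape and monotonicity, not absolute level.
* The reference cohort is a bookkeeping fixture (synthesized ids), not
  patient data; one printed patient count cannot be reproduced exactly (see
  QC section).
* Printed clinical medians/P-values on the real 633 sites are not
  recomputable without the original spectra; the package validates by
  parameter recovery on cohorts generated *from* the printed summaries.
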