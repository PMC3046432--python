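# marginspec

Visible-range (450–600 nm) diffuse reflectance spectroscopy of breast
surgical margins: a scaled Monte Carlo forward model of a multi-channel
fiber-optic probe, inverse extraction of tissue chromophores and scattering,
the clinical QC/exclusion bookkeeping of a margin study, and stratified
nonparametric statistics — validated end to end by parameter recovery on
synthetic cohorts.

## Who this is for

Researchers in tissue optics and optical margin assessment who need a tested,
self-contained reference pipeline: from probe photon transport through
spectral inversion to the group-level statistics used to ask which optical
parameters (scattering, hemoglobin, carotenoids) can distinguish malignant
from normal breast tissue across tissue types, disease depth and menopausal
status. In breast-conserving surgery, residual cancer within 2 mm of the
excised specimen's surface prompts re-excision; a fiber-optic probe pressed
against the margin can interrogate exactly that rind of tissue, if the
optical signatures of malignancy survive the marked heterogeneity of normal
breast tissue.

## The model

Per site, the measured diffuse reflectance spectrum R(λ) is modeled by photon
transport in a homogeneous semi-infinite medium with

* absorption μa(λ) = Σᵢ εᵢ(λ)·Cᵢ + A_g·exp(−(λ−515)²/(2·10²)) over the
  absorbers {HbO₂, dHb, β-carotene, Lymphazurin} plus an arbitrary Gaussian
  absorber (center 515 nm, σ 10 nm),
* reduced scattering μs′(λ) = a·(λ/500)^(−b).

The forward map (μa, μs′) → R is a scaled Monte Carlo lookup: baseline
weighted-photon simulations of the probe (19-fiber illumination core, 4
collection fibers, NA 0.22) run once at μa = 0 over a μs′ grid, re-weighted
per photon by exp(−μa·L). `SpectralInversion.fit()` inverts a spectrum by
bounded nonlinear least squares on relative residuals over
{C_HbO2, C_dHb, C_bcar, C_lymph, A_g, a, b}, returning an
`InversionResults` with estimates, standard errors, the derived summaries
THb = C_HbO2 + C_dHb, SO2 = C_HbO2/THb, ⟨μs′⟩ (grid-averaged), and
`summary()`. Group contrasts use Wilcoxon rank-sum tests with scheme-fixed
Bonferroni factors (m = 1, 3, 6 or 9). `docs/methods.md` has the full
account.

## Worked example

Forward-simulate a fibro-glandular-like site, add 2% measurement noise,
invert:

```python
import numpy as np
from marginspec import (
    ChromophoreSet, ExtinctionBasis, ProbeGeometry, ScatteringModel,
    SpectralInversion, TransportConfig, default_grid, simulate_spectrum,
)
from marginspec.transport import build_lookup

grid = default_grid()                      # 450-600 nm, 1 nm steps
basis = ExtinctionBasis.default(grid)      # packaged extinction tables
lookup = build_lookup(ProbeGeometry(), TransportConfig(seed=0))  # ~1 min

truth_c = ChromophoreSet(c_hbo2=20.5, c_dhb=13.6, c_bcar=15.3, a_gauss=0.18)
truth_s = ScatteringModel(a=11.5, b=1.2)   # <musp'> ~ 11.0 cm^-1
spec = simulate_spectrum(truth_c, truth_s, basis, grid, lookup)
rng = np.random.default_rng(42)
noisy = np.clip(spec * (1 + 0.02 * rng.standard_normal(spec.size)), 1e-12, None)

res = SpectralInversion(noisy, grid, basis, lookup).fit(restarts=3, seed=0)
print(res.summary())
```

```
Spectral inversion results
==============================================
parameter     estimate     std err
----------------------------------------------
c_hbo2           20.75       0.585  uM
c_dhb            13.88       0.635  uM
c_bcar           15.01       0.666  uM
c_lymph         0.2265       0.351  uM
a_gauss         0.1848      0.0677  cm^-1
a                 11.5        0.26  cm^-1
b                1.131      0.0836  
----------------------------------------------
THb     = 34.63 uM
SO2     = 0.599
<musp>  = 10.97 cm^-1
residual norm = 0.206, converged = True, restarts used = 3
```

The true values were THb = 34.1 μM, SO2 = 0.60, ⟨μs′⟩ = 11.0 cm⁻¹,
[β-carotene] = 15.3 μM: at 2% spectral noise every quantity is recovered
within ~2%. The dye term (true 0) stays at the noise floor.

Higher-level entry points:

* `marginspec.synthetic.generate_cohort` — synthetic cohorts with the study's
  tissue-type presets, menopausal composition, dye contamination and noise,
  ground truth attached to every site;
* `marginspec.cohort.apply_retention` / `make_reference_cohort` — the
  three-stage QC/exclusion bookkeeping (854 → 595 + 38 → 408 + 32 → 553
  sites on the packaged transcription fixture);
* `marginspec.stats.run_scheme` — the stratified rank-sum comparison tables;
* `marginspec.depth.sensing_depth` — probe sensing depth from the weighted
  photon visiting frequency;
* the `marginspec` CLI (`simulate`, `simulate-cohort`, `qc`, `extract`,
  `sensing-depth`, `analyze`, `run`) for shell pipelines.

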