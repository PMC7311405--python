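# adcaqp

Quantitative pipeline linking **ultra-high b-value diffusion-weighted MRI
(DWI) of rectal tumors** to **aquaporin (AQP) immunohistochemistry (IHC)**.
It is aimed at imaging and pathology researchers who want a reproducible,
vendor-free implementation of the full analysis chain: ADC_aqp map fitting,
whole-tumor histogram radiomics, dual IHC scoring, and the cohort-level
statistical battery — all exercisable end-to-end on synthetic phantoms with
known ground truth.

## The model

At ultra-high diffusion weighting (b ≥ 1700 s/mm²) the residual DWI signal
is dominated by very slow transmembrane water transport, mediated by
aquaporin channels. The signal is modelled mono-exponentially:

```
S(b) / S0 = exp(−b · ADC_aqp),    b ≥ 1700 s/mm²
```

with b in s/mm² and ADC_aqp in μm²/ms (exponent b · ADC · 10⁻³,
dimensionless). The map is fitted pixel-wise by ordinary least squares of
ln S on b over the five acquired b-values {1700, 2000, 2500, 3000, 3500};
the intercept absorbs S0, so no b = 0 volume is needed. Whole-tumor values
inside a NIfTI-1 mask are summarized by eight first-order histogram
features: mean, 2.5th/25th/50th/75th/97.5th percentiles, kurtosis and
skewness.

AQP expression on digitized H-DAB slides is scored two ways:

* **manual rubric** — staining intensity (0/1+/2+/3+) plus a
  positive-cell-ratio score (0: 0%, 1: 1–25%, 2: 26–50%, 3: 51–75%,
  4: >75%), summed to the manual AQP score (0–7), averaged over observers;
* **tile-based** — color deconvolution to DAB optical density
  (OD = −log₁₀ I/I_white, stain separation by inverting the unit-row
  hematoxylin/DAB/residual matrix), background correction, 100 μm × 100 μm
  tiling of the tumor ROI, then the same eight-feature histogram of the
  per-tile mean DAB OD.

The statistics layer provides two-way random-effects absolute-agreement
single-measures ICC (≥ 0.75 read as good reliability), Kolmogorov–Smirnov
normality, one-way ANOVA with Fisher's LSD post hoc under a Bonferroni
family threshold (0.05/3 = 0.017 for three differentiation groups), Pearson
correlation of matched histogram features, and independent t-tests for
T-stage and nodal-status contrasts.

## Worked example

```python
import numpy as np
from adcaqp import (PhantomSpec, generate_adc_phantom, generate_dwi_series,
                    fit_adcaqp_map, extract_masked_values,
                    compute_histogram_features)

spec = PhantomSpec(adc_mean=0.39, adc_spread=0.06, noise_sigma=10.0, seed=42)
truth, mask = generate_adc_phantom(spec)        # ground-truth field + tumor mask
series = generate_dwi_series(truth, mask, spec) # five b-value volumes, Rician noise
amap = fit_adcaqp_map(series, mask)             # pixel-wise log-linear fit
feats = compute_histogram_features(extract_masked_values(amap, mask))
print(f"mask voxels: {feats.n}")
for k, v in feats.to_dict().items():
    if k != "n_voxels":
        print(f"{k:>8}: {v: .3f}")
```

prints

```
mask voxels: 880
    mean:  0.393
    p2.5:  0.299
     p25:  0.352
     p50:  0.395
     p75:  0.433
   p97.5:  0.487
kurtosis: -0.614
skewness:  0.004
```

The recovered whole-tumor mean (0.393 μm²/ms) sits at the planted field
mean of 0.39 despite the added noise; the near-zero skewness and the
percentile spread reflect the symmetric Gaussian texture of this phantom.
With `noise_sigma=0` the fit recovers the planted field to machine
precision at every mask voxel.

A full demo run — eight synthetic subjects, DWI simulation, fitting, ROI
QC (100 mm² largest-axial-plane rule), stain-phantom scoring and the
statistical reports as CSV:

```sh
adcaqp run-all --out demo_run --seed 1
```

Individual stages are exposed as `adcaqp simulate|fit|features|score-ihc|
score-ihc-manual|qc|analyze`.

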