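# Methods

## Signal model and fitting

The package models the ultra-high b-value DWI signal mono-exponentially,
`S(b) = S0·exp(−b·ADC_aqp·10⁻³)` with b in s/mm² and ADC_aqp in μm²/ms.
This unit convention is fixed package-wide; the 10⁻³ factor converts
μm²/ms to mm²/s so the exponent is dimensionless.

The estimator is unweighted ordinary least squares of ln S on b, fitted
jointly over all available b-values (≥ 2 per voxel). Log-linear OLS is the
standard mono-exponential fit and is exact on noiseless data, which gives
the pipeline a machine-precision round-trip contract against its own
forward model. A signal²-weighted variant — the usual first-order
correction for the noise distortion introduced by the log transform — is
available via `weighted=True` / `--weighted`. Design choices that matter
for the histogram features:

* **negative estimates are kept.** Under noise the fitted slope can turn
  positive (negative ADC). Clipping at zero would bias the low-percentile
  features upward, so invalid-by-clipping is deliberately not a concept
  here; only voxels with fewer than two positive signals are invalid.
* **nonpositive signals are dropped, not offset.** An additive offset
  before the log would bias the slope; exclusion only costs degrees of
  freedom.
* b-values below 1700 s/mm² are rejected outright: below that the signal
  has perfusion/hindered-diffusion contributions and the single-exponential
  aquaporin interpretation does not hold.
* volumes and masks are assumed co-registered on one grid (acquisition
  with one spatial prescription); no registration is attempted.

## Histogram features

Eight first-order features: mean, 2.5th/25th/50th/75th/97.5th percentiles,
kurtosis, skewness. Percentiles use linear interpolation between closest
ranks (rank `1 + (n−1)q/100` on the sorted sample) — percentile dialects
differ across radiomics tools, so the convention is pinned and oracle-tested.
Skewness is the adjusted Fisher–Pearson standardized third moment; kurtosis
is reported as sample-corrected *excess* kurtosis (normal → 0) by default,
with a `raw` (Pearson, normal → 3) switch, since published feature tables
rarely state which convention their software used. Both moments are flagged
undefined for n < 4 or zero variance rather than returning a misleading
number.

## IHC scoring

The manual rubric realizes the printed integer bins as half-open real
intervals (exactly 0 → 0, (0,25] → 1, (25,50] → 2, (50,75] → 3,
(75,100] → 4) so non-integer percentages score deterministically; the
manual AQP score is intensity (0–3) plus ratio (0–4), averaged across
observers.

The tile route interprets "DAB intensity" as optical density — the
Beer–Lambert-linear quantity QuPath uses for chromogen quantification —
not a raw 8-bit channel (a `raw` switch exists). Deconvolution uses the
standard published hematoxylin/DAB vectors with a unit cross-product
residual row, overridable per run; negative deconvolved concentrations are
clipped to zero. Background correction subtracts a low percentile (default
5th, configurable) of the in-ROI DAB OD — a deliberately simple, documented
stand-in for the unspecified corrections of interactive tools. Tiling is
anchored at the ROI bounding-box origin with tile edge
`round(tile_um / microns_per_pixel)` px; tiles with under 50% ROI coverage
(configurable) are discarded so near-empty edge tiles do not dilute the
per-tile means, and retained tiles are weighted equally in the histogram.
Nonspecific-staining removal is the caller's ROI mask itself; no automatic
artifact detection is attempted.

## Statistics

* **ICC**: two-way random-effects, absolute-agreement, single-measures
  (ICC(2,1)) from the subjects × raters mean squares — the conventional
  form for two interchangeable human raters; ≥ 0.75 is labelled good
  reliability. With zero between-subject variance the coefficient is
  undefined and flagged rather than forced.
* **Normality**: one-sample Kolmogorov–Smirnov against a normal with the
  sample mean and SD.
* **Group comparison**: one-way ANOVA (α = 0.05) followed by Fisher's LSD
  pairwise t-tests on the pooled within-group mean square, flagged at the
  Bonferroni threshold family-α / #comparisons (0.05/3 → 0.017, reported
  at 3 decimals).
* **Correlation**: Pearson r with two-sided p via the t transform; each
  ADC feature is paired with its like-named tile-IHC feature, plus mean
  ADC vs the manual score.
* **Two-group contrasts**: pooled-variance (Student) t by default — the
  conventional reading of an unqualified "independent t test" — with Welch
  behind a switch. All p-values are two-sided.

scipy.stats supplies the classical distributions and tests behind this
surface; ICC and the LSD machinery are computed from explicit mean-squares
decompositions. The test suite checks every estimator against independent
brute-force formula implementations.

## Synthetic data: what it emulates, and what it does not

The phantoms define the study conditions for every test:

* **DWI phantom** — an ellipsoidal lesion in a configurable grid (default
  32×32×10 voxels at 1×1×5 mm, matching a typical small-FOV axial rectal
  protocol), with a ground-truth ADC field `mean + spread·Z` where Z is a
  Gaussian random field smoothed at a configurable texture scale (default
  3 mm) and standardized over the grid. Defaults (mean 0.39, spread 0.06
  μm²/ms) sit in the range observed for rectal tumors (whole-tumor means
  ≈ 0.35–0.44 μm²/ms across differentiation grades). The within-tumor
  spatial statistics of real ADC_aqp are not characterized anywhere; this
  smoothed-Gaussian field is an explicit stand-in, and the texture scale
  is exposed so both unimodal and skewed tumor histograms can be produced.
* **noise** — Rician, as the magnitude of the complex signal with i.i.d.
  zero-mean Gaussian perturbations of scale σ on both quadratures: the
  standard MR magnitude-noise model. No EPI distortion, motion, coil
  profile or slice-gap effects are simulated.
* **stain phantom** — disk cells with hematoxylin counterstain, a planted
  fraction of them carrying a planted DAB OD, composed as the exact inverse
  of the deconvolution model (transmission `10^(−OD·M)` times the white
  level). It is invertible by construction, which is the contract the tests
  rely on; it does not emulate nuclear texture, stain co-localization,
  scanner color response or JPEG artifacts. The float image is exact;
  saving to 8-bit PNG quantizes it, so file-round-trip tolerances are
  looser than in-memory ones.
* **cohort generator** — per-subject feature vectors drawn from bivariate
  normals with planted matched-feature correlations (defaults follow the
  observed pattern: mean/p75/p97.5 correlate at r ≈ 0.24/0.32/0.36, the
  rest null), group sizes 13/53/10 with per-group ADC feature means and
  SDs at the published values, stage labels with no planted effect. IHC
  feature scales unreported for some features are set to plausible values
  of the same order as the reported ones. Passing tests therefore show
  that the estimators recover what this generative family plants — not
  that real tumors follow it.

Consequently, passing the suite demonstrates correctness of the
computational chain (fitting, feature extraction, scoring, statistics) and
its calibration under idealized conditions; it says nothing about scanner
effects, segmentation variability, or biological validity.

## Pipeline, QC and reproducibility

The ROI-area rule excludes lesions whose largest axial plane covers less
than 100 mm² (voxel count × in-plane voxel area, axial = last axis). Other
clinical exclusions (prior treatment, DWI–surgery interval, histology,
stain quality) are metadata consumed as columns, not computed. Every run
serializes its full configuration to JSON (round-trip identity is tested),
stamps each output CSV with a config hash, logs seeds and thresholds, and
is bit-identical on rerun with the same config. Demo runs use 8 subjects
on the default grid so the whole end-to-end composition, including file
I/O through NIfTI-1 and PNG, completes in a few seconds.

Problem sizes used by the test suite: phantoms of ~10³ mask voxels for
fit-accuracy guards; 1,000 replicates for the null calibration of the
ANOVA/LSD battery at group sizes 13/53/10; 200 replicates at n = 76 for
the planted-correlation recovery band; 100 seeded random inputs per
estimator for the brute-force oracle equivalence checks.

## Known limitations

* Single-compartment model only — no IVIM, kurtosis or bi-exponential
  alternatives, and no motion/distortion correction.
* The stain phantom's geometric simplicity means tile-level feature
  distributions are narrower than on real slides.
* The ICC variant and t-test variance assumption of legacy SPSS-based
  analyses cannot be verified; the defaults here are the conventional
  choices and both are switchable.
* Whole-slide pyramidal formats and cell segmentation are out of scope;
  the positive-cell fraction for the manual rubric is observer-provided.
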