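"""Phantom generators: DWI series, stain images, and feature cohorts.

Every downstream stage of the pipeline is testable without any download:

* :func:`generate_adc_phantom` builds a spatially smooth ground-truth
  ADC_aqp field and an ellipsoidal whole-tumor mask;
* :func:`generate_dwi_series` forward-models the ultra-high b-value signal
  S(b) = S0 * exp(-b * ADC * 1e-3) and adds Rician (MR magnitude) noise;
* :func:`generate_stain_image` renders an H-DAB slide as the exact inverse
  of the color-deconvolution model used for scoring, so deconvolution
  recovers the planted DAB optical density;
* :func:`generate_cohort` draws a per-subject feature table with planted
  feature-feature correlations and group structure for the statistics
  layer.

All generators are pure functions of (spec, seed): the same spec yields
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .adc import ADCMap, DWISeries
from .ihc import DEFAULT_STAIN_MATRIX, _unit_rows

__all__ = [
    "DEFAULT_B_VALUES",
    "PhantomSpec",
    "StainPhantomSpec",
    "generate_adc_phantom",
    "generate_dwi_series",
    "generate_stain_image",
    "generate_cohort",
    "ADC_GROUP_MEANS",
    "ADC_GROUP_SDS",
]

#: the five ultra-high b-values of the acquisition protocol (s/mm²)
DEFAULT_B_VALUES = (1700.0, 2000.0, 2500.0, 3000.0, 3500.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, ADC field statistics and noise level of a DWI phantom.

    ``adc_mean``/``adc_spread`` (μm²/ms) set the per-voxel marginal of the
    ground-truth field; ``adc_texture_mm`` its spatial correlation scale.
    Defaults sit in the range observed for rectal tumors (whole-tumor mean
    ADC_aqp around 0.35-0.45 μm²/ms).
    """

    grid_shape: tuple = (32, 32, 10)
    voxel_size_mm: tuple = (1.0, 1.0, 5.0)
    lesion_radius_mm: float = 10.0
    adc_mean: float = 0.39
    adc_spread: float = 0.06
    adc_texture_mm: float = 3.0
    s0_level: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "grid_shape", tuple(int(g) for g in self.grid_shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if any(g < 1 for g in self.grid_shape):
            raise ValueError("grid_shape entries must all be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm entries must be positive")
        if self.adc_mean <= 0:
            raise ValueError("adc_mean must be positive")
        if self.adc_spread < 0 or self.noise_sigma < 0:
            raise ValueError("adc_spread and noise_sigma must be nonnegative")


@dataclass(frozen=True)
class StainPhantomSpec:
    """A simulated H-DAB slide with a known positive-cell fraction.

    Cells are rendered as disks (realism is a non-goal; invertibility under
    the stain model is the contract): every cell carries hematoxylin
    counterstain, DAB-positive cells additionally carry ``dab_od_level``
    optical density. ``background_tint`` is a small uniform DAB OD offset
    emulating nonspecific background staining.
    """

    image_shape_px: tuple = (560, 560)
    microns_per_pixel: float = 1.0
    positive_fraction: float = 0.5
    dab_od_level: float = 0.4
    n_cells: int = 800
    cell_radius_um: float = 5.0
    hematoxylin_od: float = 0.5
    background_tint: float = 0.0
    roi_margin_px: int = 20
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "image_shape_px", tuple(int(s) for s in self.image_shape_px))
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.dab_od_level < 0:
            raise ValueError("dab_od_level must be nonnegative")


# ---------------------------------------------------------------------------
# DWI phantoms
# ---------------------------------------------------------------------------

def generate_adc_phantom(spec: PhantomSpec):
    """Ground-truth ADC field plus ellipsoidal tumor mask.

    The field is ``adc_mean + adc_spread * Z`` where Z is a unit-variance
    Gaussian random field smoothed at ``adc_texture_mm`` and standardized
    over the grid, clipped to stay positive. With ``adc_spread == 0`` every
    voxel equals ``adc_mean`` exactly.

    Returns ``(truth_adc: ADCMap, mask: ndarray[bool])``.
    """
    shape = spec.grid_shape
    vs = np.asarray(spec.voxel_size_mm)
    half_extent_mm = (np.asarray(shape) * vs) / 2.0
    for ax, h in enumerate(half_extent_mm):
        if spec.lesion_radius_mm > h:
            raise ValueError(
                f"lesion radius {spec.lesion_radius_mm} mm exceeds the half grid "
                f"extent {h:g} mm along axis {ax}"
            )
    center = (np.asarray(shape) - 1) / 2.0
    coords = np.indices(shape).astype(float)
    dist2 = sum(((coords[a] - center[a]) * vs[a] / spec.lesion_radius_mm) ** 2
                for a in range(len(shape)))
    mask = dist2 <= 1.0

    if spec.adc_spread == 0.0:
        values = np.full(shape, spec.adc_mean)
    else:
        rng = np.random.default_rng([int(spec.seed), 0])
        raw = rng.standard_normal(shape)
        sigma_vox = spec.adc_texture_mm / vs
        smooth = gaussian_filter(raw, sigma=sigma_vox, mode="wrap")
        smooth = (smooth - smooth.mean()) / smooth.std()
        values = spec.adc_mean + spec.adc_spread * smooth
        values = np.clip(values, 1e-6, None)
    truth = ADCMap(values=values, valid=np.ones(shape, dtype=bool),
                   voxel_size_mm=spec.voxel_size_mm)
    return truth, mask


def generate_dwi_series(truth_adc: ADCMap, mask, spec: PhantomSpec,
                        b_values=DEFAULT_B_VALUES) -> DWISeries:
    """Forward-model the DWI series from a ground-truth ADC field.

    The noiseless signal at each voxel is s0 * exp(-b * ADC * 1e-3) with b
    in s/mm² and ADC in μm²/ms; with ``noise_sigma > 0``, Rician noise
    (magnitude of the complex signal with i.i.d. Gaussian real/imaginary
    perturbations of scale sigma) is applied independently per voxel per
    volume.
    """
    b_values = tuple(float(b) for b in b_values)
    if not b_values:
        raise ValueError("b_values must be nonempty")
    for b in b_values:
        if b < 0:
            raise ValueError(f"negative b-value {b:g} s/mm²")
    adc = np.where(np.isfinite(truth_adc.values), truth_adc.values, 0.0)
    b_col = np.asarray(b_values).reshape((-1,) + (1,) * adc.ndim)
    signal = spec.s0_level * np.exp(-b_col * adc * 1e-3)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([int(spec.seed), 1])
        g1 = rng.standard_normal(signal.shape)
        g2 = rng.standard_normal(signal.shape)
        signal = np.hypot(signal + spec.noise_sigma * g1, spec.noise_sigma * g2)
    return DWISeries(volumes=signal, b_values=b_values,
                     voxel_size_mm=truth_adc.voxel_size_mm)


# ---------------------------------------------------------------------------
# stain phantoms
# ---------------------------------------------------------------------------

def generate_stain_image(spec: StainPhantomSpec, stain_matrix=None):
    """Render an H-DAB slide phantom; returns ``(rgb, roi_mask, truth)``.

    The RGB image (float, 0-255 scale, white background 255) is composed as
    the exact inverse of the deconvolution model: per-pixel transmission
    10**(-OD @ M) scaled by the white level, where M is the unit-row stain
    matrix. ``truth`` records the planted positive fraction, DAB OD level
    and background tint.
    """
    m = DEFAULT_STAIN_MATRIX if stain_matrix is None else _unit_rows(stain_matrix)
    h, w = spec.image_shape_px
    margin = spec.roi_margin_px
    roi = np.zeros((h, w), dtype=bool)
    roi[margin:h - margin, margin:w - margin] = True
    if not roi.any():
        raise ValueError("ROI margin leaves no interior pixels")

    rng = np.random.default_rng([int(spec.seed), 2])
    od_h = np.zeros((h, w))
    od_d = np.full((h, w), float(spec.background_tint))

    radius_px = max(1.0, spec.cell_radius_um / spec.microns_per_pixel)
    n_pos = int(round(spec.positive_fraction * spec.n_cells))
    centers_r = rng.uniform(margin + radius_px, h - margin - radius_px, spec.n_cells)
    centers_c = rng.uniform(margin + radius_px, w - margin - radius_px, spec.n_cells)
    r_int = int(np.ceil(radius_px))
    for i in range(spec.n_cells):
        cr, cc = centers_r[i], centers_c[i]
        r0, r1 = max(int(cr) - r_int, 0), min(int(cr) + r_int + 1, h)
        c0, c1 = max(int(cc) - r_int, 0), min(int(cc) + r_int + 1, w)
        rr, cc_ix = np.ogrid[r0:r1, c0:c1]
        disk = (rr - cr) ** 2 + (cc_ix - cc) ** 2 <= radius_px**2
        od_h[r0:r1, c0:c1][disk] = spec.hematoxylin_od
        if i < n_pos:
            od_d[r0:r1, c0:c1][disk] = spec.dab_od_level + spec.background_tint
    od = np.stack([od_h, od_d, np.zeros_like(od_h)], axis=-1)
    rgb = 255.0 * 10.0 ** (-(od @ m))
    truth = {
        "positive_fraction": spec.positive_fraction,
        "dab_od_level": spec.dab_od_level,
        "background_od": spec.background_tint,
        "n_cells": spec.n_cells,
        "microns_per_pixel": spec.microns_per_pixel,
    }
    return rgb, roi, truth


def save_stain_phantom(rgb, roi, truth, out_dir) -> Path:
    """Write the phantom as 8-bit PNGs plus a JSON truth/calibration record."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / "slide.png", np.clip(np.round(rgb), 0, 255).astype(np.uint8))
    iio.imwrite(out_dir / "roi.png", (np.asarray(roi, bool) * 255).astype(np.uint8))
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return out_dir


# ---------------------------------------------------------------------------
# feature cohorts
# ---------------------------------------------------------------------------

_FEATS = ("mean", "p2.5", "p25", "p50", "p75", "p97.5", "kurtosis", "skewness")

#: per-group ADC_aqp feature means (good, moderate, poor), μm²/ms where dimensional
ADC_GROUP_MEANS = {
    "mean": (0.346, 0.388, 0.442), "p2.5": (0.180, 0.173, 0.168),
    "p25": (0.293, 0.315, 0.338), "p50": (0.337, 0.378, 0.421),
    "p75": (0.391, 0.451, 0.537), "p97.5": (0.545, 0.637, 0.777),
    "kurtosis": (1.422, 0.879, 0.927), "skewness": (0.420, 0.400, 0.436),
}
ADC_GROUP_SDS = {
    "mean": (0.030, 0.054, 0.090), "p2.5": (0.078, 0.096, 0.054),
    "p25": (0.025, 0.051, 0.049), "p50": (0.026, 0.054, 0.080),
    "p75": (0.035, 0.070, 0.142), "p97.5": (0.073, 0.115, 0.230),
    "kurtosis": (0.802, 0.921, 1.432), "skewness": (0.621, 0.452, 0.546),
}
# tile-score scales: mean/p75/p97.5 as observed for AQP1; the rest plausible
_IHC_MEANS = {"mean": 0.144, "p2.5": 0.050, "p25": 0.100, "p50": 0.130,
              "p75": 0.174, "p97.5": 0.285, "kurtosis": 1.0, "skewness": 0.4}
_IHC_SDS = {"mean": 0.036, "p2.5": 0.020, "p25": 0.030, "p50": 0.035,
            "p75": 0.052, "p97.5": 0.094, "kurtosis": 0.9, "skewness": 0.5}
#: planted ADC-vs-IHC correlations per matched feature (the observed pattern:
#: mean/p75/p97.5 correlate, the rest do not)
DEFAULT_PLANTED_R = {"mean": 0.237, "p2.5": 0.0, "p25": 0.0, "p50": 0.0,
                     "p75": 0.323, "p97.5": 0.362, "kurtosis": 0.0, "skewness": 0.0}


def generate_cohort(group_sizes=(13, 53, 10), planted_r=None, seed: int = 0,
                    differentiation_effect: bool = True,
                    manual_score_r: float = 0.228) -> pd.DataFrame:
    """Draw a per-subject feature table with known generative structure.

    Each matched (ADC feature, IHC feature) pair is bivariate normal with
    correlation ``planted_r`` (a scalar applied to every pair, or a dict
    per feature; default: the observed pattern where mean/p75/p97.5
    correlate and the rest are null). ``differentiation_effect`` shifts the
    ADC features by the per-group means; T stage and nodal status are
    assigned with no effect. Columns: subject_id, adc_<feature>,
    ihc_<feature>, manual_score, differentiation, t_stage, n_status.
    """
    if isinstance(planted_r, dict):
        r_by_feat = {f: float(planted_r.get(f, 0.0)) for f in _FEATS}
    elif planted_r is None:
        r_by_feat = dict(DEFAULT_PLANTED_R)
    else:
        r_by_feat = {f: float(planted_r) for f in _FEATS}
    for f, r in r_by_feat.items():
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"planted correlation for {f} must lie in [-1, 1]")
    if len(group_sizes) != 3 or any(int(g) < 1 for g in group_sizes):
        raise ValueError("group_sizes must give three positive counts (good, moderate, poor)")

    rng = np.random.default_rng([int(seed), 3])
    n = int(sum(group_sizes))
    labels = (["good"] * int(group_sizes[0]) + ["moderate"] * int(group_sizes[1])
              + ["poor"] * int(group_sizes[2]))
    gidx = np.array([0] * int(group_sizes[0]) + [1] * int(group_sizes[1])
                    + [2] * int(group_sizes[2]))

    data = {"subject_id": [f"sub-{i + 1:03d}" for i in range(n)]}
    z_mean = None
    for f in _FEATS:
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        if f == "mean":
            z_mean = z1
        r = r_by_feat[f]
        if differentiation_effect:
            mu = np.asarray(ADC_GROUP_MEANS[f])[gidx]
            sd = np.asarray(ADC_GROUP_SDS[f])[gidx]
        else:
            mu = np.asarray(ADC_GROUP_MEANS[f])[1]
            sd = np.asarray(ADC_GROUP_SDS[f])[1]
        data[f"adc_{f}"] = mu + sd * z1
        z_ihc = r * z1 + np.sqrt(1.0 - r**2) * z2
        data[f"ihc_{f}"] = _IHC_MEANS[f] + _IHC_SDS[f] * z_ihc
    zm = rng.standard_normal(n)
    data["manual_score"] = 6.07 + 0.543 * (manual_score_r * z_mean
                                           + np.sqrt(1 - manual_score_r**2) * zm)
    # stage labels carry no planted effect (the null finding is a condition)
    n_t12 = int(round(n * 22 / 76))
    t = np.array(["T1-2"] * n_t12 + ["T3-4"] * (n - n_t12))
    n_neg = int(round(n * 39 / 76))
    nn = np.array(["N-"] * n_neg + ["N+"] * (n - n_neg))
    data["differentiation"] = labels
    data["t_stage"] = rng.permutation(t)
    data["n_status"] = rng.permutation(nn)
    return pd.DataFrame(data)
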