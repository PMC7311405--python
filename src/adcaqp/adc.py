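"""Pixel-wise mono-exponential ADC_aqp fitting from ultra-high b-value DWI.

At b >= 1700 s/mm² the residual diffusion signal is modelled as

    S(b) = S0 * exp(-b * ADC_aqp * 1e-3)

with b in s/mm² and ADC_aqp in μm²/ms (the 1e-3 converts μm²/ms to mm²/s so
the exponent is dimensionless). The map is obtained voxel-wise by ordinary
least squares of ln S(b) on b; the slope is -ADC_aqp * 1e-3 and the
intercept absorbs S0 (no b = 0 volume is acquired or needed). Nonpositive
signals are dropped from a voxel's fit; a voxel is invalid when fewer than
two usable points remain. Negative estimates under noise are kept, not
clipped, so low-percentile histogram features stay unbiased.

A weighted variant (weights proportional to signal², the usual first-order
correction for log-transformed noise) is available via ``weighted=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "MIN_B_VALUE",
    "DWISeries",
    "ADCMap",
    "fit_adcaqp_voxel",
    "fit_adcaqp_map",
    "save_dwi_series",
    "load_dwi_series",
    "save_adc_map",
    "load_adc_map",
    "save_mask",
    "load_mask",
]

#: the mono-exponential aquaporin regime starts here (s/mm²)
MIN_B_VALUE = 1700.0


@dataclass
class DWISeries:
    """A stack of co-registered volumes, one per b-value.

    ``volumes`` has shape (n_b, *grid); ``b_values`` is strictly increasing,
    in s/mm².
    """

    volumes: np.ndarray
    b_values: tuple
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.b_values = tuple(float(b) for b in self.b_values)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.volumes.ndim < 2:
            raise ValueError("volumes must be a (n_b, ...) stack")
        if self.volumes.shape[0] != len(self.b_values):
            raise ValueError(
                f"{self.volumes.shape[0]} volumes but {len(self.b_values)} b-values"
            )
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be nonnegative")
        if any(b2 <= b1 for b1, b2 in zip(self.b_values, self.b_values[1:])):
            raise ValueError("b-values must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("signal magnitudes must be nonnegative")

    @property
    def grid_shape(self) -> tuple:
        return self.volumes.shape[1:]


@dataclass
class ADCMap:
    """Per-voxel ADC_aqp (μm²/ms) plus a validity mask.

    Invalid voxels carry NaN and are excluded by downstream feature
    extraction.
    """

    values: np.ndarray
    valid: np.ndarray = None
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("validity mask shape must match the value grid")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)


def fit_adcaqp_voxel(signals, b_values, weighted: bool = False):
    """Fit one voxel; returns ``(adc_um2_per_ms, valid)``.

    Least squares of ln(signal) on b; signals <= 0 are excluded rather than
    offset (an offset would bias the slope). ``valid`` is False when fewer
    than two usable points remain; that case returns NaN, not an exception.
    """
    signals = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if signals.shape != b.shape:
        raise ValueError(f"{signals.size} signals but {b.size} b-values")
    usable = signals > 0
    if usable.sum() < 2:
        return float("nan"), False
    s, bu = signals[usable], b[usable]
    y = np.log(s)
    w = s**2 if weighted else np.ones_like(s)
    wsum = w.sum()
    bbar = (w * bu).sum() / wsum
    ybar = (w * y).sum() / wsum
    denom = (w * (bu - bbar) ** 2).sum()
    if denom <= 0:
        return float("nan"), False
    slope = (w * (bu - bbar) * (y - ybar)).sum() / denom
    return float(-slope * 1e3), True


def fit_adcaqp_map(series: DWISeries, mask=None, weighted: bool = False) -> ADCMap:
    """Fit the whole grid (or the mask only; mask voxels agree either way).

    All b-values must be >= 1700 s/mm²: below that the signal is no longer
    in the mono-exponential aquaporin regime and the model does not apply.
    """
    for b in series.b_values:
        if b < MIN_B_VALUE:
            raise ValueError(
                f"b-value {b:g} s/mm² is below the {MIN_B_VALUE:g} s/mm² "
                "floor of the mono-exponential ADC_aqp model"
            )
    grid = series.grid_shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid:
            raise ValueError(f"mask shape {mask.shape} does not match grid {grid}")
        if not mask.any():
            raise ValueError("empty ROI: mask selects no voxels")

    nb = series.volumes.shape[0]
    sig = series.volumes.reshape(nb, -1)
    if mask is not None:
        cols = np.flatnonzero(mask.ravel())
        sig = sig[:, cols]
    b = np.asarray(series.b_values, dtype=float)[:, None]

    # vectorised weighted OLS with per-voxel exclusion of nonpositive signals
    usable = sig > 0
    y = np.where(usable, np.log(np.where(usable, sig, 1.0)), 0.0)
    w = np.where(usable, sig**2 if weighted else 1.0, 0.0)
    wsum = w.sum(axis=0)
    npts = usable.sum(axis=0)
    ok = npts >= 2
    safe = np.where(wsum > 0, wsum, 1.0)
    bbar = (w * b).sum(axis=0) / safe
    ybar = (w * y).sum(axis=0) / safe
    denom = (w * (b - bbar) ** 2).sum(axis=0)
    ok &= denom > 0
    slope = np.where(ok, (w * (b - bbar) * (y - ybar)).sum(axis=0), np.nan)
    slope = np.where(ok, slope / np.where(ok, denom, 1.0), np.nan)
    adc_flat = -slope * 1e3

    if mask is not None:
        values = np.full(grid, np.nan)
        valid = np.zeros(grid, dtype=bool)
        values.ravel()[cols] = adc_flat
        valid.ravel()[cols] = ok
    else:
        values = adc_flat.reshape(grid)
        valid = ok.reshape(grid)
    return ADCMap(values=values, valid=valid, voxel_size_mm=series.voxel_size_mm)


# ---------------------------------------------------------------------------
# NIfTI-1 + JSON layout
# ---------------------------------------------------------------------------

def _affine(voxel_size_mm):
    return np.diag(list(voxel_size_mm[:3]) + [1.0])


def save_dwi_series(series: DWISeries, out_dir) -> Path:
    """One NIfTI per b-value (filename embeds the b-value) + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.voxel_size_mm)
    for b, vol in zip(series.b_values, series.volumes):
        nib.save(nib.Nifti1Image(vol.astype(np.float64), aff),
                 out_dir / f"dwi_b{int(round(b))}.nii.gz")
    sidecar = {"b_values": list(series.b_values),
               "voxel_size_mm": list(series.voxel_size_mm)}
    (out_dir / "bvalues.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def load_dwi_series(in_dir) -> DWISeries:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "bvalues.json").read_text())
    vols = [np.asanyarray(nib.load(in_dir / f"dwi_b{int(round(b))}.nii.gz").dataobj)
            for b in sidecar["b_values"]]
    return DWISeries(volumes=np.stack(vols), b_values=sidecar["b_values"],
                     voxel_size_mm=sidecar["voxel_size_mm"])


def save_adc_map(adc_map: ADCMap, out_path) -> Path:
    """Float map at ``out_path``; validity flags beside it as *_valid.nii.gz."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(adc_map.voxel_size_mm)
    nib.save(nib.Nifti1Image(adc_map.values.astype(np.float64), aff), out_path)
    stem = out_path.name[: -len(".nii.gz")] if out_path.name.endswith(".nii.gz") else out_path.stem
    nib.save(nib.Nifti1Image(adc_map.valid.astype(np.uint8), aff),
             out_path.parent / f"{stem}_valid.nii.gz")
    return out_path


def load_adc_map(path) -> ADCMap:
    path = Path(path)
    img = nib.load(path)
    values = np.asanyarray(img.dataobj).astype(float)
    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    valid_path = path.parent / f"{stem}_valid.nii.gz"
    valid = (np.asanyarray(nib.load(valid_path).dataobj) > 0) if valid_path.exists() else None
    vs = img.header.get_zooms()[:3]
    return ADCMap(values=values, valid=valid, voxel_size_mm=tuple(float(v) for v in vs))


def save_mask(mask, voxel_size_mm, out_path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm)), out_path)
    return out_path


def load_mask(path):
    img = nib.load(path)
    vs = tuple(float(v) for v in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj) > 0, vs
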