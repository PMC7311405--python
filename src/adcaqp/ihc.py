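"""Aquaporin immunohistochemistry scoring.

Two scoring routes, mirroring routine pathology practice:

1. **Manual rubric** — staining intensity scored 0/1+/2+/3+ against normal
   mucosal epithelium, plus a positive-cell-ratio score binned as
   0 (0%), 1 (1-25%], 2 (25-50%], 3 (50-75%], 4 (>75%]; the manual AQP
   score is their sum (range 0-7). Sections are scored by two or more
   observers and the mean total is analysed.

2. **Tile-based DAB histogram** — the tumor ROI on a digitized slide is
   deconvolved into stain optical densities (Beer-Lambert: per-channel
   OD = -log10(I / I_white), stain separation by inverting the unit-row
   stain matrix), background-corrected, tiled into 100 μm x 100 μm tiles,
   and the per-tile mean DAB OD feeds the same eight-feature histogram
   engine used for the ADC maps.

"DAB intensity" means optical density throughout (linear in chromogen
concentration); raw channel values are available via ``intensity="raw"``
on :func:`dab_od_image`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import HistogramFeatures, compute_histogram_features

__all__ = [
    "DEFAULT_STAIN_MATRIX",
    "ManualScore",
    "TileGrid",
    "ratio_score",
    "manual_score",
    "average_observers",
    "dab_od_image",
    "background_correct",
    "tile_roi",
    "tile_histogram_features",
]


def _unit_rows(m):
    m = np.asarray(m, dtype=float)
    return m / np.linalg.norm(m, axis=1, keepdims=True)


# standard published hematoxylin / DAB vectors; residual = their unit cross
# product, completing an invertible basis
_H = np.array([0.650, 0.704, 0.286])
_D = np.array([0.268, 0.570, 0.776])
DEFAULT_STAIN_MATRIX = _unit_rows(np.vstack([_H, _D, np.cross(_H, _D)]))


# ---------------------------------------------------------------------------
# manual rubric
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManualScore:
    """Manual AQP score: staining intensity + positive-cell-ratio score."""

    intensity_score: int
    ratio_score: int

    @property
    def total(self) -> int:
        return self.intensity_score + self.ratio_score


def ratio_score(positive_percent: float) -> int:
    """Positive-cell-ratio score: 0 (0%), 1 (1-25%), 2 (26-50%), 3 (51-75%), 4 (>75%).

    The printed integer bins are realized as half-open real intervals —
    exactly 0 -> 0, (0, 25] -> 1, (25, 50] -> 2, (50, 75] -> 3,
    (75, 100] -> 4 — so non-integer percentages score deterministically.
    """
    p = float(positive_percent)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"positive-cell percentage must lie in [0, 100], got {p}")
    if p == 0.0:
        return 0
    for score, upper in ((1, 25.0), (2, 50.0), (3, 75.0)):
        if p <= upper:
            return score
    return 4


def manual_score(intensity_score: int, positive_percent: float) -> ManualScore:
    """Manual AQP score from an observer's intensity grade and positive fraction."""
    if intensity_score not in (0, 1, 2, 3):
        raise ValueError(f"staining intensity score must be one of 0,1,2,3, got {intensity_score}")
    return ManualScore(intensity_score=int(intensity_score),
                       ratio_score=ratio_score(positive_percent))


def average_observers(totals) -> float:
    """Arithmetic mean of two or more observers' manual score totals."""
    totals = [float(t) for t in totals]
    if len(totals) < 2:
        raise ValueError("averaging requires at least two observers' scores")
    return float(np.mean(totals))


# ---------------------------------------------------------------------------
# color deconvolution
# ---------------------------------------------------------------------------

def dab_od_image(rgb_image, stain_matrix=None, background_white=255.0,
                 intensity: str = "od") -> np.ndarray:
    """Per-pixel DAB signal from an RGB image by color deconvolution.

    Per-channel optical density is -log10(channel / background_white); the
    DAB concentration is the DAB row of the inverted stain matrix applied to
    the OD vector, with negative deconvolved values clipped to 0.
    ``intensity="raw"`` instead returns the inverted 8-bit DAB-channel proxy
    (background_white minus the channel most attenuated by DAB).
    """
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    bg = np.asarray(background_white, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background_white must be positive")
    if intensity not in ("od", "raw"):
        raise ValueError(f"unknown intensity convention {intensity!r}")
    m = DEFAULT_STAIN_MATRIX if stain_matrix is None else _unit_rows(stain_matrix)
    if m.shape != (3, 3):
        raise ValueError("stain matrix must be 3 x 3 (hematoxylin, DAB, residual)")
    if abs(np.linalg.det(m)) < 1e-8:
        raise ValueError("stain matrix is singular; its rows must be independent")
    if intensity == "raw":
        ch = int(np.argmax(m[1]))  # channel most attenuated by DAB
        return np.clip(np.asarray(bg) - rgb[..., ch], 0.0, None)
    # floor avoids -log10(0) on fully saturated pixels
    trans = np.clip(rgb[..., :3] / bg, 1e-8, None)
    od = -np.log10(trans)
    conc = od @ np.linalg.inv(m)
    return np.clip(conc[..., 1], 0.0, None)


def background_correct(dab: np.ndarray, roi_mask, bg_percentile: float = 5.0) -> np.ndarray:
    """Subtract nonspecific staining background, floored at zero.

    The background level is estimated as a low percentile (default the 5th)
    of the DAB OD inside the ROI.
    """
    dab = np.asarray(dab, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != dab.shape:
        raise ValueError("ROI mask shape must match the DAB image")
    if not roi.any():
        raise ValueError("empty ROI: cannot estimate staining background")
    level = float(np.percentile(dab[roi], bg_percentile))
    return np.clip(dab - level, 0.0, None)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TileGrid:
    """Axis-aligned tile footprints intersecting the ROI.

    ``tiles`` holds (row0, col0) pixel origins of ``tile_px`` x ``tile_px``
    squares anchored at the ROI bounding-box origin; ``coverage`` the
    fraction of each tile's pixels inside the ROI. Only tiles with coverage
    at or above the retention minimum are kept.
    """

    tile_um: float
    microns_per_pixel: float
    tile_px: int
    tiles: tuple
    coverage: tuple

    def __len__(self) -> int:
        return len(self.tiles)


def tile_roi(roi_mask, microns_per_pixel: float, tile_um: float = 100.0,
             min_coverage: float = 0.5) -> TileGrid:
    """Tile the ROI into tile_um x tile_um squares (default 100 μm).

    The grid is anchored at the ROI bounding-box origin; the tile edge in
    pixels is round(tile_um / microns_per_pixel). Tiles whose ROI coverage
    falls below ``min_coverage`` are discarded so near-empty edge tiles do
    not dilute the per-tile means.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be positive")
    if tile_um <= 0:
        raise ValueError("tile_um must be positive")
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI: nothing to tile")
    tile_px = int(round(tile_um / microns_per_pixel))
    if tile_px < 1:
        raise ValueError(
            f"tile of {tile_um} μm is smaller than one pixel at {microns_per_pixel} μm/px"
        )
    rows = np.any(roi, axis=1).nonzero()[0]
    cols = np.any(roi, axis=0).nonzero()[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    tiles, cov = [], []
    area = float(tile_px * tile_px)
    for r in range(r0, r1, tile_px):
        for c in range(c0, c1, tile_px):
            patch = roi[r:r + tile_px, c:c + tile_px]
            frac = float(patch.sum()) / area
            if frac >= min_coverage:
                tiles.append((r, c))
                cov.append(frac)
    if not tiles:
        raise ValueError("ROI too small to tile at the requested tile size")
    return TileGrid(tile_um=float(tile_um), microns_per_pixel=float(microns_per_pixel),
                    tile_px=tile_px, tiles=tuple(tiles), coverage=tuple(cov))


def tile_means(dab: np.ndarray, grid: TileGrid, roi_mask) -> np.ndarray:
    """Mean DAB OD over each retained tile's ROI pixels, in grid order."""
    dab = np.asarray(dab, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    out = np.empty(len(grid))
    t = grid.tile_px
    for i, (r, c) in enumerate(grid.tiles):
        patch_roi = roi[r:r + t, c:c + t]
        out[i] = dab[r:r + t, c:c + t][patch_roi].mean()
    return out


def tile_histogram_features(dab: np.ndarray, grid: TileGrid, roi_mask,
                            kurtosis_convention: str = "excess") -> HistogramFeatures:
    """Eight-feature histogram summary of the per-tile mean DAB OD.

    Each retained tile contributes one value, weighted equally.
    """
    if len(grid) == 0:
        raise ValueError("tile grid is empty")
    return compute_histogram_features(tile_means(dab, grid, roi_mask),
                                      kurtosis_convention=kurtosis_convention)
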