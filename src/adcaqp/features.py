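"""First-order histogram features of masked voxel (or tile) value sets.

The same eight-feature engine summarises whole-tumor ADC_aqp maps and
per-tile DAB optical densities: mean, the 2.5th/25th/50th/75th/97.5th
percentiles, excess kurtosis and skewness.

Conventions (fixed so results are dialect-stable across tools):

* percentiles use linear interpolation between closest ranks,
  rank r = 1 + (n - 1) * q / 100 on the sorted sample;
* skewness is the adjusted Fisher-Pearson standardized third moment;
* kurtosis is sample-corrected *excess* kurtosis (normal -> 0); raw
  (Pearson) kurtosis is available via ``kurtosis_convention="raw"``.

Skewness and kurtosis are undefined (NaN, ``moments_defined`` False) when
n < 4 or the sample variance is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "HistogramFeatures",
    "FEATURE_NAMES",
    "percentile",
    "compute_histogram_features",
    "extract_masked_values",
]

#: canonical feature order used by every CSV this package writes
FEATURE_NAMES = ("mean", "p2.5", "p25", "p50", "p75", "p97.5", "kurtosis", "skewness")


@dataclass(frozen=True)
class HistogramFeatures:
    """The eight first-order features of a value set, plus the count used."""

    mean: float
    p2_5: float
    p25: float
    p50: float
    p75: float
    p97_5: float
    kurtosis: float
    skewness: float
    n: int
    #: False when skewness/kurtosis are undefined (n < 4 or zero variance)
    moments_defined: bool = True

    def to_dict(self) -> dict:
        """Feature dict keyed by the canonical CSV column names."""
        return {
            "mean": self.mean,
            "p2.5": self.p2_5,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
            "p97.5": self.p97_5,
            "kurtosis": self.kurtosis,
            "skewness": self.skewness,
            "n_voxels": self.n,
        }


def percentile(values, q: float) -> float:
    """Percentile by linear interpolation between closest ranks.

    Parameters
    ----------
    values : array-like
        Nonempty sample.
    q : float
        Percent in [0, 100].
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty sample is undefined")
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"q must lie in [0, 100], got {q}")
    return float(np.percentile(values, q, method="linear"))


def compute_histogram_features(values, kurtosis_convention: str = "excess") -> HistogramFeatures:
    """Compute the eight-feature summary of a nonempty value set.

    ``kurtosis_convention`` is ``"excess"`` (sample-corrected, normal -> 0)
    or ``"raw"`` (Pearson, normal -> 3).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot compute histogram features of an empty sample")
    if kurtosis_convention not in ("excess", "raw"):
        raise ValueError(f"unknown kurtosis convention {kurtosis_convention!r}")
    n = int(values.size)
    defined = n >= 4 and float(np.var(values)) > 0.0
    if defined:
        skew = float(sps.skew(values, bias=False))
        kurt = float(sps.kurtosis(values, fisher=True, bias=False))
        if kurtosis_convention == "raw":
            kurt += 3.0
    else:
        skew = float("nan")
        kurt = float("nan")
    return HistogramFeatures(
        mean=float(np.mean(values)),
        p2_5=percentile(values, 2.5),
        p25=percentile(values, 25),
        p50=percentile(values, 50),
        p75=percentile(values, 75),
        p97_5=percentile(values, 97.5),
        kurtosis=kurt,
        skewness=skew,
        n=n,
        moments_defined=defined,
    )


def extract_masked_values(adc_map, mask) -> np.ndarray:
    """Values of an ADC map at valid mask voxels, in raster (C) order.

    ``adc_map`` is an :class:`adcaqp.adc.ADCMap`; ``mask`` a boolean array of
    the same grid shape. Voxels whose fit failed are excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != adc_map.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match map grid {adc_map.values.shape}"
        )
    if not mask.any():
        raise ValueError("empty ROI: mask selects no voxels")
    keep = mask & adc_map.valid
    if not keep.any():
        raise ValueError("empty ROI: no valid fitted voxels inside the mask")
    return adc_map.values[keep]
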