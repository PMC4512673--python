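"""ADC-histogram evaluation statistics.

The quality of a motion-correction method is scored on the ADC values it
produces inside an ROI, assuming the observed ADC spread is the
quadrature sum of independent acquisition-noise, biological and motion
contributions:

* ``sigma_D`` — the width of the ADC histogram: sample standard
  deviation of the ROI's ADC values (same units as ADC, 1e-5 mm^2/s).
* ``delta_sigma`` — signed quadrature difference of two widths,
  sign(s1^2 - s2^2) * sqrt(|s1^2 - s2^2|); with the uncorrected width
  first, a positive value is equivalent motion noise removed per voxel.
* ``reproducibility`` — between-scan percentage change of mean ADC,
  200 * |D1 - D2| / (D1 + D2).
* ``reproducibility_accuracy`` — first-order error propagation of the
  above through the two ROI means:
  [400 / (D1 + D2)^2] * sqrt(D2^2 s1^2 / N1 + D1^2 s2^2 / N2).

Because deformable registration inherently smooths images, comparisons
against it control the smoothness difference by Gaussian-blurring the
rigid-aligned and plain-averaged data (the "-b" method variants) before
fitting ADC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "histogram_width",
    "delta_sigma",
    "reproducibility",
    "reproducibility_accuracy",
    "gaussian_blur",
    "summarize_methods",
    "scatter_export",
]


def histogram_width(adc_values) -> float:
    """Sample standard deviation (n-1) of ROI ADC values."""
    v = np.asarray(adc_values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 ADC values")
    return float(np.std(v, ddof=1))


def delta_sigma(sigma_uncorrected: float, sigma_corrected: float) -> float:
    """Signed quadrature difference of two ADC-histogram widths.

    Positive when the corrected method narrowed the histogram, i.e.
    equivalent noise was removed; negative when it widened it.
    """
    if sigma_uncorrected < 0 or sigma_corrected < 0:
        raise ValueError("widths must be >= 0")
    diff = sigma_uncorrected ** 2 - sigma_corrected ** 2
    return float(np.sign(diff) * np.sqrt(abs(diff)))


def reproducibility(d1: float, d2: float) -> float:
    """Percentage change of mean ADC between two scans: 200|D1-D2|/(D1+D2)."""
    if d1 + d2 <= 0:
        raise ValueError("D1 + D2 must be positive")
    return float(200.0 * abs(d1 - d2) / (d1 + d2))


def reproducibility_accuracy(d1, d2, sigma1, sigma2, n1, n2) -> float:
    """First-order accuracy of the percentage-change metric.

    Propagates the standard errors sigma_i / sqrt(N_i) of the two ROI
    mean ADC values through 200|D1-D2|/(D1+D2):

        [400 / (D1+D2)^2] * sqrt(D2^2 sigma1^2 / N1 + D1^2 sigma2^2 / N2)
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("N1, N2 must be >= 1")
    pref = 400.0 / (d1 + d2) ** 2
    return float(pref * np.sqrt(d2 ** 2 * sigma1 ** 2 / n1
                                + d1 ** 2 * sigma2 ** 2 / n2))


def gaussian_blur(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian filter with reflective borders; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma_px == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma_px, mode="reflect")


def summarize_methods(delta_d: pd.DataFrame = None,
                      delta_sigma_table: pd.DataFrame = None) -> pd.DataFrame:
    """Per-method summary rows of the evaluation tables.

    Parameters
    ----------
    delta_d : DataFrame, optional
        Reproducibility values, one row per volunteer, one column per
        method.  Summarised by column mean (n denominator) and the
        within-population standard deviation (n-1).
    delta_sigma_table : DataFrame, optional
        Width-reduction values, one row per dataset pair, one column per
        method.  Summarised by column mean.

    Returns a DataFrame indexed by statistic name with method columns.
    """
    rows = {}
    if delta_d is not None:
        if len(delta_d) < 2:
            raise ValueError("need >= 2 datasets to summarise")
        rows["mean_delta_D_pct"] = delta_d.mean(axis=0)
        rows["std_delta_D_pct"] = delta_d.std(axis=0, ddof=1)
    if delta_sigma_table is not None:
        if len(delta_sigma_table) < 2:
            raise ValueError("need >= 2 datasets to summarise")
        rows["mean_delta_sigma"] = delta_sigma_table.mean(axis=0)
    if not rows:
        raise ValueError("nothing to summarise")
    return pd.DataFrame(rows).T


def scatter_export(s0_map: np.ndarray, adc_map: np.ndarray,
                   roi_mask: np.ndarray) -> pd.DataFrame:
    """Raw (S0, D) pairs over ROI voxels for cluster inspection.

    Clusters in the S0-vs-ADC plane correspond to coherent structures
    (e.g. a fluid-filled gallbladder sits in the high-S0, high-D corner);
    motion correction that preserves voxel identity sharpens them.
    """
    s0_map = np.asarray(s0_map, dtype=np.float64)
    adc_map = np.asarray(adc_map, dtype=np.float64)
    mask = np.asarray(roi_mask, dtype=bool)
    if not (s0_map.shape == adc_map.shape == mask.shape):
        raise ValueError("maps and ROI must share one shape")
    if not mask.any():
        raise ValueError("empty ROI")
    rows, cols = np.nonzero(mask)
    return pd.DataFrame({"row": rows, "col": cols,
                         "S0": s0_map[mask], "D": adc_map[mask]})
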