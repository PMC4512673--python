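"""Noise estimation and Rician-bias-corrected ADC fitting.

The apparent diffusion coefficient D is the decay constant of the
mono-exponential signal model S(b) = S0 * exp(-b * D).  Magnitude MR
images carry Rician noise, whose floor biases low-SNR intensities upward
and hence biases a plain least-squares D downward.  The fit therefore
maximises the Gaussian log-likelihood of the measured intensities around
a first-order bias-corrected model value

    f(b_k, D, S0) = sqrt( S0^2 * exp(-2 b_k D) + eta * sigma^2 ),

where sigma is the image noise standard deviation and eta a fixed
correction weight (theoretical value 1 for unsmoothed magnitude data;
smaller when the data have been spatially smoothed).  Maximising the
log-likelihood is minimising sum_k [I(b_k) - f(b_k, D, S0)]^2; the
additive normalisation constant of the likelihood plays no role.

Units: D is carried in 1e-5 mm^2/s (so liver tissue sits near D = 100)
and b in s/mm^2; the exponent is b * D * 1e-5.

sigma is estimated from the image itself: the second difference
(kernel 1, -2, 1) of a smooth signal is ~0, so in a tissue region the
second differences along x and y pool into a noise-dominated
distribution of variance 6 sigma^2; a robust width (1.4826 * MAD) of
that distribution divided by sqrt(6) estimates sigma without being
thrown off by edges or linear intensity ramps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .io_volumes import ROIMask

__all__ = [
    "NoiseEstimate",
    "ADCMap",
    "D_SCALE",
    "estimate_noise_sigma",
    "fit_adc_voxel",
    "fit_adc_map",
]

#: D is expressed in units of 1e-5 mm^2/s
D_SCALE = 1e-5

_D_MAX = 1000.0      # fit bound, 1e-5 mm^2/s


@dataclass
class NoiseEstimate:
    sigma: float
    region_voxels: int
    method_tag: str = "second-difference-mad"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class ADCMap:
    """Per-voxel D and S0 estimates over an ROI."""

    D: np.ndarray                  # 1e-5 mm^2/s; nan outside ROI
    S0: np.ndarray
    eta: float
    sigma: NoiseEstimate
    roi: ROIMask
    converged: np.ndarray          # bool per voxel

    def roi_values(self):
        """(D, S0) arrays over converged ROI voxels."""
        m = self.roi.mask & self.converged
        return self.D[m], self.S0[m]


def estimate_noise_sigma(image: np.ndarray, region: ROIMask) -> NoiseEstimate:
    """Estimate sigma from second differences inside a tissue region.

    Second differences annihilate constant and linear image structure,
    so their pooled x/y distribution in a reasonably smooth region is
    noise with variance 6 sigma^2.  The robust width 1.4826 * MAD of
    that distribution, divided by sqrt(6), is returned as sigma.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = region.mask
    if mask.shape != image.shape:
        raise ValueError("region mask must match image shape")
    rows = np.any(mask, axis=1).sum()
    cols = np.any(mask, axis=0).sum()
    if rows < 8 or cols < 8:
        raise ValueError("noise region must span at least 8x8 pixels")

    kernel = np.array([1.0, -2.0, 1.0])
    d2x = ndimage.correlate1d(image, kernel, axis=1, mode="nearest")
    d2y = ndimage.correlate1d(image, kernel, axis=0, mode="nearest")
    # keep only pixels whose 3-point stencil stays inside the region
    inner = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool),
                                   border_value=0)
    if not inner.any():
        raise ValueError("noise region empty after erosion")
    pooled = np.concatenate([d2x[inner], d2y[inner]])
    mad = np.median(np.abs(pooled - np.median(pooled)))
    sigma = 1.4826 * mad / np.sqrt(6.0)
    return NoiseEstimate(sigma=float(sigma), region_voxels=int(inner.sum()))


def _log_linear_init(signals, b_values):
    """Ordinary log-linear fit of log I vs b: starting values (D, S0)."""
    pos = signals > 0
    if pos.sum() < 2:
        return 0.0, max(float(signals.max()), 1e-6)
    coeffs = np.polyfit(b_values[pos], np.log(signals[pos]), 1)
    d0 = -coeffs[0] / D_SCALE
    s0 = float(np.exp(coeffs[1]))
    return float(np.clip(d0, 0.0, _D_MAX)), s0


def fit_adc_voxel(signals, b_values, sigma: float = 0.0, eta: float = 1.0):
    """Fit one voxel's multi-b signal; returns (D, S0, converged).

    Starting values come from an ordinary log-linear fit; a bounded
    trust-region least-squares refinement then minimises
    sum_k [I_k - f(b_k, D, S0)]^2 with the bias-corrected model f.
    D is bounded to [0, 1000] (1e-5 mm^2/s).  Negative inputs are
    clipped to 0 with a warning; an all-zero voxel is flagged
    non-converged, as is a non-positive fitted S0.
    """
    signals = np.asarray(signals, dtype=np.float64).ravel()
    b_values = np.asarray(b_values, dtype=np.float64).ravel()
    if signals.shape != b_values.shape or len(signals) < 2:
        raise ValueError("need >= 2 (signal, b) pairs of equal length")
    if np.any(b_values <= 0):
        raise ValueError("b-values must be positive")
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals must be finite")
    if np.any(signals < 0):
        warnings.warn("negative signals clipped to 0")
        signals = np.clip(signals, 0.0, None)
    if np.all(signals == 0):
        return 0.0, 0.0, False

    d0, s00 = _log_linear_init(signals, b_values)
    var_floor = eta * sigma ** 2

    def residuals(p):
        d, s0 = p
        f = np.sqrt(s0 ** 2 * np.exp(-2.0 * b_values * d * D_SCALE) + var_floor)
        return signals - f

    res = optimize.least_squares(
        residuals, x0=[d0, max(s00, 1e-6)],
        bounds=([0.0, 0.0], [_D_MAX, np.inf]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    d, s0 = res.x
    converged = bool(res.success) and s0 > 0
    return float(d), float(s0), converged


def fit_adc_map(slices, b_values, roi: ROIMask, sigma=None, eta: float = 1.0,
                noise_region: ROIMask = None) -> ADCMap:
    """Voxelwise ADC fit over an ROI from co-registered per-b slices.

    Parameters
    ----------
    slices : sequence of 2D arrays
        One aligned slice per b-value, co-registered.
    b_values : sequence of float
        Matching b-values, s/mm^2.
    roi : ROIMask
        Voxels to fit.
    sigma : float | NoiseEstimate, optional
        Noise level for the bias correction.  When omitted it is
        estimated from the lowest-b slice over ``noise_region`` (the ROI
        itself by default).
    eta : float
        Bias-correction weight; 1 for unsmoothed magnitude data.
    """
    slices = [np.asarray(s, dtype=np.float64) for s in slices]
    b_values = np.asarray(b_values, dtype=np.float64)
    if len(slices) != len(b_values):
        raise ValueError(
            f"{len(slices)} slices but {len(b_values)} b-values")
    shape = slices[0].shape
    if any(s.shape != shape for s in slices):
        raise ValueError("slices must share one shape")

    if sigma is None:
        k = int(np.argmin(b_values))
        sigma = estimate_noise_sigma(slices[k], noise_region or roi)
    if not isinstance(sigma, NoiseEstimate):
        sigma = NoiseEstimate(sigma=float(sigma), region_voxels=0,
                              method_tag="user-supplied")

    d_map = np.full(shape, np.nan)
    s0_map = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    stack = np.stack(slices, axis=0)
    rows, cols = np.nonzero(roi.mask)
    for r, c in zip(rows, cols):
        d, s0, ok = fit_adc_voxel(stack[:, r, c], b_values,
                                  sigma=sigma.sigma, eta=eta)
        d_map[r, c] = d
        s0_map[r, c] = s0
        conv[r, c] = ok
    return ADCMap(D=d_map, S0=s0_map, eta=eta, sigma=sigma, roi=roi,
                  converged=conv)
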