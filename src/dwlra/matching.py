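"""Gradient-based template matching with exhaustive integer-shift search.

Rather than comparing grey-level patches by least squares, the reference
and target patches are compared through their horizontal and vertical
gradient images.  For two scaled noisy patches I (target) and J
(reference) with scale factors satisfying alpha^2 + beta^2 = 1, the
chi-square matching cost reduces, via the substitution gamma = alpha/beta
= sqrt(B/A), to

    chi2 = (gamma^2 A + B - 2 gamma C) / (sigma^2 (1 + gamma^2))
         = 2 (B - gamma C) / (sigma^2 (1 + gamma^2)),

with A = sum I_n^2, B = sum J_n^2 and C = sum I_n J_n taken over both
gradient components inside the ROI.  B is constant when the reference is
held fixed and sigma does not vary during the search, so maximising the
cross term C is equivalent to minimising chi2; C alone is the matching
score.  Gradient patches make the score insensitive to absolute intensity
scaling, which matters when matching across b-values.

The search is exhaustive over integer in-plane shifts: there is no risk
of local optima and no interpolation is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GradientPatch",
    "MatchScore",
    "compute_gradients",
    "match_score",
    "exhaustive_search",
    "translate_int",
]

# central-difference kernel; radius 1 (correlate1d places index 0 at
# offset -1, so this computes (I[i+1] - I[i-1]) / 2)
_DIFF_KERNEL = np.array([-0.5, 0.0, 0.5])


@dataclass
class GradientPatch:
    """Horizontal/vertical gradient images restricted to an ROI.

    ``gx`` differentiates along columns (horizontal), ``gy`` along rows
    (vertical).  Sums in the matching score run only over ``roi``.
    """

    gx: np.ndarray
    gy: np.ndarray
    roi: np.ndarray

    def __post_init__(self):
        if not (self.gx.shape == self.gy.shape == self.roi.shape):
            raise ValueError("gx, gy and roi must share one shape")


@dataclass
class MatchScore:
    """Matching-score components for one candidate shift.

    ``C`` is the gradient cross term (higher is better), ``A`` and ``B``
    the target and reference gradient energies, ``gamma = sqrt(B/A)`` the
    single relative scale factor.  ``degenerate`` flags flat patches
    (A or B zero), for which C is defined as 0.
    """

    C: float
    A: float
    B: float
    gamma: float
    degenerate: bool = False


def compute_gradients(image: np.ndarray, roi: np.ndarray) -> GradientPatch:
    """Differentiate ``image`` and restrict the ROI to where the kernel fits.

    Central differences ([-1, 0, 1]/2) along each axis with edge
    replication at the image border; the ROI is eroded by the kernel
    radius (1 px, 8-connected) so no replicated border value enters any
    matching sum.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2D and at least 3x3")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError("roi shape must match image shape")
    gx = ndimage.correlate1d(image, _DIFF_KERNEL, axis=1, mode="nearest")
    gy = ndimage.correlate1d(image, _DIFF_KERNEL, axis=0, mode="nearest")
    eroded = ndimage.binary_erosion(roi, structure=np.ones((3, 3), bool),
                                    border_value=0)
    if not eroded.any():
        raise ValueError("ROI is empty after erosion by the kernel radius")
    return GradientPatch(gx=gx, gy=gy, roi=eroded)


def match_score(ref: GradientPatch, tgt: GradientPatch) -> MatchScore:
    """Score a target gradient patch against the reference patch.

    C = sum_roi (gx_ref * gx_tgt + gy_ref * gy_tgt); A and B are the
    gradient energies of target and reference.  |C| <= sqrt(A B) by
    Cauchy-Schwarz.
    """
    if ref.roi.shape != tgt.roi.shape:
        raise ValueError("reference and target patches must share one shape")
    roi = ref.roi
    a = float(np.sum(tgt.gx[roi] ** 2 + tgt.gy[roi] ** 2))
    b = float(np.sum(ref.gx[roi] ** 2 + ref.gy[roi] ** 2))
    if a == 0.0 or b == 0.0:
        return MatchScore(C=0.0, A=a, B=b, gamma=0.0, degenerate=True)
    c = float(np.sum(ref.gx[roi] * tgt.gx[roi] + ref.gy[roi] * tgt.gy[roi]))
    return MatchScore(C=c, A=a, B=b, gamma=float(np.sqrt(b / a)))


def translate_int(image: np.ndarray, d_row: int, d_col: int) -> np.ndarray:
    """Translate a 2D array by integer offsets with edge replication.

    Content moves by (+d_row, +d_col): output[r, c] = input[r - d_row,
    c - d_col].  No interpolation is performed.
    """
    out = np.asarray(image, dtype=np.float64)
    if d_row:
        pad = ((d_row, 0), (0, 0)) if d_row > 0 else ((0, -d_row), (0, 0))
        out = np.pad(out, pad, mode="edge")
        out = out[: image.shape[0]] if d_row > 0 else out[-image.shape[0]:]
    if d_col:
        pad = ((0, 0), (d_col, 0)) if d_col > 0 else ((0, 0), (0, -d_col))
        out = np.pad(out, pad, mode="edge")
        out = out[:, : image.shape[1]] if d_col > 0 else out[:, -image.shape[1]:]
    return out


def _tie_key(shift):
    d_row, d_col = shift
    return (d_row * d_row + d_col * d_col, shift)


def exhaustive_search(ref: GradientPatch, target_slice: np.ndarray,
                      roi: np.ndarray, max_shift: int = 3,
                      shifts=None):
    """Score every candidate in-plane shift of the target against the reference.

    The reference ROI stays fixed; the target is sampled through windows
    translated by each candidate shift, so the winning shift is the
    motion of the target relative to the reference.  With the default
    ``max_shift=3`` the search covers 7 x 7 = 49 shifts.

    Parameters
    ----------
    ref : GradientPatch
        Gradients of the reference slice (ROI already eroded).
    target_slice : 2D array
        Candidate slice to match.
    roi : 2D bool array
        The same ROI used to build ``ref`` (un-eroded).
    max_shift : int
        Half-width of the square search window.
    shifts : iterable of (d_row, d_col), optional
        Restrict the search to these shifts (used by the constrained
        movement space); all must satisfy the max_shift limit.

    Returns
    -------
    list of ((d_row, d_col), MatchScore)
        In row-major order over shifts; ``best_shift`` picks the argmax.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if shifts is None:
        shifts = [(dr, dc)
                  for dr in range(-max_shift, max_shift + 1)
                  for dc in range(-max_shift, max_shift + 1)]
    else:
        shifts = sorted(set((int(dr), int(dc)) for dr, dc in shifts))
        bad = [s for s in shifts if max(abs(s[0]), abs(s[1])) > max_shift]
        if bad:
            raise ValueError(f"shifts outside the +-{max_shift} limit: {bad}")

    target_slice = np.asarray(target_slice, dtype=np.float64)
    rows, cols = np.nonzero(ref.roi)
    nr, nc = target_slice.shape
    # gradient of an integer-translated image equals the translated
    # gradient away from the border, and the eroded ROI plus the bounds
    # check below keep every sample in-bounds
    gx_t = ndimage.correlate1d(target_slice, _DIFF_KERNEL, axis=1, mode="nearest")
    gy_t = ndimage.correlate1d(target_slice, _DIFF_KERNEL, axis=0, mode="nearest")
    gx_r = ref.gx[ref.roi]
    gy_r = ref.gy[ref.roi]
    b = float(np.sum(gx_r ** 2 + gy_r ** 2))

    results = []
    for dr, dc in shifts:
        rr, cc = rows + dr, cols + dc
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= nr or cc.max() >= nc:
            raise ValueError(
                f"shifted window out of bounds for shift ({dr}, {dc})")
        tx, ty = gx_t[rr, cc], gy_t[rr, cc]
        a = float(np.sum(tx ** 2 + ty ** 2))
        if a == 0.0 or b == 0.0:
            score = MatchScore(C=0.0, A=a, B=b, gamma=0.0, degenerate=True)
        else:
            c = float(np.sum(gx_r * tx + gy_r * ty))
            score = MatchScore(C=c, A=a, B=b, gamma=float(np.sqrt(b / a)))
        results.append(((dr, dc), score))
    return results


def best_shift(results):
    """Argmax of the cross term C; ties resolved by smallest Euclidean
    shift magnitude, then row-major order."""
    top_c = max(e[1].C for e in results)
    tied = [e for e in results if e[1].C == top_c]
    tied.sort(key=lambda e: _tie_key(e[0]))
    return tied[0]
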