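"""Local-rigid alignment (LRA) of repeat DW-MR acquisitions.

The aligner works one slice position at a time.  A reference slice is
taken from the lowest b-value image (best SNR).  For each b-value and
gradient direction, every repeat acquisition contributes 5 candidate
z-slices (the central slice and 2 either side); each candidate is matched
against the reference over a 7 x 7 grid of integer in-plane shifts (49
cases), i.e. 20 candidate slices per direction.  Per repeat, the best
odd-parity and best even-parity candidates are kept (8 per direction,
honouring the interleaved acquisition's two respiratory phase groups) and
the best 4 of those 8 survive.  The 4 x 3 directions = 12 selected
slices, each translated in-plane by the negative of its recovered shift
(integer translation, no interpolation), are averaged into one aligned
slice per b-value.

Because all acquisitions share the same underlying cyclic respiratory
motion, the 12 recovered 3D shifts of the reference b-value closely
follow a line in shift space.  A robust line fit (orthogonal regression
with Tukey biweight reweighting) to those shifts defines a constrained
movement space --- the lattice points within Chebyshev distance 1 of the
line --- which restricts the search for the noisier non-reference
b-values.  The full movement space is 7 x 7 x 5 = 245 lattice points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_volumes import DWSeries
from .matching import (GradientPatch, MatchScore, best_shift,
                       compute_gradients, exhaustive_search, translate_int)

__all__ = [
    "ShiftHypothesis",
    "MotionLine",
    "AlignedBValueSlice",
    "LRAResult",
    "DEFAULT_LIMITS",
    "select_reference",
    "enumerate_candidates",
    "select_best_per_direction",
    "fit_motion_line",
    "constrain_search_space",
    "full_movement_space",
    "align_bvalue",
    "run_lra",
]

#: (max in-plane shift, max slice offset): 7 x 7 x 5 = 245 movement combinations
DEFAULT_LIMITS = (3, 2)


@dataclass
class ShiftHypothesis:
    """One candidate alignment: a 3D integer shift with its matching score."""

    shift3d: tuple                 # (d_row, d_col, d_slice)
    score: MatchScore
    b_value: float
    direction: str
    repeat: int
    source_slice_index: int
    parity: str = field(init=False)  # z-parity of the source slice

    def __post_init__(self):
        self.parity = "odd" if self.source_slice_index % 2 else "even"


@dataclass
class MotionLine:
    """Robust 3D line through recovered shifts: point + unit direction."""

    point: np.ndarray
    direction: np.ndarray          # None when degenerate (all shifts equal)
    inlier_count: int
    residual_rms: float
    degenerate: bool = False


@dataclass
class AlignedBValueSlice:
    """Average of the 12 selected shifted slices for one b-value."""

    image: np.ndarray
    b_value: float
    contributors: list             # 12 ShiftHypothesis (4 per direction)


@dataclass
class LRAResult:
    """Output of the full per-slice alignment."""

    aligned: list                  # AlignedBValueSlice, in b order
    motion_line: MotionLine
    constraint: set                # shift3d lattice used for non-reference b
    reference_b: float


def _rank_key(h: ShiftHypothesis):
    """Sort key: best score first; ties by smallest shift, then repeat order."""
    return (-h.score.C, sum(v * v for v in h.shift3d), h.repeat, h.shift3d)


def select_reference(series: DWSeries, slice_index: int, direction=None,
                     repeat: int = 1) -> np.ndarray:
    """Return the reference slice: lowest b-value, given direction/repeat.

    The lowest b-value image has the best SNR and anchors the whole
    alignment; the gradient direction used for the reference is
    configurable (first direction label by default).
    """
    b_ref = min(series.b_values)
    if direction is None:
        direction = series.directions[0]
    return series.get_slice(b_ref, direction, repeat, slice_index).copy()


def enumerate_candidates(series: DWSeries, b, direction, center_slice: int,
                         roi: np.ndarray, ref_patch: GradientPatch,
                         limits=DEFAULT_LIMITS, constraint=None):
    """Best shift hypothesis for each (repeat, candidate z-slice).

    With the default limits this scores 4 repeats x 5 z-candidates x 49
    in-plane shifts and returns 20 hypotheses, each the argmax of its 49
    (fewer when a constraint set excludes a z-offset entirely).
    """
    max_shift, max_dz = limits
    n_slices = series.n_slices
    if center_slice < max_dz or center_slice > n_slices - 1 - max_dz:
        raise ValueError(
            f"center_slice {center_slice} too close to the volume edge for "
            f"+-{max_dz} candidate slices (valid range "
            f"[{max_dz}, {n_slices - 1 - max_dz}])")

    by_dz = None
    if constraint is not None:
        by_dz = {}
        for dr, dc, ds in constraint:
            by_dz.setdefault(int(ds), set()).add((int(dr), int(dc)))

    hypotheses = []
    for repeat in series.repeats:
        for dz in range(-max_dz, max_dz + 1):
            if by_dz is not None and dz not in by_dz:
                continue
            shifts = None if by_dz is None else by_dz[dz]
            z = center_slice + dz
            target = series.get_slice(b, direction, repeat, z)
            results = exhaustive_search(ref_patch, target, roi,
                                        max_shift=max_shift, shifts=shifts)
            (dr, dc), score = best_shift(results)
            hypotheses.append(ShiftHypothesis(
                shift3d=(dr, dc, dz), score=score, b_value=b,
                direction=direction, repeat=repeat, source_slice_index=z))
    return hypotheses


def select_best_per_direction(candidates):
    """Reduce one direction's candidates to its 4 contributing slices.

    Per repeat, the best odd-parity and best even-parity hypotheses are
    kept (one respiratory phase sample from each interleave block: 8 from
    4 repeats); the 4 highest-scoring of those 8 are returned.  Both
    survivors may come from the same repeat.
    """
    kept = []
    repeats = sorted({h.repeat for h in candidates})
    for repeat in repeats:
        for parity in ("odd", "even"):
            group = [h for h in candidates
                     if h.repeat == repeat and h.parity == parity]
            if not group:
                warnings.warn(
                    f"repeat {repeat} has no {parity}-parity candidate; "
                    "selection proceeds with fewer than 8")
                continue
            kept.append(min(group, key=_rank_key))
    kept.sort(key=_rank_key)
    return kept[:4]


def _pca_line(pts, w=None):
    if w is None:
        w = np.ones(len(pts))
    centroid = np.average(pts, axis=0, weights=w)
    centered = (pts - centroid) * np.sqrt(w)[:, None]
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[0]


def _ortho_dist(pts, centroid, direction):
    v = pts - centroid
    ortho = v - np.outer(v @ direction, direction)
    return np.linalg.norm(ortho, axis=1)


def fit_motion_line(shifts, n_iter: int = 3, tukey_c: float = 4.685,
                    max_trim: int = 2) -> MotionLine:
    """Robust 3D line through shift points via reweighted orthogonal regression.

    A plain principal axis is badly leveraged by a single wild shift at
    the end of the point cloud, and iterative reweighting started from
    it can stay stuck on the tilted solution.  The fit therefore
    initialises by exhaustive trimming --- the principal axis of every
    leave-d-out subset (d <= ``max_trim``), scored by the median
    orthogonal residual over all points --- and then refines with
    ``n_iter`` Tukey-biweight reweightings of the orthogonal residuals
    within the kept subset (integer rounding of the shifts makes the
    inlier scatter coarse, so a trimmed point is not re-admitted).
    Everything is deterministic; no random sampling at these small n.
    Degenerate input (all points identical) yields a flagged line with
    undefined direction.
    """
    pts = np.asarray(shifts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least 2 three-dimensional shift points")
    if np.allclose(pts, pts[0]):
        return MotionLine(point=pts[0].copy(), direction=None,
                          inlier_count=len(pts), residual_rms=0.0,
                          degenerate=True)

    n = len(pts)
    from itertools import combinations
    best = None
    for d in range(0, min(max_trim, n - 2) + 1):
        for excl in combinations(range(n), d):
            keep = np.ones(n, bool)
            keep[list(excl)] = False
            sub = pts[keep]
            if np.allclose(sub, sub[0]):
                continue
            c0, u0 = _pca_line(sub)
            crit = float(np.median(_ortho_dist(pts, c0, u0)))
            # ties resolved toward fewer exclusions (d ascending), then
            # lexicographic exclusion order
            if best is None or crit < best[0] - 1e-12:
                best = (crit, keep)
    keep = best[1]
    w = keep.astype(float)

    for _ in range(n_iter):
        centroid, direction = _pca_line(pts, w)
        r = _ortho_dist(pts, centroid, direction)
        # robust scale of the kept points' orthogonal distances (they
        # centre on 0 for points on the line)
        scale = 1.4826 * np.median(r[keep])
        if scale <= 0:
            # kept points lie exactly on the line: done
            break
        u = r / (tukey_c * scale)
        w = keep * np.where(u < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if w.sum() < 2 or np.count_nonzero(w) < 2:
            w = keep.astype(float)
            break

    # final refit with the converged weights
    centroid, direction = _pca_line(pts, w)
    # deterministic orientation: largest-magnitude component positive
    k = int(np.argmax(np.abs(direction)))
    if direction[k] < 0:
        direction = -direction
    resid = pts - centroid
    ortho = resid - np.outer(resid @ direction, direction)
    r = np.linalg.norm(ortho, axis=1)
    inliers = w > 0
    return MotionLine(point=centroid, direction=direction / np.linalg.norm(direction),
                      inlier_count=int(inliers.sum()),
                      residual_rms=float(np.sqrt(np.mean(r[inliers] ** 2))))


def full_movement_space(limits=DEFAULT_LIMITS):
    """The unconstrained shift lattice: 7 x 7 x 5 = 245 points by default."""
    max_shift, max_dz = limits
    return {(dr, dc, ds)
            for dr in range(-max_shift, max_shift + 1)
            for dc in range(-max_shift, max_shift + 1)
            for ds in range(-max_dz, max_dz + 1)}


def constrain_search_space(line: MotionLine, limits=DEFAULT_LIMITS):
    """Lattice points within Chebyshev distance 1 of the motion line.

    Each lattice point is projected orthogonally onto the line, the
    projection is clipped to the limits box, and the point is kept when
    its Chebyshev distance to that clipped projection is <= 1 ("all
    immediate neighbouring pixels of the line").  A degenerate line keeps
    the full space.
    """
    space = full_movement_space(limits)
    if line.degenerate or line.direction is None:
        return space
    max_shift, max_dz = limits
    lo = np.array([-max_shift, -max_shift, -max_dz], dtype=float)
    hi = -lo
    p0 = np.asarray(line.point, dtype=float)
    u = np.asarray(line.direction, dtype=float)
    subset = set()
    for pt in space:
        p = np.asarray(pt, dtype=float)
        proj = p0 + ((p - p0) @ u) * u
        proj = np.clip(proj, lo, hi)
        if np.max(np.abs(p - proj)) <= 1.0 + 1e-12:
            subset.add(pt)
    if not subset:        # cannot happen for a line meeting the box, but be safe
        subset = space
    return subset


def align_bvalue(series: DWSeries, b, roi: np.ndarray, center_slice: int,
                 constraint=None, ref_direction=None, ref_repeat: int = 1,
                 limits=DEFAULT_LIMITS) -> AlignedBValueSlice:
    """Produce the average aligned slice for one b-value.

    The 12 selected hypotheses' source slices are each translated
    in-plane by the negative of their recovered shift onto the reference
    frame and voxelwise averaged.  The slice offset is used for slice
    selection only; no through-plane resampling occurs.
    """
    ref_slice = select_reference(series, center_slice, ref_direction, ref_repeat)
    ref_patch = compute_gradients(ref_slice, roi)

    contributors = []
    for direction in series.directions:
        cands = enumerate_candidates(series, b, direction, center_slice, roi,
                                     ref_patch, limits=limits,
                                     constraint=constraint)
        contributors.extend(select_best_per_direction(cands))

    stack = []
    for h in contributors:
        src = series.get_slice(b, h.direction, h.repeat, h.source_slice_index)
        dr, dc, _ = h.shift3d
        stack.append(translate_int(src, -dr, -dc))
    return AlignedBValueSlice(image=np.mean(stack, axis=0), b_value=b,
                              contributors=contributors)


def run_lra(series: DWSeries, roi: np.ndarray, center_slice: int,
            ref_direction=None, ref_repeat: int = 1,
            limits=DEFAULT_LIMITS) -> LRAResult:
    """Full local-rigid alignment for one slice position.

    The lowest b-value is aligned over the full movement space; the line
    fitted to its 12 selected shifts constrains the search space for the
    remaining b-values.  Returns one aligned slice per b-value, ready for
    ADC fitting.
    """
    b_ref = min(series.b_values)
    aligned_ref = align_bvalue(series, b_ref, roi, center_slice,
                               constraint=None, ref_direction=ref_direction,
                               ref_repeat=ref_repeat, limits=limits)
    line = fit_motion_line([h.shift3d for h in aligned_ref.contributors])
    constraint = constrain_search_space(line, limits)

    aligned = [aligned_ref]
    for b in series.b_values:
        if b == b_ref:
            continue
        aligned.append(align_bvalue(series, b, roi, center_slice,
                                    constraint=constraint,
                                    ref_direction=ref_direction,
                                    ref_repeat=ref_repeat, limits=limits))
    aligned.sort(key=lambda a: a.b_value)
    return LRAResult(aligned=aligned, motion_line=line,
                     constraint=constraint, reference_b=b_ref)
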