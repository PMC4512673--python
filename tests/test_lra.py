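import numpy as np
import pytest

from dwlra.lra import (DEFAULT_LIMITS, MotionLine, align_bvalue,
                       constrain_search_space, enumerate_candidates,
                       fit_motion_line, full_movement_space, run_lra,
                       select_best_per_direction, select_reference)
from dwlra.matching import compute_gradients
from dwlra.phantom import PhantomSpec, simulate_acquisition
from dwlra.pipeline import matching_roi

from .conftest import CENTER, angle_deg, reference_relative_shifts


class TestSelectReference:
    def test_reference_from_lowest_b(self, noiseless_phantom):
        _, series, _ = noiseless_phantom
        ref = select_reference(series, CENTER)
        np.testing.assert_array_equal(
            ref, series.get_slice(100.0, "-x", 1, CENTER))

    def test_out_of_range_slice(self, noiseless_phantom):
        _, series, _ = noiseless_phantom
        with pytest.raises(Exception):
            select_reference(series, 99)


class TestEnumerateCandidates:
    def test_20_candidates_default(self, noiseless_phantom):
        _, series, truth = noiseless_phantom
        roi = matching_roi(truth.adc_map, CENTER)
        ref = compute_gradients(select_reference(series, CENTER), roi.mask)
        cands = enumerate_candidates(series, 100.0, "-x", CENTER, roi.mask, ref)
        assert len(cands) == 20                       # 4 repeats x 5 z
        assert {h.repeat for h in cands} == {1, 2, 3, 4}
        assert {h.shift3d[2] for h in cands} == {-2, -1, 0, 1, 2}

    def test_single_repeat_zero_zrange(self):
        spec = PhantomSpec(n_repeats=1, noise_sigma=0.0, motion_amplitude=0.0)
        series, truth = simulate_acquisition(spec)
        roi = matching_roi(truth.adc_map, CENTER)
        ref = compute_gradients(select_reference(series, CENTER), roi.mask)
        cands = enumerate_candidates(series, 100.0, "-x", CENTER, roi.mask,
                                     ref, limits=(3, 0))
        assert len(cands) == 1 and cands[0].shift3d == (0, 0, 0)

    def test_edge_slice_rejected(self, noiseless_phantom):
        _, series, truth = noiseless_phantom
        roi = matching_roi(truth.adc_map, CENTER)
        ref = compute_gradients(select_reference(series, 1), roi.mask)
        with pytest.raises(ValueError, match="edge"):
            enumerate_candidates(series, 100.0, "-x", 1, roi.mask, ref)

    def test_parity_matches_source_slice(self, noiseless_phantom):
        _, series, truth = noiseless_phantom
        roi = matching_roi(truth.adc_map, CENTER)
        ref = compute_gradients(select_reference(series, CENTER), roi.mask)
        for h in enumerate_candidates(series, 100.0, "y", CENTER, roi.mask, ref):
            expected = "odd" if h.source_slice_index % 2 else "even"
            assert h.parity == expected


class TestSelectBestPerDirection:
    def _mk(self, repeat, z, score_c, shift=(0, 0)):
        from dwlra.lra import ShiftHypothesis
        from dwlra.matching import MatchScore
        return ShiftHypothesis(shift3d=(shift[0], shift[1], z - CENTER),
                               score=MatchScore(C=score_c, A=1, B=1, gamma=1),
                               b_value=100.0, direction="-x", repeat=repeat,
                               source_slice_index=z)

    def test_8_then_4(self):
        cands = [self._mk(r, CENTER + dz, 10 * r + dz)
                 for r in (1, 2, 3, 4) for dz in (-2, -1, 0, 1, 2)]
        best = select_best_per_direction(cands)
        assert len(best) == 4
        # per repeat the best odd/even survive; overall top-4 by score
        scores = sorted((h.score.C for h in best), reverse=True)
        per_parity_best = []
        for r in (1, 2, 3, 4):
            for par in ("odd", "even"):
                grp = [c for c in cands if c.repeat == r and c.parity == par]
                per_parity_best.append(max(c.score.C for c in grp))
        assert scores == sorted(per_parity_best, reverse=True)[:4]

    def test_equal_scores_tiebreak_smallest_shift_then_repeat(self):
        cands = [self._mk(1, CENTER, 5.0, shift=(2, 2)),
                 self._mk(1, CENTER + 1, 5.0, shift=(0, 1)),
                 self._mk(2, CENTER, 5.0, shift=(0, 0)),
                 self._mk(2, CENTER + 1, 5.0, shift=(3, 3))]
        best = select_best_per_direction(cands)
        assert best[0].shift3d == (0, 0, 0)           # smallest |shift|
        assert best[1].shift3d == (0, 1, 1)

    def test_strictly_ordered_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(20).astype(float)
        cands = [self._mk(r, CENTER + dz, scores[i])
                 for i, (r, dz) in enumerate(
                     (r, dz) for r in (1, 2, 3, 4) for dz in (-2, -1, 0, 1, 2))]
        best = select_best_per_direction(cands)
        # oracle: brute-force reduction
        pool = []
        for r in (1, 2, 3, 4):
            for par in ("odd", "even"):
                grp = [c for c in cands if c.repeat == r and c.parity == par]
                pool.append(max(grp, key=lambda h: h.score.C))
        expected = sorted(pool, key=lambda h: -h.score.C)[:4]
        assert [h.score.C for h in best] == [h.score.C for h in expected]

    def test_missing_parity_warns_and_continues(self):
        cands = [self._mk(1, CENTER, 1.0)]            # even only
        with pytest.warns(UserWarning, match="odd"):
            best = select_best_per_direction(cands)
        assert len(best) == 1


class TestFitMotionLine:
    def test_collinear_points(self):
        line = fit_motion_line([(0, 0, 0), (1, 1, 0), (2, 2, 0)])
        np.testing.assert_allclose(np.abs(line.direction),
                                   [1 / np.sqrt(2), 1 / np.sqrt(2), 0],
                                   atol=1e-12)
        assert line.residual_rms < 1e-9

    def test_outlier_rejected(self):
        pts = [(i, i, 0) for i in range(11)] + [(0, 8, 5)]
        line = fit_motion_line(pts)
        assert angle_deg(line.direction, (1, 1, 0)) < 5.0

    def test_two_points_exact(self):
        line = fit_motion_line([(0, 0, 0), (3, 1, 2)])
        assert angle_deg(line.direction, (3, 1, 2)) < 1e-9

    def test_identical_points_degenerate(self):
        line = fit_motion_line([(1, 1, 1)] * 5)
        assert line.degenerate and line.direction is None

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_motion_line([(0, 0, 0)])


class TestConstrainSearchSpace:
    def test_full_space_245(self):
        assert len(full_movement_space()) == 7 * 7 * 5

    def test_axis_aligned_line_63_points(self):
        line = MotionLine(point=np.zeros(3), direction=np.array([1.0, 0, 0]),
                          inlier_count=12, residual_rms=0.0)
        subset = constrain_search_space(line)
        expected = {(dr, dc, ds) for dr in range(-3, 4)
                    for dc in (-1, 0, 1) for ds in (-1, 0, 1)}
        assert subset == expected
        assert len(subset) == 63

    def test_subset_contains_line_lattice_points(self):
        d = np.array([2.0, 1.0, 1.0])
        line = MotionLine(point=np.zeros(3), direction=d / np.linalg.norm(d),
                          inlier_count=12, residual_rms=0.0)
        subset = constrain_search_space(line)
        full = full_movement_space()
        assert subset <= full
        assert (0, 0, 0) in subset and (2, 1, 1) in subset and (-2, -1, -1) in subset

    def test_degenerate_line_keeps_full_space(self):
        line = MotionLine(point=np.zeros(3), direction=None, inlier_count=5,
                          residual_rms=0.0, degenerate=True)
        assert constrain_search_space(line) == full_movement_space()


class TestAlignAndRun:
    def test_12_contributors_per_bvalue(self, noiseless_lra):
        *_, result = noiseless_lra
        for a in result.aligned:
            assert len(a.contributors) == 12
            for d in ("-x", "y", "z"):
                assert sum(h.direction == d for h in a.contributors) == 4

    def test_three_aligned_slices(self, noiseless_lra):
        *_, result = noiseless_lra
        assert [a.b_value for a in result.aligned] == [100.0, 500.0, 900.0]
        assert result.reference_b == 100.0

    def test_noiseless_recovery_exact_where_parity_allows(self, noiseless_lra):
        spec, series, truth, result = noiseless_lra
        rel = reference_relative_shifts(series, truth)
        reachable = exact = 0
        for a in result.aligned:
            for h in a.contributors:
                t = tuple(int(x) for x in
                          rel[(h.b_value, h.direction, h.repeat, h.parity)])
                if (CENTER + t[2]) % 2 == (1 if h.parity == "odd" else 0):
                    reachable += 1
                    exact += h.shift3d == t
        assert reachable > 0 and exact == reachable

    def test_constraint_respected(self, noiseless_lra):
        *_, result = noiseless_lra
        for a in result.aligned:
            if a.b_value == result.reference_b:
                continue
            for h in a.contributors:
                assert h.shift3d in result.constraint

    def test_full_constraint_equals_unconstrained(self, noiseless_phantom):
        _, series, truth = noiseless_phantom
        roi = matching_roi(truth.adc_map, CENTER)
        free = align_bvalue(series, 500.0, roi.mask, CENTER)
        constrained = align_bvalue(series, 500.0, roi.mask, CENTER,
                                   constraint=full_movement_space())
        np.testing.assert_array_equal(free.image, constrained.image)
        assert ([h.shift3d for h in free.contributors]
                == [h.shift3d for h in constrained.contributors])

    def test_zero_motion_idempotent(self):
        spec = PhantomSpec(noise_sigma=0.0, motion_amplitude=0.0)
        series, truth = simulate_acquisition(spec)
        roi = matching_roi(truth.adc_map, CENTER)
        result = run_lra(series, roi.mask, CENTER)
        for a in result.aligned:
            assert all(h.shift3d == (0, 0, 0) for h in a.contributors)
        assert result.motion_line.degenerate
        assert result.constraint == full_movement_space()

    def test_motion_line_recovery(self, noiseless_lra):
        spec, series, truth, result = noiseless_lra
        rel = reference_relative_shifts(series, truth)
        true_line = fit_motion_line(np.array(list(rel.values()), float))
        assert angle_deg(result.motion_line.direction,
                         true_line.direction) <= 5.0

    def test_aligned_matches_reference_pattern_noiseless(self, noiseless_lra):
        # after alignment, the b=100 average should be much closer to the
        # reference slice than the motion-blurred plain average is
        spec, series, truth, result = noiseless_lra
        from dwlra.phantom import average_protocol_a
        ref = select_reference(series, CENTER)
        roi = matching_roi(truth.adc_map, CENTER).mask
        aligned = result.aligned[0].image
        avg = average_protocol_a(series)[100.0][:, :, CENTER]
        err_aligned = np.abs(aligned - ref)[roi].mean()
        err_avg = np.abs(avg - ref)[roi].mean()
        assert err_aligned < 0.5 * err_avg
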