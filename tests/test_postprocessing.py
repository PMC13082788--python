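"""Trajectory assembly: identity enforcement, jump correction, interpolation."""

import numpy as np
import pytest

from pairtrack import (
    correct_impossible_jumps,
    enforce_fragment_identity,
    interpolate_crossings,
)
from pairtrack.fragments import CrossingRun
from pairtrack.postprocess import DETECTED, INTERPOLATED, MISSING, TrajectorySet


def make_traj(positions, probabilities=None, fragment_map=None):
    positions = np.asarray(positions, dtype=float)
    n, t = positions.shape[:2]
    prov = np.where(np.isnan(positions[:, :, 0]), MISSING, DETECTED).astype(np.int8)
    probs = probabilities if probabilities is not None else np.where(
        prov == DETECTED, 1.0, 0.0
    )
    return TrajectorySet(
        positions=positions,
        probabilities=np.asarray(probs, dtype=float),
        provenance=prov,
        fragment_map=fragment_map,
    )


class TestEnforceFragmentIdentity:
    def test_minority_disagreement_overwritten_and_counted(self):
        ids, n = enforce_fragment_identity(1, np.array([1, 1, 2, 1]))
        assert ids.tolist() == [1, 1, 1, 1]
        assert n == 1

    def test_consistent_images_unchanged(self):
        ids, n = enforce_fragment_identity(2, np.array([2, 2, 2]))
        assert ids.tolist() == [2, 2, 2]
        assert n == 0

    def test_single_image_fragment_trivial(self):
        ids, n = enforce_fragment_identity(0, np.array([0]))
        assert ids.tolist() == [0] and n == 0


class TestCorrectImpossibleJumps:
    def test_smooth_trajectories_untouched(self):
        t = np.arange(50, dtype=float)
        pos = np.stack(
            [np.stack([t, t], axis=1), np.stack([100 - t, 100 + 0 * t], axis=1)]
        )
        traj = make_traj(pos)
        out = correct_impossible_jumps(traj, 4.0)
        assert np.array_equal(out.positions, traj.positions, equal_nan=True)
        assert all(not v for v in out.corrections["jump_frames"].values())

    def test_swap_at_crossing_detected_for_both_identities(self):
        """Two straight walkers whose identities swap mid-way: the swap frame
        shows an impossible displacement on both rows."""
        t = np.arange(60, dtype=float)
        a = np.stack([t, np.zeros(60)], axis=1)           # moves right along y=0
        b = np.stack([t, np.full(60, 40.0)], axis=1)      # parallel at y=40
        pos = np.stack([a.copy(), b.copy()])
        pos[0, 30:], pos[1, 30:] = b[30:].copy(), a[30:].copy()   # swap
        traj = make_traj(pos)
        out = correct_impossible_jumps(traj, 4.0)
        assert 30 in out.corrections["jump_frames"][0]
        assert 30 in out.corrections["jump_frames"][1]

    def test_swapped_fragments_reassigned_back(self):
        t = np.arange(60, dtype=float)
        a = np.stack([t, np.zeros(60)], axis=1)
        b = np.stack([t, np.full(60, 40.0)], axis=1)
        pos = np.stack([a.copy(), b.copy()])
        pos[0, 30:], pos[1, 30:] = b[30:].copy(), a[30:].copy()
        fmap = np.zeros((2, 60), dtype=np.int64)
        fmap[0, :30], fmap[0, 30:] = 0, 2
        fmap[1, :30], fmap[1, 30:] = 1, 3
        traj = make_traj(pos, fragment_map=fmap)
        out = correct_impossible_jumps(traj, 4.0)
        assert np.allclose(out.positions[0], a)
        assert np.allclose(out.positions[1], b)

    def test_single_frame_trajectory_degenerate_untouched(self):
        pos = np.full((2, 5, 2), np.nan)
        pos[0, 2] = (1.0, 1.0)
        traj = make_traj(pos)
        out = correct_impossible_jumps(traj, 4.0)
        assert np.array_equal(out.positions, pos, equal_nan=True)


class TestInterpolateCrossings:
    def test_linear_fill_between_anchors(self):
        pos = np.full((1, 14, 2), np.nan)
        for f in range(10):
            pos[0, f] = (f, f) if f != 9 else (0.0, 0.0)
        pos[0, 9] = (0.0, 0.0)
        pos[0, 12] = (10.0, 10.0)
        pos[0, 13] = (10.0, 10.0)
        traj = make_traj(pos)
        runs = [CrossingRun(start_frame=10, end_frame=12, blobs=[])]
        out = interpolate_crossings(traj, runs)
        assert out.positions[0, 10] == pytest.approx([10 / 3, 10 / 3])
        assert out.positions[0, 11] == pytest.approx([20 / 3, 20 / 3])
        assert out.provenance[0, 10] == INTERPOLATED
        assert out.provenance[0, 11] == INTERPOLATED

    def test_interpolated_probability_is_min_of_anchors(self):
        pos = np.full((1, 5, 2), np.nan)
        pos[0, 0] = (0.0, 0.0)
        pos[0, 4] = (4.0, 0.0)
        probs = np.zeros((1, 5))
        probs[0, 0], probs[0, 4] = 0.9, 0.6
        traj = make_traj(pos, probabilities=probs)
        out = interpolate_crossings(traj, [CrossingRun(1, 4, [])])
        assert out.probabilities[0, 2] == pytest.approx(0.6)

    def test_adjacent_anchors_leave_nothing_to_fill(self):
        pos = np.full((1, 4, 2), np.nan)
        pos[0, 1] = (0.0, 0.0)
        pos[0, 2] = (1.0, 0.0)
        traj = make_traj(pos)
        out = interpolate_crossings(traj, [CrossingRun(0, 4, [])])
        assert np.array_equal(out.positions, pos, equal_nan=True)

    def test_identity_absent_after_crossing_stays_missing(self):
        pos = np.full((1, 10, 2), np.nan)
        pos[0, :4, 0] = np.arange(4)
        pos[0, :4, 1] = 0.0
        traj = make_traj(pos)
        out = interpolate_crossings(traj, [CrossingRun(4, 6, [])])
        assert np.isnan(out.positions[0, 4:]).all()

    def test_gap_without_crossing_run_not_interpolated(self):
        pos = np.full((1, 10, 2), np.nan)
        pos[0, 0] = (0.0, 0.0)
        pos[0, 9] = (9.0, 0.0)
        traj = make_traj(pos)
        out = interpolate_crossings(traj, [])
        assert np.isnan(out.positions[0, 1:9]).all()

    def test_interpolated_points_are_convex_combinations(self, fitted_results):
        traj = fitted_results.trajectories
        for i in range(traj.n_animals):
            interp = np.flatnonzero(traj.provenance[i] == INTERPOLATED)
            for f in interp:
                before = np.flatnonzero(traj.provenance[i, :f] == DETECTED)
                after = f + 1 + np.flatnonzero(traj.provenance[i, f + 1:] == DETECTED)
                assert before.size and after.size
                p0 = traj.positions[i, before[-1]]
                p1 = traj.positions[i, after[0]]
                lo = np.minimum(p0, p1) - 1e-9
                hi = np.maximum(p0, p1) + 1e-9
                assert (traj.positions[i, f] >= lo).all()
                assert (traj.positions[i, f] <= hi).all()


class TestAssembledTrajectories:
    def test_detected_positions_match_ground_truth(self, fitted_results, small_dataset):
        """Under the best identity bijection, detected positions coincide with
        the generator's ground truth to within detection jitter."""
        traj = fitted_results.trajectories
        gt = small_dataset.positions
        errs = []
        # identity bijection by nearest mean position over detected frames
        from scipy.optimize import linear_sum_assignment

        n = traj.n_animals
        cost = np.zeros((n, n))
        for i in range(n):
            det = traj.provenance[i] == DETECTED
            for j in range(n):
                cost[i, j] = np.nanmean(
                    np.linalg.norm(traj.positions[i, det] - gt[j, det], axis=1)
                )
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            det = traj.provenance[i] == DETECTED
            errs.append(
                np.median(np.linalg.norm(traj.positions[i, det] - gt[j, det], axis=1))
            )
        assert np.max(errs) < 2.0   # centroid jitter scale, px

    def test_identity_exclusivity_per_frame(self, fitted_results):
        traj = fitted_results.trajectories
        present = ~np.isnan(traj.positions[:, :, 0])
        # each identity occupies its own row; within a frame, detected
        # positions of distinct identities never coincide exactly
        for f in range(traj.n_frames):
            ids = np.flatnonzero(present[:, f] & (traj.provenance[:, f] == DETECTED))
            pts = traj.positions[ids, f]
            if len(pts) > 1:
                d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
                assert (d[np.triu_indices(len(pts), 1)] > 1e-9).all()

    def test_missing_identity_row_has_zero_probability(self):
        pos = np.full((2, 5, 2), np.nan)
        pos[0, :, 0] = np.arange(5)
        pos[0, :, 1] = 0.0
        traj = make_traj(pos)
        assert (traj.probabilities[1] == 0).all()
        assert (traj.provenance[1] == MISSING).all()
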