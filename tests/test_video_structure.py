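"""Segmentation, blob classification, fragment linking and the coexistence graph."""

import numpy as np
import pytest

from pairtrack import (
    InvalidInputError,
    build_fragments,
    coexist,
    find_global_fragments,
    fragment_connectivity,
    segment_frame,
)
from pairtrack.blobs import CROSSING, INDIVIDUAL, classify_blob

from conftest import graph_from_intervals, make_blob, make_fragment


def disc_frame(centers, radius=6, shape=(80, 80), value=0.9):
    frame = np.zeros(shape, dtype=np.float32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cx, cy in centers:
        frame[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = value
    return frame


class TestSegmentFrame:
    def test_all_background_frame_yields_no_blobs(self):
        assert segment_frame(np.zeros((50, 50)), 0.5) == []

    def test_two_disjoint_discs_yield_two_blobs_at_disc_centers(self):
        frame = disc_frame([(20, 20), (60, 55)])
        blobs = segment_frame(frame, 0.5, frame_index=7)
        assert len(blobs) == 2
        found = sorted(b.centroid for b in blobs)
        for (gx, gy), b in zip(sorted([(20, 20), (60, 55)]), found):
            assert abs(b[0] - gx) < 0.6 and abs(b[1] - gy) < 0.6
        assert all(b.frame_index == 7 for b in blobs)

    def test_roi_mask_hides_one_disc(self):
        frame = disc_frame([(20, 20), (60, 55)])
        roi = np.zeros_like(frame, dtype=bool)
        roi[:, :40] = True   # keep only the left disc
        blobs = segment_frame(frame, 0.5, roi_mask=roi)
        assert len(blobs) == 1
        assert abs(blobs[0].centroid[0] - 20) < 0.6

    def test_occlusion_mask_pixels_treated_as_background(self):
        frame = disc_frame([(20, 20)])
        mask = np.zeros_like(frame, dtype=bool)
        mask[:40, :40] = True
        assert segment_frame(frame, 0.5, occlusion_mask=mask) == []

    def test_min_area_discards_specks(self):
        frame = np.zeros((30, 30), dtype=np.float32)
        frame[5, 5] = 1.0
        assert segment_frame(frame, 0.5, min_blob_area=10) == []

    @pytest.mark.parametrize("bad_threshold", [-0.1, 1.5])
    def test_threshold_outside_unit_interval_rejected(self, bad_threshold):
        with pytest.raises(InvalidInputError):
            segment_frame(np.zeros((10, 10)), bad_threshold)

    def test_empty_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            segment_frame(np.zeros((0, 0)), 0.5)


class TestClassifyBlob:
    def test_area_at_median_is_individual(self):
        blob = make_blob(0, area=100)
        assert classify_blob(blob, 100.0, 1.5) == INDIVIDUAL

    def test_double_area_is_crossing(self):
        blob = make_blob(0, area=200)
        assert classify_blob(blob, 100.0, 1.5) == CROSSING

    def test_multi_overlap_marks_crossing_despite_small_area(self):
        px = lambda pts: np.array(pts, dtype=np.int64)
        prev_a = make_blob(0, area=4, pixels=px([(0, 0), (0, 1)]))
        prev_b = make_blob(0, area=4, pixels=px([(5, 5), (5, 6)]))
        blob = make_blob(1, area=4, pixels=px([(0, 0), (5, 5)]))
        assert classify_blob(blob, 100.0, 1.5, [prev_a, prev_b]) == CROSSING
        single = make_blob(1, area=4, pixels=px([(0, 0)]))
        assert classify_blob(single, 100.0, 1.5, [prev_a, prev_b]) == INDIVIDUAL


class TestCoexist:
    def test_touching_half_open_ranges_do_not_coexist(self):
        assert not coexist(make_fragment(0, 0, 5), make_fragment(1, 5, 9))

    def test_one_shared_frame_is_enough(self):
        assert coexist(make_fragment(0, 0, 5), make_fragment(1, 4, 9))

    def test_containment_coexists(self):
        assert coexist(make_fragment(0, 2, 3), make_fragment(1, 0, 10))

    def test_self_comparison_rejected(self):
        frag = make_fragment(0, 0, 5)
        with pytest.raises(InvalidInputError):
            coexist(frag, frag)


class TestBuildFragments:
    def _two_walkers(self, t=20):
        """Two animals far apart for t frames, never crossing."""
        frames = []
        for f in range(t):
            frames.append(
                [make_blob(f, x=10.0 + f * 0.5, y=10.0),
                 make_blob(f, x=60.0 - f * 0.5, y=60.0)]
            )
        return frames

    def test_two_noncrossing_animals_give_two_full_fragments(self):
        graph = build_fragments(self._two_walkers(), 2, classify=False)
        assert len(graph.fragments) == 2
        assert all((f.start_frame, f.end_frame) == (0, 20) for f in graph.fragments)
        assert graph.connectivity == 1.0

    def test_single_crossing_splits_into_four_fragments(self):
        frames = []
        for f in range(10):
            frames.append([make_blob(f, x=20.0 + f, y=30.0),
                           make_blob(f, x=40.0 - f, y=30.0)])
        for f in range(10, 13):   # merged crossing blob
            frames.append([make_blob(f, x=30.0, y=30.0, area=120, kind=CROSSING)])
        for f in range(13, 23):
            d = f - 13
            frames.append([make_blob(f, x=33.0 + d, y=30.0),
                           make_blob(f, x=27.0 - d, y=30.0)])
        graph = build_fragments(frames, 2, classify=False)
        assert len(graph.fragments) == 4
        starts = sorted(f.start_frame for f in graph.fragments)
        assert starts == [0, 0, 13, 13]
        assert len(graph.crossing_runs) == 1
        run = graph.crossing_runs[0]
        assert (run.start_frame, run.end_frame) == (10, 13)
        assert sorted(run.entering) == [0, 1]
        assert sorted(run.exiting) == [2, 3]

    def test_frame_gap_terminates_fragment(self):
        frames = [[make_blob(0, x=10, y=10)], [], [make_blob(2, x=10, y=10)]]
        graph = build_fragments(frames, 2, classify=False)
        assert sorted((f.start_frame, f.end_frame) for f in graph.fragments) == [
            (0, 1), (2, 3)
        ]

    def test_every_individual_blob_in_exactly_one_fragment(self, small_dataset):
        graph = build_fragments(
            small_dataset.blobs_per_frame, small_dataset.n_animals, classify=False
        )
        seen = set()
        for frag in graph.fragments:
            for blob in frag.blobs:
                assert not blob.is_crossing
                assert id(blob) not in seen
                seen.add(id(blob))
        n_individual = sum(
            1 for fb in small_dataset.blobs_per_frame for b in fb if not b.is_crossing
        )
        assert len(seen) == n_individual


class TestConnectivityAndGlobals:
    def test_all_coexisting_gives_unit_connectivity(self):
        graph = graph_from_intervals([(0, 0, 10), (1, 0, 10), (2, 0, 10)], 3)
        assert fragment_connectivity(graph) == pytest.approx(1.0)

    def test_worked_three_fragment_example(self):
        graph = graph_from_intervals([(0, 0, 11), (1, 0, 6), (2, 6, 11)], 3)
        assert fragment_connectivity(graph) == pytest.approx((4 / 3) / 2)

    def test_warning_flag_fires_exactly_below_threshold(self):
        graph = graph_from_intervals([(0, 0, 11), (1, 0, 6), (2, 6, 11)], 3)
        fragment_connectivity(graph, warning_threshold=0.5)   # 0.667 >= 0.5
        assert not graph.low_connectivity_warning
        fragment_connectivity(graph, warning_threshold=0.7)
        assert graph.low_connectivity_warning

    def test_zero_fragments_invalid(self):
        from pairtrack import FragmentGraph

        graph = FragmentGraph(fragments=[], n_animals=3)
        with pytest.raises(InvalidInputError):
            fragment_connectivity(graph)

    def test_no_crossing_video_has_one_global_fragment(self):
        graph = graph_from_intervals([(0, 0, 10), (1, 0, 10)], 2)
        gfs = find_global_fragments(graph)
        assert len(gfs) == 1
        assert gfs[0].common_frame_range == (0, 10)
        assert gfs[0].member_fragment_ids == frozenset({0, 1})

    def test_video_without_global_fragments_returns_empty_list(self):
        graph = graph_from_intervals([(0, 0, 5), (1, 6, 10)], 2)
        assert find_global_fragments(graph) == []

    def test_three_fragment_common_range(self):
        graph = graph_from_intervals([(0, 0, 10), (1, 0, 10), (2, 3, 6)], 3)
        gfs = find_global_fragments(graph)
        assert len(gfs) == 1
        assert gfs[0].common_frame_range == (3, 6)

    def _brute_force(self, intervals, n):
        """Per-frame alive sets; maximal constant runs of exactly-n sets."""
        t_max = max(e for _, _, e in intervals)
        per_frame = []
        for f in range(t_max):
            alive = frozenset(fid for fid, s, e in intervals if s <= f < e)
            per_frame.append(alive if len(alive) == n else None)
        runs = []
        f = 0
        while f < t_max:
            if per_frame[f] is None:
                f += 1
                continue
            g = f
            while g < t_max and per_frame[g] == per_frame[f]:
                g += 1
            runs.append((per_frame[f], (f, g)))
            f = g
        return runs

    def test_sweep_line_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(2, 5))
            n_frag = int(rng.integers(n, 50))
            intervals = []
            for fid in range(n_frag):
                s = int(rng.integers(0, 60))
                e = s + int(rng.integers(1, 25))
                intervals.append((fid, s, e))
            graph = graph_from_intervals(intervals, n)
            # connectivity against brute-force pairwise overlap
            degrees = []
            for fid, s, e in intervals:
                deg = sum(
                    1 for fid2, s2, e2 in intervals
                    if fid2 != fid and s < e2 and s2 < e
                )
                degrees.append(deg)
            expected = np.mean(degrees) / (n - 1)
            assert fragment_connectivity(graph) == pytest.approx(expected)
            # global fragments against per-frame enumeration
            got = [
                (g.member_fragment_ids, g.common_frame_range)
                for g in find_global_fragments(graph)
            ]
            assert got == self._brute_force(intervals, n)


class TestOcclusionMonotonicity:
    def test_larger_sector_never_covers_more_frames(self, small_dataset):
        from pairtrack.evaluate import OcclusionSpec, apply_sector_mask

        center = small_dataset.config.arena_center
        covered = []
        for theta in [0.0, 90.0, 180.0, 270.0, 360.0]:
            spec = OcclusionSpec(sector_angle=theta, arena_center=center)
            masked = apply_sector_mask(small_dataset.blobs_per_frame, spec)
            if theta < 360:
                graph = build_fragments(masked, small_dataset.n_animals, classify=False)
                covered.append(sum(f.n_images for f in graph.fragments))
            else:
                assert all(len(fb) == 0 for fb in masked)
                covered.append(0)
        assert covered == sorted(covered, reverse=True)
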