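import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operant_arena import (
    NOSA,
    ROSA,
    Bout,
    OccupancySeries,
    annotate_bouts,
    binned_occupation_score,
    heatmap_matrix,
    latencies_to_reenter,
    occupancy_from_trajectory,
    segment_bouts,
)


def rle_oracle(values, region_true):
    """Independent run-length segmentation via itertools.groupby."""
    runs = []
    pos = 0
    for key, grp in itertools.groupby(values):
        n = len(list(grp))
        if bool(key) == region_true:
            runs.append((pos, pos + n))
        pos += n
    return runs


class TestOccupancyFromTrajectory:
    def test_toy_path(self, geom, make_traj):
        traj = make_traj([1, 6, 7, 7, 4, 8])
        occ = occupancy_from_trajectory(traj, geom)
        assert list(occ.values.astype(int)) == [0, 1, 1, 1, 0, 1]

    def test_never_crossing(self, geom, make_traj):
        occ = occupancy_from_trajectory(make_traj([1, 2, 3]), geom)
        assert not occ.values.any()

    def test_unrepaired_gap_carries_last_region(self, geom, make_traj):
        traj = make_traj([6.0, np.nan, np.nan, 2.0])
        occ = occupancy_from_trajectory(traj, geom)
        assert list(occ.values.astype(int)) == [1, 1, 1, 0]
        assert list(occ.imputed) == [False, True, True, False]

    def test_out_of_bounds_names_frame(self, geom, make_traj):
        with pytest.raises(ValueError, match="frame 1"):
            occupancy_from_trajectory(make_traj([1.0, 12.0, 2.0]), geom)


class TestBinnedOccupationScore:
    def test_single_bin(self):
        occ = OccupancySeries([1, 1, 0, 0], fps=1.0)
        np.testing.assert_allclose(binned_occupation_score(occ, 4.0), [0.5])

    def test_all_ones(self):
        occ = OccupancySeries(np.ones(120, dtype=bool), fps=2.0)
        np.testing.assert_allclose(binned_occupation_score(occ, 30.0), [1.0, 1.0])

    def test_partial_final_bin_kept(self):
        occ = OccupancySeries([1, 1, 0, 0, 1], fps=1.0)
        scores = binned_occupation_score(occ, 2.0)
        np.testing.assert_allclose(scores, [1.0, 0.0, 1.0])
        assert binned_occupation_score(occ, 2.0, drop_partial=True).shape == (2,)

    def test_matches_brute_force_means(self, random_occupancy):
        occ = random_occupancy(900 * 15, fps=15.0, seed=7)
        scores = binned_occupation_score(occ, 60.0)
        per_bin = 60 * 15
        expected = [
            occ.values[k * per_bin : (k + 1) * per_bin].mean() for k in range(15)
        ]
        np.testing.assert_allclose(scores, expected)

    def test_empty_series_errors(self):
        occ = OccupancySeries(np.zeros(0, dtype=bool), fps=1.0)
        with pytest.raises(ValueError, match="empty"):
            binned_occupation_score(occ, 1.0)


class TestSegmentBouts:
    def test_two_bouts(self):
        occ = OccupancySeries([0, 1, 1, 0, 1, 0], fps=1.0)
        bouts = segment_bouts(occ, ROSA)
        assert [(b.entry_frame, b.exit_frame) for b in bouts] == [(1, 3), (4, 5)]
        assert [b.duration_s for b in bouts] == [2.0, 1.0]
        assert not any(b.truncated for b in bouts)

    def test_exited_final_bout_not_truncated(self):
        occ = OccupancySeries([1, 1, 0], fps=1.0)
        (b,) = segment_bouts(occ, ROSA)
        assert b.duration_s == 2.0 and not b.truncated

    def test_session_end_truncates(self):
        occ = OccupancySeries([0, 1, 1], fps=1.0)
        (b,) = segment_bouts(occ, ROSA)
        assert b.truncated

    def test_min_bout_frames_discards_short_runs(self):
        occ = OccupancySeries([1, 0, 1, 1, 1, 0], fps=1.0)
        assert len(segment_bouts(occ, ROSA, min_bout_frames=2)) == 1

    def test_matches_rle_oracle_on_random_series(self, random_occupancy):
        occ = random_occupancy(200, fps=15.0, seed=11)
        for region, truth in ((ROSA, True), (NOSA, False)):
            bouts = segment_bouts(occ, region)
            assert [
                (b.entry_frame, b.exit_frame) for b in bouts
            ] == rle_oracle(occ.values, truth)

    def test_unknown_region(self, random_occupancy):
        with pytest.raises(ValueError, match="unknown region"):
            segment_bouts(random_occupancy(10), "Lobby")


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=60))
def test_bout_alternation_and_conservation(values):
    """ROSA and NoSA bouts alternate, differ by at most one in count, and
    their durations sum to the session duration (min_bout_frames=1)."""
    occ = OccupancySeries(values, fps=1.0)
    rosa = segment_bouts(occ, ROSA)
    nosa = segment_bouts(occ, NOSA)
    assert abs(len(rosa) - len(nosa)) <= 1
    total = sum(b.duration_s for b in rosa) + sum(b.duration_s for b in nosa)
    assert total == pytest.approx(occ.duration_s)
    spans = sorted(
        [(b.entry_frame, b.region) for b in rosa] + [(b.entry_frame, b.region) for b in nosa]
    )
    for (_, r1), (_, r2) in zip(spans[:-1], spans[1:]):
        assert r1 != r2


class TestLatencies:
    def test_single_gap(self):
        bouts = [
            Bout(ROSA, 1, 3, fps=1.0),
            Bout(ROSA, 4, 6, fps=1.0),
        ]
        np.testing.assert_allclose(latencies_to_reenter(bouts), [1.0])

    def test_single_bout_empty(self):
        assert latencies_to_reenter([Bout(ROSA, 0, 5, fps=1.0)]).size == 0

    def test_empty_input(self):
        assert latencies_to_reenter([]).size == 0

    def test_mixed_regions_rejected(self):
        bouts = [Bout(ROSA, 0, 2, fps=1.0), Bout(NOSA, 3, 4, fps=1.0)]
        with pytest.raises(ValueError, match="multiple regions"):
            latencies_to_reenter(bouts)


class TestAnnotateBouts:
    def test_distance_and_depth(self, geom, make_traj):
        traj = make_traj([1, 6, 7, 7, 4, 8])
        occ = occupancy_from_trajectory(traj, geom)
        bouts = annotate_bouts(segment_bouts(occ, ROSA), traj, geom)
        # first bout frames 1-3: entry step 5, then 1, then 0
        assert bouts[0].distance == pytest.approx(6.0)
        assert bouts[0].max_depth == pytest.approx(2.0)
        # second bout: single frame 5, entry step |8-4| = 4, depth 3
        assert bouts[1].distance == pytest.approx(4.0)
        assert bouts[1].max_depth == pytest.approx(3.0)


class TestHeatmap:
    def test_shape_and_values(self, random_occupancy):
        occs = [random_occupancy(900 * 15, seed=s) for s in range(2)]
        m = heatmap_matrix(occs, bin_seconds=60.0)
        assert m.shape == (2, 15)
        assert ((m >= 0) & (m <= 1)).all()

    def test_constant_fly_row_of_ones(self):
        occ = OccupancySeries(np.ones(60, dtype=bool), fps=1.0)
        other = OccupancySeries(np.zeros(60, dtype=bool), fps=1.0)
        m = heatmap_matrix([occ, other], bin_seconds=10.0)
        np.testing.assert_allclose(m[0], 1.0)
        np.testing.assert_allclose(m[1], 0.0)

    def test_row_mean_equals_whole_session_score(self, random_occupancy):
        occ = random_occupancy(900, fps=1.0, seed=3)
        m = heatmap_matrix([occ], bin_seconds=60.0)
        assert m[0].mean() == pytest.approx(occ.values.mean())

    def test_heterogeneous_durations_need_flag(self, random_occupancy):
        occs = [random_occupancy(100, seed=0), random_occupancy(80, seed=1)]
        with pytest.raises(ValueError, match="heterogeneous"):
            heatmap_matrix(occs, bin_seconds=1.0)
        m = heatmap_matrix(occs, bin_seconds=1.0, truncate=True)
        assert m.shape[0] == 2
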