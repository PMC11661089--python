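"""Breathing statistics: profiles, flipping, bubbles, feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epbdsim import (
    BubbleEvent,
    assemble_ml_features,
    average_coordinates,
    bubble_lifetime,
    bubble_probability,
    bubble_statistics,
    detect_bubbles,
    flipping_probability,
)
from epbdsim.features import (
    DEFAULT_BUBBLE_LENGTHS,
    DEFAULT_BUBBLE_THRESHOLDS,
    DEFAULT_FLIP_THRESHOLDS,
    all_open_occupancy,
    decode_one_hot,
    sweep,
)
from epbdsim.synthetic import brute_force_bubbles

from conftest import make_ensemble


def random_frames(rng, m=1, n_frames=40, n=8):
    """Displacement tensors straddling a 1 A threshold."""
    return rng.uniform(-0.5, 2.5, size=(m, n_frames, n))


class TestAverageCoordinates:
    def test_constant_frames(self):
        ens = make_ensemble(np.full((3, 5, 4), 0.25))
        prof = average_coordinates(ens)
        np.testing.assert_allclose(prof.mean_y, 0.25)
        np.testing.assert_allclose(prof.stderr_y, 0.0)

    def test_hand_computed_mean_and_stderr(self):
        frames = np.array(
            [
                [[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]],
                [[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]],
            ]
        )  # 2 runs, 3 frames, 2 positions
        prof = average_coordinates(make_ensemble(frames))
        np.testing.assert_allclose(prof.mean_y, [(2.0 + 1.0) / 2, (3.0 + 0.0) / 2])
        run_means = np.array([[2.0, 3.0], [1.0, 0.0]])
        np.testing.assert_allclose(
            prof.stderr_y, run_means.std(axis=0, ddof=1) / np.sqrt(2)
        )

    def test_zero_frames_rejected(self):
        ens = make_ensemble(np.empty((2, 0, 4)))
        with pytest.raises(ValueError, match="zero production frames"):
            average_coordinates(ens)

    def test_core_slice_excludes_flanks(self, params):
        from epbdsim import encode_sequence

        seq = encode_sequence("GG", flank_left="AA", flank_right="TT")
        frames = np.tile(np.array([0.0, 0.0, 1.0, 2.0, 0.0, 0.0]), (1, 4, 1))
        prof = average_coordinates(make_ensemble(frames, seq=seq))
        np.testing.assert_allclose(prof.mean_y, [1.0, 2.0])


class TestFlipping:
    def test_default_sweep_has_five_thresholds(self):
        np.testing.assert_allclose(
            DEFAULT_FLIP_THRESHOLDS, [0.7071, 1.4142, 2.1213, 2.8284, 3.5355]
        )

    def test_all_below_smallest_threshold(self):
        prof = flipping_probability(make_ensemble(np.full((2, 10, 3), 0.1)))
        np.testing.assert_array_equal(prof.prob, 0.0)

    def test_exact_half_count_inclusive(self):
        frames = np.zeros((1, 4, 2))
        frames[0, :2, 0] = 1.5  # position 0 open in exactly half the frames
        prof = flipping_probability(make_ensemble(frames), thresholds=[1.5])
        np.testing.assert_allclose(prof.prob[0], [0.5, 0.0])  # >= is inclusive

    def test_threshold_monotonicity_exact(self):
        rng = np.random.default_rng(21)
        prof = flipping_probability(
            make_ensemble(random_frames(rng, m=3)), thresholds=sweep(0.2, 2.4, 0.2)
        )
        assert np.all(np.diff(prof.prob, axis=0) <= 0)

    def test_invalid_thresholds_rejected(self):
        ens = make_ensemble(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            flipping_probability(ens, thresholds=[])
        with pytest.raises(ValueError):
            flipping_probability(ens, thresholds=[-1.0])


class TestDetectBubbles:
    def test_nothing_open(self):
        assert detect_bubbles(np.zeros((10, 5)), tr=1.0) == []

    def test_single_position_three_frames(self):
        frames = np.zeros((6, 4))
        frames[2:5, 1] = 2.0
        events = detect_bubbles(frames, tr=1.0)
        assert events == [BubbleEvent(n=1, l=1, start_frame=2, end_frame=4)]
        assert events[0].n_frames == 3

    def test_growth_ends_event(self):
        frames = np.zeros((4, 5))
        frames[0:2, 2] = 2.0
        frames[2:4, 2:4] = 2.0  # bubble grows from l=1 to l=2
        events = detect_bubbles(frames, tr=1.0)
        assert BubbleEvent(n=2, l=1, start_frame=0, end_frame=1) in events
        assert BubbleEvent(n=2, l=2, start_frame=2, end_frame=3) in events

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        t = int(rng.integers(1, 40))
        frames = rng.uniform(-0.5, 2.0, size=(t, n))
        assert detect_bubbles(frames, tr=1.0) == brute_force_bubbles(frames, tr=1.0)


class TestBubbleAggregation:
    def test_probability_hand_computed(self):
        # 2 runs of 10 frames at 1 ps/frame: t_s = 10 ps
        events = [
            [BubbleEvent(0, 3, 0, 3), BubbleEvent(0, 3, 6, 7)],  # 4 + 2 frames
            [BubbleEvent(2, 3, 5, 5)],  # 1 frame
        ]
        p, q = bubble_probability(events, m=2, t_s_ps=10.0, frame_interval_ps=1.0,
                                  n_positions=5, lengths=[3])
        assert p[0, 0] == pytest.approx((4 + 2) / 20)
        assert p[2, 0] == pytest.approx(1 / 20)
        assert q[0, 0] == 2 and q[2, 0] == 1

    def test_probability_is_one_when_always_open(self):
        frames = np.full((3, 8, 4), 5.0)  # entire core open for all runs
        stats = bubble_statistics(make_ensemble(frames), thresholds=[1.0], lengths=[4])
        assert stats.p[0, 0, 0] == pytest.approx(1.0)
        assert np.all(stats.p <= 1.0)

    def test_no_events_gives_zero_p_and_absent_tau(self):
        stats = bubble_statistics(
            make_ensemble(np.zeros((2, 5, 4))), thresholds=[1.0], lengths=[2, 3]
        )
        assert np.all(stats.p == 0.0)
        assert np.all(np.isnan(stats.tau))
        assert np.all(stats.q == 0)

    def test_wrong_run_count_rejected(self):
        with pytest.raises(ValueError, match="M=3"):
            bubble_probability([[]], m=3, t_s_ps=1.0, frame_interval_ps=0.1,
                               n_positions=2, lengths=[1])

    def test_lifetime_single_and_mean(self):
        one = [[BubbleEvent(1, 2, 0, 4)]]  # 5 frames
        tau = bubble_lifetime(one, frame_interval_ps=0.5, n_positions=3, lengths=[2])
        assert tau[1, 0] == pytest.approx(2.5)
        two = [[BubbleEvent(1, 2, 0, 3)], [BubbleEvent(1, 2, 2, 3)]]  # 4 and 2 frames
        tau = bubble_lifetime(two, frame_interval_ps=1.0, n_positions=3, lengths=[2])
        assert tau[1, 0] == pytest.approx((4 + 2) / 2)

    def test_pooled_mean_matches_brute_force(self):
        rng = np.random.default_rng(8)
        runs = [rng.uniform(-0.5, 2.0, size=(30, 6)) for _ in range(4)]
        events = [detect_bubbles(f, tr=1.0) for f in runs]
        tau = bubble_lifetime(events, frame_interval_ps=0.1, n_positions=6,
                              lengths=list(range(1, 7)))
        pooled = [ev for run in events for ev in run]
        for n in range(6):
            for j, l in enumerate(range(1, 7)):
                durations = [e.n_frames * 0.1 for e in pooled if e.n == n and e.l == l]
                if durations:
                    assert tau[n, j] == pytest.approx(np.mean(durations))
                else:
                    assert np.isnan(tau[n, j])


class TestOccupancy:
    def test_monotone_in_length_and_threshold(self):
        rng = np.random.default_rng(13)
        frames = random_frames(rng, m=4, n_frames=50, n=10)
        occ = all_open_occupancy(frames, thresholds=sweep(0.5, 2.0, 0.5),
                                 lengths=[1, 2, 3, 4])
        assert np.all(np.diff(occ, axis=1) <= 1e-15)  # longer window never likelier
        assert np.all(np.diff(occ, axis=2) <= 1e-15)  # higher bar never likelier

    def test_bounded_by_single_site_flipping(self):
        rng = np.random.default_rng(14)
        frames = random_frames(rng, m=2, n_frames=60, n=8)
        thr = [0.8, 1.6]
        occ = all_open_occupancy(frames, thresholds=thr, lengths=[2, 3])
        flip = flipping_probability(make_ensemble(frames), thresholds=thr)
        n = frames.shape[-1]
        for k in range(len(thr)):
            for j, l in enumerate([2, 3]):
                for start in range(n - l + 1):
                    bound = flip.prob[k, start : start + l].min()
                    assert occ[start, j, k] <= bound + 1e-12


class TestDefaultsAndFeatures:
    def test_default_bubble_sweeps(self):
        assert len(DEFAULT_BUBBLE_THRESHOLDS) == 30
        assert DEFAULT_BUBBLE_THRESHOLDS[0] == 0.5 and DEFAULT_BUBBLE_THRESHOLDS[-1] == 15.0
        np.testing.assert_array_equal(DEFAULT_BUBBLE_LENGTHS, np.arange(3, 21))

    def test_feature_vector_layout_and_roundtrip(self):
        ens = make_ensemble(np.full((2, 4, 6), 0.3))
        prof = average_coordinates(ens)
        vec = assemble_ml_features("ACGTAC", prof)
        assert vec.shape == (5 * 6,)
        np.testing.assert_array_equal(vec[:4], [1, 0, 0, 0])  # 'A' block first
        np.testing.assert_allclose(vec[24:], 0.3)
        assert decode_one_hot(vec) == "ACGTAC"

    def test_feature_length_mismatch_rejected(self):
        prof = average_coordinates(make_ensemble(np.zeros((1, 2, 4))))
        with pytest.raises(ValueError, match="length"):
            assemble_ml_features("ACGTA", prof)
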