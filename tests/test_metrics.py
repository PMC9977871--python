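import math

import numpy as np
import pytest

from tricell.metrics import (
    AOGMWeights,
    aogm,
    aogm_empty,
    boundary_prf,
    count_stats,
    ede,
    frechet,
    junction_prf,
    label_boundary,
    length_metrics,
    tra,
)
from tricell.tracking import TrackGraph


# --- independent oracle: exhaustive enumeration of monotone couplings -----

def frechet_oracle(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum over ALL monotone couplings of the max pair distance,
    enumerated recursively (feasible for m, n <= 6)."""
    m, n = len(p), len(q)
    best = [math.inf]

    def recurse(i, j, worst):
        worst = max(worst, float(np.linalg.norm(p[i] - q[j])))
        if worst >= best[0]:
            return
        if i == m - 1 and j == n - 1:
            best[0] = worst
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < m and j + dj < n:
                recurse(i + di, j + dj, worst)

    recurse(0, 0, 0.0)
    return best[0]


class TestBoundaryPRF:
    def test_identical_masks(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[4] = True
        s = boundary_prf(mask, mask, R=5)
        assert (s.precision, s.recall, s.f_score) == (1.0, 1.0, 1.0)

    def test_shift_within_tolerance(self):
        gt = np.zeros((4, 16, 16), dtype=bool)
        gt[:, 6, :] = True
        pred = np.zeros_like(gt)
        pred[:, 9, :] = True  # 3 voxels off, R=5
        s = boundary_prf(gt, pred, R=5)
        assert s.f_score == 1.0

    def test_shift_beyond_tolerance(self):
        gt = np.zeros((4, 24, 24), dtype=bool)
        gt[:, 4, :] = True
        pred = np.zeros_like(gt)
        pred[:, 13, :] = True  # 9 voxels off, R=5
        s = boundary_prf(gt, pred, R=5)
        assert s.f_score == 0.0
        # brute-force nearest-distance confirmation
        gt_pts = np.argwhere(gt).astype(float)
        pred_pts = np.argwhere(pred).astype(float)
        min_d = min(np.linalg.norm(g - p) for g in gt_pts[:5] for p in pred_pts)
        assert min_d > 5

    def test_empty_ground_truth_error(self):
        with pytest.raises(ValueError, match="recall"):
            boundary_prf(np.zeros((2, 2, 2), dtype=bool), np.ones((2, 2, 2), dtype=bool))

    def test_counts_nonnegative_and_consistent(self):
        rng = np.random.default_rng(0)
        gt = rng.uniform(size=(6, 6, 6)) < 0.2
        pred = rng.uniform(size=(6, 6, 6)) < 0.2
        if not gt.any():
            gt[0, 0, 0] = True
        s = boundary_prf(gt, pred, R=1)
        assert s.TP + s.FN == int(gt.sum())
        assert 0 <= s.precision <= 1 and 0 <= s.recall <= 1


class TestLabelBoundary:
    def test_plane_interface(self):
        labels = np.ones((2, 2, 6), dtype=np.int32)
        labels[..., 3:] = 2
        b = label_boundary(labels)
        assert b[..., 2].all() and b[..., 3].all()
        assert not b[..., 0].any()


class TestCountStats:
    def test_constant_counts(self, quadrant_labels):
        mean, sd = count_stats([quadrant_labels] * 3)
        assert (mean, sd) == (4.0, 0.0)

    def test_two_frames(self, quadrant_labels):
        other = quadrant_labels.copy()
        other[other == 4] = 3  # 3 cells
        mean, sd = count_stats([quadrant_labels, other])
        assert mean == 3.5 and sd == 0.5

    def test_single_frame(self, quadrant_labels):
        assert count_stats([quadrant_labels])[1] == 0.0


class TestJunctionPRF:
    def test_perfect(self):
        pts = {(1, 2, 3), (4, 5, 6)}
        assert junction_prf(pts, pts, tol=5) == (1.0, 1.0, 1.0)

    def test_empty_detection(self):
        p, r, f = junction_prf(set(), {(0, 0, 0)}, tol=5)
        assert r == 0.0 and f == 0.0

    def test_one_detection_two_truths(self):
        truth = {(0, 0, 0), (0, 0, 4)}
        detected = {(0, 0, 2)}  # within tol of both, can match only one
        p, r, f = junction_prf(detected, truth, tol=5)
        assert p == 1.0 and r == 0.5

    def test_tolerance_respected(self):
        p, r, f = junction_prf({(0, 0, 0)}, {(0, 0, 6)}, tol=5)
        assert (p, r, f) == (0.0, 0.0, 0.0)


class TestEDE:
    def test_identical_corrected_zero(self):
        p = [(0, 0, 0), (1, 0, 0), (3, 0, 0)]
        assert ede(p, p) == 0.0

    def test_as_printed_anomaly(self):
        # the printed formula averages within-curve chords: nonzero for P == Q
        p = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]
        assert ede(p, p, mode="as_printed") == pytest.approx(3.0)

    def test_translated_curve(self):
        p = np.array([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        q = p + np.array([0, 4, 0])
        assert ede(p, q) == pytest.approx(4.0)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=(5, 3))
        q = rng.uniform(size=(4, 3))
        assert ede(p, q) == pytest.approx(ede(p, q[::-1]))

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            ede([(0, 0, 0)], [(0, 0, 0)], mode="bogus")


class TestFrechet:
    def test_identical_zero(self):
        p = [(0, 0, 0), (1, 1, 0), (2, 0, 0)]
        assert frechet(p, p) == 0.0

    def test_parallel_unit_segments(self):
        p = [(0, 0, 0), (1, 0, 0)]
        q = [(0, 1, 0), (1, 1, 0)]
        assert frechet(p, q, orientation="fixed") == pytest.approx(1.0)
        # exhaustive confirmation
        assert frechet_oracle(np.array(p, float), np.array(q, float)) == pytest.approx(1.0)

    def test_dp_equals_enumeration_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            m, n = rng.integers(1, 7, size=2)
            p = rng.uniform(0, 10, size=(m, 3))
            q = rng.uniform(0, 10, size=(n, 3))
            assert frechet(p, q, orientation="fixed") == pytest.approx(
                frechet_oracle(p, q), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=(5, 3))
        q = rng.uniform(size=(6, 3))
        for mode in ("fixed", "min"):
            assert frechet(p, q, mode) == pytest.approx(frechet(q, p, mode))

    def test_min_orientation_le_fixed(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=(5, 3))
        q = rng.uniform(size=(5, 3))
        assert frechet(p, q, "min") <= frechet(p, q, "fixed") + 1e-12


class TestLengthMetrics:
    def test_identical(self):
        p = [(0, 0, 0), (0, 0, 5)]
        assert length_metrics(p, p) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        p = [(0, 0, 0), (0, 0, 10)]
        q = [(0, 0, 0), (0, 0, 8)]
        ld, dp = length_metrics(p, q)
        assert ld == pytest.approx(2.0) and dp == pytest.approx(25.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=(6, 3))
        q = rng.uniform(size=(5, 3))
        shift = np.array([3.0, -1.0, 2.0])
        assert length_metrics(p, q) == pytest.approx(length_metrics(p + shift, q + shift))

    def test_zero_length_ground_truth(self):
        with pytest.raises(ValueError, match="zero-length"):
            length_metrics([(0, 0, 0), (0, 0, 1)], [(0, 0, 0)])


def two_track_reference() -> TrackGraph:
    """2 tracks x 2 frames: 4 nodes, 2 link edges."""
    tg = TrackGraph()
    for track in (1, 2):
        for frame in (0, 1):
            tg.add_detection(frame, track, track=track)
        tg.add_link(0, track, track)
    return tg


class TestAOGM:
    def test_identical_graphs_zero(self):
        ref = two_track_reference()
        assert aogm(ref, two_track_reference()) == 0.0

    def test_missing_edge_costs_w_ea(self):
        ref = two_track_reference()
        result = two_track_reference()
        result.graph.remove_edge((0, 1), (1, 1))
        assert aogm(ref, result) == pytest.approx(AOGMWeights().w_EA)

    def test_empty_result_equals_aogm0(self):
        ref = two_track_reference()
        assert aogm(ref, TrackGraph()) == pytest.approx(aogm_empty(ref))

    def test_aogm0_hand_count(self):
        # 4 nodes x 10 + 2 edges x 1.5 = 43
        assert aogm_empty(two_track_reference()) == pytest.approx(43.0)

    def test_spurious_node_costs_w_fp(self):
        ref = two_track_reference()
        result = two_track_reference()
        result.add_detection(0, 99, track=99)
        assert aogm(ref, result) == pytest.approx(AOGMWeights().w_FP)

    def test_spurious_edge_costs_w_ed(self):
        ref = two_track_reference()
        ref.graph.remove_edge((0, 2), (1, 2))
        result = two_track_reference()
        assert aogm(ref, result) == pytest.approx(AOGMWeights().w_ED)


class TestTRA:
    def test_perfect_tracking(self):
        ref = two_track_reference()
        assert tra(ref, two_track_reference()) == 1.0

    def test_empty_result_zero(self):
        assert tra(two_track_reference(), TrackGraph()) == 0.0

    def test_hand_count_missing_edge(self):
        ref = two_track_reference()
        result = two_track_reference()
        result.graph.remove_edge((0, 1), (1, 1))
        assert tra(ref, result) == pytest.approx(1.0 - 1.5 / 43.0)

    def test_monotone_under_injected_errors(self):
        ref = two_track_reference()
        r1 = two_track_reference()
        r1.graph.remove_edge((0, 1), (1, 1))
        r2 = two_track_reference()
        r2.graph.remove_edge((0, 1), (1, 1))
        r2.graph.remove_node((1, 2))
        scores = [tra(ref, g) for g in (two_track_reference(), r1, r2)]
        assert scores[0] >= scores[1] >= scores[2]
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_empty_reference_error(self):
        with pytest.raises(ValueError, match="empty"):
            tra(TrackGraph(), two_track_reference())

    def test_mask_overlap_matching(self, quadrant_labels):
        from tricell.tracking import track_sequence

        # identical volumes but different label numbering: masks must align
        relabeled = np.zeros_like(quadrant_labels)
        for old, new in ((1, 3), (2, 4), (3, 1), (4, 2)):
            relabeled[quadrant_labels == old] = new
        ref, _ = track_sequence([quadrant_labels, quadrant_labels])
        res, _ = track_sequence([relabeled, relabeled])
        assert tra(ref, res) == 1.0


class TestAOGMWeights:
    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            AOGMWeights(w_FN=-1)
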