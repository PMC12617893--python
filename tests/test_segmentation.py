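import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protseg.embeddings import pool_segments
from protseg.segmentation import (
    ChangePointConfig,
    KernelChangePointSegmenter,
    boundary_score,
    gain_curve,
    merge_by_cluster,
    merge_oversegmentation,
    rbf_cost,
    resolve_bandwidth,
    score_segments,
    segment_matrix,
    segments_from_boundaries,
    select_boundaries,
)
from protseg.types import ResidueEmbeddingMatrix, Segment, segments_tile


def brute_force_rbf_cost(rows, gamma):
    """Independent O(n^2) double-loop kernel cost."""
    n = len(rows)
    total = 0.0
    for i in range(n):
        for j in range(n):
            d2 = float(np.sum((rows[i] - rows[j]) ** 2))
            total += np.exp(-gamma * d2)
    return n - total / n


class TestRbfCost:
    def test_identical_rows_cost_zero(self):
        rows = np.tile(np.arange(5.0), (8, 1))
        assert rbf_cost(rows, gamma=0.3) == pytest.approx(0.0, abs=1e-10)

    def test_single_row_cost_zero(self):
        assert rbf_cost(np.ones((1, 4)), gamma=1.0) == 0.0

    def test_two_rows_closed_form(self):
        a, b = np.zeros(4), np.array([1.0, 1.0, 0.0, 0.0])
        gamma = 0.7
        expected = 1.0 - np.exp(-gamma * 2.0)
        assert rbf_cost(np.stack([a, b]), gamma) == pytest.approx(expected, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            rows = rng.standard_normal((20, 8))
            gamma = rng.uniform(0.05, 2.0)
            assert rbf_cost(rows, gamma) == pytest.approx(
                brute_force_rbf_cost(rows, gamma), abs=1e-9
            )

    def test_non_finite_rows_rejected(self):
        rows = np.ones((3, 2))
        rows[1, 0] = np.nan
        with pytest.raises(ValueError):
            rbf_cost(rows, 1.0)


class TestGainCurve:
    def test_constant_matrix_all_gains_zero(self):
        matrix = ResidueEmbeddingMatrix("P1", np.ones((80, 4)))
        curve = gain_curve(matrix, ChangePointConfig())
        np.testing.assert_allclose(curve.gains, 0.0, atol=1e-9)

    def test_matches_from_scratch_reevaluation(self):
        rng = np.random.default_rng(2)
        matrix = ResidueEmbeddingMatrix("P1", rng.standard_normal((60, 6)))
        config = ChangePointConfig(rbf_bandwidth_rule="fixed", bandwidth_value=0.2)
        curve = gain_curve(matrix, config)
        w, half = config.window, config.window // 2
        for pos, gain in zip(curve.positions, curve.gains):
            full = brute_force_rbf_cost(matrix.values[pos - half : pos + half], 0.2)
            left = brute_force_rbf_cost(matrix.values[pos - half : pos], 0.2)
            right = brute_force_rbf_cost(matrix.values[pos : pos + half], 0.2)
            assert gain == pytest.approx(full - left - right, abs=1e-8)

    def test_two_block_argmax_at_boundary(self, two_block_matrix):
        curve = gain_curve(two_block_matrix, ChangePointConfig())
        assert curve.positions[np.argmax(curve.gains)] == 60

    def test_short_protein_empty_curve(self):
        matrix = ResidueEmbeddingMatrix("P1", np.ones((29, 4)))
        curve = gain_curve(matrix, ChangePointConfig())
        assert len(curve) == 0
        segs = segment_matrix(matrix)
        assert segs == [Segment("P1", 0, 29)]

    def test_positions_within_admissible_range(self, two_block_matrix):
        curve = gain_curve(two_block_matrix, ChangePointConfig())
        assert curve.positions[0] == 15
        assert curve.positions[-1] == two_block_matrix.length - 15


class TestBandwidth:
    def test_fixed_rule(self):
        matrix = ResidueEmbeddingMatrix("P1", np.ones((40, 4)))
        config = ChangePointConfig(rbf_bandwidth_rule="fixed", bandwidth_value=2.5)
        assert resolve_bandwidth(matrix, config) == 2.5

    def test_median_heuristic_scale_free(self):
        rng = np.random.default_rng(0)
        rows = rng.standard_normal((100, 8))
        m1 = ResidueEmbeddingMatrix("P1", rows)
        m2 = ResidueEmbeddingMatrix("P1", rows * 10)
        g1 = resolve_bandwidth(m1, ChangePointConfig())
        g2 = resolve_bandwidth(m2, ChangePointConfig())
        assert g1 / g2 == pytest.approx(100.0, rel=1e-6)

    def test_degenerate_matrix_falls_back(self):
        matrix = ResidueEmbeddingMatrix("P1", np.zeros((50, 4)))
        assert resolve_bandwidth(matrix, ChangePointConfig()) == 1.0


class TestSelectBoundaries:
    def _curve(self, gains, start=15):
        from protseg.segmentation import GainCurve

        positions = np.arange(start, start + len(gains))
        return GainCurve("P1", positions, np.asarray(gains, dtype=float))

    def test_all_zero_gains_no_boundaries(self):
        curve = self._curve([0.0] * 50)
        assert select_boundaries(curve, 100, ChangePointConfig()) == []

    def test_single_peak_selected(self):
        gains = [0.0] * 50
        gains[20] = 1.0
        curve = self._curve(gains)
        assert select_boundaries(curve, 100, ChangePointConfig()) == [35]

    def test_budget_caps_many_strong_peaks(self):
        # L=100 -> budget ceil(3*100/100)=3; 5 well-separated peaks
        gains = [0.0] * 70
        peak_positions = [0, 16, 32, 48, 64]
        for rank, idx in enumerate(peak_positions):
            gains[idx] = 5.0 - rank
        curve = self._curve(gains)
        selected = select_boundaries(curve, 100, ChangePointConfig())
        assert len(selected) == 3
        assert selected == [15, 31, 47]  # three highest-gain peaks

    def test_min_spacing_suppression(self):
        gains = [0.0] * 50
        gains[10], gains[14] = 2.0, 1.9  # 4 apart < min_spacing 15
        curve = self._curve(gains)
        assert select_boundaries(curve, 100, ChangePointConfig()) == [25]

    def test_tiny_numerical_residue_not_a_boundary(self):
        gains = [0.0] * 50
        gains[10] = 1e-13
        curve = self._curve(gains)
        assert select_boundaries(curve, 100, ChangePointConfig()) == []


class TestSegments:
    def test_boundaries_to_segments_tiling(self):
        segs = segments_from_boundaries("P1", [20, 45, 70], 100)
        assert [(s.start, s.end) for s in segs] == [(0, 20), (20, 45), (45, 70), (70, 100)]
        assert segments_tile(segs, 100)

    def test_no_boundaries_single_segment(self):
        assert segments_from_boundaries("P1", [], 50) == [Segment("P1", 0, 50)]

    def test_synthetic_three_block_recovery(self, small_noisy_corpus):
        spec, matrices, boundaries, _ = small_noisy_corpus
        m = matrices[0]
        segs = segment_matrix(m)
        assert segments_tile(segs, m.length)
        internal = sorted(s.end for s in segs[:-1])
        for true_b in boundaries[m.protein_id]:
            assert min(abs(true_b - b) for b in internal) <= 3


class TestBoundaryScore:
    def test_identical_windows_score_zero(self):
        rows = np.tile(np.arange(6.0), (40, 1))
        rng = np.random.default_rng(0)
        rows = rows + 0  # identical rows both sides
        matrix = ResidueEmbeddingMatrix("P1", rows)
        assert boundary_score(matrix, 20) == pytest.approx(0.0)

    def test_score_monotone_in_mean_shift(self):
        rng = np.random.default_rng(1)
        noise = rng.standard_normal((60, 8))
        scores = []
        for delta in (0.5, 1.0, 2.0, 4.0):
            rows = noise.copy()
            rows[30:, 0] += delta
            scores.append(boundary_score(ResidueEmbeddingMatrix("P1", rows), 30))
        assert scores == sorted(scores)

    def test_segment_score_is_mean_of_boundary_scores(self, small_noisy_corpus):
        _, matrices, _, _ = small_noisy_corpus
        m = matrices[1]
        segs = segment_matrix(m)
        scored = score_segments(m, segs)
        assert len(scored) >= 2
        internal = [s.end for s in segs[:-1]]
        b_scores = {b: boundary_score(m, b) for b in internal}
        # terminal segments: single boundary score
        assert scored[0].score == pytest.approx(b_scores[segs[0].end])
        assert scored[-1].score == pytest.approx(b_scores[segs[-1].start])
        for seg in scored[1:-1]:
            expected = np.mean([b_scores[seg.start], b_scores[seg.end]])
            assert seg.score == pytest.approx(expected)

    def test_single_segment_protein_unscored(self):
        matrix = ResidueEmbeddingMatrix("P1", np.ones((20, 4)))
        (seg,) = score_segments(matrix, [Segment("P1", 0, 20)])
        assert seg.score is None


class TestCosineMerge:
    def _matrix_with_blocks(self, block_vectors, block_len=10):
        rows = np.concatenate([np.tile(v, (block_len, 1)) for v in block_vectors])
        return ResidueEmbeddingMatrix("P1", rows)

    def test_identical_adjacent_pair_merges_then_guard_stops(self):
        # 6 segments; blocks 2 and 3 identical, all others mutually orthogonal
        eye = np.eye(8) * 4
        blocks = [eye[0], eye[1], eye[2], eye[2], eye[3], eye[4]]
        matrix = self._matrix_with_blocks(blocks)
        segs = segments_from_boundaries("P1", [10, 20, 30, 40, 50], 60)
        merged, embs = merge_oversegmentation(matrix, segs)
        assert len(merged) == 5  # one merge then count < 6 stops
        assert Segment("P1", 20, 40) in merged
        assert segments_tile(merged, 60)
        assert len(embs) == len(merged)

    def test_fewer_than_six_segments_untouched(self):
        eye = np.eye(8)
        matrix = self._matrix_with_blocks([eye[0], eye[0], eye[1]])
        segs = segments_from_boundaries("P1", [10, 20], 30)
        merged, _ = merge_oversegmentation(matrix, segs)
        assert merged == segs

    def test_most_similar_pair_non_adjacent_stops(self):
        eye = np.eye(8) * 4
        # blocks 0 and 5 identical but far apart; adjacent pairs orthogonal
        blocks = [eye[0], eye[1], eye[2], eye[3], eye[4], eye[0]]
        matrix = self._matrix_with_blocks(blocks)
        segs = segments_from_boundaries("P1", [10, 20, 30, 40, 50], 60)
        merged, _ = merge_oversegmentation(matrix, segs)
        assert merged == segs

    def test_merge_monotone_and_idempotent(self, small_noisy_corpus):
        _, matrices, _, _ = small_noisy_corpus
        for m in matrices[:5]:
            segs = segments_from_boundaries(
                m.protein_id, list(range(30, m.length - 20, 30)), m.length
            )
            merged, _ = merge_oversegmentation(m, segs)
            assert len(merged) <= len(segs)
            assert segments_tile(merged, m.length)
            again, _ = merge_oversegmentation(m, merged)
            assert again == merged


class TestClusterMerge:
    def test_adjacent_same_label_collapse(self):
        segs = segments_from_boundaries("P1", [10, 20], 30)
        merged = merge_by_cluster(segs, [1, 1, 2])
        assert [(s.start, s.end) for s in merged] == [(0, 20), (20, 30)]

    def test_all_distinct_unchanged(self):
        segs = segments_from_boundaries("P1", [10, 20], 30)
        assert merge_by_cluster(segs, [1, 2, 3]) == segs

    def test_run_length_collapse_oracle(self):
        segs = segments_from_boundaries("P1", [10, 20, 30, 40, 50], 60)
        merged = merge_by_cluster(segs, [1, 1, 1, 2, 2, 1])
        assert [(s.start, s.end) for s in merged] == [(0, 30), (30, 50), (50, 60)]

    def test_label_count_mismatch_rejected(self):
        segs = segments_from_boundaries("P1", [10], 20)
        with pytest.raises(ValueError):
            merge_by_cluster(segs, [1])


class TestEstimator:
    def test_fit_predict_transform(self, two_block_matrix):
        est = KernelChangePointSegmenter()
        est.fit(two_block_matrix.values, protein_id="P2B")
        assert est.boundaries_ == [60]
        labels = est.predict()
        assert set(labels[:60]) == {0} and set(labels[60:]) == {1}
        pooled = est.transform()
        assert pooled.shape == (2, two_block_matrix.dim)
        np.testing.assert_allclose(pooled[0], two_block_matrix.values[:60].mean(axis=0))

    def test_get_set_params_roundtrip(self):
        est = KernelChangePointSegmenter(window=20)
        params = est.get_params()
        assert params["window"] == 20
        est.set_params(boundaries_per_100aa=6.0)
        assert est.boundaries_per_100aa == 6.0

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            KernelChangePointSegmenter().predict()


@given(
    n_segs=st.integers(min_value=1, max_value=12),
    seed=st.integers(min_value=0, max_value=10_000),
)
@settings(deadline=None, max_examples=200)
def test_merge_partition_invariant_random_proteins(n_segs, seed):
    """Cosine merging never breaks the tiling, never increases the count,
    never touches proteins with < 6 segments, and terminates."""
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.choice(np.arange(4, 4 * n_segs, 4), size=n_segs - 1, replace=False)) \
        if n_segs > 1 else np.array([], dtype=int)
    L = 4 * n_segs
    rows = rng.standard_normal((L, 5))
    matrix = ResidueEmbeddingMatrix("P1", rows)
    segs = segments_from_boundaries("P1", list(map(int, cuts)), L)
    merged, embs = merge_oversegmentation(matrix, segs)
    assert segments_tile(merged, L)
    assert len(merged) <= len(segs)
    if len(segs) < 6:
        assert merged == segs
    assert len(embs) == len(merged)
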