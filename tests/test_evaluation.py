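import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protseg.evaluation import (
    boundary_distance_eval,
    dedupe_overlapping_predictions,
    evaluate_segmentation,
    filter_positives,
    iou,
    pr_at_k,
)
from protseg.types import Annotation, Segment


def position_set_iou(a, b):
    """Independent oracle: IoU by explicit residue sets."""
    sa, sb = set(range(*a)), set(range(*b))
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


class TestIoU:
    def test_identical_intervals(self):
        assert iou((3, 17), (3, 17)) == 1.0

    def test_disjoint_intervals(self):
        assert iou((0, 10), (10, 20)) == 0.0

    def test_partial_overlap(self):
        assert iou((0, 10), (5, 15)) == pytest.approx(5 / 15)
        assert iou((0, 10), (5, 15)) == pytest.approx(position_set_iou((0, 10), (5, 15)))

    @given(data=st.data())
    @settings(deadline=None, max_examples=300)
    def test_matches_position_set_oracle(self, data):
        a0 = data.draw(st.integers(0, 200))
        a1 = data.draw(st.integers(a0 + 1, 250))
        b0 = data.draw(st.integers(0, 200))
        b1 = data.draw(st.integers(b0 + 1, 250))
        assert iou((a0, a1), (b0, b1)) == pytest.approx(
            position_set_iou((a0, a1), (b0, b1)), abs=1e-12
        )


class TestFilterPositives:
    lengths = {"P1": 100, "SHORT": 59}

    def test_short_annotation_dropped(self):
        anns = [Annotation("P1", 0, 29, "D", "X")]
        assert filter_positives(anns, self.lengths) == []

    def test_30aa_on_60aa_protein_kept(self):
        anns = [Annotation("P60", 0, 30, "D", "X")]
        assert filter_positives(anns, {"P60": 60}) == anns

    def test_full_length_annotation_dropped(self):
        anns = [Annotation("P1", 0, 100, "D", "X")]
        assert filter_positives(anns, self.lengths) == []

    def test_short_protein_dropped(self):
        anns = [Annotation("SHORT", 0, 40, "D", "X")]
        assert filter_positives(anns, self.lengths) == []


class TestEvaluateSegmentation:
    def test_identical_sets_all_ones(self):
        segs = [Segment("P1", 0, 50), Segment("P1", 50, 100), Segment("P2", 10, 60)]
        rep = evaluate_segmentation(segs, segs)
        assert rep.aiou_pred == rep.aiou_pos == 1.0
        assert rep.precision == rep.recall == 1.0
        assert rep.unpaired_pos == 0

    def test_non_overlapping_prediction(self):
        pred = [Segment("P1", 0, 10)]
        pos = [Annotation("P1", 50, 90, "D", "X")]
        rep = evaluate_segmentation(pred, pos)
        assert rep.precision == 0.0
        assert rep.recall == 0.0
        assert rep.unpaired_pos == 1

    def test_empty_predictions_precision_undefined(self):
        pos = [Annotation("P1", 0, 40, "D", "X")]
        rep = evaluate_segmentation([], pos)
        assert rep.precision is None
        assert rep.aiou_pred is None
        assert rep.recall == 0.0

    def test_toy_layout_matches_brute_force(self):
        pred = [Segment("P1", 0, 40), Segment("P1", 35, 80), Segment("P1", 90, 99)]
        pos = [Annotation("P1", 0, 42, "a", "X"), Annotation("P1", 38, 80, "b", "X")]
        rep = evaluate_segmentation(pred, pos, iou_threshold=0.5)
        # exhaustive all-pairs best-match oracle
        ious = [[iou(p.interval, q.interval) for q in pos] for p in pred]
        best_pred = [max(row) for row in ious]
        best_pos = [max(col) for col in zip(*ious)]
        assert rep.aiou_pred == pytest.approx(np.mean(best_pred))
        assert rep.aiou_pos == pytest.approx(np.mean(best_pos))
        assert rep.precision == pytest.approx(np.mean([b >= 0.5 for b in best_pred]))
        assert rep.recall == pytest.approx(np.mean([b >= 0.5 for b in best_pos]))

    def test_qualifying_matches_non_increasing_in_threshold(self):
        rng = np.random.default_rng(4)
        pred, pos = [], []
        for i in range(30):
            a = int(rng.integers(0, 150))
            pred.append(Segment("P1", a, a + int(rng.integers(5, 60))))
            b = int(rng.integers(0, 150))
            pos.append(Annotation("P1", b, b + int(rng.integers(5, 60)), "D", "X"))
        prev_p, prev_r = 1.1, 1.1
        for thr in np.linspace(0, 1, 11):
            rep = evaluate_segmentation(pred, pos, iou_threshold=thr)
            assert rep.precision <= prev_p + 1e-12
            assert rep.recall <= prev_r + 1e-12
            prev_p, prev_r = rep.precision, rep.recall


class TestBoundaryDistance:
    def test_paired_distances_counted(self):
        pred = [Segment("P1", 10, 50)]
        pos = [Annotation("P1", 12, 48, "D", "X")]
        summary = boundary_distance_eval(pred, pos, tolerance=10)
        assert summary.distances == [(2, 2)]
        assert summary.pct_boundaries_within_tol == 1.0

    def test_unpaired_positive_counts_two_misses(self):
        pred = [Segment("P1", 0, 30)]
        pos = [
            Annotation("P1", 5, 28, "a", "X"),  # paired, distances (5, 2)
            Annotation("P1", 200, 260, "b", "X"),  # unpaired
        ]
        summary = boundary_distance_eval(pred, pos, tolerance=10)
        assert summary.unpaired_pos == 1
        assert summary.pct_boundaries_within_tol == pytest.approx(2 / 4)

    def test_strictly_less_than_tolerance(self):
        pred = [Segment("P1", 10, 60)]
        pos = [Annotation("P1", 0, 58, "D", "X")]  # distances (10, 2)
        summary = boundary_distance_eval(pred, pos, tolerance=10)
        assert summary.pct_boundaries_within_tol == pytest.approx(1 / 2)

    def test_exact_corpus_is_100pct(self):
        segs = [Segment("P1", 0, 40), Segment("P2", 5, 90)]
        pos = [Annotation(s.protein_id, s.start, s.end, "D", "X") for s in segs]
        assert boundary_distance_eval(segs, pos).pct_boundaries_within_tol == 1.0


class TestDedupe:
    def test_identical_intervals_keep_better_score(self):
        preds = [Segment("P1", 0, 50, score=5.0), Segment("P1", 0, 50, score=3.0)]
        kept = dedupe_overlapping_predictions(preds, higher_is_better=True)
        assert kept == [Segment("P1", 0, 50, score=5.0)]

    def test_lower_is_better_direction(self):
        preds = [Segment("P1", 0, 50, score=1e-10), Segment("P1", 0, 50, score=0.5)]
        kept = dedupe_overlapping_predictions(preds, higher_is_better=False)
        assert kept == [Segment("P1", 0, 50, score=1e-10)]

    def test_low_iou_pair_both_kept(self):
        preds = [Segment("P1", 0, 50, score=5.0), Segment("P1", 40, 100, score=3.0)]
        assert len(dedupe_overlapping_predictions(preds)) == 2

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            dedupe_overlapping_predictions([Segment("P1", 0, 50)])

    def test_chain_matches_greedy_oracle(self):
        # three mutually overlapping predictions: greedy keeps the best,
        # removes anything with IoU > 0.5 to a kept one, repeats
        preds = [
            Segment("P1", 0, 100, score=9.0),
            Segment("P1", 5, 105, score=7.0),
            Segment("P1", 10, 110, score=8.0),
        ]
        kept = dedupe_overlapping_predictions(preds)

        def greedy_oracle(items):
            remaining = sorted(items, key=lambda p: -p.score)
            out = []
            while remaining:
                best = remaining.pop(0)
                out.append(best)
                remaining = [
                    p for p in remaining if iou(p.interval, best.interval) <= 0.5
                ]
            return sorted(out, key=lambda p: p.start)

        assert kept == greedy_oracle(preds)


class TestPrAtK:
    def _scored(self, intervals, scores, pid="P1"):
        return [Segment(pid, a, b, score=s) for (a, b), s in zip(intervals, scores)]

    def test_perfect_predictor_precision_one_everywhere(self):
        pos = [Annotation("P1", 0, 40, "a", "X"), Annotation("P1", 50, 90, "b", "X")]
        pred = self._scored([(0, 40), (50, 90)], [2.0, 1.0])
        curve = pr_at_k(pred, pos)
        assert all(p == 1.0 for _, p, _ in curve)

    def test_top1_correct_rest_wrong(self):
        pos = [Annotation("P1", 0, 40, "a", "X")]
        pred = self._scored([(0, 40), (100, 140), (200, 240)], [3.0, 2.0, 1.0])
        curve = pr_at_k(pred, pos)
        for k, precision, recall in curve:
            assert precision == pytest.approx(1 / k)
            assert recall == 1.0

    def test_full_prefix_equals_global_report(self):
        rng = np.random.default_rng(9)
        pred = self._scored(
            [(int(a), int(a) + 30) for a in rng.integers(0, 300, size=10)],
            rng.standard_normal(10).tolist(),
        )
        pos = [Annotation("P1", 10, 45, "a", "X"), Annotation("P1", 100, 170, "b", "X")]
        curve = pr_at_k(pred, pos)
        rep = evaluate_segmentation(pred, pos)
        assert curve[-1] == (10, rep.precision, rep.recall)
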