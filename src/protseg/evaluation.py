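"""Segmentation benchmark: interval IoU, AIoU, precision/recall, boundaries.

Matching is "best IoU per side" rather than one-to-one assignment: every
predicted segment is scored by its best IoU against any annotated ("positive")
segment of the same protein, and vice versa. AIoU(pred) / AIoU(pos) are the
means of those per-side best IoUs; precision and recall count the segments
whose best IoU clears a threshold (0.5 by default). This mirrors how
segmentation agreement is scored in image analysis and differs from
detection-style bipartite matching — a single positive may validate several
predictions.

Boundary evaluation pairs each positive with the overlapping prediction of
highest IoU and measures the start- and end-offsets in residues; both
boundaries of an unpaired positive count as misses, so the within-tolerance
percentage is always relative to ``2 * n_pos``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .types import Annotation, ProteinRecord, Segment

Interval = Tuple[int, int]


def iou(a: Interval, b: Interval) -> float:
    """Intersection over union of two half-open integer intervals.

    ``max(min(endA, endB) - max(startA, startB), 0) /
    (max(endA, endB) - min(startA, startB))`` — the count of shared residues
    over the count of residues covered by either interval.
    """
    inter = max(min(a[1], b[1]) - max(a[0], b[0]), 0)
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def filter_positives(
    annotations: Iterable[Annotation],
    protein_lengths: Dict[str, int],
    min_annotation_length: int = 30,
    min_protein_length: int = 60,
) -> List[Annotation]:
    """Restrict annotations to the benchmark's positive set.

    Kept: annotations at least 30 residues long that do not span their whole
    protein, on proteins of at least 60 residues. Annotations on proteins of
    unknown length are dropped.
    """
    out = []
    for ann in annotations:
        L = protein_lengths.get(ann.protein_id)
        if L is None or L < min_protein_length:
            continue
        if len(ann) < min_annotation_length or len(ann) >= L:
            continue
        out.append(ann)
    return out


@dataclass
class EvaluationReport:
    """Per-side best-IoU summary of a prediction set against a positive set."""

    n_pred: int
    n_pos: int
    aiou_pred: Optional[float]
    aiou_pos: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    unpaired_pos: int
    iou_threshold: float
    matches: List[Tuple[Interval, Interval, float]] = field(default_factory=list)
    matching: str = "best IoU per side (not one-to-one)"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["matches"] = [
            {"pred": list(p), "pos": list(q), "iou": v} for p, q, v in self.matches
        ]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _group(items: Sequence, key) -> Dict[str, list]:
    grouped: Dict[str, list] = {}
    for it in items:
        grouped.setdefault(key(it), []).append(it)
    return grouped


def evaluate_segmentation(
    predictions: Sequence[Segment],
    positives: Sequence[Annotation | Segment],
    iou_threshold: float = 0.5,
) -> EvaluationReport:
    """Score predicted segments against annotated positives.

    ``aiou_pred`` is the mean over predictions of each prediction's best IoU
    against any positive on the same protein; ``aiou_pos`` is symmetric.
    Precision is the fraction of predictions whose best IoU reaches the
    threshold; recall the fraction of positives. An empty prediction set
    leaves precision/aiou_pred undefined (None) with recall 0; an empty
    positive set symmetric.
    """
    preds_by = _group(predictions, lambda s: s.protein_id)
    pos_by = _group(positives, lambda a: a.protein_id)

    best_pred: List[float] = []
    matches: List[Tuple[Interval, Interval, float]] = []
    for pid, preds in sorted(preds_by.items()):
        pos = pos_by.get(pid, [])
        for p in preds:
            scores = [iou(p.interval, q.interval) for q in pos]
            if scores:
                k = int(np.argmax(scores))
                best_pred.append(scores[k])
                matches.append((p.interval, pos[k].interval, scores[k]))
            else:
                best_pred.append(0.0)

    best_pos: List[float] = []
    unpaired = 0
    for pid, pos in sorted(pos_by.items()):
        preds = preds_by.get(pid, [])
        for q in pos:
            scores = [iou(p.interval, q.interval) for p in preds]
            best = max(scores) if scores else 0.0
            best_pos.append(best)
            if best == 0.0:
                unpaired += 1

    n_pred, n_pos = len(best_pred), len(best_pos)
    precision = (
        sum(s >= iou_threshold for s in best_pred) / n_pred if n_pred else None
    )
    recall = sum(s >= iou_threshold for s in best_pos) / n_pos if n_pos else 0.0
    return EvaluationReport(
        n_pred=n_pred,
        n_pos=n_pos,
        aiou_pred=float(np.mean(best_pred)) if n_pred else None,
        aiou_pos=float(np.mean(best_pos)) if n_pos else None,
        precision=precision,
        recall=recall,
        unpaired_pos=unpaired,
        iou_threshold=iou_threshold,
        matches=matches,
    )


@dataclass
class BoundarySummary:
    """Boundary-distance accounting for a prediction/positive comparison."""

    n_pos: int
    n_pred: int
    unpaired_pos: int
    n_boundaries_within: int
    pct_boundaries_within_tol: float
    tolerance: int
    distances: List[Tuple[int, int]] = field(default_factory=list)


def boundary_distance_eval(
    predictions: Sequence[Segment],
    positives: Sequence[Annotation | Segment],
    tolerance: int = 10,
) -> BoundarySummary:
    """Boundary agreement between positives and their best-IoU predictions.

    Each positive is paired with the overlapping (IoU > 0) prediction of
    highest IoU (ties: earlier start). Its start- and end-offsets each
    contribute one boundary; a boundary counts as recovered when its offset is
    strictly below ``tolerance``. Unpaired positives contribute two missed
    boundaries, so the denominator is exactly ``2 * n_pos``.
    """
    preds_by = _group(predictions, lambda s: s.protein_id)
    n_pos = 0
    unpaired = 0
    within = 0
    distances: List[Tuple[int, int]] = []
    for q in positives:
        n_pos += 1
        preds = preds_by.get(q.protein_id, [])
        scored = [
            (iou(p.interval, q.interval), p.start, p) for p in preds
        ]
        scored = [(s, start, p) for s, start, p in scored if s > 0]
        if not scored:
            unpaired += 1
            continue
        scored.sort(key=lambda t: (-t[0], t[1]))
        best = scored[0][2]
        d_start = abs(best.start - q.start)
        d_end = abs(best.end - q.end)
        distances.append((d_start, d_end))
        within += (d_start < tolerance) + (d_end < tolerance)
    total = 2 * n_pos
    return BoundarySummary(
        n_pos=n_pos,
        n_pred=len(predictions),
        unpaired_pos=unpaired,
        n_boundaries_within=within,
        pct_boundaries_within_tol=within / total if total else 0.0,
        tolerance=tolerance,
        distances=distances,
    )


def dedupe_overlapping_predictions(
    predictions: Sequence[Segment],
    iou_threshold: float = 0.5,
    higher_is_better: bool = True,
) -> List[Segment]:
    """Drop the worse-scoring member of heavily overlapping prediction pairs.

    External tools can emit several overlapping calls for the same region
    (with different labels); among pairs on the same protein with
    IoU > ``iou_threshold`` the worse-scoring one is removed, greedily from
    the best-scoring prediction down. For e-value-like scores pass
    ``higher_is_better=False``.
    """
    if any(p.score is None for p in predictions):
        raise ValueError("dedupe requires every prediction to carry a score")
    sign = -1.0 if higher_is_better else 1.0
    ordered = sorted(predictions, key=lambda p: (sign * p.score, p.protein_id, p.start))
    kept: List[Segment] = []
    for cand in ordered:
        clash = any(
            k.protein_id == cand.protein_id and iou(k.interval, cand.interval) > iou_threshold
            for k in kept
        )
        if not clash:
            kept.append(cand)
    return sorted(kept, key=lambda p: (p.protein_id, p.start))


def pr_at_k(
    predictions: Sequence[Segment],
    positives: Sequence[Annotation | Segment],
    iou_threshold: float = 0.5,
    higher_is_better: bool = True,
) -> List[Tuple[int, Optional[float], Optional[float]]]:
    """Precision and recall of the top-k predictions for k = 1..n_pred.

    Predictions are ranked by score (ties broken by protein id and start for
    determinism) and each prefix is scored with
    :func:`evaluate_segmentation`. The last entry (k = n_pred) reproduces the
    global report. No assumption is made that recall reaches 1: segmentation
    methods never enumerate all possible segments.
    """
    if any(p.score is None for p in predictions):
        raise ValueError("pr_at_k requires every prediction to carry a score")
    sign = -1.0 if higher_is_better else 1.0
    ordered = sorted(predictions, key=lambda p: (sign * p.score, p.protein_id, p.start))
    curve = []
    for k in range(1, len(ordered) + 1):
        rep = evaluate_segmentation(ordered[:k], positives, iou_threshold)
        curve.append((k, rep.precision, rep.recall))
    return curve
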