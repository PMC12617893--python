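"""Transfer of interval annotations onto predicted segments.

The governing rule throughout is the 30% overlap criterion: an annotation is
considered transferable to a segment when the intersection covers at least
30% of the *segment's* residues (the segment length is always the
denominator; the threshold is inclusive). Annotations of any size are
allowed here, unlike the segmentation benchmark which filters short ones.

Three modes:

* multi-class — among qualifying annotations, the single one with the
  highest IoU wins (ties broken by longer annotation, then lexicographic
  label, for determinism);
* multi-label — every label with a qualifying annotation is transferred;
  duplicate same-label annotations collapse to one membership;
* IDR flagging — a segment is called intrinsically disordered when the union
  of its disorder-annotation overlaps covers at least 30% of it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .evaluation import iou
from .types import Annotation, Segment

OVERLAP_FRACTION = 0.30


@dataclass
class LabeledSegment:
    """A segment with transferred labels and an intrinsic-disorder flag."""

    segment: Segment
    labels: Set[str] = field(default_factory=set)
    is_idr: bool = False


def _intersection(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(min(a[1], b[1]) - max(a[0], b[0]), 0)


def transfer_multiclass(
    segment: Segment,
    annotations: Sequence[Annotation],
    min_fraction: float = OVERLAP_FRACTION,
) -> Optional[str]:
    """Single best label for a segment, or None if nothing qualifies.

    Qualifying annotations intersect the segment by at least
    ``min_fraction * len(segment)`` residues; among them the highest-IoU
    annotation provides the label.
    """
    best = None  # (iou, length, label)
    threshold = min_fraction * len(segment)
    for ann in annotations:
        if ann.protein_id != segment.protein_id:
            continue
        if _intersection(segment.interval, ann.interval) < threshold:
            continue
        key = (iou(segment.interval, ann.interval), len(ann), _NegStr(ann.label))
        if best is None or key > best:
            best = key
    return str(best[2]) if best is not None else None


class _NegStr(str):
    """String ordered reversed, so max() breaks ties lexicographically ascending."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def transfer_multilabel(
    segment: Segment,
    annotations: Sequence[Annotation],
    min_fraction: float = OVERLAP_FRACTION,
) -> Set[str]:
    """All labels whose best same-label annotation covers >= 30% of the segment."""
    threshold = min_fraction * len(segment)
    labels: Set[str] = set()
    for ann in annotations:
        if ann.protein_id != segment.protein_id:
            continue
        if _intersection(segment.interval, ann.interval) >= threshold:
            labels.add(ann.label)
    return labels


def flag_idr(
    segment: Segment,
    disorder_annotations: Sequence[Annotation],
    min_fraction: float = OVERLAP_FRACTION,
) -> bool:
    """True when disorder annotations jointly cover >= 30% of the segment.

    The union of per-annotation overlaps is used, so several short disorder
    calls can together flag a segment.
    """
    covered = [False] * len(segment)
    for ann in disorder_annotations:
        if ann.protein_id != segment.protein_id:
            continue
        lo = max(ann.start, segment.start) - segment.start
        hi = min(ann.end, segment.end) - segment.start
        for i in range(max(lo, 0), max(hi, 0)):
            covered[i] = True
    return sum(covered) >= min_fraction * len(segment)


def transfer_protein_level(
    segments: Sequence[LabeledSegment],
    protein_labels: Dict[str, Set[str]],
    idr_only: bool = False,
) -> List[LabeledSegment]:
    """Broadcast protein-level label sets onto segments.

    Whole-protein annotations (e.g. compartment localization) are inherited
    by every segment of the protein, or — when ``idr_only`` — only by segments
    flagged as intrinsically disordered.
    """
    out: List[LabeledSegment] = []
    for ls in segments:
        labels = set(ls.labels)
        plabels = protein_labels.get(ls.segment.protein_id, set())
        if plabels and (ls.is_idr or not idr_only):
            labels |= plabels
        out.append(LabeledSegment(segment=ls.segment, labels=labels, is_idr=ls.is_idr))
    return out


def filter_labels_by_count(
    corpus: Sequence[LabeledSegment], min_n: int = 25
) -> List[LabeledSegment]:
    """Remove labels that occur fewer than ``min_n`` times corpus-wide.

    Segments that lose all their labels stay in the corpus (they remain valid
    nearest-neighbour candidates) but are excluded from label-based scoring
    by virtue of having no labels.
    """
    counts = Counter(label for ls in corpus for label in ls.labels)
    keep = {label for label, n in counts.items() if n >= min_n}
    return [
        LabeledSegment(segment=ls.segment, labels=ls.labels & keep, is_idr=ls.is_idr)
        for ls in corpus
    ]


def label_corpus(
    segments: Sequence[Segment],
    annotations: Sequence[Annotation],
    mode: str = "multilabel",
    disorder_sources: Tuple[str, ...] = ("MobiDB",),
    min_fraction: float = OVERLAP_FRACTION,
) -> List[LabeledSegment]:
    """Label a segment corpus against an annotation table in one pass."""
    by_protein: Dict[str, List[Annotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)
    out = []
    for seg in segments:
        anns = by_protein.get(seg.protein_id, [])
        disorder = [a for a in anns if a.source in disorder_sources]
        idr = flag_idr(seg, disorder, min_fraction) if disorder else False
        if mode == "multiclass":
            label = transfer_multiclass(seg, anns, min_fraction)
            labels = {label} if label is not None else set()
        elif mode == "multilabel":
            labels = transfer_multilabel(seg, anns, min_fraction)
        else:
            raise ValueError(f"unknown transfer mode {mode!r}")
        out.append(LabeledSegment(segment=seg, labels=labels, is_idr=idr))
    return out
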