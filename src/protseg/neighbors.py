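"""Nearest-neighbour categorization and discovery in segment-embedding space.

Labels are predicted for a segment by copying the label(s) of its nearest
neighbour under cosine distance. Two exclusion policies reflect how labels
were obtained:

* ``exclude_same_protein`` — for protein-level labels every segment of a
  protein carries the same label, so neighbours from the query's own protein
  are inadmissible;
* ``exclude_adjacent_same_protein`` — for positional labels only segments
  adjacent to the query along its own protein are inadmissible (adjacent
  segments usually share the annotation that created the label).

When the raw nearest neighbour is excluded, the next nearest admissible one
is used. The exact backend computes brute-force cosine distances; an
approximate backend can be plugged in for very large corpora, under the
contract that it returns the true nearest with its declared recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .segmentation import merge_by_cluster
from .types import Segment


@dataclass
class NeighborPolicy:
    """Admissibility rules for neighbour queries."""

    exclude_same_protein: bool = False
    exclude_adjacent_same_protein: bool = True
    backend: str = "exact"

    def __post_init__(self) -> None:
        if self.exclude_same_protein and self.exclude_adjacent_same_protein:
            raise ValueError("exactly one exclusion rule may be active")
        if self.backend not in ("exact",):
            raise ValueError(f"backend {self.backend!r} not available; use 'exact'")


@dataclass
class SegmentCorpus:
    """Aligned arrays describing a segment-embedding corpus."""

    vectors: np.ndarray  # n x D
    segments: List[Segment]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.segments):
            raise ValueError("one vector per segment required")

    def __len__(self) -> int:
        return self.vectors.shape[0]


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def _adjacent(a: Segment, b: Segment) -> bool:
    """Adjacency = same protein and a shared endpoint coordinate."""
    return a.protein_id == b.protein_id and (a.end == b.start or b.end == a.start)


def _exclusion_mask(corpus: SegmentCorpus, query_idx: int, policy: NeighborPolicy) -> np.ndarray:
    """Boolean mask of inadmissible corpus members for one query (self always excluded)."""
    q = corpus.segments[query_idx]
    mask = np.zeros(len(corpus), dtype=bool)
    mask[query_idx] = True
    for j, s in enumerate(corpus.segments):
        if j == query_idx:
            continue
        if policy.exclude_same_protein and s.protein_id == q.protein_id:
            mask[j] = True
        elif policy.exclude_adjacent_same_protein and _adjacent(q, s):
            mask[j] = True
    return mask


def nearest_neighbor(
    corpus: SegmentCorpus, query_idx: int, policy: Optional[NeighborPolicy] = None
) -> int:
    """Index of the admissible corpus member nearest (cosine) to one query."""
    policy = policy or NeighborPolicy()
    unit = _unit_rows(corpus.vectors)
    sims = unit @ unit[query_idx]
    sims[_exclusion_mask(corpus, query_idx, policy)] = -np.inf
    if not np.any(np.isfinite(sims)):
        raise ValueError("all corpus members are excluded for this query")
    return int(np.argmax(sims))


def _all_nearest(corpus: SegmentCorpus, policy: NeighborPolicy) -> np.ndarray:
    unit = _unit_rows(corpus.vectors)
    sims = unit @ unit.T
    for i in range(len(corpus)):
        sims[i, _exclusion_mask(corpus, i, policy)] = -np.inf
    if np.any(~np.isfinite(sims).any(axis=1)):
        raise ValueError("some queries have every corpus member excluded")
    return np.argmax(sims, axis=1)


def _confint(successes: int, n: int, method: str) -> Tuple[float, float]:
    lo, hi = proportion_confint(successes, n, alpha=0.05, method=method)
    return float(lo), float(hi)


@dataclass
class MulticlassReport:
    """Column-normalized confusion matrix and per-label precision with CIs."""

    counts: pd.DataFrame  # rows true, columns predicted
    normalized: pd.DataFrame
    precision: pd.Series
    ci: pd.DataFrame  # per label: lower, upper, n_predictions
    average_precision: float


def evaluate_multiclass_1nn(
    corpus: SegmentCorpus,
    labels: Sequence[str],
    policy: Optional[NeighborPolicy] = None,
    ci_method: str = "normal",
) -> MulticlassReport:
    """1-nn multi-class assessment.

    Each segment is predicted to carry the single label of its nearest
    admissible neighbour. The confusion matrix of counts ``C[true, pred]`` is
    normalized per predicted-label column so the diagonal reads precision;
    each precision carries a 95% binomial confidence interval (Wald by
    default, ``ci_method='wilson'`` for Wilson). Labels with zero predictions
    get an undefined (NaN) column.
    """
    policy = policy or NeighborPolicy()
    labels = list(labels)
    if len(labels) != len(corpus):
        raise ValueError("one label per corpus segment required")
    nn = _all_nearest(corpus, policy)
    classes = sorted(set(labels))
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for i, j in enumerate(nn):
        counts.loc[labels[i], labels[j]] += 1  # predicted label = neighbour's label
    col_totals = counts.sum(axis=0)
    normalized = counts / col_totals.replace(0, np.nan)
    rows = {}
    for c in classes:
        n = int(col_totals[c])
        if n == 0:
            rows[c] = (np.nan, np.nan, np.nan, 0)
            continue
        correct = int(counts.loc[c, c])
        p = correct / n
        lo, hi = _confint(correct, n, ci_method)
        rows[c] = (p, lo, hi, n)
    table = pd.DataFrame(rows, index=["precision", "ci_lower", "ci_upper", "n_predictions"]).T
    precision = table["precision"]
    return MulticlassReport(
        counts=counts,
        normalized=normalized,
        precision=precision,
        ci=table,
        average_precision=float(precision.dropna().mean()),
    )


@dataclass
class MultilabelReport:
    """Per-label binary classification tallies with CIs."""

    table: pd.DataFrame  # per label: tp/fp/tn/fn, precision, recall, accuracy, CIs
    average_precision: Optional[float]


def evaluate_multilabel_1nn(
    corpus: SegmentCorpus,
    label_sets: Sequence[Set[str]],
    policy: Optional[NeighborPolicy] = None,
    ci_method: str = "normal",
) -> MultilabelReport:
    """1-nn multi-label assessment: one binary task per label.

    For each label, a segment's prediction is that label's membership in its
    nearest neighbour's label set; TP/FP/TN/FN are tallied over the corpus.
    Precision is undefined (NaN) for labels never predicted; recall 0 when
    predicted but never correctly.
    """
    policy = policy or NeighborPolicy()
    label_sets = [set(s) for s in label_sets]
    if len(label_sets) != len(corpus):
        raise ValueError("one label set per corpus segment required")
    nn = _all_nearest(corpus, policy)
    all_labels = sorted(set().union(*label_sets)) if label_sets else []
    rows = {}
    n = len(corpus)
    for label in all_labels:
        truth = np.array([label in s for s in label_sets])
        pred = np.array([label in label_sets[j] for j in nn])
        tp = int(np.sum(truth & pred))
        fp = int(np.sum(~truth & pred))
        fn = int(np.sum(truth & ~pred))
        tn = n - tp - fp - fn
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        accuracy = (tp + tn) / n
        if tp + fp:
            plo, phi = _confint(tp, tp + fp, ci_method)
        else:
            plo = phi = np.nan
        rows[label] = (tp, fp, tn, fn, precision, plo, phi, recall, accuracy)
    table = pd.DataFrame(
        rows,
        index=["tp", "fp", "tn", "fn", "precision", "precision_ci_lower",
               "precision_ci_upper", "recall", "accuracy"],
    ).T
    avg = float(table["precision"].dropna().mean()) if len(table) else None
    return MultilabelReport(table=table, average_precision=avg)


def knn_query(
    corpus: SegmentCorpus,
    query_indices: Sequence[int],
    k: int = 10,
    exclude_self: bool = True,
) -> List[Segment]:
    """Discovery-mode k-NN: pooled, deduplicated, adjacency-joined results.

    The top-``k`` cosine neighbours of each query segment are pooled across
    queries; duplicate result segments are removed, and adjacent results from
    the same protein are joined into one interval. Exact self matches are
    excluded by identity (not by value: a duplicated embedding elsewhere in
    the corpus still ranks first).
    """
    unit = _unit_rows(corpus.vectors)
    n = len(corpus)
    if k > n - int(exclude_self):
        warnings.warn(f"k={k} exceeds corpus size {n}; returning all members")
        k = n - int(exclude_self)
    hits: List[int] = []
    for qi in query_indices:
        sims = unit @ unit[qi]
        if exclude_self:
            sims[qi] = -np.inf
        order = np.argsort(-sims, kind="stable")[:k]
        hits.extend(int(j) for j in order)
    # dedupe by interval identity, keep stable order
    seen = set()
    result: List[Segment] = []
    for j in sorted(set(hits), key=lambda j: (corpus.segments[j].protein_id, corpus.segments[j].start)):
        seg = corpus.segments[j]
        key = (seg.protein_id, seg.start, seg.end)
        if key not in seen:
            seen.add(key)
            result.append(seg)
    # join adjacent same-protein results: same-cluster run collapse with one label
    return merge_by_cluster(result, [0] * len(result))


class ExclusionNearestNeighbors:
    """sklearn-flavoured wrapper: fit a corpus once, query with exclusions.

    ``fit(X, segments)`` stores the corpus; ``kneighbors(i, k)`` returns the
    admissible neighbour indices of corpus member ``i`` under the policy.
    """

    def __init__(self, policy: Optional[NeighborPolicy] = None):
        self.policy = policy or NeighborPolicy()

    def fit(self, X: np.ndarray, segments: Sequence[Segment]):
        self.corpus_ = SegmentCorpus(vectors=np.asarray(X, dtype=float), segments=list(segments))
        self._unit = _unit_rows(self.corpus_.vectors)
        return self

    def kneighbors(self, i: int, k: int = 1) -> List[int]:
        sims = self._unit @ self._unit[i]
        sims[_exclusion_mask(self.corpus_, i, self.policy)] = -np.inf
        order = [int(j) for j in np.argsort(-sims, kind="stable") if np.isfinite(sims[j])]
        return order[:k]
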