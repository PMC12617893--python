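"""Zero-shot segmentation of residue-embedding matrices.

The engine is a sliding-window kernel change-point analysis. A window of
``window`` residues (default 30) is slid along the protein; at each center
the 15 residues before are compared with the 15 after via the RBF-kernel
least-squares cost

    c(rows) = n - (1/n) * sum_ij exp(-gamma * ||x_i - x_j||^2)

and the discrepancy ("gain") at a candidate boundary t is

    gain(t) = c(window) - c(left half) - c(right half).

Boundaries are local maxima of the gain curve with positive gain, selected
greedily in decreasing gain order under a minimum-spacing rule, capped at a
budget of 3 boundaries per 100 residues — a ceiling the signal itself rarely
reaches, so in practice the peaks, not the budget, limit the output.

The RBF bandwidth gamma is resolved per protein by the median heuristic
(1 / median pairwise squared row distance over a seeded sample); a fixed
value can be supplied for oracle comparisons.

Also here: the per-boundary t-test confidence score, and the two
over-segmentation corrections (cosine-similarity merging of adjacent
segments, and collapsing runs of same-cluster segments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .embeddings import pool_segments
from .types import ResidueEmbeddingMatrix, Segment, SegmentEmbedding, segments_tile


@dataclass
class ChangePointConfig:
    """Tunable parameters of the change-point engine.

    window
        Sliding-window size in residues (must be even, >= 4). Each half-window
        is ``window // 2`` residues.
    boundaries_per_100aa
        Boundary budget per 100 residues of protein length.
    rbf_bandwidth_rule
        ``"median_heuristic"`` (default) or ``"fixed"``.
    bandwidth_value
        Gamma when the rule is ``"fixed"``.
    min_spacing
        Minimum distance between selected boundaries; defaults to half the
        window so two boundaries cannot fall inside one window.
    seed
        Seed for the pairwise-distance sample used by the median heuristic.
    """

    window: int = 30
    boundaries_per_100aa: float = 3.0
    rbf_bandwidth_rule: str = "median_heuristic"
    bandwidth_value: Optional[float] = None
    min_spacing: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 4 or self.window % 2:
            raise ValueError("window must be even and >= 4")
        if self.boundaries_per_100aa <= 0:
            raise ValueError("boundaries_per_100aa must be positive")
        if self.rbf_bandwidth_rule not in ("median_heuristic", "fixed"):
            raise ValueError(f"unknown bandwidth rule {self.rbf_bandwidth_rule!r}")
        if self.rbf_bandwidth_rule == "fixed" and not (
            self.bandwidth_value and self.bandwidth_value > 0
        ):
            raise ValueError("fixed bandwidth rule requires a positive bandwidth_value")
        if self.min_spacing is None:
            self.min_spacing = self.window // 2


@dataclass
class GainCurve:
    """Discrepancy signal of the sliding-window search for one protein."""

    protein_id: str
    positions: np.ndarray  # candidate boundary indices, strictly increasing
    gains: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.positions.size and not np.all(np.diff(self.positions) > 0):
            raise ValueError("gain-curve positions must be strictly increasing")
        if not np.all(np.isfinite(self.gains)):
            raise ValueError("gain-curve gains must be finite")

    def __len__(self) -> int:
        return len(self.positions)


def resolve_bandwidth(
    matrix: ResidueEmbeddingMatrix, config: ChangePointConfig, n_samples: int = 2000
) -> float:
    """RBF gamma for one protein under the configured rule.

    Median heuristic: gamma = 1 / median of pairwise squared row distances,
    estimated from a seeded random sample of row pairs. Degenerate inputs
    (all rows identical) fall back to gamma = 1, where the kernel is constant
    anyway.
    """
    if config.rbf_bandwidth_rule == "fixed":
        return float(config.bandwidth_value)
    rows = matrix.values
    n = rows.shape[0]
    if n < 2:
        return 1.0
    rng = np.random.default_rng(config.seed)
    i = rng.integers(0, n, size=n_samples)
    j = rng.integers(0, n, size=n_samples)
    keep = i != j
    if not np.any(keep):
        return 1.0
    sq = np.sum((rows[i[keep]] - rows[j[keep]]) ** 2, axis=1)
    med = float(np.median(sq))
    if med <= 0:
        nonzero = sq[sq > 0]
        med = float(np.median(nonzero)) if nonzero.size else 1.0
    return 1.0 / med


def rbf_cost(rows: np.ndarray, gamma: float) -> float:
    """Kernel least-squares cost of one segment of rows.

    ``c = n - (1/n) * sum_ij exp(-gamma * ||x_i - x_j||^2)`` with
    ``k(x, x) = 1``; zero for a single row or identical rows.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 1:
        raise ValueError("rows must be a non-empty 2-D array")
    if not np.all(np.isfinite(rows)):
        raise ValueError("rows contain non-finite values")
    n = rows.shape[0]
    sq = np.sum(rows**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * rows @ rows.T
    np.maximum(d2, 0.0, out=d2)
    total = float(np.exp(-gamma * d2).sum())
    return max(n - total / n, 0.0)


def _banded_kernel_cumsums(
    rows: np.ndarray, gamma: float, width: int
) -> np.ndarray:
    """Cumulative sums of the kernel band K[i, i+d] for d = 1..width-1.

    ``band_cum[d]`` has length L - d + 1 with ``band_cum[d][m] =
    sum_{i < m} exp(-gamma * ||x_i - x_{i+d}||^2)``, enabling O(width) block
    sums for any window the sliding search visits.
    """
    L = rows.shape[0]
    cums = [None]  # d = 0 unused (diagonal contributes n exactly)
    for d in range(1, width):
        diff = rows[: L - d] - rows[d:]
        kvals = np.exp(-gamma * np.sum(diff**2, axis=1))
        cums.append(np.concatenate(([0.0], np.cumsum(kvals))))
    return cums


def _block_cost(cums, a: int, b: int) -> float:
    """rbf_cost of rows [a, b) from banded kernel cumsums."""
    n = b - a
    total = float(n)  # diagonal terms
    for d in range(1, min(n, len(cums))):
        # ordered pairs (i, i+d) and (i+d, i) for i in [a, b-d)
        total += 2.0 * (cums[d][b - d] - cums[d][a])
    return max(n - total / n, 0.0)


def gain_curve(matrix: ResidueEmbeddingMatrix, config: ChangePointConfig) -> GainCurve:
    """Sliding-window discrepancy at every admissible boundary position.

    For each center ``t`` in ``[window/2, L - window/2]`` the gain is the cost
    of the full window minus the costs of its two halves. Proteins shorter
    than the window yield an empty curve (and a single whole-protein segment
    downstream).
    """
    L = matrix.length
    w = config.window
    half = w // 2
    if L < w:
        return GainCurve(matrix.protein_id, np.array([], dtype=int), np.array([]))
    gamma = resolve_bandwidth(matrix, config)
    rows = matrix.values.astype(float)
    cums = _banded_kernel_cumsums(rows, gamma, w)
    positions = np.arange(half, L - half + 1)
    gains = np.empty(positions.shape, dtype=float)
    for idx, t in enumerate(positions):
        full = _block_cost(cums, t - half, t + half)
        left = _block_cost(cums, t - half, t)
        right = _block_cost(cums, t, t + half)
        gains[idx] = full - left - right
    return GainCurve(matrix.protein_id, positions, gains)


def boundary_budget(length: int, boundaries_per_100aa: float) -> int:
    return int(math.ceil(boundaries_per_100aa * length / 100.0))


def select_boundaries(
    curve: GainCurve, length: int, config: ChangePointConfig
) -> List[int]:
    """Pick boundaries from the gain curve.

    Candidates are local maxima with strictly positive gain; they are accepted
    greedily in decreasing gain order subject to ``min_spacing`` (non-maximum
    suppression) until the budget ``ceil(boundaries_per_100aa * L / 100)`` is
    reached. Fewer are returned when fewer qualifying peaks exist.

    Positivity is tested against a tolerance proportional to the window size:
    the gain is a difference of costs of magnitude ~window, so cancellation
    leaves residuals of that scale times machine epsilon.
    """
    if len(curve) == 0:
        return []
    gains = curve.gains
    positions = curve.positions
    n = len(gains)
    is_peak = np.ones(n, dtype=bool)
    if n > 1:
        is_peak[1:] &= gains[1:] >= gains[:-1]
        is_peak[:-1] &= gains[:-1] >= gains[1:]
        # plateau: keep only the first position of a flat run
        flat = np.concatenate(([False], gains[1:] == gains[:-1]))
        is_peak &= ~flat
    is_peak &= gains > 1e-9 * config.window
    candidates = np.flatnonzero(is_peak)
    order = candidates[np.argsort(-gains[candidates], kind="stable")]
    budget = boundary_budget(length, config.boundaries_per_100aa)
    selected: List[int] = []
    for idx in order:
        pos = positions[idx]
        if all(abs(pos - s) >= config.min_spacing for s in selected):
            selected.append(int(pos))
            if len(selected) >= budget:
                break
    return sorted(selected)


def segments_from_boundaries(
    protein_id: str, boundaries: Sequence[int], length: int
) -> List[Segment]:
    """Tile [0, L) from sorted internal boundaries: (0,a),(a,b),...,(c,L)."""
    edges = [0] + sorted(int(b) for b in boundaries) + [length]
    return [Segment(protein_id, a, b) for a, b in zip(edges, edges[1:])]


def segment_matrix(
    matrix: ResidueEmbeddingMatrix, config: Optional[ChangePointConfig] = None
) -> List[Segment]:
    """Full zero-shot segmentation of one protein's embedding matrix."""
    config = config or ChangePointConfig()
    curve = gain_curve(matrix, config)
    boundaries = select_boundaries(curve, matrix.length, config)
    return segments_from_boundaries(matrix.protein_id, boundaries, matrix.length)


# ---------------------------------------------------------------------------
# Boundary confidence scores
# ---------------------------------------------------------------------------

def boundary_score(
    matrix: ResidueEmbeddingMatrix, boundary: int, half_window: int = 15
) -> Optional[float]:
    """t-test confidence of one internal boundary.

    Per embedding dimension, a two-sample t statistic (Welch form) compares
    the <= ``half_window`` rows before the boundary with the <= ``half_window``
    rows after; the score is the mean absolute t over dimensions. Dimensions
    with zero mean difference and zero variance contribute 0. Returns None
    when either side has fewer than 2 rows.
    """
    L = matrix.length
    if not 0 < boundary < L:
        raise ValueError(f"boundary {boundary} not interior to [0, {L}]")
    before = matrix.values[max(0, boundary - half_window) : boundary].astype(float)
    after = matrix.values[boundary : boundary + half_window].astype(float)
    if before.shape[0] < 2 or after.shape[0] < 2:
        return None
    m1, m2 = before.mean(axis=0), after.mean(axis=0)
    v1 = before.var(axis=0, ddof=1) / before.shape[0]
    v2 = after.var(axis=0, ddof=1) / after.shape[0]
    num = m1 - m2
    denom = np.sqrt(v1 + v2)
    t = np.zeros_like(num)
    ok = denom > 0
    t[ok] = num[ok] / denom[ok]
    t[~ok & (num != 0)] = np.inf
    return float(np.mean(np.abs(t)))


def score_segments(
    matrix: ResidueEmbeddingMatrix, segments: Sequence[Segment], half_window: int = 15
) -> List[Segment]:
    """Attach a confidence score to each segment of one tiled protein.

    A segment's score is the mean of the scores of its two defining
    boundaries; the protein termini carry no score, so terminal segments use
    their single scored boundary. A single-segment protein has no scored
    boundary and keeps ``score=None``.
    """
    ordered = sorted(segments, key=lambda s: s.start)
    if not segments_tile(ordered, matrix.length):
        raise ValueError("segments must tile the protein")
    internal = [seg.end for seg in ordered[:-1]]
    scores = {b: boundary_score(matrix, b, half_window) for b in internal}
    out: List[Segment] = []
    for seg in ordered:
        parts = [
            scores[b] for b in (seg.start, seg.end) if b in scores and scores[b] is not None
        ]
        out.append(seg.with_score(float(np.mean(parts))) if parts else seg)
    return out


# ---------------------------------------------------------------------------
# Over-segmentation correction
# ---------------------------------------------------------------------------

def _cosine_similarity_matrix(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = vectors / norms
    return unit @ unit.T


def merge_oversegmentation(
    matrix: ResidueEmbeddingMatrix,
    segments: Sequence[Segment],
    min_segments: int = 6,
    iterate: bool = True,
) -> Tuple[List[Segment], List[SegmentEmbedding]]:
    """Cosine-similarity correction for over-segmentation.

    While the protein has at least ``min_segments`` segments: compute all-pairs
    cosine similarity among the current pooled segment embeddings; if the
    globally most-similar pair is adjacent in the sequence, merge it (union
    interval, embedding re-pooled from the residue matrix) and repeat;
    otherwise stop. Proteins that start below the guard are untouched — with
    few segments the most-similar pair is adjacent almost by construction, so
    merging would cascade regardless of similarity.

    With ``iterate=False`` at most one merge is applied.
    """
    ordered = sorted(segments, key=lambda s: s.start)
    if not segments_tile(ordered, matrix.length):
        raise ValueError("segments must tile the protein")
    embeddings = pool_segments(matrix, ordered)
    while len(ordered) >= min_segments:
        vectors = np.stack([e.vector for e in embeddings])
        sim = _cosine_similarity_matrix(vectors)
        np.fill_diagonal(sim, -np.inf)
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        if i > j:
            i, j = j, i
        if j != i + 1:
            break
        merged = Segment(matrix.protein_id, ordered[i].start, ordered[j].end)
        ordered[i : j + 1] = [merged]
        embeddings[i : j + 1] = pool_segments(matrix, [merged])
        if not iterate:
            break
    return ordered, embeddings


def merge_by_cluster(
    segments: Sequence[Segment], cluster_labels: Sequence[int]
) -> List[Segment]:
    """Collapse maximal runs of adjacent same-cluster segments.

    Labels and segments are aligned; segments must be adjacent in sequence
    order for a run to collapse.
    """
    if len(segments) != len(cluster_labels):
        raise ValueError("one cluster label per segment required")
    if not segments:
        return []
    pairs = sorted(zip(segments, cluster_labels), key=lambda p: (p[0].protein_id, p[0].start))
    out: List[Segment] = []
    cur_seg, cur_label = pairs[0]
    for seg, label in pairs[1:]:
        if (
            seg.protein_id == cur_seg.protein_id
            and label == cur_label
            and seg.start == cur_seg.end
        ):
            cur_seg = Segment(cur_seg.protein_id, cur_seg.start, seg.end)
        else:
            out.append(cur_seg)
            cur_seg, cur_label = seg, label
    out.append(cur_seg)
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class KernelChangePointSegmenter(BaseEstimator):
    """Sliding-window kernel change-point segmenter for one protein matrix.

    Parameters mirror :class:`ChangePointConfig`. ``fit(X)`` takes the L x D
    residue-embedding matrix of a single protein and computes the gain curve
    and boundaries; ``predict(X)`` returns an integer segment label per
    residue; ``transform(X)`` returns the pooled segment-embedding matrix
    (n_segments x D).

    Examples
    --------
    >>> import numpy as np
    >>> X = np.r_[np.zeros((60, 8)), np.ones((60, 8))]
    >>> seg = KernelChangePointSegmenter().fit(X)
    >>> seg.boundaries_
    [60]
    """

    def __init__(
        self,
        window: int = 30,
        boundaries_per_100aa: float = 3.0,
        rbf_bandwidth_rule: str = "median_heuristic",
        bandwidth_value: Optional[float] = None,
        min_spacing: Optional[int] = None,
        seed: int = 0,
    ):
        self.window = window
        self.boundaries_per_100aa = boundaries_per_100aa
        self.rbf_bandwidth_rule = rbf_bandwidth_rule
        self.bandwidth_value = bandwidth_value
        self.min_spacing = min_spacing
        self.seed = seed

    def _config(self) -> ChangePointConfig:
        return ChangePointConfig(
            window=self.window,
            boundaries_per_100aa=self.boundaries_per_100aa,
            rbf_bandwidth_rule=self.rbf_bandwidth_rule,
            bandwidth_value=self.bandwidth_value,
            min_spacing=self.min_spacing,
            seed=self.seed,
        )

    def fit(self, X, y=None, protein_id: str = "protein"):
        X = np.asarray(X, dtype=float)
        matrix = ResidueEmbeddingMatrix(protein_id=protein_id, values=X)
        config = self._config()
        self.bandwidth_ = resolve_bandwidth(matrix, config)
        self.gain_curve_ = gain_curve(matrix, config)
        self.boundaries_ = select_boundaries(self.gain_curve_, matrix.length, config)
        self.segments_ = segments_from_boundaries(protein_id, self.boundaries_, matrix.length)
        self.n_features_in_ = X.shape[1]
        self._matrix = matrix
        return self

    def predict(self, X=None) -> np.ndarray:
        """Segment label (0-based, left to right) per residue of the fitted protein."""
        self._check_fitted()
        labels = np.empty(self._matrix.length, dtype=int)
        for k, seg in enumerate(self.segments_):
            labels[seg.start : seg.end] = k
        return labels

    def fit_predict(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X, **kwargs).predict()

    def transform(self, X=None) -> np.ndarray:
        """Pooled segment embeddings (n_segments x D) of the fitted protein."""
        self._check_fitted()
        return np.stack([e.vector for e in pool_segments(self._matrix, self.segments_)])

    def score_segments(self, half_window: int = 15) -> List[Segment]:
        self._check_fitted()
        return score_segments(self._matrix, self.segments_, half_window)

    def _check_fitted(self) -> None:
        if not hasattr(self, "segments_"):
            raise RuntimeError("estimator is not fitted; call fit(X) first")
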