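"""Embedding visualization: RGB colour mapping, segment diagrams, heatmap order.

Segment embeddings are reduced to three dimensions (by default with UMAP at a
fixed seed; any corpus-to-3-vectors reducer can be plugged in), each dimension
is mean-centred across the whole corpus, squashed through a sigmoid and scaled
by 255:

    channel_d(s) = 255 / (1 + exp(-(X_d(s) - mean_d)))

The centring plus sigmoid turns the roughly normal reduced coordinates into a
more uniform spread of channel values, pushing colours away from mid-tone
greys. A segment sitting exactly at the corpus mean in a dimension maps to
127.5 in that channel; each channel is strictly increasing in its reduced
coordinate. Values are kept as floats and rounded only at serialization.

Means are computed once over the corpus passed to ``fit``; incremental
re-colouring of a growing corpus is deliberately unsupported (colours are only
comparable within one fitted corpus).
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, fcluster, optimal_leaf_ordering
from scipy.spatial.distance import pdist
from scipy.special import expit
from sklearn.base import BaseEstimator

from .types import Segment, segments_tile

Reducer = Callable[[np.ndarray], np.ndarray]


def umap_reducer(seed: int = 0, **kwargs) -> Reducer:
    """Default 3-D reducer: UMAP with a fixed seed (imported lazily)."""

    def reduce(X: np.ndarray) -> np.ndarray:
        import umap

        return umap.UMAP(n_components=3, random_state=seed, **kwargs).fit_transform(X)

    return reduce


def linear_reducer(projection: Optional[np.ndarray] = None, seed: int = 0) -> Reducer:
    """Deterministic stub reducer: a fixed random linear projection to 3-D."""

    def reduce(X: np.ndarray) -> np.ndarray:
        P = projection
        if P is None:
            rng = np.random.default_rng(seed)
            P = rng.standard_normal((X.shape[1], 3))
        return X @ P

    return reduce


class SegmentColorMapper(BaseEstimator):
    """Corpus of segment embeddings -> RGB colours in [0, 255].

    Parameters
    ----------
    reducer : callable, optional
        Maps an (n, D) corpus to (n, 3) coordinates; defaults to seeded UMAP.
    seed : int
        Seed for the default reducer.

    Attributes
    ----------
    coords_ : (n, 3) reduced coordinates of the fitted corpus.
    means_ : per-dimension corpus means used for centring.
    """

    SCALE = 255.0

    def __init__(self, reducer: Optional[Reducer] = None, seed: int = 0):
        self.reducer = reducer
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("colour mapping needs a corpus of at least 2 segments")
        reduce = self.reducer if self.reducer is not None else umap_reducer(self.seed)
        coords = np.asarray(reduce(X), dtype=float)
        if coords.shape != (X.shape[0], 3):
            raise ValueError(
                f"reducer must return an (n, 3) array; got shape {coords.shape}"
            )
        self.coords_ = coords
        self.means_ = coords.mean(axis=0)
        return self

    def transform(self, X=None) -> np.ndarray:
        """RGB float array (n, 3) for the fitted corpus."""
        if not hasattr(self, "coords_"):
            raise RuntimeError("mapper is not fitted")
        centred = self.coords_ - self.means_
        return self.SCALE * expit(centred)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform()


def embeddings_to_rgb(
    vectors: np.ndarray, reducer: Optional[Reducer] = None, seed: int = 0
) -> np.ndarray:
    """One-shot corpus-to-colours helper over :class:`SegmentColorMapper`."""
    return SegmentColorMapper(reducer=reducer, seed=seed).fit_transform(np.asarray(vectors))


def render_segment_diagram(
    protein_length: int,
    segments: Sequence[Segment],
    path,
    protein_id: Optional[str] = None,
) -> None:
    """Draw one protein as a horizontal bar of coloured segment blocks (SVG/PNG).

    Segments must tile the protein; block widths are proportional to segment
    length and boundary coordinates are annotated. Output is deterministic for
    fixed input (SVG hash salt pinned, no timestamps).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(segments, key=lambda s: s.start)
    if not segments_tile(ordered, protein_length):
        raise ValueError("segments must tile [0, protein_length) with no gaps/overlaps")
    pid = protein_id or ordered[0].protein_id
    with matplotlib.rc_context({"svg.hashsalt": pid}):
        fig, ax = plt.subplots(figsize=(8, 1.4))
        for seg in ordered:
            color = tuple(np.clip(np.asarray(seg.color, dtype=float) / 255.0, 0, 1)) \
                if seg.color is not None else (0.7, 0.7, 0.7)
            ax.axvspan(seg.start, seg.end, color=color)
            ax.axvline(seg.start, color="black", lw=0.4)
        ax.axvline(protein_length, color="black", lw=0.4)
        ax.set_xlim(0, protein_length)
        ax.set_yticks([])
        ax.set_xticks([0] + [s.end for s in ordered])
        ax.set_xlabel("residue")
        ax.set_title(pid)
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None})
        plt.close(fig)


def cluster_leaf_order(X: np.ndarray) -> np.ndarray:
    """Row permutation for heatmaps: average-linkage cosine clustering with
    optimal leaf ordering.

    Degenerate inputs where all rows are identical keep their input order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("leaf ordering needs at least 2 rows")
    if np.allclose(X, X[0]):
        return np.arange(X.shape[0])
    dist = pdist(X, metric="cosine")
    dist = np.clip(dist, 0.0, None)
    Z = linkage(dist, method="average")
    return leaves_list(optimal_leaf_ordering(Z, dist))


def residue_cluster(X: np.ndarray, distance_threshold: float = 0.5) -> np.ndarray:
    """Flat clusters of residue embeddings by cutting an average-linkage
    cosine dendrogram at ``distance_threshold``.

    Used e.g. to group the arginine embeddings of a protein family; at the
    default cut of 0.5 two orthogonal groups (cosine distance 1) separate.
    Labels are 1-based cluster ids partitioning the input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array of residue embeddings")
    n = X.shape[0]
    if n == 1:
        return np.array([1])
    dist = np.clip(pdist(X, metric="cosine"), 0.0, None)
    Z = linkage(dist, method="average")
    return fcluster(Z, t=distance_threshold, criterion="distance")
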