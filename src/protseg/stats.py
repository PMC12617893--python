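"""Statistics behind discovery claims.

Two tools live here:

* a shuffle (permutation) test asking whether a cluster of residues is
  enriched for a binary site annotation — e.g. whether a cluster of arginine
  embeddings contains more annotated methylation sites than chance. Site
  flags are permuted among exchangeable residues (residues of the same
  amino-acid type in the same protein, or within the same annotated region),
  holding cluster membership fixed; the observed in-cluster flagged fraction
  is compared with the permutation null.
* graph-community (Leiden) clustering of unannotated segment embeddings in
  full dimension, used to propose groups of functionally related segments.

Empirical p-values follow the ``r / n`` convention with a ``< 1/n`` marker
when no null draw reaches the observed value (no +1 smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors


@dataclass
class ShuffleTestResult:
    """Outcome of the cluster-enrichment shuffle test."""

    observed_fraction: float
    null_mean: float
    null_sd: float
    z_score: float
    empirical_p: Optional[float]  # None when below resolution
    p_label: str  # e.g. "12/10000" or "<1/10000"
    n_shuffles: int


def shuffle_enrichment_test(
    residues: pd.DataFrame,
    cluster: int,
    shuffle_scope: str = "within_protein",
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> ShuffleTestResult:
    """Permutation test for site enrichment in one residue cluster.

    Parameters
    ----------
    residues : DataFrame with columns ``protein_id``, ``flag`` (bool/0-1),
        ``cluster`` (int), optionally ``residue_type`` and ``region_id``.
    cluster : the cluster id whose flagged fraction is tested.
    shuffle_scope : ``"within_protein"`` permutes flags among residues of the
        same amino-acid type within each protein; ``"within_region"`` permutes
        within each annotated region (requires ``region_id``).
    n_shuffles : number of permutations.
    seed : RNG seed.

    The observed statistic is the fraction of the cluster's residues that are
    flagged. Each shuffle permutes the flags within every exchangeability
    group independently and recomputes that fraction; the z-score is
    ``(obs - null_mean) / null_sd`` and the empirical p-value is the fraction
    of null draws at least as large as the observation.
    """
    required = {"protein_id", "flag", "cluster"}
    missing = required - set(residues.columns)
    if missing:
        raise ValueError(f"residue table missing columns: {sorted(missing)}")
    if shuffle_scope == "within_protein":
        group_cols = ["protein_id"]
        if "residue_type" in residues.columns:
            group_cols.append("residue_type")
    elif shuffle_scope == "within_region":
        if "region_id" not in residues.columns:
            raise ValueError("within_region scope requires a region_id column")
        group_cols = ["protein_id", "region_id"]
    else:
        raise ValueError(f"unknown shuffle scope {shuffle_scope!r}")

    flags = residues["flag"].to_numpy().astype(bool)
    in_cluster = (residues["cluster"].to_numpy() == cluster)
    cluster_size = int(in_cluster.sum())
    if cluster_size == 0:
        raise ValueError(f"cluster {cluster!r} has no residues")
    if not flags.any():
        raise ValueError("no flagged residues anywhere; nothing to test")

    observed = float(flags[in_cluster].sum()) / cluster_size

    rng = np.random.default_rng(seed)
    null_counts = np.zeros(n_shuffles, dtype=float)
    groups = residues.groupby(group_cols, sort=True).indices
    for key in sorted(groups):
        idx = np.asarray(groups[key])
        g_flags = flags[idx]
        g_members = in_cluster[idx]
        if not g_flags.any() or not g_members.any():
            continue
        # all n_shuffles permutations of this group at once
        ranks = np.argsort(rng.random((n_shuffles, idx.size)), axis=1)
        permuted = g_flags[ranks]  # (n_shuffles, group_size)
        null_counts += permuted[:, g_members].sum(axis=1)

    null_frac = null_counts / cluster_size
    null_mean = float(null_frac.mean())
    null_sd = float(null_frac.std(ddof=0))
    z = (observed - null_mean) / null_sd if null_sd > 0 else np.inf
    r = int(np.sum(null_frac >= observed))
    if r == 0:
        p, label = None, f"<1/{n_shuffles}"
    else:
        p, label = r / n_shuffles, f"{r}/{n_shuffles}"
    return ShuffleTestResult(
        observed_fraction=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=float(z),
        empirical_p=p,
        p_label=label,
        n_shuffles=n_shuffles,
    )


class EmbeddingGraphClusterer(BaseEstimator):
    """Leiden community detection on a k-NN graph of embeddings.

    Embeddings are used in full dimension (no reduction before clustering).
    A cosine k-NN graph is built, symmetrized, and partitioned with the
    Leiden algorithm (RB-configuration quality, unlimited iterations) at the
    given resolution. Deterministic for a fixed seed; every input point is
    labelled.
    """

    def __init__(self, resolution: float = 2.0, n_neighbors: int = 15, seed: int = 0):
        self.resolution = resolution
        self.n_neighbors = n_neighbors
        self.seed = seed

    def fit_predict(self, X, y=None) -> np.ndarray:
        import igraph as ig
        import leidenalg

        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 2:
            self.labels_ = np.zeros(n, dtype=int)
            return self.labels_
        k = min(self.n_neighbors, n - 1)
        knn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(X)
        _, indices = knn.kneighbors(X)
        edges = set()
        for i in range(n):
            for j in indices[i, 1:]:
                edges.add((min(i, int(j)), max(i, int(j))))
        graph = ig.Graph(n=n, edges=sorted(edges))
        partition = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=self.resolution,
            seed=self.seed,
            n_iterations=-1,
        )
        self.labels_ = np.asarray(partition.membership, dtype=int)
        return self.labels_

    def fit(self, X, y=None):
        self.fit_predict(X)
        return self


def cluster_unannotated(
    X: np.ndarray, resolution: float = 2.0, seed: int = 0, n_neighbors: int = 15
) -> np.ndarray:
    """Community labels for unannotated segment embeddings (thin wrapper)."""
    return EmbeddingGraphClusterer(
        resolution=resolution, n_neighbors=n_neighbors, seed=seed
    ).fit_predict(X)
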