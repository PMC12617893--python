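"""Synthetic fixtures: block-structured embeddings with planted boundaries.

The generator emulates what the segmenter consumes at proteome scale — a
per-residue embedding matrix per protein — as a piecewise-constant signal:
each protein is a sequence of blocks, every block is assigned a class, and
each residue's row is its block's class mean plus isotropic Gaussian noise.
Class means are drawn once per corpus and rescaled so the minimum pairwise
distance is a stated multiple of the per-dimension noise SD, which makes
"separation" a single interpretable knob.

Also generated: labelled segment corpora for neighbour/transfer tests,
annotation sets with positional jitter and dropout, and null/enriched
site-flag tables for the shuffle test. Everything is a pure function of
(spec, seed): identical inputs regenerate identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import Annotation, ProteinRecord, ResidueEmbeddingMatrix, Segment


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic corpus.

    ``separation`` is per dimension: class means differ by ``separation``
    noise SDs per coordinate on root-mean-square average, i.e. the minimum
    pairwise Euclidean distance between class means is
    ``separation * noise_sd * sqrt(dim)``. Blocks are at least ``min_block``
    residues so a sliding window of the default size fits inside each.
    """

    n_proteins: int = 100
    length: int = 300
    n_boundaries: int = 3
    n_classes: int = 4
    dim: int = 32
    noise_sd: float = 1.0
    separation: float = 2.0
    min_block: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.dim < 1:
            raise ValueError("need at least one class and one dimension")
        if self.noise_sd < 0 or self.separation < 0:
            raise ValueError("noise_sd and separation must be non-negative")
        if (self.n_boundaries + 1) * self.min_block > self.length:
            raise ValueError("blocks of min_block residues do not fit the length")


def class_means(spec: SyntheticSpec) -> np.ndarray:
    """Corpus-wide class mean vectors with controlled minimum separation."""
    rng = np.random.default_rng([spec.seed, 7])
    means = rng.standard_normal((spec.n_classes, spec.dim))
    if spec.n_classes == 1:
        return means
    dists = [
        np.linalg.norm(means[i] - means[j])
        for i in range(spec.n_classes)
        for j in range(i + 1, spec.n_classes)
    ]
    target = spec.separation * (spec.noise_sd if spec.noise_sd > 0 else 1.0) * np.sqrt(spec.dim)
    return means * (target / min(dists))


def _plant_boundaries(rng: np.random.Generator, spec: SyntheticSpec) -> List[int]:
    """Boundary positions leaving every block at least ``min_block`` long."""
    free = spec.length - (spec.n_boundaries + 1) * spec.min_block
    cuts = np.sort(rng.integers(0, free + 1, size=spec.n_boundaries))
    return [int(c + (i + 1) * spec.min_block) for i, c in enumerate(cuts)]


def make_protein(
    spec: SyntheticSpec, index: int, means: Optional[np.ndarray] = None
) -> Tuple[ResidueEmbeddingMatrix, List[int], List[int]]:
    """One synthetic protein: (matrix, planted boundaries, block class labels).

    Deterministic per (spec.seed, index). Adjacent blocks always receive
    different classes so every planted boundary is a real change point.
    """
    if means is None:
        means = class_means(spec)
    rng = np.random.default_rng([spec.seed, index])
    boundaries = _plant_boundaries(rng, spec)
    n_blocks = spec.n_boundaries + 1
    labels: List[int] = []
    for _ in range(n_blocks):
        choices = [c for c in range(spec.n_classes) if not labels or c != labels[-1]]
        if not choices:  # single-class corpus: change points carry no signal
            choices = list(range(spec.n_classes))
        labels.append(int(rng.choice(choices)))
    edges = [0] + boundaries + [spec.length]
    rows = np.empty((spec.length, spec.dim))
    for (a, b), label in zip(zip(edges, edges[1:]), labels):
        block = means[label] + spec.noise_sd * rng.standard_normal((b - a, spec.dim))
        rows[a:b] = block
    matrix = ResidueEmbeddingMatrix(protein_id=f"SYN{index:04d}", values=rows)
    return matrix, boundaries, labels


def make_corpus(
    spec: SyntheticSpec,
) -> Tuple[List[ResidueEmbeddingMatrix], Dict[str, List[int]], Dict[str, List[int]]]:
    """All proteins of the corpus plus truth maps id -> boundaries, id -> labels."""
    means = class_means(spec)
    matrices, truth_b, truth_l = [], {}, {}
    for i in range(spec.n_proteins):
        m, b, l = make_protein(spec, i, means)
        matrices.append(m)
        truth_b[m.protein_id] = b
        truth_l[m.protein_id] = l
    return matrices, truth_b, truth_l


def true_segments(
    matrices: Sequence[ResidueEmbeddingMatrix], boundaries: Dict[str, List[int]]
) -> List[Segment]:
    """Ground-truth block intervals as Segment objects."""
    out = []
    for m in matrices:
        edges = [0] + boundaries[m.protein_id] + [m.length]
        out.extend(Segment(m.protein_id, a, b) for a, b in zip(edges, edges[1:]))
    return out


def make_labeled_corpus(
    spec: SyntheticSpec,
) -> Tuple[List[Segment], List[str], np.ndarray]:
    """Pooled true-block embeddings with class labels, for 1-nn/transfer tests."""
    matrices, truth_b, truth_l = make_corpus(spec)
    segments: List[Segment] = []
    labels: List[str] = []
    vectors: List[np.ndarray] = []
    for m in matrices:
        edges = [0] + truth_b[m.protein_id] + [m.length]
        for (a, b), label in zip(zip(edges, edges[1:]), truth_l[m.protein_id]):
            segments.append(Segment(m.protein_id, a, b))
            labels.append(f"class{label}")
            vectors.append(m.values[a:b].mean(axis=0))
    return segments, labels, np.stack(vectors)


def make_annotations(
    matrices: Sequence[ResidueEmbeddingMatrix],
    boundaries: Dict[str, List[int]],
    labels: Dict[str, List[int]],
    jitter_sd: float = 0.0,
    drop_rate: float = 0.0,
    seed: int = 0,
    source: str = "synthetic",
) -> List[Annotation]:
    """True blocks as annotations, with endpoint jitter and dropout.

    Endpoints are perturbed by rounded Gaussian jitter (clipped to the
    protein); perturbations that would invert or empty an interval are
    resampled. A ``drop_rate`` fraction of annotations is removed at random.
    """
    rng = np.random.default_rng([seed, 11])
    out: List[Annotation] = []
    for m in matrices:
        edges = [0] + boundaries[m.protein_id] + [m.length]
        for (a, b), label in zip(zip(edges, edges[1:]), labels[m.protein_id]):
            if drop_rate > 0 and rng.random() < drop_rate:
                continue
            start, end = a, b
            if jitter_sd > 0:
                for _ in range(1000):
                    start = int(np.clip(round(a + jitter_sd * rng.standard_normal()), 0, m.length - 1))
                    end = int(np.clip(round(b + jitter_sd * rng.standard_normal()), 1, m.length))
                    if start < end:
                        break
                else:  # pragma: no cover - vanishing probability
                    start, end = a, b
            out.append(
                Annotation(
                    protein_id=m.protein_id,
                    start=start,
                    end=end,
                    label=f"class{label}",
                    source=source,
                )
            )
    return out


def make_site_table(
    n_proteins: int = 20,
    residues_per_protein: int = 30,
    flag_rate: float = 0.3,
    cluster_rate: float = 0.25,
    enrichment: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Residue table for the shuffle test, null or enriched.

    Each residue carries a protein id, a binary site flag and a cluster
    membership (cluster 1 vs 0). Under ``enrichment=0`` flags are assigned
    uniformly at random within each protein, independent of cluster — the
    exchangeable null. Positive ``enrichment`` tilts flag placement towards
    cluster members: within each protein, the same number of flags is placed
    with sampling weights ``1 + enrichment`` on cluster members.
    """
    rng = np.random.default_rng([seed, 23])
    rows = []
    for p in range(n_proteins):
        pid = f"P{p:03d}"
        n = residues_per_protein
        n_flags = rng.binomial(n, flag_rate)
        members = rng.random(n) < cluster_rate
        weights = np.where(members, 1.0 + enrichment, 1.0)
        weights = weights / weights.sum()
        flagged_idx = rng.choice(n, size=min(n_flags, n), replace=False, p=weights)
        flags = np.zeros(n, dtype=bool)
        flags[flagged_idx] = True
        for i in range(n):
            rows.append(
                {
                    "protein_id": pid,
                    "residue_type": "R",
                    "flag": bool(flags[i]),
                    "cluster": int(members[i]),
                }
            )
    return pd.DataFrame(rows)


class SyntheticProvider:
    """Embedding provider serving matrices of a synthetic corpus by protein id."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self._means = class_means(spec)

    def embed(self, protein: ProteinRecord) -> ResidueEmbeddingMatrix:
        if not protein.id.startswith("SYN"):
            raise KeyError(f"protein {protein.id!r} not in synthetic corpus")
        index = int(protein.id[3:])
        matrix, _, _ = make_protein(self.spec, index, self._means)
        return matrix
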