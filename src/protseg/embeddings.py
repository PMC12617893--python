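"""Per-residue and per-segment vector representations.

The segment representation at the heart of the toolkit is average pooling:
the embedding of a segment ``[a, b)`` is the column-wise mean of rows
``a .. b-1`` of the protein's residue-level matrix. Fragments are never
re-embedded; segments are always cut out of the full-protein matrix.

K-mer count vectors over the segment's subsequence serve as a
sequence-composition baseline: overlapping windows, lexicographic dimension
order, unit Euclidean norm. Rare/ambiguous letters (U, Z, O, B) are mapped to
X, which participates as a 21st symbol, so the k-mer space has 21**k
dimensions.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Mapping, Optional, Protocol

import numpy as np

from .types import (
    STANDARD_AA,
    ProteinRecord,
    ResidueEmbeddingMatrix,
    Segment,
    SegmentEmbedding,
)

#: Alphabet used for k-mer counting: the 20 standard residues plus X.
KMER_ALPHABET = "".join(sorted(STANDARD_AA + "X"))

#: Ambiguity mapping applied before k-mer counting.
AMBIGUOUS_TO_X = str.maketrans({c: "X" for c in "UZOB"})


def pool_segment(matrix: ResidueEmbeddingMatrix, segment: Segment) -> SegmentEmbedding:
    """Average-pool the residue matrix over one segment.

    For a segment spanning ``[100, 125)`` on an L x 1024 matrix this takes the
    25 x 1024 sub-matrix and reduces it to a single 1024-vector by the
    arithmetic mean of its rows.
    """
    if segment.protein_id != matrix.protein_id:
        raise ValueError(
            f"segment protein {segment.protein_id!r} != matrix protein {matrix.protein_id!r}"
        )
    if segment.end > matrix.length:
        raise ValueError(
            f"segment [{segment.start}, {segment.end}) exceeds protein length {matrix.length}"
        )
    vector = matrix.values[segment.start : segment.end].mean(axis=0)
    return SegmentEmbedding(
        protein_id=matrix.protein_id, segment=segment, vector=vector, provenance="pooled_pLM"
    )


def pool_segments(
    matrix: ResidueEmbeddingMatrix, segments: Iterable[Segment]
) -> List[SegmentEmbedding]:
    return [pool_segment(matrix, seg) for seg in segments]


def kmer_vocabulary(k: int) -> List[str]:
    """All k-mers over the 21-letter alphabet in lexicographic order."""
    return ["".join(p) for p in itertools.product(KMER_ALPHABET, repeat=k)]


def kmer_embedding(
    fragment: str,
    k: int,
    protein_id: str = "",
    segment: Optional[Segment] = None,
) -> SegmentEmbedding:
    """Normalized overlapping k-mer count vector of a sequence fragment.

    ``len(fragment) - k + 1`` windows are counted into a 21**k vector
    (lexicographic dimension order) and the result is scaled to unit
    Euclidean norm. 1-mers are one-hot composition counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fragment = fragment.upper().translate(AMBIGUOUS_TO_X)
    if len(fragment) < k:
        raise ValueError(f"fragment of length {len(fragment)} is shorter than k={k}")
    bad = set(fragment) - set(KMER_ALPHABET)
    if bad:
        raise ValueError(f"fragment contains letters outside the alphabet: {sorted(bad)}")
    counts = kmer_raw_counts(fragment, k)
    vector = counts / np.linalg.norm(counts)
    seg = segment if segment is not None else Segment(protein_id or "fragment", 0, len(fragment))
    return SegmentEmbedding(
        protein_id=seg.protein_id,
        segment=seg,
        vector=vector,
        provenance="one_hot" if k == 1 else f"kmer_{k}",
    )


def kmer_raw_counts(fragment: str, k: int) -> np.ndarray:
    """Unnormalized overlapping k-mer counts (diagnostic helper)."""
    fragment = fragment.upper().translate(AMBIGUOUS_TO_X)
    if len(fragment) < k:
        raise ValueError(f"fragment of length {len(fragment)} is shorter than k={k}")
    index = {aa: i for i, aa in enumerate(KMER_ALPHABET)}
    n_letters = len(KMER_ALPHABET)
    counts = np.zeros(n_letters**k, dtype=float)
    for start in range(len(fragment) - k + 1):
        pos = 0
        for c in fragment[start : start + k]:
            pos = pos * n_letters + index[c]
        counts[pos] += 1
    return counts


# ---------------------------------------------------------------------------
# Providers
# ---------------------------------------------------------------------------

class LookupError_(KeyError):
    """A protein is absent from an embedding provider."""


class EmbeddingProvider(Protocol):
    """Anything that maps a :class:`ProteinRecord` to its residue matrix."""

    def embed(self, protein: ProteinRecord) -> ResidueEmbeddingMatrix: ...


class StoreProvider:
    """Provider backed by precomputed matrices (e.g. read from an HDF5 store)."""

    def __init__(self, matrices: Mapping[str, ResidueEmbeddingMatrix]):
        self._matrices = dict(matrices)

    def embed(self, protein: ProteinRecord) -> ResidueEmbeddingMatrix:
        try:
            matrix = self._matrices[protein.id]
        except KeyError:
            raise LookupError_(f"protein {protein.id!r} not in embedding store") from None
        if matrix.length != len(protein):
            raise ValueError(
                f"stored matrix for {protein.id!r} has {matrix.length} rows but the "
                f"sequence has {len(protein)} residues"
            )
        return matrix


class ProtT5Provider:
    """Adapter contract for the ProtT5-XL-UniRef50 half-precision encoder.

    The encoder itself is an optional runtime dependency (``torch`` +
    ``transformers``); this class validates inputs — in particular it refuses
    sequences of 8000 residues or more, the model's practical context limit —
    before attempting to load the model, so the contract is testable without
    the model installed.
    """

    MODEL_NAME = "Rostlab/prot_t5_xl_half_uniref50-enc"

    def __init__(self, max_length: int = 8000, device: str = "cpu"):
        self.max_length = max_length
        self.device = device
        self._model = None

    def embed(self, protein: ProteinRecord) -> ResidueEmbeddingMatrix:
        if len(protein) >= self.max_length:
            raise ValueError(
                f"protein {protein.id!r} has {len(protein)} residues; the encoder "
                f"accepts only sequences shorter than {self.max_length}"
            )
        self._load()
        raise NotImplementedError  # pragma: no cover - requires torch at runtime

    def _load(self):  # pragma: no cover - requires torch at runtime
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the ProtT5 adapter requires torch and transformers; install them "
                "or use a precomputed embedding store"
            ) from exc


def get_provider(name: str, **kwargs) -> EmbeddingProvider:
    """Provider registry keyed by CLI flag value."""
    if name == "store":
        return StoreProvider(kwargs["matrices"])
    if name == "synthetic":
        from .synthetic import SyntheticProvider

        return SyntheticProvider(kwargs["spec"])
    if name == "prott5":
        return ProtT5Provider(**kwargs)
    raise ValueError(f"unknown embedding provider {name!r}")
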