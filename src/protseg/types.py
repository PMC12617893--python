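"""Core domain objects shared across the toolkit.

All interval coordinates are 0-based, half-open ``[start, end)`` internally;
1-based inclusive conventions (UniProt-style feature tables) are converted at
the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

#: Standard amino acids plus ambiguity/rare letters accepted in sequences.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AA = STANDARD_AA + "XUBZO"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - set(EXTENDED_AA)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: residues outside accepted alphabet: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


def _check_interval(start: int, end: int, what: str) -> None:
    if start < 0 or end <= start:
        raise ValueError(f"{what}: invalid interval [{start}, {end})")


@dataclass(frozen=True)
class Segment:
    """A 0-based half-open interval on one protein, optionally scored/coloured."""

    protein_id: str
    start: int
    end: int
    score: Optional[float] = None
    color: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        _check_interval(self.start, self.end, f"segment on {self.protein_id!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def with_score(self, score: float) -> "Segment":
        return replace(self, score=score)

    def with_color(self, color: Tuple[float, float, float]) -> "Segment":
        return replace(self, color=color)


@dataclass(frozen=True)
class Annotation:
    """A labelled interval on a protein with a source tag.

    ``source`` mirrors the provenance tags of UniProt feature rows
    (e.g. ``UniProt``, ``MobiDB``, ``ProRule``) or the name of an external
    prediction tool; ``score`` carries e-values / profile scores for the
    latter.
    """

    protein_id: str
    start: int
    end: int
    label: str
    source: str = "UniProt"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        _check_interval(self.start, self.end, f"annotation on {self.protein_id!r}")
        if not self.label:
            raise ValueError(f"annotation on {self.protein_id!r}: empty label")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ResidueEmbeddingMatrix:
    """Per-residue embedding of one protein: an L x D float matrix.

    Rows are residues in sequence order; columns are embedding dimensions
    (1024 for ProtT5, arbitrary here). Entries must be finite; half precision
    input is promoted to single precision.
    """

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(
                f"embedding for {self.protein_id!r}: expected 2-D L x D matrix, "
                f"got shape {arr.shape}"
            )
        if arr.dtype != np.float64:
            arr = arr.astype(np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"embedding for {self.protein_id!r}: non-finite entries")
        self.values = arr

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SegmentEmbedding:
    """A D-vector representing one segment, with its provenance."""

    protein_id: str
    segment: Segment
    vector: np.ndarray
    provenance: str = "pooled_pLM"  # pooled_pLM | kmer_1 | kmer_3 | one_hot

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.ndim != 1:
            raise ValueError("segment embedding vector must be 1-D")
        if not np.all(np.isfinite(vec)):
            raise ValueError("segment embedding vector has non-finite entries")
        object.__setattr__(self, "vector", vec)


def segments_tile(segments: Sequence[Segment], length: int) -> bool:
    """True iff ``segments`` partition ``[0, length)`` with no gaps/overlaps."""
    if not segments:
        return False
    ordered = sorted(segments, key=lambda s: s.start)
    if ordered[0].start != 0 or ordered[-1].end != length:
        return False
    return all(a.end == b.start for a, b in zip(ordered, ordered[1:]))


def sort_segments(segments: Sequence[Segment]) -> list:
    return sorted(segments, key=lambda s: (s.protein_id, s.start, s.end))
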