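"""Readers and writers for the external representations.

Formats handled here:

* FASTA protein sequences (via Biopython).
* Tab-separated annotation tables with columns
  ``protein_id  start  end  label  source  [score]``; UniProt-style tables are
  declared 1-based inclusive at read time and converted to the internal
  0-based half-open convention.
* A hierarchical array container (HDF5) holding one named L x D float dataset
  per protein for residue-level embeddings.
* BED-like segment tables (0-based half-open, stated in a header comment).

Rows with non-numeric positions (``1-?``, ``<1-100`` and the like, which mark
positional uncertainty in UniProt exports) are dropped and counted rather than
guessed at.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
from Bio import SeqIO

from .types import Annotation, ProteinRecord, ResidueEmbeddingMatrix, Segment, sort_segments

PathLike = Union[str, Path]

SEGMENT_HEADER = "#coords=0-based,half-open"


class ParseError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> List[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; duplicate identifiers and empty sequences are
    rejected with an error naming the offending record.
    """
    records: List[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA entry with empty header")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate protein id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
        seen.add(rec.id)
    return records


def write_fasta(path: PathLike, records: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Parsed annotations plus bookkeeping about dropped/rejected rows."""

    annotations: List[Annotation] = field(default_factory=list)
    n_dropped_non_numeric: int = 0
    n_rejected: int = 0

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)


def _parse_position(text: str) -> Optional[int]:
    text = text.strip()
    if not text:
        return None
    try:
        return int(text)
    except ValueError:
        return None


def read_annotations(
    path: PathLike,
    one_based_inclusive: bool = False,
    protein_lengths: Optional[Dict[str, int]] = None,
) -> AnnotationTable:
    """Read a TSV annotation table.

    Expected columns: ``protein_id  start  end  label  source  [score]``.
    A header line starting with ``protein_id`` or ``#`` is skipped.

    Rows whose positions contain non-numeric characters are dropped and
    counted in ``n_dropped_non_numeric``. Rows that are inverted after
    coordinate conversion are rejected with a warning. When
    ``one_based_inclusive`` is true, ``(start, end)`` is converted to the
    internal convention as ``(start - 1, end)``.
    """
    table = AnnotationTable()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "protein_id":
                continue
            if len(row) < 5:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 5 tab-separated columns, got {len(row)}"
                )
            pid, start_s, end_s, label, source = (c.strip() for c in row[:5])
            score = None
            if len(row) > 5 and row[5].strip():
                try:
                    score = float(row[5])
                except ValueError:
                    warnings.warn(f"{path}:{lineno}: unparsable score {row[5]!r}; row rejected")
                    table.n_rejected += 1
                    continue
            start = _parse_position(start_s)
            end = _parse_position(end_s)
            if start is None or end is None:
                table.n_dropped_non_numeric += 1
                continue
            if one_based_inclusive:
                start, end = start - 1, end
            if start < 0 or end <= start:
                warnings.warn(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) for {pid!r}; row rejected"
                )
                table.n_rejected += 1
                continue
            if protein_lengths is not None and pid in protein_lengths and end > protein_lengths[pid]:
                warnings.warn(
                    f"{path}:{lineno}: annotation end {end} beyond protein length "
                    f"{protein_lengths[pid]} for {pid!r}; row rejected"
                )
                table.n_rejected += 1
                continue
            table.annotations.append(
                Annotation(protein_id=pid, start=start, end=end, label=label, source=source, score=score)
            )
    return table


def write_annotations(
    path: PathLike, annotations: Iterable[Annotation], one_based_inclusive: bool = False
) -> None:
    """Write annotations as TSV; optionally back in 1-based inclusive coordinates."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "start", "end", "label", "source", "score"])
        for ann in annotations:
            start, end = ann.start, ann.end
            if one_based_inclusive:
                start = start + 1
            writer.writerow(
                [ann.protein_id, start, end, ann.label, ann.source,
                 "" if ann.score is None else repr(ann.score)]
            )


# ---------------------------------------------------------------------------
# Embedding store (HDF5)
# ---------------------------------------------------------------------------

def write_embedding_store(path: PathLike, matrices: Dict[str, np.ndarray]) -> None:
    """Write one float dataset per protein id to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        for pid, arr in matrices.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"embedding for {pid!r} is not 2-D")
            fh.create_dataset(pid, data=arr)


def read_embedding_store(
    path: PathLike, sequences: Optional[Dict[str, str]] = None
) -> Dict[str, ResidueEmbeddingMatrix]:
    """Read an HDF5 embedding container into a mapping of matrices.

    The embedding dimension must be consistent across the corpus; when
    ``sequences`` is given, each matrix row count must equal the corresponding
    sequence length. Half precision data is promoted to single precision.
    """
    out: Dict[str, ResidueEmbeddingMatrix] = {}
    dim: Optional[int] = None
    with h5py.File(path, "r") as fh:
        for pid in sorted(fh.keys()):
            arr = np.asarray(fh[pid])
            if arr.ndim != 2:
                raise ParseError(f"{path}: dataset {pid!r} is not a 2-D matrix")
            if dim is None:
                dim = arr.shape[1]
            elif arr.shape[1] != dim:
                raise ParseError(
                    f"{path}: inconsistent embedding dimension for {pid!r}: "
                    f"{arr.shape[1]} != {dim}"
                )
            if sequences is not None and pid in sequences and arr.shape[0] != len(sequences[pid]):
                raise ParseError(
                    f"{path}: matrix for {pid!r} has {arr.shape[0]} rows but the "
                    f"sequence has {len(sequences[pid])} residues"
                )
            out[pid] = ResidueEmbeddingMatrix(protein_id=pid, values=arr)
    return out


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

def _format_color(color) -> str:
    r, g, b = (int(round(float(c))) for c in color)
    return f"{r},{g},{b}"


def write_segments(path: PathLike, segments: Iterable[Segment]) -> None:
    """Write a BED-like segment TSV, deterministically ordered by (protein, start)."""
    with open(path, "w", newline="") as fh:
        fh.write(SEGMENT_HEADER + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "start", "end", "score", "color"])
        for seg in sort_segments(list(segments)):
            writer.writerow(
                [
                    seg.protein_id,
                    seg.start,
                    seg.end,
                    "" if seg.score is None else repr(float(seg.score)),
                    "" if seg.color is None else _format_color(seg.color),
                ]
            )


def read_segments(path: PathLike) -> List[Segment]:
    segments: List[Segment] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "protein_id":
                continue
            pid, start, end = row[0], int(row[1]), int(row[2])
            score = float(row[3]) if len(row) > 3 and row[3] else None
            color = None
            if len(row) > 4 and row[4]:
                color = tuple(float(c) for c in row[4].split(","))
            segments.append(Segment(protein_id=pid, start=start, end=end, score=score, color=color))
    return segments
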