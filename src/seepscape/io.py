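"""Readers and writers for the tabular, matrix, and sequence formats.

Profile tables travel as TSV/CSV with a fixed header; distance matrices as
PHYLIP square or lower-triangle text; alignments as FASTA. Every
reader/writer pair round-trips valid data exactly (values serialized at 10
significant digits), and readers raise typed errors instead of coercing.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, FormatError, ValidationError
from .profiles import PROFILE_COLUMNS, ProfileTable

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


def read_profile_table(path, dialect: str = "tsv") -> ProfileTable:
    """Read and validate a core-interval measurement table."""
    if dialect not in _DIALECT_SEP:
        raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    path = Path(path)
    df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], dtype={"core_id": str, "variable": str})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns and c != "replicate"]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    return ProfileTable(df)


def write_profile_table(table: ProfileTable, path, dialect: str = "tsv") -> None:
    """Write a profile table; numeric values at 10 significant digits."""
    if dialect not in _DIALECT_SEP:
        raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    df = table.df.copy()
    for col in ("depth_top_cm", "depth_bottom_cm", "value"):
        df[col] = df[col].map(lambda v: f"{v:.10g}")
    df["replicate"] = df["replicate"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=_DIALECT_SEP[dialect], index=False)


@dataclass(frozen=True)
class DistanceMatrixFile:
    """Labeled symmetric pairwise distance matrix with entries in [0, 1]."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if np.any(d < 0) or np.any(d > 1):
            raise ValidationError("distances must lie in [0, 1]")
        if np.any(np.abs(np.diag(d)) > 1e-9):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(np.abs(d - d.T) > 1e-9):
            i, j = np.unravel_index(np.argmax(np.abs(d - d.T)), d.shape)
            raise ValidationError(
                f"matrix asymmetric beyond 1e-9 at ({self.labels[i]}, {self.labels[j]})"
            )
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", list(self.labels))


def read_distance_matrix(path) -> DistanceMatrixFile:
    """Read a PHYLIP distance matrix, square or lower-triangle dialect.

    The first line carries the taxon count; each following row a label and
    its distances. Lower-triangle input (row i holds i entries) is mirrored
    into a full symmetric matrix.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path.name}: empty file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise FormatError(f"{path.name}: first line must be the taxon count") from exc
    if len(lines) - 1 != n:
        raise FormatError(f"{path.name}: expected {n} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path.name}: non-numeric distance in row {parts[0]!r}") from exc
    counts = [len(r) for r in rows]
    if counts == [n] * n:
        d = np.array(rows)
    elif counts == list(range(n)):
        d = np.zeros((n, n))
        for i, r in enumerate(rows):
            d[i, :i] = r
        d = d + d.T
    else:
        raise FormatError(
            f"{path.name}: rows are neither square ({n} entries each) nor lower-triangle"
        )
    return DistanceMatrixFile(labels, d)


def write_distance_matrix(m: DistanceMatrixFile, path) -> None:
    """Write a PHYLIP square distance matrix at 10 significant digits."""
    with open(path, "w") as fh:
        fh.write(f"{len(m.labels)}\n")
        for label, row in zip(m.labels, m.d):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass(frozen=True)
class Alignment:
    """Ordered aligned sequence set; equal lengths, gaps preserved, uppercase."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            seen, dup = set(), None
            for i in self.ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise AlignmentError(f"duplicate sequence id {dup!r}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            ref = len(self.sequences[0])
            off = next(i for i, s in zip(self.ids, self.sequences) if len(s) != ref)
            raise AlignmentError(f"record {off!r} length differs from first record ({ref})")
        object.__setattr__(self, "sequences", [s.upper() for s in self.sequences])

    def __len__(self) -> int:
        return len(self.ids)


def read_alignment_fasta(path) -> Alignment:
    """Read an aligned FASTA file (all records the same length)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{Path(path).name}: no FASTA records")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.ids, alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")
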