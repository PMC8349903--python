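"""File interfaces: FASTQ pair streaming and count/profile matrix I/O.

Matrices are cells x probes.  TSV is the canonical dialect (UTF-8,
tab-separated, header row, first column ``cell_id``); MatrixMarket
coordinate files with ``.rows.txt`` / ``.cols.txt`` sidecars are supported
for sparse interchange.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO


class FastqError(ValueError):
    pass


class MalformedFastqError(FastqError):
    """A FASTQ record is truncated or structurally invalid."""


class PairDesyncError(FastqError):
    """Paired FASTQ files have different record counts."""


class MatrixError(ValueError):
    pass


# ---------------------------------------------------------------------------
# matrices


@dataclass
class CountMatrix:
    """Non-negative integer barcode counts, cells x probes.

    ``unassigned_per_cell`` tallies reads whose index pair resolved to the
    cell but whose probe decoding failed; it is reporting metadata and is
    not part of the counts table written by :func:`write_matrix`.
    """

    cell_ids: list[str]
    probe_ids: list[str]
    counts: np.ndarray
    unassigned_per_cell: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.probe_ids)):
            raise MatrixError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.probe_ids)} probes"
            )
        if self.counts.size and (
            np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer)
        ):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.round(self.counts)
            ) and np.all(self.counts >= 0):
                self.counts = self.counts.astype(np.int64)
            else:
                raise MatrixError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64, copy=False)
        if self.unassigned_per_cell is None:
            self.unassigned_per_cell = np.zeros(len(self.cell_ids), dtype=np.int64)
        else:
            self.unassigned_per_cell = np.asarray(
                self.unassigned_per_cell, dtype=np.int64
            )
            if self.unassigned_per_cell.shape != (len(self.cell_ids),):
                raise MatrixError("unassigned_per_cell must have one entry per cell")

    def totals(self) -> np.ndarray:
        """Per-cell total barcode counts (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.cell_ids, columns=self.probe_ids)
        df.index.name = "cell_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.probe_ids == other.probe_ids
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.unassigned_per_cell, other.unassigned_per_cell)
        )


@dataclass
class GlycanProfileMatrix:
    """Percent-normalized glycan profiles; rows sum to 100 over the
    denominator probes used at normalization time."""

    cell_ids: list[str]
    probe_ids: list[str]
    percent: np.ndarray

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if self.percent.shape != (len(self.cell_ids), len(self.probe_ids)):
            raise MatrixError("percent shape does not match names")
        if self.percent.size and np.any(self.percent < -1e-12):
            raise MatrixError("percentages must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.percent, index=self.cell_ids, columns=self.probe_ids)
        df.index.name = "cell_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GlycanProfileMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanProfileMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.probe_ids == other.probe_ids
            and np.allclose(self.percent, other.percent, rtol=0, atol=1e-12)
        )


def write_matrix(
    matrix: CountMatrix | GlycanProfileMatrix, path: str | Path, format: str = "tsv"
) -> Path:
    """Write a matrix as TSV (cells x probes) or MatrixMarket + sidecars."""
    path = Path(path)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        values = (
            matrix.counts if isinstance(matrix, CountMatrix) else matrix.percent
        )
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(values))
        _sidecar(path, "rows").write_text("\n".join(matrix.cell_ids) + "\n")
        _sidecar(path, "cols").write_text("\n".join(matrix.probe_ids) + "\n")
    else:
        raise MatrixError(f"unknown matrix format {format!r}")
    return path


def _sidecar(path: Path, which: str) -> Path:
    return path.with_suffix(path.suffix + f".{which}.txt")


def read_matrix(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` as a DataFrame."""
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0)
    if format == "mtx":
        values = np.asarray(scipy.io.mmread(str(path)).todense())
        rows = _sidecar(path, "rows").read_text().splitlines()
        cols = _sidecar(path, "cols").read_text().splitlines()
        df = pd.DataFrame(values, index=rows, columns=cols)
        df.index.name = "cell_id"
        return df
    raise MatrixError(f"unknown matrix format {format!r}")


def read_count_matrix(path: str | Path, format: str | None = None) -> CountMatrix:
    return CountMatrix.from_frame(read_matrix(path, format))


def read_profile_matrix(path: str | Path, format: str | None = None) -> GlycanProfileMatrix:
    return GlycanProfileMatrix.from_frame(read_matrix(path, format))


# ---------------------------------------------------------------------------
# FASTQ


@dataclass
class PairStreamStats:
    """Mutable tally updated while a read-pair stream is consumed."""

    yielded: int = 0
    skipped_short: int = 0


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_fastq(path: str | Path):
    with _open_text(path) as fh:
        try:
            yield from SeqIO.parse(fh, "fastq")
        except ValueError as exc:
            raise MalformedFastqError(f"malformed FASTQ in {path}: {exc}") from exc


def _index_from_header(description: str, path: str | Path) -> tuple[str, str]:
    # Illumina-style "... <flags>:<i5>+<i7>" or a bare "<i5>+<i7>" comment.
    fields = description.split()
    token = fields[-1].rsplit(":", 1)[-1] if fields else ""
    if "+" not in token:
        raise MalformedFastqError(
            f"malformed FASTQ in {path}: no i5+i7 index in header {description!r}"
        )
    i5, i7 = token.split("+", 1)
    return i5, i7


_SENTINEL = object()


def read_fastq_pairs(
    path_r1: str | Path,
    path_r2: str | Path,
    index_r1: str | Path | None = None,
    index_r2: str | Path | None = None,
    min_read_len: int | None = None,
    stats: PairStreamStats | None = None,
) -> Iterator[tuple[str, str, str]]:
    """Stream (read1_sequence, i5, i7) tuples from a FASTQ pair.

    Index sequences come from the read-1 header comment (``i5+i7``, the
    default) or, when ``index_r1``/``index_r2`` are given, from separate
    index-read FASTQ files.  Gzip input is handled transparently.  Reads
    shorter than ``min_read_len`` are skipped with a warning and counted in
    ``stats.skipped_short``.
    """
    from itertools import zip_longest

    streams = [_parse_fastq(path_r1), _parse_fastq(path_r2)]
    if index_r1 is not None:
        streams.append(_parse_fastq(index_r1))
        streams.append(_parse_fastq(index_r2))
    for records in zip_longest(*streams, fillvalue=_SENTINEL):
        if any(r is _SENTINEL for r in records):
            raise PairDesyncError(
                "pair desync: FASTQ files have different record counts"
            )
        r1 = records[0]
        seq1 = str(r1.seq)
        if min_read_len is not None and len(seq1) < min_read_len:
            warnings.warn(
                f"skipping read {r1.id}: length {len(seq1)} < {min_read_len}",
                stacklevel=2,
            )
            if stats is not None:
                stats.skipped_short += 1
            continue
        if index_r1 is not None:
            i5, i7 = str(records[2].seq), str(records[3].seq)
        else:
            i5, i7 = _index_from_header(r1.description, path_r1)
        if stats is not None:
            stats.yielded += 1
        yield seq1, i5, i7
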