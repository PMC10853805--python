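"""Readers and writers for the formats the pipeline touches.

Dense matrices travel as TSV with a header row and an index column, sparse
ones as MatrixMarket coordinate files, interaction networks optionally as
two/three-column edge lists, and sequences as FASTA. Every writer/reader pair
round-trips losslessly on its own output.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO


class MatrixParseError(ValueError):
    """Malformed matrix file; the message names the offending line."""


class FastaFormatError(ValueError):
    """Empty FASTA file or a record with an empty sequence."""


class LabeledMatrix(NamedTuple):
    """A numeric matrix with ordered row and column identifiers."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


def read_matrix(path: str | Path, format: str = "dense-tsv") -> LabeledMatrix:
    """Read a labeled numeric matrix.

    ``format`` is one of ``dense-tsv`` (header row + index column), ``mtx``
    (MatrixMarket coordinate, positional labels) or ``edge-list`` (two or
    three whitespace-separated columns: source, target[, weight]; the matrix
    is assembled over the union of observed labels in lexicographic order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense-tsv":
        return _read_dense_tsv(path)
    if format == "mtx":
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        rows = [f"r{i}" for i in range(mat.shape[0])]
        cols = [f"c{j}" for j in range(mat.shape[1])]
        return LabeledMatrix(mat, rows, cols)
    if format == "edge-list":
        return _read_edge_list(path)
    raise ValueError(f"unknown matrix format {format!r}")


def _read_dense_tsv(path: Path) -> LabeledMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise MatrixParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise MatrixParseError(f"{path}: duplicate row label {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric_line(path)
        raise MatrixParseError(f"{path}: non-numeric cell at line {bad}") from exc
    return LabeledMatrix(values, [str(x) for x in df.index], [str(c) for c in df.columns])


def _first_non_numeric_line(path: Path) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1:
                continue
            for cell in line.rstrip("\n").split("\t")[1:]:
                try:
                    float(cell)
                except ValueError:
                    return lineno
    return -1


def _read_edge_list(path: Path) -> LabeledMatrix:
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise MatrixParseError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            src, dst = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise MatrixParseError(
                        f"{path}: line {lineno}: non-numeric weight {parts[2]!r}"
                    ) from exc
            else:
                weight = 1.0
            key = (src, dst)
            if key in edges and edges[key] != weight:
                raise MatrixParseError(
                    f"{path}: line {lineno}: conflicting duplicate edge {src}->{dst}"
                )
            edges[key] = weight
    rows = sorted({s for s, _ in edges})
    cols = sorted({t for _, t in edges})
    ridx = {r: i for i, r in enumerate(rows)}
    cidx = {c: j for j, c in enumerate(cols)}
    mat = np.zeros((len(rows), len(cols)))
    for (s, t), w in edges.items():
        mat[ridx[s], cidx[t]] = w
    return LabeledMatrix(mat, rows, cols)


def write_matrix(
    path: str | Path,
    matrix: np.ndarray | LabeledMatrix,
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
    format: str = "dense-tsv",
) -> None:
    """Write a labeled matrix in ``dense-tsv`` or ``mtx`` format."""
    if isinstance(matrix, LabeledMatrix):
        values, row_labels, col_labels = matrix
    else:
        values = np.asarray(matrix)
        if row_labels is None:
            row_labels = [f"r{i}" for i in range(values.shape[0])]
        if col_labels is None:
            col_labels = [f"c{j}" for j in range(values.shape[1])]
    path = Path(path)
    if format == "dense-tsv":
        pd.DataFrame(values, index=row_labels, columns=col_labels).to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(values))
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(identifier, uppercase sequence)`` in file order.

    The identifier is the header token up to the first whitespace; wrapped
    sequence lines are concatenated.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
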