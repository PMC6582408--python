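"""Gene expression matrix (GEM) I/O and preprocessing.

The GEM is a genes x cells matrix of non-negative expression values
(counts, FPKM or TPM -- the downstream statistic is rank-based and
unit-agnostic).  Two on-disk dialects are supported:

* dense -- TSV/CSV with a header row of cell ids and gene ids in the
  first column;
* mtx -- MatrixMarket coordinate format with ``genes.txt`` /
  ``cells.txt`` sidecar files (one id per line) in the same directory.

Preprocessing follows the usual single-cell recipe: drop genes expressed
in fewer than ``min_cells`` cells (default 10), then ``log(1 + x)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._errors import ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "filter_genes",
    "log1p_transform",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of non-negative finite expression values.

    Attributes
    ----------
    values
        ``(m, n)`` float array, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique row / column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} rows"
            )
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} columns"
            )
        if len(set(self.gene_ids)) != m:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            g, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression at gene {self.gene_ids[g]!r}, "
                f"cell {self.cell_ids[c]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class LabelVector:
    """One categorical or ordinal label per cell (cell type, time stage...)."""

    cell_ids: list[str]
    labels: list

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = list(self.labels)
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("one label per cell required")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in label vector")

    def reindex(self, cell_ids: Sequence[str]) -> "LabelVector":
        """Reorder to match ``cell_ids``; the cell sets must coincide."""
        lookup = dict(zip(self.cell_ids, self.labels))
        missing = [c for c in cell_ids if c not in lookup]
        if missing or len(cell_ids) != len(self.cell_ids):
            raise ValidationError(
                "label cell set does not match the expression matrix "
                f"(first missing: {missing[:3]})"
            )
        return LabelVector(list(cell_ids), [lookup[c] for c in cell_ids])

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="label")


def _dense_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _infer_format(path: Path) -> str:
    return "mtx" if path.suffix.lower() == ".mtx" else "dense"


def read_expression(path: str | os.PathLike, format: str | None = None) -> ExpressionMatrix:
    """Read a GEM from disk.

    Parameters
    ----------
    path
        Dense TSV/CSV file, or a ``.mtx`` MatrixMarket file whose directory
        also holds ``genes.txt`` and ``cells.txt``.
    format
        ``"dense"`` or ``"mtx"``; inferred from the extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "dense":
        try:
            df = pd.read_csv(path, sep=_dense_sep(path), index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ParseError(f"malformed dense matrix {path}: {exc}") from exc
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ParseError(f"non-numeric entry in {path}: {exc}") from exc
        return ExpressionMatrix(values, list(df.index), list(df.columns))
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ParseError(f"malformed MatrixMarket file {path}: {exc}") from exc
        genes_file = path.parent / "genes.txt"
        cells_file = path.parent / "cells.txt"
        for side in (genes_file, cells_file):
            if not side.exists():
                raise ParseError(f"missing sidecar {side} for {path}")
        gene_ids = genes_file.read_text().split()
        cell_ids = cells_file.read_text().split()
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        return ExpressionMatrix(values, gene_ids, cell_ids)
    raise ValueError(f"unknown format {fmt!r}")


def write_expression(gem: ExpressionMatrix, path: str | os.PathLike,
                     format: str | None = None) -> None:
    """Write a GEM in the dense or mtx dialect (see :func:`read_expression`)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "dense":
        gem.to_frame().to_csv(path, sep=_dense_sep(path))
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(gem.values))
        (path.parent / "genes.txt").write_text("\n".join(gem.gene_ids) + "\n")
        (path.parent / "cells.txt").write_text("\n".join(gem.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path: str | os.PathLike) -> LabelVector:
    """Read a two-column (cell_id, label) TSV without header."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed label file {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise ParseError(f"label file {path} must have exactly two columns")
    return LabelVector(list(df[0]), list(df[1]))


def write_labels(labels: LabelVector, path: str | os.PathLike) -> None:
    pd.DataFrame({0: labels.cell_ids, 1: labels.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def filter_genes(gem: ExpressionMatrix, min_cells: int = 10) -> ExpressionMatrix:
    """Keep genes with nonzero expression in at least ``min_cells`` cells.

    A gene expressed in exactly ``min_cells`` cells is kept (strict "fewer
    than" reading of the cutoff).  Idempotent for fixed ``min_cells``.
    """
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    expressed_in = (gem.values > 0).sum(axis=1)
    keep = expressed_in >= min_cells
    if not keep.any():
        raise ValidationError(
            f"no gene is expressed in >= {min_cells} cells; "
            "lower the min_cells threshold"
        )
    return ExpressionMatrix(
        gem.values[keep],
        [g for g, k in zip(gem.gene_ids, keep) if k],
        list(gem.cell_ids),
    )


def log1p_transform(gem: ExpressionMatrix) -> ExpressionMatrix:
    """Natural ``log(1 + x)`` transform; zeros stay zero, order is preserved."""
    return ExpressionMatrix(np.log1p(gem.values), list(gem.gene_ids), list(gem.cell_ids))
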