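"""Network degree matrix (NDM).

The NDM aggregates the n per-cell networks back into a genes x cells
matrix: entry (x, k) is the number of edges incident to gene x in cell
k's network.  It has the same shape, row order and column order as the
GEM, so any expression-based pipeline (clustering, embedding,
pseudotime) can run on it unchanged -- degree replaces expression as the
per-gene, per-cell feature.

Because denser cells accumulate more edges overall, columns are
normalized before cross-cell comparison: each column is scaled so its
total degree equals the mean raw column total.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .core import CellNetwork
from .gem import ExpressionMatrix

__all__ = ["DegreeMatrix", "degree_matrix", "normalize_ndm", "write_ndm", "read_ndm"]


@dataclass
class DegreeMatrix:
    """Genes x cells matrix of per-cell network degrees."""

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if len(self.gene_ids) != m or len(self.cell_ids) != n:
            raise ValidationError("id lengths do not match the degree matrix")
        if np.any(self.values < 0):
            raise ValidationError("degrees must be non-negative")
        if not self.normalized:
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("raw degrees must be integers")
            if np.any(self.values > m - 1):
                raise ValidationError("a gene can have at most m-1 edges")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def as_expression(self) -> ExpressionMatrix:
        """View the NDM as an :class:`ExpressionMatrix` (drop-in contract)."""
        return ExpressionMatrix(self.values, list(self.gene_ids), list(self.cell_ids))


def degree_matrix(
    networks: Iterable[CellNetwork],
    gene_ids: list[str],
    cell_ids: list[str] | None = None,
) -> DegreeMatrix:
    """Count per-gene edges in each cell's network.

    ``cell_ids`` fixes the column order; by default columns follow the
    stream order.  Duplicate cell ids in the stream are an error.
    """
    networks = list(networks)
    seen: dict[str, np.ndarray] = {}
    for net in networks:
        if net.m != len(gene_ids):
            raise ValidationError(
                f"network of cell {net.cell_id!r} has {net.m} genes, "
                f"expected {len(gene_ids)}"
            )
        if net.cell_id in seen:
            raise ValidationError(f"duplicate cell id {net.cell_id!r} in stream")
        seen[net.cell_id] = net.degrees()
    if cell_ids is None:
        cell_ids = [net.cell_id for net in networks]
    missing = [c for c in cell_ids if c not in seen]
    if missing:
        raise ValidationError(f"no network for cells {missing[:3]}")
    values = np.column_stack([seen[c] for c in cell_ids]) if cell_ids else np.zeros((len(gene_ids), 0))
    return DegreeMatrix(values, list(gene_ids), list(cell_ids), normalized=False)


def normalize_ndm(ndm: DegreeMatrix) -> DegreeMatrix:
    """Scale each column so its total degree equals the mean raw column total.

    Within-column ratios are preserved (scalar scaling).  All-zero columns
    (cells with empty networks) are left at zero with a warning.
    """
    if ndm.normalized:
        raise ValidationError("degree matrix is already normalized")
    sums = ndm.values.sum(axis=0)
    if not np.any(sums > 0):
        raise ValidationError(
            "all cells have empty networks; consider relaxing alpha or box_size"
        )
    target = sums.mean()
    zero_cols = sums == 0
    if zero_cols.any():
        names = [c for c, z in zip(ndm.cell_ids, zero_cols) if z][:5]
        warnings.warn(
            f"{int(zero_cols.sum())} cell(s) have empty networks and stay "
            f"zero after normalization, e.g. {names}"
        )
    scale = np.divide(target, sums, out=np.zeros_like(sums, dtype=float), where=~zero_cols)
    return DegreeMatrix(
        ndm.values * scale, list(ndm.gene_ids), list(ndm.cell_ids), normalized=True
    )


def write_ndm(ndm: DegreeMatrix, path: str | os.PathLike) -> None:
    """Write in the same dense TSV/CSV dialect as the GEM."""
    from .gem import write_expression

    write_expression(ndm.as_expression(), path, format="dense")


def read_ndm(path: str | os.PathLike, normalized: bool = False) -> DegreeMatrix:
    from .gem import read_expression

    gem = read_expression(path, format="dense")
    return DegreeMatrix(gem.values, gem.gene_ids, gem.cell_ids, normalized=normalized)
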