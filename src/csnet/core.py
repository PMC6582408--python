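"""Cell-specific network (CSN) construction.

For every cell *k* and every unordered gene pair (*x*, *y*) the method asks
whether the two genes are statistically associated *in that cell*.  Around
the point (x_k, y_k) of the pair's scatter diagram it draws a neighborhood
box per gene -- the cells whose expression of that gene falls in a rank
window around the focal cell's value -- and counts occupancies n_x, n_y and
their intersection n_xy.  The plug-in independence statistic

    rho_xy^(k) = n_xy/n - (n_x/n)(n_y/n)

has null mean 0 and standard deviation

    sigma = sqrt( n_x n_y (n-n_x)(n-n_y) / (n^4 (n-1)) ),

and the normalized statistic rho_hat = rho/sigma is compared to the
upper-``alpha`` standard-normal quantile (one-sided test, default
``alpha = 0.01``): an edge is drawn when the box around the focal cell is
significantly over-occupied, i.e. the pair is locally positively dependent.
Repeating over all pairs yields one sparse undirected gene-gene network per
cell.

Counting convention
-------------------
The focal cell lies in all three boxes by construction, which inflates the
overlap count under independence (E[n_xy] = 1 + (n_x-1)(n_y-1)/(n-1) rather
than n_x n_y / n).  The statistic is therefore computed on the *other* n-1
cells: with counts (n-1, n_x-1, n_y-1, n_xy-1) the null law of the overlap
is exactly Hypergeometric(n-1, n_x-1, n_y-1) -- the boxes of two
independent genes are uniform random subsets of the non-focal cells -- and
the mean/sigma formulas above are exact rather than asymptotic.  Set
``include_focal=True`` on :class:`NeighborhoodSpec` for the literal
count-every-point-in-the-box convention (biased upward by roughly
``9/sqrt(n)`` at box size 0.1; see docs/methods.md).

Zeros: in scRNA-seq most zeros are dropouts, so by default
(``zero_mode="drop_zero_edges"``) a cell in which either gene reads zero
gets no edge for that pair, regardless of the statistic.  With
``zero_mode="trust_zeros"`` the statistic alone decides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import DegenerateBoxError, SizeCapError, ValidationError
from .gem import ExpressionMatrix

__all__ = [
    "NeighborhoodSpec",
    "NeighborhoodCounts",
    "PairCellStatistic",
    "CellNetwork",
    "z_star",
    "neighborhood",
    "neighborhood_counts",
    "pair_cell_statistic",
    "edge_decision",
    "build_cell_network",
    "build_all_networks",
]

ZeroMode = Literal["drop_zero_edges", "trust_zeros"]
Sink = Literal["edge_lists", "degree_only", "stat_tensor"]


def z_star(alpha: float) -> float:
    """Upper-``alpha`` quantile of the standard normal (rejection threshold)."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    return float(norm.ppf(1.0 - alpha))


@dataclass
class NeighborhoodSpec:
    """Parameters of the per-cell test.

    ``box_size`` is the neighborhood size as a fraction of the cells; the
    per-gene window targets ``round(box_size * n)`` cells (0.1 by default,
    the setting under which the method was calibrated).  ``alpha`` is the
    one-sided significance level of the edge test (default 0.01).
    """

    box_size: float = 0.1
    alpha: float = 0.01
    zero_mode: ZeroMode = "drop_zero_edges"
    include_focal: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.box_size <= 1:
            raise ValidationError("box_size must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.zero_mode not in ("drop_zero_edges", "trust_zeros"):
            raise ValidationError(f"unknown zero_mode {self.zero_mode!r}")

    def target_count(self, n: int) -> int:
        """Window size ``h = round(box_size * n)``, at least 1."""
        return max(1, int(round(self.box_size * n)))


@dataclass
class NeighborhoodCounts:
    """Box occupancies for one (gene pair, cell): total n, marginal boxes
    n_x and n_y, and their intersection n_xy."""

    n: int
    n_x: int
    n_y: int
    n_xy: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_xy <= min(self.n_x, self.n_y) <= self.n):
            raise ValidationError(
                f"inconsistent box counts n={self.n} n_x={self.n_x} "
                f"n_y={self.n_y} n_xy={self.n_xy}"
            )


@dataclass
class PairCellStatistic:
    """The raw statistic rho, its null moments and normalized form."""

    rho: float
    mu: float
    sigma: float
    rho_hat: float
    edge: bool | None = None


def _window_bounds(values: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (lower, upper) window boundary *values* for one gene.

    The window is the contiguous rank window of target size ``h`` centered
    on each cell's rank -- ceil((h-1)/2) ranks below, the rest above --
    shifted inward at the extremes.  Membership is later evaluated by value
    comparison, which automatically expands over boundary ties.
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    rank = np.empty(n, dtype=np.intp)
    rank[order] = np.arange(n)
    sorted_vals = values[order]
    below = (h - 1 + 1) // 2  # ceil((h-1)/2)
    lo = np.clip(rank - below, 0, max(n - h, 0))
    hi = np.minimum(lo + h - 1, n - 1)
    return sorted_vals[lo], sorted_vals[hi]


def neighborhood(values: np.ndarray, k: int, box_size: float) -> set[int]:
    """Cells in the neighborhood box of cell ``k`` for one gene.

    Returns the tie-expanded rank window around ``k``; always contains
    ``k`` and at least ``round(box_size * n)`` cells.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValidationError("neighborhood undefined for fewer than 2 cells")
    if not 0 <= k < n:
        raise ValidationError(f"cell index {k} out of range")
    spec = NeighborhoodSpec(box_size=box_size)
    lower, upper = _window_bounds(values, spec.target_count(n))
    return set(np.flatnonzero((values >= lower[k]) & (values <= upper[k])).tolist())


def neighborhood_counts(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    box_size: float = 0.1,
    include_focal: bool = False,
) -> NeighborhoodCounts:
    """Box occupancies for genes ``x``, ``y`` at cell ``k``.

    With ``include_focal=False`` (default) the focal cell is removed from
    all three boxes and from the total, making the null of the overlap
    exactly hypergeometric (see module docstring).
    """
    sx = neighborhood(np.asarray(x, float), k, box_size)
    sy = neighborhood(np.asarray(y, float), k, box_size)
    n = len(np.asarray(x))
    if include_focal:
        return NeighborhoodCounts(n, len(sx), len(sy), len(sx & sy))
    return NeighborhoodCounts(n - 1, len(sx) - 1, len(sy) - 1, len(sx & sy) - 1)


def pair_cell_statistic(counts: NeighborhoodCounts) -> PairCellStatistic:
    """Evaluate rho, its null moments and the normalized statistic.

    Raises :class:`DegenerateBoxError` when a marginal box is empty or
    spans every cell (sigma = 0; e.g. a constant gene after tie expansion).
    """
    n, nx, ny, nxy = counts.n, counts.n_x, counts.n_y, counts.n_xy
    if n < 2:
        raise ValidationError("statistic undefined for n < 2")
    if nx in (0, n) or ny in (0, n):
        raise DegenerateBoxError(
            f"degenerate box (n={n}, n_x={nx}, n_y={ny}): sigma = 0"
        )
    rho = nxy / n - (nx / n) * (ny / n)
    sigma = float(np.sqrt(nx * ny * (n - nx) * (n - ny) / (n**4 * (n - 1))))
    rho_hat = float(
        np.sqrt(n - 1) * (n * nxy - nx * ny) / np.sqrt(nx * ny * (n - nx) * (n - ny))
    )
    return PairCellStatistic(rho=float(rho), mu=0.0, sigma=sigma, rho_hat=rho_hat)


def edge_decision(stat: PairCellStatistic | float, alpha: float = 0.01) -> bool:
    """One-sided test: edge iff rho_hat exceeds the upper-``alpha`` normal
    quantile."""
    rho_hat = stat.rho_hat if isinstance(stat, PairCellStatistic) else float(stat)
    return bool(rho_hat > z_star(alpha))


def pair_statistics(
    x: np.ndarray, y: np.ndarray, spec: NeighborhoodSpec | None = None
) -> np.ndarray:
    """Normalized statistic of one gene pair in every cell (length n).

    Vectorized over cells; degenerate boxes yield 0.  The edge rule and
    zero handling are left to the caller (threshold against
    ``z_star(alpha)``; in ``drop_zero_edges`` mode mask cells where either
    gene reads zero).
    """
    spec = spec or NeighborhoodSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValidationError("x and y must have the same length")
    if n < 2:
        raise ValidationError("statistic undefined for fewer than 2 cells")
    h = spec.target_count(n)
    lox, upx = _window_bounds(x, h)
    loy, upy = _window_bounds(y, h)
    bx = (x[None, :] >= lox[:, None]) & (x[None, :] <= upx[:, None])
    by = (y[None, :] >= loy[:, None]) & (y[None, :] <= upy[:, None])
    if spec.include_focal:
        total = n
    else:
        np.fill_diagonal(bx, False)
        np.fill_diagonal(by, False)
        total = n - 1
    nx = bx.sum(axis=1)
    ny = by.sum(axis=1)
    nxy = (bx & by).sum(axis=1)
    degenerate = (nx == 0) | (nx == total) | (ny == 0) | (ny == total)
    nx_s = np.where((nx == 0) | (nx == total), 1, nx)
    ny_s = np.where((ny == 0) | (ny == total), 1, ny)
    rho_hat = (
        np.sqrt(total - 1)
        * (total * nxy - nx * ny)
        / np.sqrt(nx_s * ny_s * (total - nx_s) * (total - ny_s))
    )
    rho_hat[degenerate] = 0.0
    return rho_hat


@dataclass
class CellNetwork:
    """One cell's undirected boolean gene-gene network (the CSN)."""

    cell_id: str
    m: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValidationError("self-edges are not allowed")
            canon.add((min(a, b), max(a, b)))
        self.edges = frozenset(canon)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Per-gene edge counts (length m)."""
        deg = np.zeros(self.m, dtype=np.int64)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


class _Warnings:
    """Collects once-per-gene degenerate-box warnings during a build."""

    def __init__(self, gene_ids: list[str]):
        self.gene_ids = gene_ids
        self.flagged: set[int] = set()

    def add(self, gene_indices: np.ndarray) -> None:
        self.flagged.update(int(i) for i in gene_indices)

    def emit(self) -> None:
        if self.flagged:
            names = [self.gene_ids[i] for i in sorted(self.flagged)][:10]
            warnings.warn(
                f"{len(self.flagged)} gene(s) produced degenerate boxes "
                f"(constant or near-constant); their edges are 0. "
                f"Examples: {names}",
                stacklevel=3,
            )


def _precompute_bounds(values: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-gene window bounds into (m, n) arrays."""
    lowers = np.empty_like(values)
    uppers = np.empty_like(values)
    for i in range(values.shape[0]):
        lowers[i], uppers[i] = _window_bounds(values[i], h)
    return lowers, uppers


def _cell_stat_matrix(
    values: np.ndarray,
    lowers: np.ndarray,
    uppers: np.ndarray,
    k: int,
    spec: NeighborhoodSpec,
    warn: _Warnings | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (rho_hat, edge) matrices for one cell.

    Membership of cell j in gene i's box around cell k is a value
    comparison against the precomputed window bounds, so the m x n boolean
    membership matrix and the m x m overlap counts come out of one matmul.
    """
    n = values.shape[1]
    member = (values >= lowers[:, k, None]) & (values <= uppers[:, k, None])
    if spec.include_focal:
        total = n
    else:
        member = member.copy()
        member[:, k] = False
        total = n - 1
    occ = member.sum(axis=1).astype(np.float64)  # n_x per gene
    overlap = member.astype(np.float64) @ member.T.astype(np.float64)  # n_xy
    degenerate = (occ == 0) | (occ == total)
    if warn is not None and degenerate.any():
        warn.add(np.flatnonzero(degenerate))
    occ_safe = np.where(degenerate, 1.0, occ)
    denom = np.sqrt(np.outer(occ_safe * (total - occ_safe), occ_safe * (total - occ_safe)))
    rho_hat = np.sqrt(total - 1) * (total * overlap - np.outer(occ, occ)) / denom
    rho_hat[degenerate, :] = 0.0
    rho_hat[:, degenerate] = 0.0
    np.fill_diagonal(rho_hat, 0.0)
    edges = rho_hat > z_star(spec.alpha)
    if spec.zero_mode == "drop_zero_edges":
        zero_genes = values[:, k] == 0
        edges[zero_genes, :] = False
        edges[:, zero_genes] = False
    np.fill_diagonal(edges, False)
    return rho_hat, edges


def _check_gem(gem: ExpressionMatrix) -> None:
    if gem.n_cells < 2:
        raise ValidationError("at least 2 cells are required")


def build_cell_network(
    gem: ExpressionMatrix, k: int, spec: NeighborhoodSpec | None = None
) -> CellNetwork:
    """Construct the CSN of cell ``k``: test every unordered gene pair."""
    spec = spec or NeighborhoodSpec()
    _check_gem(gem)
    if not 0 <= k < gem.n_cells:
        raise ValidationError(f"cell index {k} out of range")
    lowers, uppers = _precompute_bounds(gem.values, spec.target_count(gem.n_cells))
    warn = _Warnings(gem.gene_ids)
    _, edges = _cell_stat_matrix(gem.values, lowers, uppers, k, spec, warn)
    warn.emit()
    a, b = np.nonzero(np.triu(edges, 1))
    return CellNetwork(gem.cell_ids[k], gem.n_genes, frozenset(zip(a.tolist(), b.tolist())))


def iter_cell_networks(
    gem: ExpressionMatrix, spec: NeighborhoodSpec | None = None
) -> Iterator[CellNetwork]:
    """Yield one :class:`CellNetwork` per cell (memory: one cell at a time)."""
    spec = spec or NeighborhoodSpec()
    _check_gem(gem)
    lowers, uppers = _precompute_bounds(gem.values, spec.target_count(gem.n_cells))
    warn = _Warnings(gem.gene_ids)
    for k in range(gem.n_cells):
        _, edges = _cell_stat_matrix(gem.values, lowers, uppers, k, spec, warn)
        a, b = np.nonzero(np.triu(edges, 1))
        yield CellNetwork(gem.cell_ids[k], gem.n_genes, frozenset(zip(a.tolist(), b.tolist())))
    warn.emit()


def build_all_networks(
    gem: ExpressionMatrix,
    spec: NeighborhoodSpec | None = None,
    sink: Sink = "degree_only",
    stat_cap: int = 20_000_000,
):
    """Run the per-cell tests over all gene pairs and cells.

    Parameters
    ----------
    sink
        ``"degree_only"`` -- accumulate the network degree matrix without
        storing networks; returns a raw :class:`csnet.ndm.DegreeMatrix`.
        ``"edge_lists"`` -- return ``list[CellNetwork]``.
        ``"stat_tensor"`` -- return the full pairs x cells table of
        normalized statistics as a DataFrame with a (gene_a, gene_b)
        MultiIndex; refused above ``stat_cap`` entries.
    """
    from .ndm import DegreeMatrix  # local import to avoid a cycle

    spec = spec or NeighborhoodSpec()
    _check_gem(gem)
    m, n = gem.n_genes, gem.n_cells
    if sink == "edge_lists":
        return list(iter_cell_networks(gem, spec))
    lowers, uppers = _precompute_bounds(gem.values, spec.target_count(n))
    warn = _Warnings(gem.gene_ids)
    if sink == "degree_only":
        ndm = np.zeros((m, n), dtype=np.int64)
        for k in range(n):
            _, edges = _cell_stat_matrix(gem.values, lowers, uppers, k, spec, warn)
            ndm[:, k] = edges.sum(axis=0)
        warn.emit()
        return DegreeMatrix(ndm, list(gem.gene_ids), list(gem.cell_ids), normalized=False)
    if sink == "stat_tensor":
        n_pairs = m * (m - 1) // 2
        if n_pairs * n > stat_cap:
            raise SizeCapError(
                f"stat_tensor would hold {n_pairs} pairs x {n} cells = "
                f"{n_pairs * n:,} statistics (cap {stat_cap:,})"
            )
        iu, ju = np.triu_indices(m, 1)
        table = np.empty((n_pairs, n))
        for k in range(n):
            rho_hat, _ = _cell_stat_matrix(gem.values, lowers, uppers, k, spec, warn)
            table[:, k] = rho_hat[iu, ju]
        warn.emit()
        index = pd.MultiIndex.from_arrays(
            [np.asarray(gem.gene_ids)[iu], np.asarray(gem.gene_ids)[ju]],
            names=["gene_a", "gene_b"],
        )
        return pd.DataFrame(table, index=index, columns=gem.cell_ids)
    raise ValueError(f"unknown sink {sink!r}")
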