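"""Group-level network analyses: marker edges, hub genes, 'dark' genes,
and rewiring along ordered stages.

All comparisons are one-vs-rest per group, tested with the two-sided
Wilcoxon rank-sum (Mann-Whitney U) and Benjamini-Hochberg adjusted across
the family of tests actually performed.  Rank tests are the natural
choice here: per-cell degrees and statistics are heavy-tailed and often
zero-inflated.

A *dark* gene is the method's signature finding: a gene whose expression
does not separate two cell groups but whose network degree does --
regulatory activity visible only through its associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .core import z_star
from .gem import ExpressionMatrix, LabelVector
from .ndm import DegreeMatrix

__all__ = [
    "DifferentialResult",
    "differential_edges",
    "hub_genes",
    "dark_genes",
    "rewiring_summary",
]

RESULT_COLUMNS = ["unit_id", "group", "effect", "p_value", "q_value", "tested_on"]


@dataclass
class DifferentialResult:
    """One unit (gene or gene pair), one group-vs-rest contrast."""

    unit_id: str
    group: str
    effect: float  # difference of group medians of the tested quantity
    p_value: float
    q_value: float
    tested_on: str  # expression | degree | edge_statistic


def _rank_test(in_group: np.ndarray, rest: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum; degenerate all-constant input gives p = 1."""
    pooled = np.concatenate([in_group, rest])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    effect = float(np.median(in_group) - np.median(rest))
    p = float(mannwhitneyu(in_group, rest, alternative="two-sided").pvalue)
    return effect, p


def _one_vs_rest_tests(
    table: pd.DataFrame, labels: LabelVector, tested_on: str, min_cells: int = 3
) -> pd.DataFrame:
    """Run unit x group rank tests on a units x cells table; BH across all."""
    labels = labels.reindex(list(table.columns))
    lab = np.asarray(labels.labels)
    rows = []
    for group in pd.unique(lab):
        mask = lab == group
        if mask.sum() < min_cells or (~mask).sum() < min_cells:
            warnings.warn(
                f"group {group!r} has fewer than {min_cells} cells on one "
                "side of the contrast; skipped"
            )
            continue
        a = table.loc[:, mask].to_numpy()
        b = table.loc[:, ~mask].to_numpy()
        for i, unit in enumerate(table.index):
            effect, p = _rank_test(a[i], b[i])
            rows.append((unit, group, effect, p, np.nan, tested_on))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("q_value", kind="stable").reset_index(drop=True)
    return out


def _pair_label(index_entry) -> str:
    if isinstance(index_entry, tuple):
        return "|".join(map(str, index_entry))
    return str(index_entry)


def differential_edges(
    stats: pd.DataFrame,
    labels: LabelVector,
    pairs: list[tuple[str, str]] | None = None,
    min_cells_with_edge: int = 0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Marker edges: pairs whose per-cell statistic differs between a group
    and the rest.

    ``stats`` is the pairs x cells normalized-statistic table from
    ``build_all_networks(..., sink="stat_tensor")``.  Pairs whose edge
    (statistic above the ``alpha`` threshold) appears in fewer than
    ``min_cells_with_edge`` cells overall can be excluded up front.
    Returns a DataFrame sorted by q_value.
    """
    if pairs is not None:
        stats = stats.loc[pd.MultiIndex.from_tuples(pairs, names=stats.index.names)]
    if min_cells_with_edge > 0:
        keep = (stats.to_numpy() > z_star(alpha)).sum(axis=1) >= min_cells_with_edge
        stats = stats.loc[keep]
    flat = stats.copy()
    flat.index = [_pair_label(i) for i in stats.index]
    return _one_vs_rest_tests(flat, labels, tested_on="edge_statistic")


def hub_genes(
    ndm: DegreeMatrix,
    labels: LabelVector | None = None,
    top_k: int = 10,
) -> dict[str, list[str]]:
    """Top-``top_k`` genes by mean degree per group (or globally).

    Ties are broken by gene id, ascending, so rankings are deterministic.
    """
    if top_k < 1 or top_k > ndm.n_genes:
        raise ValidationError("top_k must lie in [1, n_genes]")
    df = ndm.to_frame()
    groups: dict[str, pd.Series]
    if labels is None:
        groups = {"all": df.mean(axis=1)}
    else:
        labels = labels.reindex(list(df.columns))
        lab = np.asarray(labels.labels)
        groups = {str(g): df.loc[:, lab == g].mean(axis=1) for g in pd.unique(lab)}
    out = {}
    for g, means in groups.items():
        order = sorted(means.index, key=lambda gene: (-means[gene], gene))
        out[g] = order[:top_k]
    return out


def dark_genes(
    gem: ExpressionMatrix,
    ndm: DegreeMatrix,
    labels: LabelVector,
    alpha_expr: float = 0.05,
    alpha_deg: float = 0.05,
) -> pd.DataFrame:
    """Genes significant in degree but not in expression, per contrast.

    For each (gene, group-vs-rest) contrast both a degree-based and an
    expression-based rank test are run (BH-adjusted within each family).
    A gene is *dark* for a contrast iff q_degree < ``alpha_deg`` and
    q_expression >= ``alpha_expr``.  Returns the full audit table with
    one row per (gene, group): expression and degree effect/p/q columns
    plus a boolean ``dark`` column.
    """
    if gem.gene_ids != ndm.gene_ids or gem.cell_ids != ndm.cell_ids:
        raise ValidationError("GEM and NDM must share gene and cell ids in order")
    if len(set(labels.labels)) < 2:
        warnings.warn("fewer than two groups; no dark-gene contrast possible")
        return pd.DataFrame(
            columns=["unit_id", "group", "effect_expr", "p_expr", "q_expr",
                     "effect_deg", "p_deg", "q_deg", "dark"]
        )
    expr = _one_vs_rest_tests(gem.to_frame(), labels, tested_on="expression")
    deg = _one_vs_rest_tests(ndm.to_frame(), labels, tested_on="degree")
    merged = expr.merge(
        deg, on=["unit_id", "group"], suffixes=("_expr", "_deg")
    ).rename(
        columns={
            "effect_expr": "effect_expr", "p_value_expr": "p_expr",
            "q_value_expr": "q_expr", "effect_deg": "effect_deg",
            "p_value_deg": "p_deg", "q_value_deg": "q_deg",
        }
    )
    merged = merged.drop(columns=["tested_on_expr", "tested_on_deg"])
    merged["dark"] = (merged["q_deg"] < alpha_deg) & (merged["q_expr"] >= alpha_expr)
    return merged.sort_values(["dark", "q_deg"], ascending=[False, True], kind="stable").reset_index(drop=True)


def rewiring_summary(
    stats: pd.DataFrame,
    stage_labels: LabelVector,
    alpha: float = 0.01,
) -> dict:
    """Per-stage association profiles for a gene panel.

    ``stats`` is the pairs x cells statistic table restricted to the panel.
    Returns per-stage mean statistic per pair, per-stage mean within-panel
    degree per gene (edges = statistic above the ``alpha`` threshold), and
    each gene's peak stage.  Stages are sorted by their natural order.
    """
    stage_labels = stage_labels.reindex(list(stats.columns))
    stages = np.asarray(stage_labels.labels)
    uniq = sorted(pd.unique(stages).tolist())
    genes = sorted({g for pair in stats.index for g in pair})
    edge = stats.to_numpy() > z_star(alpha)
    # per-cell within-panel degree
    deg = pd.DataFrame(0, index=genes, columns=stats.columns, dtype=float)
    for row, pair in enumerate(stats.index):
        a, b = pair
        deg.loc[a] += edge[row]
        deg.loc[b] += edge[row]
    pair_stage = pd.DataFrame(
        {s: stats.loc[:, stages == s].mean(axis=1) for s in uniq}
    )
    gene_stage = pd.DataFrame({s: deg.loc[:, stages == s].mean(axis=1) for s in uniq})
    peaks = gene_stage.idxmax(axis=1)
    return {"pair_stage_mean": pair_stage, "gene_stage_degree": gene_stage,
            "peak_stage": peaks}
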