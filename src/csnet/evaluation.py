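"""Scoring of clustering and pseudo-trajectory outputs.

Clustering agreement against known cell types is scored by ARI,
pairwise F1, purity and (conditional) entropy.  A no-branch
pseudo-trajectory that assigns each cell an ordering score is scored
against known stages by T/(T+F): over all ordered cell pairs whose
stages differ, the fraction in which the later-stage cell got the
strictly larger score (ties count against, so the measure is
tie-penalizing).

The clustering algorithms themselves are pluggable: seeded scikit-learn
methods behind :func:`cluster_cells`, applied with *identical*
parameters to expression and to network degree, so representation -- not
algorithm tuning -- drives any score difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import comb
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.metrics import adjusted_rand_score

from ._errors import ValidationError
from .gem import ExpressionMatrix, LabelVector
from .ndm import DegreeMatrix

__all__ = [
    "ClusteringScore",
    "TrajectoryScore",
    "clustering_scores",
    "trajectory_accuracy",
    "cluster_cells",
    "compare_representations",
    "run_comparison",
]


@dataclass
class ClusteringScore:
    ari: float
    f1: float
    purity: float
    entropy: float


@dataclass
class TrajectoryScore:
    T: int
    F: int

    @property
    def accuracy(self) -> float:
        return self.T / (self.T + self.F)


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((len(pu), len(tu)), dtype=np.int64)
    np.add.at(table, (pi, ti), 1)
    return table


def clustering_scores(predicted: LabelVector, truth: LabelVector) -> ClusteringScore:
    """Score a predicted partition against the reference partition.

    F1 is the pairwise variant (precision/recall over co-clustered cell
    pairs); purity is the weighted majority fraction per predicted
    cluster; entropy is the conditional entropy H(truth | predicted) in
    bits, 0 when every predicted cluster is pure.
    """
    truth = truth.reindex(predicted.cell_ids)
    pred = np.asarray(predicted.labels)
    ref = np.asarray(truth.labels)
    if pred.size < 2:
        raise ValidationError("at least 2 cells required")
    n = pred.size
    table = _contingency(pred, ref)
    ari = float(adjusted_rand_score(ref, pred))
    # pairwise F1 over co-clustered pairs
    tp = comb(table, 2).sum()
    pred_pairs = comb(table.sum(axis=1), 2).sum()
    true_pairs = comb(table.sum(axis=0), 2).sum()
    precision = tp / pred_pairs if pred_pairs else 0.0
    recall = tp / true_pairs if true_pairs else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    purity = float(table.max(axis=1).sum() / n)
    sizes = table.sum(axis=1)
    p = table / np.maximum(sizes[:, None], 1)
    plogp = np.zeros_like(p)
    pos = p > 0
    plogp[pos] = p[pos] * np.log2(p[pos])
    entropy = float(-((sizes / n) * plogp.sum(axis=1)).sum())
    return ClusteringScore(ari=ari, f1=float(f1), purity=purity, entropy=entropy)


def trajectory_accuracy(order_values, stages: LabelVector) -> TrajectoryScore:
    """Score an inferred cell ordering against known ordinal stages.

    ``order_values`` maps each cell to a real score (dict, Series, or an
    array aligned with ``stages.cell_ids``).  For every ordered pair with
    stage(i) strictly later than stage(j): T += (score_i > score_j) else
    F += 1.  Accuracy = T/(T+F).
    """
    if isinstance(order_values, dict):
        vals = np.asarray([order_values[c] for c in stages.cell_ids], dtype=float)
    elif isinstance(order_values, pd.Series):
        vals = order_values.reindex(stages.cell_ids).to_numpy(dtype=float)
    else:
        vals = np.asarray(order_values, dtype=float)
        if vals.size != len(stages.cell_ids):
            raise ValidationError("order_values length does not match stages")
    stage = np.asarray(stages.labels)
    if len(np.unique(stage)) < 2:
        raise ValidationError("at least 2 distinct stages required")
    later = stage[:, None] > stage[None, :]
    greater = vals[:, None] > vals[None, :]
    T = int(np.sum(later & greater))
    F = int(np.sum(later & ~greater))
    return TrajectoryScore(T=T, F=F)


_METHODS = {"kmeans", "hierarchical", "spectral"}


def cluster_cells(
    matrix: ExpressionMatrix | DegreeMatrix,
    n_clusters: int,
    method: str = "kmeans",
    seed: int = 0,
    **params,
) -> LabelVector:
    """Cluster cells (columns) of a GEM or NDM with a seeded sklearn method."""
    if method not in _METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    X = matrix.values.T  # cells x genes
    if method == "kmeans":
        model = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10, **params)
    elif method == "hierarchical":
        model = AgglomerativeClustering(n_clusters=n_clusters, **params)
    else:
        model = SpectralClustering(n_clusters=n_clusters, random_state=seed, **params)
    labels = model.fit_predict(X)
    return LabelVector(list(matrix.cell_ids), labels.tolist())


def compare_representations(
    gem: ExpressionMatrix,
    ndm: DegreeMatrix,
    truth: LabelVector,
    n_clusters: int | None = None,
    method: str = "kmeans",
    seed: int = 0,
    **params,
) -> pd.DataFrame:
    """Cluster GEM and NDM with identical method/parameters and score both."""
    if n_clusters is None:
        n_clusters = len(set(truth.labels))
    rows = {}
    for name, matrix in (("gem", gem), ("ndm", ndm)):
        pred = cluster_cells(matrix, n_clusters, method=method, seed=seed, **params)
        score = clustering_scores(pred, truth)
        rows[name] = {"ari": score.ari, "f1": score.f1,
                      "purity": score.purity, "entropy": score.entropy}
    return pd.DataFrame(rows).T


def run_comparison(config: str | Path | dict) -> pd.DataFrame:
    """YAML-driven comparison harness.

    Config keys: ``gem`` (path), ``ndm`` (path), ``labels`` (path),
    ``method``, ``params`` (mapping), ``seed``, optional ``n_clusters``.
    """
    from .gem import read_expression, read_labels
    from .ndm import read_ndm

    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    gem = read_expression(config["gem"])
    ndm = read_ndm(config["ndm"], normalized=True)
    truth = read_labels(config["labels"])
    return compare_representations(
        gem, ndm, truth.reindex(gem.cell_ids),
        n_clusters=config.get("n_clusters"),
        method=config.get("method", "kmeans"),
        seed=int(config.get("seed", 0)),
        **(config.get("params") or {}),
    )
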