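"""Synthetic data generators.

Two layers of fixtures:

* :func:`generate_pair` -- a single gene pair over n cells in one of five
  dependence scenarios (independent; dependent in a subset of cells,
  linearly or nonlinearly; fully dependent), the setting under which the
  per-cell statistic's null and power behavior is studied (n = 500 and
  box occupancy 0.1n in the reference simulations).

* :func:`generate_population` -- a multi-cell-type expression matrix in
  which cell types differ in *association structure*: within a type, the
  genes of a module share a latent factor.  With ``marginal_matched=True``
  every gene's within-type values are rank-remapped onto a common
  zero-inflated log-normal reference, so per-gene marginals are identically
  distributed across types while associations differ.  This is the
  construction that plants *dark* genes:
  undetectable by expression tests, detectable by network degree.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
spec + seed reproduce outputs bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import lognorm

from ._errors import ValidationError
from .gem import ExpressionMatrix, LabelVector

__all__ = [
    "ScenarioSpec",
    "PopulationSpec",
    "generate_pair",
    "generate_population",
    "null_calibration",
]

Kind = Literal[
    "independent", "partial_linear", "partial_nonlinear", "full_linear", "full_nonlinear"
]

_KINDS = {"independent", "partial_linear", "partial_nonlinear",
          "full_linear", "full_nonlinear"}


@dataclass
class ScenarioSpec:
    """One gene-pair dependence scenario.

    ``dependent_fraction`` defaults by kind (0 / 0.5 / 1).  ``noise_sd``
    is the conditional noise of the dependent cells relative to the
    spread of x (0.1 keeps the dependence strong, as in the reference
    scatter archetypes).  ``marginal`` in {"lognormal", "uniform"};
    ``nonlinear_form`` in {"quadratic", "arc"}.
    """

    kind: Kind = "independent"
    n: int = 500
    dependent_fraction: float | None = None
    noise_sd: float = 0.1
    marginal: str = "lognormal"
    nonlinear_form: str = "quadratic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown scenario kind {self.kind!r}")
        if self.n < 50:
            raise ValidationError("n >= 50 required for stable box counts")
        if self.dependent_fraction is None:
            self.dependent_fraction = {
                "independent": 0.0,
                "partial_linear": 0.5,
                "partial_nonlinear": 0.5,
                "full_linear": 1.0,
                "full_nonlinear": 1.0,
            }[self.kind]
        f = self.dependent_fraction
        if not 0 <= f <= 1:
            raise ValidationError("dependent_fraction must lie in [0, 1]")
        if self.kind == "independent" and f != 0:
            raise ValidationError("independent scenario requires fraction 0")
        if self.kind.startswith("full") and f != 1:
            raise ValidationError("full scenarios require fraction 1")


def _draw_marginal(rng: np.random.Generator, n: int, marginal: str) -> np.ndarray:
    if marginal == "lognormal":
        return rng.lognormal(mean=0.0, sigma=0.5, size=n)
    if marginal == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    raise ValidationError(f"unknown marginal {marginal!r}")


def generate_pair(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one gene pair.

    Returns ``(values, flags)``: a (2, n) non-negative matrix and a
    boolean vector marking the ground-truth dependent cells (exactly
    ``floor(dependent_fraction * n)`` of them, chosen uniformly).
    Dependent cells follow y = g(x) + noise with g linear or unimodal
    nonlinear; the rest draw y independently.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    x = _draw_marginal(rng, n, spec.marginal)
    y = _draw_marginal(rng, n, spec.marginal)
    n_dep = int(np.floor(spec.dependent_fraction * n))
    flags = np.zeros(n, dtype=bool)
    if n_dep:
        flags[rng.permutation(n)[:n_dep]] = True
        xd = x[flags]
        scale = np.std(x) or 1.0
        noise = spec.noise_sd * scale * rng.standard_normal(n_dep)
        if spec.kind.endswith("linear") and not spec.kind.endswith("nonlinear"):
            g = xd
        elif spec.nonlinear_form == "quadratic":
            g = (xd - np.median(x)) ** 2 / scale
        elif spec.nonlinear_form == "arc":
            # half-circle over the x range: unimodal, non-monotone
            u = (xd - x.min()) / (np.ptp(x) or 1.0)
            g = scale * np.sqrt(np.clip(1.0 - (2 * u - 1.0) ** 2, 0.0, 1.0))
        else:
            raise ValidationError(f"unknown nonlinear_form {spec.nonlinear_form!r}")
        y[flags] = np.maximum(g + noise, 0.0)
    return np.vstack([x, y]), flags


def null_calibration(
    n_pairs: int = 200,
    n: int = 500,
    box_size: float = 0.1,
    alpha: float = 0.01,
    marginal: str = "lognormal",
    seed: int = 0,
) -> dict:
    """Monte-Carlo calibration of the statistic on independent pairs.

    Simulates ``n_pairs`` independent gene pairs of ``n`` cells each,
    computes the normalized statistic for every cell, and returns pooled
    mean, variance and one-sided edge rate at ``alpha``, plus clustered
    standard errors (cells within a pair share boxes, so the pair -- not
    the cell -- is the unit of replication).
    """
    from .core import NeighborhoodSpec, pair_statistics, z_star

    rng = np.random.default_rng(seed)
    spec_core = NeighborhoodSpec(box_size=box_size, alpha=alpha)
    pair_means = np.empty(n_pairs)
    pair_vars = np.empty(n_pairs)
    pair_rates = np.empty(n_pairs)
    threshold = z_star(alpha)
    for i in range(n_pairs):
        pair_seed = int(rng.integers(2**31 - 1))
        values, _ = generate_pair(
            ScenarioSpec(kind="independent", n=n, marginal=marginal, seed=pair_seed)
        )
        rho_hat = pair_statistics(values[0], values[1], spec_core)
        pair_means[i] = rho_hat.mean()
        pair_vars[i] = rho_hat.var()
        pair_rates[i] = (rho_hat > threshold).mean()
    # pooled variance = mean within-pair var + var of pair means
    mean = float(pair_means.mean())
    var = float(pair_vars.mean() + pair_means.var())
    rate = float(pair_rates.mean())
    return {
        "n_pairs": n_pairs,
        "n": n,
        "mean": mean,
        "var": var,
        "edge_rate": rate,
        "se_mean": float(pair_means.std(ddof=1) / np.sqrt(n_pairs)),
        "se_rate": float(pair_rates.std(ddof=1) / np.sqrt(n_pairs)),
    }


@dataclass
class PopulationSpec:
    """Multi-cell-type matrix with type-specific association modules.

    ``modules_per_type`` maps type index -> list of gene-index modules
    active in that type; by default type t gets one module of
    ``module_size`` genes in its own disjoint block.  ``noise_sd`` is the
    per-gene noise around the module latent factor; the default 0.1
    (within-module rank correlation about 0.99, a tightly co-regulated
    module) is the documented effect size: the box test is local, so its
    power requires the conditional rank spread of a dependent pair to be
    comparable to the box width (see docs/methods.md).  ``zero_inflation``
    is the dropout-like point mass at zero of the common reference
    marginal.
    """

    n_types: int = 2
    cells_per_type: tuple[int, ...] | None = None
    m: int = 30
    module_size: int = 8
    modules_per_type: dict[int, list[list[int]]] | None = None
    marginal_matched: bool = True
    noise_sd: float = 0.1
    zero_inflation: float = 0.1
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValidationError("n_types must be >= 1")
        if self.cells_per_type is None:
            self.cells_per_type = (100,) * self.n_types
        if len(self.cells_per_type) != self.n_types:
            raise ValidationError("cells_per_type length must equal n_types")
        if not 0 <= self.dropout_rate <= 1:
            raise ValidationError("dropout_rate must lie in [0, 1]")
        if not 0 <= self.zero_inflation < 1:
            raise ValidationError("zero_inflation must lie in [0, 1)")
        if self.modules_per_type is None:
            if self.module_size * self.n_types > self.m:
                raise ValidationError(
                    "default disjoint modules need module_size * n_types <= m"
                )
            self.modules_per_type = {
                t: [list(range(t * self.module_size, (t + 1) * self.module_size))]
                for t in range(self.n_types)
            }
        for t, mods in self.modules_per_type.items():
            for mod in mods:
                if any(g >= self.m or g < 0 for g in mod):
                    raise ValidationError(f"module gene index out of range in type {t}")


def _reference_quantile(q: np.ndarray, zero_inflation: float) -> np.ndarray:
    """Inverse CDF of the common reference marginal: a point mass of
    ``zero_inflation`` at zero, log-normal(sigma=0.5) above it."""
    out = np.zeros_like(q)
    above = q >= zero_inflation
    if zero_inflation < 1:
        qq = (q[above] - zero_inflation) / (1 - zero_inflation)
        out[above] = lognorm.ppf(qq, s=0.5)
    return out


def generate_population(
    spec: PopulationSpec,
) -> tuple[ExpressionMatrix, LabelVector, dict]:
    """Simulate the population; returns (GEM, type labels, ground truth).

    Ground truth holds the module definitions per type and the set of
    association-differential ("planted dark") genes: genes in a module of
    some type but not of every type.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.m
    blocks = []
    labels = []
    cell_ids = []
    for t, n_t in enumerate(spec.cells_per_type):
        raw = rng.standard_normal((m, n_t))
        for mod in spec.modules_per_type.get(t, []):
            z = rng.standard_normal(n_t)
            for g in mod:
                raw[g] = z + spec.noise_sd * rng.standard_normal(n_t)
        if spec.marginal_matched:
            # Rank-remap each gene onto the common reference distribution via
            # a jittered probability-integral transform: q = (rank + U)/n_t
            # with U ~ Uniform(0,1) keeps the within-type order exactly while
            # making q -- hence the remapped value -- exactly
            # reference-distributed.  A deterministic grid would duplicate
            # every value across equally sized types, and such systematic
            # cross-type ties distort the box windows asymmetrically.
            ranks = np.argsort(np.argsort(raw, axis=1, kind="stable"), axis=1)
            q = (ranks + rng.random(raw.shape)) / n_t
            vals = _reference_quantile(q, spec.zero_inflation)
        else:
            vals = np.abs(raw)
        blocks.append(vals)
        labels += [f"type{t}"] * n_t
        cell_ids += [f"t{t}c{i:04d}" for i in range(n_t)]
    values = np.concatenate(blocks, axis=1)
    if spec.dropout_rate > 0:
        mask = rng.random(values.shape) < spec.dropout_rate
        values = np.where(mask, 0.0, values)
    gene_ids = [f"g{i:04d}" for i in range(m)]
    gem = ExpressionMatrix(values, gene_ids, cell_ids)
    lab = LabelVector(cell_ids, labels)
    in_module = {
        t: sorted({g for mod in mods for g in mod})
        for t, mods in spec.modules_per_type.items()
    }
    everywhere = set.intersection(*(set(v) for v in in_module.values())) if in_module else set()
    planted = sorted(
        {g for v in in_module.values() for g in v} - everywhere
    ) if spec.n_types > 1 else []
    truth = {
        "modules_per_type": {t: mods for t, mods in spec.modules_per_type.items()},
        "planted_dark_genes": [gene_ids[g] for g in planted],
        "seed": spec.seed,
    }
    return gem, lab, truth
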