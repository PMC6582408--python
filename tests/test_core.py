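"""Neighborhood construction, the per-cell statistic, and network building."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import hypergeom

from csnet import (
    DegenerateBoxError,
    ExpressionMatrix,
    NeighborhoodCounts,
    NeighborhoodSpec,
    SizeCapError,
    ValidationError,
    build_all_networks,
    build_cell_network,
    edge_decision,
    iter_cell_networks,
    neighborhood,
    neighborhood_counts,
    pair_cell_statistic,
    pair_statistics,
    z_star,
)
from csnet.synthetic import ScenarioSpec, generate_pair, null_calibration


from _oracles import naive_neighborhood


class TestNeighborhood:
    def test_full_box(self):
        vals = np.arange(1.0, 11.0)
        for k in (0, 4, 9):
            assert neighborhood(vals, k, 1.0) == set(range(10))

    def test_all_tied_expands_to_everything(self):
        assert neighborhood(np.array([5.0, 5, 5, 5]), 0, 0.5) == {0, 1, 2, 3}

    def test_centered_window_on_distinct_values(self, rng):
        vals = np.sort(rng.random(100))  # sorted => rank == index
        got = neighborhood(vals, 50, 0.1)
        assert got == set(range(45, 55))
        assert len(got) == 10 and 50 in got

    def test_contains_focal_and_meets_target(self, rng):
        vals = rng.integers(0, 5, size=37).astype(float)  # heavy ties
        for k in range(37):
            s = neighborhood(vals, k, 0.2)
            assert k in s
            assert len(s) >= round(0.2 * 37)

    def test_matches_naive_oracle_with_ties_and_zeros(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            vals = rng.integers(0, 6, size=n).astype(float)
            vals[rng.random(n) < 0.3] = 0.0
            k = int(rng.integers(n))
            box = float(rng.uniform(0.05, 1.0))
            assert neighborhood(vals, k, box) == naive_neighborhood(vals, k, box)

    def test_too_few_cells(self):
        with pytest.raises(ValidationError):
            neighborhood(np.array([1.0]), 0, 0.5)


class TestPairCellStatistic:
    def test_exact_independence_gives_zero(self):
        s = pair_cell_statistic(NeighborhoodCounts(500, 50, 50, 5))
        assert s.rho == pytest.approx(0.0, abs=1e-15)
        assert s.rho_hat == pytest.approx(0.0, abs=1e-12)
        assert s.mu == 0.0

    def test_hand_evaluated_value(self):
        # sqrt(499) * (500*10 - 2500) / sqrt(50*50*450*450)
        s = pair_cell_statistic(NeighborhoodCounts(500, 50, 50, 10))
        expected = math.sqrt(499) * 2500 / 22500
        assert s.rho_hat == pytest.approx(expected)
        assert s.rho_hat == pytest.approx(2.4820, abs=1e-4)
        assert s.sigma > 0

    def test_symmetric_in_marginal_boxes(self):
        a = pair_cell_statistic(NeighborhoodCounts(500, 40, 60, 5))
        b = pair_cell_statistic(NeighborhoodCounts(500, 60, 40, 5))
        assert a.rho_hat == pytest.approx(b.rho_hat)

    @pytest.mark.parametrize("nx,ny", [(0, 10), (100, 10), (10, 0), (10, 100)])
    def test_degenerate_boxes_raise(self, nx, ny):
        with pytest.raises(DegenerateBoxError):
            pair_cell_statistic(NeighborhoodCounts(100, nx, ny, 0))

    def test_rho_bounded_small_exhaustive(self):
        # every valid count configuration up to n=12
        for n in range(2, 13):
            for nx in range(1, n):
                for ny in range(1, n):
                    for nxy in range(max(0, nx + ny - n), min(nx, ny) + 1):
                        s = pair_cell_statistic(NeighborhoodCounts(n, nx, ny, nxy))
                        assert -1.0 <= s.rho <= 1.0

    def test_counts_consistent_with_vectorized_path(self, rng):
        # per-pair formula route equals the all-pairs matrix route
        x = rng.lognormal(size=80)
        y = rng.lognormal(size=80)
        rho_hat = pair_statistics(x, y, NeighborhoodSpec(box_size=0.2))
        for k in (0, 17, 79):
            c = neighborhood_counts(x, y, k, box_size=0.2)
            assert pair_cell_statistic(c).rho_hat == pytest.approx(rho_hat[k])


class TestEdgeDecision:
    def test_normal_quantiles(self):
        assert z_star(0.01) == pytest.approx(2.3263478740, abs=1e-6)
        assert z_star(0.05) == pytest.approx(1.6448536270, abs=1e-6)

    @pytest.mark.parametrize(
        "rho_hat,alpha,expected",
        [(2.482, 0.01, True), (0.0, 0.01, False), (0.0, 0.4, False),
         (2.0, 0.05, True), (2.0, 0.01, False)],
    )
    def test_threshold_rule(self, rho_hat, alpha, expected):
        assert edge_decision(rho_hat, alpha) is expected


class TestBuildNetworks:
    def _dependent_gem(self, rng, n=500):
        t = rng.lognormal(size=n)
        return ExpressionMatrix(np.vstack([t, t]), ["gx", "gy"],
                                [f"c{i}" for i in range(n)])

    def test_perfect_dependence_gives_edge(self, rng):
        gem = self._dependent_gem(rng)
        k = int(np.argsort(gem.values[0])[250])  # interior cell
        net = build_cell_network(gem, k)
        assert (0, 1) in net.edges

    def test_outlier_cell_gets_no_edge(self, rng):
        n = 500
        t = rng.lognormal(size=n)
        x, y = t.copy(), t.copy()
        x[0], y[0] = x.max() * 100, 1e-6  # far off the dependence curve
        gem = ExpressionMatrix(np.vstack([x, y]), ["gx", "gy"],
                               [f"c{i}" for i in range(n)])
        assert (0, 1) not in build_cell_network(gem, 0).edges

    def test_zero_expression_drops_incident_edges(self, rng):
        n = 200
        t = rng.lognormal(size=n)
        values = np.vstack([t, t, t + 0.01 * rng.standard_normal(n)])
        values[0, 7] = 0.0
        gem = ExpressionMatrix(values, ["gx", "gy", "gz"],
                               [f"c{i}" for i in range(n)])
        net = build_cell_network(gem, 7, NeighborhoodSpec(zero_mode="drop_zero_edges"))
        assert all(0 not in e for e in net.edges)

    def test_all_zero_matrix_yields_empty_networks(self):
        gem = ExpressionMatrix(np.zeros((3, 4)), list("abc"), list("wxyz"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nets = build_all_networks(gem, sink="edge_lists")
        assert len(nets) == 4 and all(n.n_edges == 0 for n in nets)

    def test_symmetry_and_no_self_edges(self, rng):
        vals = rng.lognormal(size=(5, 60))
        gem = ExpressionMatrix(vals, [f"g{i}" for i in range(5)],
                               [f"c{j}" for j in range(60)])
        for net in iter_cell_networks(gem):
            for a, b in net.edges:
                assert a < b  # canonical undirected storage, no self-loops

    def test_sink_modes_agree(self, rng):
        vals = rng.lognormal(size=(6, 50))
        vals[rng.random(vals.shape) < 0.2] = 0.0
        vals[0] = rng.lognormal(size=50)  # keep at least one informative gene
        gem = ExpressionMatrix(vals, [f"g{i}" for i in range(6)],
                               [f"c{j}" for j in range(50)])
        ndm = build_all_networks(gem, sink="degree_only")
        nets = build_all_networks(gem, sink="edge_lists")
        from csnet import degree_matrix

        ndm2 = degree_matrix(nets, gem.gene_ids, gem.cell_ids)
        np.testing.assert_array_equal(ndm.values, ndm2.values)

    def test_stat_tensor_matches_pair_route(self, rng):
        vals = rng.lognormal(size=(4, 60))
        gem = ExpressionMatrix(vals, list("abcd"), [f"c{j}" for j in range(60)])
        spec = NeighborhoodSpec()
        stats = build_all_networks(gem, spec, sink="stat_tensor")
        for (ga, gb) in stats.index:
            ia, ib = gem.gene_ids.index(ga), gem.gene_ids.index(gb)
            expected = pair_statistics(vals[ia], vals[ib], spec)
            np.testing.assert_allclose(stats.loc[(ga, gb)].to_numpy(), expected)

    def test_stat_tensor_cap(self, rng):
        vals = rng.lognormal(size=(10, 50))
        gem = ExpressionMatrix(vals, [f"g{i}" for i in range(10)],
                               [f"c{j}" for j in range(50)])
        with pytest.raises(SizeCapError, match="cap"):
            build_all_networks(gem, sink="stat_tensor", stat_cap=100)

    def test_constant_gene_warns_and_stays_isolated(self, rng):
        t = rng.lognormal(size=80)
        vals = np.vstack([t, t, np.full(80, 3.0)])
        gem = ExpressionMatrix(vals, ["gx", "gy", "flat"],
                               [f"c{j}" for j in range(80)])
        with pytest.warns(UserWarning, match="degenerate"):
            ndm = build_all_networks(gem, sink="degree_only")
        assert np.all(ndm.values[2] == 0)

    def test_invariant_to_cell_permutation(self, rng):
        vals = rng.lognormal(size=(5, 60))
        gem = ExpressionMatrix(vals, [f"g{i}" for i in range(5)],
                               [f"c{j}" for j in range(60)])
        perm = rng.permutation(60)
        gem_p = ExpressionMatrix(vals[:, perm], gem.gene_ids,
                                 [gem.cell_ids[j] for j in perm])
        ndm = build_all_networks(gem, sink="degree_only")
        ndm_p = build_all_networks(gem_p, sink="degree_only")
        np.testing.assert_array_equal(ndm.values[:, perm], ndm_p.values)


class TestNullBehavior:
    def test_null_calibration_matches_exact_level(self):
        """Independent pairs: mean ~ 0, variance ~ 1, and the empirical
        edge rate matches the exact hypergeometric level of the threshold
        rule (computed by an independent scipy oracle)."""
        r = null_calibration(n_pairs=120, n=500, box_size=0.1, alpha=0.01, seed=11)
        assert abs(r["mean"]) < 3 * r["se_mean"]
        assert abs(r["var"] - 1.0) < 0.1
        # exact level: edge iff overlap count >= smallest integer with
        # rho_hat > z*; boxes hold 49 non-focal cells out of 499
        N, nx = 499, 49
        thr = (z_star(0.01) * nx * (N - nx) / math.sqrt(N - 1) + nx * nx) / N
        level = hypergeom.sf(math.floor(thr), N, nx, nx)
        assert abs(r["edge_rate"] - level) < 3 * r["se_rate"]

    def test_partial_dependence_power(self):
        """Cells in the dependent subpopulation show edges far above the
        significance level; independent cells stay near it."""
        spec = NeighborhoodSpec()
        dep_rates, ind_rates = [], []
        for seed in range(30):
            values, flags = generate_pair(
                ScenarioSpec(kind="partial_linear", n=500, seed=seed)
            )
            rho_hat = pair_statistics(values[0], values[1], spec)
            edges = rho_hat > z_star(spec.alpha)
            dep_rates.append(edges[flags].mean())
            ind_rates.append(edges[~flags].mean())
        dep, ind = np.mean(dep_rates), np.mean(ind_rates)
        assert dep > 0.5
        # the dependent mass distorts the marginal windows, so independent
        # cells sit somewhat above the nominal level but far below the
        # dependent subpopulation
        assert ind < 0.25
        assert dep > 3 * ind

    def test_planted_pair_dominates_independent_pairs(self, rng):
        """One dependent pair among independent genes: its edge count
        across cells exceeds every independent pair's."""
        n = 300
        t = rng.lognormal(size=n)
        vals = np.vstack(
            [t, t * np.exp(0.05 * rng.standard_normal(n))]
            + [rng.lognormal(size=n) for _ in range(4)]
        )
        gem = ExpressionMatrix(vals, [f"g{i}" for i in range(6)],
                               [f"c{j}" for j in range(n)])
        nets = build_all_networks(gem, sink="edge_lists")
        counts = {}
        for net in nets:
            for e in net.edges:
                counts[e] = counts.get(e, 0) + 1
        planted = counts.pop((0, 1), 0)
        assert planted > 0.5 * n
        assert all(c < 0.2 * n for c in counts.values())
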