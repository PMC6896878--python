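"""Join counts, Moran's I, permutation inference, and GWR."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtspill import (
    ModelSpec,
    SimulationConfig,
    cluster_smr_values,
    fit,
    gwr_poisson,
    join_count_test,
    join_counts,
    morans_i,
    morans_i_test,
    queen_adjacency,
    residual_morans,
    simulate_trial,
)
from crtspill.explore import StatisticError, suggest_bandwidth

from conftest import grid_adjacency


def checkerboard(nrow, ncol):
    return np.array([(r + c) % 2 for r in range(nrow) for c in range(ncol)])


class TestJoinCounts:
    def test_checkerboard_all_bw(self):
        adj = grid_adjacency(3, 3)
        bb, ww, bw = join_counts(adj, checkerboard(3, 3))
        assert (bb, ww, bw) == (0, 0, 12)

    def test_all_same_color(self):
        adj = grid_adjacency(3, 3)
        bb, ww, bw = join_counts(adj, np.ones(9, dtype=int))
        assert bb == adj.n_joins and ww == 0 and bw == 0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=9, max_size=9))
    def test_conservation_any_labeling(self, labels):
        adj = grid_adjacency(3, 3)
        bb, ww, bw = join_counts(adj, np.array(labels))
        assert bb + ww + bw == adj.n_joins

    def test_permutation_mean_matches_nonfree_sampling_expectation(self):
        # 3x3 rook grid, 5 black cells: E[BB] = J*nB*(nB-1)/(n*(n-1)) = 12*20/72
        adj = grid_adjacency(3, 3)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0])
        res = join_count_test(adj, labels, color=1, n_sim=4999, seed=0)
        expect = 12 * 5 * 4 / (9 * 8)
        mcse = res.null_draws.std(ddof=1) / math.sqrt(len(res.null_draws))
        assert res.null_draws.mean() == pytest.approx(expect, abs=4 * mcse)

    def test_checkerboard_p_near_one(self):
        adj = grid_adjacency(4, 4)
        res = join_count_test(adj, checkerboard(4, 4), color=1, n_sim=499, seed=1)
        assert res.observed == 0
        assert res.p_value > 0.9

    def test_solid_halves_small_p(self):
        adj = grid_adjacency(4, 4)
        labels = np.array([1] * 8 + [0] * 8)  # top half black
        res = join_count_test(adj, labels, color=1, n_sim=999, seed=2)
        assert res.p_value <= 0.05

    def test_p_value_formula_extreme(self):
        adj = grid_adjacency(4, 4)
        labels = np.array([1] * 8 + [0] * 8)
        res = join_count_test(adj, labels, color=1, n_sim=999, seed=3)
        exceed = int((res.null_draws >= res.observed).sum())
        assert res.p_value == (1 + exceed) / 1000
        if exceed == 0:
            assert res.p_value == pytest.approx(0.001)

    def test_absent_color_rejected(self):
        adj = grid_adjacency(2, 2)
        with pytest.raises(StatisticError):
            join_count_test(adj, np.ones(4, dtype=int), color=0)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        adj = grid_adjacency(4, 4)
        vals = np.where(checkerboard(4, 4) == 1, 1.0, -1.0)
        assert morans_i(adj, vals) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_values_rejected(self):
        adj = grid_adjacency(3, 3)
        with pytest.raises(StatisticError):
            morans_i(adj, np.full(9, 2.5))

    def test_matches_brute_force_double_sum(self, voronoi_geography):
        adj = queen_adjacency(voronoi_geography.clusters)
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(size=len(adj.cluster_ids))
            z = v - v.mean()
            k = len(v)
            num = sum(
                adj.W[i, j] * z[i] * z[j] for i in range(k) for j in range(k)
            )
            oracle = k / adj.W.sum() * num / (z @ z)
            assert morans_i(adj, v) == pytest.approx(oracle, abs=1e-12)

    def test_permutation_null_mean_is_minus_one_over_n_minus_one(self):
        adj = grid_adjacency(4, 4)
        rng = np.random.default_rng(7)
        res = morans_i_test(adj, rng.normal(size=16), n_sim=4999, seed=4)
        mcse = res.null_draws.std(ddof=1) / math.sqrt(len(res.null_draws))
        assert res.null_draws.mean() == pytest.approx(-1 / 15, abs=4 * mcse)

    def test_clustered_field_detected(self):
        cfg = SimulationConfig(n_clusters=96, households_per_cluster_mean=124,
                               seed=21, spatial_field="icar", icar_sd=0.5)
        trial, _ = simulate_trial(cfg, with_distances=False)
        adj = queen_adjacency(trial.clusters)
        res = morans_i_test(adj, cluster_smr_values(trial), n_sim=999, seed=5)
        assert res.p_value <= 0.01

    def test_checkerboard_greater_alternative_p_near_one(self):
        adj = grid_adjacency(4, 4)
        vals = np.where(checkerboard(4, 4) == 1, 1.0, -1.0)
        res = morans_i_test(adj, vals, n_sim=499, seed=6, alternative="greater")
        assert res.p_value > 0.95


class TestResidualMorans:
    def test_degenerate_residuals_propagate_domain_error(self, small_trial):
        from types import SimpleNamespace

        trial, _, _ = small_trial
        adj = queen_adjacency(trial.clusters)
        hh = trial.households
        # fitted means exactly equal to observed -> all residuals zero
        exact = SimpleNamespace(
            fitted=pd.Series(
                hh["observed"].to_numpy(dtype=float).clip(min=0.5),
                index=hh["household_id"].to_numpy(),
            )
        )
        exact.fitted[:] = 1.0  # constant means with constant counts below
        t2 = trial.copy()
        t2.households["observed"] = 1
        with pytest.raises(StatisticError):
            residual_morans(t2, exact, adj, n_sim=99)

    def test_detects_icar_field(self):
        """Power > 0.5 against a cluster-level spatial field at default SD."""
        rej = 0
        n = 20
        for seed in range(n):
            cfg = SimulationConfig(seed=1000 + seed, spillover_per_100m=0.0,
                                   spatial_field="icar")
            trial, _ = simulate_trial(cfg, with_distances=False)
            adj = queen_adjacency(trial.clusters)
            f = fit(trial, ModelSpec(random_structure="iid"))
            r = residual_morans(trial, f, adj, n_sim=199, seed=seed)
            rej += r.p_value <= 0.05
        assert rej / n > 0.5


class TestGWR:
    def test_global_bandwidth_reproduces_global_estimate(self, small_trial):
        import statsmodels.api as sm

        trial, _, _ = small_trial
        hh = trial.households
        X = np.column_stack([np.ones(len(hh)), hh["arm"].to_numpy(dtype=float)])
        glob = sm.GLM(
            hh["observed"].to_numpy(), X, family=sm.families.Poisson(),
            offset=np.log(hh["expected"].to_numpy()),
        ).fit()
        surf = gwr_poisson(trial, bandwidth_m=1e8, kernel="uniform", min_neighbors=1)
        np.testing.assert_allclose(
            surf.table["estimate"], math.exp(glob.params[1]), rtol=1e-8
        )

    def test_two_cluster_neighborhood_equals_smr_ratio(self):
        from shapely.geometry import box

        from conftest import toy_trial

        hh = [
            ("h0", 0.5, 0.5, "a", 0, 4, 2.0),
            ("h1", 0.6, 0.5, "a", 0, 2, 1.0),
            ("h2", 1.5, 0.5, "b", 1, 3, 2.0),
            ("h3", 1.6, 0.5, "b", 1, 1, 2.0),
        ]
        trial = toy_trial(hh, [("a", 0, box(0, 0, 1, 1)), ("b", 1, box(1, 0, 2, 1))])
        surf = gwr_poisson(trial, bandwidth_m=100.0, kernel="uniform", min_neighbors=1)
        ratio = (4 / 4) / (6 / 3)  # intervention SMR / control SMR
        np.testing.assert_allclose(surf.table["estimate"], ratio, rtol=1e-8)

    def test_iqr_shrinks_with_bandwidth(self, small_trial):
        trial, _, _ = small_trial
        bw0 = suggest_bandwidth(trial, min_neighbors=5)
        narrow = gwr_poisson(trial, bw0, min_neighbors=5).summary()
        wide = gwr_poisson(trial, 5 * bw0, min_neighbors=5).summary()
        iqr = lambda s: s["iqr"][1] - s["iqr"][0]
        assert iqr(wide) <= iqr(narrow)

    def test_undefined_focal_points_flagged(self, small_trial):
        trial, _, _ = small_trial
        surf = gwr_poisson(trial, bandwidth_m=2000.0, min_neighbors=5)
        assert {"defined", "n_local"} <= set(surf.table.columns)
        assert surf.table["defined"].any()
        assert surf.table.loc[~surf.table["defined"], "estimate"].isna().all()
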