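"""SMR model engine: oracles, limit cases, structural contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import roots_hermitenorm

from crtspill import (
    ModelSpec,
    SimulationConfig,
    fit,
    interaction_analysis,
    parametric_bootstrap,
    queen_adjacency,
    simulate_trial,
    spillover_fit,
)
from crtspill.models import DegenerateArmError, FitError


def gauss_hermite_ml(trial, n_nodes=40):
    """Independent oracle: exact-quadrature ML for the Poisson random-intercept
    model with intervention covariate, integrating each cluster's effect with
    Gauss-Hermite nodes and maximizing the true marginal likelihood."""
    hh = trial.households[trial.households["expected"] > 0]
    y = hh["observed"].to_numpy(dtype=float)
    x = hh["arm"].to_numpy(dtype=float)
    E = hh["expected"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(hh["cluster_id"])
    nodes, weights = roots_hermitenorm(n_nodes)
    logw = np.log(weights / math.sqrt(2 * math.pi)) + nodes**2 / 2  # vs N(0,1)
    logw = np.log(weights) - 0.5 * np.log(2 * np.pi) + 0.5 * nodes**2
    # simpler: weights already include exp(-z^2/2) factor for hermitenorm
    logw = np.log(weights / np.sqrt(2 * np.pi))

    def nll(params):
        a, b, logs = params
        s = math.exp(logs)
        total = 0.0
        for j in range(len(uniques)):
            m = codes == j
            ll_nodes = []
            for z, lw in zip(nodes, logw):
                eta = a + b * x[m] + s * z
                mu = E[m] * np.exp(eta)
                ll_nodes.append(lw + (y[m] * eta - mu + y[m] * np.log(E[m])).sum())
            total += float(np.logaddexp.reduce(ll_nodes))
        return -total

    res = optimize.minimize(nll, [0.0, 0.0, math.log(0.2)], method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000})
    return {"alpha": res.x[0], "beta": res.x[1], "sigma": math.exp(res.x[2])}


class TestIIDOracle:
    def test_matches_gauss_hermite_ml(self):
        cfg = SimulationConfig.scaled(10, 40, seed=13)
        trial, _ = simulate_trial(cfg, with_distances=False)
        oracle = gauss_hermite_ml(trial)
        res = fit(trial, ModelSpec(random_structure="iid"))
        assert res.coefficients.loc["intervention", "estimate"] == pytest.approx(
            oracle["beta"], abs=0.01
        )
        assert res.coefficients.loc["intercept", "estimate"] == pytest.approx(
            oracle["alpha"], abs=0.02
        )

    def test_sigma_zero_limit_matches_plain_poisson(self):
        import statsmodels.api as sm

        cfg = SimulationConfig(seed=14, sigma_cluster=0.0, spillover_per_100m=0.0)
        trial, _ = simulate_trial(cfg, with_distances=False)
        hh = trial.households
        X = np.column_stack([np.ones(len(hh)), hh["arm"].to_numpy(dtype=float)])
        glm = sm.GLM(hh["observed"].to_numpy(), X, family=sm.families.Poisson(),
                     offset=np.log(hh["expected"].to_numpy())).fit()
        res = fit(trial, ModelSpec(random_structure="iid"))
        assert res.variance_components["sigma_cluster"] < 0.05
        assert res.coefficients.loc["intervention", "estimate"] == pytest.approx(
            glm.params[1], rel=0.01, abs=0.005
        )


class TestStructures:
    def test_two_cluster_icar_sum_to_zero(self):
        from shapely.geometry import box

        from conftest import toy_trial

        rng = np.random.default_rng(0)
        hh = []
        for i in range(60):
            cid = "a" if i < 30 else "b"
            hh.append((f"h{i}", 0.5 + (i >= 30), 0.5, cid, int(i >= 30),
                       int(rng.poisson(0.5)), 0.4))
        trial = toy_trial(hh, [("a", 0, box(0, 0, 1, 1)), ("b", 1, box(1, 0, 2, 1))])
        adj = queen_adjacency(trial.clusters)
        res = fit(trial, ModelSpec(random_structure="car", min_arm_size=10), adj=adj)
        v = res.random_effects["icar"]
        assert v["a"] == pytest.approx(-v["b"], abs=1e-8)

    def test_gp_kernel_values(self):
        # exponential covariance: sigma^2 at 0, exp(-1)*sigma^2 at the range
        sigma, rho = 0.7, 850.0
        k = lambda d: sigma**2 * math.exp(-d / rho)
        assert k(0) == pytest.approx(sigma**2)
        assert k(rho) == pytest.approx(math.exp(-1) * sigma**2)

    def test_car_requires_adjacency_and_cluster_constant_covariates(self, small_trial):
        trial, _, _ = small_trial
        with pytest.raises(FitError, match="Adjacency"):
            fit(trial, ModelSpec(random_structure="car"))
        adj = queen_adjacency(trial.clusters)
        with pytest.raises(FitError, match="varies"):
            fit(trial, ModelSpec(random_structure="car", distance=True), adj=adj)

    def test_intervals_bracket_estimates_and_smr_is_exp(self, small_trial):
        trial, _, _ = small_trial
        adj = queen_adjacency(trial.clusters)
        for structure in ("iid", "car", "bym"):
            res = fit(trial, ModelSpec(random_structure=structure), adj=adj)
            c = res.coefficients
            assert (c["lower95"] <= c["estimate"]).all()
            assert (c["estimate"] <= c["upper95"]).all()
            np.testing.assert_allclose(
                res.smr_table.to_numpy(),
                np.exp(c[["estimate", "lower95", "upper95"]].to_numpy()),
            )


class TestStructuralContracts:
    def test_offset_rescaling_shifts_intercept_only(self, small_trial):
        trial, _, _ = small_trial
        res1 = fit(trial, ModelSpec(random_structure="iid"))
        t2 = trial.copy()
        t2.households["expected"] *= 3.0
        res2 = fit(t2, ModelSpec(random_structure="iid"))
        a1 = res1.coefficients.loc["intercept", "estimate"]
        a2 = res2.coefficients.loc["intercept", "estimate"]
        b1 = res1.coefficients.loc["intervention", "estimate"]
        b2 = res2.coefficients.loc["intervention", "estimate"]
        assert a2 == pytest.approx(a1 - math.log(3.0), abs=5e-3)
        assert b2 == pytest.approx(b1, abs=1e-3)

    def test_label_swap_antisymmetry(self, small_trial):
        trial, _, _ = small_trial
        res1 = fit(trial, ModelSpec(random_structure="iid"))
        t2 = trial.copy()
        t2.households["arm"] = 1 - t2.households["arm"]
        t2.clusters["arm"] = 1 - t2.clusters["arm"]
        res2 = fit(t2, ModelSpec(random_structure="iid"))
        assert res2.coefficients.loc["intervention", "estimate"] == pytest.approx(
            -res1.coefficients.loc["intervention", "estimate"], abs=1e-3
        )

    def test_cluster_totals_are_sufficient(self, small_trial):
        """Household-level and cluster-aggregated IID fits give the same
        intervention estimate when no household covariate is present."""
        from shapely.geometry import box

        from conftest import toy_trial

        trial, _, _ = small_trial
        res1 = fit(trial, ModelSpec(random_structure="iid"))
        agg = trial.households.groupby("cluster_id", sort=True).agg(
            observed=("observed", "sum"), expected=("expected", "sum"), arm=("arm", "first")
        ).reset_index()
        rows = [
            (f"agg_{r.cluster_id}", i, 0.5, r.cluster_id, int(r.arm),
             int(r.observed), float(r.expected))
            for i, r in agg.iterrows()
        ]
        clusters = [
            (r.cluster_id, int(r.arm), box(i, 0, i + 1, 1)) for i, r in agg.iterrows()
        ]
        t_agg = toy_trial(rows, clusters)
        res2 = fit(t_agg, ModelSpec(random_structure="iid", min_arm_size=2))
        assert res2.coefficients.loc["intervention", "estimate"] == pytest.approx(
            res1.coefficients.loc["intervention", "estimate"], abs=1e-5
        )

    def test_degenerate_arm_refused(self, small_trial):
        trial, _, _ = small_trial
        t2 = trial.copy()
        t2.households["arm"] = 1
        t2.clusters["arm"] = 1
        with pytest.raises(DegenerateArmError):
            fit(t2, ModelSpec(random_structure="iid"))

    def test_zero_expected_households_excluded_with_count(self, small_trial):
        trial, _, _ = small_trial
        t2 = trial.copy()
        idx = t2.households.index[:5]
        t2.households.loc[idx, "expected"] = 0.0
        t2.households.loc[idx, "observed"] = 0
        res = fit(t2, ModelSpec(random_structure="iid"))
        assert res.n_excluded_zero_expected == 5
        assert len(res.fitted) == len(t2.households) - 5


class TestSpillover:
    def test_pure_linear_decay_recovery(self):
        """With an infinite spillover range the IID+distance model is
        correctly specified and recovers psi."""
        est, se = [], []
        for seed in range(8):
            cfg = SimulationConfig(
                n_clusters=48, households_per_cluster_mean=60, seed=30 + seed,
                spillover_range_m=math.inf,
            )
            trial, truth = simulate_trial(cfg)
            res = spillover_fit(trial)
            c = res.coefficients.loc["distance_per_100m"]
            est.append(c["estimate"])
            se.append(c["se"])
        bias = np.mean(est) - math.log(1.017)
        mcse = np.std(est, ddof=1) / math.sqrt(len(est))
        assert abs(bias) < 2.5 * mcse

    def test_distance_term_leaves_intervention_unchanged_in_expectation(self):
        d0, d1 = [], []
        for seed in range(10):
            cfg = SimulationConfig.scaled(12, 50, seed=60 + seed, spillover_per_100m=0.0)
            trial, _ = simulate_trial(cfg)
            b0 = fit(trial, ModelSpec(random_structure="iid"))
            b1 = fit(trial, ModelSpec(random_structure="iid", distance=True))
            d0.append(b0.coefficients.loc["intervention", "estimate"])
            d1.append(b1.coefficients.loc["intervention", "estimate"])
        diff = np.array(d1) - np.array(d0)
        assert abs(diff.mean()) < 2.5 * diff.std(ddof=1) / math.sqrt(len(diff)) + 0.02


class TestInteraction:
    def test_reference_cells_are_exactly_one(self, small_trial):
        trial, _, _ = small_trial
        tab = interaction_analysis(trial, threshold_m=400.0)
        refs = tab.rows[tab.rows["lower95"].isna()]
        assert (refs["smr"] == 1.0).all()
        assert len(refs) == 4

    def test_contrast_consistency(self, small_trial):
        """Both conditioning directions come from one model: the product of
        (no-bednets far / no-bednets near) ratios must be internally consistent."""
        trial, _, _ = small_trial
        tab = interaction_analysis(trial, threshold_m=400.0)
        r = tab.rows.set_index(["conditioning", "stratum", "group"])["smr"]
        lhs = r[("distance", "far", "no bed nets")] / r[("distance", "near", "no bed nets")]
        rhs = r[("arm", "bed nets", "near")] / r[("arm", "no bed nets", "near")]
        # lhs = exp(-b_xfar); rhs = exp(-b_far-b_xfar)/exp(-b_far) = exp(-b_xfar)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_empty_stratum_named(self, small_trial):
        trial, _, _ = small_trial
        with pytest.raises(FitError, match="empty stratum"):
            interaction_analysis(trial, threshold_m=1e9)


class TestBootstrap:
    def test_mean_near_base_and_interval_brackets(self, small_trial):
        trial, _, _ = small_trial
        spec = ModelSpec(random_structure="iid", distance=True)
        boot = parametric_bootstrap(trial, spec, n_boot=120, seed=3)
        sd = boot.draws.std(ddof=1)
        assert boot.draws.mean() == pytest.approx(
            boot.base_estimate, abs=4 * sd / math.sqrt(len(boot.draws)) + 0.01
        )
        assert boot.lower95 < boot.upper95
        assert not boot.flagged

    def test_flag_consistency(self, small_trial):
        trial, _, _ = small_trial
        spec = ModelSpec(random_structure="iid", distance=True)
        boot = parametric_bootstrap(trial, spec, n_boot=30, seed=4)
        assert boot.flagged == (boot.n_failed > 0.05 * 30 or boot.lower95 == boot.upper95)
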