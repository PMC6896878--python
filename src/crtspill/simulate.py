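"""Synthetic cluster-randomized bed-net trials.

Emulates the geographic and statistical structure a spatial CRT reanalysis
assumes: a rectangle tiled by contiguous Voronoi cluster polygons, household
point locations, 1:1 cluster randomization, household expected deaths as a
Poisson offset, a multiplicative intervention effect, and an asymmetric
distance-decaying spillover — control mortality rises with distance from the
nearest bed-net household up to a range R, intervention mortality is flat in
distance.  Optional cluster-level ICAR or household-level Gaussian-process
fields add residual spatial structure for testing the spatial models against
their own generative assumptions.

The generative linear predictor for household h in cluster j is::

    eta_h = alpha + beta * x_j + u_j + s_h + spill_h
    spill_h = psi * min(d_h, R) / 100   (control; d_h = distance to nearest
                                         intervention household)
    spill_h = psi * R / 100             (intervention: range plateau)
    observed_h ~ Poisson(expected_h * exp(eta_h))

so that beyond the spillover range the two arms differ only by beta, and
beta is the intervention effect at distance >= R.  alpha is chosen so the
control arm's marginal SMR at distance >= R equals a configurable baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box

from .data import TrialData, distance_to_discordant

#: default rectangle gives ~6.25 km^2 per cluster at 96 clusters
DEFAULT_EXTENT = (30_000.0, 20_000.0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic trial.

    Defaults are the emulated trial's scale: 96 contiguous clusters of ~124
    households each (~12,000 total), intervention SMR 0.83, spillover SMR
    1.017 per 100 m attenuating at 400 m, control-arm baseline SMR 1.37,
    cluster random-effect SD 0.2.
    """

    n_clusters: int = 96
    households_per_cluster_mean: float = 124.0
    study_extent: tuple = DEFAULT_EXTENT  # (width_m, height_m)
    allocation: str = "1:1"
    baseline_expected_mean: float = 0.06  # expected deaths per household
    expected_dispersion: float = 2.0  # gamma shape; variance = mean^2 / shape
    log_intervention_effect: float = math.log(0.83)  # beta
    spillover_per_100m: float = math.log(1.017)  # psi
    spillover_range_m: float = 400.0  # R
    sigma_cluster: float = 0.2  # SD of IID cluster effect u_j
    baseline_control_smr: float = 1.37  # marginal control SMR at d >= R
    spatial_field: str = "off"  # off | icar | gp
    icar_sd: float = 0.3  # marginal SD of the ICAR cluster field
    gp_sigma: float = 0.3  # GP field SD at households
    gp_range_m: float = 1_000.0  # exponential covariance range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.households_per_cluster_mean <= 0:
            raise ValueError("households_per_cluster_mean must be positive")
        if self.spillover_range_m < 0:
            raise ValueError("spillover_range_m must be nonnegative")
        if min(self.sigma_cluster, self.icar_sd, self.gp_sigma) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.spatial_field not in ("off", "icar", "gp"):
            raise ValueError("spatial_field must be off|icar|gp")

    @classmethod
    def scaled(cls, n_clusters: int, households_per_cluster_mean: float, **kw) -> "SimulationConfig":
        """A smaller trial with the same per-cluster area (≈6.25 km²) and 3:2
        aspect, so spillover ranges in meters stay comparable to defaults."""
        area = DEFAULT_EXTENT[0] * DEFAULT_EXTENT[1] / 96 * n_clusters
        width = math.sqrt(area * 1.5)
        kw.setdefault("study_extent", (width, area / width))
        return cls(
            n_clusters=n_clusters,
            households_per_cluster_mean=households_per_cluster_mean,
            **kw,
        )


@dataclass
class GroundTruth:
    """Realized parameters sufficient to reconstruct every Poisson mean."""

    alpha: float
    beta: float
    psi: float
    spillover_range_m: float
    u: dict  # cluster_id -> IID effect
    cluster_field: dict  # cluster_id -> ICAR effect (empty if off)
    household_field: dict  # household_id -> GP effect (empty if off)
    eta: dict  # household_id -> linear predictor
    seed: int = 0

    def mean_for(self, household_id: str, expected: float) -> float:
        return expected * math.exp(self.eta[household_id])

    def to_dict(self) -> dict:
        return asdict(self)


def _voronoi_polygons(points: np.ndarray, extent: tuple) -> list:
    """Voronoi cells of ``points`` clipped to the rectangle.

    Mirrors the seeds across all four edges so every cell of an original
    point is bounded, then intersects with the rectangle: the cells tile it
    exactly.
    """
    w, h = extent
    mirrored = [points]
    for refl in (
        np.array([[-1, 1]]) * points,  # across x=0
        np.array([[1, -1]]) * points,  # across y=0
        np.array([[-1, 1]]) * points + np.array([[2 * w, 0]]),  # across x=w
        np.array([[1, -1]]) * points + np.array([[0, 2 * h]]),  # across y=h
    ):
        mirrored.append(refl)
    vor = Voronoi(np.vstack(mirrored))
    rect = box(0, 0, w, h)
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(rect)
        polys.append(poly)
    return polys


def _sample_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(4 * (n - len(out)), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def generate_geography(config: SimulationConfig) -> TrialData:
    """Cluster polygons (Voronoi tessellation of the study rectangle),
    household locations uniform within their polygon, and a balanced 1:1
    randomization of clusters to arms.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    w, h = config.study_extent
    k = config.n_clusters
    seeds = np.column_stack([rng.uniform(0, w, k), rng.uniform(0, h, k)])
    # coincident seeds would degenerate the tessellation; perturb locally
    while len(np.unique(np.round(seeds, 6), axis=0)) < k:
        seeds += rng.normal(scale=1e-3, size=seeds.shape)
    polys = _voronoi_polygons(seeds, (w, h))

    arms = np.array([1] * (k // 2) + [0] * (k - k // 2))
    arms = rng.permutation(arms)

    cluster_ids = [f"c{i:03d}" for i in range(k)]
    clusters = pd.DataFrame({"cluster_id": cluster_ids, "arm": arms, "geometry": polys})

    counts = rng.poisson(config.households_per_cluster_mean, size=k)
    rows = []
    hid = 0
    for cid, arm, poly, n in zip(cluster_ids, arms, polys, counts):
        if n == 0:
            continue
        xy = _sample_in_polygon(poly, int(n), rng)
        for x, y in xy:
            rows.append((f"h{hid:06d}", x, y, cid, int(arm), 0, 0.0))
            hid += 1
    households = pd.DataFrame(
        rows, columns=["household_id", "x", "y", "cluster_id", "arm", "observed", "expected"]
    )
    return TrialData(households, clusters, crs_note="synthetic planar meters")


def _icar_sample(W: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic CAR on graph W, sum-to-zero, scaled so the
    marginal SD (mean of per-node variances) equals ``sd``."""
    D = np.diag(W.sum(axis=1))
    Q = (D - W).astype(float)
    # generalized inverse on the sum-to-zero subspace
    vals, vecs = np.linalg.eigh(Q)
    keep = vals > 1e-8
    cov = (vecs[:, keep] / vals[keep]) @ vecs[:, keep].T
    scale = sd / math.sqrt(np.mean(np.diag(cov)))
    z = rng.standard_normal(keep.sum())
    return scale * (vecs[:, keep] * np.sqrt(1.0 / vals[keep])) @ z


def generate_outcomes(trial: TrialData, config: SimulationConfig):
    """Draw expected deaths, spillover distances, random effects and Poisson
    outcomes; returns (completed TrialData, GroundTruth)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = trial.copy()
    hh = out.households
    n = len(hh)
    arms = hh["arm"].to_numpy()
    if not (arms == 1).any() or not (arms == 0).any():
        raise ValueError("both arms must be non-empty")

    shape = config.expected_dispersion
    expected = rng.gamma(shape, config.baseline_expected_mean / shape, size=n)
    hh["expected"] = expected

    # distance from each household to the nearest opposite-arm household
    xy = hh[["x", "y"]].to_numpy(dtype=float)
    d_disc = np.empty(n)
    for a in (0, 1):
        tree = cKDTree(xy[arms == (1 - a)])
        d_disc[arms == a], _ = tree.query(xy[arms == a], k=1)
    R = config.spillover_range_m
    psi = config.spillover_per_100m
    if math.isinf(R):
        # pure linear decay: symmetric in arms (the finite-range asymmetric
        # form has no finite infinite-range limit)
        spill = psi * d_disc / 100.0
        plateau = 0.0
    else:
        spill = np.full(n, psi * R / 100.0)  # intervention plateau
        spill[arms == 0] = psi * np.minimum(d_disc[arms == 0], R) / 100.0
        plateau = psi * R / 100.0

    cluster_ids = list(trial.clusters["cluster_id"])
    u = rng.normal(0.0, config.sigma_cluster, size=len(cluster_ids))
    u_map = dict(zip(cluster_ids, u))

    field_var = 0.0
    cluster_field: dict = {}
    s_house = np.zeros(n)
    if config.spatial_field == "icar":
        from .spatial import queen_adjacency

        adj = queen_adjacency(trial.clusters)
        v = _icar_sample(adj.W, config.icar_sd, rng)
        cluster_field = dict(zip(adj.cluster_ids, v))
        s_house = np.array([cluster_field[c] for c in hh["cluster_id"]])
        field_var = config.icar_sd**2
    elif config.spatial_field == "gp":
        if n > 4000:
            raise ValueError("gp field generation is capped at 4000 households")
        dist = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        cov = config.gp_sigma**2 * np.exp(-dist / config.gp_range_m)
        cov[np.diag_indices_from(cov)] += 1e-10
        s_house = np.linalg.cholesky(cov) @ rng.standard_normal(n)
        field_var = config.gp_sigma**2

    # alpha fixes the control-arm marginal SMR at the spillover plateau
    # (at d=0 when the range is infinite)
    alpha = (
        math.log(config.baseline_control_smr)
        - plateau
        - config.sigma_cluster**2 / 2.0
        - field_var / 2.0
    )
    beta = config.log_intervention_effect
    u_house = np.array([u_map[c] for c in hh["cluster_id"]])
    eta = alpha + beta * arms + u_house + s_house + spill
    mu = expected * np.exp(eta)
    hh["observed"] = rng.poisson(mu)

    truth = GroundTruth(
        alpha=alpha,
        beta=beta,
        psi=psi,
        spillover_range_m=R,
        u=u_map,
        cluster_field=cluster_field,
        household_field=(
            dict(zip(hh["household_id"], s_house)) if config.spatial_field == "gp" else {}
        ),
        eta=dict(zip(hh["household_id"], eta)),
        seed=config.seed,
    )
    return out, truth


def simulate_trial(config: SimulationConfig, with_distances: bool = True):
    """Geography + outcomes (+ discordant distances) in one call."""
    trial = generate_geography(config)
    trial, truth = generate_outcomes(trial, config)
    if with_distances:
        trial = distance_to_discordant(trial)
    return trial, truth


def scenario_grid(configs, n_replicates: int, model_specs, seed: int = 0) -> pd.DataFrame:
    """Fit each model spec to ``n_replicates`` fresh trials per scenario.

    Returns a tidy frame: scenario, replicate, model, term, estimate,
    lower95, upper95, truth, bias, covered, error.  Fit failures are
    recorded per replicate, never fatal.
    """
    from dataclasses import replace

    from .models import fit as fit_model

    rows = []
    for s_idx, config in enumerate(configs):
        for rep in range(n_replicates):
            cfg = replace(config, seed=int(np.random.SeedSequence([seed, s_idx, rep]).generate_state(1)[0] % (2**31)))
            trial, truth = simulate_trial(cfg)
            truths = {"intervention": truth.beta, "distance_per_100m": truth.psi}
            for spec in model_specs:
                try:
                    res = fit_model(trial, spec)
                    for term in ("intervention", "distance_per_100m"):
                        if term not in res.coefficients.index:
                            continue
                        est = res.coefficients.loc[term]
                        tr = truths[term]
                        rows.append(
                            {
                                "scenario": s_idx,
                                "replicate": rep,
                                "model": spec.label(),
                                "term": term,
                                "estimate": est["estimate"],
                                "lower95": est["lower95"],
                                "upper95": est["upper95"],
                                "truth": tr,
                                "bias": est["estimate"] - tr,
                                "covered": bool(est["lower95"] <= tr <= est["upper95"]),
                                "error": "",
                            }
                        )
                except Exception as exc:  # record, don't abort the grid
                    rows.append(
                        {
                            "scenario": s_idx,
                            "replicate": rep,
                            "model": spec.label(),
                            "term": "",
                            "estimate": np.nan,
                            "lower95": np.nan,
                            "upper95": np.nan,
                            "truth": np.nan,
                            "bias": np.nan,
                            "covered": False,
                            "error": str(exc),
                        }
                    )
    return pd.DataFrame(rows)
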