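"""Join counts, Moran's I with permutation inference, and geographically
weighted Poisson regression.

All inference here is Monte Carlo: the observed statistic is compared with
its distribution under random permutation of labels/values over clusters,
and p = (1 + #{null >= observed}) / (1 + n_sim) for the one-sided "greater"
alternative.  The spatial weight matrix is the binary Queen's-case
contiguity, not row-standardized; Moran's I uses the (n/S0) normalization
accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialData
from .models import FitResult
from .spatial import AdjacencyMatrix

logger = logging.getLogger(__name__)


class StatisticError(ValueError):
    pass


@dataclass
class PermutationTestResult:
    statistic_name: str
    observed: float
    n_sim: int
    null_draws: np.ndarray
    p_value: float
    alternative: str
    seed: int

    def summary(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "n_sim": self.n_sim,
            "null_mean": float(np.mean(self.null_draws)),
            "null_sd": float(np.std(self.null_draws, ddof=1)),
        }


def _perm_p(observed: float, null: np.ndarray, alternative: str) -> float:
    n_sim = len(null)
    if alternative == "greater":
        return (1 + int((null >= observed).sum())) / (1 + n_sim)
    if alternative == "less":
        return (1 + int((null <= observed).sum())) / (1 + n_sim)
    if alternative == "two-sided":
        pg = (1 + int((null >= observed).sum())) / (1 + n_sim)
        pl = (1 + int((null <= observed).sum())) / (1 + n_sim)
        return min(1.0, 2.0 * min(pg, pl))
    raise StatisticError(f"unknown alternative {alternative!r}")


def _align_labels(adj: AdjacencyMatrix, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        missing = [c for c in adj.cluster_ids if c not in labels.index]
        if missing:
            raise StatisticError(f"labels missing for clusters: {missing[:5]}")
        return labels.loc[adj.cluster_ids].to_numpy()
    arr = np.asarray(labels)
    if len(arr) != len(adj.cluster_ids):
        raise StatisticError("labels length does not match adjacency")
    return arr


def join_counts(adj: AdjacencyMatrix, labels) -> tuple[int, int, int]:
    """Counts of adjacent unordered pairs by type: (BB, WW, BW) with B=1, W=0.

    Conservation: BB + WW + BW equals the number of graph edges.
    """
    lab = _align_labels(adj, labels).astype(int)
    if not set(lab).issubset({0, 1}):
        raise StatisticError("labels must be binary 0/1")
    ii, jj = np.nonzero(np.triu(adj.W, k=1))
    s = lab[ii] + lab[jj]
    bb = int((s == 2).sum())
    ww = int((s == 0).sum())
    bw = int((s == 1).sum())
    return bb, ww, bw


def join_count_test(adj: AdjacencyMatrix, labels, color: int, n_sim: int = 999,
                    seed: int = 0, alternative: str = "greater") -> PermutationTestResult:
    """Permutation test of same-color join clustering for the given color.

    The statistic is the count of adjacent pairs where both clusters carry
    ``color``; the null permutes the labels over clusters.
    """
    if n_sim < 99:
        raise StatisticError("n_sim must be >= 99")
    lab = _align_labels(adj, labels).astype(int)
    if color not in set(lab):
        raise StatisticError(f"color {color} absent from labels")

    def same_color(v):
        bb, ww, _ = join_counts(adj, v)
        return bb if color == 1 else ww

    observed = same_color(lab)
    rng = np.random.default_rng(seed)
    null = np.array([same_color(rng.permutation(lab)) for _ in range(n_sim)], dtype=float)
    return PermutationTestResult(
        statistic_name=f"join_count_{'intervention' if color == 1 else 'control'}",
        observed=float(observed),
        n_sim=n_sim,
        null_draws=null,
        p_value=_perm_p(observed, null, alternative),
        alternative=alternative,
        seed=seed,
    )


def morans_i(adj: AdjacencyMatrix, values) -> float:
    """Global Moran's I with binary weights:

        I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,  z = values - mean.

    Clusters without neighbors contribute to the denominator only (logged).
    """
    v = _align_labels(adj, values).astype(float)
    z = v - v.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise StatisticError("Moran's I undefined: values have zero variance")
    W = adj.W
    S0 = float(W.sum())
    if S0 <= 0:
        raise StatisticError("Moran's I undefined: no joins in adjacency")
    iso = int((W.sum(axis=1) == 0).sum())
    if iso:
        logger.info("%d isolated cluster(s) contribute to the denominator only", iso)
    return float(len(v) / S0 * (z @ W @ z) / denom)


def morans_i_test(adj: AdjacencyMatrix, values, n_sim: int = 999, seed: int = 0,
                  alternative: str = "greater") -> PermutationTestResult:
    """Monte Carlo test: values shuffled over cluster locations."""
    if n_sim < 99:
        raise StatisticError("n_sim must be >= 99")
    v = _align_labels(adj, values).astype(float)
    observed = morans_i(adj, v)
    rng = np.random.default_rng(seed)
    null = np.array([morans_i(adj, rng.permutation(v)) for _ in range(n_sim)])
    return PermutationTestResult(
        statistic_name="morans_i",
        observed=observed,
        n_sim=n_sim,
        null_draws=null,
        p_value=_perm_p(observed, null, alternative),
        alternative=alternative,
        seed=seed,
    )


def cluster_smr_values(trial: TrialData) -> pd.Series:
    """Per-cluster SMR (observed/expected totals), indexed by cluster_id."""
    g = trial.households.groupby("cluster_id")[["observed", "expected"]].sum()
    bad = g[g["expected"] <= 0]
    if len(bad):
        raise StatisticError(f"cluster(s) with zero expected deaths: {list(bad.index)[:5]}")
    return g["observed"] / g["expected"]


def residual_morans(trial: TrialData, fit_result: FitResult, adj: AdjacencyMatrix,
                    n_sim: int = 999, seed: int = 0,
                    alternative: str = "greater") -> PermutationTestResult:
    """Moran's I on cluster-mean Pearson residuals from a fitted model —
    spatial autocorrelation net of the intervention effect and clustering.

    r_h = (observed_h - mu_h) / sqrt(mu_h); the cluster value is the
    arithmetic mean of its households' residuals.
    """
    hh = trial.households.set_index("household_id")
    mu = fit_result.fitted
    if (mu <= 0).any():
        raise StatisticError("fitted means must be positive")
    obs = hh.loc[mu.index, "observed"].to_numpy(dtype=float)
    r = (obs - mu.to_numpy()) / np.sqrt(mu.to_numpy())
    cl = hh.loc[mu.index, "cluster_id"].to_numpy()
    means = pd.Series(r).groupby(cl).mean()
    means = means.reindex(adj.cluster_ids).dropna()
    adj_used = adj
    if len(means) != len(adj.cluster_ids):
        from .spatial import subset_adjacency

        adj_used = subset_adjacency(adj, list(means.index))
    res = morans_i_test(adj_used, means, n_sim=n_sim, seed=seed, alternative=alternative)
    res.statistic_name = "morans_i_residuals"
    return res


@dataclass
class GWRSurface:
    """Local intervention SMR estimates at cluster centroids."""

    table: pd.DataFrame  # cluster_id, x, y, estimate, n_local, defined
    bandwidth_m: float
    kernel: str

    def summary(self) -> dict:
        est = self.table.loc[self.table["defined"], "estimate"]
        if est.empty:
            raise StatisticError("no focal point has a defined local estimate")
        return {
            "median": float(est.median()),
            "iqr": [float(est.quantile(0.25)), float(est.quantile(0.75))],
            "n_defined": int(len(est)),
            "n_above_one": int((est > 1).sum()),
        }


def _kernel_weights(dist: np.ndarray, bandwidth: float, kernel: str) -> np.ndarray:
    inside = dist <= bandwidth
    w = np.zeros_like(dist)
    if kernel == "uniform":
        w[inside] = 1.0
    elif kernel == "bisquare":
        w[inside] = (1.0 - (dist[inside] / bandwidth) ** 2) ** 2
    else:
        raise StatisticError(f"unknown kernel {kernel!r}")
    return w


def suggest_bandwidth(trial: TrialData, step_m: float = 250.0,
                      min_neighbors: int = 10) -> float:
    """Smallest radius (searched on a grid) at which every cluster centroid
    has at least ``min_neighbors`` households of each arm within it."""
    cl = trial.clusters
    hh = trial.households
    cxy = cl[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    hxy = hh[["x", "y"]].to_numpy(dtype=float)
    arm = hh["arm"].to_numpy()
    d = np.sqrt(((cxy[:, None, :] - hxy[None, :, :]) ** 2).sum(-1))
    bw = step_m
    dmax = d.max()
    while bw <= dmax + step_m:
        ok = True
        for a in (0, 1):
            counts = (d[:, arm == a] <= bw).sum(axis=1)
            if (counts < min_neighbors).any():
                ok = False
                break
        if ok:
            return float(bw)
        bw += step_m
    return float(dmax)


def gwr_poisson(trial: TrialData, bandwidth_m: float, kernel: str = "bisquare",
                min_neighbors: int = 10) -> GWRSurface:
    """Geographically weighted Poisson regression of deaths on the
    intervention, offset log(expected), at each cluster centroid.

    Households within ``bandwidth_m`` of the focal centroid enter with
    kernel weights; the local model has no cluster random effect.  Focal
    clusters with fewer than ``min_neighbors`` households in either arm are
    flagged undefined.
    """
    import statsmodels.api as sm

    if bandwidth_m <= 0:
        raise StatisticError("bandwidth_m must be positive")
    hh = trial.households[trial.households["expected"] > 0]
    hxy = hh[["x", "y"]].to_numpy(dtype=float)
    y = hh["observed"].to_numpy(dtype=float)
    x = hh["arm"].to_numpy(dtype=float)
    off = np.log(hh["expected"].to_numpy(dtype=float))

    rows = []
    for _, c in trial.clusters.iterrows():
        dist = np.sqrt((hxy[:, 0] - c["centroid_x"]) ** 2 + (hxy[:, 1] - c["centroid_y"]) ** 2)
        w = _kernel_weights(dist, bandwidth_m, kernel)
        sel = w > 0
        n0 = int((sel & (x == 0)).sum())
        n1 = int((sel & (x == 1)).sum())
        row = {
            "cluster_id": c["cluster_id"],
            "x": c["centroid_x"],
            "y": c["centroid_y"],
            "estimate": np.nan,
            "n_local": int(sel.sum()),
            "defined": False,
        }
        if min(n0, n1) >= min_neighbors:
            X = np.column_stack([np.ones(sel.sum()), x[sel]])
            try:
                glm = sm.GLM(
                    y[sel], X, family=sm.families.Poisson(), offset=off[sel], var_weights=w[sel]
                )
                fit = glm.fit()
                row["estimate"] = float(np.exp(fit.params[1]))
                row["defined"] = True
            except Exception as exc:  # separation / all-zero neighborhoods
                logger.warning("GWR fit failed at %s: %s", c["cluster_id"], exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table["defined"].any():
        raise StatisticError("no focal point has both arms represented within the bandwidth")
    return GWRSurface(table=table, bandwidth_m=float(bandwidth_m), kernel=kernel)
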