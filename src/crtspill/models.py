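"""Poisson SMR models with spatial random effects, spillover and interaction.

All models share the Poisson likelihood with log expected deaths as offset,
so coefficients act on the SMR scale::

    observed_h ~ Poisson(expected_h * exp(eta_h))
    eta_h = alpha + beta * x_j [+ psi * d_h/100 ...] + random effects

Random-effect structures:

``iid``
    independent Normal(0, sigma_u^2) intercept per cluster — the standard
    CRT analysis.
``car``
    intrinsic conditional autoregressive (Besag) effect on the cluster
    contiguity graph, sum-to-zero constrained; requires aggregation of
    households to clusters (one observation per area).
``bym``
    Besag–York–Mollié convolution: IID plus ICAR cluster effects, fitted at
    household level.
``gp``
    household-level zero-mean Gaussian field with exponential covariance
    sigma^2 * exp(-d / rho), evaluated with an exact dense covariance and a
    seeded household subsample above a size cap.

Inference is a nested Laplace approximation (``laplace_map``): a joint
Newton ascent over fixed and random effects conditional on the variance
parameters, with the variance parameters maximizing the Laplace-approximate
marginal likelihood (random effects integrated out, fixed effects
profiled).  Weakly-informative penalties — Normal(0, 10^2) on fixed
effects, half-Normal(0, 1) on standard deviations — stabilize the fit.
95% intervals are Wald intervals from the joint precision at the mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.stats import chi2, norm

from .data import TrialData
from .spatial import AdjacencyMatrix

logger = logging.getLogger(__name__)

RANDOM_STRUCTURES = ("iid", "car", "bym", "gp")


class FitError(RuntimeError):
    pass


class DegenerateArmError(FitError):
    """A fit was requested on an assignment with an (near-)empty arm."""


@dataclass
class ModelSpec:
    """Which model to fit: random structure, covariates, and hyperparameters.

    ``distance_cap_m`` replaces the linear distance d/100 with the capped
    form min(d, cap)/100, the same functional family used when exploring
    distance decay; ``distance_threshold_m`` adds the binary far/near
    indicator, and ``interaction`` its product with the intervention.
    """

    random_structure: str = "iid"
    intervention: bool = True
    distance: bool = False  # d_discordant / 100 m
    distance_quadratic: bool = False
    distance_cap_m: float | None = None
    distance_threshold_m: float | None = None
    interaction: bool = False
    inference: str = "laplace_map"
    fixed_prior_sd: float = 10.0
    sd_prior_scale: float = 1.0
    gp_range_m: float = 1_000.0
    gp_max_households: int = 3_000
    min_arm_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(f"random_structure must be one of {RANDOM_STRUCTURES}")
        if self.inference != "laplace_map":
            raise ValueError("only the laplace_map engine is implemented")
        if self.interaction and self.distance_threshold_m is None:
            raise ValueError("interaction requires distance_threshold_m")

    def label(self) -> str:
        parts = [self.random_structure]
        if self.distance:
            parts.append("distance")
        if self.distance_quadratic:
            parts.append("quadratic")
        if self.distance_threshold_m is not None:
            parts.append("threshold")
        if self.interaction:
            parts.append("interaction")
        return "+".join(parts)


@dataclass
class FitResult:
    """Estimates on the log scale plus SMR-scale transforms and diagnostics."""

    model: ModelSpec
    coefficients: pd.DataFrame  # index: term; cols: estimate, se, lower95, upper95
    smr_table: pd.DataFrame  # exp() of the above
    fitted: pd.Series  # household_id -> fitted Poisson mean
    random_effects: dict
    variance_components: dict
    loglik_marginal: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    engine: str = "laplace_map"
    n_excluded_zero_expected: int = 0
    coef_cov: np.ndarray | None = None

    def coefficient(self, term: str) -> pd.Series:
        return self.coefficients.loc[term]

    def smr(self, term: str = "intervention") -> pd.Series:
        return self.smr_table.loc[term]

    def table_row(self) -> dict:
        t = self.smr_table.loc["intervention"]
        return {
            "model": self.model.label(),
            "term": "intervention",
            "smr": t["estimate"],
            "lower95": t["lower95"],
            "upper95": t["upper95"],
        }


# ---------------------------------------------------------------------------
# Laplace engine


def _poisson_ll(y, eta, off):
    mu = np.exp(np.clip(eta + off, -30, 30))
    return float(y @ (eta + off) - mu.sum()), mu


def _newton(y, off, A, P, u0, max_iter=100, tol=1e-9):
    """Joint mode of the penalized Poisson log-likelihood.

    Returns (u, H, ll_poisson, ok); H is the penalized Hessian at the mode.
    """
    u = u0.copy()
    ll, mu = _poisson_ll(y, A @ u, off)
    obj = ll - 0.5 * u @ (P @ u)
    ok = False
    for _ in range(max_iter):
        grad = A.T @ (y - mu) - P @ u
        H = (A.T * mu) @ A + P
        try:
            c = cho_factor(H)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(len(u))
            c = cho_factor(H)
        step = cho_solve(c, grad)
        t = 1.0
        for _ in range(40):
            u_new = u + t * step
            ll_new, mu_new = _poisson_ll(y, A @ u_new, off)
            obj_new = ll_new - 0.5 * u_new @ (P @ u_new)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        improved = obj_new - obj
        u, ll, mu, obj = u_new, ll_new, mu_new, obj_new
        if np.max(np.abs(grad)) < tol * (1 + abs(ll)) or improved < 1e-10:
            ok = True
            break
    H = (A.T * mu) @ A + P
    return u, H, ll, ok


class _Penalty:
    """Builds the random-effect precision block Q(theta) and its log-det."""

    def __init__(self, blocks):
        # blocks: list of (size, kind, payload); kind in {iid, icar, gp}
        self.blocks = blocks
        self.n_theta = len(blocks)
        self.size = sum(b[0] for b in blocks)

    def build(self, theta):
        mats, logdet = [], 0.0
        for (m, kind, payload), th in zip(self.blocks, theta):
            sig2 = math.exp(2.0 * th)
            if kind == "iid":
                mats.append(np.eye(m) / sig2)
                logdet += -m * 2.0 * th
            elif kind == "icar":
                Qc, ld = payload  # T'(D-W+eps)T and its logdet
                mats.append(Qc / sig2)
                logdet += ld - m * 2.0 * th
            elif kind == "gp":
                Kinv, logdetK = payload
                mats.append(Kinv / sig2)
                logdet += -logdetK - m * 2.0 * th
        Q = np.zeros((self.size, self.size))
        i = 0
        for M in mats:
            m = M.shape[0]
            Q[i : i + m, i : i + m] = M
            i += m
        return Q, logdet


def _laplace(y, off, X, Z, penalty: _Penalty, fixed_prior_sd, sd_prior_scale, theta0=None):
    """Nested Laplace fit.  Returns a dict with mode, covariance, theta, logL."""
    n, p = X.shape
    mb = Z.shape[1] if Z is not None else 0
    A = np.hstack([X, Z]) if mb else X
    m = p + mb
    P_fix = np.zeros((m, m))
    P_fix[:p, :p] = np.eye(p) / fixed_prior_sd**2

    cache = {"u": np.zeros(m)}

    def neg_marginal(theta):
        Q, logdetQ = penalty.build(theta)
        P = P_fix.copy()
        P[p:, p:] += Q
        u, H, ll, ok = _newton(y, off, A, P, cache["u"])
        if ok:
            cache["u"] = u
        b = u[p:]
        pen = 0.5 * b @ (Q @ b) + 0.5 * u[:p] @ (P_fix[:p, :p] @ u[:p])
        try:
            c = cho_factor(H[p:, p:])
            logdetH = 2.0 * np.log(np.diag(c[0])).sum()
        except np.linalg.LinAlgError:
            return 1e10
        # half-Normal(0, s) penalty on each SD
        prior = -0.5 * sum(math.exp(2 * th) / sd_prior_scale**2 for th in theta)
        logL = ll - pen + 0.5 * logdetQ - 0.5 * logdetH + prior
        return -logL

    if penalty.n_theta == 0:
        theta = np.array([])
        nll = neg_marginal(theta)
    elif penalty.n_theta == 1:
        res = optimize.minimize_scalar(
            lambda t: neg_marginal([t]), bounds=(math.log(1e-3), math.log(5.0)),
            method="bounded", options={"xatol": 0.01},
        )
        theta = np.array([res.x])
        nll = res.fun
    else:
        t0 = theta0 if theta0 is not None else np.full(penalty.n_theta, math.log(0.2))
        res = optimize.minimize(
            neg_marginal, t0, method="Nelder-Mead",
            options={"xatol": 0.02, "fatol": 1e-4, "maxiter": 80 * penalty.n_theta},
        )
        theta = np.clip(res.x, math.log(1e-3), math.log(5.0))
        nll = neg_marginal(theta)

    Q, _ = penalty.build(theta)
    P = P_fix.copy()
    P[p:, p:] += Q
    u, H, ll, ok = _newton(y, off, A, P, cache["u"])
    try:
        cov = cho_solve(cho_factor(H), np.eye(m))
        pd_ok = True
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        pd_ok = False
    mu = np.exp(np.clip(A @ u + off, -30, 30))
    return {
        "u": u,
        "cov": cov,
        "theta": theta,
        "logL": -nll,
        "mu": mu,
        "converged": bool(ok and pd_ok),
        "p": p,
    }


# ---------------------------------------------------------------------------
# design construction


def _design(hh: pd.DataFrame, spec: ModelSpec):
    """Fixed-effect design matrix and term names from a household table."""
    n = len(hh)
    cols = [np.ones(n)]
    names = ["intercept"]
    if spec.intervention:
        cols.append(hh["arm"].to_numpy(dtype=float))
        names.append("intervention")
    needs_d = spec.distance or spec.distance_quadratic or spec.distance_threshold_m is not None
    if needs_d:
        if "d_discordant" not in hh.columns:
            raise FitError("distance terms require d_discordant (run distance_to_discordant)")
        d = hh["d_discordant"].to_numpy(dtype=float)
    if spec.distance:
        dv = np.minimum(d, spec.distance_cap_m) if spec.distance_cap_m else d
        cols.append(dv / 100.0)
        names.append("distance_per_100m")
        if spec.distance_quadratic:
            cols.append((dv / 100.0) ** 2)
            names.append("distance_per_100m_sq")
    if spec.distance_threshold_m is not None:
        far = (d > spec.distance_threshold_m).astype(float)
        cols.append(far)
        names.append("far")
        if spec.interaction:
            cols.append(far * hh["arm"].to_numpy(dtype=float))
            names.append("intervention_x_far")
    return np.column_stack(cols), names


def _icar_block(adj: AdjacencyMatrix):
    """Sum-to-zero reparametrized intrinsic CAR precision: T, T'(D-W)T, logdet."""
    W = adj.W.astype(float)
    q = W.shape[0]
    Qfull = np.diag(W.sum(axis=1)) - W + 1e-6 * np.eye(q)
    T = null_space(np.ones((1, q)))  # q x (q-1), orthonormal, columns sum to 0
    Qc = T.T @ Qfull @ T
    sign, ld = np.linalg.slogdet(Qc)
    if sign <= 0:
        raise FitError("ICAR precision not positive definite on the constraint space")
    return T, Qc, ld


def _check_arms(hh: pd.DataFrame, spec: ModelSpec):
    counts = hh["arm"].value_counts()
    if spec.intervention and (len(counts) < 2 or counts.min() < spec.min_arm_size):
        raise DegenerateArmError(
            f"arm sizes {dict(counts)} below minimum {spec.min_arm_size}; refusing fit"
        )


def fit(trial: TrialData, spec: ModelSpec, adj: AdjacencyMatrix | None = None) -> FitResult:
    """Fit a Poisson SMR model per the ModelSpec; see module docstring for forms.

    Households with expected = 0 (and observed = 0) are excluded from the
    likelihood with a logged count.  ``car``/``bym`` require the cluster
    adjacency; ``car`` additionally requires all covariates to be constant
    within cluster, since it aggregates households to one observation per
    cluster.
    """
    hh = trial.households
    excl = (hh["expected"].to_numpy(dtype=float) <= 0)
    n_excl = int(excl.sum())
    if n_excl:
        if (hh.loc[excl, "observed"] > 0).any():
            raise FitError("household with expected=0 but observed>0")
        logger.info("excluding %d household(s) with expected=0 from the likelihood", n_excl)
        hh = hh[~excl]
    _check_arms(hh, spec)

    if spec.random_structure in ("car", "bym") and adj is None:
        raise FitError(f"{spec.random_structure} requires an AdjacencyMatrix")

    rng = np.random.default_rng(spec.seed)
    cluster_ids = list(trial.clusters["cluster_id"])
    gp_sub_ids = None

    if spec.random_structure == "car":
        X_house, names = _design(hh, spec)
        # covariates must be cluster-constant to aggregate
        for jcol, name in enumerate(names):
            v = pd.Series(X_house[:, jcol]).groupby(hh["cluster_id"].to_numpy()).nunique()
            if (v > 1).any():
                raise FitError(f"car model requires cluster-constant covariates; {name!r} varies")
        agg = hh.groupby("cluster_id", sort=False).agg(
            observed=("observed", "sum"), expected=("expected", "sum"), arm=("arm", "first")
        )
        agg = agg.reindex([c for c in cluster_ids if c in agg.index])
        present = list(agg.index)
        y = agg["observed"].to_numpy(dtype=float)
        off = np.log(agg["expected"].to_numpy(dtype=float))
        Xa = np.column_stack(
            [np.ones(len(agg))] + ([agg["arm"].to_numpy(dtype=float)] if spec.intervention else [])
        )
        names = ["intercept"] + (["intervention"] if spec.intervention else [])
        subset_ids = present
        from .spatial import subset_adjacency

        adj_used = subset_adjacency(adj, subset_ids) if set(subset_ids) != set(adj.cluster_ids) else adj
        T, Qc, ld = _icar_block(adj_used)
        Z = T  # one row per cluster
        penalty = _Penalty([(T.shape[1], "icar", (Qc, ld))])
        res = _laplace(y, off, Xa, Z, penalty, spec.fixed_prior_sd, spec.sd_prior_scale)
        # distribute cluster-level fitted means back to households
        eta_c = Xa @ res["u"][: res["p"]] + Z @ res["u"][res["p"]:]
        eta_map = dict(zip(present, eta_c))
        fitted = hh["expected"].to_numpy(dtype=float) * np.exp(
            np.array([eta_map[c] for c in hh["cluster_id"]])
        )
        re_dict = {"icar": dict(zip(present, Z @ res["u"][res["p"]:]))}
        vc = {"sigma_icar": float(math.exp(res["theta"][0]))}
        X = Xa
    else:
        if spec.random_structure == "gp" and len(hh) > spec.gp_max_households:
            idx = np.sort(rng.choice(len(hh), spec.gp_max_households, replace=False))
            hh = hh.iloc[idx]
            _check_arms(hh, spec)
            gp_sub_ids = list(hh["household_id"])
        X, names = _design(hh, spec)
        y = hh["observed"].to_numpy(dtype=float)
        off = np.log(hh["expected"].to_numpy(dtype=float))
        present = [c for c in cluster_ids if c in set(hh["cluster_id"])]
        cidx = pd.Categorical(hh["cluster_id"], categories=present).codes
        C = np.zeros((len(hh), len(present)))
        C[np.arange(len(hh)), cidx] = 1.0

        blocks, Zparts, re_names = [], [], []
        # IID cluster intercept is part of every household-level structure
        Zparts.append(C)
        blocks.append((len(present), "iid", None))
        re_names.append("iid")
        if spec.random_structure == "bym":
            from .spatial import subset_adjacency

            adj_used = (
                subset_adjacency(adj, present) if set(present) != set(adj.cluster_ids) else adj
            )
            T, Qc, ld = _icar_block(adj_used)
            Zparts.append(C @ T)
            blocks.append((T.shape[1], "icar", (Qc, ld)))
            re_names.append("icar")
        elif spec.random_structure == "gp":
            xy = hh[["x", "y"]].to_numpy(dtype=float)
            dmat = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
            K = np.exp(-dmat / spec.gp_range_m)
            K[np.diag_indices_from(K)] += 1e-8
            cK = cho_factor(K)
            Kinv = cho_solve(cK, np.eye(len(hh)))
            logdetK = 2.0 * np.log(np.diag(cK[0])).sum()
            Zparts.append(np.eye(len(hh)))
            blocks.append((len(hh), "gp", (Kinv, logdetK)))
            re_names.append("gp")

        Z = np.hstack(Zparts)
        penalty = _Penalty(blocks)
        res = _laplace(y, off, X, Z, penalty, spec.fixed_prior_sd, spec.sd_prior_scale)
        fitted = res["mu"]
        b = res["u"][res["p"]:]
        re_dict, vc, i = {}, {}, 0
        for (msz, kind, _), nm, th in zip(blocks, re_names, res["theta"]):
            seg = b[i : i + msz]
            if nm == "iid":
                re_dict["iid"] = dict(zip(present, seg))
                vc["sigma_cluster"] = float(math.exp(th))
            elif nm == "icar":
                re_dict["icar"] = dict(zip(present, T @ seg))
                vc["sigma_icar"] = float(math.exp(th))
            elif nm == "gp":
                re_dict["gp"] = dict(zip(hh["household_id"], seg))
                vc["sigma_gp"] = float(math.exp(th))
                vc["gp_range_m"] = spec.gp_range_m
            i += msz

    p = res["p"]
    est = res["u"][:p]
    se = np.sqrt(np.diag(res["cov"])[:p])
    zq = norm.ppf(0.975)
    coef = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "lower95": est - zq * se,
            "upper95": est + zq * se,
        },
        index=names,
    )
    smr_table = np.exp(coef[["estimate", "lower95", "upper95"]])

    fitted_s = pd.Series(fitted, index=hh["household_id"].to_numpy(), name="fitted")
    diagnostics = {
        "n_households": int(len(hh)),
        "max_abs_gradient_ok": res["converged"],
        "theta": [float(t) for t in res["theta"]],
    }
    if gp_sub_ids is not None:
        diagnostics["gp_subsample"] = len(gp_sub_ids)
    if not res["converged"]:
        logger.warning("fit flagged non-converged: %s", diagnostics)
    return FitResult(
        model=spec,
        coefficients=coef,
        smr_table=smr_table,
        fitted=fitted_s,
        random_effects=re_dict,
        variance_components=vc,
        loglik_marginal=float(res["logL"]),
        converged=res["converged"],
        diagnostics=diagnostics,
        n_excluded_zero_expected=n_excl,
        coef_cov=res["cov"][:p, :p],
    )


def spillover_fit(trial: TrialData, spec: ModelSpec | None = None,
                  adj: AdjacencyMatrix | None = None, quadratic: bool = False) -> FitResult:
    """IID (or spatial) model with the discordant distance per 100 m; exp(psi)
    is the SMR multiplier per additional 100 m from the nearest opposite-arm
    household."""
    if spec is None:
        spec = ModelSpec(random_structure="iid", distance=True)
    else:
        spec = replace(spec, distance=True, distance_quadratic=quadratic or spec.distance_quadratic)
    return fit(trial, spec, adj=adj)


@dataclass
class StratumSMRTable:
    """Stratum-specific contrasts from the threshold-interaction model."""

    threshold_m: float
    rows: pd.DataFrame  # conditioning, stratum, group, smr, lower95, upper95
    interaction_p: float
    lrt_stat: float

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out["interaction_p"] = self.interaction_p
        return out


def interaction_analysis(trial: TrialData, threshold_m: float = 400.0,
                         spec: ModelSpec | None = None) -> StratumSMRTable:
    """Threshold interaction between intervention and near/far discordant
    distance, with stratum-specific SMRs in both conditioning directions and
    a likelihood-ratio global test for interaction.

    Contrasts are read off the IID model
    eta = alpha + b_x * x + b_far * far + b_xfar * x * far + u_j with the
    reference category (SMR 1.00) being bed nets within each distance
    stratum, and "further than threshold" within each arm.
    """
    base = spec or ModelSpec(random_structure="iid")
    full_spec = replace(base, distance=False, distance_threshold_m=threshold_m, interaction=True)
    red_spec = replace(base, distance=False, distance_threshold_m=threshold_m, interaction=False)

    hh = trial.households
    if "d_discordant" not in hh.columns:
        raise FitError("interaction_analysis requires d_discordant")
    far = hh["d_discordant"] > threshold_m
    for arm in (0, 1):
        for f in (False, True):
            if not ((hh["arm"] == arm) & (far == f)).any():
                raise FitError(
                    f"empty stratum: arm={arm}, {'far' if f else 'near'} at {threshold_m} m"
                )

    full = fit(trial, full_spec)
    red = fit(trial, red_spec)
    lrt = max(0.0, 2.0 * (full.loglik_marginal - red.loglik_marginal))
    p_int = float(chi2.sf(lrt, df=1))

    names = list(full.coefficients.index)
    cov = full.coef_cov
    est = full.coefficients["estimate"]

    def contrast(vec_terms):
        v = np.zeros(len(names))
        for term, wgt in vec_terms.items():
            v[names.index(term)] = wgt
        e = float(v @ est.to_numpy())
        s = float(math.sqrt(v @ cov @ v))
        zq = norm.ppf(0.975)
        return math.exp(e), math.exp(e - zq * s), math.exp(e + zq * s)

    rows = []

    def add(conditioning, stratum, group, c):
        if c is None:
            rows.append(dict(conditioning=conditioning, stratum=stratum, group=group,
                             smr=1.0, lower95=np.nan, upper95=np.nan))
        else:
            smr_, lo, hi = c
            rows.append(dict(conditioning=conditioning, stratum=stratum, group=group,
                             smr=smr_, lower95=lo, upper95=hi))

    # within distance strata: no-bednets relative to bednets
    add("distance", "near", "bed nets", None)
    add("distance", "near", "no bed nets", contrast({"intervention": -1.0}))
    add("distance", "far", "bed nets", None)
    add("distance", "far", "no bed nets",
        contrast({"intervention": -1.0, "intervention_x_far": -1.0}))
    # within arms: near relative to far
    add("arm", "bed nets", "far", None)
    add("arm", "bed nets", "near", contrast({"far": -1.0, "intervention_x_far": -1.0}))
    add("arm", "no bed nets", "far", None)
    add("arm", "no bed nets", "near", contrast({"far": -1.0}))

    return StratumSMRTable(threshold_m, pd.DataFrame(rows), p_int, lrt)


@dataclass
class BootstrapResult:
    term: str
    base_estimate: float  # log scale
    draws: np.ndarray  # log scale
    lower95: float
    upper95: float
    n_failed: int
    flagged: bool

    @property
    def smr_interval(self):
        return math.exp(self.lower95), math.exp(self.upper95)


def parametric_bootstrap(trial: TrialData, spec: ModelSpec, n_boot: int = 2_000,
                         seed: int = 0, term: str | None = None,
                         adj: AdjacencyMatrix | None = None) -> BootstrapResult:
    """Simulate counts from the fitted model (re-drawing cluster effects),
    refit, and take the percentile 95% interval of the collected estimates.

    Checks robustness of the spillover estimate to the random-effect
    distributional assumptions.  More than 5% refit failures, or a
    degenerate zero-width interval, flags the result.
    """
    if spec.random_structure != "iid":
        raise FitError("parametric bootstrap is implemented for the iid structure")
    base = fit(trial, spec, adj=adj)
    if not base.converged:
        raise FitError("base fit did not converge; bootstrap refused")
    if term is None:
        term = "distance_per_100m" if spec.distance else "intervention"

    hh = trial.households[trial.households["expected"] > 0]
    X, names = _design(hh, spec)
    beta = base.coefficients["estimate"].to_numpy()
    sigma_u = base.variance_components["sigma_cluster"]
    present = sorted(set(hh["cluster_id"]))
    cidx = pd.Categorical(hh["cluster_id"], categories=present).codes
    E = hh["expected"].to_numpy(dtype=float)
    eta_fix = X @ beta

    rng = np.random.default_rng(seed)
    draws, n_failed = [], 0
    sim = trial.copy()
    keep = trial.households["expected"] > 0
    for _ in range(n_boot):
        u = rng.normal(0.0, sigma_u, size=len(present))
        mu = E * np.exp(eta_fix + u[cidx])
        yb = rng.poisson(mu)
        sim.households.loc[keep, "observed"] = yb
        try:
            res = fit(sim, spec, adj=adj)
            draws.append(res.coefficients.loc[term, "estimate"])
        except Exception:
            n_failed += 1
    draws = np.asarray(draws)
    if len(draws) == 0:
        raise FitError("all bootstrap refits failed")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    flagged = n_failed > 0.05 * n_boot or math.isclose(lo, hi, abs_tol=1e-12)
    if flagged:
        logger.warning("bootstrap flagged: %d/%d failures, width %.3g", n_failed, n_boot, hi - lo)
    return BootstrapResult(
        term=term,
        base_estimate=float(base.coefficients.loc[term, "estimate"]),
        draws=draws,
        lower95=float(lo),
        upper95=float(hi),
        n_failed=n_failed,
        flagged=bool(flagged),
    )


def table1_specs(threshold_m: float = 400.0) -> list[ModelSpec]:
    """The seven model variants of the spatial-model comparison: IID, CAR,
    BYM, GP, and IID/BYM/GP each with the discordant distance."""
    return [
        ModelSpec(random_structure="iid"),
        ModelSpec(random_structure="car"),
        ModelSpec(random_structure="bym"),
        ModelSpec(random_structure="gp"),
        ModelSpec(random_structure="iid", distance=True),
        ModelSpec(random_structure="bym", distance=True),
        ModelSpec(random_structure="gp", distance=True),
    ]
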