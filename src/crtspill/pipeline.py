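"""End-to-end orchestration of the three-part spatial reanalysis.

Given a trial (read from files or simulated), the pipeline runs:

1. exploratory spatial analysis — join counts of the arm allocation,
   Moran's I of cluster SMRs (overall / per arm / model residuals), a GWR
   surface, and the cluster reallocation sweep;
2. spatial modeling — the seven SMR model variants (IID, CAR, BYM, GP,
   each ± discordant distance);
3. spillover and interaction — the distance-per-100 m coefficient by model,
   a parametric bootstrap of it, and the 400 m threshold interaction with
   stratum-specific SMRs.

Every stage derives its seed from the master seed by a fixed offset, so
reruns are byte-identical and adding a stage never perturbs earlier ones.
Stage failures are logged and recorded; later independent stages still run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import explore, models, realloc
from .data import (
    TrialData,
    distance_to_discordant,
    read_trial,
    summaries_frame,
    summarize,
    write_trial,
)
from .simulate import SimulationConfig, simulate_trial
from .spatial import queen_adjacency, subset_adjacency

logger = logging.getLogger(__name__)

# fixed stage-seed offsets from the master seed
STAGE_OFFSETS = {
    "simulate": 1,
    "explore": 2,
    "models": 3,
    "realloc": 4,
    "spillover": 5,
    "bootstrap": 6,
}


@dataclass
class AnalysisConfig:
    """Pipeline configuration; exactly one of (input paths, simulation)."""

    households_path: str | None = None
    clusters_path: str | None = None
    simulation: SimulationConfig | None = None
    n_sim: int = 999  # permutation draws
    gwr_bandwidth_m: float | None = None  # None -> data-driven suggestion
    gwr_kernel: str = "bisquare"
    gwr_min_neighbors: int = 10
    realloc_buffers: tuple = realloc.DEFAULT_BUFFERS
    distance_threshold_m: float = 400.0
    n_boot: int = 2_000
    gp_max_households: int = 3_000
    gp_range_m: float = 1_000.0
    min_arm_size: int = 30
    master_seed: int = 0
    output_dir: str = "crtspill_output"

    def __post_init__(self) -> None:
        has_paths = self.households_path is not None and self.clusters_path is not None
        if has_paths == (self.simulation is not None):
            raise ValueError("set exactly one of (households/clusters paths, simulation)")

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed + STAGE_OFFSETS[stage]) % (2**31)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        d["stage_seeds"] = {k: self.stage_seed(k) for k in STAGE_OFFSETS}
        d["realloc_buffers"] = list(self.realloc_buffers)
        if isinstance(d["simulation"], dict) and "study_extent" in d["simulation"]:
            d["simulation"]["study_extent"] = list(d["simulation"]["study_extent"])
        return d


def _model_spec(config: AnalysisConfig, **kw) -> models.ModelSpec:
    kw.setdefault("gp_max_households", config.gp_max_households)
    kw.setdefault("gp_range_m", config.gp_range_m)
    kw.setdefault("min_arm_size", config.min_arm_size)
    kw.setdefault("seed", config.stage_seed("models"))
    return models.ModelSpec(**kw)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run all stages, writing the report bundle into ``config.output_dir``.

    Returns a dict of the in-memory results; artifacts on disk:
    summary.csv, table1_models.csv, table2_exploratory.csv,
    table3_spillover.csv, reallocation_curve.csv, gwr_surface.csv, run.log,
    config_resolved.json (plus households.csv / clusters.geojson /
    ground_truth.json when simulating).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("crtspill")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    failures: dict[str, str] = {}
    results: dict = {}

    with open(out / "config_resolved.json", "w") as f:
        json.dump(config.to_json(), f, indent=2, default=str)

    try:
        # ------------------------------------------------------------ data
        logger.info("stage 1/3: data and exploratory spatial analysis")
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.stage_seed("simulate"))
            trial, truth = simulate_trial(sim)
            write_trial(trial, out / "households.csv", out / "clusters.geojson")
            with open(out / "ground_truth.json", "w") as f:
                json.dump(
                    {
                        "alpha": truth.alpha,
                        "beta": truth.beta,
                        "psi": truth.psi,
                        "spillover_range_m": truth.spillover_range_m,
                        "seed": truth.seed,
                    },
                    f,
                    indent=2,
                )
            results["truth"] = truth
        else:
            trial = read_trial(config.households_path, config.clusters_path)
            trial = distance_to_discordant(trial)
        results["trial"] = trial

        summ = summarize(trial)
        summaries_frame(summ).to_csv(out / "summary.csv", index=False, float_format="%.6f")
        results["summary"] = summ

        adj = queen_adjacency(trial.clusters)
        results["adjacency"] = adj

        # ---------------------------------------------- exploratory statistics
        table2_rows = []
        seed_e = config.stage_seed("explore")
        arm_labels = trial.cluster_arm()
        for color, name in ((0, "join_count_control"), (1, "join_count_intervention")):
            try:
                r = explore.join_count_test(
                    adj, arm_labels, color=color, n_sim=config.n_sim, seed=seed_e + color
                )
                table2_rows.append({"method": name, "statistic": r.observed, "p_value": r.p_value})
            except Exception as exc:
                failures[name] = str(exc)

        smr_vals = explore.cluster_smr_values(trial)
        scopes = [("morans_i_all", None)]
        scopes += [("morans_i_control", 0), ("morans_i_intervention", 1)]
        for i, (name, arm) in enumerate(scopes):
            try:
                if arm is None:
                    a, v = adj, smr_vals
                else:
                    keep = list(arm_labels[arm_labels == arm].index)
                    a, v = subset_adjacency(adj, keep), smr_vals.loc[keep]
                r = explore.morans_i_test(a, v, n_sim=config.n_sim, seed=seed_e + 10 + i)
                table2_rows.append({"method": name, "statistic": r.observed, "p_value": r.p_value})
            except Exception as exc:
                failures[name] = str(exc)

        iid_fit = None
        try:
            iid_fit = models.fit(trial, _model_spec(config, random_structure="iid"))
            r = explore.residual_morans(trial, iid_fit, adj, n_sim=config.n_sim, seed=seed_e + 20)
            table2_rows.append(
                {"method": "morans_i_residuals", "statistic": r.observed, "p_value": r.p_value}
            )
        except Exception as exc:
            failures["morans_i_residuals"] = str(exc)

        try:
            bw = config.gwr_bandwidth_m or explore.suggest_bandwidth(
                trial, min_neighbors=config.gwr_min_neighbors
            )
            surface = explore.gwr_poisson(
                trial, bw, kernel=config.gwr_kernel, min_neighbors=config.gwr_min_neighbors
            )
            surface.table.to_csv(out / "gwr_surface.csv", index=False, float_format="%.6f")
            gs = surface.summary()
            table2_rows.append(
                {"method": "gwr_median_smr", "statistic": gs["median"], "p_value": np.nan}
            )
            results["gwr"] = surface
        except Exception as exc:
            failures["gwr"] = str(exc)

        try:
            curve = realloc.reallocation_sweep(
                trial,
                _model_spec(config, random_structure="iid"),
                buffers=config.realloc_buffers,
            )
            curve.table.to_csv(out / "reallocation_curve.csv", index=False, float_format="%.6f")
            cs = realloc.curve_summary(curve)
            for arm_name in ("control_larger", "intervention_larger"):
                table2_rows.append(
                    {
                        "method": f"reallocation_{arm_name}_mean_smr",
                        "statistic": cs[arm_name]["mean"],
                        "p_value": np.nan,
                    }
                )
            results["reallocation"] = curve
            results["reallocation_summary"] = cs
        except Exception as exc:
            failures["reallocation"] = str(exc)

        pd.DataFrame(table2_rows).to_csv(
            out / "table2_exploratory.csv", index=False, float_format="%.6f"
        )
        results["table2"] = pd.DataFrame(table2_rows)

        # ----------------------------------------------------- model comparison
        logger.info("stage 2/3: spatial SMR models")
        t1_rows = []
        fits = {}
        for spec in models.table1_specs():
            spec = dataclasses.replace(
                spec,
                gp_max_households=config.gp_max_households,
                gp_range_m=config.gp_range_m,
                min_arm_size=config.min_arm_size,
                seed=config.stage_seed("models"),
            )
            try:
                res = models.fit(trial, spec, adj=adj)
                fits[spec.label()] = res
                t1_rows.append(res.table_row())
            except Exception as exc:
                failures[f"model_{spec.label()}"] = str(exc)
        pd.DataFrame(t1_rows).to_csv(out / "table1_models.csv", index=False, float_format="%.6f")
        results["table1"] = pd.DataFrame(t1_rows)
        results["fits"] = fits

        # ------------------------------------------- spillover and interaction
        logger.info("stage 3/3: spillover and interaction")
        t3_rows = []
        for structure in ("iid", "bym", "gp"):
            key = f"{structure}+distance"
            if key in fits and "distance_per_100m" in fits[key].smr_table.index:
                t = fits[key].smr_table.loc["distance_per_100m"]
                t3_rows.append(
                    {
                        "variable": "distance_per_100m",
                        "model": structure,
                        "smr": t["estimate"],
                        "lower95": t["lower95"],
                        "upper95": t["upper95"],
                    }
                )
        try:
            boot = models.parametric_bootstrap(
                trial,
                _model_spec(config, random_structure="iid", distance=True),
                n_boot=config.n_boot,
                seed=config.stage_seed("bootstrap"),
            )
            lo, hi = boot.smr_interval
            t3_rows.append(
                {
                    "variable": "distance_per_100m",
                    "model": "bootstrap",
                    "smr": float(np.exp(np.mean(boot.draws))),
                    "lower95": lo,
                    "upper95": hi,
                }
            )
            results["bootstrap"] = boot
        except Exception as exc:
            failures["bootstrap"] = str(exc)
        try:
            strata = models.interaction_analysis(
                trial,
                threshold_m=config.distance_threshold_m,
                spec=_model_spec(config, random_structure="iid"),
            )
            for _, r in strata.rows.iterrows():
                t3_rows.append(
                    {
                        "variable": f"stratum[{r['conditioning']}:{r['stratum']}:{r['group']}]",
                        "model": "iid_interaction",
                        "smr": r["smr"],
                        "lower95": r["lower95"],
                        "upper95": r["upper95"],
                    }
                )
            t3_rows.append(
                {
                    "variable": "interaction_p",
                    "model": "iid_interaction",
                    "smr": strata.interaction_p,
                    "lower95": np.nan,
                    "upper95": np.nan,
                }
            )
            results["interaction"] = strata
        except Exception as exc:
            failures["interaction"] = str(exc)
        pd.DataFrame(t3_rows).to_csv(out / "table3_spillover.csv", index=False, float_format="%.6f")
        results["table3"] = pd.DataFrame(t3_rows)

        if failures:
            logger.warning("stage failures: %s", failures)
        results["failures"] = failures
        logger.info("pipeline complete; %d stage failure(s)", len(failures))
        return results
    finally:
        root.removeHandler(handler)
        handler.close()


def load_config(path, **overrides) -> AnalysisConfig:
    """Load a flat-key JSON config file; keyword overrides win."""
    with open(path) as f:
        raw = json.load(f)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    sim = raw.pop("simulation", None)
    if sim is not None:
        if "study_extent" in sim:
            sim["study_extent"] = tuple(sim["study_extent"])
        sim = SimulationConfig(**sim)
    raw.pop("stage_seeds", None)
    if "realloc_buffers" in raw:
        raw["realloc_buffers"] = tuple(raw["realloc_buffers"])
    return AnalysisConfig(simulation=sim, **raw)
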