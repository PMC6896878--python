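"""Trial data model: households, cluster polygons, SMRs and discordant distances.

The unit of observation is the household (compound): a point location in
planar meter coordinates with an observed death count and an expected death
count derived from baseline demography.  Clusters are simple polygons, the
unit of randomization; ``arm`` is 1 for intervention (bed nets) and 0 for
control.  The standardized mortality ratio (SMR) is observed / expected
deaths, and the "discordant distance" of a household is the Euclidean
distance to the nearest household of the opposite arm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

HOUSEHOLD_COLUMNS = ["household_id", "x", "y", "cluster_id", "arm", "observed", "expected"]

#: households farther than this from their cluster polygon trigger a warning
SNAP_TOLERANCE_M = 1.0


class TrialValidationError(ValueError):
    """A household or cluster record violates a data invariant."""


@dataclass
class TrialData:
    """A cluster randomized trial: household table plus cluster polygons.

    ``households`` columns: household_id, x, y, cluster_id, arm, observed,
    expected, and optionally d_discordant once computed.  ``clusters``
    columns: cluster_id, arm, geometry (shapely), centroid_x, centroid_y.
    """

    households: pd.DataFrame
    clusters: pd.DataFrame
    crs_note: str = "planar meters (any consistent projected system)"

    def __post_init__(self) -> None:
        self.households = self.households.reset_index(drop=True)
        self.clusters = self.clusters.reset_index(drop=True)
        if "centroid_x" not in self.clusters.columns and "geometry" in self.clusters.columns:
            cents = [g.centroid for g in self.clusters["geometry"]]
            self.clusters["centroid_x"] = [c.x for c in cents]
            self.clusters["centroid_y"] = [c.y for c in cents]

    def copy(self) -> "TrialData":
        return TrialData(self.households.copy(), self.clusters.copy(), self.crs_note)

    @property
    def n_households(self) -> int:
        return len(self.households)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_arm(self) -> pd.Series:
        return self.clusters.set_index("cluster_id")["arm"]

    def validate(self, snap_tol: float = SNAP_TOLERANCE_M) -> None:
        validate_trial(self, snap_tol=snap_tol)


@dataclass
class SMRSummary:
    scope: str  # overall | arm | cluster
    label: str
    observed_total: int
    expected_total: float
    smr: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.smr is None and self.expected_total > 0:
            self.smr = smr(self.observed_total, self.expected_total)


def smr(observed_total: float, expected_total: float) -> float:
    """Standardized mortality ratio: observed deaths over expected deaths."""
    if expected_total <= 0:
        raise TrialValidationError(
            f"SMR undefined: expected_total={expected_total!r} must be positive"
        )
    return observed_total / expected_total


def validate_trial(trial: TrialData, snap_tol: float = SNAP_TOLERANCE_M) -> None:
    """Check all data invariants; raise TrialValidationError naming offenders.

    Households outside their cluster polygon by more than ``snap_tol``
    meters are warned about, not rejected: real trial geographies have gaps.
    """
    hh, cl = trial.households, trial.clusters

    missing = [c for c in HOUSEHOLD_COLUMNS if c not in hh.columns]
    if missing:
        raise TrialValidationError(f"household table missing columns: {missing}")
    for col in ("cluster_id", "arm"):
        if col not in cl.columns:
            raise TrialValidationError(f"cluster table missing column: {col}")

    dup = hh["household_id"][hh["household_id"].duplicated()]
    if len(dup):
        raise TrialValidationError(f"duplicate household_id: {sorted(set(dup))[:5]}")
    dup = cl["cluster_id"][cl["cluster_id"].duplicated()]
    if len(dup):
        raise TrialValidationError(f"duplicate cluster_id: {sorted(set(dup))[:5]}")

    if not set(hh["arm"]).issubset({0, 1}) or not set(cl["arm"]).issubset({0, 1}):
        raise TrialValidationError("arm must be binary 0/1")
    if len(set(cl["arm"])) < 2:
        raise TrialValidationError("both arms must be represented among clusters")

    unknown = set(hh["cluster_id"]) - set(cl["cluster_id"])
    if unknown:
        raise TrialValidationError(f"households reference unknown cluster_id: {sorted(unknown)[:5]}")

    obs = hh["observed"].to_numpy()
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        bad = hh.loc[(obs < 0) | ~np.isclose(obs, np.round(obs)), "household_id"]
        raise TrialValidationError(f"observed must be nonnegative integers; offenders: {list(bad[:5])}")
    exp = hh["expected"].to_numpy(dtype=float)
    if (exp < 0).any():
        bad = hh.loc[exp < 0, "household_id"]
        raise TrialValidationError(f"expected must be nonnegative; offenders: {list(bad[:5])}")
    bad = hh.loc[(exp == 0) & (obs > 0), "household_id"]
    if len(bad):
        raise TrialValidationError(
            f"expected=0 with observed>0 is inconsistent; offenders: {list(bad[:5])}"
        )

    arm_of = cl.set_index("cluster_id")["arm"]
    mism = hh.loc[hh["arm"].to_numpy() != arm_of.loc[hh["cluster_id"]].to_numpy(), "household_id"]
    if len(mism):
        raise TrialValidationError(
            f"household arm differs from its cluster's arm; offenders: {list(mism[:5])}"
        )

    if "geometry" in cl.columns:
        geoms = cl.set_index("cluster_id")["geometry"]
        for g, cid in zip(geoms, geoms.index):
            if g is None or not g.is_valid or g.area <= 0:
                raise TrialValidationError(f"cluster {cid!r}: invalid or zero-area polygon")
        import shapely

        n_out = 0
        for cid, grp in hh.groupby("cluster_id"):
            pts = shapely.points(grp[["x", "y"]].to_numpy(dtype=float))
            n_out += int((shapely.distance(geoms.loc[cid], pts) > snap_tol).sum())
        if n_out:
            logger.warning(
                "%d household(s) lie more than %.3g m outside their cluster polygon", n_out, snap_tol
            )


def read_trial(households_path, clusters_path) -> TrialData:
    """Read and validate a trial from a households CSV and a clusters GeoJSON.

    CSV header must be ``household_id,x,y,cluster_id,arm,observed,expected``;
    the GeoJSON is a FeatureCollection of (Multi)Polygons with properties
    ``cluster_id`` and ``arm``.
    """
    hh = pd.read_csv(households_path, dtype={"household_id": str, "cluster_id": str})
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in hh.columns]
    if missing:
        raise TrialValidationError(f"{households_path}: missing columns {missing}")

    with open(clusters_path) as f:
        gj = json.load(f)
    if gj.get("type") != "FeatureCollection":
        raise TrialValidationError(f"{clusters_path}: expected a GeoJSON FeatureCollection")
    rows = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        if "cluster_id" not in props or "arm" not in props:
            raise TrialValidationError(
                f"{clusters_path}: feature missing required properties cluster_id/arm"
            )
        rows.append(
            {
                "cluster_id": str(props["cluster_id"]),
                "arm": int(props["arm"]),
                "geometry": shape(feat["geometry"]),
            }
        )
    cl = pd.DataFrame(rows)
    trial = TrialData(hh, cl)
    validate_trial(trial)
    return trial


def write_trial(trial: TrialData, households_path, clusters_path) -> None:
    """Write households CSV + clusters GeoJSON (lossless round-trip partner of read_trial)."""
    cols = list(HOUSEHOLD_COLUMNS)
    if "d_discordant" in trial.households.columns:
        cols.append("d_discordant")
    trial.households[cols].to_csv(households_path, index=False, float_format="%.6f")
    feats = []
    for _, row in trial.clusters.iterrows():
        feats.append(
            {
                "type": "Feature",
                "properties": {"cluster_id": row["cluster_id"], "arm": int(row["arm"])},
                "geometry": mapping(row["geometry"]),
            }
        )
    with open(clusters_path, "w") as f:
        json.dump({"type": "FeatureCollection", "features": feats}, f)


def distance_to_discordant(trial: TrialData) -> TrialData:
    """Fill ``d_discordant``: distance from each household to the nearest
    opposite-arm household (KD-tree per arm; exact Euclidean)."""
    hh = trial.households
    arms = hh["arm"].to_numpy()
    if not (arms == 1).any() or not (arms == 0).any():
        raise TrialValidationError("both arms must be non-empty to compute discordant distances")
    xy = hh[["x", "y"]].to_numpy(dtype=float)
    d = np.empty(len(hh), dtype=float)
    for arm in (0, 1):
        tree = cKDTree(xy[arms == (1 - arm)])
        d[arms == arm], _ = tree.query(xy[arms == arm], k=1)
    out = trial.copy()
    out.households["d_discordant"] = d
    return out


def summarize(trial: TrialData) -> dict:
    """SMR summaries for overall / each arm / each cluster, plus discordant
    distance medians and IQRs (overall and among control households).

    A scope whose expected total is zero is reported with ``smr=None``
    rather than dropped.
    """
    hh = trial.households

    def _summary(scope: str, label: str, sub: pd.DataFrame) -> SMRSummary:
        o = int(sub["observed"].sum())
        e = float(sub["expected"].sum())
        return SMRSummary(scope, label, o, e, smr=(o / e if e > 0 else None))

    summaries = [_summary("overall", "all", hh)]
    for arm, name in ((0, "control"), (1, "intervention")):
        summaries.append(_summary("arm", name, hh[hh["arm"] == arm]))
    for cid, grp in hh.groupby("cluster_id", sort=True):
        summaries.append(_summary("cluster", str(cid), grp))

    out = {"smr": summaries}
    if "d_discordant" in hh.columns:
        d = hh["d_discordant"].to_numpy(dtype=float)
        dc = hh.loc[hh["arm"] == 0, "d_discordant"].to_numpy(dtype=float)
        out["d_discordant"] = {
            "overall": {
                "median": float(np.median(d)),
                "iqr": [float(np.percentile(d, 25)), float(np.percentile(d, 75))],
            },
            "control": {
                "median": float(np.median(dc)),
                "iqr": [float(np.percentile(dc, 25)), float(np.percentile(dc, 75))],
            },
        }
    return out


def summaries_frame(summaries: dict) -> pd.DataFrame:
    """Tidy CSV-ready frame (scope,label,observed,expected,smr) from summarize()."""
    return pd.DataFrame(
        [
            {
                "scope": s.scope,
                "label": s.label,
                "observed": s.observed_total,
                "expected": s.expected_total,
                "smr": s.smr,
            }
            for s in summaries["smr"]
        ]
    )
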