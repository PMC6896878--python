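"""Cluster adjacency and boundary-dilation geometry.

Queen's-case contiguity: two cluster polygons are neighbors if they share at
least one boundary point (edge or single vertex), evaluated within a snap
tolerance to absorb floating-point vertex mismatch.  Dilation buffers the
union of one arm's polygons outward and captures opposite-arm households
that fall inside — the geometric primitive behind the cluster reallocation
diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .data import TrialData

logger = logging.getLogger(__name__)

#: exact synthetic geometries coincide to machine precision
DEFAULT_SNAP_TOL_M = 1e-6


class GeometryError(ValueError):
    pass


@dataclass
class AdjacencyMatrix:
    """Binary symmetric Queen's-case contiguity among clusters."""

    cluster_ids: list
    W: np.ndarray  # (k, k) {0,1}, zero diagonal

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        k = len(self.cluster_ids)
        assert self.W.shape == (k, k)

    @property
    def n_joins(self) -> int:
        """Number of unordered adjacent pairs (graph edges)."""
        return int(self.W.sum()) // 2

    def index_of(self, cluster_id) -> int:
        return self.cluster_ids.index(cluster_id)

    def to_edge_list(self) -> pd.DataFrame:
        ii, jj = np.nonzero(np.triu(self.W, k=1))
        return pd.DataFrame(
            {
                "cluster_a": [self.cluster_ids[i] for i in ii],
                "cluster_b": [self.cluster_ids[j] for j in jj],
            }
        )


@dataclass
class DilatedAssignment:
    """Household arm labels after buffering one arm's cluster union."""

    buffer_m: float
    dilated_arm: int
    reassigned_ids: set
    arm_labels: pd.Series  # index household_id, values 0/1
    pseudo_cluster: pd.Series  # cluster_id after reallocation, index household_id
    degenerate: bool = False


def queen_adjacency(clusters: pd.DataFrame, snap_tol: float = DEFAULT_SNAP_TOL_M) -> AdjacencyMatrix:
    """Queen's-case contiguity: W[i,j]=1 iff polygons i,j come within snap_tol.

    A shared vertex counts (corner touch).  Isolated clusters are permitted
    but logged, since they cannot share information in CAR-type models.
    """
    ids = list(clusters["cluster_id"])
    geoms = list(clusters["geometry"])
    if len(ids) < 2:
        raise GeometryError("need at least 2 clusters for adjacency")
    for cid, g in zip(ids, geoms):
        if g is None or not g.is_valid or g.area <= 0:
            raise GeometryError(f"cluster {cid!r}: invalid polygon")
    k = len(ids)
    W = np.zeros((k, k), dtype=int)
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        # dwithin = distance <= snap_tol: shared point within tolerance
        for j in tree.query(g, predicate="dwithin", distance=snap_tol):
            if j != i:
                W[i, j] = W[j, i] = 1
    iso = [ids[i] for i in range(k) if W[i].sum() == 0]
    if iso:
        logger.warning("isolated clusters (no Queen neighbors): %s", iso)
    return AdjacencyMatrix(ids, W)


def subset_adjacency(adj: AdjacencyMatrix, keep) -> AdjacencyMatrix:
    """Induced subgraph on ``keep`` (no re-contiguity through removed clusters)."""
    keep = list(keep)
    unknown = set(keep) - set(adj.cluster_ids)
    if unknown:
        raise GeometryError(f"unknown cluster ids: {sorted(unknown)}")
    if not keep:
        raise GeometryError("keep must be non-empty")
    idx = [adj.cluster_ids.index(c) for c in keep]
    return AdjacencyMatrix(keep, adj.W[np.ix_(idx, idx)])


def dilate_and_reassign(trial: TrialData, dilated_arm: int, buffer_m: float) -> DilatedAssignment:
    """Buffer the dilated arm's polygon union outward by ``buffer_m`` and move
    every opposite-arm household inside the buffered union into that arm.

    Households of the dilated arm never change.  Reassigned households get a
    pseudo-cluster id ``realloc_<arm>_<nearest original dilated-arm cluster>``
    so cluster random effects stay definable after reallocation.  If the
    opposite arm is emptied the assignment is flagged degenerate; model fits
    must refuse it.
    """
    if buffer_m < 0:
        raise GeometryError("buffer_m must be nonnegative")
    hh = trial.households
    cl = trial.clusters
    arm_geoms = cl.loc[cl["arm"] == dilated_arm, "geometry"]
    union = unary_union(list(arm_geoms))

    labels = pd.Series(hh["arm"].to_numpy(copy=True), index=hh["household_id"], name="arm")
    pseudo = pd.Series(
        hh["cluster_id"].to_numpy(copy=True), index=hh["household_id"], name="cluster_id"
    )

    opp = hh["arm"].to_numpy() != dilated_arm
    reassigned: set = set()
    if buffer_m > 0 and opp.any():
        pts = shapely.points(hh.loc[opp, ["x", "y"]].to_numpy(dtype=float))
        # membership in the buffered union == point-to-union distance <= buffer
        inside = shapely.distance(union, pts) <= buffer_m
        moved = hh.loc[opp].loc[inside]
        if len(moved):
            reassigned = set(moved["household_id"])
            labels.loc[moved["household_id"]] = dilated_arm
            donors = cl[cl["arm"] == dilated_arm]
            cent = donors[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
            from scipy.spatial import cKDTree

            _, nearest = cKDTree(cent).query(moved[["x", "y"]].to_numpy(dtype=float), k=1)
            donor_ids = donors["cluster_id"].to_numpy()
            pseudo.loc[moved["household_id"]] = [
                f"realloc_{dilated_arm}_{donor_ids[i]}" for i in nearest
            ]
    degenerate = (labels == (1 - dilated_arm)).sum() == 0
    return DilatedAssignment(
        buffer_m=float(buffer_m),
        dilated_arm=int(dilated_arm),
        reassigned_ids=reassigned,
        arm_labels=labels,
        pseudo_cluster=pseudo,
        degenerate=bool(degenerate),
    )


def apply_assignment(trial: TrialData, assign: DilatedAssignment) -> TrialData:
    """Return a trial with arms and cluster ids replaced by the reallocation.

    Pseudo-clusters inherit the dilated arm; original clusters keep their
    polygons.  The cluster table gains rows (without geometry) for each
    pseudo-cluster so validation of membership still passes downstream fits.
    """
    out = trial.copy()
    hh = out.households
    hh["arm"] = assign.arm_labels.loc[hh["household_id"]].to_numpy()
    hh["cluster_id"] = assign.pseudo_cluster.loc[hh["household_id"]].to_numpy()
    new_ids = sorted(set(hh["cluster_id"]) - set(out.clusters["cluster_id"]))
    if new_ids:
        extra = pd.DataFrame(
            {
                "cluster_id": new_ids,
                "arm": assign.dilated_arm,
                "geometry": [None] * len(new_ids),
                "centroid_x": np.nan,
                "centroid_y": np.nan,
            }
        )
        out.clusters = pd.concat([out.clusters, extra], ignore_index=True)
    return out


def assignment_frame(trial: TrialData, assign: DilatedAssignment) -> pd.DataFrame:
    """CSV-ready record: household_id, original_arm, assigned_arm, buffer_m."""
    hh = trial.households
    return pd.DataFrame(
        {
            "household_id": hh["household_id"],
            "original_arm": hh["arm"],
            "assigned_arm": assign.arm_labels.loc[hh["household_id"]].to_numpy(),
            "buffer_m": assign.buffer_m,
        }
    )
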