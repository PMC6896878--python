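import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from crtspill import SimulationConfig, TrialData, generate_geography, simulate_trial
from crtspill.spatial import AdjacencyMatrix


def grid_adjacency(nrow: int, ncol: int, queen: bool = False) -> AdjacencyMatrix:
    """Adjacency of an nrow x ncol grid of unit squares (rook by default)."""
    ids = [f"g{r}_{c}" for r in range(nrow) for c in range(ncol)]
    k = nrow * ncol
    W = np.zeros((k, k), dtype=int)
    for r in range(nrow):
        for c in range(ncol):
            i = r * ncol + c
            steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
            if queen:
                steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol:
                    j = rr * ncol + cc
                    W[i, j] = W[j, i] = 1
    return AdjacencyMatrix(ids, W)


def grid_polygons(nrow: int, ncol: int, size: float = 1.0):
    return [
        (f"g{r}_{c}", box(c * size, r * size, (c + 1) * size, (r + 1) * size))
        for r in range(nrow)
        for c in range(ncol)
    ]


def toy_trial(households: list[tuple], clusters: list[tuple]) -> TrialData:
    """Build a TrialData from explicit tuples.

    households: (household_id, x, y, cluster_id, arm, observed, expected)
    clusters: (cluster_id, arm, polygon)
    """
    hh = pd.DataFrame(
        households,
        columns=["household_id", "x", "y", "cluster_id", "arm", "observed", "expected"],
    )
    cl = pd.DataFrame(clusters, columns=["cluster_id", "arm", "geometry"])
    return TrialData(hh, cl)


@pytest.fixture(scope="session")
def voronoi_geography() -> TrialData:
    """96-cluster Voronoi tessellation with household locations (no outcomes)."""
    cfg = SimulationConfig(n_clusters=96, households_per_cluster_mean=6, seed=2024)
    return generate_geography(cfg)


@pytest.fixture(scope="session")
def small_trial():
    """A complete scaled synthetic trial (12 clusters, ~600 households)."""
    cfg = SimulationConfig.scaled(12, 50, seed=7)
    trial, truth = simulate_trial(cfg)
    return trial, truth, cfg
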