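"""F/G spatial statistics over cell positions and the Spatial Distribution
Index (SDI) against constrained randomisations.

The G-function is the cdf of nearest same-type-neighbour distances and
responds to clustering; the F-function is the cdf of distances from every
cell position to the nearest target-type cell and responds to voids.  Both
run either in calibrated Euclidean micrometres or in *cell distance* (hop
count on the contact graph).  The null model never invents positions: it
reassigns the target type over the existing cells only (type shuffling), as
appropriate for a packed tissue where cells cannot sit anywhere.

SDI is the mid-rank of the observed deviation statistic
``T = max |cdf_obs - cdf_mean|`` within the deviations of a separate set of
randomised organisations; values outside [0.05, 0.95] flag a non-random
pattern at the 95% level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .network import LABELED_TYPES, cell_distances

log = logging.getLogger(__name__)

__all__ = [
    "SpatialStatsResult",
    "g_distances",
    "f_distances",
    "sdi",
    "shuffled_distance_sampler",
    "find_clusters",
    "collapse_clusters",
]


@dataclass
class SpatialStatsResult:
    grid: np.ndarray
    cdf_obs: np.ndarray
    cdf_mean: np.ndarray
    t_obs: float
    t_env: np.ndarray
    sdi: float
    non_random: bool
    n_infinite_dropped: int = 0

    def summary(self) -> dict:
        return {
            "T_obs": float(self.t_obs),
            "SDI": float(self.sdi),
            "non_random": bool(self.non_random),
            "n_env": int(len(self.t_env)),
        }


def _positions(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x_um", "y_um", "z_um"]].to_numpy(float)


def _typed_ids(cells: pd.DataFrame, cell_type: str) -> np.ndarray:
    return cells.loc[cells["type"] == cell_type, "cell_id"].to_numpy()


def g_distances(
    cells: pd.DataFrame,
    g: nx.Graph | None,
    cell_type: str,
    mode: str = "euclidean_um",
) -> np.ndarray:
    """Distance from each cell of ``cell_type`` to its nearest other cell of
    the same type (µm, or hops in ``cell_graph`` mode)."""
    ids = _typed_ids(cells, cell_type)
    if len(ids) < 2:
        raise ValueError(f"need >= 2 cells of type {cell_type!r}")
    if mode == "euclidean_um":
        pos = _positions(cells.set_index("cell_id").loc[ids].reset_index())
        tree = cKDTree(pos)
        d, _ = tree.query(pos, k=2)
        return d[:, 1]
    if mode == "cell_graph":
        out = []
        id_set = set(int(i) for i in ids)
        for i in ids:
            dist = cell_distances(g, {int(i)})
            best = min(
                (dist[j] for j in id_set if j != int(i)), default=math.inf
            )
            out.append(best)
        return np.asarray(out, float)
    raise ValueError(f"unknown mode {mode!r}")


def f_distances(
    cells: pd.DataFrame,
    g: nx.Graph | None,
    cell_type: str,
    mode: str = "euclidean_um",
) -> np.ndarray:
    """Distance from every cell (reference points = all cell positions) to
    the nearest cell of ``cell_type``; zero when the reference itself is of
    the target type."""
    ids = _typed_ids(cells, cell_type)
    if len(ids) == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    if mode == "euclidean_um":
        tpos = _positions(cells.set_index("cell_id").loc[ids].reset_index())
        tree = cKDTree(tpos)
        d, _ = tree.query(_positions(cells), k=1)
        return d
    if mode == "cell_graph":
        dist = cell_distances(g, {int(i) for i in ids})
        return np.asarray([dist[int(i)] for i in cells.cell_id], float)
    raise ValueError(f"unknown mode {mode!r}")


def _ecdf_on(grid: np.ndarray, sample: np.ndarray) -> np.ndarray:
    s = np.sort(sample)
    return np.searchsorted(s, grid, side="right") / len(s)


def _finite(sample: np.ndarray) -> tuple[np.ndarray, int]:
    arr = np.asarray(sample, float)
    fin = arr[np.isfinite(arr)]
    return fin, int(len(arr) - len(fin))


def sdi(
    observed: np.ndarray,
    sampler: Callable[[np.random.Generator], np.ndarray],
    n_avg: int = 100,
    n_env: int = 100,
    rng: np.random.Generator | int = 0,
) -> SpatialStatsResult:
    """Spatial Distribution Index of an observed distance sample.

    ``sampler(rng)`` must yield the distance sample of one randomised
    organisation.  The mean cdf is taken over ``n_avg`` randomisations and
    the deviation statistics over a *different* set of ``n_env``
    randomisations (disjoint seed streams).  SDI is the mid-rank of
    ``T_obs = max |cdf_obs - cdf_mean|`` among the envelope deviations; the
    degenerate case where observed and all envelope cdfs coincide exactly
    yields 0.  Infinite distances (unreachable cells in graph mode) are
    dropped with a logged count.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    obs, n_inf = _finite(observed)
    if n_inf:
        log.info("SDI: dropped %d infinite distances from observed sample", n_inf)
    if len(obs) == 0:
        raise ValueError("observed sample is empty after dropping infinities")
    avg_runs = [_finite(sampler(rng))[0] for _ in range(n_avg)]
    env_runs = [_finite(sampler(rng))[0] for _ in range(n_env)]
    if all(len(r) and np.array_equal(r, avg_runs[0]) for r in avg_runs + env_runs):
        if not np.array_equal(np.sort(obs), np.sort(avg_runs[0])):
            raise ValueError("randomizer is degenerate: identical tissues")
    grid = np.unique(np.concatenate([obs] + avg_runs + env_runs))
    cdf_obs = _ecdf_on(grid, obs)
    cdf_mean = np.mean([_ecdf_on(grid, r) for r in avg_runs], axis=0)
    t_obs = float(np.max(np.abs(cdf_obs - cdf_mean)))
    t_env = np.array(
        [float(np.max(np.abs(_ecdf_on(grid, r) - cdf_mean))) for r in env_runs]
    )
    # averaging identical step functions leaves ~1e-16 dust; treat it as zero
    if t_obs < 1e-12:
        t_obs = 0.0
    t_env[t_env < 1e-12] = 0.0
    if t_obs == 0 and np.all(t_env == 0):
        value = 0.0
    else:
        value = (np.sum(t_env < t_obs) + 0.5 * np.sum(t_env == t_obs)) / len(t_env)
    return SpatialStatsResult(
        grid=grid,
        cdf_obs=cdf_obs,
        cdf_mean=cdf_mean,
        t_obs=t_obs,
        t_env=t_env,
        sdi=float(value),
        non_random=not (0.05 <= value <= 0.95),
        n_infinite_dropped=n_inf,
    )


def shuffled_distance_sampler(
    cells: pd.DataFrame,
    g: nx.Graph | None,
    cell_type: str,
    function: str = "G",
    mode: str = "euclidean_um",
) -> Callable[[np.random.Generator], np.ndarray]:
    """Null-model sampler: shuffle the target type over existing cells, then
    recompute the F or G distances on the shuffled tissue."""
    from .network import shuffle_types

    fn = {"G": g_distances, "F": f_distances}[function]

    def sample(rng: np.random.Generator) -> np.ndarray:
        shuffled = shuffle_types(cells, cell_type, rng)
        if g is not None and mode == "cell_graph":
            g2 = g.copy()
            for row in shuffled.itertuples(index=False):
                g2.nodes[int(row.cell_id)]["type"] = row.type
            return fn(shuffled, g2, cell_type, mode)
        return fn(shuffled, None, cell_type, mode)

    return sample


def find_clusters(g: nx.Graph, cell_type: str) -> list[set[int]]:
    """Connected components of the subgraph induced by cells of
    ``cell_type`` (cell distance 1 = direct contact); singletons count."""
    nodes = [n for n, d in g.nodes(data=True) if d.get("type") == cell_type]
    sub = g.subgraph(nodes)
    comps = [set(c) for c in nx.connected_components(sub)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def collapse_clusters(g: nx.Graph, clusters: list[set[int]]) -> nx.Graph:
    """Quotient graph: each cluster becomes one node at the mean position of
    its members; edges to outside cells are kept (deduplicated)."""
    seen: set[int] = set()
    for c in clusters:
        if seen & c:
            raise ValueError("clusters overlap")
        seen |= c
    member_of: dict[int, int] = {}
    for idx, c in enumerate(clusters):
        for n in c:
            member_of[n] = idx
    out = nx.Graph()
    next_id = (max(g.nodes) if g.number_of_nodes() else 0) + 1
    cluster_ids = {}
    for idx, c in enumerate(clusters):
        cid = next_id + idx
        cluster_ids[idx] = cid
        pos = np.mean([g.nodes[n].get("pos", (0, 0, 0)) for n in sorted(c)], axis=0)
        ctype = g.nodes[min(c)].get("type")
        out.add_node(cid, pos=tuple(float(p) for p in pos), type=ctype, size=len(c))
    for n, d in g.nodes(data=True):
        if n not in member_of:
            out.add_node(n, **d)
    for a, b in g.edges():
        na = cluster_ids[member_of[a]] if a in member_of else a
        nb = cluster_ids[member_of[b]] if b in member_of else b
        if na != nb:
            out.add_edge(na, nb)
    return out
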