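"""Cell-contact graph construction and interaction-frequency analysis.

Two cells interact when a voxel of one cell's zone touches a voxel of the
other's under 26-connectivity (3x3x3 neighbourhood), or when both zones touch
a shared frontier voxel of the zone watershed.  The graph is undirected with
unit-weight edges; cell distance is the hop count along contact edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import networkx as nx
import numpy as np
import pandas as pd

from .core import LabelVolume

log = logging.getLogger(__name__)

__all__ = [
    "LABELED_TYPES",
    "PAIR_KEYS",
    "CompositionTable",
    "build_interaction_graph",
    "interaction_frequencies",
    "theoretical_random_frequencies",
    "cell_distances",
    "shuffle_types",
    "label_adjacency",
]

LABELED_TYPES = ("alpha", "beta", "delta")
PAIR_KEYS = tuple(
    f"{a}-{b}" for a, b in combinations_with_replacement(LABELED_TYPES, 2)
)
_OFFSETS = [
    (ox, oy, oz)
    for ox in (-1, 0, 1)
    for oy in (-1, 0, 1)
    for oz in (-1, 0, 1)
    if (ox, oy, oz) > (0, 0, 0)
]  # 13 half-space offsets; symmetry covers the other 13


@dataclass
class CompositionTable:
    """Counts and proportions of labelled cells (unlabeled excluded from the
    denominator)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {t: int(self.counts.get(t, 0)) for t in LABELED_TYPES}
        if self.total == 0:
            raise ValueError("no labelled cells")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        return {t: c / self.total for t, c in self.counts.items()}

    @property
    def percentages(self) -> dict[str, float]:
        """Display percentages rounded to 1 decimal."""
        return {t: round(100.0 * c / self.total, 1) for t, c in self.counts.items()}

    @classmethod
    def from_cells(cls, cells: pd.DataFrame) -> "CompositionTable":
        vc = cells["type"].value_counts()
        return cls({t: int(vc.get(t, 0)) for t in LABELED_TYPES})


def _shift_pairs(lab: np.ndarray) -> np.ndarray:
    """Unordered pairs (a, b), a < b, of distinct nonzero labels that touch
    under 26-connectivity, found by comparing the array with its shifts."""
    pairs = []
    for ox, oy, oz in _OFFSETS:
        a = lab[
            max(ox, 0) : lab.shape[0] + min(ox, 0),
            max(oy, 0) : lab.shape[1] + min(oy, 0),
            max(oz, 0) : lab.shape[2] + min(oz, 0),
        ]
        b = lab[
            max(-ox, 0) : lab.shape[0] + min(-ox, 0),
            max(-oy, 0) : lab.shape[1] + min(-oy, 0),
            max(-oz, 0) : lab.shape[2] + min(-oz, 0),
        ]
        m = (a > 0) & (b > 0) & (a != b)
        if m.any():
            p = np.stack([a[m], b[m]], axis=1)
            pairs.append(np.unique(np.sort(p, axis=1), axis=0))
    if not pairs:
        return np.empty((0, 2), dtype=lab.dtype)
    return np.unique(np.concatenate(pairs), axis=0)


def label_adjacency(lab: np.ndarray) -> set[tuple[int, int]]:
    """Set of touching label pairs (a < b) under 26-connectivity."""
    return {(int(a), int(b)) for a, b in _shift_pairs(lab)}


def build_interaction_graph(
    zones: LabelVolume,
    cells: pd.DataFrame,
    frontier: np.ndarray | None = None,
) -> nx.Graph:
    """Graph over cell ids with an edge for every zone contact.

    Frontier voxels (zone-watershed contact surface, owned by no zone) link
    every pair of distinct zone labels found in their 26-neighbourhood.
    """
    lab = zones.values
    present = set(int(v) for v in np.unique(lab) if v > 0)
    known = set(int(c) for c in cells.cell_id)
    missing = present - known
    if missing:
        raise ValueError(f"zone labels missing from the cell table: {sorted(missing)}")
    g = nx.Graph()
    for row in cells.itertuples(index=False):
        g.add_node(
            int(row.cell_id),
            type=row.type,
            pos=(float(row.x_um), float(row.y_um), float(row.z_um)),
        )
    g.add_edges_from((int(a), int(b)) for a, b in _shift_pairs(lab))
    if frontier is not None and frontier.any():
        nx_, ny_, nz_ = lab.shape
        for x, y, z in np.argwhere(frontier):
            neigh = lab[
                max(x - 1, 0) : x + 2, max(y - 1, 0) : y + 2, max(z - 1, 0) : z + 2
            ]
            labs = np.unique(neigh)
            labs = labs[labs > 0]
            for a, b in combinations(labs.tolist(), 2):
                g.add_edge(int(a), int(b))
    return g


def interaction_frequencies(g: nx.Graph) -> dict[str, float]:
    """Proportions of the six type pairs among edges between labelled cells.

    Edges touching an unlabeled cell are excluded from the denominator and
    reported under ``"unlabeled_edges"``.
    """
    counts = {k: 0 for k in PAIR_KEYS}
    unlabeled = 0
    for a, b in g.edges():
        ta, tb = g.nodes[a].get("type"), g.nodes[b].get("type")
        if ta in LABELED_TYPES and tb in LABELED_TYPES:
            key = f"{min(ta, tb)}-{max(ta, tb)}"
            counts[key] += 1
        else:
            unlabeled += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no edges between labelled cells")
    out = {k: v / total for k, v in counts.items()}
    out["unlabeled_edges"] = unlabeled
    return out


def theoretical_random_frequencies(comp: CompositionTable) -> dict[str, float]:
    """Contact frequencies expected from random mixing: homotypic pairs at
    P_x^2 and heterotypic pairs at 2 P_x P_y (both orderings of the pair)."""
    p = comp.proportions
    out = {}
    for a, b in combinations_with_replacement(LABELED_TYPES, 2):
        out[f"{a}-{b}"] = p[a] * p[b] if a == b else 2 * p[a] * p[b]
    return out


def cell_distances(g: nx.Graph, reference: set[int]) -> dict[int, float]:
    """Minimum hop count from each cell to the nearest reference cell.

    Reference cells are at 0; cells in no path to any reference get
    ``math.inf`` (counted and logged by downstream consumers).
    """
    reference = set(reference)
    if not reference:
        raise ValueError("reference set must be nonempty")
    unknown = reference - set(g.nodes)
    if unknown:
        raise ValueError(f"reference cells not in graph: {sorted(unknown)}")
    dist = {n: math.inf for n in g.nodes}
    frontier = list(reference)
    for n in frontier:
        dist[n] = 0
    depth = 0
    while frontier:
        depth += 1
        nxt = []
        for n in frontier:
            for m in g.adj[n]:
                if dist[m] == math.inf:
                    dist[m] = depth
                    nxt.append(m)
        frontier = nxt
    return dist


def shuffle_types(cells: pd.DataFrame, target_type: str, rng) -> pd.DataFrame:
    """Randomise the positions of one cell type by type swaps.

    For each cell of ``target_type`` (in table order) a partner cell is drawn
    uniformly over all cells; when the two types differ they are swapped
    (drawing itself or a same-type partner leaves the tissue unchanged, which
    makes a lone target cell end up on every position with equal
    probability).  Positions and the type multiset are unchanged; only the
    assignment moves.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    types = cells["type"].to_numpy().copy()
    if target_type not in types:
        raise ValueError(f"no cells of type {target_type!r}")
    n = len(types)
    targets = np.flatnonzero(types == target_type)
    for i in targets:
        j = int(rng.integers(0, n))
        if types[j] != types[i]:
            types[i], types[j] = types[j], types[i]
    out = cells.copy()
    out["type"] = types
    return out
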