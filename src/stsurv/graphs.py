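"""Area adjacency graphs and the intrinsic-CAR quadratic form.

Areal models treat two administrative areas as neighbours when they share a
boundary.  This module holds that neighbourhood relation (:class:`AreaGraph`),
file readers/writers for edge lists, two synthetic graph builders used when no
boundary file is available, and the pairwise-difference quadratic form
``Q(theta) = sum_{i~j} (theta_i - theta_j)^2`` that defines the intrinsic CAR
(ICAR) prior log-density ``-(tau/2) Q(theta)`` up to constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass(frozen=True)
class AreaGraph:
    """Symmetric adjacency structure over ``n_areas`` areas.

    Parameters
    ----------
    n_areas : int
        Number of areas, indexed ``0..n_areas-1``.
    edges : frozenset of 2-tuples
        Unordered neighbour pairs ``(i, j)`` stored with ``i < j``.
    """

    n_areas: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError(f"n_areas must be positive, got {self.n_areas}")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on area {i}")
            if not (0 <= i < self.n_areas and 0 <= j < self.n_areas):
                raise ValueError(f"edge ({i},{j}) out of range for {self.n_areas} areas")
            if i > j:
                raise ValueError(f"edge ({i},{j}) not stored in sorted order")
        if self.n_islands:
            warnings.warn(
                f"{self.n_islands} area(s) have no neighbours; each connected "
                "component gets its own sum-to-zero constraint in the ICAR prior",
                stacklevel=2,
            )

    @classmethod
    def from_edges(cls, n_areas: int, edges) -> "AreaGraph":
        """Build from any iterable of (i, j) pairs; duplicates and order collapse."""
        canon = frozenset((min(i, j), max(i, j)) for i, j in edges)
        return cls(n_areas=n_areas, edges=canon)

    @property
    def neighbor_counts(self) -> np.ndarray:
        """Per-area neighbour count ``m_i``."""
        m = np.zeros(self.n_areas, dtype=int)
        for i, j in self.edges:
            m[i] += 1
            m[j] += 1
        return m

    @property
    def n_islands(self) -> int:
        return int(np.sum(self.neighbor_counts == 0))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, i: int) -> list[int]:
        return sorted(
            {b for a, b in self.edges if a == i} | {a for a, b in self.edges if b == i}
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return g

    def components(self) -> list[np.ndarray]:
        """Connected components as sorted index arrays (islands are singletons)."""
        comps = nx.connected_components(self.to_networkx())
        return [np.array(sorted(c), dtype=int) for c in comps]

    @property
    def is_connected(self) -> bool:
        return len(self.components()) == 1

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as two parallel index arrays (deterministic sorted order)."""
        if not self.edges:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        e = np.array(sorted(self.edges), dtype=int)
        return e[:, 0], e[:, 1]

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 adjacency matrix W."""
        ii, jj = self.edge_arrays()
        data = np.ones(2 * len(ii))
        rows = np.concatenate([ii, jj])
        cols = np.concatenate([jj, ii])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_areas, self.n_areas))

    def laplacian(self) -> sp.csr_matrix:
        """Graph Laplacian D - W (the ICAR structure matrix)."""
        w = self.adjacency_matrix()
        d = sp.diags(np.asarray(w.sum(axis=1)).ravel())
        return (d - w).tocsr()

    def coloring(self) -> list[np.ndarray]:
        """Partition areas into independent sets (greedy colouring).

        Within one colour class no two areas are neighbours, so their ICAR full
        conditionals are mutually independent and can be updated in parallel.
        """
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        k = max(colors.values(), default=0) + 1
        return [
            np.array(sorted(i for i, c in colors.items() if c == col), dtype=int)
            for col in range(k)
        ]


def build_lattice_graph(n_rows: int, n_cols: int) -> AreaGraph:
    """Rook-adjacency grid graph with ``n_rows * n_cols`` areas."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"grid dimensions must be positive, got ({n_rows},{n_cols})")
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((i, i + 1))
            if r + 1 < n_rows:
                edges.append((i, i + n_cols))
    return AreaGraph.from_edges(n_rows * n_cols, edges)


def build_random_planar_graph(n_areas: int, seed: int) -> AreaGraph:
    """Irregular planar-style adjacency emulating an administrative map.

    Scatters ``n_areas`` points uniformly in the unit square and connects them
    by Delaunay triangulation, then trims the longest edges until the mean
    degree falls below 6.2 (keeping connectivity).  Typical areal maps have
    mean degree between roughly 4 and 7; raw Delaunay sits near 6.

    Deterministic given ``seed``.
    """
    if n_areas < 3:
        raise ValueError(f"need at least 3 areas, got {n_areas}")
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n_areas, 2))
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))

    # drop the longest edges (boundary slivers) while staying connected
    g = nx.Graph()
    g.add_nodes_from(range(n_areas))
    g.add_edges_from(edges)
    by_length = sorted(edges, key=lambda e: -np.hypot(*(pts[e[0]] - pts[e[1]])))
    for i, j in by_length:
        if 2 * g.number_of_edges() / n_areas <= 6.2:
            break
        g.remove_edge(i, j)
        if nx.has_path(g, i, j):
            continue
        g.add_edge(i, j)
    return AreaGraph.from_edges(n_areas, g.edges())


def read_adjacency(path, n_areas: int | None = None) -> AreaGraph:
    """Read an edge-list CSV ("area_i,area_j", one pair per line, 0-based).

    A header line is optional; duplicate and reversed pairs collapse.  If
    ``n_areas`` is omitted it is taken as ``max index + 1``.
    """
    edges = []
    max_idx = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'i,j', got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: non-integer indices in {line!r}")
            if i == j:
                raise ValueError(f"{path}:{lineno}: self-loop on area {i}")
            if i < 0 or j < 0:
                raise ValueError(f"{path}:{lineno}: negative area index")
            edges.append((i, j))
            max_idx = max(max_idx, i, j)
    n = max_idx + 1 if n_areas is None else n_areas
    if max_idx >= n:
        raise ValueError(f"area index {max_idx} >= declared n_areas {n}")
    return AreaGraph.from_edges(n, edges)


def write_adjacency(graph: AreaGraph, path, labels: dict[int, str] | None = None) -> None:
    """Write the edge list as CSV; optional sidecar label map ``<path>.labels.csv``."""
    with open(path, "w") as fh:
        fh.write("area_i,area_j\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{i},{j}\n")
    if labels is not None:
        pd.DataFrame(
            {"index": list(labels), "label": [labels[k] for k in labels]}
        ).to_csv(f"{path}.labels.csv", index=False)


def icar_quadratic_form(values, graph: AreaGraph) -> float:
    """Pairwise-difference quadratic form ``sum over edges of (v_i - v_j)^2``.

    Equals ``v' (D - W) v`` for the graph Laplacian; enters the ICAR prior as
    ``-(tau/2) * Q``.  Invariant to adding a constant to all values.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (graph.n_areas,):
        raise ValueError(f"values has shape {v.shape}, expected ({graph.n_areas},)")
    ii, jj = graph.edge_arrays()
    return float(np.sum((v[ii] - v[jj]) ** 2))
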