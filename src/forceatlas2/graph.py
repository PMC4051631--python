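"""Graph container used by the layout engine.

The layout only ever needs node identities, edge endpoints with weights,
node sizes (radii, for overlap prevention) and 2D positions, so the graph
is stored as flat numpy arrays indexed by a dense integer node index.
Degrees — and from them the node masses ``deg(n) + 1`` that weight
repulsion, gravity and the kinetic aggregates — are derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = ["Graph", "random_positions", "randomize_positions"]


@dataclass
class Graph:
    """A node/edge list with layout attributes.

    Parameters
    ----------
    ids
        Node identifiers, one per node; must be unique. The integer index
        of an id in this list is the node's index everywhere else.
    edges
        ``(E, 2)`` integer array of endpoint indices. For directed input
        the first column is the edge source (used only by the
        dissuade-hubs attraction mode).
    weights
        ``(E,)`` non-negative edge weights; default 1.
    sizes
        ``(N,)`` non-negative node radii; default 1.
    directed
        Whether the input declared edge directions. Undirected edges keep
        their stored endpoint order, and that first endpoint is treated
        as the source where a source is needed.
    positions
        Optional ``(N, 2)`` float array of current coordinates.
    """

    ids: list
    edges: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]
    sizes: np.ndarray = None  # type: ignore[assignment]
    directed: bool = False
    positions: np.ndarray | None = None
    _index: dict = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        if len(set(map(str, self.ids))) != len(self.ids):
            raise ValueError("duplicate node ids")
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n, e = len(self.ids), len(self.edges)
        if e and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge endpoint refers to a missing node")
        if self.weights is None:
            self.weights = np.ones(e)
        self.weights = np.asarray(self.weights, dtype=float).reshape(e)
        if np.any(self.weights < 0):
            raise ValueError("edge weights must be non-negative")
        if self.sizes is None:
            self.sizes = np.ones(n)
        self.sizes = np.asarray(self.sizes, dtype=float).reshape(n)
        if np.any(self.sizes < 0):
            raise ValueError("node sizes must be non-negative")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float).reshape(n, 2)
        self._index = {nid: i for i, nid in enumerate(self.ids)}

    # -- derived quantities -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        """Edge-endpoint counts; a self-loop contributes 2 so that
        ``sum(degrees) == 2 * n_edges`` (handshake identity)."""
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    @property
    def masses(self) -> np.ndarray:
        """``deg(n) + 1`` — the repulsion weight; ≥ 1 even for isolated nodes."""
        return self.degrees + 1.0

    def index_of(self, node_id: Hashable) -> int:
        return self._index[node_id]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edge_pairs(
        cls,
        pairs: Iterable[tuple],
        weights: Sequence[float] | None = None,
        directed: bool = False,
    ) -> "Graph":
        """Build a graph from ``(source, target)`` id pairs.

        Nodes appear in first-seen order; parallel edges are kept and each
        counts toward degree.
        """
        pairs = list(pairs)
        ids: list = []
        index: dict = {}
        for u, v in pairs:
            for x in (u, v):
                if x not in index:
                    index[x] = len(ids)
                    ids.append(x)
        edges = np.array([[index[u], index[v]] for u, v in pairs], dtype=np.int64)
        edges = edges.reshape(-1, 2)
        return cls(ids=ids, edges=edges, weights=weights, directed=directed)

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        """Convert a networkx graph, honouring ``weight`` and ``size``
        (or GEXF ``viz`` size) attributes."""
        ids = list(g.nodes())
        index = {nid: i for i, nid in enumerate(ids)}
        edges, weights = [], []
        for u, v, data in g.edges(data=True):
            edges.append((index[u], index[v]))
            weights.append(float(data.get("weight", 1.0)))
        sizes = np.ones(len(ids))
        positions = None
        for nid, data in g.nodes(data=True):
            i = index[nid]
            if "size" in data:
                sizes[i] = float(data["size"])
            elif isinstance(data.get("viz"), dict) and "size" in data["viz"]:
                sizes[i] = float(data["viz"]["size"])
            viz = data.get("viz")
            if isinstance(viz, dict) and "position" in viz:
                if positions is None:
                    positions = np.zeros((len(ids), 2))
                positions[i] = (viz["position"]["x"], viz["position"]["y"])
            elif "x" in data and "y" in data:
                if positions is None:
                    positions = np.zeros((len(ids), 2))
                positions[i] = (float(data["x"]), float(data["y"]))
        edges_arr = np.array(edges, dtype=np.int64).reshape(-1, 2)
        return cls(
            ids=ids,
            edges=edges_arr,
            weights=np.array(weights, dtype=float),
            sizes=sizes,
            directed=g.is_directed(),
            positions=positions,
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph() if self.directed else nx.MultiGraph()
        for i, nid in enumerate(self.ids):
            attrs = {"size": float(self.sizes[i])}
            if self.positions is not None:
                attrs["viz"] = {
                    "position": {
                        "x": float(self.positions[i, 0]),
                        "y": float(self.positions[i, 1]),
                        "z": 0.0,
                    }
                }
            g.add_node(nid, **attrs)
        for (u, v), w in zip(self.edges, self.weights):
            g.add_edge(self.ids[u], self.ids[v], weight=float(w))
        return g


def random_positions(
    n: int, extent: float, seed: int, max_redraws: int = 100
) -> np.ndarray:
    """Uniform positions in the square ``[-extent, extent]²``, seeded.

    Exact coordinate collisions are re-drawn so all positions are pairwise
    distinct (the force kernels skip coincident pairs, so duplicates would
    never separate).
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-extent, extent, size=(n, 2))
    for _ in range(max_redraws):
        _, first = np.unique(pos, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(n), first)
        if dup.size == 0:
            break
        pos[dup] = rng.uniform(-extent, extent, size=(dup.size, 2))
    return pos


def default_extent(n: int) -> float:
    """Initial placement half-width ``100·sqrt(n)``: keeps the initial node
    density independent of graph size."""
    return 100.0 * np.sqrt(max(n, 1))


def randomize_positions(graph: Graph, seed: int, extent: float | None = None) -> Graph:
    """Assign seeded uniform random positions to ``graph`` (in place) and
    return it. ``extent`` defaults to ``100·sqrt(n)``."""
    if extent is None:
        extent = default_extent(graph.n_nodes)
    graph.positions = random_positions(graph.n_nodes, extent, seed)
    return graph
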