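"""Layout quality, the benchmark protocol, and synthetic networks.

Quality is the inverse of Noack's normalized edge length: mean pairwise
distance over all node pairs divided by mean edge length. Lower
normalized edge length is better, so the inverse makes higher better —
a layout that keeps connected nodes close relative to the overall
spread scores high. The measure is invariant under translation,
rotation and uniform scaling, and equals exactly 1 on a complete graph.

The benchmark protocol samples quality at every power-of-2 step and its
successor (1, 2, 3, 4, 5, 8, 9, … 2048, 2049), averages each pair to
damp oscillations, and reports two points per run: the quick-and-dirty
point (first sampled step at 50% of the run's maximum averaged quality,
a rough spatialization) and the quasi-optimal point (90%, a satisfying
layout). Runs are repeated over several seeded randomizations of the
initial positions and the points averaged.

Synthetic generators replace the benchmark's network collection:
scale-free (preferential attachment), Erdős–Rényi random, balanced
trees, Watts–Strogatz small-world, planted clusters, and "ego-like"
networks (scale-free communities plus the ego node adjacent to
everyone, emulating social ego-networks).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .engine import LayoutSettings, LayoutState, default_settings, run
from .graph import Graph

__all__ = [
    "QualitySeries",
    "BenchmarkPoints",
    "SyntheticSpec",
    "layout_quality",
    "schedule_steps",
    "pair_average",
    "detect_points",
    "run_benchmark",
    "BenchmarkResult",
    "generate_network",
    "ego_like_network",
    "compare_speed_policies",
]

#: above this node count the all-pairs mean distance is estimated from
#: a seeded sample of pairs instead of computed exactly
EXACT_PAIRS_LIMIT = 3_000
SAMPLED_PAIRS = 100_000


@dataclass
class QualitySeries:
    """Ordered (step, quality) records from one layout run."""

    steps: list[int] = field(default_factory=list)
    qualities: list[float] = field(default_factory=list)
    randomization_seed: int | None = None
    timestamps_ms: list[float] = field(default_factory=list)

    def append(self, step_index: int, quality: float, timestamp_ms: float | None = None) -> None:
        if self.steps and step_index <= self.steps[-1]:
            raise ValueError("steps must be strictly increasing")
        if not np.isfinite(quality):
            raise ValueError("quality must be finite")
        self.steps.append(int(step_index))
        self.qualities.append(float(quality))
        self.timestamps_ms.append(
            float(timestamp_ms) if timestamp_ms is not None else float("nan")
        )


@dataclass(frozen=True)
class BenchmarkPoints:
    """Summary of one quality trajectory."""

    max_quality: float
    qnd_step: int  # quick-and-dirty: first sampled step at 50% of max
    qo_step: int  # quasi-optimal: first sampled step at 90% of max


def _mean_pairwise_distance(positions: np.ndarray, sample_seed: int = 0) -> float:
    n = len(positions)
    if n <= EXACT_PAIRS_LIMIT:
        return float(pdist(positions).mean())
    rng = np.random.default_rng(sample_seed)
    i = rng.integers(0, n, size=SAMPLED_PAIRS)
    j = rng.integers(0, n, size=SAMPLED_PAIRS)
    keep = i != j
    diff = positions[i[keep]] - positions[j[keep]]
    return float(np.hypot(diff[:, 0], diff[:, 1]).mean())


def layout_quality(
    graph: Graph, positions: np.ndarray | None = None, sample_seed: int = 0
) -> float:
    """Inverse normalized edge length (higher is better).

    ``quality = mean(all-pairs distance) / mean(edge length)``. Needs at
    least 2 nodes and 1 non-self-loop edge; undefined when all positions
    coincide. Exact for ≤ 3,000 nodes, seeded pair-sampling above.
    """
    if positions is None:
        positions = graph.positions
    if positions is None:
        raise ValueError("no positions given")
    positions = np.asarray(positions, dtype=float)
    if graph.n_nodes < 2:
        raise ValueError("quality needs at least 2 nodes")
    edges = graph.edges[graph.edges[:, 0] != graph.edges[:, 1]]
    if len(edges) == 0:
        raise ValueError("quality needs at least one (non-loop) edge")
    if np.ptp(positions[:, 0]) == 0 and np.ptp(positions[:, 1]) == 0:
        raise ValueError("quality undefined: all positions coincide")
    dvec = positions[edges[:, 0]] - positions[edges[:, 1]]
    mean_edge = float(np.hypot(dvec[:, 0], dvec[:, 1]).mean())
    if mean_edge == 0:
        raise ValueError("quality undefined: all edges have zero length")
    return _mean_pairwise_distance(positions, sample_seed) / mean_edge


def schedule_steps(max_power: int) -> list[int]:
    """Sorted union of ``{2^k}`` and ``{2^k + 1}`` for k = 0..max_power."""
    if max_power < 0:
        raise ValueError("max_power must be non-negative")
    out: set[int] = set()
    for k in range(max_power + 1):
        out.add(2**k)
        out.add(2**k + 1)
    return sorted(out)


def pair_average(series: QualitySeries) -> QualitySeries:
    """Average each power-of-2 sample with its successor-step sample.

    Returns a series indexed at the power-of-2 steps; a power-of-2 step
    whose successor was not sampled keeps its raw value.
    """
    by_step = dict(zip(series.steps, series.qualities))
    ts = dict(zip(series.steps, series.timestamps_ms))
    out = QualitySeries(randomization_seed=series.randomization_seed)
    for s in series.steps:
        if s & (s - 1) != 0 and s != 1:  # not a power of two
            continue
        q = by_step[s]
        if s + 1 in by_step:
            q = 0.5 * (q + by_step[s + 1])
        out.append(s, q, ts.get(s))
    return out


def detect_points(series: QualitySeries) -> BenchmarkPoints:
    """Max quality and the first sampled steps reaching 50% / 90% of it."""
    if not series.steps:
        raise ValueError("empty quality series")
    q = np.asarray(series.qualities)
    steps = series.steps
    qmax = float(q.max())
    qnd = steps[int(np.argmax(q >= 0.5 * qmax))]
    qo = steps[int(np.argmax(q >= 0.9 * qmax))]
    return BenchmarkPoints(max_quality=qmax, qnd_step=qnd, qo_step=qo)


@dataclass
class BenchmarkResult:
    """Per-randomization series and points, their means, and a tabular
    record mirroring the protocol's CSV output."""

    series: list[QualitySeries]
    averaged: list[QualitySeries]
    points: list[BenchmarkPoints]
    mean_max_quality: float
    mean_qnd_step: float
    mean_qo_step: float
    records: pd.DataFrame


def run_benchmark(
    graph: Graph,
    settings: LayoutSettings | None = None,
    n_randomizations: int = 3,
    seeds: Sequence[int] | None = None,
    max_power: int = 11,
    network_id: str = "network",
    extent: float = 100.0,
) -> BenchmarkResult:
    """Run the full protocol: one layout per randomization, quality
    sampled at the power-of-2 schedule, pair-averaged, points detected,
    and everything averaged over randomizations. Initial positions are
    randomized in the fixed square ``[-extent, extent]²`` (default 100),
    emulating the randomize-then-layout workflow the protocol measures."""
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    if seeds is None:
        seeds = list(range(n_randomizations))
    seeds = list(seeds)[:n_randomizations]
    if len(seeds) != n_randomizations:
        raise ValueError("need one seed per randomization")
    if settings is None:
        settings = default_settings(graph.n_nodes)
    sample_at = set(schedule_steps(max_power))
    n_steps = max(sample_at)

    all_series: list[QualitySeries] = []
    rows = []
    for seed in seeds:
        series = QualitySeries(randomization_seed=seed)
        t0 = time.perf_counter()

        def observer(iteration: int, positions: np.ndarray, _state: LayoutState) -> None:
            if iteration in sample_at:
                series.append(
                    iteration,
                    layout_quality(graph, positions),
                    (time.perf_counter() - t0) * 1e3,
                )

        run(graph, settings, n_steps=n_steps, seed=seed, callback=observer, extent=extent)
        all_series.append(series)

    averaged = [pair_average(s) for s in all_series]
    points = [detect_points(s) for s in averaged]
    for series, avg in zip(all_series, averaged):
        avg_by_step = dict(zip(avg.steps, avg.qualities))
        for s, q, t in zip(series.steps, series.qualities, series.timestamps_ms):
            rows.append(
                {
                    "network": network_id,
                    "seed": series.randomization_seed,
                    "step": s,
                    "quality_raw": q,
                    "quality_averaged": avg_by_step.get(s, np.nan),
                    "timestamp_ms": t,
                }
            )
    return BenchmarkResult(
        series=all_series,
        averaged=averaged,
        points=points,
        mean_max_quality=float(np.mean([p.max_quality for p in points])),
        mean_qnd_step=float(np.mean([p.qnd_step for p in points])),
        mean_qo_step=float(np.mean([p.qo_step for p in points])),
        records=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# synthetic networks


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic network.

    kind: ``scale_free`` (preferential attachment; ``attachment`` edges
    per new node), ``random`` (``edge_prob``), ``tree`` (``branching``
    and ``depth``; node count is ``(b^(depth+1)−1)/(b−1)``),
    ``small_world`` (``neighbors`` ring degree, ``rewiring_prob``),
    ``planted_clusters`` (``n_clusters`` of ``n_nodes // n_clusters``
    nodes, ``p_intra``, ``p_inter``).
    """

    kind: str
    n_nodes: int = 0
    attachment: int = 2
    edge_prob: float = 0.05
    branching: int = 2
    depth: int = 3
    neighbors: int = 4
    rewiring_prob: float = 0.1
    n_clusters: int = 4
    p_intra: float = 0.3
    p_inter: float = 0.01
    seed: int = 0


def generate_network(spec: SyntheticSpec) -> Graph:
    """Seeded synthetic graph of the given kind (see
    :class:`SyntheticSpec`); reproducible for equal specs."""
    import networkx as nx

    if spec.kind == "scale_free":
        if spec.n_nodes <= spec.attachment:
            raise ValueError("scale_free needs n_nodes > attachment")
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=spec.seed)
    elif spec.kind == "random":
        if not 0 <= spec.edge_prob <= 1:
            raise ValueError("edge_prob must lie in [0, 1]")
        g = nx.gnp_random_graph(spec.n_nodes, spec.edge_prob, seed=spec.seed)
    elif spec.kind == "tree":
        if spec.branching < 1 or spec.depth < 0:
            raise ValueError("tree needs branching >= 1 and depth >= 0")
        g = nx.balanced_tree(spec.branching, spec.depth)
    elif spec.kind == "small_world":
        g = nx.watts_strogatz_graph(
            spec.n_nodes, spec.neighbors, spec.rewiring_prob, seed=spec.seed
        )
    elif spec.kind == "planted_clusters":
        if not (0 <= spec.p_intra <= 1 and 0 <= spec.p_inter <= 1):
            raise ValueError("cluster probabilities must lie in [0, 1]")
        size = spec.n_nodes // spec.n_clusters
        g = nx.planted_partition_graph(
            spec.n_clusters, size, spec.p_intra, spec.p_inter, seed=spec.seed
        )
    else:
        raise ValueError(f"unknown synthetic network kind {spec.kind!r}")
    return Graph.from_networkx(nx.Graph(g))


def ego_like_network(
    n_clusters: int = 4,
    cluster_size: int = 50,
    attachment: int = 10,
    p_inter: float = 0.004,
    seed: int = 0,
) -> Graph:
    """A synthetic social ego-network: scale-free communities plus the ego.

    Each community is a preferential-attachment graph (heavy-tailed
    degrees, like real friend circles), communities are tied by sparse
    random edges, and one apex node — the ego — is adjacent to every
    other node. Defaults give ~200 nodes with mean degree ≈ 20, matching
    the size and density of typical social ego-networks.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    blocks = []
    offset = 0
    for c in range(n_clusters):
        sub = nx.barabasi_albert_graph(cluster_size, attachment, seed=seed * 100 + c)
        g.update(nx.relabel_nodes(sub, {i: i + offset for i in sub}))
        blocks.append(range(offset, offset + cluster_size))
        offset += cluster_size
    for a in range(n_clusters):
        for b in range(a + 1, n_clusters):
            for u in blocks[a]:
                for v in blocks[b]:
                    if rng.random() < p_inter:
                        g.add_edge(u, v)
    apex = offset
    g.add_edges_from((apex, v) for v in range(offset))
    return Graph.from_networkx(g)


def star_of_stars(n_hubs: int = 8, leaves_per_hub: int = 12) -> Graph:
    """A central hub connected to ``n_hubs`` sub-hubs, each carrying
    ``leaves_per_hub`` leaves — the leaf-forest structure that motivates
    repulsion by degree."""
    pairs: list[tuple[int, int]] = []
    nid = 1
    for _ in range(n_hubs):
        hub = nid
        nid += 1
        pairs.append((0, hub))
        for _ in range(leaves_per_hub):
            pairs.append((hub, nid))
            nid += 1
    return Graph.from_edge_pairs(pairs)


# ---------------------------------------------------------------------------
# speed-policy comparison


def compare_speed_policies(
    graph: Graph,
    fixed_speeds: Sequence[float],
    n_steps: int = 2049,
    seeds: Sequence[int] = (0,),
    settings: LayoutSettings | None = None,
    max_power: int | None = None,
    extent: float = 100.0,
) -> pd.DataFrame:
    """Adaptive local speed vs constant-speed variants.

    Each variant clamps every node's local speed to a fixed value (the
    engine is otherwise identical); the adaptive policy is the standard
    one. Returns a long-form table (policy, seed, step, quality,
    quality_averaged) sampled at the power-of-2 schedule.
    """
    if not fixed_speeds:
        raise ValueError("fixed_speeds must be non-empty")
    if settings is None:
        settings = default_settings(graph.n_nodes)
    if max_power is None:
        max_power = int(np.floor(np.log2(max(n_steps - 1, 1))))
    sample_at = [s for s in schedule_steps(max_power) if s <= n_steps]
    policies: list[tuple[str, LayoutSettings]] = [("adaptive", settings)]
    from dataclasses import replace

    for v in fixed_speeds:
        policies.append((f"fixed_{v:g}", replace(settings, fixed_local_speed=float(v))))

    rows = []
    for name, pol_settings in policies:
        for seed in seeds:
            series = QualitySeries(randomization_seed=seed)
            sample = set(sample_at)

            def observer(iteration, positions, _state, series=series, sample=sample):
                if iteration in sample:
                    series.append(iteration, layout_quality(graph, positions))

            run(graph, pol_settings, n_steps=n_steps, seed=seed, callback=observer, extent=extent)
            avg = pair_average(series)
            avg_by_step = dict(zip(avg.steps, avg.qualities))
            for s, q in zip(series.steps, series.qualities):
                rows.append(
                    {
                        "policy": name,
                        "seed": seed,
                        "step": s,
                        "quality": q,
                        "quality_averaged": avg_by_step.get(s, np.nan),
                    }
                )
    return pd.DataFrame(rows)
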