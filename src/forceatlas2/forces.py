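"""ForceAtlas2 force kernels and exact O(n²) accumulation.

The model: connected nodes attract linearly in distance (or as
``log(1 + d)`` in LinLog mode), every node pair repulses as
``k_r · (deg₁+1)(deg₂+1) / d``, and optional gravity pulls nodes toward
the origin with the same mass weighting. Attraction carries no constant
of its own — the single ``scaling`` constant ``k_r`` on repulsion sets
the size of the layout.

With overlap prevention on, all kernels use the border-to-border
distance ``d' = d − size₁ − size₂``: nodes at ``d' > 0`` interact
normally through ``d'``, intersecting nodes (``d' < 0``) feel no
attraction and a strong constant repulsion ``k_r' · m₁ · m₂`` with
``k_r' = 100``, and touching nodes (``d' = 0``) feel nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import LayoutSettings
    from .graph import Graph

__all__ = [
    "PairGeometry",
    "pair_geometry",
    "attraction_magnitude",
    "repulsion_magnitude",
    "gravity_force",
    "accumulate_forces_exact",
]

#: adjusted distances within this band of zero count as "touching":
#: no attraction and no repulsion (measure-zero branch of the overlap rules).
TOUCH_TOL = 1e-12


@dataclass(frozen=True)
class PairGeometry:
    """Geometry of one node pair: Euclidean distance, the (possibly
    negative) border-to-border adjusted distance, and the unit vector from
    the first node toward the second (zero vector for coincident nodes)."""

    distance: float
    adjusted_distance: float
    unit_direction: tuple[float, float]


def pair_geometry(
    pos1, pos2, size1: float = 0.0, size2: float = 0.0, prevent_overlap: bool = False
) -> PairGeometry:
    """Distance, adjusted distance and direction for one node pair."""
    if size1 < 0 or size2 < 0:
        raise ValueError("node sizes must be non-negative")
    dx = float(pos2[0]) - float(pos1[0])
    dy = float(pos2[1]) - float(pos1[1])
    d = math.hypot(dx, dy)
    adjusted = d - size1 - size2 if prevent_overlap else d
    unit = (dx / d, dy / d) if d > 0 else (0.0, 0.0)
    return PairGeometry(distance=d, adjusted_distance=adjusted, unit_direction=unit)


def attraction_magnitude(
    geom: PairGeometry,
    weight: float,
    settings: "LayoutSettings",
    source_mass: float = 1.0,
    compensation: float = 1.0,
) -> float:
    """Attraction along one edge.

    Base term is the adjusted distance (linear) or ``log(1 + d')``
    (LinLog; the +1 keeps superposed nodes finite), multiplied by
    ``w^δ`` with ``0⁰ := 1`` so ``δ = 0`` ignores weights entirely.
    In dissuade-hubs mode the term is divided by the edge source's mass
    and multiplied by ``compensation`` (the engine passes the mean node
    mass, restoring the average attraction strength). Intersecting nodes
    under overlap prevention attract not at all.
    """
    if weight < 0:
        raise ValueError("edge weight must be non-negative")
    d_eff = geom.adjusted_distance
    if settings.prevent_overlap and d_eff <= TOUCH_TOL:
        return 0.0
    base = math.log1p(d_eff) if settings.linlog else d_eff
    delta = settings.edge_weight_influence
    wf = 1.0 if delta == 0 else weight**delta
    mag = base * wf
    if settings.dissuade_hubs:
        mag = mag / source_mass * compensation
    return mag


def repulsion_magnitude(
    geom: PairGeometry, mass1: float, mass2: float, settings: "LayoutSettings"
) -> float:
    """Degree-weighted repulsion between one node pair.

    ``k_r·m₁·m₂/d'`` while separated; ``k_r'·m₁·m₂`` while intersecting
    (overlap prevention); zero at contact and for coincident nodes
    (coincident pairs are skipped — initialization guarantees distinct
    positions, so the zero-distance case cannot persist).
    """
    dp = geom.adjusted_distance
    if abs(dp) <= TOUCH_TOL:
        return 0.0
    m = mass1 * mass2
    if dp > 0:
        return settings.scaling * m / dp
    return settings.overlap_repulsion * m


def gravity_force(position, mass: float, settings: "LayoutSettings") -> np.ndarray:
    """Gravity pulling one node toward the origin.

    Regular mode: magnitude ``k_g·mass``, independent of distance (it
    compensates repulsion far from the center). Strong mode:
    ``k_g·mass·d(n)``. A node exactly at the origin feels nothing.
    """
    x, y = float(position[0]), float(position[1])
    d = math.hypot(x, y)
    if d == 0 or settings.gravity == 0:
        return np.zeros(2)
    mag = settings.gravity * mass * (d if settings.strong_gravity else 1.0)
    return np.array([-x / d * mag, -y / d * mag])


# ---------------------------------------------------------------------------
# vectorized accumulation


def _repulsion_masses(graph: "Graph", settings: "LayoutSettings") -> np.ndarray:
    if settings.repulsion_by_degree:
        return graph.masses
    return np.ones(graph.n_nodes)


def repulsion_forces_exact(
    positions: np.ndarray, masses: np.ndarray, sizes: np.ndarray, settings: "LayoutSettings"
) -> np.ndarray:
    """All-pairs repulsion, O(n²) vectorized."""
    x, y = positions[:, 0], positions[:, 1]
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    d = np.hypot(dx, dy)
    if settings.prevent_overlap:
        dp = d - sizes[:, None] - sizes[None, :]
    else:
        dp = d
    mm = masses[:, None] * masses[None, :]
    # coefficient C such that F_i += sum_j C_ij * (dx_ij, dy_ij)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(
            dp > TOUCH_TOL,
            settings.scaling * mm / (dp * np.where(d > 0, d, 1.0)),
            np.where(
                dp < -TOUCH_TOL,
                settings.overlap_repulsion * mm / np.where(d > 0, d, 1.0),
                0.0,
            ),
        )
    coef[d <= 0] = 0.0  # coincident pairs (and the diagonal) are skipped
    fx = np.einsum("ij,ij->i", coef, dx)
    fy = np.einsum("ij,ij->i", coef, dy)
    return np.column_stack([fx, fy])


def attraction_forces(
    graph: "Graph", positions: np.ndarray, settings: "LayoutSettings"
) -> np.ndarray:
    """Per-edge attraction accumulated onto both endpoints (equal
    magnitude, opposite direction; dissuade-hubs divides the shared
    magnitude by the source's mass and applies the mean-mass
    compensation). Self-loops generate no attraction."""
    forces = np.zeros_like(positions)
    if graph.n_edges == 0:
        return forces
    src, tgt = graph.edges[:, 0], graph.edges[:, 1]
    dvec = positions[tgt] - positions[src]
    d = np.hypot(dvec[:, 0], dvec[:, 1])
    if settings.prevent_overlap:
        d_eff = d - graph.sizes[src] - graph.sizes[tgt]
    else:
        d_eff = d
    if settings.linlog:
        base = np.where(d_eff > 0, np.log1p(np.maximum(d_eff, 0.0)), 0.0)
    else:
        base = d_eff
    delta = settings.edge_weight_influence
    wf = np.ones_like(d) if delta == 0 else graph.weights**delta
    mag = base * wf
    if settings.prevent_overlap:
        mag = np.where(d_eff > TOUCH_TOL, mag, 0.0)
    if settings.dissuade_hubs:
        masses = graph.masses
        mag = mag / masses[src] * masses.mean()
    active = (d > 0) & (src != tgt)
    unit = np.zeros_like(dvec)
    unit[active] = dvec[active] / d[active, None]
    contrib = mag[:, None] * unit
    np.add.at(forces, src, contrib)
    np.add.at(forces, tgt, -contrib)
    return forces


def gravity_forces(
    positions: np.ndarray, masses: np.ndarray, settings: "LayoutSettings"
) -> np.ndarray:
    if settings.gravity == 0:
        return np.zeros_like(positions)
    d = np.hypot(positions[:, 0], positions[:, 1])
    mag = settings.gravity * masses * (d if settings.strong_gravity else 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(d > 0, mag / d, 0.0)
    return -positions * scale[:, None]


def accumulate_forces_exact(
    graph: "Graph", settings: "LayoutSettings", positions: np.ndarray | None = None
) -> np.ndarray:
    """Resultant force F(n) per node: exact all-pairs repulsion plus edge
    attraction plus gravity."""
    if positions is None:
        positions = graph.positions
    if positions is None:
        raise ValueError("graph has no positions")
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite positions")
    masses = graph.masses
    rep_masses = _repulsion_masses(graph, settings)
    forces = repulsion_forces_exact(positions, rep_masses, graph.sizes, settings)
    forces += attraction_forces(graph, positions, settings)
    forces += gravity_forces(positions, masses, settings)
    return forces
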