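"""Layout settings and the continuous step loop.

ForceAtlas2 is a continuous layout: there are no phases and no
auto-stop, and every setting may change between steps. The engine
therefore exposes a step-at-a-time stateful API (:func:`step`) plus the
batch wrapper :func:`run`; :func:`run` never halts on its own.

One iteration: forces (exact or Barnes-Hut repulsion per settings) →
per-node swinging/traction → global aggregates → global speed → local
speeds → displacement, with the previous forces rotated out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import dynamics
from .barnes_hut import repulsion_forces_bh
from .forces import (
    _repulsion_masses,
    attraction_forces,
    gravity_forces,
    repulsion_forces_exact,
)
from .graph import Graph, default_extent, random_positions

__all__ = ["LayoutSettings", "LayoutState", "default_settings", "default_tolerance", "step", "run"]

logger = logging.getLogger(__name__)


def default_tolerance(n_nodes: int) -> float:
    """Size-banded jitter tolerance: 0.1 under 5,000 nodes, 1 up to
    50,000, 10 above."""
    if n_nodes < 5_000:
        return 0.1
    if n_nodes <= 50_000:
        return 1.0
    return 10.0


@dataclass
class LayoutSettings:
    """All tunable constants of the layout.

    Attributes
    ----------
    scaling
        ``k_r``, the repulsion constant; the one knob that sets the size
        of the layout (attraction has no constant of its own).
    gravity
        ``k_g``; 0 disables gravity. ``strong_gravity`` switches to the
        distance-proportional variant.
    linlog
        Logarithmic attraction (Noack's LinLog energy model); expect to
        lower ``scaling`` (the benchmark value is 0.1) when enabling it.
    edge_weight_influence
        δ: 0 ignores weights, 1 uses them proportionally, >1 emphasizes.
    dissuade_hubs
        Divide each edge's attraction by its source's mass (with mean-mass
        compensation), pushing hubs peripheral, authorities central.
    prevent_overlap
        Border-to-border distances with strong contact repulsion
        ``overlap_repulsion`` (100); apply only after convergence.
    barnes_hut, theta
        ``"on"``/``"off"``/``"auto"`` (auto: on above 1,000 nodes) and
        the opening criterion θ.
    tolerance
        τ of the global-speed rule; ``None`` selects the size-banded
        default.
    k_s, k_smax
        Local-speed constant (0.1) and the displacement cap (10).
    repulsion_by_degree
        When False, repulsion ignores masses (all set to 1) — the
        degree-ignoring reference variant, for comparison only.
    fixed_local_speed
        When set, replaces the adaptive per-node speed by this constant
        (the displacement cap still applies) — the benchmark's fixed-speed
        reference policies.
    """

    scaling: float = 2.0
    gravity: float = 0.0
    strong_gravity: bool = False
    linlog: bool = False
    edge_weight_influence: float = 1.0
    dissuade_hubs: bool = False
    prevent_overlap: bool = False
    overlap_repulsion: float = 100.0
    barnes_hut: str = "auto"
    theta: float = 1.2
    tolerance: float | None = None
    k_s: float = 0.1
    k_smax: float = 10.0
    repulsion_by_degree: bool = True
    fixed_local_speed: float | None = None

    def __post_init__(self) -> None:
        if not (self.scaling > 0 and np.isfinite(self.scaling)):
            raise ValueError("scaling must be positive and finite")
        if self.edge_weight_influence < 0:
            raise ValueError("edge_weight_influence must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.gravity < 0:
            raise ValueError("gravity must be non-negative")
        if self.barnes_hut not in ("on", "off", "auto"):
            raise ValueError("barnes_hut must be 'on', 'off' or 'auto'")
        if self.tolerance is not None and self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")

    def resolved_tolerance(self, n_nodes: int) -> float:
        return default_tolerance(n_nodes) if self.tolerance is None else self.tolerance

    def uses_barnes_hut(self, n_nodes: int) -> bool:
        if self.prevent_overlap:
            return False  # cells carry no node sizes; overlap needs exact terms
        if self.barnes_hut == "on":
            return True
        if self.barnes_hut == "off":
            return False
        return n_nodes > 1_000


def default_settings(n_nodes: int) -> LayoutSettings:
    """Defaults with the tolerance band resolved for ``n_nodes``."""
    if n_nodes < 0:
        raise ValueError("n_nodes must be non-negative")
    return LayoutSettings(tolerance=default_tolerance(n_nodes))


@dataclass
class LayoutState:
    """Engine state after ``iteration`` steps; reproducible from
    (graph, settings, seed, iteration)."""

    iteration: int
    positions: np.ndarray
    force_prev: np.ndarray
    global_speed: float = 1.0
    swinging: np.ndarray | None = None
    traction: np.ndarray | None = None
    speeds: np.ndarray | None = None
    forces: np.ndarray | None = None
    global_swinging: float = 0.0
    global_traction: float = 0.0
    rng_seed: int | None = None

    @classmethod
    def initial(cls, positions: np.ndarray, seed: int | None = None) -> "LayoutState":
        positions = np.asarray(positions, dtype=float)
        return cls(
            iteration=0,
            positions=positions,
            force_prev=np.zeros_like(positions),
            global_speed=1.0,
            rng_seed=seed,
        )


def _forces(graph: Graph, positions: np.ndarray, settings: LayoutSettings) -> np.ndarray:
    masses = graph.masses
    rep_masses = _repulsion_masses(graph, settings)
    if settings.uses_barnes_hut(graph.n_nodes):
        rep = repulsion_forces_bh(positions, rep_masses, settings.theta, settings)
    else:
        rep = repulsion_forces_exact(positions, rep_masses, graph.sizes, settings)
    return rep + attraction_forces(graph, positions, settings) + gravity_forces(
        positions, masses, settings
    )


def step(graph: Graph, state: LayoutState, settings: LayoutSettings) -> LayoutState:
    """Advance the layout by one iteration; returns the new state.

    Settings are re-read on every call, so they may change while the
    layout runs. Every displacement norm is bounded by ``k_smax``.
    """
    positions = state.positions
    if positions.shape != (graph.n_nodes, 2):
        raise ValueError("state positions do not match the graph")
    if not np.all(np.isfinite(positions)):
        raise FloatingPointError("non-finite positions entering step")

    forces = _forces(graph, positions, settings)
    swg, tra = dynamics.swinging_traction(forces, state.force_prev)
    swg_g, tra_g = dynamics.global_aggregates(swg, tra, graph.masses)
    tol = settings.resolved_tolerance(graph.n_nodes)
    speed_g = dynamics.update_global_speed(swg_g, tra_g, tol, state.global_speed)
    force_norms = np.hypot(forces[:, 0], forces[:, 1])
    if settings.fixed_local_speed is not None:
        speeds = np.full(graph.n_nodes, float(settings.fixed_local_speed))
        with np.errstate(divide="ignore"):
            cap = np.where(force_norms > 0, settings.k_smax / force_norms, np.inf)
        speeds = np.minimum(speeds, cap)
    else:
        speeds = dynamics.node_speeds(
            speed_g,
            swg,
            force_norms,
            k_s=settings.k_s,
            k_smax=settings.k_smax,
            prevent_overlap=settings.prevent_overlap,
        )
    new_positions = dynamics.displace(positions, forces, speeds)
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "step %d: S(G)=%.6g swg(G)=%.6g tra(G)=%.6g",
            state.iteration + 1,
            speed_g,
            swg_g,
            tra_g,
        )
    return LayoutState(
        iteration=state.iteration + 1,
        positions=new_positions,
        force_prev=forces,
        global_speed=speed_g,
        swinging=swg,
        traction=tra,
        speeds=speeds,
        forces=forces,
        global_swinging=swg_g,
        global_traction=tra_g,
        rng_seed=state.rng_seed,
    )


def run(
    graph: Graph,
    settings: LayoutSettings | None = None,
    n_steps: int = 100,
    seed: int = 0,
    callback: Callable[[int, np.ndarray, LayoutState], None] | None = None,
    state: LayoutState | None = None,
    extent: float | None = None,
) -> LayoutState:
    """Initialize (seeded uniform positions) and run ``n_steps`` steps.

    ``callback(iteration, positions, state)`` is invoked after every
    step. Pass an existing ``state`` to continue a layout instead of
    re-initializing (e.g. to enable overlap prevention after
    convergence). Identical (graph, settings, seed, n_steps) give
    identical output, bit for bit.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if settings is None:
        settings = default_settings(graph.n_nodes)
    if state is None:
        if extent is None:
            extent = default_extent(graph.n_nodes)
        positions = random_positions(graph.n_nodes, extent, seed)
        state = LayoutState.initial(positions, seed=seed)
    for _ in range(n_steps):
        state = step(graph, state, settings)
        if callback is not None:
            callback(state.iteration, state.positions, state)
    graph.positions = state.positions
    return state
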