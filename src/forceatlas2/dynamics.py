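"""Adaptive speed system: swinging, effective traction, global and local
speed, displacement.

A node that keeps being pushed the same way is converging; a node whose
force keeps flipping is oscillating around its balance point. Swinging
``swg(n) = |F_t(n) − F_{t−1}(n)|`` measures the oscillation; effective
traction ``tra(n) = |F_t(n) + F_{t−1}(n)| / 2`` the useful, convergent
share. Their degree-weighted sums set the global speed
``S(G) = τ · tra(G) / swg(G)`` — as fast as possible while keeping total
swinging under the tolerance ratio τ — limited to ×1.5 growth per step.
Each node then moves at its own speed
``s(n) = k_s · S(G) / (1 + S(G) · √swg(n))``, capped so its displacement
``s(n)·|F(n)|`` never exceeds ``k_smax``, and divided by 10 in overlap
mode (where swinging is biased by the contact forces).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "node_swinging",
    "node_traction",
    "swinging_traction",
    "global_aggregates",
    "update_global_speed",
    "node_speed",
    "node_speeds",
    "displace",
    "GLOBAL_SPEED_MAX_RISE",
]

#: the global speed may grow by at most this factor between steps
GLOBAL_SPEED_MAX_RISE = 1.5


def node_swinging(force_now, force_prev) -> float:
    """``|F_t − F_{t−1}|`` — zero for a node holding its course."""
    return math.hypot(
        float(force_now[0]) - float(force_prev[0]),
        float(force_now[1]) - float(force_prev[1]),
    )


def node_traction(force_now, force_prev) -> float:
    """``|F_t + F_{t−1}| / 2`` — zero for a perfectly swinging node."""
    return 0.5 * math.hypot(
        float(force_now[0]) + float(force_prev[0]),
        float(force_now[1]) + float(force_prev[1]),
    )


def swinging_traction(
    forces_now: np.ndarray, forces_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-node swinging and traction."""
    diff = forces_now - forces_prev
    summ = forces_now + forces_prev
    swg = np.hypot(diff[:, 0], diff[:, 1])
    tra = 0.5 * np.hypot(summ[:, 0], summ[:, 1])
    return swg, tra


def global_aggregates(
    swinging: np.ndarray, traction: np.ndarray, masses: np.ndarray
) -> tuple[float, float]:
    """Mass-weighted (degree+1) sums: ``swg(G)`` and ``tra(G)``."""
    return float(np.dot(masses, swinging)), float(np.dot(masses, traction))


def update_global_speed(
    swg_global: float, tra_global: float, tolerance: float, previous_speed: float
) -> float:
    """``S(G) = τ·tra(G)/swg(G)``, capped at 1.5 × the previous speed.

    Zero global swinging means no oscillation at all; the candidate is
    then unbounded and the cap alone applies.
    """
    if swg_global > 0:
        candidate = tolerance * tra_global / swg_global
    else:
        candidate = math.inf
    return min(candidate, GLOBAL_SPEED_MAX_RISE * previous_speed)


def node_speed(
    global_speed: float,
    swinging: float,
    force_norm: float,
    k_s: float = 0.1,
    k_smax: float = 10.0,
    prevent_overlap: bool = False,
) -> float:
    """Local speed of one node (see module docstring for the formula)."""
    s = k_s * global_speed / (1.0 + global_speed * math.sqrt(max(swinging, 0.0)))
    if force_norm > 0:
        s = min(s, k_smax / force_norm)
    if prevent_overlap:
        s /= 10.0
    return s


def node_speeds(
    global_speed: float,
    swinging: np.ndarray,
    force_norms: np.ndarray,
    k_s: float = 0.1,
    k_smax: float = 10.0,
    prevent_overlap: bool = False,
) -> np.ndarray:
    """Vectorized local speeds."""
    s = k_s * global_speed / (1.0 + global_speed * np.sqrt(np.maximum(swinging, 0.0)))
    with np.errstate(divide="ignore"):
        cap = np.where(force_norms > 0, k_smax / force_norms, np.inf)
    s = np.minimum(s, cap)
    if prevent_overlap:
        s = s / 10.0
    return s


def displace(
    positions: np.ndarray, forces: np.ndarray, speeds: np.ndarray
) -> np.ndarray:
    """``x ← x + s(n)·F(n)``; rejects non-finite results by node."""
    new = positions + speeds[:, None] * forces
    if not np.all(np.isfinite(new)):
        bad = int(np.flatnonzero(~np.isfinite(new).all(axis=1))[0])
        raise FloatingPointError(f"non-finite displacement for node index {bad}")
    return new
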