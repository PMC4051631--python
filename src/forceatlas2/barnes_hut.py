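"""Barnes-Hut quadtree for approximate O(n log n) repulsion.

The plane is recursively split into square quadrants; each cell stores
the total mass and barycenter of the nodes it contains. When evaluating
the repulsion on a node, a distant cell is treated as a single point
mass at its barycenter whenever ``distance · theta > side`` (side = the
cell's edge length) — the standard opening criterion, with ``theta``
controlling the accuracy/speed trade-off (default 1.2; smaller is more
exact). The approximation does not otherwise change the layout model,
and it can be disabled.

The tree is rebuilt from current positions every iteration. Node sizes
are not represented in cells, so the engine falls back to exact
summation when overlap prevention is active.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import LayoutSettings

__all__ = ["QuadCell", "build_quadtree", "repulsion_on_node", "repulsion_forces_bh"]

#: coincident points deeper than this are merged into one leaf bundle
MAX_DEPTH = 32


class QuadCell:
    """One square cell: bounds (center + half-width), aggregate mass and
    barycenter, and either 4 children or a leaf payload of node indices."""

    __slots__ = ("cx", "cy", "half", "mass", "bx", "by", "children", "indices")

    def __init__(self, cx: float, cy: float, half: float):
        self.cx = cx
        self.cy = cy
        self.half = half
        self.mass = 0.0
        self.bx = 0.0
        self.by = 0.0
        self.children: list["QuadCell"] | None = None
        self.indices: np.ndarray | None = None

    @property
    def side(self) -> float:
        return 2.0 * self.half

    def is_leaf(self) -> bool:
        return self.children is None


def _build(
    cell: QuadCell, idx: np.ndarray, positions: np.ndarray, masses: np.ndarray, depth: int
) -> None:
    m = masses[idx]
    cell.mass = float(m.sum())
    if cell.mass > 0:
        cell.bx = float(np.dot(m, positions[idx, 0]) / cell.mass)
        cell.by = float(np.dot(m, positions[idx, 1]) / cell.mass)
    else:  # all-zero masses: plain mean keeps the barycenter defined
        cell.bx = float(positions[idx, 0].mean())
        cell.by = float(positions[idx, 1].mean())
    if len(idx) == 1 or depth >= MAX_DEPTH:
        cell.indices = idx
        return
    # all points coincident: subdivision would never separate them
    if np.ptp(positions[idx, 0]) == 0 and np.ptp(positions[idx, 1]) == 0:
        cell.indices = idx
        return
    half = cell.half / 2.0
    east = positions[idx, 0] >= cell.cx
    north = positions[idx, 1] >= cell.cy
    cell.children = []
    for ex, ny in ((False, False), (False, True), (True, False), (True, True)):
        sel = idx[(east == ex) & (north == ny)]
        if sel.size == 0:
            continue
        child = QuadCell(
            cell.cx + (half if ex else -half),
            cell.cy + (half if ny else -half),
            half,
        )
        _build(child, sel, positions, masses, depth + 1)
        cell.children.append(child)


def build_quadtree(positions: np.ndarray, masses: np.ndarray) -> QuadCell:
    """Build the tree over all nodes; root bounds are the smallest
    enclosing square."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    masses = np.asarray(masses, dtype=float).reshape(-1)
    n = len(positions)
    if n == 0:
        raise ValueError("cannot build a quadtree over zero nodes")
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite positions")
    lo = positions.min(axis=0)
    hi = positions.max(axis=0)
    center = (lo + hi) / 2.0
    half = float(max((hi - lo).max() / 2.0, 1e-9))
    root = QuadCell(float(center[0]), float(center[1]), half)
    _build(root, np.arange(n, dtype=np.int64), positions, masses, 0)
    return root


def repulsion_on_node(
    tree: QuadCell,
    position,
    mass: float,
    theta: float,
    settings: "LayoutSettings",
    skip_index: int | None = None,
    positions: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Approximate repulsion on one node.

    Cells satisfying the opening criterion contribute as point masses;
    leaves contribute exact pairwise terms (the query node itself, and
    coincident partners, contribute nothing).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    px, py = float(position[0]), float(position[1])
    fx = fy = 0.0
    k_r = settings.scaling
    stack = [tree]
    while stack:
        cell = stack.pop()
        dx = px - cell.bx
        dy = py - cell.by
        d = math.hypot(dx, dy)
        if not cell.is_leaf():
            # never approximate a cell the query point lies inside: the
            # barycenter distance could satisfy the criterion while the
            # cell contains the node itself
            inside = abs(px - cell.cx) <= cell.half and abs(py - cell.cy) <= cell.half
            if not inside and d * theta > cell.side:
                if d > 0:
                    f = k_r * mass * cell.mass / (d * d)
                    fx += f * dx
                    fy += f * dy
            else:
                stack.extend(cell.children)
            continue
        # leaf: exact pairwise terms, skipping the query node itself
        if positions is not None:
            for j in cell.indices:
                if skip_index is not None and j == skip_index:
                    continue
                ddx = px - positions[j, 0]
                ddy = py - positions[j, 1]
                dd = math.hypot(ddx, ddy)
                if dd > 0:
                    jm = masses[j] if masses is not None else cell.mass
                    f = k_r * mass * jm / (dd * dd)
                    fx += f * ddx
                    fy += f * ddy
        else:
            # no per-node arrays: use the leaf's aggregate, subtracting the
            # query node's own mass when it lives in this leaf
            cm = cell.mass
            if skip_index is not None and skip_index in cell.indices:
                cm -= mass
            if cm > 0 and d > 0:
                f = k_r * mass * cm / (d * d)
                fx += f * dx
                fy += f * dy
    return np.array([fx, fy])


def repulsion_forces_bh(
    positions: np.ndarray,
    masses: np.ndarray,
    theta: float,
    settings: "LayoutSettings",
    tree: QuadCell | None = None,
) -> np.ndarray:
    """Approximate repulsion for every node (tree built here unless given)."""
    if tree is None:
        tree = build_quadtree(positions, masses)
    out = np.empty_like(positions)
    for i in range(len(positions)):
        out[i] = repulsion_on_node(
            tree,
            positions[i],
            float(masses[i]),
            theta,
            settings,
            skip_index=i,
            positions=positions,
            masses=masses,
        )
    return out
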