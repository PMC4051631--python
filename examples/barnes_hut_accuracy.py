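"""Measure the Barnes-Hut approximation error against exact summation.

Builds 500 random point masses, evaluates repulsion exactly and through
the quadtree at several theta values, and prints the median per-node
relative error: near zero for tiny theta (full traversal), growing with
theta as more cells are approximated by their barycenters.
"""

import numpy as np

from forceatlas2 import LayoutSettings, repulsion_forces_bh
from forceatlas2.forces import repulsion_forces_exact

rng = np.random.default_rng(0)
n = 500
positions = rng.uniform(-100, 100, size=(n, 2))
masses = rng.uniform(1, 8, n)
settings = LayoutSettings()

exact = repulsion_forces_exact(positions, masses, np.ones(n), settings)
norm = np.hypot(exact[:, 0], exact[:, 1])

for theta in (1e-6, 0.5, 1.2, 2.0):
    approx = repulsion_forces_bh(positions, masses, theta=theta, settings=settings)
    err = np.hypot(*(approx - exact).T) / norm
    print(f"theta {theta:>6}: median relative error {np.median(err):.3e}")
print("error grows with theta: coarser approximation, faster evaluation")
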