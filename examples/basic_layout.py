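"""Lay out a small scale-free network and inspect the result.

Builds a 100-node preferential-attachment graph, runs 500 layout steps at
default settings, and prints the mean edge length and the layout quality
(inverse normalized edge length — higher means connected nodes sit close
relative to the overall spread).
"""

import numpy as np

from forceatlas2 import (
    LayoutSettings,
    SyntheticSpec,
    generate_network,
    layout_quality,
    run,
)

graph = generate_network(SyntheticSpec("scale_free", n_nodes=100, attachment=2, seed=1))
state = run(graph, LayoutSettings(), n_steps=500, seed=1)

edge_vec = state.positions[graph.edges[:, 0]] - state.positions[graph.edges[:, 1]]
mean_edge = np.hypot(edge_vec[:, 0], edge_vec[:, 1]).mean()
print(f"nodes: {graph.n_nodes}, edges: {graph.n_edges}")
print(f"mean edge length after 500 steps: {mean_edge:.2f} layout units")
print(f"layout quality: {layout_quality(graph):.3f}")
print("(quality > 1 means edges are shorter than the average node pair distance)")
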