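# Methods

## The force model

ForceAtlas2 spatializes a graph by simulating forces until positions
balance. Connected nodes attract; all node pairs repulse; optional
gravity pulls everything toward the origin. For nodes $n_1, n_2$ at
Euclidean distance $d$:

- **Attraction** (per edge): $F_a = d$ in the linear (default) mode, or
  $F_a = \log(1 + d)$ in LinLog mode (the $+1$ keeps superposed nodes
  finite). Attraction deliberately has no constant of its own; the
  layout's size is governed entirely by the repulsion constant.
- **Repulsion** (per pair): $F_r = k_r \, (deg(n_1)+1)(deg(n_2)+1) / d$,
  with $k_r$ the `scaling` setting (default 2). Weighting by
  $mass = deg + 1$ keeps leaves close to their hubs relative to the
  graph's spread and lets isolated nodes still repulse.
- **Gravity**: $F_g = k_g \, mass(n)$ toward the origin
  (distance-independent, so it compensates repulsion far from the
  center), or $F_g = k_g \, mass(n) \, d(n)$ in strong mode.
- **Edge weights** enter attraction as $w^\delta$ with $0^0 := 1$, so
  `edge_weight_influence` $\delta = 0$ ignores weights and $\delta = 1$
  uses them proportionally.
- **Dissuade hubs**: each edge's attraction is divided by the *source*
  node's mass and multiplied by the graph's mean mass. The division
  pushes high-outdegree hubs peripheral; the mean-mass compensation
  restores the average attraction magnitude so the layout keeps a
  comparable spread. The divided magnitude is applied to both endpoints
  (equal and opposite), so momentum is still conserved per edge. For
  undirected input the stored first endpoint acts as source.
- **Overlap prevention**: all kernels switch to the border-to-border
  distance $d' = d - size_1 - size_2$. Intersecting nodes ($d' < 0$)
  feel no attraction and a strong constant repulsion
  $k_r' \, m_1 m_2$ with $k_r' = 100$; touching nodes ($|d'| \le
  10^{-12}$, a tolerance that keeps the measure-zero contact branch from
  flapping) feel nothing. The mode adds heavy friction and is meant to
  be switched on only after the layout has converged.

Coincident node pairs contribute zero repulsion (their direction is
undefined); seeded initialization guarantees pairwise-distinct
positions, so this state cannot persist. Self-loops count 2 toward
degree (preserving the handshake identity $\sum deg = 2E$) and generate
no attraction.

## Adaptive speed

Per node, with $F_t$ the resultant force at step $t$:

- swinging $swg(n) = |F_t - F_{t-1}|$ — oscillation around the balance
  point;
- effective traction $tra(n) = |F_t + F_{t-1}|/2$ — the useful,
  convergent share of the force.

Globally, both are summed weighted by $deg+1$, and the global speed is
$S(G) = \tau \cdot tra(G) / swg(G)$: as fast as the tolerated swinging
ratio $\tau$ allows. An excessive rise of $S$ is harmful, so it may grow
by at most ×1.5 per step. Each node then moves by $D(n) = s(n) F_t(n)$
with

$$s(n) = \frac{k_s S(G)}{1 + S(G)\sqrt{swg(n)}}, \qquad
  s(n) \le \frac{k_{s,max}}{|F_t(n)|},$$

$k_s = 0.1$, $k_{s,max} = 10$ — so no node ever moves farther than 10
layout units in one step. In overlap mode the local speed is divided by
10 after the cap (swinging is biased by contact forces there; the
ordering of the two reductions is a design choice, consequential only
when the cap binds).

Initial conditions: $S(G) = 1$ and $F_{-1} = 0$, so first-step swinging
equals $|F_1|$. When $swg(G) = 0$ the speed takes the capped value
$1.5 \times$ previous (continuity of the cap rule). Tolerance defaults
by graph size: 0.1 under 5,000 nodes, 1 up to 50,000 (inclusive), 10
above.

The engine is continuous: no phases, no auto-stop; settings are re-read
every step and may be changed while the layout runs. State at step $t$
is a pure function of (graph, settings, seed, $t$); the implementation
is single-threaded and bit-reproducible.

## Barnes-Hut approximation

Repulsion is $O(n^2)$; the quadtree approximation reduces it to
$O(n \log n)$. Cells store total mass and barycenter; a cell is treated
as one point mass when $d \cdot \theta > side$ (side = cell edge
length; the side convention, rather than the diagonal, is a documented
choice), never when the query point lies inside the cell's bounds
(otherwise a skewed barycenter could fold a node's own mass into its
force). Leaves are summed exactly. The tree is rebuilt every iteration
(no incremental updates — simplicity over constant-factor speed); depth
is capped at 32, with deeper coincident bundles merged as one point
mass. Default $\theta = 1.2$; `auto` mode enables the approximation
above 1,000 nodes, where the $O(n^2)$ path stops being comfortable.
Cells carry no node sizes, so the engine always uses exact summation
when overlap prevention is active (a small-graph, post-convergence
feature anyway).

## Layout quality and the benchmark protocol

Quality is the inverse of the normalized edge length:
$$Q = \frac{\text{mean all-pairs distance}}{\text{mean edge length}},$$
higher is better, invariant under translation, rotation and uniform
scaling, and exactly 1 on a complete graph. The reciprocal (rather than
negation) keeps the 50%/90% thresholds meaningful on a positive scale.
The all-pairs mean is exact up to 3,000 nodes and estimated from
100,000 seeded sampled pairs above. Self-loop edges are excluded from
the edge-length mean.

The protocol samples quality at steps $2^k$ and $2^k+1$ (k = 0..11 by
default, i.e. up to 2049), averages each pair to damp oscillations, and
reports the quick-and-dirty point (first sampled step reaching 50% of
the run's maximum averaged quality) and the quasi-optimal point (90%).
Points are reported in *steps*: millisecond timestamps are recorded in
the output table for parity with interactive use, but wall-clock values
are hardware-bound and not comparable across machines. Each network is
laid out from several (default 3) seeded randomizations and the points
averaged.

Protocol runs randomize initial positions in a fixed ±100 square — the
typical randomize-then-layout workflow the benchmark emulates — whereas
the engine's own default initial extent is $100\sqrt{n}$, which keeps
the initial *density* independent of graph size. The benchmark runs at
jitter tolerance 1.0 (the medium profile used for benchmarking) when
the caller passes it; `default_settings` otherwise applies the size
bands.

## Fixed-speed reference policies

`compare_speed_policies` re-runs the engine with every node's local
speed clamped to a constant (0.001, 0.01, 0.1 being the instructive
values) against the adaptive policy. The $k_{s,max}/|F|$ displacement
cap is retained in the fixed variants: it is a protection of the
displacement rule, not part of the adaptive formula, and without it a
fixed speed $s$ destabilizes every node whose effective stiffness
exceeds $2/s$ into unbounded divergence (high-degree nodes overflow
within a few hundred steps). With the cap, too low a speed converges
slowly and too high a speed oscillates without diverging — the
behaviors the comparison is meant to expose.

## Synthetic networks

The generators stand in for a benchmark collection of real networks
(social and biological networks, trees, random and small-world graphs):

- `scale_free`: preferential attachment (heavy-tailed degrees);
- `random`: Erdős–Rényi $G(n, p)$;
- `tree`: balanced $b$-ary tree of given depth;
- `small_world`: Watts–Strogatz ring rewiring;
- `planted_clusters`: planted partition (dense intra, sparse inter) —
  the testbed for LinLog's cluster tightening;
- `ego_like_network`: scale-free communities (preferential attachment
  within each), sparse inter-community edges, plus one apex node — the
  ego — adjacent to everyone. Defaults (4 communities × 50 nodes,
  attachment 10, inter-community edge probability 0.004) give ~200
  nodes at mean degree ≈ 20, the size and density of typical social
  ego-networks.

All generators are seeded and reproducible. What they do *not* emulate:
overlapping communities, degree assortativity, triadic closure beyond
what preferential attachment produces, and the label/attribute noise of
real data. Passing tests therefore demonstrate the layout's mechanics
and its qualitative responses to structure, not performance claims
about any particular real-world dataset.

## Numerical and design choices

- Equilibrium checks use the closed form for two connected degree-1
  nodes: $d^* = \sqrt{k_r m_1 m_2} = \sqrt{8}$ at defaults. At *equal*
  scaling, the LinLog balance point of the same pair is *larger*
  (because $\log(1+d) < d$); LinLog's cluster tightening is a
  relative effect and appears at its readjusted scaling (0.1), which is
  how the planted-cluster comparison runs.
- The repulsion-by-degree comparison (degree-weighted vs mass-1
  repulsion) is evaluated scale-relatively — hub–leaf distance divided
  by the layout's mean pairwise distance — because the absolute balance
  distance necessarily grows with the mass product; the claim under
  test is about where leaves sit *within* the global scheme, matching
  how layouts of comparable size are compared.
- Degrees, masses and forces are float64 throughout; force accumulation
  is vectorized but sequential-equivalent, so runs are deterministic.
- The engine aborts a step with a diagnostic naming the node if any
  position or displacement becomes non-finite.

## Problem sizes

Default test and benchmark runs use graphs of 2–1,500 nodes and up to
~2,050 steps — sizes at which the exact $O(n^2)$ force path is fast and
every reported number can be recomputed from scratch in seconds to a
few minutes. The algorithm itself is routinely used interactively up to
~100,000 nodes with Barnes-Hut enabled.

## Known limitations

- 2D only; no 3D octree.
- The Barnes-Hut path ignores node sizes (exact summation is used when
  overlap prevention is on).
- Wall-clock benchmark points are recorded but not meaningful across
  hardware; step-indexed points are the comparable quantity.
- No convergence detection by design (continuous layout): the caller
  decides when to stop.
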