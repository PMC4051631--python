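"""Run the layout-quality benchmark protocol on a synthetic network.

Lays out a 100-node scale-free graph three times from different seeded
randomizations, sampling quality at every power-of-2 step (and its
successor, for oscillation-damping pair averages), then prints each
run's maximum quality and its quick-and-dirty (50% of max) and
quasi-optimal (90% of max) steps.
"""

from forceatlas2 import SyntheticSpec, generate_network, run_benchmark

graph = generate_network(SyntheticSpec("scale_free", n_nodes=100, attachment=2, seed=7))
result = run_benchmark(graph, n_randomizations=3, seeds=[1, 2, 3], max_power=11)

for pts, series in zip(result.points, result.series):
    print(
        f"seed {series.randomization_seed}: max quality {pts.max_quality:.3f}, "
        f"QND step {pts.qnd_step}, QO step {pts.qo_step}"
    )
print(
    f"means: max quality {result.mean_max_quality:.3f}, "
    f"QND {result.mean_qnd_step:.1f}, QO {result.mean_qo_step:.1f}"
)
print("QND = rough spatialization; QO = satisfying layout")
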