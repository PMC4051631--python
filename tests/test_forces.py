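"""Force kernels: geometry, attraction variants, degree-weighted repulsion,
gravity, exact accumulation, and the closed-form two-node equilibrium."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from forceatlas2 import (
    Graph,
    LayoutSettings,
    accumulate_forces_exact,
    attraction_magnitude,
    gravity_force,
    pair_geometry,
    repulsion_magnitude,
    run,
)


class TestPairGeometry:
    def test_border_to_border_separated(self):
        g = pair_geometry((0, 0), (10, 0), 3, 4, prevent_overlap=True)
        assert g.distance == 10
        assert g.adjusted_distance == 3

    def test_border_to_border_overlapping(self):
        g = pair_geometry((0, 0), (5, 0), 3, 4, prevent_overlap=True)
        assert g.adjusted_distance == -2

    def test_overlap_off_identity(self):
        g = pair_geometry((0, 0), (5, 0), 3, 4, prevent_overlap=False)
        assert g.adjusted_distance == g.distance == 5

    def test_coincident_zero_direction(self):
        g = pair_geometry((1, 1), (1, 1))
        assert g.distance == 0
        assert g.unit_direction == (0.0, 0.0)

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            pair_geometry((0, 0), (1, 0), -1, 0)


class TestAttraction:
    def test_linear_equals_distance(self):
        geom = pair_geometry((0, 0), (3, 0))
        s = LayoutSettings()
        assert attraction_magnitude(geom, 1.0, s) == 3.0

    def test_linlog_superposed_nodes_finite(self):
        geom = pair_geometry((0, 0), (0, 0))
        s = LayoutSettings(linlog=True)
        assert attraction_magnitude(geom, 1.0, s) == 0.0

    def test_linlog_is_log1p(self):
        geom = pair_geometry((0, 0), (math.e - 1, 0))
        s = LayoutSettings(linlog=True)
        assert attraction_magnitude(geom, 1.0, s) == pytest.approx(1.0)

    def test_zero_influence_ignores_weights(self):
        geom = pair_geometry((0, 0), (3, 0))
        s = LayoutSettings(edge_weight_influence=0.0)
        assert attraction_magnitude(geom, 5.0, s) == 3.0
        assert attraction_magnitude(geom, 0.0, s) == 3.0  # 0^0 == 1

    def test_weight_influence_powers(self):
        geom = pair_geometry((0, 0), (3, 0))
        assert (
            attraction_magnitude(geom, 2.0, LayoutSettings(edge_weight_influence=2.0))
            == 12.0
        )

    def test_dissuade_hubs_divides_by_source_mass(self):
        geom = pair_geometry((0, 0), (4, 0))
        s = LayoutSettings(dissuade_hubs=True)
        assert attraction_magnitude(geom, 1.0, s, source_mass=4.0) == 1.0

    def test_dissuade_compensation_scales(self):
        geom = pair_geometry((0, 0), (4, 0))
        s = LayoutSettings(dissuade_hubs=True)
        assert attraction_magnitude(geom, 1.0, s, source_mass=4.0, compensation=2.0) == 2.0

    def test_no_attraction_while_overlapping(self):
        geom = pair_geometry((0, 0), (5, 0), 3, 4, prevent_overlap=True)
        s = LayoutSettings(prevent_overlap=True)
        assert attraction_magnitude(geom, 1.0, s) == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            attraction_magnitude(pair_geometry((0, 0), (1, 0)), -1.0, LayoutSettings())


class TestRepulsion:
    def test_two_isolated_nodes(self):
        geom = pair_geometry((0, 0), (2, 0))
        assert repulsion_magnitude(geom, 1, 1, LayoutSettings(scaling=2.0)) == 1.0

    def test_mass_product(self):
        geom = pair_geometry((0, 0), (1, 0))
        assert repulsion_magnitude(geom, 4, 2, LayoutSettings(scaling=2.0)) == 16.0

    def test_touching_no_force(self):
        geom = pair_geometry((0, 0), (7, 0), 3, 4, prevent_overlap=True)
        s = LayoutSettings(prevent_overlap=True)
        assert repulsion_magnitude(geom, 2, 2, s) == 0.0

    def test_overlapping_strong_constant(self):
        geom = pair_geometry((0, 0), (5, 0), 3, 4, prevent_overlap=True)
        s = LayoutSettings(prevent_overlap=True)
        assert repulsion_magnitude(geom, 2, 2, s) == 400.0

    def test_coincident_pair_skipped(self):
        geom = pair_geometry((1, 1), (1, 1))
        assert repulsion_magnitude(geom, 3, 3, LayoutSettings()) == 0.0

    @given(
        d1=st.floats(0.5, 50),
        d2=st.floats(0.5, 50),
        m=st.floats(1, 20),
    )
    @hsettings(max_examples=50, deadline=None)
    def test_decreasing_in_distance_linear_in_mass(self, d1, d2, m):
        s = LayoutSettings()
        lo, hi = sorted((d1, d2))
        if hi - lo > 1e-9:
            r_lo = repulsion_magnitude(pair_geometry((0, 0), (lo, 0)), 2, 3, s)
            r_hi = repulsion_magnitude(pair_geometry((0, 0), (hi, 0)), 2, 3, s)
            assert r_lo > r_hi
        base = repulsion_magnitude(pair_geometry((0, 0), (d1, 0)), 1, 3, s)
        scaled = repulsion_magnitude(pair_geometry((0, 0), (d1, 0)), m, 3, s)
        assert scaled == pytest.approx(m * base, rel=1e-12)


class TestGravity:
    def test_node_at_origin_zero(self):
        s = LayoutSettings(gravity=5.0)
        assert np.array_equal(gravity_force((0, 0), 3.0, s), [0, 0])

    def test_regular_distance_independent(self):
        s = LayoutSettings(gravity=1.0)
        f = gravity_force((4, 0), 3.0, s)
        assert np.allclose(f, [-3.0, 0.0])
        f_far = gravity_force((400, 0), 3.0, s)
        assert np.allclose(f_far, [-3.0, 0.0])

    def test_strong_scales_with_distance(self):
        s = LayoutSettings(gravity=1.0, strong_gravity=True)
        f = gravity_force((4, 0), 3.0, s)
        assert np.allclose(f, [-12.0, 0.0])


class TestAccumulation:
    def test_two_isolated_nodes_action_reaction(self):
        g = Graph(ids=["a", "b"], edges=np.empty((0, 2), dtype=int))
        g.positions = np.array([[0.0, 0.0], [3.0, 4.0]])
        f = accumulate_forces_exact(g, LayoutSettings())
        assert np.allclose(f[0], -f[1])
        # along the connecting line
        assert f[0, 0] * 4.0 - f[0, 1] * 3.0 == pytest.approx(0.0, abs=1e-12)

    def test_single_node_strong_gravity(self):
        g = Graph(ids=["a"], edges=np.empty((0, 2), dtype=int))
        g.positions = np.array([[3.0, 4.0]])
        f = accumulate_forces_exact(g, LayoutSettings(gravity=1.0, strong_gravity=True))
        assert np.hypot(*f[0]) == pytest.approx(5.0)
        assert np.allclose(f[0] / np.hypot(*f[0]), [-0.6, -0.8])

    def test_equilateral_triangle_forces_cancel(self):
        g = Graph.from_edge_pairs([("a", "b"), ("b", "c"), ("c", "a")])
        r = 2.0
        g.positions = np.array(
            [
                [r * np.cos(a), r * np.sin(a)]
                for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)
            ]
        )
        f = accumulate_forces_exact(g, LayoutSettings())
        assert np.allclose(f.sum(axis=0), [0.0, 0.0], atol=1e-9)

    def test_matches_scalar_kernels_on_small_graph(self, rng):
        """Vectorized accumulation agrees with a brute-force loop over the
        scalar kernels (independent path)."""
        g = Graph.from_edge_pairs([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        g.positions = rng.normal(size=(4, 2)) * 5
        s = LayoutSettings(gravity=0.7)
        expected = np.zeros((4, 2))
        masses = g.masses
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                geom = pair_geometry(g.positions[j], g.positions[i])
                mag = repulsion_magnitude(geom, masses[j], masses[i], s)
                expected[i] += mag * np.asarray(geom.unit_direction)
        for (u, v), w in zip(g.edges, g.weights):
            geom = pair_geometry(g.positions[u], g.positions[v])
            mag = attraction_magnitude(geom, w, s)
            expected[u] += mag * np.asarray(geom.unit_direction)
            expected[v] -= mag * np.asarray(geom.unit_direction)
        for i in range(4):
            expected[i] += gravity_force(g.positions[i], masses[i], s)
        got = accumulate_forces_exact(g, s)
        assert np.allclose(got, expected, atol=1e-9)

    def test_total_force_zero_without_gravity(self, rng):
        g = Graph.from_edge_pairs([(i, (i + 3) % 10) for i in range(10)])
        g.positions = rng.normal(size=(10, 2)) * 10
        f = accumulate_forces_exact(g, LayoutSettings())
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_self_loop_generates_no_attraction(self):
        g = Graph.from_edge_pairs([("a", "a"), ("a", "b")])
        g.positions = np.array([[0.0, 0.0], [5.0, 0.0]])
        f1 = accumulate_forces_exact(g, LayoutSettings())
        g2 = Graph.from_edge_pairs([("a", "b")])
        g2.positions = g.positions.copy()
        f2 = accumulate_forces_exact(g2, LayoutSettings())
        # self-loop raises a's degree (affecting repulsion mass) but adds no pull
        assert np.sign(f1[0, 0]) == np.sign(f2[0, 0])
        attr_only = LayoutSettings(scaling=1e-12)
        fa = accumulate_forces_exact(g, attr_only)
        fb = accumulate_forces_exact(g2, attr_only)
        assert np.allclose(fa[1], fb[1], atol=1e-9)


class TestEquilibria:
    def test_two_node_equilibrium_closed_form(self):
        """attraction d = repulsion k_r·m1·m2/d  =>  d* = sqrt(k_r·4) = sqrt(8)."""
        g = Graph.from_edge_pairs([("a", "b")])
        st_ = run(g, LayoutSettings(), n_steps=500, seed=1)
        d = float(np.linalg.norm(st_.positions[0] - st_.positions[1]))
        assert d == pytest.approx(np.sqrt(8.0), rel=0.01)

    def test_linlog_equilibrium_larger_at_equal_scaling(self):
        """log(1+d) < d, so the LinLog balance point of the same two-node
        system lies farther out at equal scaling; the cluster-tightening
        effect appears at the readjusted scaling (see evaluation tests)."""
        from scipy.optimize import brentq

        k = 2.0 * 2.0 * 2.0  # k_r·m1·m2
        d_lin = np.sqrt(k)
        d_ll = brentq(lambda d: d * np.log1p(d) - k, 1e-9, 1e3)
        assert d_ll > d_lin
        g = Graph.from_edge_pairs([("a", "b")])
        st_ = run(g, LayoutSettings(linlog=True), n_steps=800, seed=1)
        d = float(np.linalg.norm(st_.positions[0] - st_.positions[1]))
        assert d == pytest.approx(d_ll, rel=0.01)

    def test_zero_weight_influence_matches_unit_weights_bitwise(self):
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0), (1, 3)]
        g1 = Graph.from_edge_pairs(pairs, weights=[5.0, 0.1, 2.0, 7.0, 0.5])
        g2 = Graph.from_edge_pairs(pairs, weights=[1.0] * 5)
        s1 = LayoutSettings(edge_weight_influence=0.0)
        s2 = LayoutSettings(edge_weight_influence=1.0)
        a = run(g1, s1, n_steps=50, seed=9)
        b = run(g2, s2, n_steps=50, seed=9)
        assert np.array_equal(a.positions, b.positions)
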