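import numpy as np
import pytest

import pulmoperf as pp
from pulmoperf.geometry import (ARTERIAL_STRAHLER_RATIO, TreeGrowthParams,
                                initial_macro_tree)


class TestLungShapes:
    def test_right_fraction_exact(self):
        left, right = pp.generate_lung_shapes(6.8e-3, 0.525)
        assert right.volume == pytest.approx(3.57e-3, rel=1e-6)
        assert (left.volume + right.volume) == pytest.approx(6.8e-3, rel=1e-9)

    def test_equal_fraction_gives_equal_volumes(self):
        left, right = pp.generate_lung_shapes(4e-3, 0.5)
        assert left.volume == pytest.approx(right.volume, rel=1e-12)

    def test_monte_carlo_volume_matches_analytic(self):
        left, right = pp.generate_lung_shapes()
        rng = np.random.default_rng(0)
        for shape in (left, right):
            lo, hi = shape.bounding_box()
            pts = rng.uniform(lo, hi, size=(200_000, 3))
            box_vol = np.prod(hi - lo)
            mc = shape.contains(pts).mean() * box_vol
            assert mc == pytest.approx(shape.volume, rel=0.01)

    def test_shapes_do_not_overlap(self):
        left, right = pp.generate_lung_shapes()
        rng = np.random.default_rng(1)
        lo, hi = left.bounding_box()
        pts = rng.uniform(lo, hi, size=(50_000, 3))
        inside_left = left.contains(pts)
        assert not right.contains(pts[inside_left]).any()

    def test_hilum_inside_shape(self):
        for shape in pp.generate_lung_shapes():
            assert shape.contains(shape.hilum[None, :])[0]

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            pp.generate_lung_shapes(-1.0, 0.5)
        with pytest.raises(ValueError):
            pp.generate_lung_shapes(4e-3, 1.2)


class TestSeeding:
    def test_count_membership_and_determinism(self):
        left, _ = pp.generate_lung_shapes()
        seeds = pp.seed_acini(left, 1000, rng_seed=3)
        assert len(seeds) == 1000
        assert left.contains(seeds.points).all()
        again = pp.seed_acini(left, 1000, rng_seed=3)
        np.testing.assert_array_equal(seeds.points, again.points)

    def test_quasi_uniform_spacing(self):
        from scipy.spatial import cKDTree

        left, _ = pp.generate_lung_shapes()
        seeds = pp.seed_acini(left, 800, rng_seed=0)
        d, _ = cKDTree(seeds.points).query(seeds.points, k=2)
        nn = d[:, 1]
        assert nn.std() / nn.mean() < 0.5

    def test_rejects_zero_count(self):
        left, _ = pp.generate_lung_shapes()
        with pytest.raises(ValueError):
            pp.seed_acini(left, 0)


class TestTreeGrowth:
    def test_single_seed_single_branch(self):
        left, _ = pp.generate_lung_shapes()
        seeds = pp.seed_acini(left, 1, rng_seed=0)
        net0 = initial_macro_tree()
        net = pp.grow_volume_filling_tree(net0, seeds)
        assert net.n_elements == net0.n_elements + 1
        assert net.n_acini == 1
        np.testing.assert_allclose(net.acinus_xyz[0], seeds.points[0])

    def test_one_terminal_per_seed_inside_shape(self):
        left, _ = pp.generate_lung_shapes()
        seeds = pp.seed_acini(left, 400, rng_seed=2)
        net = pp.grow_volume_filling_tree(initial_macro_tree(), seeds,
                                          rng_seed=2)
        assert net.n_acini == 400
        assert left.contains(net.acinus_xyz).all()

    def test_branch_angles_respect_limit(self):
        left, _ = pp.generate_lung_shapes()
        seeds = pp.seed_acini(left, 300, rng_seed=5)
        params = TreeGrowthParams()
        net = pp.grow_volume_filling_tree(initial_macro_tree(), seeds, params)
        # exhaustive parent/child direction check on grown (non-terminal)
        # elements; terminal closing branches go straight to their seed
        term = set(net.acinus_art_elem.tolist())
        d = net.node_xyz[net.elem_node_out] - net.node_xyz[net.elem_node_in]
        d = d / np.linalg.norm(d, axis=1)[:, None]
        by_in = {}
        for e in range(net.n_elements):
            by_in.setdefault(int(net.elem_node_in[e]), []).append(e)
        limit = np.deg2rad(params.branch_angle_limit) + 1e-9
        macro = set(net.macro_element_ids.tolist())
        for e in range(net.n_elements):
            for c in by_in.get(int(net.elem_node_out[e]), []):
                if c in term or c in macro:
                    continue  # template angles are anatomy, not growth
                ang = np.arccos(np.clip(d[e] @ d[c], -1, 1))
                assert ang <= limit

    def test_space_filling(self):
        from scipy.spatial import cKDTree

        left, _ = pp.generate_lung_shapes()
        seeds = pp.seed_acini(left, 500, rng_seed=1)
        net = pp.grow_volume_filling_tree(initial_macro_tree(), seeds)
        dist, _ = cKDTree(net.acinus_xyz).query(seeds.points)
        assert (dist < 0.02).mean() > 0.99


class TestStrahler:
    def _two_level_tree(self):
        xyz = np.array([[0, 0, 0], [0, 0, 1.0], [-1, 0, 2.0], [1, 0, 2.0]])
        return pp.VesselNetwork(
            node_xyz=xyz,
            elem_node_in=np.array([0, 1, 1]),
            elem_node_out=np.array([1, 2, 3]),
            elem_type=np.zeros(3, int),
            elem_D0=np.full(3, 1e-3),
            elem_order=np.zeros(3, int),
            elem_generation=np.array([0, 1, 1]),
        )

    def test_symmetric_bifurcation_diameters(self):
        net = pp.assign_strahler_radii(self._two_level_tree(), 0.02, 1.52)
        assert net.elem_D0[0] == pytest.approx(0.02)
        assert net.elem_D0[1] == pytest.approx(0.02 / 1.52, rel=1e-12)
        assert net.elem_D0[1] == pytest.approx(0.01316, rel=1e-3)

    def test_single_element_keeps_inlet_diameter(self):
        net = self._two_level_tree()
        sub = pp.VesselNetwork(
            node_xyz=net.node_xyz[:2],
            elem_node_in=np.array([0]), elem_node_out=np.array([1]),
            elem_type=np.zeros(1, int), elem_D0=np.array([1e-3]),
            elem_order=np.zeros(1, int), elem_generation=np.zeros(1, int))
        out = pp.assign_strahler_radii(sub, 0.015, 1.52)
        assert out.elem_D0[0] == pytest.approx(0.015)

    def test_ratio_must_exceed_one(self):
        with pytest.raises(ValueError):
            pp.assign_strahler_radii(self._two_level_tree(), 0.02, 0.9)

    def test_cycle_rejected(self):
        net = self._two_level_tree()
        net.elem_node_out[2] = 0  # close a loop
        with pytest.raises(ValueError):
            pp.assign_strahler_radii(net, 0.02, 1.52)

    def test_ratio_recovered_by_order_regression(self, small_network):
        net = small_network
        art = [e for e in range(net.n_elements)
               if net.elem_type[e] == 0 and e not in set(net.macro_element_ids)]
        orders = net.elem_order[art]
        D = net.elem_D0[art]
        means = [np.log(D[orders == o].mean())
                 for o in range(1, orders.max() + 1)]
        slope = np.polyfit(np.arange(1, orders.max() + 1), means, 1)[0]
        assert np.exp(slope) == pytest.approx(ARTERIAL_STRAHLER_RATIO,
                                              abs=0.05)

    def test_diameter_monotone_root_to_leaf(self, small_network):
        net = small_network
        by_out = {int(net.elem_node_out[e]): e for e in range(net.n_elements)
                  if net.elem_type[e] == 0}
        for e in range(net.n_elements):
            if net.elem_type[e] != 0:
                continue
            parent = by_out.get(int(net.elem_node_in[e]))
            if parent is not None:
                assert net.elem_D0[e] <= net.elem_D0[parent] + 1e-15


class TestMirrorAndAssembly:
    def test_mirror_counts_and_colocation(self):
        left, _ = pp.generate_lung_shapes()
        seeds = pp.seed_acini(left, 200, rng_seed=4)
        art = pp.grow_volume_filling_tree(initial_macro_tree(), seeds)
        art = pp.assign_strahler_radii(
            art, 0.0219, 1.52,
            root_elem=[e for e in range(art.n_elements)
                       if art.elem_node_in[e] == art.interface_nodes["LPA"]
                       and e not in set(art.macro_element_ids)][0])
        ven = pp.mirror_venous_network(art)
        assert ven.n_elements == art.n_elements
        np.testing.assert_allclose(ven.node_xyz[ven.acinus_ven_node],
                                   art.node_xyz[art.acinus_art_node])

    def test_venous_terminals_match_arterial_calibers(self):
        # deterministic radii: terminal venules are sized to equal their
        # arterial counterparts (the venous root absorbs the ratio change)
        net = pp.build_circulation(n_acini=150, rng_seed=3, diameter_cv=0.0,
                                   acinar_size_cv=0.0)
        art_term_D = net.elem_D0[net.acinus_art_elem]
        ven = net.subgraph_element_ids("vein")
        by_in = {int(net.elem_node_in[e]): e for e in ven}
        ven_term_D = np.array([net.elem_D0[by_in[int(n)]]
                               for n in net.acinus_ven_node])
        np.testing.assert_allclose(ven_term_D, art_term_D, rtol=1e-8)

    def test_full_circulation_connected(self, small_network):
        import networkx as nx

        net = small_network
        g = nx.Graph()
        for i in range(net.n_elements):
            g.add_edge(int(net.elem_node_in[i]), int(net.elem_node_out[i]))
        for a, v in zip(net.acinus_art_node, net.acinus_ven_node):
            g.add_edge(int(a), int(v))
        assert nx.is_connected(g)

    def test_acinus_count_equals_terminals(self, small_network):
        assert small_network.n_acini == 400

    def test_determinism_byte_identical(self, tmp_path):
        from pulmoperf.io import write_network

        for run in ("a", "b"):
            net = pp.build_circulation(n_acini=120, rng_seed=11)
            write_network(net, tmp_path / run)
        for name in ("nodes.csv", "elements.csv", "acini.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
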