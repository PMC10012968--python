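import numpy as np
import pytest

import pulmoperf as pp
from pulmoperf.flow_solver import ALVEOLAR_DIAMETER_THRESHOLD


class TestElementRelations:
    def test_poiseuille_drop(self):
        fluid = pp.FluidProperties()
        dp = pp.element_pressure_drop(0.01, 0.001, 1e-6, fluid,
                                      cos_theta=0.0, g=9.81)
        assert dp == pytest.approx(1426.0, rel=1e-3)

    def test_hydrostatic_only(self):
        fluid = pp.FluidProperties()
        dp = pp.element_pressure_drop(0.01, 0.001, 0.0, fluid,
                                      cos_theta=1.0, g=9.81)
        assert dp == pytest.approx(103.0, rel=1e-3)

    def test_zero_flow_horizontal(self):
        dp = pp.element_pressure_drop(0.01, 0.001, 0.0, pp.FluidProperties(),
                                      cos_theta=0.0, g=9.81)
        assert dp == 0.0

    def test_rejects_nonpositive_diameter(self):
        with pytest.raises(ValueError):
            pp.element_pressure_drop(0.01, 0.0, 1e-6, pp.FluidProperties(),
                                     0.0, 9.81)

    def test_diameter_law(self):
        law = pp.ComplianceLaw()
        assert pp.update_diameter(1e-3, 0.0, law) == pytest.approx(1e-3)
        assert pp.update_diameter(1e-3, 1000.0, law) == \
            pytest.approx(1.149e-3, rel=1e-6)
        assert pp.update_diameter(1e-3, -1e6, law) == pytest.approx(1e-4)

    def test_extravascular_pressure_rules(self):
        bcs = pp.BoundaryConditionSet()
        # small vessels see alveolar pressure
        assert pp.extravascular_pressure(100e-6, 0.1, bcs, h_mid=0.1) == \
            bcs.alveolar_pressure
        # large vessels at mid-height see the reference recoil
        assert pp.extravascular_pressure(1e-3, 0.1, bcs, h_mid=0.1) == \
            pytest.approx(bcs.recoil_ref)
        # linear in height with the configured slope
        p1 = pp.extravascular_pressure(1e-3, 0.15, bcs, h_mid=0.1)
        p2 = pp.extravascular_pressure(1e-3, 0.05, bcs, h_mid=0.1)
        assert p1 - p2 == pytest.approx(bcs.recoil_slope * 0.1)
        assert ALVEOLAR_DIAMETER_THRESHOLD == 200e-6


def _single_tube():
    xyz = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]])
    return pp.VesselNetwork(
        node_xyz=xyz,
        elem_node_in=np.array([0]), elem_node_out=np.array([1]),
        elem_type=np.zeros(1, int), elem_D0=np.array([0.003]),
        elem_order=np.ones(1, int), elem_generation=np.ones(1, int),
        inlet_node=0, outlet_node=1)


class TestSolveNetwork:
    def test_single_rigid_tube_closed_form(self):
        net = _single_tube()
        Q = 2e-5
        bcs = pp.BoundaryConditionSet(inflows={0: Q},
                                      venous_outlet_pressure=666.0)
        state = pp.solve_network(net, bcs, pp.PostureContext.from_name("zero_g"),
                                 law=pp.ComplianceLaw(alpha=0.0))
        mu, L, D = 0.0035, 0.1, 0.003
        expected = 666.0 + 128 * mu * L * Q / (np.pi * D**4)
        assert state.node_pressure[0] == pytest.approx(expected, rel=1e-10)
        assert state.elem_flow[0] == pytest.approx(Q, rel=1e-12)

    def test_symmetric_bifurcation_splits_evenly(self):
        xyz = np.array([[0, 0, 0], [0.05, 0, 0], [0.1, 0.02, 0],
                        [0.1, -0.02, 0], [0.15, 0, 0]], float)
        net = pp.VesselNetwork(
            node_xyz=xyz,
            elem_node_in=np.array([0, 1, 1, 2, 3]),
            elem_node_out=np.array([1, 2, 3, 4, 4]),
            elem_type=np.zeros(5, int),
            elem_D0=np.array([4e-3, 2e-3, 2e-3, 2e-3, 2e-3]),
            elem_order=np.ones(5, int), elem_generation=np.ones(5, int),
            inlet_node=0, outlet_node=4)
        bcs = pp.BoundaryConditionSet(inflows={0: 1e-5})
        st = pp.solve_network(net, bcs, pp.PostureContext.from_name("zero_g"),
                              law=pp.ComplianceLaw(alpha=0.0))
        assert st.elem_flow[1] == pytest.approx(st.elem_flow[2], rel=1e-10)
        assert st.elem_flow[1] == pytest.approx(5e-6, rel=1e-10)

    def test_conservation_full_network(self, small_network, ladder):
        Q = pp.lmin_to_si(4.8)
        bcs = pp.BoundaryConditionSet(inflows={small_network.inlet_node: Q})
        st = pp.solve_network(small_network, bcs,
                              pp.PostureContext.from_name("supine"),
                              ladder=ladder)
        assert st.acinar_flow.sum() == pytest.approx(Q, rel=1e-8)
        assert st.converged

    def test_zero_gravity_invariant_to_posture_name(self, small_network, ladder):
        Q = pp.lmin_to_si(4.8)
        bcs = pp.BoundaryConditionSet(inflows={small_network.inlet_node: Q})
        sols = []
        for name in ("supine", "upright"):
            post = pp.PostureContext(name=name, g=0.0,
                                     gravity_dir=np.array([0.0, 1.0, 0.0])
                                     if name == "supine"
                                     else np.array([0.0, 0.0, -1.0]))
            st = pp.solve_network(small_network, bcs, post, ladder=ladder)
            sols.append(st.node_pressure)
        np.testing.assert_allclose(sols[0], sols[1], atol=1e-6)

    def test_pressure_drop_increases_with_cardiac_output(self, small_network,
                                                         ladder):
        pins = []
        for co in (4.0, 5.6):
            bcs = pp.BoundaryConditionSet(
                inflows={small_network.inlet_node: pp.lmin_to_si(co)})
            st = pp.solve_network(small_network, bcs,
                                  pp.PostureContext.from_name("zero_g"),
                                  ladder=ladder)
            pins.append(st.node_pressure[small_network.inlet_node])
        assert pins[1] > pins[0]

    def test_rigid_saturated_equals_single_linear_solve(self, toy_network):
        """With zero compliance and no acini the fixed-point loop must land
        exactly on the one-shot sparse solution of the rigid network."""
        import scipy.sparse.linalg as spla

        from pulmoperf.flow_solver import _SolverScratch, _assemble

        bcs = pp.BoundaryConditionSet(inflows={0: 3e-5, 1: 2e-5},
                                      include_macro_elements=True)
        post = pp.PostureContext.from_name("zero_g")
        st = pp.solve_network(toy_network, bcs, post,
                              law=pp.ComplianceLaw(alpha=0.0))
        sc = _SolverScratch.prepare(toy_network, bcs, post, None,
                                    pp.FluidProperties())
        A, rhs = _assemble(toy_network, bcs, sc, sc.D0,
                           np.zeros(0), pp.FluidProperties())
        direct = spla.spsolve(A, rhs)
        np.testing.assert_allclose(st.node_pressure, direct, atol=1e-9)

    def test_negative_inflow_rejected(self):
        with pytest.raises(ValueError):
            pp.BoundaryConditionSet(inflows={0: -1e-6})
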