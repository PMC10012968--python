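import threading
import time

import numpy as np
import pytest

import pulmoperf as pp
from pulmoperf.coupling import CouplingConfig, run_coupled
from pulmoperf.macro import (FileExchangeMacro, LumpedBifurcationParams,
                             serve_exchange_request)


def linear_macro(a_L=2e9, a_R=2.5e9, a_mpa=1e8):
    """A linear macro model whose branch resistances dominate the toy 1D
    tubes (~6e7 Pa s/m^3), so the plain constant-factor exchange loop is
    contractive and every scheme can be compared on the same problem."""
    return LumpedBifurcationParams(
        a={"LPA": a_L, "RPA": a_R}, b={"LPA": 0.0, "RPA": 0.0}, a_mpa=a_mpa,
        areas={"LPA": 3.77e-4, "RPA": 3.54e-4})


class TestUnderrelax:
    def test_full_factor_returns_new(self):
        assert pp.underrelax(2000.0, 1000.0, 1.0) == 2000.0

    def test_half_blend(self):
        assert pp.underrelax(2000.0, 1000.0, 0.5) == 1500.0

    def test_geometric_convergence(self):
        lam, target, x = 0.3, 5000.0, 0.0
        errs = []
        for _ in range(10):
            x = float(pp.underrelax(target, x, lam))
            errs.append(abs(x - target))
        ratios = np.array(errs[1:]) / np.array(errs[:-1])
        np.testing.assert_allclose(ratios, 1 - lam, rtol=1e-10)

    def test_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            pp.underrelax(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            pp.underrelax(1.0, 0.0, 1.5)


class TestCouplingError:
    def test_identical_pressures_converged(self):
        P = {"LPA": 2000.0, "RPA": 1900.0}
        assert pp.coupling_error(P, dict(P)) == 0.0

    def test_printed_sum_of_squares(self):
        e = pp.coupling_error({"LPA": 10.2, "RPA": 20.1},
                              {"LPA": 10.0, "RPA": 20.0})
        assert e == pytest.approx(0.05)
        assert e <= 0.1  # converged at the default threshold

    def test_single_interface_not_converged(self):
        e = pp.coupling_error({"LPA": 10.4}, {"LPA": 10.0})
        assert e == pytest.approx(0.16)
        assert e > 0.1

    def test_variants(self):
        a = {"LPA": 3.0, "RPA": 0.0}
        b = {"LPA": 0.0, "RPA": 4.0}
        assert pp.coupling_error(a, b, "max_abs") == 4.0
        assert pp.coupling_error(a, b, "rms") == pytest.approx(
            np.sqrt(12.5))

    def test_mismatched_interfaces_rejected(self):
        with pytest.raises(ValueError):
            pp.coupling_error({"LPA": 1.0}, {"RPA": 1.0})


def _monolithic_toy_solution(net, params, Q_in, P_out):
    """Direct resistor-network solution of macro + rigid toy 1D."""
    mu = 0.0035
    L = net.elem_length
    R1d = 128 * mu * L / (np.pi * net.elem_D0**4)
    # series: branch a_i + tube R_i from interface to outlet, in parallel
    RL = params.a["LPA"] + R1d[0]
    RR = params.a["RPA"] + R1d[1]
    QL = Q_in * RR / (RL + RR)
    QR = Q_in - QL
    P_junction = P_out + QL * RL
    return {
        "P_in": P_junction + params.a_mpa * Q_in,
        "P_LPA": P_out + QL * R1d[0],
        "P_RPA": P_out + QR * R1d[1],
        "Q_LPA": QL, "Q_RPA": QR,
    }


class TestRunCoupled:
    def test_linear_toy_matches_monolithic(self, toy_network):
        params = linear_macro()
        Q_in, P_out = 8e-5, 666.0
        exact = _monolithic_toy_solution(toy_network, params, Q_in, P_out)
        res = run_coupled(params, toy_network, Q_in,
                          pp.PostureContext.from_name("zero_g"),
                          config=CouplingConfig(flow_consistency_tol=1e-12),
                          bcs=pp.BoundaryConditionSet(
                              venous_outlet_pressure=P_out),
                          law=pp.ComplianceLaw(alpha=0.0))
        assert res.converged
        assert res.P_interface["LPA"] == pytest.approx(exact["P_LPA"],
                                                       abs=1e-8)
        assert res.P_interface["RPA"] == pytest.approx(exact["P_RPA"],
                                                       abs=1e-8)
        assert res.Q_interface["LPA"] == pytest.approx(exact["Q_LPA"],
                                                       rel=1e-8)
        assert res.inlet_pressure == pytest.approx(exact["P_in"], abs=1e-6)

    def test_constant_lambda_one_converges_fast_on_linear_toy(self):
        """On a fully symmetric linear problem the exchanged quantities are
        exact after one full sweep, so lambda = 1 settles within three
        iterations."""
        xyz = np.array([[-0.03, 0.0, 0.1], [0.03, 0.0, 0.1], [0.0, 0.0, 0.0]])
        net = pp.VesselNetwork(
            node_xyz=xyz,
            elem_node_in=np.array([0, 1]), elem_node_out=np.array([2, 2]),
            elem_type=np.array([0, 0]), elem_D0=np.array([0.004, 0.004]),
            elem_order=np.ones(2, int), elem_generation=np.ones(2, int),
            inlet_node=-1, outlet_node=2,
            interface_nodes={"LPA": 0, "RPA": 1})
        res = run_coupled(linear_macro(a_L=2e9, a_R=2e9), net, 8e-5,
                          pp.PostureContext.from_name("zero_g"),
                          config=CouplingConfig(lam=1.0, adaptive=False),
                          law=pp.ComplianceLaw(alpha=0.0))
        assert res.converged
        assert res.coupling.iterations <= 3
        assert res.Q_interface["LPA"] == pytest.approx(4e-5, rel=1e-10)

    def test_solution_independent_of_relaxation_factor(self, toy_network):
        sols = []
        for lam in (0.3, 0.7):
            res = run_coupled(linear_macro(), toy_network, 8e-5,
                              pp.PostureContext.from_name("zero_g"),
                              config=CouplingConfig(
                                  lam=lam, adaptive=False, epsilon=1e-10,
                                  flow_consistency_tol=1e-10),
                              law=pp.ComplianceLaw(alpha=0.0))
            assert res.converged
            sols.append(res.P_interface)
        for k in ("LPA", "RPA"):
            assert sols[0][k] == pytest.approx(sols[1][k], abs=1e-3)

    def test_interface_flows_sum_to_cardiac_output(self, toy_network):
        Q_in = 8e-5
        res = run_coupled(linear_macro(), toy_network, Q_in,
                          pp.PostureContext.from_name("zero_g"),
                          law=pp.ComplianceLaw(alpha=0.0))
        assert abs(sum(res.Q_interface.values()) - Q_in) / Q_in < 1e-10

    def test_error_trace_eventually_settles(self, toy_network):
        res = run_coupled(linear_macro(), toy_network, 8e-5,
                          pp.PostureContext.from_name("zero_g"),
                          law=pp.ComplianceLaw(alpha=0.0))
        trace = np.array(res.coupling.error_trace)
        # no growth over any trailing window once past the transient
        if len(trace) > 5:
            tail = trace[5:]
            assert np.all(np.diff(np.minimum.accumulate(tail)) <= 0)
        assert trace[-1] <= 0.1

    def test_external_macro_via_exchange_files(self, toy_network, tmp_path):
        """The built-in surrogate served over exchange files yields the same
        coupled solution as calling it in-process."""
        params = linear_macro()
        direct = run_coupled(params, toy_network, 8e-5,
                             pp.PostureContext.from_name("zero_g"),
                             law=pp.ComplianceLaw(alpha=0.0))

        bridge = FileExchangeMacro(tmp_path, poll_interval=0.005, timeout=30)
        stop = threading.Event()

        def responder():
            served = 0
            while not stop.is_set():
                k = served + 1
                if (tmp_path / f"request_{k}.json").exists():
                    serve_exchange_request(tmp_path, params, k)
                    served = k
                else:
                    time.sleep(0.005)

        t = threading.Thread(target=responder, daemon=True)
        t.start()
        try:
            via_files = run_coupled(params, toy_network, 8e-5,
                                    pp.PostureContext.from_name("zero_g"),
                                    law=pp.ComplianceLaw(alpha=0.0),
                                    macro_solver=bridge)
        finally:
            stop.set()
            t.join(timeout=5)
        for k in ("LPA", "RPA"):
            assert via_files.P_interface[k] == pytest.approx(
                direct.P_interface[k], abs=1e-6)
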