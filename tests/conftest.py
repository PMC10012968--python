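import numpy as np
import pytest

import pulmoperf as pp


@pytest.fixture(scope="session")
def small_network():
    """A 400-acinus circulation shared by solver-level tests."""
    return pp.build_circulation(n_acini=400, rng_seed=7)


@pytest.fixture(scope="session")
def ladder():
    return pp.LadderAcinus()


@pytest.fixture()
def sheet_params():
    return pp.CapillarySheetParams()


@pytest.fixture()
def toy_network():
    """Two parallel rigid tubes from the interface nodes to a common outlet.

    The minimal 1D side for coupling tests: no acini, linear once the
    compliance constant is zero.
    """
    xyz = np.array([
        [-0.03, 0.0, 0.10],   # 0: LPA interface
        [0.03, 0.0, 0.10],    # 1: RPA interface
        [0.0, 0.0, 0.0],      # 2: venous outlet
    ])
    return pp.VesselNetwork(
        node_xyz=xyz,
        elem_node_in=np.array([0, 1]),
        elem_node_out=np.array([2, 2]),
        elem_type=np.array([0, 0]),
        elem_D0=np.array([0.004, 0.005]),
        elem_order=np.array([1, 1]),
        elem_generation=np.array([1, 1]),
        inlet_node=-1,
        outlet_node=2,
        interface_nodes={"LPA": 0, "RPA": 1},
    )
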