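"""Steady-state solution of the full 1D pulmonary circulation.

Each vessel element obeys a modified Poiseuille law with a hydrostatic term,

    dP = 128 mu L Q / (pi D^4) + rho_b g L cos(theta),

where theta is the angle between the vessel centerline and gravity.  Vessel
diameter responds linearly to transmural pressure, D = D0 (1 + alpha Ptm),
floored at 0.1 D0.  Extravascular pressure is alveolar pressure for vessels
with D0 < 200 um and a linearly height-varying elastic-recoil (tethering)
pressure for larger vessels.  Terminal acini are the nonlinear ladder units
of :mod:`pulmoperf.capillary`.

The solver is a damped fixed-point outer loop: freeze diameters and acinar
conductances, assemble nodal flow-conservation as a sparse linear system in
pressures, solve, then update diameters/conductances from the new pressures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .capillary import LadderAcinus, LadderSolver
from .geometry import VesselNetwork
from .posture import PostureContext

ALVEOLAR_DIAMETER_THRESHOLD = 200e-6  # m: below this, extravascular P = alveolar


@dataclass(frozen=True)
class FluidProperties:
    mu: float = 0.0035  # blood viscosity, Pa s
    rho_b: float = 1050.0  # blood density, kg/m^3

    def __post_init__(self):
        if self.mu <= 0 or self.rho_b <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class ComplianceLaw:
    """Linear diameter-transmural-pressure law for extra-acinar vessels."""

    alpha: float = 1.49e-4  # Pa^-1
    diameter_floor_factor: float = 0.1

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("compliance constant must be >= 0")


@dataclass
class BoundaryConditionSet:
    """Flow inlet(s), venous outlet pressure, and extravascular references.

    ``inflows`` maps node id -> volumetric inflow (m^3/s).  For uncoupled
    runs this is the single MPA inlet; for coupled runs, the two macro/1D
    interface nodes.  ``include_macro_elements`` drops the MPA/LPA/RPA
    centerline elements when the macro model represents them instead.
    """

    inflows: dict = field(default_factory=dict)
    venous_outlet_pressure: float = 666.0  # Pa (~5 mmHg left atrium)
    alveolar_pressure: float = 0.0  # Pa (static breath-hold)
    recoil_ref: float = -500.0  # Pa at mid-height
    recoil_slope: float = -981.0  # Pa/m along height (tethering strongest up top)
    include_macro_elements: bool = True

    def __post_init__(self):
        if any(q < 0 for q in self.inflows.values()):
            raise ValueError("inflows must be >= 0")


@dataclass
class SolverOptions:
    damping: float = 0.5
    pressure_tol: float = 1e-4  # Pa, max nodal pressure change
    diameter_tol: float = 1e-6  # relative diameter change
    max_outer_iter: int = 500


@dataclass
class NetworkState:
    """Converged nodal/element solution plus per-acinus flows."""

    node_pressure: np.ndarray
    elem_flow: np.ndarray
    elem_diameter: np.ndarray
    acinar_flow: np.ndarray
    acinar_height: np.ndarray  # m, 0 at most dependent acinus
    rung_flows: np.ndarray | None
    converged: bool
    iterations: int
    residual_trace: np.ndarray


class SolverConvergenceError(RuntimeError):
    def __init__(self, msg, trace):
        super().__init__(msg)
        self.residual_trace = trace


# -- element-level relations (exposed for direct use and testing) ---------

def element_pressure_drop(L, D, Q, fluid: FluidProperties, cos_theta,
                          g: float, include_hydrostatic=True):
    """Pressure drop (Pa) along an element: Poiseuille + hydrostatic.

    ``cos_theta`` follows :meth:`PostureContext.cos_theta`: +1 for a vessel
    pointing straight up (blood loses 'rho g L' of static pressure climbing
    it).  The hydrostatic term applies to extra-acinar vessels only.
    """
    D = np.asarray(D, float)
    if np.any(D <= 0):
        raise ValueError("diameter must be positive")
    visc = 128.0 * fluid.mu * np.asarray(L) * np.asarray(Q) / (np.pi * D**4)
    hyd = fluid.rho_b * g * np.asarray(L) * np.asarray(cos_theta)
    return visc + np.where(include_hydrostatic, hyd, 0.0)


def update_diameter(D0, Ptm, law: ComplianceLaw):
    """D = D0 (1 + alpha Ptm), floored at ``diameter_floor_factor * D0``."""
    D0 = np.asarray(D0, float)
    if np.any(D0 <= 0):
        raise ValueError("unstrained diameter must be positive")
    D = D0 * (1.0 + law.alpha * np.asarray(Ptm, float))
    return np.maximum(D, law.diameter_floor_factor * D0)


def extravascular_pressure(D0, height, bcs: BoundaryConditionSet,
                           h_mid: float):
    """Alveolar pressure for D0 < 200 um, linear recoil profile otherwise."""
    D0 = np.asarray(D0, float)
    h = np.asarray(height, float)
    recoil = bcs.recoil_ref + bcs.recoil_slope * (h - h_mid)
    return np.where(D0 < ALVEOLAR_DIAMETER_THRESHOLD,
                    bcs.alveolar_pressure, recoil)


def solve_network(
    network: VesselNetwork,
    bcs: BoundaryConditionSet,
    posture: PostureContext,
    fluid: FluidProperties = FluidProperties(),
    law: ComplianceLaw = ComplianceLaw(),
    ladder: LadderAcinus | None = None,
    options: SolverOptions = SolverOptions(),
    warm_start: "_SolverScratch | None" = None,
) -> NetworkState:
    """Solve the circulation for nodal pressures, element and acinar flows.

    Boundary conditions are one or more nodal inflows plus a single venous
    outlet pressure (Dirichlet).  Pass ``warm_start`` (the ``scratch``
    attribute of a previous state for the same network/posture) to continue
    from an earlier solution, e.g. across coupling iterations.
    """
    scratch = warm_start or _SolverScratch.prepare(network, bcs, posture,
                                                   ladder, fluid)
    sc = scratch
    n_nodes = network.n_nodes
    opts = options

    P = sc.P.copy()
    D = sc.D.copy()
    G_ac = sc.G_ac.copy()

    trace = []
    converged = False
    for it in range(opts.max_outer_iter):
        A, rhs = _assemble(network, bcs, sc, D, G_ac, fluid)
        P_new = spla.spsolve(A.tocsr(), rhs)
        dP = np.abs(P_new - P).max() if it > 0 else np.inf
        P = P_new

        # pressure-dependent updates, damped
        Pmid = 0.5 * (P[sc.e_in] + P[sc.e_out])
        Ptm = Pmid - sc.P_ev
        D_new = update_diameter(sc.D0, Ptm, law)
        rel_dD = (np.abs(D_new - D) / sc.D0).max() if len(D) else 0.0
        D = opts.damping * D_new + (1 - opts.damping) * D

        if sc.ladder_solver is not None:
            P_art = P[network.acinus_art_node]
            P_ven = P[network.acinus_ven_node]
            Q_lad, rungs, _ = sc.ladder_solver.solve(P_art, P_ven)
            dPav = P_art - P_ven
            G_new = np.where(np.abs(dPav) > 1e-9, Q_lad / np.where(
                np.abs(dPav) > 1e-9, dPav, 1.0), G_ac)
            G_new = np.maximum(G_new, 1e-18)
            G_ac = opts.damping * G_new + (1 - opts.damping) * G_ac

        trace.append(dP)
        if it > 0 and dP < opts.pressure_tol and rel_dD < opts.diameter_tol:
            converged = True
            break

    if not converged:
        raise SolverConvergenceError(
            f"outer fixed-point did not converge in {opts.max_outer_iter} "
            f"iterations (last dP={trace[-1]:.3e} Pa)", np.array(trace))

    # final consistent flows from the last linear solve
    Q_e = np.zeros(network.n_elements)
    g_e = _element_conductance(sc, D, fluid)
    Q_e[sc.active] = g_e * (P[sc.e_in] - P[sc.e_out] - sc.hyd[sc.active])
    Q_ac = G_ac * (P[network.acinus_art_node] - P[network.acinus_ven_node]) \
        if network.n_acini else np.zeros(0)

    rungs_out = None
    if sc.ladder_solver is not None:
        _, rungs_out, _ = sc.ladder_solver.solve(
            P[network.acinus_art_node], P[network.acinus_ven_node])

    sc.P, sc.D, sc.G_ac = P, D, G_ac
    state = NetworkState(
        node_pressure=P,
        elem_flow=Q_e,
        elem_diameter=_full_diameter(network, sc, D),
        acinar_flow=Q_ac,
        acinar_height=sc.acinar_height,
        rung_flows=rungs_out,
        converged=True,
        iterations=it + 1,
        residual_trace=np.array(trace),
    )
    state.scratch = sc  # type: ignore[attr-defined]
    return state


def _full_diameter(network, sc, D):
    out = network.elem_D0.copy()
    out[sc.active] = D
    return out


def _element_conductance(sc, D, fluid):
    return np.pi * D**4 / (128.0 * fluid.mu * sc.L)


@dataclass
class _SolverScratch:
    """Precomputed geometry/BC arrays plus the damped iteration state."""

    active: np.ndarray  # active element ids
    e_in: np.ndarray
    e_out: np.ndarray
    L: np.ndarray
    D0: np.ndarray
    hyd: np.ndarray  # per-element rho g L cos(theta), full length array
    P_ev: np.ndarray  # extravascular pressure per active element
    acinar_height: np.ndarray
    ladder_solver: LadderSolver | None
    P: np.ndarray
    D: np.ndarray
    G_ac: np.ndarray

    @classmethod
    def prepare(cls, network, bcs, posture, ladder,
                fluid: FluidProperties = FluidProperties()):
        n_e = network.n_elements
        active = np.arange(n_e)
        if not bcs.include_macro_elements and len(network.macro_element_ids):
            active = np.setdiff1d(active, network.macro_element_ids)
        e_in = network.elem_node_in[active]
        e_out = network.elem_node_out[active]
        L_all = network.elem_length
        L = L_all[active]
        D0 = network.elem_D0[active]

        cosq = posture.cos_theta(network.node_xyz[network.elem_node_in],
                                 network.node_xyz[network.elem_node_out])
        hyd = fluid.rho_b * posture.g * L_all * cosq

        node_h = posture.heights(network.node_xyz)
        h_mid = 0.5 * (node_h.max() + node_h.min())
        h_elem = 0.5 * (node_h[e_in] + node_h[e_out])
        # the recoil gradient is gravity-induced: it scales with g and
        # vanishes in weightlessness (posture then has no influence at all)
        from dataclasses import replace as _replace

        g_scale = posture.g / 9.81
        bcs_eff = _replace(bcs, recoil_slope=bcs.recoil_slope * g_scale) \
            if isinstance(bcs, BoundaryConditionSet) else bcs
        P_ev = extravascular_pressure(D0, h_elem, bcs_eff, h_mid)

        ac_h = node_h[network.acinus_art_node] if network.n_acini else np.zeros(0)
        if network.n_acini:
            ac_h = ac_h - ac_h.min()

        ladder_solver = None
        G0 = np.zeros(0)
        if ladder is not None and network.n_acini:
            from dataclasses import replace

            lad = replace(ladder, n_acini=network.n_acini,
                          alveolar_pressure=bcs.alveolar_pressure)
            ladder_solver = LadderSolver(
                lad, sa_weights=network.acinus_sa_weight)
            G0 = np.full(network.n_acini,
                         1e-11 * lad.n_merge, float)
        elif network.n_acini:
            raise ValueError("network has acini but no ladder model given")

        P0 = np.full(network.n_nodes, bcs.venous_outlet_pressure + 800.0)
        P0[network.outlet_node] = bcs.venous_outlet_pressure
        return cls(active=active, e_in=e_in, e_out=e_out, L=L, D0=D0,
                   hyd=hyd, P_ev=P_ev, acinar_height=ac_h,
                   ladder_solver=ladder_solver, P=P0, D=D0.copy(), G_ac=G0)


def _assemble(network, bcs, sc, D, G_ac, fluid):
    """Sparse nodal conservation system with the outlet pressure pinned."""
    n = network.n_nodes
    g_e = _element_conductance(sc, D, fluid)
    hyd = sc.hyd[sc.active]
    rhs = np.zeros(n)

    i_arr, j_arr = sc.e_in, sc.e_out
    rows_np = np.concatenate([i_arr, i_arr, j_arr, j_arr])
    cols_np = np.concatenate([i_arr, j_arr, j_arr, i_arr])
    vals_np = np.concatenate([g_e, -g_e, g_e, -g_e])
    # hydrostatic head contributes to the RHS: flow through an element is
    # Q = g (P_in - P_out - rho g L cos_theta), with cos_theta > 0 uphill
    np.add.at(rhs, i_arr, g_e * hyd)
    np.add.at(rhs, j_arr, -g_e * hyd)

    if network.n_acini:
        a = network.acinus_art_node
        v = network.acinus_ven_node
        rows_np = np.concatenate([rows_np, a, a, v, v])
        cols_np = np.concatenate([cols_np, a, v, v, a])
        vals_np = np.concatenate([vals_np, G_ac, -G_ac, G_ac, -G_ac])

    for node, q in bcs.inflows.items():
        rhs[node] += q

    out = network.outlet_node
    # Dirichlet at the outlet, identity rows for nodes cut off from the
    # active subnetwork (e.g. the MPA trunk when the macro model owns it)
    degree = np.bincount(rows_np, minlength=n)
    pinned = np.flatnonzero(degree == 0)
    pinned = pinned[pinned != out]
    keep = rows_np != out
    rows_np, cols_np, vals_np = rows_np[keep], cols_np[keep], vals_np[keep]
    pin_rows = np.concatenate([[out], pinned])
    rows_np = np.concatenate([rows_np, pin_rows])
    cols_np = np.concatenate([cols_np, pin_rows])
    vals_np = np.concatenate([vals_np, np.ones(len(pin_rows))])
    rhs[pinned] = bcs.venous_outlet_pressure
    rhs[out] = bcs.venous_outlet_pressure
    A = sp.coo_matrix((vals_np, (rows_np, cols_np)), shape=(n, n))
    return A.tocsr(), rhs
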