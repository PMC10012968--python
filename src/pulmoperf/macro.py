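"""Lumped macro-scale model of the MPA/LPA/RPA junction.

The macro domain fulfils one contract: given the cardiac inflow at the main
pulmonary artery and a pressure at each of its two outlets (the LPA and RPA
interfaces with the 1D network), return the outlet flows, the inlet
pressure, and wall-shear diagnostics, with the outlet flows summing exactly
to the inflow.

The built-in surrogate is a nonlinear lumped bifurcation: each branch obeys

    P_junction - P_i = a_i Q_i + b_i Q_i |Q_i|,

a linear (Poiseuille) coefficient plus a convective/minor-loss term that
gives the convex, flow-dependent resistance characteristic of 3D flow in
these vessels.  The inlet adds a linear MPA drop.  A real external CFD
solver can replace the surrogate through the exchange-file interface in
:mod:`pulmoperf.io` without touching the coupling loop.

The wall-shear metric exposed here is an explicit Poiseuille-tube analogue
(tau = 32 mu Q / (pi D^3), area-weighted over the three vessels); it is an
approximation and is not comparable in magnitude to wall shear stress
integrated over a real 3D luminal surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import LPA_AREA, MPA_AREA, RPA_AREA, area_to_diameter

#: assumed axial lengths of the lumped macro vessels, m
MPA_LENGTH = 0.05
BRANCH_LENGTH = 0.03


@dataclass(frozen=True)
class LumpedBifurcationParams:
    """Coefficients of the two-outlet macro surrogate.

    ``a`` maps branch name -> linear coefficient (Pa s/m^3); ``b`` maps
    branch name -> quadratic (minor-loss) coefficient (Pa s^2/m^6);
    ``areas`` are branch cross-sections (m^2) used for shear diagnostics
    and calibration.
    """

    a: dict = field(default_factory=dict)
    b: dict = field(default_factory=dict)
    a_mpa: float = 0.0
    areas: dict = field(default_factory=dict)
    mpa_area: float = MPA_AREA

    def __post_init__(self):
        if any(v <= 0 for v in self.a.values()):
            raise ValueError("linear coefficients must be positive")
        if any(v < 0 for v in self.b.values()):
            raise ValueError("loss coefficients must be >= 0")

    @property
    def interfaces(self) -> tuple:
        return tuple(sorted(self.a))


@dataclass(frozen=True)
class SawssRecord:
    """Poiseuille-analogue wall shear stress per vessel and area-weighted."""

    tau: dict  # Pa per vessel name (incl. "MPA")
    area_weighted: float  # Pa

    @property
    def area_weighted_dyne_cm2(self) -> float:
        return 10.0 * self.area_weighted


def poiseuille_resistance(L: float, D: float, mu: float) -> float:
    return 128.0 * mu * L / (np.pi * D**4)


def sawss_poiseuille(Q: float, D: float, mu: float = 0.0035) -> float:
    """Wall shear stress of Poiseuille flow in a tube: tau = 32 mu Q/(pi D^3)."""
    if D <= 0:
        raise ValueError("diameter must be positive")
    return 32.0 * mu * abs(Q) / (np.pi * D**3)


def _branch_flow(dP, a, b):
    """Invert dP = a Q + b Q |Q| for Q (monotone, sign-symmetric)."""
    s = np.sign(dP)
    m = abs(dP)
    if b == 0.0:
        return s * m / a
    return s * (-a + np.sqrt(a * a + 4.0 * b * m)) / (2.0 * b)


def surrogate_solve(Q_in: float, P_out: dict,
                    params: LumpedBifurcationParams,
                    mu: float = 0.0035):
    """Solve the lumped bifurcation for outlet flows and inlet pressure.

    ``P_out`` maps interface name ("LPA"/"RPA") -> outlet pressure (Pa).
    Returns ``(P_in, Q_out, sawss)`` with ``sum(Q_out.values()) == Q_in`` to
    machine precision.  The junction pressure is found by a bracketed
    scalar root-find on the flow-balance residual (tolerance 1e-9 Pa).
    """
    if Q_in < 0:
        raise ValueError("inlet flow must be >= 0")
    names = params.interfaces
    if set(P_out) != set(names):
        raise ValueError(f"outlet pressures must be given for {names}")

    def excess(Pj):
        return sum(_branch_flow(Pj - P_out[k], params.a[k], params.b[k])
                   for k in names) - Q_in

    lo = min(P_out.values())
    # at Pj = lo, every branch flow <= 0, so excess <= -Q_in <= 0
    span = max(1.0, Q_in * max(params.a.values()))
    hi = lo + span
    for _ in range(80):
        if excess(hi) >= 0.0:
            break
        span *= 2.0
        hi = lo + span
    else:  # pragma: no cover
        raise RuntimeError("could not bracket the junction pressure")
    if excess(lo) == 0.0:
        Pj = lo
    else:
        Pj = brentq(excess, lo, hi, xtol=1e-9)

    Q_raw = {k: _branch_flow(Pj - P_out[k], params.a[k], params.b[k])
             for k in names}
    total = sum(Q_raw.values())
    # distribute the (tiny) root-finding remainder so conservation is exact
    if Q_in > 0 and total > 0:
        Q_out = {k: q * (Q_in / total) for k, q in Q_raw.items()}
    else:
        Q_out = {k: q - (total - Q_in) / len(names) for k, q in Q_raw.items()}
    P_in = Pj + params.a_mpa * Q_in

    tau = {"MPA": sawss_poiseuille(Q_in, area_to_diameter(params.mpa_area), mu)}
    areas = {"MPA": params.mpa_area}
    for k in names:
        A = params.areas.get(k, params.mpa_area)
        tau[k] = sawss_poiseuille(Q_out[k], area_to_diameter(A), mu)
        areas[k] = A
    wsum = sum(areas.values())
    sawss = SawssRecord(tau=tau,
                        area_weighted=sum(tau[k] * areas[k] for k in tau) / wsum)
    return P_in, Q_out, sawss


def branch_residuals(P_in, Q_out, P_out, params: LumpedBifurcationParams):
    """Residual (Pa) of each branch law at a reported operating point."""
    Pj = P_in - params.a_mpa * sum(Q_out.values())
    return {k: (Pj - P_out[k])
            - (params.a[k] * Q_out[k] + params.b[k] * Q_out[k] * abs(Q_out[k]))
            for k in params.interfaces}


class FileExchangeMacro:
    """Macro solver served over exchange files by an external CFD process.

    Each call writes ``request_<k>.json`` (iteration, inlet flow, outlet
    pressures) into the exchange directory and blocks until the counterpart
    writes ``response_<k>.json`` carrying outlet flows and inlet pressure.
    The payloads use the exchange-record schema of :mod:`pulmoperf.io`.
    """

    def __init__(self, directory, poll_interval: float = 0.05,
                 timeout: float = 3600.0, mpa_area: float = MPA_AREA,
                 areas: dict | None = None, mu: float = 0.0035):
        from pathlib import Path

        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.poll = poll_interval
        self.timeout = timeout
        self.iteration = 0
        self.mpa_area = mpa_area
        self.areas = areas or {"LPA": LPA_AREA, "RPA": RPA_AREA}
        self.mu = mu

    def __call__(self, Q_in: float, P_out: dict):
        import time

        from .io import read_exchange, write_exchange

        self.iteration += 1
        k = self.iteration
        write_exchange({
            "iteration": k,
            "inlet_flow_m3s": float(Q_in),
            "outlet": [{"id": name, "pressure_Pa": float(p), "flow_m3s": None}
                       for name, p in sorted(P_out.items())],
            "inlet_pressure_Pa": None,
        }, self.dir / f"request_{k}.json")
        resp_path = self.dir / f"response_{k}.json"
        deadline = time.monotonic() + self.timeout
        while not resp_path.exists():
            if time.monotonic() > deadline:
                raise TimeoutError(f"no macro response for iteration {k}")
            time.sleep(self.poll)
        rec = read_exchange(resp_path)
        Q_out = {o["id"]: float(o["flow_m3s"]) for o in rec["outlet"]}
        P_in = float(rec["inlet_pressure_Pa"])
        tau = {"MPA": sawss_poiseuille(Q_in, area_to_diameter(self.mpa_area),
                                       self.mu)}
        areas = {"MPA": self.mpa_area, **self.areas}
        for name, q in Q_out.items():
            tau[name] = sawss_poiseuille(
                q, area_to_diameter(self.areas[name]), self.mu)
        w = sum(areas.values())
        return P_in, Q_out, SawssRecord(
            tau=tau, area_weighted=sum(tau[k2] * areas[k2] for k2 in tau) / w)


def serve_exchange_request(directory, params: LumpedBifurcationParams,
                           iteration: int, mu: float = 0.0035) -> None:
    """Answer one pending exchange request with the built-in surrogate.

    Utility for demonstrations and tests of the external-CFD mode: a real
    CFD wrapper would implement the same read-solve-write cycle.
    """
    from pathlib import Path

    from .io import read_exchange, write_exchange

    d = Path(directory)
    req = read_exchange(d / f"request_{iteration}.json")
    P_out = {o["id"]: o["pressure_Pa"] for o in req["outlet"]}
    P_in, Q_out, _ = surrogate_solve(req["inlet_flow_m3s"], P_out, params, mu)
    write_exchange({
        "iteration": iteration,
        "inlet_flow_m3s": req["inlet_flow_m3s"],
        "outlet": [{"id": name, "pressure_Pa": P_out[name],
                    "flow_m3s": Q_out[name]} for name in sorted(Q_out)],
        "inlet_pressure_Pa": P_in,
    }, d / f"response_{iteration}.json")


def default_macro_params(
    mu: float = 0.0035,
    rho_b: float = 1050.0,
    calibration_flow: float = 8.0e-5,  # 4.8 L/min in m^3/s
    lpa_fraction_target: float = 0.5285,
) -> LumpedBifurcationParams:
    """Build and calibrate the standard surrogate.

    Linear coefficients come from Poiseuille resistance of the equivalent
    cylinders (areas from the recorded macro-vessel cross-sections, lengths
    5 cm MPA / 3 cm branches).  The loss coefficients are b_i = K rho_b /
    (2 A_i^2) with a single K calibrated so that, under equal outlet
    pressures at 4.8 L/min, the LPA carries ``lpa_fraction_target`` of the
    inflow (mid-point of the 52.5-53.2 % band characteristic of 3D flow in
    this junction).
    """
    areas = {"LPA": LPA_AREA, "RPA": RPA_AREA}
    a = {k: poiseuille_resistance(BRANCH_LENGTH, area_to_diameter(A), mu)
         for k, A in areas.items()}
    a_mpa = poiseuille_resistance(MPA_LENGTH, area_to_diameter(MPA_AREA), mu)

    def lpa_fraction(K):
        params = LumpedBifurcationParams(
            a=a, b={k: K * rho_b / (2.0 * A * A) for k, A in areas.items()},
            a_mpa=a_mpa, areas=areas)
        _, Q, _ = surrogate_solve(calibration_flow,
                                  {"LPA": 0.0, "RPA": 0.0}, params, mu)
        return Q["LPA"] / calibration_flow

    f0 = lpa_fraction(0.0)
    if f0 <= lpa_fraction_target:
        K = 0.0
    else:
        K_hi = 1.0
        for _ in range(60):
            if lpa_fraction(K_hi) < lpa_fraction_target:
                break
            K_hi *= 4.0
        K = brentq(lambda K: lpa_fraction(K) - lpa_fraction_target, 0.0, K_hi,
                   xtol=1e-6)
    return LumpedBifurcationParams(
        a=a, b={k: K * rho_b / (2.0 * A * A) for k, A in areas.items()},
        a_mpa=a_mpa, areas=areas)
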