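"""Sheet-flow capillary model and the series-parallel ("ladder") acinus.

The pulmonary capillary bed is modelled as flow between two compliant
membranes (Fung's sheet-flow description).  The sheet height H responds to
transmural pressure Ptm (blood minus alveolar pressure):

    H = 0                      Ptm < 0        (collapsed, West zone 1)
    H = H0 + alpha_c * Ptm     0 <= Ptm < PCU (compliant / recruiting)
    H = Hmax                   Ptm >= PCU     (fully distended)

with PCU = (Hmax - H0)/alpha_c.  Sheet flow integrates H^3 between the
venous- and arterial-side transmural pressures,

    Q = SA / (mu_c * f * lc^2) * integral(H^3 dPtm),

which has a piecewise closed form (collapsed segments contribute nothing,
the compliant segment integrates to a quartic, the distended segment is
linear).  A negative venous-side Ptm clamps the lower limit to zero: the
zone-2 "waterfall".

An acinus is a 9-generation ladder: symmetric arteriole and venule chains
(2^(g-1) parallel vessels in generation g) joined at every generation by one
lumped capillary sheet.  :class:`LadderSolver` solves many such ladders at
once with a vectorized damped-Newton iteration; it is the terminal boundary
model of the 1D network solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import N_ACINI_REFERENCE


@dataclass(frozen=True)
class CapillarySheetParams:
    """Micro-circulatory constants (SI units).

    Defaults are the model's standard parameter set: unstrained/maximal sheet
    heights and sheet compliance from ex-vivo morphometry, capillary blood
    viscosity, the sheet-flow numerical factor f, the arteriole-to-venule
    path length, and the whole-lung capillary surface area.
    """

    H0: float = 3.5e-6  # unstrained sheet height, m
    Hmax: float = 7.7e-6  # maximum sheet height, m
    alpha_c: float = 1.3e-9  # sheet compliance, m/Pa
    mu_c: float = 0.0019  # capillary blood viscosity, Pa s
    f: float = 21.6  # sheet-flow numerical factor
    l_c: float = 1186e-6  # average arteriole->venule path length, m
    SA_total: float = 65.4  # total capillary surface area, m^2

    def __post_init__(self):
        if not (self.Hmax > self.H0 > 0):
            raise ValueError("need Hmax > H0 > 0")
        if min(self.alpha_c, self.mu_c, self.f, self.l_c, self.SA_total) <= 0:
            raise ValueError("all sheet parameters must be positive")

    @property
    def P_CU(self) -> float:
        """Upper recruitment pressure: sheet height saturates above this."""
        return (self.Hmax - self.H0) / self.alpha_c


def sheet_height(Ptm, params: CapillarySheetParams):
    """Capillary sheet height H(Ptm); continuous and non-decreasing."""
    P = np.asarray(Ptm, dtype=float)
    H = np.where(
        P < 0.0, 0.0,
        np.where(P < params.P_CU, params.H0 + params.alpha_c * P, params.Hmax),
    )
    return H if P.ndim else float(H)


def _cumulative_H3_integral(P, params: CapillarySheetParams):
    """F(P) = integral of H(p)^3 dp from 0 to P (F = 0 for P <= 0)."""
    P = np.asarray(P, dtype=float)
    a, H0, Hmax, Pcu = params.alpha_c, params.H0, params.Hmax, params.P_CU
    Pc = np.clip(P, 0.0, Pcu)
    F = ((H0 + a * Pc) ** 4 - H0**4) / (4.0 * a)
    F = F + Hmax**3 * np.maximum(P - Pcu, 0.0)
    return F


def sheet_flow(Ptm_art, Ptm_ven, params: CapillarySheetParams,
               SA_sheet: float):
    """Flow (m^3/s) through one capillary sheet of surface area ``SA_sheet``.

    Antisymmetric in its pressure arguments; zero when both sides are
    collapsed (zone 1); the collapsed venous side clamps the lower
    integration limit at zero (zone 2 waterfall).
    """
    coeff = SA_sheet / (params.mu_c * params.f * params.l_c**2)
    q = coeff * (_cumulative_H3_integral(Ptm_art, params)
                 - _cumulative_H3_integral(Ptm_ven, params))
    return q if np.ndim(q) else float(q)


def sheet_conductance(Ptm, params: CapillarySheetParams, SA_sheet: float):
    """dQ/dPtm_art = coeff * H(Ptm)^3 (used in Newton Jacobians)."""
    coeff = SA_sheet / (params.mu_c * params.f * params.l_c**2)
    return coeff * sheet_height(Ptm, params) ** 3


@dataclass(frozen=True)
class LadderAcinus:
    """Geometry of the 9-generation intra-acinar ladder.

    The template is fixed: generation-1 arterioles/venules of 210 um
    diameter and 1 mm length, shrinking by a factor 0.8 in both diameter and
    length per generation, with 2^(g-1) parallel vessels in generation g.
    Generation 1 of the (merged, see below) unit corresponds to a pre-acinar
    vessel feeding a few anatomical acini; its caliber is set so the whole
    model reproduces a mean pulmonary artery pressure of ~2.2 kPa at a
    cardiac output of 4.8 L/min, the characteristic operating point of the
    full-scale anatomy.  Intra-acinar vessels are below the 200 um threshold, so
    they are compliant against *alveolar* pressure,
    D = D0 (1 + alpha (P_blood - P_alv)), floored at 0.1 D0; the
    hydrostatic term is neglected at this scale.

    In a scaled-down network each model acinus stands for
    ``n_reference / n_acini`` anatomical acini lumped in parallel; all ladder
    conductances (vessels and sheets) are multiplied by that factor, which
    keeps per-acinus pressures and the pressure-flow curve approximately
    independent of the resolved acinar count.
    """

    n_generations: int = 9
    D1: float = 210e-6  # generation-1 (pre-acinar feeder) diameter, m
    L1: float = 1.0e-3  # generation-1 segment length, m
    diameter_ratio: float = 0.8
    length_ratio: float = 0.8
    mu_blood: float = 0.0035  # Pa s, intra-acinar (extra-capillary) viscosity
    alveolar_pressure: float = 0.0  # Pa, static breath-hold
    alpha: float = 1.49e-4  # Pa^-1: D(Ptm) compliance of ladder segments
    diameter_floor_factor: float = 0.1
    sheet: CapillarySheetParams = field(default_factory=CapillarySheetParams)
    n_acini: int = N_ACINI_REFERENCE
    n_reference: int = N_ACINI_REFERENCE

    @property
    def n_merge(self) -> float:
        return self.n_reference / self.n_acini

    @property
    def SA_sheet(self) -> float:
        """Surface area of one lumped sheet: equal split of the whole-lung
        capillary surface over all acini and all rungs."""
        return self.sheet.SA_total / (self.n_acini * self.n_generations)

    def segment_conductances(self) -> np.ndarray:
        """Per-generation lumped Poiseuille conductance (m^3 s^-1 Pa^-1) of
        the arteriole (= venule) chain, including parallel counts and the
        parallel-merge factor."""
        g = np.arange(1, self.n_generations + 1)
        D = self.D1 * self.diameter_ratio ** (g - 1)
        L = self.L1 * self.length_ratio ** (g - 1)
        single = np.pi * D**4 / (128.0 * self.mu_blood * L)
        return single * 2.0 ** (g - 1) * self.n_merge


class LadderSolver:
    """Vectorized Kirchhoff solution of many identical-template ladders.

    Unknowns per acinus: arteriole node pressures Pa_1..G and venule node
    pressures Pv_1..G.  Residuals are flow balances at every node; sheets are
    the only nonlinearity.  A Newton iteration with backtracking (halving)
    damping is used; iterates are warm-started between calls.
    """

    def __init__(self, ladder: LadderAcinus, n_acini: int | None = None,
                 sa_weights: np.ndarray | None = None):
        self.ladder = ladder
        self.n = int(n_acini if n_acini is not None else ladder.n_acini)
        G = ladder.n_generations
        self.G = G
        cond = ladder.segment_conductances()
        self.ga0 = np.broadcast_to(cond, (self.n, G))
        self.gv0 = self.ga0
        # SA_sheet already carries the parallel-merge scaling (it divides the
        # whole-lung surface area by the resolved acinar count).  Optional
        # per-acinus size weights scale the whole unit: sheet surface area
        # and the parallel arteriole/venule counts alike, since a larger
        # acinus has proportionally more micro-vascular paths.
        if sa_weights is not None and len(sa_weights):
            w = np.asarray(sa_weights, float)
            if len(w) != self.n:
                raise ValueError("sa_weights length must equal acinar count")
            self.coeff = ladder.SA_sheet * w[:, None]
            self.ga0 = self.ga0 * w[:, None]
            self.gv0 = self.ga0
        else:
            self.coeff = ladder.SA_sheet
        self._X = None  # warm-start state (n, 2G)

    # -- residual and Jacobian -------------------------------------------
    def _segment_conductances_at(self, X, P_in, P_out):
        """Compliant segment conductances at the current pressure state:
        the base Poiseuille value scaled by (1 + alpha Ptm)^4 evaluated at
        each segment's mean blood pressure (floored at the collapse limit)."""
        lad, G = self.ladder, self.G
        Pa, Pv = X[:, :G], X[:, G:]
        Pa_up = np.concatenate([P_in[:, None], Pa[:, :-1]], axis=1)
        Pv_up = np.concatenate([P_out[:, None], Pv[:, :-1]], axis=1)
        Ptm_a = 0.5 * (Pa_up + Pa) - lad.alveolar_pressure
        Ptm_v = 0.5 * (Pv_up + Pv) - lad.alveolar_pressure
        floor = lad.diameter_floor_factor
        fa = np.clip(1.0 + lad.alpha * Ptm_a, floor, None) ** 4
        fv = np.clip(1.0 + lad.alpha * Ptm_v, floor, None) ** 4
        return self.ga0 * fa, self.gv0 * fv

    def _residual(self, X, P_in, P_out):
        lad, G = self.ladder, self.G
        Pa, Pv = X[:, :G], X[:, G:]
        Palv = lad.alveolar_pressure
        Pa_up = np.concatenate([P_in[:, None], Pa[:, :-1]], axis=1)
        Pv_up = np.concatenate([P_out[:, None], Pv[:, :-1]], axis=1)
        ga, gv = self._segment_conductances_at(X, P_in, P_out)
        Qa = ga * (Pa_up - Pa)  # arteriole flow into node g
        Qv = gv * (Pv - Pv_up)  # venule flow from node g toward outlet
        Qs = sheet_flow(Pa - Palv, Pv - Palv, lad.sheet, self.coeff)
        Qa_next = np.concatenate([Qa[:, 1:], np.zeros((len(X), 1))], axis=1)
        Qv_next = np.concatenate([Qv[:, 1:], np.zeros((len(X), 1))], axis=1)
        Ra = Qa - Qs - Qa_next
        Rv = Qs + Qv_next - Qv
        return np.concatenate([Ra, Rv], axis=1), Qa, Qs

    def _jacobian(self, X, P_in, P_out):
        """Quasi-Newton Jacobian: segment conductances are evaluated at the
        current state but held fixed (their pressure derivative is omitted);
        the sheet nonlinearity carries exact derivatives."""
        lad, G = self.ladder, self.G
        n = len(X)
        Pa, Pv = X[:, :G], X[:, G:]
        Palv = lad.alveolar_pressure
        gsa = sheet_conductance(Pa - Palv, lad.sheet, self.coeff)
        gsv = sheet_conductance(Pv - Palv, lad.sheet, self.coeff)
        ga, gv = self._segment_conductances_at(X, P_in, P_out)
        J = np.zeros((n, 2 * G, 2 * G))
        idx = np.arange(G)
        ga_next = np.concatenate([ga[:, 1:], np.zeros((n, 1))], axis=1)
        gv_next = np.concatenate([gv[:, 1:], np.zeros((n, 1))], axis=1)
        # arteriole residual rows 0..G-1
        J[:, idx, idx] = -ga - gsa - ga_next
        J[:, idx[1:], idx[:-1]] = ga[:, 1:]
        J[:, idx[:-1], idx[1:]] = ga_next[:, :-1]
        J[:, idx, G + idx] = gsv
        # venule residual rows G..2G-1
        J[:, G + idx, G + idx] = -gv - gsv - gv_next
        J[:, G + idx[1:], G + idx[:-1]] = gv[:, 1:]
        J[:, G + idx[:-1], G + idx[1:]] = gv_next[:, :-1]
        J[:, G + idx, idx] = gsa
        return J

    def solve(self, P_in, P_out, tol: float = 1e-8, max_iter: int = 200):
        """Solve all ladders for boundary pressures ``P_in``/``P_out`` (Pa).

        Returns ``(Q_total, rung_flows, X)`` with Q_total (n,) the acinar
        flow, rung_flows (n, G) the per-sheet flows, and X the internal
        pressure state.  Raises :class:`LadderConvergenceError` if the
        Newton iteration stalls.
        """
        P_in = np.broadcast_to(np.asarray(P_in, float), (self.n,)).copy()
        P_out = np.broadcast_to(np.asarray(P_out, float), (self.n,)).copy()
        G = self.G
        if self._X is None or len(self._X) != self.n:
            # initialize by linear interpolation between boundary pressures
            t = (np.arange(1, G + 1) / (G + 1.0))[None, :]
            Pa0 = P_in[:, None] * (1 - 0.5 * t) + P_out[:, None] * 0.5 * t
            Pv0 = P_out[:, None] * (1 - 0.5 * t) + P_in[:, None] * 0.5 * t
            X = np.concatenate([Pa0, Pv0], axis=1)
        else:
            X = self._X.copy()
        R, _, _ = self._residual(X, P_in, P_out)
        rnorm = np.abs(R).max(axis=1)
        for _ in range(max_iter):
            J = self._jacobian(X, P_in, P_out)
            dx = np.linalg.solve(J, -R[..., None])[..., 0]
            step = np.ones(len(X))
            for _bt in range(6):
                X_try = X + step[:, None] * dx
                R_try, _, _ = self._residual(X_try, P_in, P_out)
                r_try = np.abs(R_try).max(axis=1)
                worse = (r_try > rnorm) & (r_try > 1e-16)
                if not worse.any():
                    break
                step[worse] *= 0.5  # damped-Newton fallback
            X = X + step[:, None] * dx
            R, _, _ = self._residual(X, P_in, P_out)
            rnorm = np.abs(R).max(axis=1)
            if np.abs(step[:, None] * dx).max() < tol:
                break
        else:
            scale = np.maximum(np.abs(P_in - P_out), 1.0)
            if (np.abs(dx).max(axis=1) > 1e-6 * scale).any():
                raise LadderConvergenceError(
                    f"ladder Newton stalled; max residual {rnorm.max():.3e}")
        self._X = X
        R, Qa, Qs = self._residual(X, P_in, P_out)
        return Qa[:, 0], Qs, X


class LadderConvergenceError(RuntimeError):
    """Raised when the intra-acinar Newton iteration fails to converge."""


def solve_ladder(P_in: float, P_out: float, P_alv: float,
                 ladder: LadderAcinus):
    """Solve a single ladder acinus.

    Returns ``(Q_total, rung_flows, internal_pressures)``; the internal
    pressure vector is ordered [Pa_1..Pa_G, Pv_1..Pv_G].
    """
    lad = ladder if ladder.alveolar_pressure == P_alv else \
        _with_alveolar(ladder, P_alv)
    solver = LadderSolver(lad, n_acini=1)
    Q, Qs, X = solver.solve(np.array([P_in]), np.array([P_out]))
    return float(Q[0]), Qs[0], X[0]


def _with_alveolar(ladder: LadderAcinus, P_alv: float) -> LadderAcinus:
    from dataclasses import replace

    return replace(ladder, alveolar_pressure=P_alv)
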