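# Methods

This note documents the model implemented by `pulmoperf`: its equations and
assumptions, the parameters that matter (with units, defaults and
provenance), what the synthetic geometry generator does and does not
emulate, the numerical schemes, and the design choices made where the
design was genuinely open.

## 1. Model structure

The circulation is resolved at three scales:

1. **Macro vessels** (main, left and right pulmonary arteries): a lumped
   nonlinear bifurcation, `P_junction − P_i = a_i Q̇_i + b_i Q̇_i|Q̇_i|`
   per branch plus a linear MPA term, standing in for a 3D CFD domain.
2. **1D network**: centerline elements from the two macro/1D interfaces
   (at the lung hila) through bifurcating arterial trees to ~10⁴ acini and
   back through mirrored venous trees to a single left-atrial outlet.
3. **Micro-circulation**: each acinus is a 9-generation "ladder" of
   symmetric arteriole/venule chains bridged at every generation by a
   compliant capillary sheet.

### 1D vessel elements

Pressure–flow in every extra-capillary vessel follows a modified Poiseuille
law, `ΔP = 128 μ L Q̇/(π D⁴) + ρ_b g L cos θ`, with θ measured against the
ascending direction (blood loses `ρ g L` of static pressure climbing a
vertical vessel).  Kirchhoff continuity holds at every junction.  Diameters
follow `D = D₀(1 + α P_tm)` floored at `0.1 D₀`; transmural pressure is the
element's mean blood pressure minus its extravascular pressure, which is

* **alveolar pressure** (default 0 Pa, a static breath-hold) for vessels
  with `D₀ < 200 µm` — in this network, the intra-acinar segments;
* **elastic recoil** for larger vessels: `P_ev(h) = P_ref + m·(h − h_mid)`
  with `P_ref = −500 Pa` and `m = −981 Pa/m` (tethering strongest in the
  non-dependent lung).  The recoil gradient is gravity-induced, so `m`
  scales with `g/9.81` and vanishes in weightlessness — this makes
  zero-gravity solutions exactly independent of the posture label.

### Capillary sheets and the ladder acinus

Sheet height H responds to transmural (blood minus air) pressure: zero when
collapsed (`P_tm < 0`), `H₀ + α_c P_tm` while recruiting, and `H_max` above
`P_CU = (H_max − H₀)/α_c ≈ 3231 Pa`.  Note the recruitment step at
`P_tm = 0` is a genuine jump (0 → H₀): recruitment is an opening event, and
only the saturation knee is continuous.  Sheet flow integrates H³ between
the venous- and arterial-side transmural pressures with the closed-form
piecewise antiderivative (collapsed segments contribute nothing — the
zone-2 "waterfall" clamps the lower limit at zero).  The literal sheet
height expression in the source description (`H₀(1 + α_c P_tm)`) is
dimensionally inconsistent with α_c in m/Pa and is implemented as
`H₀ + α_c P_tm`, which also makes the `H_max = H₀ + α_c P_CU` branch exact.

The ladder has 2^(g−1) parallel arteriole/venule segments in generation
g = 1…9 and one lumped sheet per generation.  Ladder segments are *below*
the 200 µm threshold, so they are compliant against alveolar pressure —
this matters: with rigid intra-acinar segments the gravitational
perfusion gradient collapses to ~2 %/cm because the recruitment lever is
diluted by a large height-independent series resistance.  The hydrostatic
term is neglected inside the acinus (sub-millimeter height differences).

### Macro surrogate and coupling

The linear coefficients come from Poiseuille resistance of equivalent
cylinders (areas: MPA 7.72×10⁻⁴, LPA 3.77×10⁻⁴, RPA 3.54×10⁻⁴ m²;
lengths 5 cm MPA, 3 cm branches).  The loss coefficients are
`b_i = K ρ_b/(2 A_i²)` with the single constant K calibrated (by Brent
root-finding) so that at equal outlet pressures and 4.8 L/min the LPA
carries 52.85 % of inflow — the midpoint of the 52.5–53.2 % band that
characterizes 3D flow in this junction.  The surrogate's pressure–flow
curve is convex and strictly increasing.  **The macro domain carries no
gravity body force** (matching a CFD domain run without one), which has a
real physical consequence: the coupled interface condition equalizes hilum
pressures, so posture-driven left/right redistribution is governed by each
lung's tissue distribution *relative to its own hilum* plus the venous
trunk hydrostatics, not by the arterial trunk head.

Coupling alternates macro and 1D solves, exchanging outlet flows and
interface pressures, and declares convergence when the summed squared
inter-iteration pressure change is ≤ ε = 0.1 (the printed form of this
metric has units Pa² against a threshold quoted in Pa; it is implemented
as printed, with `rms` and `max_abs` variants available).  A constant
under-relaxation factor cannot stabilize this particular exchange: the
macro junction's internal resistance is a few Pa·s/mL while the 1D lung
impedance is ~10⁷ Pa·s/m³, so the raw loop gain is O(10²).  The default
scheme therefore solves the loop's single degree of freedom — the LPA flow
fraction — by a guarded bracketed regula-falsi (Illinois) on the macro/1D
flow-consistency residual, passing pressures through; convergence
additionally requires the hand-off to be self-consistent to 10⁻⁴ of the
cardiac output.  The as-printed constant-λ scheme is available
(`adaptive=False`) and is used where the macro resistance dominates (e.g.
the linear verification toy, where λ = 1 settles in ≤ 3 iterations).
Interface flows sum to the cardiac output exactly at every iteration by
construction of the hand-off.

## 2. Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| μ | blood viscosity | 0.0035 | Pa·s |
| ρ_b | blood density | 1050 | kg/m³ |
| α | extra-acinar compliance | 1.49×10⁻⁴ | Pa⁻¹ |
| μ_c | capillary blood viscosity | 0.0019 | Pa·s |
| f | sheet-flow numerical factor | 21.6 | – |
| l_c | arteriole→venule path length | 1186×10⁻⁶ | m |
| H₀ / H_max | unstrained / maximal sheet height | 3.5 / 7.7 ×10⁻⁶ | m |
| α_c | sheet compliance | 1.3×10⁻⁹ | m/Pa |
| SA | total capillary surface area | 65.4 | m² |
| – | Strahler diameter ratio, arteries / veins | 1.52 / 1.56 | – |
| g | gravitational acceleration | 9.81 (0 in 0g) | m/s² |
| P_LA | venous outlet pressure | 666 (~5 mmHg) | Pa |
| P_alv | alveolar pressure | 0 | Pa |
| P_ref, m | recoil reference and slope | −500, −981 | Pa, Pa/m |
| λ, ε | under-relaxation seed, convergence threshold | 0.5, 0.1 | –, (Pa²) |

Iteration controls: 1D outer loop damping 0.5, tolerances 10⁻⁴ Pa on nodal
pressures and 10⁻⁶ relative on diameters, ≤ 500 iterations; ladder Newton
tolerance 10⁻⁸ Pa, ≤ 200 iterations, full steps with halving backtracking.

## 3. Synthetic geometry: what it emulates, what it does not

The generator replaces CT-derived anatomy with parametric stand-ins chosen
once on anatomical grounds:

* **Lung envelopes**: half-ellipsoids; right lung 52.5 % of a 4.0 L total
  volume (imaging at ~50 % vital capacity for an adult of FRC 3.4 L);
  right lung wider, dorso-ventrally deeper and cranio-caudally shorter
  than the left; centers at x = ∓7.5 cm with dorso-ventral offsets ∓8 mm.
* **Hila** at 60 % cranio-caudal height, ventral of center, just inside
  the mediastinal surface (~3 cm from midline).  The ventral offset is
  larger on the right (0.38 vs 0.22 of the dorso-ventral semi-axis): the
  right lung carries more tissue dorsal of its hilum, which is the
  anatomical lever that sends flow to the right lung in supine and to the
  left in prone once hilum pressures are equalized by the coupling.
* **Trees**: volume-filling centroid-split growth into jittered-grid seed
  points (length fraction 0.4, branch-angle limit 60°, minimum branch
  1.2 mm), one terminal per acinar seed; Strahler diameters anchored at
  the feeding-stub calibers with ratio 1.52; within-order log-normal
  diameter scatter (CV 0.15, clamped monotone root→leaf) emulating the
  caliber variability of cast morphometry.  Veins mirror the arterial
  topology with ratio 1.56; the venous root is sized so terminal venules
  match their arterial counterparts, making veins at least as wide as the
  companion artery at every order (physiological sub-arterial venous
  resistance; capillary outlet pressure lands at ~8 mmHg).
* **Acinar size heterogeneity**: log-normal per-acinus weights (CV 0.30,
  normalized to preserve SA = 65.4 m²) scale each unit's sheet area *and*
  parallel segment counts — a larger acinus has proportionally more
  micro-vascular paths.

**Scaled-down acinar count.** The study scale is N = 10,000 acini (the
full-scale anatomy resolves 30,676).  Each model acinus represents
`30676/N` anatomical acini merged in parallel: sheet areas scale through
the SA partition and all ladder segment conductances carry the same merge
factor, keeping per-acinus pressures approximately independent of N.  The
ladder template (generation-1 caliber 210 µm, length 1 mm, ratio 0.8 per
generation) is fixed; its generation-1 caliber — a quantity the anatomy
sources do not state for a merged unit — was set so the whole model's
inlet pressure at 4.8 L/min matches the ~2.21 kPa mean pulmonary artery
pressure characteristic of the full-scale system.

What the generator does *not* reproduce: lobar fissures and lobe-specific
trees, the image-derived pre-segmental venous anatomy, airway–vessel
interdigitation, and the detailed shape of real lungs.  Consequently the
*structural* component of perfusion heterogeneity is smaller than in
CT-based anatomy: at zero gravity the model's COV is ~28 %, below the
33–47 % band reported for image-based networks, and the whole-lung
gravitational gradient G comes out at ~4.8–5.8 %/cm against the 6.8–9.1
%/cm of the CT-based antecedent.  Passing gravity-posture checks therefore
demonstrates the mechanisms (recruitment, compliance, West zones, posture
redistribution), not CT-level anatomical fidelity.

## 4. Numerical scheme

The 1D solver is a damped fixed point: freeze diameters and acinar
conductances, assemble nodal conservation as a sparse linear system (the
venous outlet pressure is pinned; hydrostatic heads enter the right-hand
side), solve with SuperLU, then update diameters and ladder conductances
with damping 0.5.  Acinar ladders are solved for all acini simultaneously
by a vectorized quasi-Newton iteration (18 unknowns per acinus; sheet
derivatives exact, compliant-segment conductances frozen within each
Jacobian), warm-started across outer iterations and coupling steps.
Acinar flows are reported from the converged linear system, so summed
acinar flow matches the inflow to solver precision (≤ 10⁻⁸ relative,
typically ~10⁻¹⁰).  Degenerate cases: a zone-1 acinus (alveolar pressure
above both vascular pressures) carries exactly zero flow and leaves the
system nonsingular; empty seed subsets prune the affected branch; colinear
seed subsets fall back to a longest-axis median split.

## 5. Known limitations

* Steady state only: no pulsatility, wave propagation or vessel inertia;
  no fluid–structure interaction in the macro domain.
* The macro surrogate reproduces the *contract* and convex character of a
  3D junction, not its geometry; the wall-shear analogue
  (`τ = 32 μ Q̇/(π D³)`, area-weighted) is explicitly not comparable in
  magnitude to shear integrated over a real 3D luminal surface.
* The linear `D(P_tm)` law is uncapped in distension; at strongly elevated
  transmural pressures (dependent lung in lateral posture) it may
  overstate vessel widening.
* Whole-lung G is reported; in lateral postures the gradient becomes
  lung-specific and the whole-lung value is not meaningful (the lateral
  posture is accordingly excluded from G summaries).
* The uncoupled 1D model, which retains the arterial trunk hydrostatics,
  redistributes flow between lungs far more strongly in lateral posture
  than the coupled model does; its lateral left-lung share falls well
  below the 46–47 % range quoted for image-based networks, a combined
  effect of the synthetic geometry's hilum placement and the strong
  gravity response at this scale.
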