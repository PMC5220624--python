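# Methods

## Model structure

The circulation is a closed loop of 14 lumped compartments.  Each
compartment is a linear capacitance C (L/mmHg) holding volume V (L); its
pressure is

    P_i = P0 + (V_i − V0_i)/C_i + lung_i·P_lung(t) + m_i·P_M(t) + plr_i·P_PLR(t)

where V0_i is the initial (cardiac-arrest) volume, used as the zero-strain
reference, and P0 is the uniform mean circulatory filling pressure of the
arrest state (default 7 mmHg).  Because all elements respond to pressure
*differences*, P0 shifts only absolute reported pressures (relevant to the
pulmonary-oedema check, which compares an absolute pressure to the colloid
osmotic threshold) and nothing else; this is verified by test.

Directed edges carry flow ΔP/R; valve edges (tricuspid, pulmonary, mitral,
aortic, jugular-return, femoral-return, coronary) are ideal diodes,
max(0, ΔP/R).  Inter-compartment edges use the upstream compartment's
printed outflow resistance, with two deliberate exceptions taken from the
governing flow balances: the femoral inflow (abdominal aorta → femoral
artery) runs through the femoral arterial resistance R = 360 mmHg·s/L,
and the five peripheral beds use their own resistances (head 5520,
coronary 10780, splanchnic 1800, legs 8520, pulmonary capillaries
105 mmHg·s/L).  Under this printed-equation assignment three tabulated
resistances (peripheral pulmonary arteries, carotid arteries, abdominal
aorta) sit on no edge; they are kept in the parameter table for fidelity
but are inert.  The two atria print R = 0; a configurable ε_R = 1 mmHg·s/L
replaces them on the atrio-ventricular valve edges so the ODE stays
well-posed at a 1 ms step (atrioventricular filling is nearly unresisted;
the resulting filling time constant ≈ 5–10 ms is far below the 300 ms
restoring phase, so filling still equilibrates each cycle).

The coronary edge is not drawn in the usual network diagrams of this model
family; it is connected thoracic aorta → right atrium, the standard choice
in ancestral CPR models and the same pair of nodes whose gradient defines
coronary perfusion pressure.  Coronary flow is gated by the instantaneous
sternal force: zero whenever force exceeds 1e-9 N (compression phase),
max(0, ΔP/R_ht) otherwise.

## Forcing

Compressions are non-overlapping half-sinusoids: within each 0.6 s cycle,
force = A·sin(π·τ/0.3) for τ ∈ [0, 0.3) s and 0 otherwise (A = 400 N,
100 min⁻¹, 50 % duty).  The sternal force maps linearly to two external
pressures: P_lung = k_lung·F on every chest compartment and
P_M = k_med·F distributed by the thoracic pump factor f_tp — in full on
the two ventricles, scaled by f_tp on the remaining coupled chest
compartments, and not at all on the peripheral pulmonary vessels buried
in the lungs.  The peripheral pulmonary vessels do receive P_lung; the
intrathoracic pressure acts on everything inside the chest.

The two coefficients are not separately identifiable from a single
cardiac-output working point, so they are tied by a fixed ratio
k_med/k_lung (default 1.0, configurable) and their common scale is
calibrated by bisection — cardiac output is monotone in the scale — until
steady-state CO at f_tp = 0.75 without PLR equals 1.30 L/min within 0.1 %.
The result (k_lung = k_med = 0.0575 mmHg/N, i.e. peak pressures of
23 mmHg each at 400 N) ships frozen in the defaults.  With this single
scalar fixed, the simulated working points across the pump-factor range
come out close to published values for this model class: CO ≈ 2.1 / 1.6 /
1.0 L/min and coronary flow ≈ 1.8 / 1.4 / 0.9 mL/s at f_tp = 0 / 0.5 / 1,
and CPP ≈ 24 mmHg at f_tp = 0.75.

Passive leg raising adds P_PLR = ρ·g·(l/2)·sin α (converted at
133.322 Pa/mmHg) to both femoral compartments: the leg blood is a uniform
column of length l = 0.79 m (45 % of a 175 cm subject) whose centre of
gravity is at mid-column.  ρ = 1060 kg/m³, g = 9.8 N/kg, so 90° gives
30.78 mmHg.  Onset is an instantaneous step at 20 s by default; a linear
ramp is available for sensitivity checks.

## Numerics

State: the 14 volumes only.  Pressures are recovered algebraically from
the closed form above rather than co-integrating the incremental pressure
recurrences; the two are exactly equivalent (the closed form is the
integral of the incremental form from the zero-forcing equilibrium) and
the algebraic route cannot drift.  Integration is classic fixed-step RK4
at dt = 1 ms for 40 s; an explicit-Euler mode implements the incremental
equations taken literally and agrees with RK4 on cycle-averaged CO within
0.1 % (tested at 2 %).  Diode discontinuities are taken head-on inside
the RK4 stages — no event detection — which is adequate because the
fastest network time constants (≈ 2–6 ms) stay above the step and every
run is verified for exact volume conservation (< 1e-12 L drift observed,
1e-6 L asserted), valve non-negativity and non-negative volumes.
Non-finite volumes abort the run naming the first offending compartment
and time.

Traces can be decimated on recording; decimated rows are *block averages*
of the full-rate samples, not point samples, so windowed means are immune
to aliasing of fast transients (the coronary inflow spike at each
restoring-phase onset is only ≈ 4 ms wide).  Summary windows (pre-PLR
10–20 s, post-PLR 30–40 s; the system is periodic well before 8 s) are
truncated to a whole number of compression cycles ([10, 19.6] and
[30, 39.6] s) so the phase of the window boundary does not bias the mean;
CPP is averaged over restoring-phase samples only.  The integrator was
validated against the closed-form relaxation of a two-compartment RC
fixture (τ = R·C1·C2/(C1+C2); half-life reproduced to < 1e-4 relative).

## Behaviour under leg raising — an exact structural property

Because every element is linear and every external pressure enters
additively, the pressure dynamics close on themselves: dP_i/dt =
(net inflow)_i/C_i + d(external)_i/dt, with volumes nowhere on the
right-hand side.  Two consequences, both confirmed numerically:

1. **Uniform-shift zero mode.**  Adding δ to every pressure (equivalently
   C_i·δ to every volume) leaves all flows unchanged.  Steady-state
   cycle-mean flows are therefore independent of total blood volume and
   of P0.
2. **PLR is a pressure step, not a pump.**  The gravitational step on the
   two femoral nodes kicks the pressure state once and the system then
   relaxes back to the *same* periodic attractor, displaced along the
   zero mode by (C12+C13)·P_PLR/ΣC ≈ +1.7 mmHg at 90°.  Steady-state CO,
   CPP, Q_heart and Q_head are consequently unchanged by PLR (residual
   +0.1…0.6 % in the 30–40 s window is the tail of slow redistribution
   modes, τ ≈ 40–70 s).  What PLR *does* change is stored volume: the
   legs lose (C12+C13)·P_PLR·(1 − (C12+C13)/ΣC) ≈ 143 mL at 90°,
   exactly proportional to sin α (≈ 17/24/29/33 % of the pre-PLR leg
   volume at 30/45/60/90°), about a quarter of which lodges in the
   abdominal veins and the rest centrally.

Sustained flow benefits from leg raising therefore require a
symmetry-breaking nonlinearity this model deliberately omits — most
plausibly a saturating (nonlinear) venous pressure–volume law or venous
collapse, which would both give the heart genuine preload sensitivity
(a Starling-like response to central volume) and bend the transferred
volume's sin α dependence into the diminishing-returns shape seen
clinically.  With linear compliances and rigid vessels (the stated
assumption here), the model predicts volume redistribution without a
steady perfusion gain.  Reported experimental and clinical PLR responses
(percent-level gains in cardiac output and cerebral flow) should be read
against this limitation.

## Tunable parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| f_tp | 0.75 | – | thoracic pump share of mediastinal pressure |
| amplitude | 400 | N | compression peak force |
| frequency | 100 | min⁻¹ | compression rate (0.6 s period) |
| duty_cycle | 0.5 | – | compressing fraction of each cycle |
| k_lung, k_med | 0.0575 | mmHg/N | force→pressure couplings (calibrated) |
| angle_deg | 90 | ° | leg elevation |
| start_time | 20 | s | PLR onset |
| leg_length | 0.79 | m | blood-column length in the legs |
| P0 | 7 | mmHg | arrest filling pressure (level only) |
| epsilon_R | 1 | mmHg·s/L | stand-in for printed zero resistances |
| dt | 0.001 | s | RK4 step |
| oedema threshold | 25 | mmHg | conservative end of the 25–30 colloid band |

## Scope of the test conditions

The protocols exercised by the tests and the acceptance script are the
model's native study conditions — a single average subject (175 cm,
4.36 L blood), idealized periodic compressions at fixed depth-equivalent
force, instantaneous PLR — not recordings of real resuscitations.
Passing tests show the network, forcing, calibration and reductions are
implemented correctly and that the model's exact invariants hold; they do
not show that a real patient's circulation responds linearly, and the
structural property above is precisely where real venous physiology is
expected to depart from the model.  There is no respiratory or gas
transport model (end-tidal CO₂ is bridged from CO percent changes by the
empirical linear map y = 0.33x + 0.13, applied symmetrically to increases
and decreases), no baroreflex, no ventilation pauses, and no
depth–force chest mechanics (force is the input; depth is metadata).
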