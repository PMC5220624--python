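# cprhemo

A lumped-parameter hemodynamic model of chest-compression-only
cardiopulmonary resuscitation (CO-CPR) with passive leg raising (PLR),
for researchers in resuscitation science and computational physiology who
want a transparent, fully deterministic testbed for compression mechanics
and posture manoeuvres during cardiac arrest.

## The model

The circulation is a closed loop of 14 compartments (right atrium and
great veins, right ventricle, pulmonary arteries and veins, left atrium,
left ventricle, thoracic aorta, carotid/jugular vessels, abdominal aorta,
femoral artery and vein, inferior vena cava).  Each compartment *i* is a
linear capacitance C_i drained through resistances; the four heart valves,
the jugular and femoral venous valves and the coronary bed are ideal
diodes (flow = max(0, ΔP/R)).  Inertia is neglected (flow velocities in
CPR are low), so the state is the volume vector V and

    P_i = P0 + (V_i − V0_i)/C_i + lung_i·P_lung + m_i·P_M + plr_i·P_PLR

with P0 the uniform mean circulatory filling pressure of the arrest
equilibrium.  Sternal compressions are non-overlapping half-sinusoids
(400 N, 100 min⁻¹, 50 % duty cycle) mapped linearly to an intrathoracic
pressure P_lung (all chest compartments) and a mediastinal pressure P_M.
The **thoracic pump factor** f_tp ∈ [0, 1] sets how much of P_M reaches
the non-ventricular chest compartments (m_i = 1 on the ventricles, f_tp
on the other coupled chest compartments, 0 elsewhere): f_tp = 0 is a pure
cardiac pump (direct ventricular squeeze), f_tp = 1 a pure thoracic pump.
Coronary flow (thoracic aorta → right atrium through R_ht) is blocked
during the compression phase.  Raising the legs by an angle α adds the
hydrostatic pressure of the mid-column of leg blood,

    P_PLR = ρ·g·(l/2)·sin α     (≈ 30.8 mmHg at 90° for l = 0.79 m),

to the femoral arterial and venous compartments.  The volume ODEs are
integrated with classic fixed-step RK4 at 1 ms.  Reported metrics are
cycle-averaged over steady-state windows: cardiac output (CO, aortic-valve
flow), coronary perfusion pressure (CPP, restoring-phase aorto-right-atrial
gradient), coronary flow Q_heart, cerebral flow Q_head, regional volumes
and peripheral pulmonary venous pressure (oedema safety).

The single free constant — the force→pressure coupling scale — is
calibrated once so that CO-CPR at f_tp = 0.75 yields a steady-state CO of
1.30 L/min, and is shipped frozen in the default configuration.

## Worked example

```python
from cprhemo import (build_default_parameters, ForcingProtocol, PlrConfig,
                     compare_plr, leg_volume_transfer)

params = build_default_parameters(tpf=0.75)
protocol = ForcingProtocol(plr=PlrConfig(angle_deg=90.0), duration=40.0)
result = compare_plr(params, protocol)      # PLR starts at 20 s

print(f"CO  before PLR : {result.before.co:.2f} L/min")
print(f"CO  after  PLR : {result.after.co:.2f} L/min")
print(f"CPP before PLR : {result.before.cpp:.1f} mmHg")
print(f"Q_head before  : {result.before.q_head:.2f} mL/s")
moved, pct = leg_volume_transfer(result)
print(f"leg volume     : {result.before.v_legs:.0f} -> "
      f"{result.after.v_legs:.0f} mL ({moved:.0f} mL = {pct:.0f}% shifted)")
```

prints

```
CO  before PLR : 1.30 L/min
CO  after  PLR : 1.30 L/min
CPP before PLR : 24.4 mmHg
Q_head before  : 6.43 mL/s
leg volume     : 427 -> 284 mL (143 mL = 33% shifted)
```

Raising the legs to 90° moves 143 mL (a third of the leg blood) into the
abdomen and chest, but steady-state cardiac output is essentially
unchanged — in this strictly linear network the gravitational step relaxes
to the same periodic flow pattern, shifted only by a uniform pressure
offset (see `docs/methods.md` for why, and for what nonlinearity would be
needed to obtain a sustained preload effect).

The same experiments are available from the shell:

```bash
cprhemo compare --tpf 0.75 --angle 90 --outdir out/
cprhemo sweep-tpf --tpfs 0,0.25,0.5,0.75,1 --outdir out/
cprhemo sweep-angle --angles 0,30,45,60,90 --outdir out/
cprhemo edema-grid --outdir out/
cprhemo table3 --outdir out/
cprhemo calibrate --target-co 1.30
```

Each command writes CSV tables and a JSON summary with a config hash and
the coupling constants; everything is reproducible bit-for-bit from the
configuration alone.

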