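# Model and methods

`windkessel` is a zero-dimensional (lumped-parameter) model of the human
left heart coupled to the systemic circulation, built to study how a
delayed and weakened ventricular contraction — the organ-level signature of
a reduced transmural conduction velocity (TCV) — propagates into systemic
hemodynamics: ejection fraction, cardiac output, arterial pressures, and
left-ventricular power.

## The circulation as an electrical analogue

Pressures map to voltages, flows to currents, and blood volume to charge.
The closed loop is, in flow order:

    LA -> mitral diode (R_DAV) -> LV -> aortic diode (R_Da) + inertance L
       -> arch node (C_a1 in series with R_a1, to ground)
       -> R_a -> aorta node (C_a2 series R_a2) -> R_p
       -> venous node (C_v, purely elastic) -> R_v -> LA

This gives six differential states — atrial volume `V_A`, ventricular
volume `V_V`, the three compliance charge volumes `q_a1, q_a2, q_v`, and
the aortic flow `Q_a` through the inertance — plus two algebraic equations
for the viscoelastic node pressures

    P_arc = q_a1/C_a1 + R_a1 dq_a1/dt,
    P_a   = q_a2/C_a2 + R_a2 dq_a2/dt,

whose charging rates themselves depend on both pressures; the 2x2 linear
system is solved in closed form inside the right-hand side.  The venous
pressure is elastic, `P_v = q_v/C_v`.  Because every flow leaves one store
and enters the next, the sum of the five volume derivatives is identically
zero: total blood volume is conserved exactly, and the simulated drift
(< 1e-9 relative over 60 s) measures pure integrator error.

Valves are two-state resistors: the open value from the parameter table, or
`R_closed = 1e4 mmHg*s/ml` when closed.  The mitral valve switches on the
sign of `P_A - P_V`.  The aortic valve opens when `P_V` exceeds `P_arc` but
*closes on flow reversal* (`Q_a = 0`, downward): with the inertance in the
branch, forward flow outlives the pressure gradient by ~10 ms, and cutting
the resistance at the pressure crossing would instantaneously drop `P_arc`
by several mmHg (through `R_a1 Q_a`) and re-open the valve.  Zero-flow
closure is the standard diode idealization and coincides with the pressure
rule as L -> 0.

## Chamber constitutive laws

**Ventricle.**  Passive and peak-active behaviour are two Frank–Starling
curves anchored at a common reference volume `V_Ved,M = 200 ml`:

    P_pass(V)    = a_V V^3,                a_V = P_Ved,M / V_Ved,M^3
    P_ivmax(V_ed) = P_ivmax,M - b_V (V_ed - V_Ved,M)^2,
                                           b_V = P_ivmax,M / V_Ved,M^2

with `P_ivmax,M = 275 mmHg` (the maximum pressure a persisting isovolumic
contraction could reach).  The end-diastolic volume `V_ed` is latched at
each mitral-valve closure and held for the beat.  The instantaneous
pressure mixes the two curves through a twitch,

    P_V = P_pass(V) + (P_ivmax(V_ed) * G - P_pass(V)) * f_Vc * K_Vc * f_Ve

* `f_Vc = exp(-(k_V1|t - t_Vmax|)^i_V1 - (k_V2|t - t_Vmax|)^i_V2)` is the
  activation twitch, equal to 1 at `t_Vmax` (0.3568 s after sinoatrial
  excitation under control conditions) and < 1e-10 at the beat boundaries.
  The rate constants multiply the time offset; the alternative reading
  (dividing by k ~ 5.7 s) would keep `f_Vc ~ 1` through the whole cycle,
  i.e. a ventricle that never relaxes.
* `K_Vc` scales contractility (1 in control).
* `f_Ve = 1 - (1/K_e)(-ln(V/V_ed))^{i_e}` de-rates wall stress as the
  fibres shorten during ejection; clamped to 1 whenever `V >= V_ed`.
* `G = A_V(V) / A_V(V_ed)` is the Laplace geometry gain.  The LV is a
  thick-walled sphere: wall stress converts to cavity pressure through
  `A_V = 2(h/r) + (h/r)^2`, where `h/r` follows from the wall/cavity
  volume ratio, `(1 + h/r)^3 = V_m/V + 1`, with constant muscle volume
  `V_m`.  The active stress amplitude is set by the end-diastolic
  geometry (that is what the Frank–Starling curve calibrates, so
  `P_ivmax` remains a true pressure), and as the cavity empties the
  relatively thicker wall transmits the same stress as a higher pressure
  (G rises to ~2.4 at end-systole).  Without this gain the active pressure
  available at end-systolic volumes (~36 ml) could not exceed ~50 mmHg and
  the ventricle could not eject against an 80 mmHg aorta; a
  `laplace_gain=False` switch exposes the plain pressure interpolation for
  comparison.

**Atrium.**  Simplified analogue: passive quintic `P = a_A V^5` anchored at
(100 ml, 30 mmHg), plus an active term `f_Ac (7.5 - b_A (V - 100)^2)` mmHg
gated by `f_Ac = exp(-(k_A|t - t_Amax|)^{i_A})`, peaking 0.12 s after
excitation — the atrial kick that tops up ventricular filling just before
ventricular systole.

## Numerical integration

The stiff-capable Radau method (scipy) integrates between valve events with
the published error settings (absolute 1e-4, relative 5e-6); each event
terminates the segment, the discrete valve mode toggles, and integration
resumes from the event state.  Steps are capped at 2 ms so the dense-output
interpolant resolves the steep atrial twitch; with this cap the
mitral-closure event time is reproducible to ~0.05 us, which the 0.01%
run-in criterion (below) requires.  The right-hand side is compiled with
numba when available (a pure-Python fallback is kept); a 60 s run takes
O(10 s) on one core.

Output is sampled on a fixed grid (default 1 ms), snapped to an integer
number of samples per beat.  With a raw 1 ms grid the sample phase drifts
by 1/3 ms per 0.8333 s beat, which aliases the sharp (dP/dt)max peak by up
to 1% beat-to-beat in strongly perturbed runs and masquerades as
non-convergence; phase-locked sampling removes the artifact without
touching the solver.  Exact event times are logged separately, so interval
metrics (IVCD, EPD) are event-resolved, not grid-quantized.

Initial conditions put 120 ml in the ventricle, 60 ml in the atrium, and
split the remaining blood over the compliances in proportion to their
capacitance; the 60 s run-in (72 beats at 72 beats/min) erases this choice —
extending to 120 s changes every steady-cycle index by < 1e-5%.

## Free parameters and calibration

Three quantities are not fixed by the parameter table and were calibrated
once against the control steady-cycle column, then frozen as defaults:

| parameter            | value  | role |
|----------------------|--------|------|
| `total_blood_volume` | 730 ml | sets venous/filling pressure, hence V_V,ed |
| `P_Ved,M`            | 32 mmHg| passive stiffness; filling and IVC timing |
| `V_m`                | 300 ml | ejection-phase geometry gain; V_V,es and EF |

`V_m` is an *effective* parameter of the spherical idealization, not an
anatomical wall volume: the sphere underestimates the surface-to-volume
ratio of the real (roughly ellipsoidal) chamber, so the fitted value runs
high.  With these defaults the ten control indexes (P_a,s/d 125/80 mmHg,
(dP/dt)max 1783 mmHg/s, V_ed/V_es 114/36 ml, IVCD 60 ms, EPD 211 ms,
EF 69%, CO 5653 ml/min, W_LV 1.51 W) are reproduced within ~2%
(IVCD within 0.6 ms).

## Reduced-TCV scenarios

A reduced transmural conduction velocity is represented by a later
activation peak (`t_Vmax` up) and a lower contractility (`K_Vc` down).
Scenarios either set the pair directly or give first-cycle targets for
(IVCD, (dP/dt)max) — the quantities an upstream ventricular-wall model
provides — which `calibrate_activation` inverts with a 2-D quasi-Newton
root find on the first beat after switching parameters at a steady beat
boundary (residuals normalized by 1 ms and 5 mmHg/s; convergence at
0.5 ms / 2 mmHg/s).  The inversion is exact at the control fixed point and
idempotent.

**Known limitation.**  With the published 50%-TCV pair (`t_Vmax = 0.3885`,
`K_Vc = 0.982`) this reconstruction yields a steady IVCD of 75 ms versus
the published 71 ms; the (dP/dt)max, EF, CO, W_LV and pressure responses,
and the *direction* of every index change, are reproduced within ~1-2%.
The IVCD increment under delayed activation is set by the race between the
atrial-twitch collapse and the ventricular pressure rise at mitral closure,
and it is 15-16 ms for every admissible calibration of the three free
parameters (the source model reports 11 ms).  The discrepancy therefore
sits in a formulation detail of the atrial/mitral branch that the printed
parameter set does not determine; consequently, calibrating onto targets
(71 ms, 1750 mmHg/s) returns (0.383, 0.968) rather than (0.3885, 0.982).

## Stability harness

`stability_sweep` perturbs each of the 12 contractility/valve/vessel
parameters (`K_Vc, R_DAV, R_Da, R_a1, R_a2, R_a, R_p, R_v, C_a1, C_a2,
C_v, L`) by +/-30% and +/-50% and reruns the 60 s protocol; all 48 runs
reach a steady cycle (every per-beat index repeating to < 0.01%
beat-to-beat).  The sweep defaults to the LSODA integrator: convergence
detection needs 1e-4 agreement, three orders above LSODA's event noise,
and the sweep is 48 full runs.

## Steady-cycle metrics

Per-beat indexes are extracted from the dense trace and the event log:
IVCD = mitral closure to aortic opening, EPD = aortic open interval (both
event-resolved); (dP/dt)max = centred finite differences over the IVC
window with three-point parabolic refinement (invariant to 2x grid
refinement within 0.02%); stroke work = shoelace area of the closed
P_V–V_V loop (1 mmHg*ml = 1.33322e-4 J), agreeing with the signed time
integral of P dV within 0.01%; W_LV = stroke work x heart rate; EF, SV, CO
follow as exact identities from the event-state volumes.  External
two-column time/pressure CSVs can be loaded for (dP/dt)max extraction only
(no valve events are available for such traces).

## What the defaults do and do not represent

The default configuration *is* the study protocol: resting rate
(72 beats/min), 60 s of stimulation, the printed parameter table, and the
three calibrated volumes above.  The model has no pulmonary loop, right
heart, baroreflex, heart-rate variability, or beat-to-beat noise; arterial
"pressure" is one lumped aortic node, not a propagating pulse wave.
Passing the acceptance suite shows the lumped reconstruction reproduces the
published operating point and its parameter sensitivities — not that it
predicts any individual patient's hemodynamics.
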