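# windkessel

A lumped-parameter ("Windkessel") model of the human left heart and
systemic circulation, with an experiment layer for studying how a reduced
**transmural conduction velocity (TCV)** — the speed at which excitation
propagates from endocardium to epicardium across the left-ventricular
wall — degrades pump function.

A slower TCV desynchronizes the onset of contraction across the wall.  At
the organ level this appears as a longer isovolumic contraction (IVCD) and
a slightly lower peak pressure-rise rate ((dP/dt)max).  This package
carries those two effects into systemic hemodynamics: the left ventricle
and atrium are nonlinear pressure sources (Frank–Starling polynomial
curves, a double-exponential activation twitch, thick-walled-sphere
Laplace geometry), the vasculature is an electrical-analogue circuit
(diode valves, viscoelastic compliances, blood inertance), and the whole
loop is integrated as a stiff six-state ODE system with valve-event
switching until a steady cardiac cycle is reached.  It is intended for
computational physiologists and modellers who need a fast, reproducible
0-D test bench for contraction-timing experiments.

## Model core

Ventricular pressure mixes a passive cubic and a Frank–Starling
isovolumic-maximum curve through the activation twitch:

    P_V = P_pass(V_V) + (P_ivmax(V_ed) · G − P_pass(V_V)) · f_Vc · K_Vc · f_Ve

    P_pass(V) = a_V V³          P_ivmax(V_ed) = P_ivmax,M − b_V (V_ed − V_Ved,M)²
    f_Vc = exp(−(k_V1|t−t_Vmax|)^i_V1 − (k_V2|t−t_Vmax|)^i_V2)
    f_Ve = 1 − (1/K_e)(−ln(V_V/V_ed))^i_e
    G    = A_V(V_V)/A_V(V_ed),   A_V = 2(h/r) + (h/r)²  (law of Laplace)

with `V_ed` latched at each mitral closure.  `t_Vmax` (time from
sinoatrial excitation to peak contraction) and the contractility
coefficient `K_Vc` are the two dials a reduced TCV turns.  The circuit
(mitral/aortic diodes, inertance L, arch and aortic viscoelastic
compliances C_a1·R_a1 / C_a2·R_a2, peripheral and venous resistances,
elastic venous pool C_v) closes the loop and conserves total blood volume
exactly.  See `docs/methods.md` for the full formulation, the numerical
scheme, and known limitations.

## Worked example

```python
from windkessel import ModelConfig, run, beat_metrics, detect_steady_cycle

cfg = ModelConfig()                       # parameter-table defaults, 72 bpm, 60 s
trace = run(cfg.simulation, cfg.ventricle, cfg.atrium, cfg.circuit)
steady = detect_steady_cycle(trace)
m = beat_metrics(trace, trace.n_beats - 1)
print(f"steady after beat {steady.beat_index}")
print(f"IVCD {m.IVCD_ms:.1f} ms  EPD {m.EPD_ms:.1f} ms  "
      f"(dP/dt)max {m.dPdt_max:.0f} mmHg/s")
print(f"P_a {m.P_a_s:.0f}/{m.P_a_d:.0f} mmHg  EF {m.EF:.1f} %  "
      f"CO {m.CO:.0f} ml/min  W_LV {m.W_LV:.2f} W")
```

prints

    steady after beat 10
    IVCD 59.5 ms  EPD 209.5 ms  (dP/dt)max 1800 mmHg/s
    P_a 126/79 mmHg  EF 69.0 %  CO 5668 ml/min  W_LV 1.52 W

i.e. a resting healthy operating point: ~60 ms of isovolumic contraction,
126/79 mmHg aortic pressure, 69% ejection fraction, 5.7 l/min output and
1.5 W of mechanical LV power.  The 50%-TCV experiment delays the
activation peak and trims contractility:

```python
from windkessel import TCVScenario, run_comparison

comp = run_comparison(TCVScenario(name="tcv50", t_Vmax=0.3885, K_Vc=0.982), cfg)
print({k: round(float(v), 1) for k, v in comp.deltas_pct.items()
       if k in ("EF", "CO", "W_LV", "P_a_s", "IVCD_ms")})
```

    {'IVCD_ms': 26.0, 'EF': -1.3, 'CO': -1.6, 'P_a_s': -1.6, 'W_LV': -3.3}

— a substantially longer isovolumic contraction but only a ~2% loss of
output and ~3% loss of LV power: at rest, a halved TCV costs surprisingly
little, which is the study's central observation.

The same operations are available from a shell:

    windkessel --out results simulate
    windkessel --out results compare --name tcv50 --t-vmax 0.3885 --k-vc 0.982
    windkessel --out results calibrate --target-ivcd 71 --target-dpdt 1750
    windkessel --out results stability

Configuration is one flat YAML namespace mirroring the model symbols
(`R_p: 1.0`, `C_v: 70`, `t_Vmax: 0.3568`, ...); an empty file means "all
defaults", unknown keys are rejected by name.

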