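import numpy as np
import pytest

from windkessel import beat_metrics, run
from windkessel.config import ModelConfig

TCV_T_VMAX = 0.3885
TCV_K_VC = 0.982


@pytest.fixture(scope="session")
def cfg() -> ModelConfig:
    """Default configuration (parameter-table values plus calibrated volumes)."""
    return ModelConfig()


@pytest.fixture(scope="session")
def control_trace(cfg):
    """Full 60 s control run-in (72 beats at 72 bpm); shared across tests."""
    return run(cfg.simulation, cfg.ventricle, cfg.atrium, cfg.circuit)


@pytest.fixture(scope="session")
def control_metrics(control_trace):
    return beat_metrics(control_trace, control_trace.n_beats - 1)


@pytest.fixture(scope="session")
def tcv_trace(cfg):
    """Steady cycle with the reduced-conduction-velocity activation
    parameters (later contraction peak, slightly lower contractility)."""
    vent = cfg.ventricle.model_copy(update={"t_Vmax": TCV_T_VMAX, "K_Vc": TCV_K_VC})
    return run(cfg.simulation, vent, cfg.atrium, cfg.circuit)


@pytest.fixture(scope="session")
def tcv_metrics(tcv_trace):
    return beat_metrics(tcv_trace, tcv_trace.n_beats - 1)


@pytest.fixture(scope="session")
def short_trace(cfg):
    """Cheap 12 s run for structural checks that do not need a steady cycle."""
    sim = cfg.simulation.model_copy(update={"duration": 12.0})
    return run(sim, cfg.ventricle, cfg.atrium, cfg.circuit)


def tile_beats(beat_trace, n_beats, scale_per_beat=1.0):
    """Tile a single synthetic beat into an n-beat trace.

    ``scale_per_beat`` multiplies pressures and volumes of each successive
    beat (1.0 gives a perfectly periodic trace; >1 a monotone drift).
    """
    from dataclasses import replace as dreplace

    from windkessel.engine import SimulatedTrace, ValveEvent

    period = beat_trace.period
    ts, fields = [], {k: [] for k in ("P_V", "P_A", "P_arc", "P_a", "P_v", "V_V", "V_A", "Q_a", "V_Ved")}
    mo, ao, events = [], [], []
    for b in range(n_beats):
        s = scale_per_beat**b
        ts.append(beat_trace.t + b * period)
        for k in fields:
            fields[k].append(getattr(beat_trace, k) * s)
        mo.append(beat_trace.mitral_open)
        ao.append(beat_trace.aortic_open)
        for e in beat_trace.events:
            events.append(ValveEvent(t=e.t + b * period, kind=e.kind, V_V=e.V_V * s, V_A=e.V_A * s))
    return SimulatedTrace(
        t=np.concatenate(ts),
        **{k: np.concatenate(v) for k, v in fields.items()},
        mitral_open=np.concatenate(mo),
        aortic_open=np.concatenate(ao),
        events=events,
        period=period,
        heart_rate=beat_trace.heart_rate,
        final_state=beat_trace.final_state,
    )
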