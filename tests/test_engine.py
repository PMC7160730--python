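"""Integration engine: events, conservation, steady-cycle detection."""

import numpy as np
import pytest

from windkessel import (
    DegenerateBeatError,
    SimulationConfig,
    beat_metrics,
    detect_steady_cycle,
    run,
)
from windkessel.engine import auto_initial_state
from windkessel.synthetic import rectangle_loop_beat

from conftest import tile_beats


class TestRunStructure:
    def test_time_grid_strictly_increasing(self, short_trace):
        assert np.all(np.diff(short_trace.t) > 0)

    def test_beat_boundaries_align_with_stimulation(self, short_trace):
        period = short_trace.period
        assert np.allclose(np.diff(short_trace.beat_starts), period)
        assert short_trace.n_beats == int(12.0 / period)

    def test_four_valve_events_per_settled_beat(self, short_trace):
        for b in range(5, short_trace.n_beats):
            kinds = [e.kind for e in short_trace.events_in_beat(b)]
            assert kinds == ["mitral_close", "aortic_open", "aortic_close", "mitral_open"]

    def test_valve_state_consistent_with_pressure_drops(self, short_trace):
        """Samples must respect the diode logic up to interpolation noise."""
        tr = short_trace
        tol = 0.25  # mmHg; dense-output interpolation noise at event flanks
        drop_av = tr.P_A - tr.P_V
        assert drop_av[~tr.mitral_open].max() < tol
        assert drop_av[tr.mitral_open].min() > -tol
        # open aortic valve carries forward flow (closes at zero crossing)
        assert tr.Q_a[tr.aortic_open].min() > -1.0
        drop_ao = tr.P_V - tr.P_arc
        assert drop_ao[~tr.aortic_open & (tr.t > 0.1)].max() < tol

    def test_end_diastolic_latch_constant_within_systole(self, short_trace):
        tr = short_trace
        b = tr.beat_indices(tr.n_beats - 1)
        systole = b[(tr.P_V[b] > 30.0)]
        assert np.ptp(tr.V_Ved[systole]) == 0.0

    def test_total_volume_conserved(self, short_trace):
        tv = short_trace.total_volume
        assert np.ptp(tv) / tv[0] < 1e-6

    def test_determinism_bit_identical(self, cfg):
        sim = cfg.simulation.model_copy(update={"duration": 5.0})
        a = run(sim, cfg.ventricle, cfg.atrium, cfg.circuit)
        b = run(sim, cfg.ventricle, cfg.atrium, cfg.circuit)
        assert np.array_equal(a.P_V, b.P_V)
        assert np.array_equal(a.V_V, b.V_V)
        assert [e.t for e in a.events] == [e.t for e in b.events]

    def test_trace_csv_round_trip(self, short_trace, tmp_path):
        import pandas as pd

        path = tmp_path / "trace.csv"
        short_trace.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "t", "P_V", "P_A", "P_arc", "P_a", "P_v", "V_V", "V_A", "Q_a",
            "mitral_open", "aortic_open",
        ]
        assert len(df) == len(short_trace.t)
        assert df["P_V"].to_numpy() == pytest.approx(short_trace.P_V)


class TestInitialState:
    def test_auto_distributes_total_volume(self, cfg):
        state = auto_initial_state(cfg.simulation, cfg.circuit)
        assert state.total_volume == pytest.approx(cfg.simulation.total_blood_volume)
        assert state.V_V == 120.0 and state.V_A == 60.0
        # remainder split proportionally to compliance = equal pressures
        assert state.q_a1 / cfg.circuit.C_a1 == pytest.approx(state.q_v / cfg.circuit.C_v)

    def test_too_small_volume_rejected(self, cfg):
        sim = cfg.simulation.model_copy(update={"total_blood_volume": 100.0})
        with pytest.raises(ValueError):
            auto_initial_state(sim, cfg.circuit)


class TestZeroContractility:
    def test_decays_to_no_flow_equilibrium(self, cfg):
        """With no active stress anywhere the loop relaxes passively."""
        vent = cfg.ventricle.model_copy(update={"K_Vc": 1e-9})
        atr = cfg.atrium.model_copy(update={"P_Ac_max": 1e-9})
        sim = cfg.simulation.model_copy(update={"duration": 12.0})
        tr = run(sim, vent, atr, cfg.circuit)
        b = tr.beat_indices(tr.n_beats - 1)
        assert not any(e.kind == "aortic_open" for e in tr.events_in_beat(tr.n_beats - 1))
        assert np.abs(tr.Q_a[b]).max() < 1.0
        with pytest.raises(DegenerateBeatError):
            beat_metrics(tr, tr.n_beats - 1)


class TestSteadyCycleDetection:
    def test_periodic_trace_converges_with_zero_metric(self):
        tr = tile_beats(rectangle_loop_beat(), 5)
        res = detect_steady_cycle(tr)
        assert res.converged and res.metric < 1e-12 and res.beat_index == 1

    def test_monotone_drift_reported_not_converged(self):
        tr = tile_beats(rectangle_loop_beat(), 6, scale_per_beat=1.01)
        res = detect_steady_cycle(tr)
        assert not res.converged
        assert res.beat_index is None
        assert res.metric > 1e-3

    def test_requires_three_beats(self):
        tr = tile_beats(rectangle_loop_beat(), 2)
        with pytest.raises(ValueError):
            detect_steady_cycle(tr)

    def test_control_run_converges_well_before_60_s(self, control_trace):
        res = detect_steady_cycle(control_trace)
        assert res.converged
        assert res.beat_index < 30


class TestSolverAccuracy:
    def test_tolerance_tightening_leaves_metrics_unchanged(self, cfg):
        """Integration error is below the steady-state criterion: 10x
        tighter solver tolerances move no steady-cycle metric by 0.01%."""
        sim = cfg.simulation.model_copy(update={"duration": 20.0})
        a = run(sim, cfg.ventricle, cfg.atrium, cfg.circuit)
        tight = sim.model_copy(update={"abs_tol": 1e-5, "rel_tol": 5e-7})
        b = run(tight, cfg.ventricle, cfg.atrium, cfg.circuit)
        ma = beat_metrics(a, a.n_beats - 1)
        mb = beat_metrics(b, b.n_beats - 1)
        for name, va in ma.as_dict().items():
            assert abs(getattr(mb, name) - va) / abs(va) < 1e-4, name


class TestConfigValidation:
    def test_rejects_nonpositive_tolerances(self):
        with pytest.raises(ValueError):
            SimulationConfig(abs_tol=0.0)

    def test_rejects_subbeat_duration(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=0.5)

    def test_period_from_heart_rate(self):
        assert SimulationConfig(heart_rate=72.0).period == pytest.approx(60.0 / 72.0)
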