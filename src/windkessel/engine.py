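"""Beat-resolved integration of the circulation ODEs.

The solver integrates the six-state circuit between valve events: each
valve switch terminates the current ``solve_ivp`` segment, the discrete
valve mode is toggled, the end-diastolic volume is latched at mitral
closure, and integration resumes from the event state.  Mitral transitions
are located on the atrioventricular pressure-drop sign; the aortic valve
opens on the ventriculo-arterial pressure drop and closes on aortic flow
reversal (with the small blood inertance, the forward flow persists briefly
after the pressure gradient reverses; closing the diode at zero flow is the
limit the two-state resistance footnote describes and avoids re-opening
chatter from the instantaneous pressure jump a flow cut-off causes).

Dense output is sampled on a fixed grid (1 ms default) for metric
extraction; exact event times are kept separately so interval metrics such
as the isovolumic contraction duration are not grid-quantized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.integrate import solve_ivp

from .chambers import AtriumParameters, VentricleParameters
from .circuit import CircuitParameters, CirculationState, make_rhs

__all__ = [
    "SimulationConfig",
    "auto_initial_state",
    "SimulatedTrace",
    "ValveEvent",
    "SteadyCycleResult",
    "SimulationError",
    "run",
    "detect_steady_cycle",
]

log = logging.getLogger("windkessel")

TRACE_COLUMNS = [
    "t",
    "P_V",
    "P_A",
    "P_arc",
    "P_a",
    "P_v",
    "V_V",
    "V_A",
    "Q_a",
    "mitral_open",
    "aortic_open",
]


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid time and state."""

    def __init__(self, message: str, t: float, state: CirculationState):
        super().__init__(f"{message} (t={t:.6f} s)")
        self.t = t
        self.state = state


class SimulationConfig(BaseModel):
    """Run settings: stimulation rate, duration, solver tolerances.

    ``total_blood_volume`` is the conserved sum of the two chamber volumes
    and the three compliance charge volumes; it is one of the model's
    calibrated free parameters (the venous pool, and with it the filling
    pressure, absorbs most of it).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    heart_rate: float = 72.0
    duration: float = 60.0
    abs_tol: float = 1.0e-4
    rel_tol: float = 5.0e-6
    total_blood_volume: float = 730.0
    output_dt: float = 0.001
    method: str = "Radau"
    max_step: float = 0.002

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.heart_rate <= 0 or self.duration <= 0:
            raise ValueError("heart_rate and duration must be positive")
        if self.abs_tol <= 0 or self.rel_tol <= 0 or self.output_dt <= 0:
            raise ValueError("tolerances and output_dt must be positive")
        if self.duration < 60.0 / self.heart_rate:
            raise ValueError("duration must cover at least one beat")
        return self

    @property
    def period(self) -> float:
        """Stimulation interval in seconds (0.8333 s at 72 beats/min)."""
        return 60.0 / self.heart_rate


@dataclass
class ValveEvent:
    """A valve transition: exact time, kind, and chamber volumes."""

    t: float
    kind: str  # mitral_close | mitral_open | aortic_open | aortic_close
    V_V: float
    V_A: float


@dataclass
class SimulatedTrace:
    """Dense time series of one run plus the exact valve-event log."""

    t: np.ndarray
    P_V: np.ndarray
    P_A: np.ndarray
    P_arc: np.ndarray
    P_a: np.ndarray
    P_v: np.ndarray
    V_V: np.ndarray
    V_A: np.ndarray
    Q_a: np.ndarray
    V_Ved: np.ndarray
    mitral_open: np.ndarray
    aortic_open: np.ndarray
    events: list
    period: float
    heart_rate: float
    final_state: CirculationState
    config: Optional[SimulationConfig] = None
    beat_starts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.beat_starts is None:
            # the final sample closes the beat it falls in: a single beat
            # sampled on [0, period) counts as one complete beat
            step = self.t[-1] - self.t[-2] if len(self.t) > 1 else 0.0
            n = int(math.floor((self.t[-1] + step) / self.period + 1e-9))
            self.beat_starts = np.arange(n + 1) * self.period

    @property
    def n_beats(self) -> int:
        """Number of complete beats contained in the trace."""
        return len(self.beat_starts) - 1

    def beat_indices(self, beat: int) -> np.ndarray:
        """Sample indices of beat ``beat`` (0-based), half-open in time."""
        if not 0 <= beat < self.n_beats:
            raise IndexError(f"beat {beat} out of range (n_beats={self.n_beats})")
        t0 = self.beat_starts[beat]
        t1 = self.beat_starts[beat + 1]
        return np.nonzero((self.t >= t0 - 1e-12) & (self.t < t1 - 1e-12))[0]

    def events_in_beat(self, beat: int) -> list:
        t0 = self.beat_starts[beat]
        t1 = self.beat_starts[beat + 1]
        return [e for e in self.events if t0 - 1e-9 <= e.t < t1 - 1e-9]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "P_V": self.P_V,
                "P_A": self.P_A,
                "P_arc": self.P_arc,
                "P_a": self.P_a,
                "P_v": self.P_v,
                "V_V": self.V_V,
                "V_A": self.V_A,
                "Q_a": self.Q_a,
                "mitral_open": self.mitral_open.astype(int),
                "aortic_open": self.aortic_open.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        """One row per sample, columns as in ``TRACE_COLUMNS``."""
        self.to_dataframe().to_csv(path, index=False)

    @property
    def total_volume(self) -> np.ndarray:
        """Instantaneous conserved blood volume at every sample."""
        # charge volumes are recoverable from node pressures only up to the
        # viscoelastic term, so recompute from the stored state trajectory
        return self._state_volumes

    _state_volumes: np.ndarray = field(default=None, repr=False)  # type: ignore


def auto_initial_state(
    config: SimulationConfig, circ: CircuitParameters
) -> CirculationState:
    """Default initial condition: V_V = 120 ml, V_A = 60 ml, the remaining
    blood split across the compliances proportionally to capacitance (equal
    starting pressures).  The 60 s run-in erases this choice."""
    V_V, V_A = 120.0, 60.0
    rest = config.total_blood_volume - V_V - V_A
    if rest <= 0:
        raise ValueError("total_blood_volume too small for default chambers")
    C_sum = circ.C_a1 + circ.C_a2 + circ.C_v
    return CirculationState(
        V_A=V_A,
        V_V=V_V,
        q_a1=rest * circ.C_a1 / C_sum,
        q_a2=rest * circ.C_a2 / C_sum,
        q_v=rest * circ.C_v / C_sum,
        Q_a=0.0,
        V_Ved_latch=V_V,
        mitral_open=True,
        aortic_open=False,
    )


def run(
    config: SimulationConfig,
    vent: VentricleParameters,
    atr: AtriumParameters,
    circ: CircuitParameters,
    initial: Optional[CirculationState] = None,
) -> SimulatedTrace:
    """Integrate the circulation for ``config.duration`` seconds.

    ``initial`` continues from an explicit state (e.g. the final state of a
    previous run, for scenario switching at a beat boundary); otherwise the
    auto initial condition distributes ``total_blood_volume``.
    """
    period = config.period
    f, pressures = make_rhs(vent, atr, circ, period)
    state = initial if initial is not None else auto_initial_state(config, circ)
    y = np.asarray(state.y, dtype=float)
    latch = state.V_Ved_latch
    T = config.duration

    # make the initial discrete valve modes consistent with the pressures
    P_A0, P_V0, P_arc0, _, _ = pressures(0.0, y, latch)
    mitral_open = P_A0 > P_V0
    aortic_open = state.aortic_open and y[5] > 0.0
    if not aortic_open and P_V0 > P_arc0:
        aortic_open = True
    if initial is None and not mitral_open:
        # auto start is early diastole; latch end-diastolic volume at once
        latch = y[1]

    # snap the sampling step to an integer number of samples per beat so
    # every beat is sampled at identical phases (beat-to-beat metric
    # comparisons are then free of grid-phase aliasing)
    n_per_beat = max(int(round(period / config.output_dt)), 3)
    dt_eff = period / n_per_beat
    grid = np.arange(0, int(math.ceil(T / dt_eff)) + 1) * dt_eff
    grid = grid[grid <= T + 1e-12]

    ts, ys, latches = [], [], []
    modes = []
    events_log: list[ValveEvent] = []

    def ev_mitral(t, yv, *args):
        P_A, P_V, *_ = pressures(t, yv, latch)
        return P_A - P_V

    def ev_aortic_open(t, yv, *args):
        _, P_V, P_arc, _, _ = pressures(t, yv, latch)
        return P_V - P_arc

    def ev_aortic_close(t, yv, *args):
        return yv[5]

    for e in (ev_mitral, ev_aortic_open, ev_aortic_close):
        e.terminal = True

    t0 = 0.0
    n_segments = 0
    max_segments = int(12 * T / period) + 50
    while t0 < T - 1e-12:
        ev_mitral.direction = -1.0 if mitral_open else 1.0
        if aortic_open:
            events = [ev_mitral, ev_aortic_close]
            ev_aortic_close.direction = -1.0
        else:
            events = [ev_mitral, ev_aortic_open]
            ev_aortic_open.direction = 1.0

        t_eval = grid[(grid > t0 + 1e-12) & (grid <= T + 1e-12)]
        sol = solve_ivp(
            f,
            (t0, T),
            y,
            method=config.method,
            t_eval=t_eval if len(t_eval) else None,
            events=events,
            args=(mitral_open, aortic_open, latch),
            rtol=config.rel_tol,
            atol=config.abs_tol,
            max_step=config.max_step,
        )
        if sol.status == -1:
            raise SimulationError(
                f"integrator failed: {sol.message}",
                t0,
                state.with_y(y),
            )
        if len(sol.t):
            ts.append(sol.t)
            ys.append(sol.y)
            latches.append(np.full(len(sol.t), latch))
            modes.append(
                np.tile(np.array([[mitral_open], [aortic_open]]), (1, len(sol.t)))
            )
        if sol.status == 1:
            # earliest triggered event wins
            cand = [
                (te[0], i) for i, te in enumerate(sol.t_events) if len(te)
            ]
            t_ev, which = min(cand)
            y_ev = sol.y_events[which][0].copy()
            ev_fun = events[which]
            if ev_fun is ev_mitral:
                mitral_open = not mitral_open
                kind = "mitral_open" if mitral_open else "mitral_close"
                if kind == "mitral_close":
                    latch = y_ev[1]
            elif ev_fun is ev_aortic_open:
                aortic_open = True
                kind = "aortic_open"
            else:
                aortic_open = False
                kind = "aortic_close"
                y_ev[5] = 0.0
            events_log.append(ValveEvent(t=t_ev, kind=kind, V_V=y_ev[1], V_A=y_ev[0]))
            t0, y = t_ev, y_ev
        else:
            t0 = T
            y = sol.y[:, -1] if len(sol.t) else y
        n_segments += 1
        if n_segments > max_segments:
            raise SimulationError(
                "valve chattering: too many integration segments",
                t0,
                state.with_y(y),
            )

    t_arr = np.concatenate(ts) if ts else np.array([0.0])
    y_arr = np.concatenate(ys, axis=1) if ys else y[:, None]
    latch_arr = np.concatenate(latches) if latches else np.array([latch])
    mode_arr = np.concatenate(modes, axis=1) if modes else np.array(
        [[mitral_open], [aortic_open]]
    )

    n = len(t_arr)
    P_A_a = np.empty(n)
    P_V_a = np.empty(n)
    P_arc_a = np.empty(n)
    P_a_a = np.empty(n)
    P_v_a = np.empty(n)
    for i in range(n):
        P_A_a[i], P_V_a[i], P_arc_a[i], P_a_a[i], P_v_a[i] = pressures(
            t_arr[i], y_arr[:, i], latch_arr[i]
        )

    final_state = CirculationState(
        V_A=y[0],
        V_V=y[1],
        q_a1=y[2],
        q_a2=y[3],
        q_v=y[4],
        Q_a=y[5],
        V_Ved_latch=latch,
        mitral_open=bool(mitral_open),
        aortic_open=bool(aortic_open),
    )
    trace = SimulatedTrace(
        t=t_arr,
        P_V=P_V_a,
        P_A=P_A_a,
        P_arc=P_arc_a,
        P_a=P_a_a,
        P_v=P_v_a,
        V_V=y_arr[1],
        V_A=y_arr[0],
        Q_a=y_arr[5],
        V_Ved=latch_arr,
        mitral_open=mode_arr[0].astype(bool),
        aortic_open=mode_arr[1].astype(bool),
        events=events_log,
        period=period,
        heart_rate=config.heart_rate,
        final_state=final_state,
        config=config,
    )
    trace._state_volumes = y_arr[0] + y_arr[1] + y_arr[2] + y_arr[3] + y_arr[4]
    log.debug(
        "run finished: %d beats, %d samples, %d valve events",
        trace.n_beats,
        n,
        len(events_log),
    )
    return trace


@dataclass
class SteadyCycleResult:
    """Outcome of steady-cycle detection.

    ``beat_index`` is the first beat whose metrics all agree with the
    previous beat to within ``threshold`` (relative); ``None`` if the run
    never converged.  ``metric`` is the max relative beat-to-beat change at
    that beat (or at the final beat when not converged).
    """

    converged: bool
    beat_index: Optional[int]
    metric: float
    threshold: float = 1e-4


_STEADY_FIELDS = (
    "IVCD_ms",
    "EPD_ms",
    "dPdt_max",
    "EF",
    "SV",
    "CO",
    "P_a_s",
    "P_a_d",
    "V_Ved",
    "V_Ves",
    "W_LV",
)


def detect_steady_cycle(
    trace: SimulatedTrace, threshold: float = 1e-4
) -> SteadyCycleResult:
    """First beat whose per-beat indexes repeat to within ``threshold``.

    Requires at least three complete beats.  Non-convergence is a reported
    result, not an exception.
    """
    from . import metrics as _metrics

    if trace.n_beats < 3:
        raise ValueError("steady-cycle detection requires >= 3 complete beats")
    prev = None
    last_change = math.inf
    for b in range(trace.n_beats):
        try:
            m = _metrics.beat_metrics(trace, b)
        except _metrics.DegenerateBeatError:
            prev = None
            continue
        if prev is not None:
            rel = 0.0
            for name in _STEADY_FIELDS:
                a, p = getattr(m, name), getattr(prev, name)
                denom = abs(p) if p != 0 else 1.0
                rel = max(rel, abs(a - p) / denom)
            last_change = rel
            if rel < threshold:
                return SteadyCycleResult(True, b, rel, threshold)
        prev = m
    return SteadyCycleResult(False, None, last_change, threshold)
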