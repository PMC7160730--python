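"""Analytic single-beat traces with known metric values.

These builders emit :class:`~windkessel.engine.SimulatedTrace` objects whose
indexes are exact by construction (linear pressure ramps, rectangular
pressure-volume loops, sinusoidal arterial pressure), for validating the
metric extractors independently of the ODE solver.  They are synthetic
stand-ins, not simulator output.
"""

from __future__ import annotations

import numpy as np

from .circuit import CirculationState
from .engine import SimulatedTrace, ValveEvent

__all__ = ["ramp_beat", "rectangle_loop_beat", "sinusoidal_beat"]

_PERIOD = 60.0 / 72.0


def _empty_state() -> CirculationState:
    return CirculationState(
        V_A=0.0, V_V=0.0, q_a1=0.0, q_a2=0.0, q_v=0.0, Q_a=0.0, V_Ved_latch=0.0
    )


def _assemble(t, P_V, P_a, V_V, events, period) -> SimulatedTrace:
    n = len(t)
    z = np.zeros(n)
    return SimulatedTrace(
        t=t,
        P_V=P_V,
        P_A=z.copy(),
        P_arc=P_a.copy(),
        P_a=P_a,
        P_v=z.copy(),
        V_V=V_V,
        V_A=z.copy(),
        Q_a=z.copy(),
        V_Ved=np.full(n, V_V.max() if len(V_V) else 0.0),
        mitral_open=np.zeros(n, dtype=bool),
        aortic_open=np.zeros(n, dtype=bool),
        events=events,
        period=period,
        heart_rate=60.0 / period,
        final_state=_empty_state(),
    )


def ramp_beat(
    p_start: float = 0.0,
    p_end: float = 80.0,
    ivc_duration: float = 0.050,
    dt: float = 0.001,
    period: float = _PERIOD,
) -> SimulatedTrace:
    """One beat whose LV pressure rises linearly over the IVC window.

    The exact peak dP/dt is ``(p_end - p_start)/ivc_duration``; outside the
    window the pressure is held constant.
    """
    t = np.round(np.arange(0.0, period, dt), 9)
    t_mc, t_ao = 0.1, 0.1 + ivc_duration
    slope = (p_end - p_start) / ivc_duration
    P_V = np.clip((t - t_mc) * slope + p_start, p_start, p_end)
    P_V[t < t_mc] = p_start
    V = np.full_like(t, 120.0)
    t_ac = min(t_ao + 0.2, period - 2 * dt)
    events = [
        ValveEvent(t=t_mc, kind="mitral_close", V_V=120.0, V_A=0.0),
        ValveEvent(t=t_ao, kind="aortic_open", V_V=120.0, V_A=0.0),
        ValveEvent(t=t_ac, kind="aortic_close", V_V=120.0, V_A=0.0),
    ]
    return _assemble(t, P_V, P_V.copy(), V, events, period)


def rectangle_loop_beat(
    p_low: float = 80.0,
    p_high: float = 120.0,
    v_low: float = 40.0,
    v_high: float = 120.0,
    dt: float = 0.001,
    period: float = _PERIOD,
    clockwise: bool = True,
) -> SimulatedTrace:
    """One beat tracing a rectangular P_V-V_V loop.

    Exact loop area is ``(p_high - p_low) * (v_high - v_low)`` mmHg*ml
    regardless of traversal direction.
    """
    t = np.round(np.arange(0.0, period, dt), 9)
    n = len(t)
    q = n // 4
    P_V = np.empty(n)
    V = np.empty(n)
    # corners: (v_high,p_low) -> (v_high,p_high) -> (v_low,p_high) -> (v_low,p_low)
    seg = [
        (v_high, v_high, p_low, p_high),
        (v_high, v_low, p_high, p_high),
        (v_low, v_low, p_high, p_low),
        (v_low, v_high, p_low, p_low),
    ]
    bounds = [0, q, 2 * q, 3 * q, n]
    for (v0, v1, pp0, pp1), lo, hi in zip(seg, bounds[:-1], bounds[1:]):
        frac = np.linspace(0.0, 1.0, hi - lo, endpoint=False)
        V[lo:hi] = v0 + (v1 - v0) * frac
        P_V[lo:hi] = pp0 + (pp1 - pp0) * frac
    if not clockwise:
        V = V[::-1].copy()
        P_V = P_V[::-1].copy()
    events = [
        ValveEvent(t=t[0], kind="mitral_close", V_V=v_high, V_A=0.0),
        ValveEvent(t=t[q], kind="aortic_open", V_V=v_high, V_A=0.0),
        ValveEvent(t=t[2 * q], kind="aortic_close", V_V=v_low, V_A=0.0),
        ValveEvent(t=t[3 * q], kind="mitral_open", V_V=v_low, V_A=0.0),
    ]
    return _assemble(t, P_V, np.full(n, p_low), V, events, period)


def sinusoidal_beat(
    mean: float = 100.0,
    amplitude: float = 20.0,
    dt: float = 0.001,
    period: float = _PERIOD,
) -> SimulatedTrace:
    """One beat with a sinusoidal aortic pressure (exact extrema mean +/- amplitude)."""
    t = np.round(np.arange(0.0, period, dt), 9)
    P_a = mean + amplitude * np.sin(2.0 * np.pi * t / period)
    P_V = np.zeros_like(t)
    V = np.full_like(t, 100.0)
    events = [
        ValveEvent(t=t[1], kind="mitral_close", V_V=100.0, V_A=0.0),
        ValveEvent(t=t[2], kind="aortic_open", V_V=100.0, V_A=0.0),
        ValveEvent(t=t[3], kind="aortic_close", V_V=100.0, V_A=0.0),
    ]
    tr = _assemble(t, P_V, P_a.copy(), V, events, period)
    tr.P_a = P_a
    return tr
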