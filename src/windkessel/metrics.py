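"""Per-beat hemodynamic indexes extracted from a simulated trace.

Phase boundaries come from the exact valve-event log rather than from
pressure thresholds, so interval metrics (IVCD, EPD) are event-resolved and
not quantized to the output grid.  (dP/dt)max is a centred finite
difference over the isovolumic-contraction window with a local quadratic
refinement; LV power is the pressure-volume loop area times heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SimulatedTrace

__all__ = [
    "MMHG_ML_TO_J",
    "BeatMetrics",
    "BeatPhases",
    "DegenerateBeatError",
    "segment_beat",
    "dpdt_max",
    "dpdt_max_series",
    "pv_loop_power",
    "arterial_extrema",
    "beat_metrics",
    "read_pressure_csv",
]

#: 1 mmHg*ml in joules (single place for the unit conversion).
MMHG_ML_TO_J = 1.33322e-4


class DegenerateBeatError(ValueError):
    """The beat lacks a full valve cycle (e.g. the aortic valve never opened)."""


@dataclass(frozen=True)
class BeatPhases:
    """Event times (s, absolute) delimiting the phases of one beat."""

    mitral_close: float
    aortic_open: float
    aortic_close: float
    mitral_open: Optional[float]

    @property
    def IVCD_ms(self) -> float:
        return 1e3 * (self.aortic_open - self.mitral_close)

    @property
    def EPD_ms(self) -> float:
        return 1e3 * (self.aortic_close - self.aortic_open)


@dataclass(frozen=True)
class BeatMetrics:
    """Steady-cycle indexes of one beat.

    ``IVCD_ms``: isovolumic contraction duration; ``EPD_ms``: ejection
    phase duration; ``dPdt_max``: peak LV pressure-rise rate (mmHg/s);
    ``EF`` in %, ``SV`` in ml, ``CO`` in ml/min; ``P_a_s``/``P_a_d``:
    systolic/diastolic aortic pressure; ``V_Ved``/``V_Ves``: end-diastolic /
    end-systolic LV volume; ``stroke_work_J`` in J and ``W_LV`` in W.
    """

    IVCD_ms: float
    EPD_ms: float
    dPdt_max: float
    EF: float
    SV: float
    CO: float
    P_a_s: float
    P_a_d: float
    V_Ved: float
    V_Ves: float
    stroke_work_J: float
    W_LV: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def segment_beat(trace: "SimulatedTrace", beat: int) -> BeatPhases:
    """Phase boundaries of beat ``beat`` from the valve-event log.

    Raises :class:`DegenerateBeatError` when the beat has no complete
    mitral-close -> aortic-open -> aortic-close sequence.
    """
    evs = trace.events_in_beat(beat)
    times = {}
    for e in evs:
        times.setdefault(e.kind, e.t)
    try:
        mc, ao, ac = (
            times["mitral_close"],
            times["aortic_open"],
            times["aortic_close"],
        )
    except KeyError as missing:
        raise DegenerateBeatError(
            f"beat {beat}: missing valve transition {missing}"
        ) from None
    if not mc < ao < ac:
        raise DegenerateBeatError(f"beat {beat}: valve events out of order")
    return BeatPhases(
        mitral_close=mc,
        aortic_open=ao,
        aortic_close=ac,
        mitral_open=times.get("mitral_open"),
    )


def dpdt_max_series(t: np.ndarray, P: np.ndarray) -> float:
    """Peak dP/dt of a sampled pressure series (mmHg/s).

    Centred finite differences on the interior samples with a quadratic
    (three-point parabola) refinement around the discrete maximum.
    """
    t = np.asarray(t, dtype=float)
    P = np.asarray(P, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples for a centred dP/dt")
    dp = (P[2:] - P[:-2]) / (t[2:] - t[:-2])
    k = int(np.argmax(dp))
    if 0 < k < len(dp) - 1:
        y0, y1, y2 = dp[k - 1], dp[k], dp[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0.0:
            return y1 - 0.125 * (y2 - y0) ** 2 / denom
    return float(dp[k])


def dpdt_max(trace: "SimulatedTrace", beat: int) -> float:
    """(dP_V/dt)max over the isovolumic-contraction window of ``beat``."""
    ph = segment_beat(trace, beat)
    mask = (trace.t >= ph.mitral_close) & (trace.t <= ph.aortic_open)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"beat {beat}: IVC window holds fewer than 3 samples; reduce output_dt"
        )
    return dpdt_max_series(trace.t[mask], trace.P_V[mask])


def pv_loop_power(
    trace: "SimulatedTrace", beat: int, heart_rate: Optional[float] = None
) -> dict:
    """Stroke work (J) and LV power (W) from the closed P_V-V_V loop.

    Shoelace integral over the beat's samples, closed between the last and
    first sample; orientation-independent (absolute area).
    """
    hr = heart_rate if heart_rate is not None else trace.heart_rate
    idx = trace.beat_indices(beat)
    P = trace.P_V[idx]
    V = trace.V_V[idx]
    # trapezoidal shoelace with explicit closure segment
    area = 0.5 * np.sum((P[1:] + P[:-1]) * (V[1:] - V[:-1]))
    area += 0.5 * (P[0] + P[-1]) * (V[0] - V[-1])
    stroke_work = abs(float(area)) * MMHG_ML_TO_J
    return {"stroke_work": stroke_work, "W_LV": stroke_work * hr / 60.0}


def arterial_extrema(trace: "SimulatedTrace", beat: int) -> dict:
    """Systolic (max) and diastolic (min) aortic pressure over one beat."""
    idx = trace.beat_indices(beat)
    P = trace.P_a[idx]
    return {"P_a_s": float(P.max()), "P_a_d": float(P.min())}


def beat_metrics(trace: "SimulatedTrace", beat: int) -> BeatMetrics:
    """Assemble all Table-style indexes for one beat.

    End-diastolic volume is the ventricular volume at mitral closure and
    end-systolic volume the ventricular volume at aortic closure, both read
    from the exact event states.
    """
    ph = segment_beat(trace, beat)
    evs = {e.kind: e for e in trace.events_in_beat(beat)}
    V_ed = evs["mitral_close"].V_V
    V_es = evs["aortic_close"].V_V
    sv = V_ed - V_es
    power = pv_loop_power(trace, beat)
    art = arterial_extrema(trace, beat)
    return BeatMetrics(
        IVCD_ms=ph.IVCD_ms,
        EPD_ms=ph.EPD_ms,
        dPdt_max=dpdt_max(trace, beat),
        EF=100.0 * sv / V_ed,
        SV=sv,
        CO=sv * trace.heart_rate,
        P_a_s=art["P_a_s"],
        P_a_d=art["P_a_d"],
        V_Ved=V_ed,
        V_Ves=V_es,
        stroke_work_J=power["stroke_work"],
        W_LV=power["W_LV"],
    )


def read_pressure_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Load an external two-column time/pressure series (t in s, P in mmHg).

    For such traces only :func:`dpdt_max_series` applies (no valve events).
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected a two-column CSV (time, pressure)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    P = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    return t, P
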