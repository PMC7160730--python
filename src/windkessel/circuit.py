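"""Electrical-analogue circuit of the left heart and systemic circulation.

Topology (left to right): left atrium -> mitral valve (diode, resistance
R_DAV) -> left ventricle -> aortic valve (diode, R_Da) in series with the
blood inertance L -> aortic-arch node (viscoelastic compliance C_a1 with
series resistance R_a1) -> aortic flow resistance R_a -> aorta node
(viscoelastic compliance C_a2, series R_a2) -> peripheral resistance R_p ->
venous node (purely elastic compliance C_v) -> venous return resistance R_v
-> back to the atrium.  The loop is closed, so total blood volume is
conserved exactly by construction.

State vector (6 differential states):

    y = [V_A, V_V, q_a1, q_a2, q_v, Q_a]

with chamber volumes V_A, V_V (ml), stored compliance volumes q_a1, q_a2,
q_v (ml) and aortic flow Q_a (ml/s) through the inertance.  The two
viscoelastic node pressures P_arc and P_a are algebraic: each depends on its
own charging rate, which in turn depends on both pressures, giving a 2x2
linear system solved in closed form at every evaluation.

Valves are two-state resistors: the open resistance from the parameter set,
or ``R_closed`` (1e4 mmHg*s/ml) when the forward pressure drop is
non-positive.  Switching is instantaneous; the integrator locates the sign
changes with event functions (see :mod:`windkessel.engine`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .chambers import AtriumParameters, VentricleParameters

__all__ = [
    "CircuitParameters",
    "CirculationState",
    "valve_resistance",
    "node_pressures",
    "rhs",
    "make_rhs",
]


class CircuitParameters(BaseModel):
    """Resistances (mmHg*s/ml), compliances (ml/mmHg) and inertance
    (mmHg*s^2/ml) of the systemic circuit."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    R_DAV: float = 0.012
    R_Da: float = 0.025
    R_closed: float = 1.0e4
    R_a1: float = 0.05
    R_a2: float = 0.026
    R_a: float = 0.0001
    R_p: float = 1.0
    R_v: float = 0.01
    C_a1: float = 0.08
    C_a2: float = 1.3
    C_v: float = 70.0
    L: float = 0.0003

    @model_validator(mode="after")
    def _check_positivity(self) -> "CircuitParameters":
        for name in self.__class__.model_fields:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        return self


@dataclass
class CirculationState:
    """Instantaneous state of the circulation.

    ``V_Ved_latch`` is the end-diastolic volume sampled at the most recent
    mitral-valve closure (per-beat Frank-Starling anchor); ``mitral_open``
    and ``aortic_open`` are the discrete valve modes.
    """

    V_A: float
    V_V: float
    q_a1: float
    q_a2: float
    q_v: float
    Q_a: float
    V_Ved_latch: float
    mitral_open: bool = True
    aortic_open: bool = False

    @property
    def y(self) -> np.ndarray:
        return np.array(
            [self.V_A, self.V_V, self.q_a1, self.q_a2, self.q_v, self.Q_a]
        )

    @property
    def total_volume(self) -> float:
        return self.V_A + self.V_V + self.q_a1 + self.q_a2 + self.q_v

    def with_y(self, y: np.ndarray) -> "CirculationState":
        return replace(
            self, V_A=y[0], V_V=y[1], q_a1=y[2], q_a2=y[3], q_v=y[4], Q_a=y[5]
        )


def valve_resistance(
    forward_pressure_drop: float, open_R: float, R_closed: float
) -> float:
    """State-dependent diode resistance.

    Open resistance for a strictly positive forward drop, ``R_closed``
    otherwise (tie at zero drop broken toward closed).
    """
    return open_R if forward_pressure_drop > 0.0 else R_closed


def node_pressures(
    state: CirculationState,
    P_A: float,
    P_V: float,
    cp: CircuitParameters,
) -> dict:
    """Solve the two algebraic viscoelastic node pressures.

    P_arc = q_a1/C_a1 + R_a1*dq_a1/dt and P_a = q_a2/C_a2 + R_a2*dq_a2/dt,
    where the charging rates are flow balances that themselves involve
    P_arc and P_a; the resulting 2x2 linear system is solved exactly.
    P_v = q_v/C_v is purely elastic.
    """
    P_v = state.q_v / cp.C_v
    alpha = cp.R_a1 / cp.R_a
    beta = cp.R_a2 / cp.R_a
    gamma = cp.R_a2 / cp.R_p
    b1 = state.q_a1 / cp.C_a1 + cp.R_a1 * state.Q_a
    b2 = state.q_a2 / cp.C_a2 + gamma * P_v
    a11 = 1.0 + alpha
    a12 = -alpha
    a21 = -beta
    a22 = 1.0 + beta + gamma
    det = a11 * a22 - a12 * a21
    if det == 0.0 or not math.isfinite(det):
        raise ValueError("singular viscoelastic node system; check R_a, R_a1, R_a2")
    P_arc = (b1 * a22 - a12 * b2) / det
    P_a = (a11 * b2 - a21 * b1) / det
    return {"P_arc": P_arc, "P_a": P_a, "P_v": P_v}


def _build_cores(decorate):
    """Scalar evaluation cores; ``decorate`` is numba.njit when available."""
    if decorate is None:
        decorate = lambda f: f  # noqa: E731

    @decorate
    def chamber_pressures(t_c, V_A, V_V, V_ed, c):
        # ventricle
        dt = abs(t_c - c[6])
        f_Vc = math.exp(-((c[2] * dt) ** c[4]) - (c[3] * dt) ** c[5])
        ratio = V_V / V_ed
        if ratio >= 1.0:
            f_Ve = 1.0
        else:
            f_Ve = 1.0 - (1.0 / c[7]) * (-math.log(ratio)) ** c[8]
        p_pass = c[0] * V_V * V_V * V_V
        p_iv = c[10] - c[1] * (V_ed - c[11]) ** 2
        if c[12] > 0.0:
            x_v = (c[9] / V_V + 1.0) ** (1.0 / 3.0) - 1.0
            x_e = (c[9] / V_ed + 1.0) ** (1.0 / 3.0) - 1.0
            p_iv *= (2.0 * x_v + x_v * x_v) / (2.0 * x_e + x_e * x_e)
        P_V = p_pass + (p_iv - p_pass) * f_Vc * c[13] * f_Ve
        # atrium
        dta = abs(t_c - c[18])
        f_Ac = math.exp(-((c[16] * dta) ** c[17]))
        P_A = c[14] * V_A**5 + f_Ac * (c[20] - c[15] * (V_A - c[19]) ** 2)
        return P_A, P_V

    @decorate
    def rhs_core(t, y, c, mitral_open, aortic_open, latch):
        t_c = t % c[21]
        P_A, P_V = chamber_pressures(t_c, y[0], y[1], latch, c)
        P_v = y[4] / c[33]
        b1 = y[2] / c[31] + c[24] * y[5]
        b2 = y[3] / c[32] + c[37] * P_v
        P_arc = (b1 * c[35] + c[36] * b2) * c[38]
        P_a = (c[34] * b2 + c[39] * b1) * c[38]
        Q_AV = (P_A - P_V) / (c[22] if mitral_open else c[40])
        Q_1 = (P_arc - P_a) / c[26]
        Q_2 = (P_a - P_v) / c[27]
        Q_ven = (P_v - P_A) / c[28]
        dQ_a = (P_V - P_arc - (c[23] if aortic_open else c[40]) * y[5]) / c[30]
        out = np.empty(6)
        out[0] = Q_ven - Q_AV
        out[1] = Q_AV - y[5]
        out[2] = y[5] - Q_1
        out[3] = Q_1 - Q_2
        out[4] = Q_2 - Q_ven
        out[5] = dQ_a
        return out

    @decorate
    def pressures_core(t, y, c, latch):
        t_c = t % c[21]
        P_A, P_V = chamber_pressures(t_c, y[0], y[1], latch, c)
        P_v = y[4] / c[33]
        b1 = y[2] / c[31] + c[24] * y[5]
        b2 = y[3] / c[32] + c[37] * P_v
        P_arc = (b1 * c[35] + c[36] * b2) * c[38]
        P_a = (c[34] * b2 + c[39] * b1) * c[38]
        return P_A, P_V, P_arc, P_a, P_v

    return chamber_pressures, rhs_core, pressures_core


try:  # pragma: no cover - exercised when numba is installed
    from numba import njit as _njit

    _chamber_core, _rhs_core, _pressures_core = _build_cores(_njit(cache=False))
except ImportError:  # pragma: no cover
    _chamber_core, _rhs_core, _pressures_core = _build_cores(None)


def make_rhs(
    vent: VentricleParameters,
    atr: AtriumParameters,
    circ: CircuitParameters,
    period: float,
):
    """Build fast scalar closures over the model parameters.

    Returns ``(f, pressures)`` where ``f(t, y, mitral_open, aortic_open,
    V_Ved_latch)`` evaluates the six time derivatives and ``pressures(t, y,
    V_Ved_latch)`` returns ``(P_A, P_V, P_arc, P_a, P_v)``.  Both accept
    scalar ``t`` with array-broadcastable ``y`` only in ``pressures``.
    """
    c = np.empty(41)
    c[0] = vent.a_V
    c[1] = vent.b_V
    c[2] = vent.k_V1
    c[3] = vent.k_V2
    c[4] = vent.i_V1
    c[5] = vent.i_V2
    c[6] = vent.t_Vmax
    c[7] = vent.K_e
    c[8] = vent.i_e
    c[9] = vent.V_m
    c[10] = vent.P_Vivmax_M
    c[11] = vent.V_Ved_M
    c[12] = 1.0 if vent.laplace_gain else 0.0
    c[13] = vent.K_Vc
    c[14] = atr.a_A
    c[15] = atr.b_A
    c[16] = atr.k_A
    c[17] = atr.i_A
    c[18] = atr.t_Amax
    c[19] = atr.V_A_M
    c[20] = atr.P_Ac_max
    c[21] = period
    c[22] = circ.R_DAV
    c[23] = circ.R_Da
    c[24] = circ.R_a1
    c[25] = circ.R_a2
    c[26] = circ.R_a
    c[27] = circ.R_p
    c[28] = circ.R_v
    c[29] = 0.0
    c[30] = circ.L
    c[31] = circ.C_a1
    c[32] = circ.C_a2
    c[33] = circ.C_v
    alpha = circ.R_a1 / circ.R_a
    beta = circ.R_a2 / circ.R_a
    gamma = circ.R_a2 / circ.R_p
    a11 = 1.0 + alpha
    a22 = 1.0 + beta + gamma
    c[34] = a11
    c[35] = a22
    c[36] = alpha
    c[37] = gamma
    c[38] = 1.0 / (a11 * a22 - alpha * beta)
    c[39] = beta
    c[40] = circ.R_closed

    def f(t, y, mitral_open, aortic_open, V_Ved_latch):
        return _rhs_core(t, y, c, mitral_open, aortic_open, V_Ved_latch)

    def pressures(t, y, V_Ved_latch):
        return _pressures_core(t, y, c, V_Ved_latch)

    return f, pressures


def rhs(
    t: float,
    state: CirculationState,
    vent: VentricleParameters,
    atr: AtriumParameters,
    circ: CircuitParameters,
    period: float,
) -> np.ndarray:
    """Time derivatives d/dt [V_A, V_V, q_a1, q_a2, q_v, Q_a] at time ``t``.

    Reference entry point for single evaluations; the simulation engine uses
    the closures from :func:`make_rhs` instead.
    """
    f, _ = make_rhs(vent, atr, circ, period)
    dy = f(t, state.y, state.mitral_open, state.aortic_open, state.V_Ved_latch)
    if not np.all(np.isfinite(dy)):
        labels = ["dV_A", "dV_V", "dq_a1", "dq_a2", "dq_v", "dQ_a"]
        bad = [lab for lab, v in zip(labels, dy) if not math.isfinite(v)]
        raise ArithmeticError(f"non-finite derivative(s): {', '.join(bad)}")
    return dy
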