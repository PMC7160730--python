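"""Constitutive laws of the left ventricle and left atrium.

The ventricle is a thick-walled sphere (law of Laplace) whose wall develops
active stress according to a twitch activation function, scaled by the
Frank-Starling relation between end-diastolic volume and contraction
strength.  Passive and peak-isovolumic behaviour are low-order polynomial
pressure-volume curves; the atrium is a simplified quintic bag with a short
active twitch timed ahead of the ventricle.

All pressures are in mmHg, volumes in ml, times in seconds (measured from
the sinoatrial excitation that starts the current beat).
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "VentricleParameters",
    "AtriumParameters",
    "passive_lv_pressure",
    "isovolumic_max_pressure",
    "area_factor",
    "lv_activation",
    "ejection_derating",
    "lv_wall_stress",
    "lv_pressure",
    "atrial_activation",
    "la_pressure",
]


class VentricleParameters(BaseModel):
    """Constitutive constants of the left ventricle.

    ``P_Vivmax_M`` is the peak isovolumic pressure (mmHg) achievable at the
    end-diastolic volume ``V_Ved_M`` (ml); ``P_Ved_M`` is the passive
    end-diastolic pressure at that same volume.  The polynomial coefficients
    ``a_V`` (mmHg/ml^3) and ``b_V`` (mmHg/ml^2) follow from these anchor
    points and are exposed as derived properties.

    ``k_V1, k_V2`` (1/s) and ``i_V1, i_V2`` shape the contraction /
    relaxation twitch, which peaks ``t_Vmax`` seconds after sinoatrial
    excitation.  ``K_Vc`` scales the active stress (contractility, 1 under
    control conditions); ``K_e, i_e`` shape the ejection de-rating of wall
    stress as the cavity empties.  ``V_m`` is the (constant) muscle-wall
    volume in ml used by the spherical Laplace geometry.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    P_Vivmax_M: float = 275.0
    V_Ved_M: float = 200.0
    P_Ved_M: float = 32.0
    K_Vc: float = 1.0
    k_V1: float = 5.68722
    k_V2: float = 5.2270
    i_V1: float = 2.0224
    i_V2: float = 9.11538
    t_Vmax: float = 0.3568
    K_e: float = 1.355
    i_e: float = 0.35
    V_m: float = 300.0
    laplace_gain: bool = True

    @model_validator(mode="after")
    def _check_positivity(self) -> "VentricleParameters":
        for name in ("K_Vc", "k_V1", "k_V2", "V_m", "V_Ved_M", "t_Vmax", "K_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (self.P_Vivmax_M > self.P_Ved_M > 0):
            raise ValueError("require P_Vivmax_M > P_Ved_M > 0")
        return self

    @property
    def a_V(self) -> float:
        """Cubic passive coefficient, P_Ved_M / V_Ved_M^3 (mmHg/ml^3)."""
        return self.P_Ved_M / self.V_Ved_M**3

    @property
    def b_V(self) -> float:
        """Quadratic isovolumic-maximum coefficient, P_Vivmax_M / V_Ved_M^2."""
        return self.P_Vivmax_M / self.V_Ved_M**2


class AtriumParameters(BaseModel):
    """Constitutive constants of the left atrium.

    Passive behaviour is the quintic ``P = a_A V^5`` anchored at
    (``V_A_M`` = 100 ml, ``P_A_M`` = 30 mmHg); the active twitch adds up to
    ``P_Ac_max`` = 7.5 mmHg, tapered by ``b_A`` away from ``V_A_M`` and gated
    by an activation pulse peaking at ``t_Amax``.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    V_A_M: float = 100.0
    P_A_M: float = 30.0
    b_A: float = 0.00075
    P_Ac_max: float = 7.5
    k_A: float = 24.0
    i_A: float = 7.0
    t_Amax: float = 0.12

    @model_validator(mode="after")
    def _check_positivity(self) -> "AtriumParameters":
        for name in ("V_A_M", "P_A_M", "k_A", "t_Amax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        return self

    @property
    def a_A(self) -> float:
        """Quintic passive coefficient, P_A_M / V_A_M^5 (mmHg/ml^5)."""
        return self.P_A_M / self.V_A_M**5


def passive_lv_pressure(V: float, p: VentricleParameters) -> float:
    """Passive (end-diastolic) LV pressure a_V*V^3 at cavity volume ``V`` ml."""
    if V < 0:
        raise ValueError("ventricular volume must be non-negative")
    return p.a_V * V**3


def isovolumic_max_pressure(V_ed: float, p: VentricleParameters) -> float:
    """Peak pressure of a persisting isovolumic contraction at volume ``V_ed``.

    Quadratic Frank-Starling curve with maximum ``P_Vivmax_M`` at
    ``V_Ved_M``; contraction strength falls off on both sides.
    """
    if V_ed < 0:
        raise ValueError("end-diastolic volume must be non-negative")
    return p.P_Vivmax_M - p.b_V * (V_ed - p.V_Ved_M) ** 2


def area_factor(V_m: float, V_V: float) -> float:
    """Laplace geometry factor A_V = 2(h/r) + (h/r)^2 of a thick spherical shell.

    ``h/r`` is recovered from the wall-to-cavity volume ratio via the real
    root of (1 + h/r)^3 = V_m/V_V + 1.  P_V = sigma_V * A_V converts wall
    stress to cavity pressure; A_V grows as the cavity empties.
    """
    if V_V <= 0:
        raise ValueError("cavity volume must be strictly positive")
    if V_m < 0:
        raise ValueError("wall volume must be non-negative")
    x = (V_m / V_V + 1.0) ** (1.0 / 3.0) - 1.0  # h/r
    return 2.0 * x + x * x


def lv_activation(t_cycle: float, p: VentricleParameters) -> float:
    """Ventricular twitch f_Vc in [0, 1], peaking at ``t_Vmax``.

    ``exp(-(k_V1|t - t_Vmax|)^i_V1 - (k_V2|t - t_Vmax|)^i_V2)``: the slow
    first term shapes the rise, the steep second term forces near-complete
    relaxation within ~0.35 s of the peak.
    """
    dt = abs(t_cycle - p.t_Vmax)
    return math.exp(-((p.k_V1 * dt) ** p.i_V1) - (p.k_V2 * dt) ** p.i_V2)


def ejection_derating(V_V: float, V_Ved: float, p: VentricleParameters) -> float:
    """Stress de-rating f_Ve = 1 - (1/K_e)(-ln(V_V/V_Ved))^i_e during ejection.

    Models the loss of fibre stretch as the cavity empties below the
    end-diastolic volume; clamped to 1 whenever V_V >= V_Ved (filling).
    """
    if V_V <= 0:
        raise ValueError("cavity volume must be strictly positive")
    ratio = V_V / V_Ved
    if ratio >= 1.0:
        return 1.0
    return 1.0 - (1.0 / p.K_e) * (-math.log(ratio)) ** p.i_e


def lv_pressure(
    t_cycle: float, V_V: float, V_Ved: float, p: VentricleParameters
) -> float:
    """Instantaneous LV cavity pressure (mmHg).

    Mixes the passive cubic and the Frank-Starling isovolumic-maximum curve
    through the activation twitch:

        P_V = P_pass(V_V) + (P_ivmax(V_Ved)*G - P_pass(V_V)) * f_Vc*K_Vc*f_Ve

    where G = A_V(V_V)/A_V(V_Ved) is the Laplace geometry gain: the active
    wall-stress amplitude is anchored at end-diastolic geometry, so as the
    cavity empties during ejection the relatively thicker wall transmits the
    same stress into a higher cavity pressure (G > 1).  With
    ``laplace_gain=False`` the geometry factor cancels (G = 1) and P_V is a
    pure pressure interpolation.
    """
    p_pass = passive_lv_pressure(V_V, p)
    act = lv_activation(t_cycle, p) * p.K_Vc * ejection_derating(V_V, V_Ved, p)
    if p.laplace_gain:
        gain = area_factor(p.V_m, V_V) / area_factor(p.V_m, V_Ved)
    else:
        gain = 1.0
    return p_pass + (isovolumic_max_pressure(V_Ved, p) * gain - p_pass) * act


def lv_wall_stress(
    t_cycle: float, V_V: float, V_Ved: float, p: VentricleParameters
) -> float:
    """Normal wall stress sigma_V (mmHg) such that P_V = sigma_V * A_V(V_V)."""
    return lv_pressure(t_cycle, V_V, V_Ved, p) / area_factor(p.V_m, V_V)


def atrial_activation(t_cycle: float, p: AtriumParameters) -> float:
    """Atrial twitch f_Ac = exp(-(k_A|t - t_Amax|)^i_A), peaking at ``t_Amax``."""
    dt = abs(t_cycle - p.t_Amax)
    return math.exp(-((p.k_A * dt) ** p.i_A))


def la_pressure(t_cycle: float, V_A: float, p: AtriumParameters) -> float:
    """Instantaneous LA pressure: passive quintic plus gated active term.

    ``P_A = a_A V_A^5 + f_Ac * (P_Ac_max - b_A (V_A - V_A_M)^2)``.
    """
    if V_A < 0:
        raise ValueError("atrial volume must be non-negative")
    f_Ac = atrial_activation(t_cycle, p)
    return p.a_A * V_A**5 + f_Ac * (p.P_Ac_max - p.b_A * (V_A - p.V_A_M) ** 2)
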