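"""Oxygen-transport bookkeeping for the shunted Fontan circulation.

The atrial discharge is a right-to-left shunt: it drains partially
oxygenated device blood straight into the atrium, diluting the pulmonary-
vein return.  With perfect mixing the steady oxygen balance at the heart,

    Q_P * C_PV + Q_AD * C_AD = CO * C_sa,

together with the mixing closure C_AD = C_sv + m * (C_sa - C_sv), the
Fontan venous relation C_sv = 0.6 * C_sa, and the atrial mass balance
CO = Q_P + Q_AD, gives the closed form

    C_sa = Q_P * C_PV / (CO - (0.6 + 0.4 m) * Q_AD).

``m`` is the fraction of atrial-discharge oxygen content attributable to
aortic (arterial) blood; the 0D surrogate for the passive-scalar
surface average is perfect mixing at the throat, m = Q_AoG/(Q_AoG+Q_IVC).
Saturations are fractions in [0, 1] internally; reports use percent.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OxygenState",
    "C_PV_DEFAULT",
    "mixing_coefficient",
    "systemic_saturation",
    "venous_saturation",
    "ad_saturation",
    "oxygen_state",
    "qp_qs_check",
    "QP_QS_LIMIT",
    "SHUNT_FRACTION_BOUND",
]

#: pulmonary-vein saturation, chosen conservatively (avoids overestimating
#: arterial saturation).
C_PV_DEFAULT = 0.95

#: physiological limit on the pulmonary-to-systemic flow ratio; chronic
#: left-to-right shunt loads above it risk ventricular dysfunction.
QP_QS_LIMIT = 1.5

#: equivalent bound on Q_shunt/Q_S implied by Qp/Qs < 1.5 with the graft
#: as the only shunt (Q_P = Q_S + Q_shunt).
SHUNT_FRACTION_BOUND = QP_QS_LIMIT - 1.0


@dataclass(frozen=True)
class OxygenState:
    """Saturations (fractions) and the mixing coefficient for one solve."""

    C_sa: float
    C_sv: float
    C_AD: float
    C_PV: float
    m: float

    @property
    def C_sa_pct(self) -> float:
        return self.C_sa * 100.0

    @property
    def C_sv_pct(self) -> float:
        return self.C_sv * 100.0


def mixing_coefficient(Q_AoG: float, Q_IVC: float) -> float:
    """Perfect-mixing aortic contribution to the atrial discharge.

    m = Q_AoG / (Q_AoG + Q_IVC), clamped to [0, 1].  Undefined when both
    flows vanish (callers must short-circuit when the discharge carries
    no flow).
    """
    if Q_AoG < 0 or Q_IVC < 0:
        raise ValueError("flows must be non-negative")
    total = Q_AoG + Q_IVC
    if total == 0:
        raise ValueError("mixing coefficient undefined when both flows are zero")
    return min(1.0, max(0.0, Q_AoG / total))


def systemic_saturation(Q_P: float, Q_AD: float, CO: float, m: float,
                        C_PV: float = C_PV_DEFAULT) -> float:
    """Closed-form systemic arterial saturation (fraction)."""
    if CO <= 0:
        raise ValueError("cardiac output must be positive")
    if not 0.0 <= m <= 1.0:
        raise ValueError("mixing coefficient must be in [0, 1]")
    denom = CO - (0.6 + 0.4 * m) * Q_AD
    if denom <= 0:
        raise ValueError("unphysical flow set: saturation denominator <= 0")
    return Q_P * C_PV / denom


def venous_saturation(C_sa: float) -> float:
    """Fontan systemic venous saturation, C_sv = 0.6 * C_sa."""
    if not 0.0 < C_sa <= 1.0:
        raise ValueError("arterial saturation must be in (0, 1]")
    return 0.6 * C_sa


def ad_saturation(C_sa: float, C_sv: float, m: float) -> float:
    """Atrial-discharge saturation: convex mix of venous and arterial blood."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("mixing coefficient must be in [0, 1]")
    return C_sv + m * (C_sa - C_sv)


def oxygen_state(Q_AoG: float, Q_IVC: float, Q_AD: float, Q_P: float, CO: float,
                 C_PV: float = C_PV_DEFAULT) -> OxygenState:
    """Full oxygen bookkeeping for one solved hemodynamic state.

    When the atrial discharge carries no forward flow (Q_AD <= 0, i.e.
    closed or reversed) there is no right-to-left shunt and the arterial
    saturation equals the pulmonary-vein saturation.
    """
    if Q_AD <= 0.0:
        c_sa = C_PV
        m = mixing_coefficient(Q_AoG, Q_IVC) if (Q_AoG + Q_IVC) > 0 else 0.0
    else:
        m = mixing_coefficient(Q_AoG, Q_IVC)
        c_sa = systemic_saturation(Q_P, Q_AD, CO, m, C_PV)
    c_sv = venous_saturation(c_sa)
    c_ad = ad_saturation(c_sa, c_sv, m)
    return OxygenState(C_sa=c_sa, C_sv=c_sv, C_AD=c_ad, C_PV=C_PV, m=m)


def qp_qs_check(Q_shunt: float, Q_S: float) -> tuple[float, bool]:
    """Aortic graft flow criterion.

    With the graft as the only shunt, Qp/Qs = 1 + Q_shunt/Q_S; the design
    passes iff Q_shunt/Q_S < 0.5 (strictly), equivalently Qp/Qs < 1.5.
    """
    if Q_S <= 0:
        raise ValueError("systemic flow must be positive")
    if Q_shunt < 0:
        raise ValueError("shunt flow must be non-negative")
    ratio = 1.0 + Q_shunt / Q_S
    return ratio, Q_shunt / Q_S < SHUNT_FRACTION_BOUND
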