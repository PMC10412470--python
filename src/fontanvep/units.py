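"""Unit conversion constants.

Clinical quantities (pressures in mmHg, flows in L/min, diameters in mm)
are used at every public interface; all hydraulic arithmetic is done in SI
(Pa, m^3/s, m).  Keeping the conversions in one place avoids the classic
0.95-vs-95 / mmHg-vs-Pa class of bug.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

LMIN_TO_M3S = 1.0 / 60000.0
M3S_TO_LMIN = 60000.0

MM_TO_M = 1.0e-3


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa * PA_TO_MMHG


def lmin_to_m3s(q_lmin: float) -> float:
    return q_lmin * LMIN_TO_M3S


def m3s_to_lmin(q_m3s: float) -> float:
    return q_m3s * M3S_TO_LMIN
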