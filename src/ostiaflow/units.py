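"""Unit conversions used at the configuration and report boundary.

Everything inside the package is SI (m, s, kg, Pa). Millimetres of mercury,
millimetres, and cgs shear-stress units (dyn/cm^2) appear only in config keys
and reports, always with unit-bearing names.
"""

MMHG_TO_PA = 133.322
#: 1 mmHg.s/mL in Pa.s/m^3 (1 mL = 1e-6 m^3)
MMHG_S_PER_ML_TO_SI = MMHG_TO_PA / 1e-6
#: 1 Pa = 10 dyn/cm^2
PA_TO_CGS = 10.0
MM_TO_M = 1e-3


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def resistance_to_si(r_mmhg_s_per_ml: float) -> float:
    return r_mmhg_s_per_ml * MMHG_S_PER_ML_TO_SI


def resistance_from_si(r_si: float) -> float:
    return r_si / MMHG_S_PER_ML_TO_SI
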