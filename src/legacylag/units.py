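"""Unit conversions between field-reporting units and the internal canon.

Internal canon: years, metres, g/m^2 (areal mass), g/m^3 == mg/L
(concentration).  Configuration files accept the units the quantities are
usually reported in (kg/ha for soil N stocks, mm/y for recharge).
"""

KG_PER_HA_TO_G_PER_M2 = 0.1
MM_PER_Y_TO_M_PER_Y = 1.0e-3


def kg_per_ha_to_g_per_m2(x: float) -> float:
    return x * KG_PER_HA_TO_G_PER_M2


def g_per_m2_to_kg_per_ha(x: float) -> float:
    return x / KG_PER_HA_TO_G_PER_M2


def mm_per_y_to_m_per_y(x: float) -> float:
    return x * MM_PER_Y_TO_M_PER_Y


def m_per_y_to_mm_per_y(x: float) -> float:
    return x / MM_PER_Y_TO_M_PER_Y
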