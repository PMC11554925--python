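"""Unit conventions at the envelope/FBA boundary.

Specific rates on the production-envelope side are expressed in
g·gDW⁻¹·h⁻¹ (mass-based, convenient for process mass balances), while the
flux-balance side works in mmol·gDW⁻¹·h⁻¹. Conversion happens only here.
"""

# g/mol
MOLAR_MASS = {
    "glucose": 180.16,
    "acetoin": 88.11,
    "btd": 90.12,  # 2,3-butanediol
}


def g_to_mmol(species: str, rate_g: float) -> float:
    """Convert a mass-specific rate (g·gDW⁻¹·h⁻¹) to mmol·gDW⁻¹·h⁻¹."""
    return rate_g / MOLAR_MASS[species] * 1000.0


def mmol_to_g(species: str, rate_mmol: float) -> float:
    """Convert a molar-specific rate (mmol·gDW⁻¹·h⁻¹) to g·gDW⁻¹·h⁻¹."""
    return rate_mmol * MOLAR_MASS[species] / 1000.0
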