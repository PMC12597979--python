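"""Unit conversions for phosphorus concentrations.

Orthophosphate-phosphorus (PO4-P) concentrations are reported either as a
mass of elemental phosphorus per litre (μg·L⁻¹) or as a molar concentration
(μmol·L⁻¹).  Because PO4-P counts phosphorus atoms, the conversion uses the
atomic mass of phosphorus, not of the phosphate ion.
"""

PHOSPHORUS_MOLAR_MASS = 30.97
"""Atomic mass of phosphorus in g·mol⁻¹ (4 significant figures, the
precision conventionally used when preparing phosphate media; experimental
design tables round-trip exactly at this precision)."""


def ug_per_l_to_umol_per_l(ug_per_l: float) -> float:
    """Convert a PO4-P mass concentration (μg·L⁻¹) to μmol·L⁻¹."""
    return ug_per_l / PHOSPHORUS_MOLAR_MASS


def umol_per_l_to_ug_per_l(umol_per_l: float) -> float:
    """Convert a PO4-P molar concentration (μmol·L⁻¹) to μg·L⁻¹."""
    return umol_per_l * PHOSPHORUS_MOLAR_MASS
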