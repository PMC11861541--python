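"""Independent closed-form re-derivation of the workday risk index.

Deliberately coded as bare arithmetic against the raw table dictionaries —
no engine imports beyond the data containers — so it can serve as an
independent cross-check of the phase-ledger implementation.
"""

from pestrisk.reference_data import Formulation, ReferenceTables
from pestrisk.scenario import Phase, Scenario

# default engine constants, restated here on purpose
_WEIGHTS = {"head": 0.06, "face": 0.04, "hands": 0.20, "body": 0.60, "feet": 0.10}
_MAN_CONTACT = 3.0e-4


def _pf(tables: ReferenceTables, item: str) -> float:
    return 0.0 if item == "none" else tables.protection_table[item].fraction


def _band_fraction(tables: ReferenceTables, formulation: Formulation, conc: float) -> float:
    form = (
        Formulation.LIQUID_CONCENTRATE
        if formulation is Formulation.SOLUBLE_GRANULE
        else formulation
    )
    if conc < 30:
        band = (0.0, 30.0)
    elif conc < 60:
        band = (30.0, 60.0)
    elif conc < 80:
        band = (60.0, 80.0)
    else:
        band = (80.0, 100.0)
    return tables.formulation_table[form][band]


def closed_form_risk_percent(scenario: Scenario, tables: ReferenceTables) -> float:
    """Total workday risk in % of AOEL, as one pass of plain formulas."""
    p = tables.products[scenario.product_name.casefold()]
    ai = p.active_ingredient
    conc = p.concentration / 100.0
    applied_mg = p.gap * scenario.area_ha * conc * 1000.0

    if scenario.skip_mixing_loading or p.formulation is Formulation.SOLUBLE_BAG:
        ml = 0.0
    else:
        ml = (
            p.gap * scenario.area_ha * 1000.0
            * _band_fraction(tables, p.formulation, p.concentration)
            * conc
            * (1.0 - _pf(tables, scenario.ppe[Phase.MIXING_LOADING].hands))
            * ai.dermal_absorption
        )

    dep = tables.deposition_table[scenario.application.equipment]
    app_sel = scenario.ppe[Phase.APPLICATION]
    app = (
        applied_mg * dep * 1e-6
        * sum(
            _WEIGHTS[r] * (1.0 - _pf(tables, getattr(app_sel, r)))
            for r in _WEIGHTS
        )
        * ai.dermal_absorption
    )

    spray_mass_kg = scenario.application.spray_volume_hl_per_ha * 100.0 * scenario.area_ha
    man = (
        scenario.application.tank_volume_l  # 1 kg/L
        * _MAN_CONTACT
        * (applied_mg / spray_mass_kg)
        * (1.0 - _pf(tables, scenario.ppe[Phase.MAINTENANCE].hands))
        * ai.dermal_absorption
    )

    return 100.0 * (ml + app + man) / (ai.aoel * scenario.body_weight_kg)
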