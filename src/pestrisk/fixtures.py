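"""Packaged demo database and deterministic random-scenario generator.

``build_demo_database`` writes the four reference CSVs that ship with the
package: the formulation, deposition, and clothing tables carry the endorsed
coefficient values verbatim, and the product database holds 16 active
ingredients — the published KILLER/ACTIVOL exercise entry first, followed by
15 clearly synthetic ``DEMO-`` entries spanning all formulation types and
AOEL values across three orders of magnitude (0.001–1 mg/kg bw). No entry
other than the first corresponds to a real authorization record.

``generate_random_scenario`` draws valid scenarios for property testing:
deterministic per seed, always passing :func:`~pestrisk.scenario.validate_scenario`
without error-severity findings.
"""

from __future__ import annotations

import random
from pathlib import Path

from . import reference_data as rd
from .scenario import CROP_HEIGHT_LOOKUP, Phase, PPESelection, ApplicationSpec, Scenario

__all__ = ["build_demo_database", "generate_random_scenario", "demo_tables"]


# --- canonical table contents -------------------------------------------------

# M&L contact fractions per formulation and AI-concentration band (% bands
# <30, 30-60, 60-80, >80). Values are dimensionless fractions (table prints
# them in %: e.g. 0.045% -> 0.00045). Soluble granules are an alias of
# liquid_concentrate, not a stored row.
_FORMULATION_FRACTIONS: dict[str, tuple[float, float, float, float]] = {
    "soluble_bag": (0.0, 0.0, 0.0, 0.0),
    "liquid_concentrate": (0.00030, 0.00045, 0.00070, 0.00090),
    "powder": (0.00003, 0.00005, 0.00007, 0.00009),
}

# Deposition on the operator, ppm of applied mix (0.1 mL/hL or mg/kg).
# The charcoal-filtered cab is the forced-ventilation value reduced by a
# further 99% (the filter's stated efficiency): 0.1 x (1 - 0.99) = 0.001.
_DEPOSITION_PPM: dict[str, float] = {
    "knapsack": 1000.0,
    "towed_pipe_manual": 100.0,
    "tractor_open": 10.0,
    "tractor_closed_natural": 1.0,
    "tractor_closed_forced": 0.1,
    "tractor_closed_charcoal": 0.001,
}

# Protection factors: fraction of the deposit the barrier keeps off the skin.
# The five body garments carry the endorsed clothing-table values; gloves,
# headdress, mask, shoes and boots are declared package defaults consistent
# with the generic-vs-technical span of that table.
_PROTECTION: list[tuple[str, str, float]] = [
    ("underwear", "body", 0.50),
    ("generic_clothes", "body", 0.70),
    ("cotton_coverall", "body", 0.90),
    ("nonwoven_coverall", "body", 0.90),
    ("hazmat_coverall", "body", 0.99),
    ("generic_gloves", "hands", 0.90),
    ("specific_gloves", "hands", 0.99),
    ("headdress", "head", 0.90),
    ("mask", "face", 0.90),
    ("shoes", "feet", 0.70),
    ("boots", "feet", 0.99),
]

# product_name, ai_name, formulation, conc %, GAP g/ha, AOEL mg/kg, absorption %.
# Row 1 is the published worked-exercise product; the rest are synthetic.
_PRODUCTS: list[tuple[str, str, str, float, float, float, float]] = [
    ("KILLER", "ACTIVOL", "powder", 50.0, 100.0, 0.05, 5.0),
    ("DEMO-LIQUIDA 10", "DEMO-AI-01", "liquid_concentrate", 10.0, 2000.0, 0.10, 10.0),
    ("DEMO-LIQUIDA 45", "DEMO-AI-02", "liquid_concentrate", 45.0, 1500.0, 0.02, 25.0),
    ("DEMO-LIQUIDA 75", "DEMO-AI-03", "liquid_concentrate", 75.0, 800.0, 0.005, 10.0),
    ("DEMO-LIQUIDA 95", "DEMO-AI-04", "liquid_concentrate", 95.0, 500.0, 0.50, 2.0),
    ("DEMO-POLVERE 20", "DEMO-AI-05", "powder", 20.0, 3000.0, 0.01, 10.0),
    ("DEMO-POLVERE 65", "DEMO-AI-06", "powder", 65.0, 400.0, 0.001, 50.0),
    ("DEMO-POLVERE 90", "DEMO-AI-07", "powder", 90.0, 250.0, 1.0, 1.0),
    ("DEMO-GRANULI 30", "DEMO-AI-08", "soluble_granule", 30.0, 1200.0, 0.05, 8.0),
    ("DEMO-GRANULI 80", "DEMO-AI-09", "soluble_granule", 80.0, 600.0, 0.002, 30.0),
    ("DEMO-BUSTE 25", "DEMO-AI-10", "soluble_bag", 25.0, 1000.0, 0.02, 15.0),
    ("DEMO-BUSTE 50", "DEMO-AI-11", "soluble_bag", 50.0, 700.0, 0.30, 5.0),
    ("DEMO-ERBICIDA", "DEMO-AI-12", "liquid_concentrate", 36.0, 4000.0, 0.10, 3.0),
    ("DEMO-FUNGICIDA", "DEMO-AI-13", "powder", 80.0, 2000.0, 0.025, 10.0),
    ("DEMO-INSETTICIDA", "DEMO-AI-14", "liquid_concentrate", 25.0, 300.0, 0.005, 40.0),
    ("DEMO-ACARICIDA", "DEMO-AI-15", "soluble_granule", 55.0, 900.0, 0.015, 20.0),
]


def build_demo_database(out_dir: str | Path) -> list[Path]:
    """Write the four demo reference CSVs into ``out_dir``; returns the paths.

    Output is deterministic — regenerated files are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out / "formulation_fractions.csv"
    lines = [
        "# pestrisk reference table v1: M&L contact fractions (dimensionless)",
        "# Bands on AI concentration in the formulation, % by mass: [0,30) [30,60) [60,80) [80,100].",
        "# Soluble granules share the liquid_concentrate row (alias in the loader).",
        "# Note: the source text ranks powder above liquid concentrate verbally, but the",
        "# printed coefficients rank liquid (0.030-0.090%) above powder (0.003-0.009%);",
        "# the printed table is taken as ground truth here.",
        "formulation,band_lo,band_hi,fraction",
    ]
    for form, values in _FORMULATION_FRACTIONS.items():
        for (lo, hi), frac in zip(rd.CONCENTRATION_BANDS, values):
            lines.append(f"{form},{lo:g},{hi:g},{frac:g}")
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths.append(p)

    p = out / "deposition_factors.csv"
    lines = [
        "# pestrisk reference table v1: deposition factors (ppm of applied mix; 0.1 mL/hL or mg/kg)",
        "# tractor_closed_charcoal = tractor_closed_forced (0.1 ppm) reduced by the",
        "# charcoal filter's 99%: 0.1 x (1 - 0.99) = 0.001 ppm.",
        "equipment,ppm",
    ]
    for eq in rd.EQUIPMENT_ORDER:
        lines.append(f"{eq.value},{_DEPOSITION_PPM[eq.value]:g}")
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths.append(p)

    p = out / "protection_factors.csv"
    lines = [
        "# pestrisk reference table v1: PPE protection factors (fraction kept off the skin)",
        "# Body garments carry endorsed clothing-table values; gloves/headdress/mask/",
        "# shoes/boots are declared package defaults (flagged in the audit map).",
        "item,body_region_applicability,fraction",
    ]
    for item, regions, frac in _PROTECTION:
        lines.append(f"{item},{regions},{frac:g}")
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths.append(p)

    p = out / "products.csv"
    lines = [
        "# pestrisk reference table v1: demo product / active-ingredient database (16 entries)",
        "# Row 1 (KILLER/ACTIVOL) is the published worked-exercise product; all DEMO-*",
        "# entries are synthetic and correspond to no real authorization record.",
        "product_name,ai_name,formulation,concentration_pct,gap_g_per_ha,aoel_mg_per_kg,dermal_absorption_pct",
    ]
    for row in _PRODUCTS:
        name, ai, form, conc, gap, aoel, absorption = row
        lines.append(f"{name},{ai},{form},{conc:g},{gap:g},{aoel:g},{absorption:g}")
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths.append(p)

    return paths


def demo_tables() -> rd.ReferenceTables:
    """Load the packaged demo reference tables."""
    return rd.load_reference_tables(rd.default_tables_dir())


# --- random scenarios ---------------------------------------------------------

_CROPS = sorted(CROP_HEIGHT_LOOKUP)


def generate_random_scenario(seed: int, tables: rd.ReferenceTables) -> Scenario:
    """Draw a random valid scenario; deterministic per seed.

    Samples area in [0.1, 100] ha, any product, any equipment, any
    region-applicable PPE (or none), spray volume in [1, 20] hL/ha, tank in
    [100, 3000] L, pressure in [0, 20] bar. Always passes
    ``validate_scenario`` with no error-severity findings.
    """
    rng = random.Random(seed)
    crop = rng.choice(_CROPS)
    product = tables.products[rng.choice(sorted(tables.products))]
    equipment = rng.choice([e for e in rd.EQUIPMENT_ORDER if e in tables.deposition_table])

    items_by_region: dict[str, list[str]] = {r: ["none"] for r in rd.BODY_REGIONS}
    for item in tables.protection_table.values():
        for region in item.regions:
            items_by_region[region].append(item.name)

    ppe = {}
    for phase in Phase:
        ppe[phase] = PPESelection(
            phase=phase,
            **{r: rng.choice(sorted(items_by_region[r])) for r in rd.BODY_REGIONS},
        )

    return Scenario(
        crop_name=crop,
        crop_height=CROP_HEIGHT_LOOKUP[crop],
        pest=rng.choice(["aphids", "fruit fly", "downy mildew", "weeds", "mites"]),
        area_ha=round(rng.uniform(0.1, 100.0), 3),
        product_name=product.name,
        application=ApplicationSpec(
            spray_volume_hl_per_ha=round(rng.uniform(1.0, 20.0), 2),
            tank_volume_l=round(rng.uniform(100.0, 3000.0), 1),
            pressure_bar=round(rng.uniform(0.0, 20.0), 1),
            equipment=equipment,
        ),
        ppe=ppe,
        body_weight_kg=round(rng.uniform(50.0, 100.0), 1),
        skip_mixing_loading=rng.random() < 0.1,
    )
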