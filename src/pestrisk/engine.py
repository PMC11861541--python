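"""The exposure model core.

For each work phase the chain is the same mass-transfer ledger::

    potential dermal exposure (mg AI reaching clothing/skin surface)
      -> minus the fraction retained by PPE (protection factor PF)
      -> skin loading (mg AI on skin)
      -> x dermal absorption fraction
      -> absorbed dose (mg AI crossing the skin)

Phase sources differ:

* **Mixing & loading (M&L)** — the operator handles the *concentrate*; a
  formulation- and concentration-dependent contact fraction of the handled
  formulation mass reaches the hands.
* **Application (APP)** — a deposition factor (ppm of the applied mix, i.e.
  mg on the operator per kg applied; the mix/AI ratio cancels) of the applied
  AI mass lands on the operator, split over five body regions, each with its
  own PPE barrier.
* **Maintenance & cleaning (MAN)** — the operator handles the *dilute* spray
  solution; a contact fraction of the handled mix mass, at the tank's AI
  concentration, reaches the hands.

The risk index is the summed absorbed dose as a percentage of the acceptable
daily dose AOEL x body weight; the tier is green below ``green_lt`` %,
red above ``red_gt`` % (AOEL exceedance), yellow in between.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any

from . import reference_data as rd
from .errors import PestriskError, ScenarioValidationError
from .scenario import Phase, Scenario

__all__ = [
    "Tier",
    "EngineSettings",
    "PhaseExposure",
    "RiskResult",
    "load_settings",
    "ai_mass_applied",
    "n_tank_loads",
    "exposure_mixing_loading",
    "exposure_application",
    "exposure_maintenance",
    "assess_scenario",
    "classify_tier",
]

MG_PER_G = 1000.0
G_PER_HL_WATER = 1.0e5  # 1 hL water = 100 L = 100 kg at density 1 kg/L
L_PER_HL = 100.0

#: PPE items whose protection factor comes from the endorsed clothing table;
#: every other item's factor is a declared package default and is flagged as
#: such in the audit map.
TABLE_BACKED_PF_ITEMS = frozenset(
    {
        "underwear",
        "generic_clothes",
        "cotton_coverall",
        "nonwoven_coverall",
        "hazmat_coverall",
    }
)


class Tier(str, Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"

    @property
    def rank(self) -> int:
        return {"green": 0, "yellow": 1, "red": 2}[self.value]


def _default_region_weights() -> dict[str, float]:
    # split of the application-phase deposit over the five PPE regions;
    # follows adult body-surface proportions, configurable
    return {"head": 0.06, "face": 0.04, "hands": 0.20, "body": 0.60, "feet": 0.10}


@dataclass(frozen=True)
class EngineSettings:
    """Every tunable constant of the calculation chain, with defaults.

    Attributes
    ----------
    body_region_weights
        Fractional split of the application-phase deposit over the five body
        regions; must sum to 1.
    maintenance_contact_fraction
        Fraction of the handled dilute mix that contacts the hands during
        cleaning/maintenance (default 3e-4, the dilute-liquid contact
        fraction of the lowest concentration band).
    maintenance_handled_mass_kg
        Mass of dilute mix handled during maintenance; ``None`` (default)
        means one tank volume at the mix density.
    tier_green_lt / tier_red_gt
        Tier thresholds in % of AOEL: risk < green_lt is green, > red_gt red.
    crop_height_multipliers / pressure_multipliers
        Multiplicative modifiers on the deposition factor; both default to
        no effect (the deposition table does not quantify them).
    mix_density_kg_per_l
        Density of the dilute spray mix (water-like, 1 kg/L).
    """

    body_region_weights: dict[str, float] = field(default_factory=_default_region_weights)
    maintenance_contact_fraction: float = 3.0e-4
    maintenance_handled_mass_kg: float | None = None
    tier_green_lt: float = 50.0
    tier_red_gt: float = 100.0
    crop_height_multipliers: dict[str, float] = field(
        default_factory=lambda: {"low": 1.0, "high": 1.0}
    )
    pressure_multipliers: tuple[tuple[float, float], ...] = ()
    mix_density_kg_per_l: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.body_region_weights.get(r, 0.0) for r in rd.BODY_REGIONS)
        if abs(total - 1.0) > 1e-9:
            raise PestriskError(
                f"body_region_weights must sum to 1 over {rd.BODY_REGIONS}, got {total}"
            )
        if set(self.body_region_weights) - set(rd.BODY_REGIONS):
            raise PestriskError(
                f"body_region_weights has unknown regions: "
                f"{sorted(set(self.body_region_weights) - set(rd.BODY_REGIONS))}"
            )
        if not self.tier_green_lt <= self.tier_red_gt:
            raise PestriskError(
                f"tier thresholds must satisfy green_lt <= red_gt, got "
                f"{self.tier_green_lt} > {self.tier_red_gt}"
            )
        if not 0.0 <= self.maintenance_contact_fraction <= 1.0:
            raise PestriskError(
                "maintenance_contact_fraction must be in [0, 1], got "
                f"{self.maintenance_contact_fraction}"
            )
        if not self.mix_density_kg_per_l > 0:
            raise PestriskError("mix_density_kg_per_l must be > 0")


def load_settings(path: str | Path) -> EngineSettings:
    """Read EngineSettings overrides from a TOML file; absent keys keep defaults."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    kwargs: dict[str, Any] = {}
    if "body_region_weights" in data:
        kwargs["body_region_weights"] = {
            k: float(v) for k, v in data["body_region_weights"].items()
        }
    for key in ("maintenance_contact_fraction", "maintenance_handled_mass_kg",
                "tier_green_lt", "tier_red_gt", "mix_density_kg_per_l"):
        if key in data:
            kwargs[key] = float(data[key])
    if "crop_height_multipliers" in data:
        kwargs["crop_height_multipliers"] = {
            k: float(v) for k, v in data["crop_height_multipliers"].items()
        }
    if "pressure_multipliers" in data:
        kwargs["pressure_multipliers"] = tuple(
            (float(u), float(m)) for u, m in data["pressure_multipliers"]
        )
    return EngineSettings(**kwargs)


@dataclass(frozen=True)
class PhaseExposure:
    """Per-phase mass ledger, all amounts in mg of active ingredient.

    Invariant: ``potential_exposure_mg == retained_by_ppe_mg + skin_loading_mg``
    and ``absorbed_mg == skin_loading_mg x dermal absorption``.
    """

    phase: Phase
    potential_exposure_mg: float
    retained_by_ppe_mg: float
    skin_loading_mg: float
    absorbed_mg: float
    excluded: bool = False
    detail: dict[str, Any] = field(default_factory=dict, compare=False)

    @staticmethod
    def zero(phase: Phase, *, excluded: bool = False, **detail: Any) -> "PhaseExposure":
        return PhaseExposure(phase, 0.0, 0.0, 0.0, 0.0, excluded=excluded, detail=detail)


@dataclass(frozen=True)
class RiskResult:
    """Assessment outcome: phase ledgers, totals, risk index, and tier."""

    phases: tuple[PhaseExposure, ...]
    total_absorbed_mg: float
    acceptable_dose_mg: float
    risk_percent: float
    tier: Tier
    n_tank_loads: int
    audit: dict[str, Any] = field(compare=False, default_factory=dict)

    def phase(self, phase: Phase) -> PhaseExposure:
        for p in self.phases:
            if p.phase is phase:
                return p
        raise KeyError(phase)


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------


def ai_mass_applied(product: rd.Product, area_ha: float) -> float:
    """Active-ingredient mass applied over the treatment, in mg.

    GAP (g formulation/ha) x area (ha) x AI mass fraction, converted to mg.
    """
    if not area_ha > 0:
        raise ScenarioValidationError(f"area must be > 0 ha, got {area_ha}")
    return product.gap * area_ha * (product.concentration / 100.0) * MG_PER_G


def n_tank_loads(spray_volume_hl_per_ha: float, area_ha: float, tank_volume_l: float) -> int:
    """Number of tank fills needed: ceil(total spray volume / tank volume), >= 1."""
    total_l = spray_volume_hl_per_ha * L_PER_HL * area_ha
    ratio = total_l / tank_volume_l
    # guard the ceiling against float noise on exact multiples
    n = math.ceil(ratio - 1e-9 * max(1.0, ratio))
    return max(1, n)


def _pf(tables: rd.ReferenceTables, item: str, audit_slot: dict[str, Any], key: str) -> float:
    pf = rd.protection_factor(tables, item)
    source = (
        "reference table"
        if item in TABLE_BACKED_PF_ITEMS
        else ("no barrier" if item == "none" else "package default (non-table item)")
    )
    audit_slot[key] = {"item": item, "protection_factor": pf, "source": source}
    return pf


def _ledger(phase: Phase, potential: float, skin: float, absorbed: float,
            detail: dict[str, Any]) -> PhaseExposure:
    # store the ledger so that potential == retained + skin holds exactly in
    # floating point: recompose potential from its two parts (at most 1 ulp
    # away from the product formula)
    retained = potential - skin
    return PhaseExposure(phase, retained + skin, retained, skin, absorbed, detail=detail)


# ---------------------------------------------------------------------------
# phase estimators
# ---------------------------------------------------------------------------


def exposure_mixing_loading(
    scenario: Scenario,
    tables: rd.ReferenceTables,
    settings: EngineSettings | None = None,
) -> PhaseExposure:
    """M&L phase: contact with the concentrate, hands only.

    potential = handled formulation mass x contact fraction x AI mass fraction;
    gloves retain PF of it; the rest is skin loading.
    """
    settings = settings or EngineSettings()
    product = rd.get_product(tables, scenario.product_name)
    detail: dict[str, Any] = {}

    if scenario.skip_mixing_loading:
        return PhaseExposure.zero(
            Phase.MIXING_LOADING, excluded=True, reason="mixing/loading performed off-farm"
        )
    if product.formulation is rd.Formulation.SOLUBLE_BAG:
        return PhaseExposure.zero(
            Phase.MIXING_LOADING, reason="pre-dosed soluble bags: no contact with concentrate"
        )

    fraction = rd.formulation_exposure_fraction(
        tables, product.formulation, product.concentration
    )
    handled_formulation_mg = product.gap * scenario.area_ha * MG_PER_G
    potential = handled_formulation_mg * fraction * (product.concentration / 100.0)

    pf = _pf(tables, scenario.ppe[Phase.MIXING_LOADING].hands, detail, "hands_ppe")
    skin = potential * (1.0 - pf)
    absorbed = skin * product.active_ingredient.dermal_absorption
    detail.update(
        handled_formulation_mg=handled_formulation_mg,
        contact_fraction=fraction,
        ai_mass_fraction=product.concentration / 100.0,
    )
    return _ledger(Phase.MIXING_LOADING, potential, skin, absorbed, detail)


def exposure_application(
    scenario: Scenario,
    tables: rd.ReferenceTables,
    settings: EngineSettings | None = None,
) -> PhaseExposure:
    """APP phase: ppm-scale deposition of the applied mix, split over body regions."""
    settings = settings or EngineSettings()
    product = rd.get_product(tables, scenario.product_name)
    detail: dict[str, Any] = {}

    dep_ppm = rd.deposition_factor(
        tables,
        scenario.application.equipment,
        scenario.crop_height,
        scenario.application.pressure_bar,
        crop_height_multipliers=settings.crop_height_multipliers,
        pressure_multipliers=settings.pressure_multipliers,
    )
    applied_mg = ai_mass_applied(product, scenario.area_ha)
    potential = applied_mg * dep_ppm * 1e-6

    sel = scenario.ppe[Phase.APPLICATION]
    skin = 0.0
    regions: dict[str, Any] = {}
    for region in rd.BODY_REGIONS:
        weight = settings.body_region_weights.get(region, 0.0)
        deposit = potential * weight
        pf = _pf(tables, sel.items()[region], regions, region)
        through = deposit * (1.0 - pf)
        regions[region].update(weight=weight, deposit_mg=deposit, skin_mg=through)
        skin += through
    absorbed = skin * product.active_ingredient.dermal_absorption
    detail.update(
        deposition_factor_ppm=dep_ppm,
        ai_mass_applied_mg=applied_mg,
        regions=regions,
    )
    return _ledger(Phase.APPLICATION, potential, skin, absorbed, detail)


def exposure_maintenance(
    scenario: Scenario,
    tables: rd.ReferenceTables,
    settings: EngineSettings | None = None,
) -> PhaseExposure:
    """MAN phase: contact with the dilute mix during cleaning, hands only."""
    settings = settings or EngineSettings()
    product = rd.get_product(tables, scenario.product_name)
    detail: dict[str, Any] = {}

    handled_kg = (
        settings.maintenance_handled_mass_kg
        if settings.maintenance_handled_mass_kg is not None
        else scenario.application.tank_volume_l * settings.mix_density_kg_per_l
    )
    applied_mg = ai_mass_applied(product, scenario.area_ha)
    spray_mass_kg = (
        scenario.application.spray_volume_hl_per_ha
        * L_PER_HL
        * scenario.area_ha
        * settings.mix_density_kg_per_l
    )
    mix_conc_mg_per_kg = applied_mg / spray_mass_kg
    potential = handled_kg * settings.maintenance_contact_fraction * mix_conc_mg_per_kg

    pf = _pf(tables, scenario.ppe[Phase.MAINTENANCE].hands, detail, "hands_ppe")
    skin = potential * (1.0 - pf)
    absorbed = skin * product.active_ingredient.dermal_absorption
    detail.update(
        handled_mix_kg=handled_kg,
        contact_fraction=settings.maintenance_contact_fraction,
        mix_concentration_mg_per_kg=mix_conc_mg_per_kg,
    )
    return _ledger(Phase.MAINTENANCE, potential, skin, absorbed, detail)


# ---------------------------------------------------------------------------
# assessment
# ---------------------------------------------------------------------------


def classify_tier(
    risk_percent: float, green_lt: float = 50.0, red_gt: float = 100.0
) -> Tier:
    """Green iff risk < green_lt; red iff risk > red_gt; yellow otherwise."""
    if risk_percent < 0:
        raise PestriskError(f"risk_percent must be >= 0, got {risk_percent}")
    if risk_percent < green_lt:
        return Tier.GREEN
    if risk_percent > red_gt:
        return Tier.RED
    return Tier.YELLOW


def assess_scenario(
    scenario: Scenario,
    tables: rd.ReferenceTables,
    settings: EngineSettings | None = None,
) -> RiskResult:
    """Run the three phase estimators and classify the workday risk.

    The audit map records every table value, multiplier, and default used, so
    a trained reader can reproduce the numbers by hand.
    """
    settings = settings or EngineSettings()
    product = rd.get_product(tables, scenario.product_name)

    try:
        phases = (
            exposure_mixing_loading(scenario, tables, settings),
            exposure_application(scenario, tables, settings),
            exposure_maintenance(scenario, tables, settings),
        )
    except PestriskError as exc:
        raise type(exc)(f"while assessing scenario for {product.name!r}: {exc}") from exc

    total = sum(p.absorbed_mg for p in phases)
    acceptable = product.active_ingredient.aoel * scenario.body_weight_kg
    risk = 100.0 * total / acceptable
    tier = classify_tier(risk, settings.tier_green_lt, settings.tier_red_gt)
    loads = n_tank_loads(
        scenario.application.spray_volume_hl_per_ha,
        scenario.area_ha,
        scenario.application.tank_volume_l,
    )

    audit: dict[str, Any] = {
        "product": {
            "name": product.name,
            "active_ingredient": product.active_ingredient.name,
            "formulation": product.formulation.value,
            "concentration_pct": product.concentration,
            "gap_g_per_ha": product.gap,
            "aoel_mg_per_kg_bw": product.active_ingredient.aoel,
            "dermal_absorption": product.active_ingredient.dermal_absorption,
        },
        "scenario": {
            "area_ha": scenario.area_ha,
            "crop": scenario.crop_name,
            "crop_height": scenario.crop_height.value,
            "pest": scenario.pest,
            "equipment": scenario.application.equipment.value,
            "spray_volume_hl_per_ha": scenario.application.spray_volume_hl_per_ha,
            "tank_volume_l": scenario.application.tank_volume_l,
            "pressure_bar": scenario.application.pressure_bar,
            "body_weight_kg": scenario.body_weight_kg,
            "skip_mixing_loading": scenario.skip_mixing_loading,
        },
        "settings": {
            "body_region_weights": dict(settings.body_region_weights),
            "maintenance_contact_fraction": settings.maintenance_contact_fraction,
            "maintenance_handled_mass_kg": settings.maintenance_handled_mass_kg,
            "tier_green_lt": settings.tier_green_lt,
            "tier_red_gt": settings.tier_red_gt,
            "crop_height_multipliers": dict(settings.crop_height_multipliers),
            "pressure_multipliers": list(settings.pressure_multipliers),
            "mix_density_kg_per_l": settings.mix_density_kg_per_l,
        },
        "phases": {p.phase.value: dict(p.detail) for p in phases},
        "n_tank_loads": loads,
        "acceptable_dose_mg": acceptable,
    }
    return RiskResult(
        phases=phases,
        total_absorbed_mg=total,
        acceptable_dose_mg=acceptable,
        risk_percent=risk,
        tier=tier,
        n_tank_loads=loads,
        audit=audit,
    )
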