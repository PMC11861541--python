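"""Typed treatment scenarios: parsing, serialization, and validation.

A scenario is everything the operator declares before spraying: crop and
treated area, the product, the application rig (spray volume, tank, pressure,
equipment), a PPE selection for each of the three work phases, and the
operator's body weight. Configs are TOML (JSON accepted as an alternate) with
sections ``[crop]``, ``[product]``, ``[application]``,
``[ppe.mixing_loading|application|maintenance]``, and ``[operator]``.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any

from . import reference_data as rd
from .errors import ScenarioSchemaError, ScenarioValidationError

__all__ = [
    "Phase",
    "PPESelection",
    "ApplicationSpec",
    "Scenario",
    "Finding",
    "DEFAULT_BODY_WEIGHT_KG",
    "CROP_HEIGHT_LOOKUP",
    "parse_scenario",
    "serialize_scenario",
    "validate_scenario",
]


class Phase(str, Enum):
    """The three implemented work phases (re-entry is out of scope)."""

    MIXING_LOADING = "mixing_loading"
    APPLICATION = "application"
    MAINTENANCE = "maintenance"


#: Default operator body weight in kg (the EFSA operator-exposure convention);
#: configurable per scenario.
DEFAULT_BODY_WEIGHT_KG = 60.0

#: Editable crop-name → height lookup; unknown crops must state an explicit
#: height in the config.
CROP_HEIGHT_LOOKUP: dict[str, rd.CropHeight] = {
    "cereals": rd.CropHeight.LOW,
    "wheat": rd.CropHeight.LOW,
    "barley": rd.CropHeight.LOW,
    "maize": rd.CropHeight.LOW,
    "potato": rd.CropHeight.LOW,
    "sugar beet": rd.CropHeight.LOW,
    "vegetables": rd.CropHeight.LOW,
    "vineyard": rd.CropHeight.HIGH,
    "olive": rd.CropHeight.HIGH,
    "orchard": rd.CropHeight.HIGH,
    "apple": rd.CropHeight.HIGH,
    "peach": rd.CropHeight.HIGH,
    "citrus": rd.CropHeight.HIGH,
}


@dataclass(frozen=True)
class PPESelection:
    """PPE worn in one phase: one item id per body region ("none" allowed)."""

    phase: Phase
    face: str = "none"
    head: str = "none"
    hands: str = "none"
    body: str = "none"
    feet: str = "none"

    def items(self) -> dict[str, str]:
        return {r: getattr(self, r) for r in rd.BODY_REGIONS}


@dataclass(frozen=True)
class ApplicationSpec:
    """Spray rig parameters: volume rate (hL/ha), tank (L), pressure (bar), equipment."""

    spray_volume_hl_per_ha: float
    tank_volume_l: float
    pressure_bar: float
    equipment: rd.Equipment

    def __post_init__(self) -> None:
        if not self.spray_volume_hl_per_ha > 0:
            raise ScenarioValidationError(
                f"application.spray_volume_hl_per_ha must be > 0, "
                f"got {self.spray_volume_hl_per_ha}"
            )
        if not self.tank_volume_l > 0:
            raise ScenarioValidationError(
                f"application.tank_volume_l must be > 0, got {self.tank_volume_l}"
            )
        if self.pressure_bar < 0:
            raise ScenarioValidationError(
                f"application.pressure_bar must be >= 0, got {self.pressure_bar}"
            )


@dataclass(frozen=True)
class Scenario:
    """A complete planned treatment (one product, one workday)."""

    crop_name: str
    crop_height: rd.CropHeight
    pest: str
    area_ha: float
    product_name: str
    application: ApplicationSpec
    ppe: dict[Phase, PPESelection]
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG
    skip_mixing_loading: bool = False
    #: defaults filled in during parsing; excluded from equality so that the
    #: parse/serialize round-trip compares on substance only
    parse_log: tuple[str, ...] = field(default=(), compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.area_ha > 0:
            raise ScenarioValidationError(f"crop.area_ha must be > 0, got {self.area_ha}")
        if not self.body_weight_kg > 0:
            raise ScenarioValidationError(
                f"operator.body_weight_kg must be > 0, got {self.body_weight_kg}"
            )
        if set(self.ppe) != set(Phase):
            raise ScenarioValidationError(
                "exactly one PPE selection per phase is required; got "
                f"{sorted(p.value for p in self.ppe)}"
            )
        for phase, sel in self.ppe.items():
            if sel.phase is not phase:
                raise ScenarioValidationError(
                    f"PPE selection filed under {phase.value!r} is tagged {sel.phase.value!r}"
                )

    def with_ppe_item(self, phase: Phase, region: str, item: str) -> "Scenario":
        """Copy of the scenario with one PPE slot changed."""
        new_sel = replace(self.ppe[phase], **{region: item})
        return replace(self, ppe={**self.ppe, phase: new_sel})

    def with_equipment(self, equipment: rd.Equipment) -> "Scenario":
        return replace(self, application=replace(self.application, equipment=equipment))


@dataclass(frozen=True)
class Finding:
    """One validation finding; severity is 'error', 'warning', or 'info'."""

    severity: str
    code: str
    message: str


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _require(mapping: dict[str, Any], path: str) -> Any:
    node: Any = mapping
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ScenarioSchemaError(f"scenario config is missing required key {path!r}")
        node = node[part]
    return node


def _number(raw: Any, path: str) -> float:
    if isinstance(raw, bool) or not isinstance(raw, (int, float)):
        raise ScenarioSchemaError(f"scenario key {path!r} must be a number, got {raw!r}")
    return float(raw)


def parse_scenario(config_text: str) -> Scenario:
    """Parse a scenario config (TOML, or JSON as alternate) into a validated Scenario.

    Missing optional keys are filled with documented defaults and the
    substitutions recorded on ``Scenario.parse_log``.
    """
    data = _load_config(config_text)
    log: list[str] = []

    crop_name = str(_require(data, "crop.name"))
    pest = str(data.get("crop", {}).get("pest", ""))
    area = _number(_require(data, "crop.area_ha"), "crop.area_ha")

    raw_height = data.get("crop", {}).get("height")
    if raw_height is not None:
        try:
            height = rd.CropHeight(raw_height)
        except ValueError:
            raise ScenarioSchemaError(
                f"scenario key 'crop.height' must be 'low' or 'high', got {raw_height!r}"
            ) from None
    else:
        height = CROP_HEIGHT_LOOKUP.get(crop_name.casefold())
        if height is None:
            raise ScenarioSchemaError(
                f"crop {crop_name!r} is not in the built-in height lookup; "
                "set 'crop.height' to 'low' or 'high' explicitly"
            )
        log.append(f"crop.height defaulted to {height.value!r} from crop name {crop_name!r}")

    product_section = _require(data, "product")
    if isinstance(product_section, list) or (
        isinstance(product_section, dict) and isinstance(product_section.get("name"), list)
    ):
        raise ScenarioValidationError(
            "one product per scenario: tank mixes of several products are not supported"
        )
    product_name = str(_require(data, "product.name"))

    try:
        equipment = rd.Equipment(_require(data, "application.equipment"))
    except ValueError:
        raise ScenarioSchemaError(
            "scenario key 'application.equipment' must be one of "
            f"{[e.value for e in rd.Equipment]}"
        ) from None
    application = ApplicationSpec(
        spray_volume_hl_per_ha=_number(
            _require(data, "application.spray_volume_hl_per_ha"),
            "application.spray_volume_hl_per_ha",
        ),
        tank_volume_l=_number(
            _require(data, "application.tank_volume_l"), "application.tank_volume_l"
        ),
        pressure_bar=_number(
            _require(data, "application.pressure_bar"), "application.pressure_bar"
        ),
        equipment=equipment,
    )

    ppe: dict[Phase, PPESelection] = {}
    for phase in Phase:
        section = data.get("ppe", {}).get(phase.value)
        if section is None:
            ppe[phase] = PPESelection(phase=phase)
            log.append(f"ppe.{phase.value} defaulted to 'none' for every region")
            continue
        items = {}
        for region in rd.BODY_REGIONS:
            item = section.get(region, "none")
            if not isinstance(item, str):
                raise ScenarioSchemaError(
                    f"scenario key 'ppe.{phase.value}.{region}' must be a PPE item id"
                )
            items[region] = item
        ppe[phase] = PPESelection(phase=phase, **items)

    operator = data.get("operator", {})
    if "body_weight_kg" in operator:
        body_weight = _number(operator["body_weight_kg"], "operator.body_weight_kg")
    else:
        body_weight = DEFAULT_BODY_WEIGHT_KG
        log.append(f"operator.body_weight_kg defaulted to {DEFAULT_BODY_WEIGHT_KG}")
    skip_ml = bool(operator.get("skip_mixing_loading", False))

    return Scenario(
        crop_name=crop_name,
        crop_height=height,
        pest=pest,
        area_ha=area,
        product_name=product_name,
        application=application,
        ppe=ppe,
        body_weight_kg=body_weight,
        skip_mixing_loading=skip_ml,
        parse_log=tuple(log),
    )


def _load_config(text: str) -> dict[str, Any]:
    stripped = text.lstrip()
    if stripped.startswith("{"):
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ScenarioSchemaError(f"invalid JSON scenario config: {exc}") from exc
    else:
        try:
            data = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ScenarioSchemaError(f"invalid TOML scenario config: {exc}") from exc
    if not isinstance(data, dict):
        raise ScenarioSchemaError("scenario config must be a table/object at top level")
    return data


def serialize_scenario(scenario: Scenario, fmt: str = "toml") -> str:
    """Serialize a scenario so that ``parse_scenario`` round-trips it exactly."""
    if fmt == "json":
        return json.dumps(_scenario_dict(scenario), indent=2)
    if fmt != "toml":
        raise ValueError(f"unknown scenario format {fmt!r}; use 'toml' or 'json'")
    d = _scenario_dict(scenario)
    lines = [
        "[crop]",
        f'name = "{scenario.crop_name}"',
        f'height = "{scenario.crop_height.value}"',
        f'pest = "{scenario.pest}"',
        f"area_ha = {_toml_num(scenario.area_ha)}",
        "",
        "[product]",
        f'name = "{scenario.product_name}"',
        "",
        "[application]",
        f"spray_volume_hl_per_ha = {_toml_num(scenario.application.spray_volume_hl_per_ha)}",
        f"tank_volume_l = {_toml_num(scenario.application.tank_volume_l)}",
        f"pressure_bar = {_toml_num(scenario.application.pressure_bar)}",
        f'equipment = "{scenario.application.equipment.value}"',
        "",
    ]
    for phase in Phase:
        lines.append(f"[ppe.{phase.value}]")
        for region, item in d["ppe"][phase.value].items():
            lines.append(f'{region} = "{item}"')
        lines.append("")
    lines += [
        "[operator]",
        f"body_weight_kg = {_toml_num(scenario.body_weight_kg)}",
        f"skip_mixing_loading = {'true' if scenario.skip_mixing_loading else 'false'}",
        "",
    ]
    return "\n".join(lines)


def _toml_num(x: float) -> str:
    # always emit a float literal so TOML round-trips the Python float exactly
    return repr(float(x))


def _scenario_dict(scenario: Scenario) -> dict[str, Any]:
    return {
        "crop": {
            "name": scenario.crop_name,
            "height": scenario.crop_height.value,
            "pest": scenario.pest,
            "area_ha": scenario.area_ha,
        },
        "product": {"name": scenario.product_name},
        "application": {
            "spray_volume_hl_per_ha": scenario.application.spray_volume_hl_per_ha,
            "tank_volume_l": scenario.application.tank_volume_l,
            "pressure_bar": scenario.application.pressure_bar,
            "equipment": scenario.application.equipment.value,
        },
        "ppe": {phase.value: scenario.ppe[phase].items() for phase in Phase},
        "operator": {
            "body_weight_kg": scenario.body_weight_kg,
            "skip_mixing_loading": scenario.skip_mixing_loading,
        },
    }


# ---------------------------------------------------------------------------
# validation against reference tables
# ---------------------------------------------------------------------------


def validate_scenario(scenario: Scenario, tables: rd.ReferenceTables) -> list[Finding]:
    """Cross-check a scenario against the reference tables.

    Returns findings instead of raising: an empty list means every reference
    resolves and every invariant holds. Severity 'error' findings make the
    scenario unassessable; warnings and infos do not.
    """
    findings: list[Finding] = []

    product = None
    try:
        product = rd.get_product(tables, scenario.product_name)
    except rd.ProductNotFoundError as exc:
        findings.append(Finding("error", "unknown-product", str(exc)))

    if scenario.application.equipment not in tables.deposition_table:
        findings.append(
            Finding(
                "error",
                "unknown-equipment",
                f"equipment {scenario.application.equipment.value!r} has no "
                "deposition-table entry",
            )
        )

    for phase in Phase:
        for region, item in scenario.ppe[phase].items().items():
            if item == "none":
                continue
            entry = tables.protection_table.get(item)
            if entry is None:
                findings.append(
                    Finding(
                        "error",
                        "unknown-ppe-item",
                        f"ppe.{phase.value}.{region}: unknown item {item!r}",
                    )
                )
            elif region not in entry.regions:
                findings.append(
                    Finding(
                        "warning",
                        "ppe-region-mismatch",
                        f"ppe.{phase.value}.{region}: item {item!r} is meant for "
                        f"{sorted(entry.regions)}, not {region!r}",
                    )
                )

    if product is not None and product.formulation is rd.Formulation.SOLUBLE_BAG:
        ml_hands = scenario.ppe[Phase.MIXING_LOADING].hands
        if ml_hands != "none" and not scenario.skip_mixing_loading:
            findings.append(
                Finding(
                    "warning",
                    "soluble-bag-ml-zero",
                    "M&L exposure is zero for soluble bags; the selected M&L "
                    f"gloves ({ml_hands!r}) have no effect on the result",
                )
            )

    if scenario.skip_mixing_loading:
        findings.append(
            Finding(
                "info",
                "ml-excluded",
                "M&L phase excluded from assessment (loading performed off-farm)",
            )
        )

    # bare hands during manual phases: re-donning contaminated gloves cannot be
    # modelled, so absent gloves in a manual phase are flagged for attention
    for phase in (Phase.MIXING_LOADING, Phase.MAINTENANCE):
        if phase is Phase.MIXING_LOADING and scenario.skip_mixing_loading:
            continue
        if scenario.ppe[phase].hands == "none":
            findings.append(
                Finding(
                    "warning",
                    "bare-hands-manual-phase",
                    f"no gloves selected for the manual {phase.value} phase; "
                    "hand contamination dominates exposure in manual work",
                )
            )

    return findings
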