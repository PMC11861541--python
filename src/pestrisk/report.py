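"""Assessment reports and the what-if improvement search.

``render_report`` turns a :class:`~pestrisk.engine.RiskResult` into JSON (the
machine-readable record, audit map included) or Markdown (the printable
document: tier pictogram, per-phase table, warnings, parameter appendix).

``suggest_improvements`` automates the iterate-until-green workflow: it
exhaustively searches the finite lattice of protective upgrades (better PPE
item per region and phase, lower-deposition equipment) and returns the change
sets that reach a better tier, ranked by tier, number of changes, then risk.
Agronomic givens — product, area, AOEL — are never touched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Any
from itertools import combinations

from . import reference_data as rd
from .engine import EngineSettings, RiskResult, Tier, assess_scenario
from .errors import PestriskError
from .scenario import Finding, Phase, Scenario, _scenario_dict

__all__ = ["render_report", "suggest_improvements", "Change", "Suggestion", "result_from_json"]

_TIER_TOKEN = {Tier.GREEN: "✅", Tier.YELLOW: "⚠️", Tier.RED: "⛔"}
_TIER_LABEL = {
    Tier.GREEN: "GREEN — safe application conditions",
    Tier.YELLOW: "YELLOW — borderline conditions; improvement recommended",
    Tier.RED: "RED — unsafe conditions; improvement mandatory before application",
}


def _sig3(x: float) -> str:
    """Render to 3 significant figures (reports only; tiers use full precision)."""
    return format(float(f"{x:.3g}"), "g")


def render_report(
    result: RiskResult,
    scenario: Scenario,
    format: str = "markdown",
    findings: list[Finding] | None = None,
) -> str:
    """Render an assessment as a JSON or Markdown document."""
    if format == "json":
        return json.dumps(_result_dict(result, scenario, findings), indent=2)
    if format != "markdown":
        raise PestriskError(f"unknown report format {format!r}; use 'json' or 'markdown'")
    return _render_markdown(result, scenario, findings or [])


def _result_dict(
    result: RiskResult, scenario: Scenario, findings: list[Finding] | None
) -> dict[str, Any]:
    return {
        "scenario": _scenario_dict(scenario),
        "phases": [
            {
                "phase": p.phase.value,
                "potential_exposure_mg": p.potential_exposure_mg,
                "retained_by_ppe_mg": p.retained_by_ppe_mg,
                "skin_loading_mg": p.skin_loading_mg,
                "absorbed_mg": p.absorbed_mg,
                "excluded": p.excluded,
            }
            for p in result.phases
        ],
        "total_absorbed_mg": result.total_absorbed_mg,
        "acceptable_dose_mg": result.acceptable_dose_mg,
        "risk_percent": result.risk_percent,
        "tier": result.tier.value,
        "n_tank_loads": result.n_tank_loads,
        "findings": [asdict(f) for f in (findings or [])],
        "audit": result.audit,
    }


def result_from_json(text: str) -> dict[str, Any]:
    """Reparse a JSON report; convenience for round-trip checks and tooling."""
    return json.loads(text)


def _render_markdown(
    result: RiskResult, scenario: Scenario, findings: list[Finding]
) -> str:
    lines = [
        "# Pesticide risk assessment",
        "",
        f"**Verdict: {_TIER_TOKEN[result.tier]} {_TIER_LABEL[result.tier]}**",
        "",
        f"- Crop: {scenario.crop_name} ({scenario.crop_height.value}); "
        f"pest: {scenario.pest or '—'}; area: {_sig3(scenario.area_ha)} ha",
        f"- Product: {scenario.product_name}; equipment: "
        f"{scenario.application.equipment.value}",
        f"- Tank loads needed: {result.n_tank_loads}",
        f"- Operator body weight: {_sig3(scenario.body_weight_kg)} kg",
        "",
        "## Risk index",
        "",
        f"Absorbed dose **{_sig3(result.total_absorbed_mg)} mg** of "
        f"**{_sig3(result.acceptable_dose_mg)} mg** acceptable "
        f"(AOEL × body weight) → **{_sig3(result.risk_percent)} % of AOEL**.",
        "",
        "## Per-phase breakdown (mg active ingredient)",
        "",
        "| Phase | Potential | Retained by PPE | Skin loading | Absorbed |",
        "|---|---|---|---|---|",
    ]
    for p in result.phases:
        if p.excluded:
            lines.append(f"| {p.phase.value} | excluded | excluded | excluded | excluded |")
        else:
            lines.append(
                f"| {p.phase.value} | {_sig3(p.potential_exposure_mg)} | "
                f"{_sig3(p.retained_by_ppe_mg)} | {_sig3(p.skin_loading_mg)} | "
                f"{_sig3(p.absorbed_mg)} |"
            )
    warn = [f for f in findings if f.severity in ("warning", "error")]
    info = [f for f in findings if f.severity == "info"]
    if warn:
        lines += ["", "## Warnings", ""]
        lines += [f"- **{f.severity}** ({f.code}): {f.message}" for f in warn]
    if info:
        lines += ["", "## Notes", ""]
        lines += [f"- {f.message}" for f in info]
    lines += ["", "## Parameter audit", "", "```json", json.dumps(result.audit, indent=2), "```", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# what-if search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Change:
    """One protective upgrade: a PPE slot replacement or an equipment swap."""

    kind: str  # "ppe" or "equipment"
    phase: Phase | None
    region: str | None
    new_value: str

    def describe(self) -> str:
        if self.kind == "equipment":
            return f"switch equipment to {self.new_value}"
        return f"{self.phase.value}: wear {self.new_value} on {self.region}"

    def apply(self, scenario: Scenario) -> Scenario:
        if self.kind == "equipment":
            return scenario.with_equipment(rd.Equipment(self.new_value))
        return scenario.with_ppe_item(self.phase, self.region, self.new_value)


@dataclass(frozen=True)
class Suggestion:
    """A change set with the tier and risk it achieves when applied."""

    changes: tuple[Change, ...]
    risk_percent: float
    tier: Tier


def _candidate_changes(
    scenario: Scenario, tables: rd.ReferenceTables
) -> list[Change]:
    candidates: list[Change] = []
    current_dep = tables.deposition_table[scenario.application.equipment]
    for eq in rd.EQUIPMENT_ORDER:
        if eq in tables.deposition_table and tables.deposition_table[eq] < current_dep:
            candidates.append(Change("equipment", None, None, eq.value))
    for phase in Phase:
        sel = scenario.ppe[phase]
        for region in rd.BODY_REGIONS:
            current_pf = rd.protection_factor(tables, sel.items()[region])
            for item in tables.protection_table.values():
                if region in item.regions and item.fraction > current_pf:
                    candidates.append(Change("ppe", phase, region, item.name))
    return candidates


def _target(change: Change) -> tuple:
    return ("equipment",) if change.kind == "equipment" else ("ppe", change.phase, change.region)


def suggest_improvements(
    scenario: Scenario,
    tables: rd.ReferenceTables,
    settings: EngineSettings | None = None,
    max_changes: int = 2,
) -> list[Suggestion]:
    """Exhaustive search for minimal protective upgrades reaching a better tier.

    Returns suggestions sorted by (achieved tier, number of changes, risk);
    empty if the scenario is already green, ``max_changes`` is 0, or no
    combination within the budget improves the tier.
    """
    settings = settings or EngineSettings()
    base = assess_scenario(scenario, tables, settings)
    if base.tier is Tier.GREEN or max_changes <= 0:
        return []

    candidates = _candidate_changes(scenario, tables)
    suggestions: list[Suggestion] = []
    for size in range(1, max_changes + 1):
        for combo in combinations(candidates, size):
            targets = [_target(c) for c in combo]
            if len(set(targets)) != size:
                continue  # two changes to the same slot are redundant
            trial = scenario
            for change in combo:
                trial = change.apply(trial)
            outcome = assess_scenario(trial, tables, settings)
            if outcome.tier.rank < base.tier.rank:
                suggestions.append(Suggestion(combo, outcome.risk_percent, outcome.tier))
    suggestions.sort(key=lambda s: (s.tier.rank, len(s.changes), s.risk_percent))
    return suggestions
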