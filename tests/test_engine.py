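"""Exposure-engine arithmetic, the phase ledgers, and model invariants."""

import math

import pytest
from hypothesis import given, strategies as st

from pestrisk import engine
from pestrisk import reference_data as rd
from pestrisk.engine import (
    EngineSettings,
    Tier,
    ai_mass_applied,
    assess_scenario,
    classify_tier,
    exposure_application,
    exposure_maintenance,
    exposure_mixing_loading,
    n_tank_loads,
)
from pestrisk.errors import PestriskError, ScenarioValidationError
from pestrisk.fixtures import generate_random_scenario
from pestrisk.scenario import Phase, parse_scenario, serialize_scenario
from risk_oracle import closed_form_risk_percent


def _with(scenario, **tweaks):
    import dataclasses
    return dataclasses.replace(scenario, **tweaks)


# --- elementary quantities ----------------------------------------------------

def test_ai_mass_applied(tables):
    killer = rd.get_product(tables, "KILLER")
    assert ai_mass_applied(killer, 10.0) == pytest.approx(500_000.0)
    full = rd.Product("X", killer.active_ingredient, rd.Formulation.POWDER, 100.0, 100.0)
    assert ai_mass_applied(full, 1.0) == pytest.approx(100_000.0)
    assert ai_mass_applied(killer, 1e-9) == pytest.approx(0.0, abs=1e-3)
    with pytest.raises(ScenarioValidationError):
        ai_mass_applied(killer, 0.0)


@pytest.mark.parametrize(
    ("spray", "area", "tank", "expected"),
    [(10.0, 10.0, 1000.0, 10), (9.5, 1.0, 1000.0, 1), (10.0, 10.0, 999.0, 11),
     (0.1, 0.1, 3000.0, 1), (3.0, 7.0, 700.0, 3)],
)
def test_n_tank_loads(spray, area, tank, expected):
    assert n_tank_loads(spray, area, tank) == expected


# --- phase oracles (hand-computed from the table coefficients) -----------------

def test_mixing_loading_hand_calculation(tables, killer_scenario):
    # 1000 g formulation x 5e-5 contact x 0.5 AI fraction = 25 mg on hands;
    # no gloves; x 5% absorption = 1.25 mg
    p = exposure_mixing_loading(killer_scenario, tables)
    assert p.potential_exposure_mg == pytest.approx(25.0, rel=1e-12)
    assert p.absorbed_mg == pytest.approx(1.25, rel=1e-12)
    gloved = killer_scenario.with_ppe_item(Phase.MIXING_LOADING, "hands", "specific_gloves")
    assert exposure_mixing_loading(gloved, tables).absorbed_mg == pytest.approx(
        0.0125, rel=1e-12
    )


def test_mixing_loading_zero_cases(tables, killer_scenario):
    bag = _with(killer_scenario, product_name="DEMO-BUSTE 25")
    ledger = exposure_mixing_loading(bag, tables)
    assert ledger.potential_exposure_mg == ledger.absorbed_mg == 0.0
    assert not ledger.excluded

    skipped = _with(killer_scenario, skip_mixing_loading=True)
    ledger = exposure_mixing_loading(skipped, tables)
    assert ledger.absorbed_mg == 0.0
    assert ledger.excluded


def test_application_hand_calculation(tables, killer_scenario):
    # 5e5 mg AI applied x 10 ppm = 5 mg potential; no PPE -> x 5% = 0.25 mg
    p = exposure_application(killer_scenario, tables)
    assert p.potential_exposure_mg == pytest.approx(5.0, rel=1e-12)
    assert p.absorbed_mg == pytest.approx(0.25, rel=1e-12)
    # hazmat coverall on the body region only: skin = 5 x (1 - 0.60 x 0.99)
    suited = killer_scenario.with_ppe_item(Phase.APPLICATION, "body", "hazmat_coverall")
    assert exposure_application(suited, tables).skin_loading_mg == pytest.approx(
        5.0 * (1 - 0.60 * 0.99), rel=1e-12
    )


def test_application_zero_deposition_gives_zero_ledger(tables, killer_scenario):
    zero_dep = rd.ReferenceTables(
        formulation_table=tables.formulation_table,
        deposition_table={rd.Equipment.TRACTOR_OPEN: 0.0},
        protection_table=tables.protection_table,
        products=tables.products,
    )
    p = exposure_application(killer_scenario, zero_dep)
    assert p.potential_exposure_mg == p.skin_loading_mg == p.absorbed_mg == 0.0


def test_maintenance_hand_calculation(tables, killer_scenario):
    # 1000 kg mix handled x 3e-4 contact x 50 mg AI/kg mix = 15 mg potential
    p = exposure_maintenance(killer_scenario, tables)
    assert p.potential_exposure_mg == pytest.approx(15.0, rel=1e-12)
    assert p.absorbed_mg == pytest.approx(0.75, rel=1e-12)
    gloved = killer_scenario.with_ppe_item(Phase.MAINTENANCE, "hands", "generic_gloves")
    assert exposure_maintenance(gloved, tables).absorbed_mg == pytest.approx(
        0.075, rel=1e-12
    )


def test_maintenance_potential_halves_when_mix_twice_as_dilute(tables, killer_scenario):
    base = exposure_maintenance(killer_scenario, tables).potential_exposure_mg
    app = killer_scenario.application
    import dataclasses
    diluted = _with(
        killer_scenario,
        application=dataclasses.replace(
            app, spray_volume_hl_per_ha=2 * app.spray_volume_hl_per_ha
        ),
    )
    assert exposure_maintenance(diluted, tables).potential_exposure_mg == pytest.approx(
        base / 2, rel=1e-12
    )


# --- full assessment ----------------------------------------------------------

def test_reference_assessment(tables, killer_scenario):
    r = assess_scenario(killer_scenario, tables)
    assert r.total_absorbed_mg == pytest.approx(2.25, rel=1e-12)
    assert r.acceptable_dose_mg == pytest.approx(3.0, rel=1e-12)
    assert r.risk_percent == pytest.approx(75.0, rel=1e-12)
    assert r.tier is Tier.YELLOW
    assert r.n_tank_loads == 10
    assert r.audit["product"]["aoel_mg_per_kg_bw"] == 0.05


def test_full_ppe_strictly_reduces_risk(tables, killer_scenario):
    base = assess_scenario(killer_scenario, tables).risk_percent
    s = killer_scenario
    for phase in Phase:
        s = s.with_ppe_item(phase, "hands", "specific_gloves")
        s = s.with_ppe_item(phase, "body", "hazmat_coverall")
    assert assess_scenario(s, tables).risk_percent < base


def test_huge_aoel_drives_risk_to_green(tables, killer_scenario, tmp_path):
    from pestrisk.fixtures import build_demo_database
    build_demo_database(tmp_path)
    path = tmp_path / "products.csv"
    path.write_text(path.read_text().replace(
        "KILLER,ACTIVOL,powder,50,100,0.05,5", "KILLER,ACTIVOL,powder,50,100,1e6,5"))
    benign = rd.load_reference_tables(tmp_path)
    r = assess_scenario(killer_scenario, benign)
    assert r.risk_percent == pytest.approx(0.0, abs=1e-4)
    assert r.tier is Tier.GREEN


@pytest.mark.parametrize(
    ("risk", "tier"),
    [(0.0, Tier.GREEN), (49.999, Tier.GREEN), (50.0, Tier.YELLOW), (75.0, Tier.YELLOW),
     (100.0, Tier.YELLOW), (100.001, Tier.RED), (101.0, Tier.RED)],
)
def test_classify_tier_default_thresholds(risk, tier):
    assert classify_tier(risk) is tier


def test_classify_tier_rejects_negative_risk():
    with pytest.raises(PestriskError):
        classify_tier(-1.0)


# --- settings -----------------------------------------------------------------

def test_settings_invariants():
    with pytest.raises(PestriskError, match="sum to 1"):
        EngineSettings(body_region_weights={"head": 0.5, "body": 0.4})
    with pytest.raises(PestriskError, match="green_lt"):
        EngineSettings(tier_green_lt=120.0, tier_red_gt=100.0)


def test_load_settings_overrides(tmp_path):
    cfg = tmp_path / "settings.toml"
    cfg.write_text(
        "maintenance_contact_fraction = 0.001\n"
        "tier_green_lt = 20.0\n"
        "[crop_height_multipliers]\nlow = 1.0\nhigh = 2.0\n"
    )
    s = engine.load_settings(cfg)
    assert s.maintenance_contact_fraction == 0.001
    assert s.tier_green_lt == 20.0
    assert s.crop_height_multipliers["high"] == 2.0
    assert s.tier_red_gt == 100.0  # untouched default


def test_crop_height_multiplier_scales_application_only(tables, killer_scenario):
    settings = EngineSettings(crop_height_multipliers={"low": 1.0, "high": 3.0})
    base = assess_scenario(killer_scenario, tables)
    scaled = assess_scenario(killer_scenario, tables, settings)
    assert scaled.phase(Phase.APPLICATION).potential_exposure_mg == pytest.approx(
        3 * base.phase(Phase.APPLICATION).potential_exposure_mg
    )
    assert scaled.phase(Phase.MIXING_LOADING) == base.phase(Phase.MIXING_LOADING)


# --- invariants ---------------------------------------------------------------

@given(seed=st.integers(min_value=0, max_value=10_000))
def test_mass_ledger_conservation(tables, seed):
    """potential = retained-by-PPE + skin loading, exactly, in every phase."""
    s = generate_random_scenario(seed, tables)
    for p in assess_scenario(s, tables).phases:
        assert p.potential_exposure_mg == p.retained_by_ppe_mg + p.skin_loading_mg
        assert p.skin_loading_mg <= p.potential_exposure_mg * (1 + 1e-12)


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_ppm_sanity(tables, seed):
    """APP potential / AI applied equals deposition x 1e-6."""
    s = generate_random_scenario(seed, tables)
    p = exposure_application(s, tables)
    applied = ai_mass_applied(rd.get_product(tables, s.product_name), s.area_ha)
    dep = rd.deposition_factor(tables, s.application.equipment)
    assert p.potential_exposure_mg == pytest.approx(applied * dep * 1e-6, rel=1e-12)


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_ppe_upgrade_never_increases_risk(tables, seed):
    s = generate_random_scenario(seed, tables)
    base = assess_scenario(s, tables).risk_percent
    for phase in Phase:
        for region, item in [("hands", "specific_gloves"), ("body", "hazmat_coverall")]:
            upgraded = s.with_ppe_item(phase, region, item)
            assert assess_scenario(upgraded, tables).risk_percent <= base * (1 + 1e-12)


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_lower_deposition_equipment_never_increases_risk(tables, seed):
    s = generate_random_scenario(seed, tables)
    order = list(rd.EQUIPMENT_ORDER)
    idx = order.index(s.application.equipment)
    if idx == len(order) - 1:
        return
    base = assess_scenario(s, tables).risk_percent
    quieter = s.with_equipment(order[idx + 1])
    assert assess_scenario(quieter, tables).risk_percent <= base * (1 + 1e-12)


@given(seed=st.integers(min_value=0, max_value=10_000),
       k=st.floats(min_value=1.1, max_value=10.0))
def test_ml_and_app_absorbed_scale_linearly_with_area(tables, seed, k):
    s = generate_random_scenario(seed, tables)
    r1 = assess_scenario(s, tables)
    r2 = assess_scenario(_with(s, area_ha=k * s.area_ha), tables)
    for phase in (Phase.MIXING_LOADING, Phase.APPLICATION):
        a1, a2 = r1.phase(phase).absorbed_mg, r2.phase(phase).absorbed_mg
        if a1 > 0:
            assert a2 / a1 == pytest.approx(k, rel=1e-9)
    assert r2.risk_percent >= r1.risk_percent * (1 - 1e-12)


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_assessment_matches_independent_oracle(tables, seed):
    s = generate_random_scenario(seed, tables)
    r = assess_scenario(s, tables)
    expected = closed_form_risk_percent(s, tables)
    assert r.risk_percent == pytest.approx(expected, rel=1e-9)
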