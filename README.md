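# pestrisk

Preventive risk assessment for occupational pesticide use. From a declarative
treatment scenario — crop, treated area, product, spray rig, and the personal
protective equipment (PPE) worn in each work phase — the package computes the
operator's phase-wise dermal exposure, the absorbed daily dose, and the risk
index as a percentage of the Acceptable Operator Exposure Level (AOEL), then
classifies the planned workday as **green** (safe), **yellow** (borderline),
or **red** (unacceptable; do not spray).

It is written for the people who must produce a documented risk assessment
*before* a pesticide application: farmers and small estates, the occupational
physicians and consultants who assist them, and field inspectors who need a
quick screening calculation.

## The model

A pesticide workday has three modelled phases — **mixing & loading (M&L)**,
**application (APP)**, and **maintenance & cleaning (MAN)** (re-entry into the
treated field is out of scope). Each phase follows the same mass-transfer
ledger:

```
potential dermal exposure  →  × (1 − PF)  →  skin loading  →  × f_abs  →  absorbed dose
   (mg AI reaching the         PPE barrier                     dermal
    clothing/skin surface)                                     absorption
```

with phase-specific sources of the potential exposure:

- **M&L** (handles the *concentrate*, hands only):
  `E_ML = GAP · A · c_f(F, C) · C` — GAP the application rate (g formulation/ha),
  A the area (ha), C the AI mass fraction, and `c_f` a contact fraction that
  depends on the formulation type F (powder / liquid concentrate ≡ soluble
  granules / soluble bags) and the concentration band (<30, 30–60, 60–80, >80 %).
  Pre-dosed soluble bags give zero M&L exposure.
- **APP**: `E_APP = M_AI · d(eq) · 10⁻⁶` — `M_AI = GAP · A · C` the applied AI
  mass and `d(eq)` the equipment deposition factor in ppm of the applied mix
  (1000 for a knapsack down to 0.001 for a charcoal-filtered sealed cab). The
  deposit is split over five body regions (head, face, hands, body, feet),
  each attenuated by its own PPE protection factor.
- **MAN** (handles the *dilute* mix, hands only):
  `E_MAN = m_handled · c_MAN · χ_mix`, with one tank load of mix handled by
  default and `χ_mix` the AI concentration in the tank.

The risk index is

```
R = 100 · Σ_phase D_abs / (AOEL · BW)      [% of AOEL]
```

with BW the operator body weight (default 60 kg). Default tiers: green for
R < 50 %, red for R > 100 % (AOEL exceedance), yellow between. Every constant
— region weights, contact fractions, tier thresholds, crop-height and
pressure modifiers — lives in `EngineSettings` / `settings.toml` and is
recorded in the report's audit map.

The parameter tables (formulation contact fractions, deposition factors,
clothing protection factors) ship as commented CSV files under
`src/pestrisk/data/`, together with a 16-entry demo product database whose
first entry is the published worked-exercise product (KILLER/ACTIVOL); the
other 15 are clearly labelled `DEMO-` synthetics.

## Worked example

`scenario.toml` — treating 10 ha of olive grove with the demo powder product
from an open-cockpit tractor, no PPE:

```toml
[crop]
name = "olive"
area_ha = 10.0
pest = "olive fruit fly"

[product]
name = "KILLER"

[application]
spray_volume_hl_per_ha = 10.0
tank_volume_l = 1000.0
pressure_bar = 3.0
equipment = "tractor_open"
```

```sh
pestrisk assess --scenario scenario.toml
```

prints (abridged):

```
**Verdict: ⚠️ YELLOW — borderline conditions; improvement recommended**

Absorbed dose **2.25 mg** of **3 mg** acceptable (AOEL × body weight) → **75 % of AOEL**.

| Phase          | Potential | Retained by PPE | Skin loading | Absorbed |
|----------------|-----------|-----------------|--------------|----------|
| mixing_loading | 25        | 0               | 25           | 1.25     |
| application    | 5         | 0               | 5            | 0.25     |
| maintenance    | 15        | 0               | 15           | 0.75     |
```

Reading the numbers: of the 500 g of active ingredient applied, 25 mg reach
the bare hands while handling the concentrate, 5 mg land on the body during
spraying (10 ppm of the applied mass), and 15 mg come from handling the dilute
mix during cleaning; at 5 % dermal absorption the operator absorbs 2.25 mg
against an acceptable 3 mg/day (AOEL 0.05 mg/kg × 60 kg), i.e. 75 % of AOEL —
borderline, so the exit code is 2 (0 = green, 2 = yellow, 3 = red, 1 = error).

The what-if search finds the cheapest way out:

```
$ pestrisk what-if --scenario scenario.toml --max-changes 1
current: 75 % of AOEL (yellow)
1. [green, 33.8 %] mixing_loading: wear specific_gloves on hands
2. [green, 37.5 %] mixing_loading: wear generic_gloves on hands
```

The same functionality is available as a library (`pestrisk.parse_scenario`,
`pestrisk.assess_scenario`, `pestrisk.suggest_improvements`,
`pestrisk.render_report`).

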