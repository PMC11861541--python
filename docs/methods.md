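# Methods

## Scope and intent

`pestrisk` is a *preventive* (pre-application) screening model of operator
exposure during agricultural pesticide use. It answers one question: given a
planned treatment — product, area, rig, and PPE — is the operator's absorbed
daily dose of active ingredient (AI) acceptable against the AOEL set at
product authorization? It is a deterministic point-estimate model in the
tradition of the operator-exposure calculators used in pre-marketing
assessment (German model / UK POEM / EFSA calculator): handled or applied
mass × a transfer fraction × (1 − protection factor) × dermal absorption,
summed over phases and normalised by AOEL × body weight.

Three work phases are modelled: mixing & loading (M&L), application (APP),
and maintenance & cleaning (MAN). Worker re-entry into the treated field,
inhalation exposure, bystander/environmental endpoints, multi-product tank
mixes, and multi-day aggregation are all out of scope.

## The calculation chain

All phases share a mass ledger (per workday, in mg AI):

* potential dermal exposure `E` — AI reaching the clothing/skin surface;
* skin loading `L = E·(1 − PF)` — past the PPE barrier (PF = fraction retained);
* absorbed dose `D = L·f_abs` — across the skin (`f_abs` = dermal absorption).

Phase sources:

| Phase | Potential exposure | PPE applied |
|---|---|---|
| M&L | `GAP·A·c_f(F, C)·C` (handles the concentrate) | hands (gloves) only |
| APP | `GAP·A·C·d(eq)·10⁻⁶` | per-region split, 5 barriers |
| MAN | `m_handled·c_MAN·χ_mix` (handles the dilute mix) | hands (gloves) only |

`GAP` is the application rate in g formulation/ha, `A` the area in ha, `C`
the AI mass fraction, `c_f` the formulation/band contact fraction, `d(eq)`
the equipment deposition factor in ppm of applied mix (since it is a mass
ratio, ppm of mix and ppm of AI cancel identically), `m_handled` the dilute
mix mass handled during cleaning, and `χ_mix = M_AI / (V_spray·A·ρ)` the AI
concentration of the tank mix.

Risk index: `R = 100·ΣD / (AOEL·BW)` in % of AOEL. Tier: green if
`R < green_lt` (default 50 %), red if `R > red_gt` (default 100 %, the
regulatory acceptability bound), yellow between. The tier is decided on the
unrounded value; reports round to 3 significant figures.

The M&L ledger is zero when the product comes in pre-dosed soluble bags (no
contact with the concentrate) and when the scenario declares that loading is
performed off-farm at a staffed loading station (`skip_mixing_loading`); the
report shows the latter as *excluded* rather than computed-zero.

## Parameter tables

Shipped as commented, versioned CSVs (`src/pestrisk/data/`), regenerable
byte-identically by `pestrisk.fixtures.build_demo_database`:

* **Contact fractions** `c_f`: per formulation and AI-concentration band
  (<30, 30–60, 60–80, >80 %). Liquid concentrate 0.030/0.045/0.070/0.090 %,
  powder 0.003/0.005/0.007/0.009 %, soluble bags 0 everywhere; soluble
  granules alias the liquid-concentrate row (their coefficients are alike).
  Bands are half-open on the left — [0,30), [30,60), [60,80), [80,100] — a
  deterministic convention chosen because the printed band labels do not
  assign ownership of the boundaries. The banding variable is the AI mass
  concentration in the formulation, the only concentration the user declares.
  The accompanying source text verbally ranks powders above liquids while the
  printed coefficients rank liquids higher; the printed table is implemented
  as ground truth and the conflict is noted in the data-file comments.
* **Deposition factors** `d(eq)`, ppm of applied mix: knapsack 1000, manual
  towed pipe 100, open tractor 10, closed cab (natural ventilation) 1, closed
  cab (forced ventilation) 0.1, charcoal-filtered sealed cab 0.001. The last
  value is the forced-ventilation cab reduced by the filter's stated 99 %
  efficiency (0.1 × 0.01), preserving the order-of-magnitude-per-row
  progression. Crop height and spray pressure are acknowledged exposure
  determinants without published coefficients, so they enter as configurable
  multiplicative modifiers that default to 1.0 — defaults must not invent
  effect sizes.
* **Protection factors** PF: underwear 0.50, generic clothes 0.70, cotton
  coverall 0.90, non-woven single-use coverall 0.90, HazMat disposable
  coverall 0.99 (the endorsed clothing table), plus declared package defaults
  for the slots the data-entry model exposes but the clothing table omits:
  generic gloves 0.90, specific gloves 0.99, headdress 0.90, mask 0.90
  (dermal face protection only — inhalation is not modelled), shoes 0.70,
  boots 0.99. The audit map flags these as package defaults, not table values.
* **Product database**: 16 active ingredients. Entry 1 is the published
  worked-exercise product (KILLER / ACTIVOL: powder, 50 g/100 g, GAP
  100 g/ha, AOEL 0.05 mg/kg bw, dermal absorption 5 %); the identities of the
  other prototype ingredients are not published, so entries 2–16 are
  synthetic, `DEMO-`-prefixed, and span all four formulation types and AOELs
  from 0.001 to 1 mg/kg bw.

## Tunable constants (`EngineSettings`)

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| body weight | 60 | kg | operator-exposure convention of the EFSA-style calculators; configurable per scenario |
| body-region weights (APP) | head .06, face .04, hands .20, body .60, feet .10 | fraction, sum 1 | adult body-surface proportions; no published split exists for the five PPE slots |
| MAN contact fraction `c_MAN` | 3·10⁻⁴ | – | the dilute-liquid (<30 % band) contact fraction, since tank mix is always dilute |
| MAN handled mass | one tank volume | kg | cleaning handles roughly one tank's worth of mix |
| mix density ρ | 1 | kg/L | water-like spray mix; formulation concentration treated as mass fraction for liquids too |
| tier thresholds | green < 50, red > 100 | % AOEL | 100 % is the regulatory bound; 50 % gives the borderline band a quantitative edge |
| crop-height / pressure multipliers | 1.0 | – | named determinants without published values |

Every value used in an assessment — table cells, multipliers, defaults and
their provenance — is serialized into the result's audit map and appended to
the reports, so a trained reader can reproduce the numbers by hand.

## Design choices where the design was open

* **Fraction model, not event model, for M&L**: M&L exposure scales with the
  total formulation mass handled (GAP·A), not with the number of tank loads.
  The number of tank loads is still computed (`⌈V_spray·A / V_tank⌉`, min 1)
  and reported, so an event-scaled variant can be swapped in without changing
  the interface.
* **Single dermal-absorption coefficient**: the product record carries one
  skin-absorption value, applied to concentrate (M&L) and dilute mix
  (APP/MAN) alike; calculators that distinguish the two can be emulated by
  editing the product database.
* **Hands-only M&L and MAN**: both phases are manual-contact phases; the
  deposit is assigned entirely to the hands and only gloves attenuate it.
* **Re-donning contaminated gloves** is a recognised extra-absorption
  mechanism with no parameters to model it; it surfaces as a report warning
  whenever a manual phase is run bare-handed.
* **What-if search** is exhaustive over the finite upgrade lattice (better
  PPE item per region and phase, lower-deposition equipment, combinations up
  to `max_changes`); the lattice is desk-scale, so no heuristics. Product,
  area, and AOEL are agronomic givens and are never touched.
* **Reports**: JSON (machine record, audit included) and Markdown (printable
  document with the tier pictogram); PDF generation is a platform feature,
  not model content.

## Numerical choices

* Internal arithmetic in double precision, no intermediate rounding; reports
  round to 3 significant figures; tiers are decided on unrounded values.
* The phase ledger is stored so that `potential = retained + skin_loading`
  holds *exactly* in floating point (the potential is recomposed from its two
  parts, at most 1 ulp from the product formula).
* The tank-load ceiling subtracts a 10⁻⁹ relative guard before `ceil` so that
  exact multiples (10 000 L / 1 000 L) do not round up spuriously.
* Concentration bands are half-open-left; concentration 100 % belongs to the
  top band; concentration 0 is rejected (a product must contain some AI).
* Table validation is strict at load time: fractions in [0,1], deposition
  non-negative and strictly decreasing along the equipment ladder, bands
  partitioning (0,100], duplicate product names rejected case-insensitively.

## Synthetic data and what the tests show

The random-scenario generator draws areas of 0.1–100 ha, spray volumes of
1–20 hL/ha, tanks of 100–3000 L, any product, equipment, and PPE combination,
10 % off-farm-loading scenarios, and body weights of 50–100 kg — deliberately
covering the full cross-product, including agronomically implausible corners
(a knapsack over 100 ha) so that monotonicity and conservation properties are
exercised at the extremes. It does *not* emulate correlations present in real
work (equipment choice follows farm size; PPE use correlates across phases),
within-day variability, or measurement error: passing tests demonstrate the
arithmetic correctness and ordering properties of the model, not the field
accuracy of the coefficient tables, whose validation requires biological and
environmental monitoring campaigns.

The test suite checks, among others: verbatim reproduction of every shipped
table coefficient through the lookup layer; a hand-computed reference
treatment (25/5/15 mg potential → 1.25/0.25/0.75 mg absorbed → 75 % of AOEL,
yellow); equivalence with an independently coded closed-form oracle to 1e-9
relative on seeded random scenarios; exact mass-ledger conservation; PPE and
equipment monotonicity; area linearity of M&L and APP; zero cases; band
totality at the 30/60/80 boundaries; and that every what-if suggestion,
re-applied and re-assessed, reproduces its quoted risk exactly.

## Known limitations

* The coefficient tables merge heterogeneous monitoring sources; the model's
  absolute accuracy is bounded by theirs, and field measurements are often
  1–3 orders of magnitude below such screening estimates.
* Inhalation is not modelled; the mask's factor protects dermal face exposure
  only.
* One product, one workday; no aggregation across days or products.
* The MAN phase parameters (contact fraction, handled mass) are declared
  best-guess defaults — manual cleaning work resists rigorous modelling.
* Tier thresholds other than the 100 % AOEL bound are conventions, not
  regulatory values; jurisdictions may require different banding.
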