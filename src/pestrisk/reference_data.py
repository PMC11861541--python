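"""Reference parameter tables: loading, validation, and lookups.

The model is driven by three small parameter tables plus a product database,
shipped as comma-delimited UTF-8 text with ``#`` comment/version headers so
that parameter updates can be reviewed line-by-line:

* ``formulation_fractions.csv`` — mixing-and-loading contact fractions per
  formulation type and active-ingredient concentration band;
* ``deposition_factors.csv``   — fractional deposition on the operator during
  application, in ppm of the applied spray mix, per equipment type;
* ``protection_factors.csv``   — fraction of deposited product retained by a
  garment or PPE item (kept off the skin), per item;
* ``products.csv``             — commercial products with their active
  ingredient's AOEL and dermal-absorption coefficient.

All invariants (fractions in [0, 1], deposition non-negative and strictly
decreasing from knapsack to charcoal-filtered cab, bands partitioning
(0, 100]) are checked once at load time; lookups afterwards are plain
dictionary reads.
"""

from __future__ import annotations

import csv
import difflib
import io
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

from .errors import (
    DomainLookupError,
    ProductNotFoundError,
    TableLoadError,
    TableValidationError,
)

__all__ = [
    "Formulation",
    "Equipment",
    "CropHeight",
    "ActiveIngredient",
    "Product",
    "ProtectionItem",
    "ReferenceTables",
    "CONCENTRATION_BANDS",
    "EQUIPMENT_ORDER",
    "BODY_REGIONS",
    "load_reference_tables",
    "write_reference_tables",
    "default_tables_dir",
    "formulation_exposure_fraction",
    "deposition_factor",
    "protection_factor",
    "get_product",
]


class Formulation(str, Enum):
    """Physical form of the commercial product."""

    POWDER = "powder"
    LIQUID_CONCENTRATE = "liquid_concentrate"
    SOLUBLE_GRANULE = "soluble_granule"
    SOLUBLE_BAG = "soluble_bag"


class Equipment(str, Enum):
    """Spraying equipment, ordered from most to least operator-contaminating."""

    KNAPSACK = "knapsack"
    TOWED_PIPE_MANUAL = "towed_pipe_manual"
    TRACTOR_OPEN = "tractor_open"
    TRACTOR_CLOSED_NATURAL = "tractor_closed_natural"
    TRACTOR_CLOSED_FORCED = "tractor_closed_forced"
    TRACTOR_CLOSED_CHARCOAL = "tractor_closed_charcoal"


class CropHeight(str, Enum):
    """Low crops are sprayed downwards (cereals); high crops upwards (trees, vines)."""

    LOW = "low"
    HIGH = "high"


#: Deposition must be strictly decreasing along this order (one order of
#: magnitude per step in the shipped table).
EQUIPMENT_ORDER: tuple[Equipment, ...] = (
    Equipment.KNAPSACK,
    Equipment.TOWED_PIPE_MANUAL,
    Equipment.TRACTOR_OPEN,
    Equipment.TRACTOR_CLOSED_NATURAL,
    Equipment.TRACTOR_CLOSED_FORCED,
    Equipment.TRACTOR_CLOSED_CHARCOAL,
)

#: AI-concentration bands (% by mass in the formulation). Half-open on the
#: left — [0, 30), [30, 60), [60, 80), [80, 100] — so every concentration in
#: (0, 100] falls in exactly one band and the boundaries 30/60/80 belong to
#: the upper band.
CONCENTRATION_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 30.0),
    (30.0, 60.0),
    (60.0, 80.0),
    (80.0, 100.0),
)

#: Body regions with a dedicated PPE slot, one per data-entry field.
BODY_REGIONS: tuple[str, ...] = ("face", "head", "hands", "body", "feet")

#: Soluble granules share the liquid-concentrate contact fractions (the two
#: behave alike during mixing and loading), so the table stores one row and
#: the lookup resolves the alias.
_FORMULATION_ALIASES: dict[Formulation, Formulation] = {
    Formulation.SOLUBLE_GRANULE: Formulation.LIQUID_CONCENTRATE,
}

_FILENAMES = (
    "formulation_fractions.csv",
    "deposition_factors.csv",
    "protection_factors.csv",
    "products.csv",
)


@dataclass(frozen=True)
class ActiveIngredient:
    """Toxicological identity of an active substance.

    Parameters
    ----------
    name
        Identifier of the active ingredient.
    aoel
        Acceptable Operator Exposure Level, mg active ingredient per kg body
        weight per day. Must be positive.
    dermal_absorption
        Fraction of the skin loading that crosses the skin, in [0, 1].
    """

    name: str
    aoel: float
    dermal_absorption: float

    def __post_init__(self) -> None:
        if not self.aoel > 0:
            raise TableValidationError(
                f"active ingredient {self.name!r}: aoel must be > 0, got {self.aoel}"
            )
        if not 0.0 <= self.dermal_absorption <= 1.0:
            raise TableValidationError(
                f"active ingredient {self.name!r}: dermal_absorption must be in "
                f"[0, 1], got {self.dermal_absorption}"
            )


@dataclass(frozen=True)
class Product:
    """A commercial pesticide formulation.

    ``concentration`` is the mass fraction of active ingredient in the
    formulation in g per 100 g (i.e., percent); ``gap`` the authorized
    application rate in g of formulation per hectare.
    """

    name: str
    active_ingredient: ActiveIngredient
    formulation: Formulation
    concentration: float
    gap: float

    def __post_init__(self) -> None:
        if not 0.0 < self.concentration <= 100.0:
            raise TableValidationError(
                f"product {self.name!r}: concentration must be in (0, 100], "
                f"got {self.concentration}"
            )
        if not self.gap > 0:
            raise TableValidationError(
                f"product {self.name!r}: gap must be > 0, got {self.gap}"
            )


@dataclass(frozen=True)
class ProtectionItem:
    """A garment or PPE item with its protection factor.

    ``fraction`` is the share of deposited product the barrier retains
    (1 − fraction passes through to the skin). ``regions`` lists the body
    regions the item can be worn on.
    """

    name: str
    regions: frozenset[str]
    fraction: float


@dataclass(frozen=True)
class ReferenceTables:
    """The validated parameter set the exposure engine runs on."""

    formulation_table: Mapping[Formulation, Mapping[tuple[float, float], float]]
    deposition_table: Mapping[Equipment, float]
    protection_table: Mapping[str, ProtectionItem]
    products: Mapping[str, Product] = field(default_factory=dict)

    def product_names(self) -> list[str]:
        return [p.name for p in self.products.values()]


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------


def default_tables_dir() -> Path:
    """Path of the packaged demo reference tables."""
    pkg_dir = resources.files(__package__) / "data"
    try:
        return Path(str(pkg_dir))
    except TypeError:  # pragma: no cover - zip installs
        return Path(__file__).parent / "data"


def _read_rows(path: Path, expected_cols: Sequence[str]) -> list[dict[str, str]]:
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise TableLoadError(f"cannot read table file {path}: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(io.StringIO("\n".join(lines)))
    if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(expected_cols):
        raise TableLoadError(
            f"{path.name}: expected columns {list(expected_cols)}, "
            f"got {reader.fieldnames}"
        )
    return [{k: v.strip() for k, v in row.items()} for row in reader]


def _parse_float(path_name: str, row_no: int, col: str, raw: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise TableValidationError(
            f"{path_name} row {row_no}, column {col!r}: not a number: {raw!r}"
        ) from None


def load_reference_tables(directory_path: str | Path) -> ReferenceTables:
    """Load and validate the three parameter tables and the product database.

    Raises
    ------
    TableLoadError
        If any of the four files is missing or malformed; the message lists
        every missing file.
    TableValidationError
        If any value violates its range or consistency invariant; the message
        names the file, row, and column.
    """
    directory = Path(directory_path)
    missing = [name for name in _FILENAMES if not (directory / name).is_file()]
    if missing:
        raise TableLoadError(
            f"missing reference table file(s) in {directory}: {', '.join(missing)}"
        )

    # --- formulation contact fractions ---
    formulation_table: dict[Formulation, dict[tuple[float, float], float]] = {}
    fname = "formulation_fractions.csv"
    for i, row in enumerate(
        _read_rows(directory / fname, ("formulation", "band_lo", "band_hi", "fraction")), 1
    ):
        try:
            form = Formulation(row["formulation"])
        except ValueError:
            raise TableValidationError(
                f"{fname} row {i}, column 'formulation': unknown value {row['formulation']!r}"
            ) from None
        lo = _parse_float(fname, i, "band_lo", row["band_lo"])
        hi = _parse_float(fname, i, "band_hi", row["band_hi"])
        frac = _parse_float(fname, i, "fraction", row["fraction"])
        if not 0.0 <= frac <= 1.0:
            raise TableValidationError(
                f"{fname} row {i}, column 'fraction': contact fraction must be "
                f"in [0, 1], got {frac}"
            )
        if (lo, hi) not in CONCENTRATION_BANDS:
            raise TableValidationError(
                f"{fname} row {i}: band ({lo}, {hi}) is not one of the four "
                f"concentration bands {CONCENTRATION_BANDS}"
            )
        formulation_table.setdefault(form, {})[(lo, hi)] = frac
    for form, bands in formulation_table.items():
        if set(bands) != set(CONCENTRATION_BANDS):
            raise TableValidationError(
                f"{fname}: formulation {form.value!r} does not cover all four "
                f"concentration bands; (0, 100] must be partitioned"
            )

    # --- deposition factors ---
    deposition_table: dict[Equipment, float] = {}
    fname = "deposition_factors.csv"
    for i, row in enumerate(_read_rows(directory / fname, ("equipment", "ppm")), 1):
        try:
            equip = Equipment(row["equipment"])
        except ValueError:
            raise TableValidationError(
                f"{fname} row {i}, column 'equipment': unknown value {row['equipment']!r}"
            ) from None
        ppm = _parse_float(fname, i, "ppm", row["ppm"])
        if ppm < 0:
            raise TableValidationError(
                f"{fname} row {i}, column 'ppm': deposition factor must be >= 0, got {ppm}"
            )
        if equip in deposition_table:
            raise TableValidationError(f"{fname} row {i}: duplicate equipment {equip.value!r}")
        deposition_table[equip] = ppm
    present = [e for e in EQUIPMENT_ORDER if e in deposition_table]
    for a, b in zip(present, present[1:]):
        if not deposition_table[a] > deposition_table[b]:
            raise TableValidationError(
                f"{fname}: deposition must be strictly decreasing from "
                f"{a.value} ({deposition_table[a]}) to {b.value} ({deposition_table[b]})"
            )

    # --- protection factors ---
    protection_table: dict[str, ProtectionItem] = {}
    fname = "protection_factors.csv"
    for i, row in enumerate(
        _read_rows(directory / fname, ("item", "body_region_applicability", "fraction")), 1
    ):
        item = row["item"]
        frac = _parse_float(fname, i, "fraction", row["fraction"])
        if not 0.0 <= frac <= 1.0:
            raise TableValidationError(
                f"{fname} row {i}, column 'fraction': protection factor must be "
                f"in [0, 1], got {frac}"
            )
        regions = frozenset(
            r.strip() for r in row["body_region_applicability"].split(";") if r.strip()
        )
        bad = regions - set(BODY_REGIONS)
        if bad:
            raise TableValidationError(
                f"{fname} row {i}, column 'body_region_applicability': unknown "
                f"region(s) {sorted(bad)}"
            )
        if item in protection_table:
            raise TableValidationError(f"{fname} row {i}: duplicate item {item!r}")
        protection_table[item] = ProtectionItem(item, regions, frac)

    # --- products ---
    products: dict[str, Product] = {}
    fname = "products.csv"
    cols = (
        "product_name",
        "ai_name",
        "formulation",
        "concentration_pct",
        "gap_g_per_ha",
        "aoel_mg_per_kg",
        "dermal_absorption_pct",
    )
    for i, row in enumerate(_read_rows(directory / fname, cols), 1):
        try:
            form = Formulation(row["formulation"])
        except ValueError:
            raise TableValidationError(
                f"{fname} row {i}, column 'formulation': unknown value {row['formulation']!r}"
            ) from None
        try:
            ai = ActiveIngredient(
                name=row["ai_name"],
                aoel=_parse_float(fname, i, "aoel_mg_per_kg", row["aoel_mg_per_kg"]),
                dermal_absorption=_parse_float(
                    fname, i, "dermal_absorption_pct", row["dermal_absorption_pct"]
                )
                / 100.0,
            )
            product = Product(
                name=row["product_name"],
                active_ingredient=ai,
                formulation=form,
                concentration=_parse_float(
                    fname, i, "concentration_pct", row["concentration_pct"]
                ),
                gap=_parse_float(fname, i, "gap_g_per_ha", row["gap_g_per_ha"]),
            )
        except TableValidationError as exc:
            raise TableValidationError(f"{fname} row {i}: {exc}") from None
        key = product.name.casefold()
        if key in products:
            raise TableValidationError(
                f"{fname} row {i}: duplicate product name {product.name!r}"
            )
        products[key] = product

    return ReferenceTables(
        formulation_table=formulation_table,
        deposition_table=deposition_table,
        protection_table=protection_table,
        products=products,
    )


def write_reference_tables(tables: ReferenceTables, directory_path: str | Path) -> None:
    """Write ``tables`` back to the four delimited files (round-trips with the loader)."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "formulation_fractions.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write("# pestrisk reference table v1: M&L contact fractions (dimensionless)\n")
        w = csv.writer(fh)
        w.writerow(["formulation", "band_lo", "band_hi", "fraction"])
        for form in Formulation:
            for (lo, hi), frac in sorted(tables.formulation_table.get(form, {}).items()):
                w.writerow([form.value, _fmt(lo), _fmt(hi), _fmt(frac)])

    with open(directory / "deposition_factors.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write("# pestrisk reference table v1: deposition factors (ppm of applied mix)\n")
        w = csv.writer(fh)
        w.writerow(["equipment", "ppm"])
        for equip in EQUIPMENT_ORDER:
            if equip in tables.deposition_table:
                w.writerow([equip.value, _fmt(tables.deposition_table[equip])])

    with open(directory / "protection_factors.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write("# pestrisk reference table v1: PPE protection factors (fraction retained)\n")
        w = csv.writer(fh)
        w.writerow(["item", "body_region_applicability", "fraction"])
        for item in tables.protection_table.values():
            w.writerow([item.name, ";".join(sorted(item.regions)), _fmt(item.fraction)])

    with open(directory / "products.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write("# pestrisk reference table v1: product / active-ingredient database\n")
        w = csv.writer(fh)
        w.writerow(
            [
                "product_name",
                "ai_name",
                "formulation",
                "concentration_pct",
                "gap_g_per_ha",
                "aoel_mg_per_kg",
                "dermal_absorption_pct",
            ]
        )
        for p in tables.products.values():
            w.writerow(
                [
                    p.name,
                    p.active_ingredient.name,
                    p.formulation.value,
                    _fmt(p.concentration),
                    _fmt(p.gap),
                    _fmt(p.active_ingredient.aoel),
                    _fmt(p.active_ingredient.dermal_absorption * 100.0),
                ]
            )


def _fmt(x: float) -> str:
    return format(x, "g")


# ---------------------------------------------------------------------------
# lookups
# ---------------------------------------------------------------------------


def formulation_exposure_fraction(
    tables: ReferenceTables, formulation: Formulation | str, ai_concentration_pct: float
) -> float:
    """Mixing-and-loading contact fraction for a formulation and AI concentration.

    The concentration (% AI by mass in the formulation, in (0, 100]) selects
    one of the four bands; soluble bags always return 0 and soluble granules
    resolve to the liquid-concentrate row.
    """
    try:
        form = Formulation(formulation)
    except ValueError:
        raise DomainLookupError(
            f"unknown formulation {formulation!r}; valid: "
            f"{[f.value for f in Formulation]}"
        ) from None
    if not 0.0 < ai_concentration_pct <= 100.0:
        raise DomainLookupError(
            f"AI concentration must be in (0, 100] %, got {ai_concentration_pct}"
        )
    form = _FORMULATION_ALIASES.get(form, form)
    bands = tables.formulation_table.get(form)
    if bands is None:
        raise DomainLookupError(
            f"formulation {form.value!r} has no row in the contact-fraction table"
        )
    for lo, hi in CONCENTRATION_BANDS:
        # half-open [lo, hi), except the last band which includes 100
        if lo <= ai_concentration_pct < hi or (hi == 100.0 and ai_concentration_pct == 100.0):
            return bands[(lo, hi)]
    raise AssertionError("bands partition (0, 100]")  # pragma: no cover


def deposition_factor(
    tables: ReferenceTables,
    equipment: Equipment | str,
    crop_height: CropHeight | str = CropHeight.LOW,
    pressure_bar: float = 0.0,
    *,
    crop_height_multipliers: Mapping[str, float] | None = None,
    pressure_multipliers: Sequence[tuple[float, float]] = (),
) -> float:
    """Deposition factor in ppm: base table value × crop-height × pressure multipliers.

    Both multipliers default to 1.0 (no effect). ``pressure_multipliers`` is a
    sequence of ``(upper_bound_bar, multiplier)`` bands scanned in order; a
    pressure above every bound gets the last band's multiplier.
    """
    try:
        equip = Equipment(equipment)
    except ValueError:
        raise DomainLookupError(
            f"unknown equipment {equipment!r}; valid: {[e.value for e in Equipment]}"
        ) from None
    if pressure_bar < 0:
        raise DomainLookupError(f"spray pressure must be >= 0 bar, got {pressure_bar}")
    if equip not in tables.deposition_table:
        raise DomainLookupError(
            f"equipment {equip.value!r} has no row in the deposition table"
        )
    base = tables.deposition_table[equip]
    height = CropHeight(crop_height)
    h_mult = 1.0
    if crop_height_multipliers is not None:
        h_mult = float(crop_height_multipliers.get(height.value, 1.0))
    p_mult = 1.0
    for upper, mult in pressure_multipliers:
        p_mult = mult
        if pressure_bar <= upper:
            break
    return base * h_mult * p_mult


def protection_factor(tables: ReferenceTables, item: str) -> float:
    """Protection fraction in [0, 1] for a PPE item; ``"none"`` means no barrier."""
    if item == "none":
        return 0.0
    entry = tables.protection_table.get(item)
    if entry is None:
        raise DomainLookupError(
            f"unknown PPE item {item!r}; valid: "
            f"{['none', *sorted(tables.protection_table)]}"
        )
    return entry.fraction


def get_product(tables: ReferenceTables, name: str) -> Product:
    """Case-insensitive product lookup; unknown names list near matches."""
    product = tables.products.get(name.casefold())
    if product is None:
        near = difflib.get_close_matches(
            name.casefold(), list(tables.products), n=3, cutoff=0.6
        )
        hint = (
            f"; did you mean {', '.join(tables.products[k].name for k in near)}?"
            if near
            else ""
        )
        raise ProductNotFoundError(f"unknown product {name!r}{hint}")
    return product
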