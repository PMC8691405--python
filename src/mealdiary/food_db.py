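"""Food-composition data model and I/O.

Records follow the USDA Standard Reference convention: nutrients are stored
per 100 g of edible food, and each record carries an ordered list of
household portion units with gram weights.  Converting an (amount, unit)
pair to nutrients is then a single linear map, and aggregation over a day
is plain vector addition.

Databases from several sources (e.g. a national standard-reference table,
a branded-foods table, restaurant scrapes) merge into one searchable
collection; entries are keyed by ``(code, source)`` and duplicates of the
same food across sources are deliberately retained.
"""

from __future__ import annotations

import csv
import json
import math
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NUTRIENT_FIELDS",
    "ATWATER_KCAL_PER_G",
    "NutrientVector",
    "FoodEntry",
    "FoodDBError",
    "UnknownUnitError",
    "normalize_text",
    "load_food_db",
    "write_food_db",
    "index_entries",
    "scale_nutrients",
    "load_fixture_db",
]

NUTRIENT_FIELDS = ("energy_kcal", "protein_g", "fat_g", "carbohydrate_g", "alcohol_g")

#: General (Atwater) energy-conversion factors, kcal per gram.
ATWATER_KCAL_PER_G = {"protein_g": 4.0, "carbohydrate_g": 4.0, "fat_g": 9.0, "alcohol_g": 7.0}

_WS_RE = re.compile(r"\s+")


class FoodDBError(ValueError):
    """Malformed food-database content (bad row, duplicate key, bad schema)."""


class UnknownUnitError(KeyError):
    """A portion unit not present on the entry was requested."""


def normalize_text(text: str) -> str:
    """NFC-normalize, case-fold and collapse whitespace (matching key form)."""
    return _WS_RE.sub(" ", unicodedata.normalize("NFC", text).casefold()).strip()


@dataclass(frozen=True)
class NutrientVector:
    """Energy and macronutrients; additive, and linear under scaling."""

    energy_kcal: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0
    carbohydrate_g: float = 0.0
    alcohol_g: float = 0.0

    def __post_init__(self) -> None:
        for name in NUTRIENT_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise FoodDBError(f"nutrient {name} must be finite and >= 0, got {v!r}")

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(
            **{n: getattr(self, n) + getattr(other, n) for n in NUTRIENT_FIELDS}
        )

    def scaled(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise ValueError(f"scaling factor must be non-negative, got {factor}")
        return NutrientVector(**{n: getattr(self, n) * factor for n in NUTRIENT_FIELDS})

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in NUTRIENT_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "NutrientVector":
        return cls(**{n: float(d.get(n, 0.0)) for n in NUTRIENT_FIELDS})


@dataclass(frozen=True)
class FoodEntry:
    """One food-composition record from one source database.

    ``portions`` is an ordered tuple of ``(unit_name, gram_weight)`` pairs;
    the first-listed unit is the entry's default.  A bare ``("gram", 1.0)``
    portion is appended automatically when absent so every entry is always
    loggable by weight.
    """

    code: str
    source: str
    description: str
    nutrients_per_100g: NutrientVector
    brand: str | None = None
    portions: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.code or not self.source:
            raise FoodDBError("code and source must be non-empty")
        if not self.description:
            raise FoodDBError(f"entry {self.code}/{self.source}: empty description")
        portions = tuple((str(u), float(g)) for u, g in self.portions)
        if not any(normalize_text(u) == "gram" for u, _ in portions):
            portions = portions + (("gram", 1.0),)
        for unit, grams in portions:
            if not unit:
                raise FoodDBError(f"entry {self.code}/{self.source}: empty unit name")
            if not math.isfinite(grams) or grams <= 0:
                raise FoodDBError(
                    f"entry {self.code}/{self.source}: gram weight for unit "
                    f"{unit!r} must be > 0, got {grams!r}"
                )
        object.__setattr__(self, "portions", portions)

    @property
    def key(self) -> tuple[str, str]:
        return (self.code, self.source)

    @property
    def description_norm(self) -> str:
        return normalize_text(self.description)

    @property
    def unit_names(self) -> tuple[str, ...]:
        return tuple(u for u, _ in self.portions)

    def gram_weight(self, unit_name: str) -> float:
        want = normalize_text(unit_name)
        for unit, grams in self.portions:
            if normalize_text(unit) == want:
                return grams
        raise UnknownUnitError(
            f"unknown unit {unit_name!r} for {self.code}/{self.source}; "
            f"available units: {', '.join(self.unit_names)}"
        )


def scale_nutrients(entry: FoodEntry, unit_name: str, amount: float) -> NutrientVector:
    """Nutrients for ``amount`` of ``unit_name`` of the entry.

    Linear in the amount: ``per_100g * amount * gram_weight(unit) / 100``.
    """
    if amount < 0:
        raise ValueError(f"amount must be non-negative, got {amount}")
    factor = amount * entry.gram_weight(unit_name) / 100.0
    return entry.nutrients_per_100g.scaled(factor)


# ---------------------------------------------------------------------------
# I/O.  CSV schema:
#   code,source,description,brand,energy_kcal,protein_g,fat_g,carbohydrate_g,
#   alcohol_g,portions
# with portions encoded "unit:grams;unit:grams;...".  JSON mirrors the same
# fields as a list of objects (portions as [[unit, grams], ...]).
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("code", "source", "description", "brand") + NUTRIENT_FIELDS + ("portions",)


def _parse_portions(text: str, where: str) -> tuple[tuple[str, float], ...]:
    if not text.strip():
        return ()
    out = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        unit, sep, grams = part.rpartition(":")
        if not sep:
            raise FoodDBError(f"{where}: malformed portion {part!r} (want unit:grams)")
        try:
            out.append((unit.strip(), float(grams)))
        except ValueError as exc:
            raise FoodDBError(f"{where}: non-numeric gram weight in {part!r}") from exc
    return tuple(out)


def _format_portions(portions: Sequence[tuple[str, float]]) -> str:
    return ";".join(f"{u}:{g:g}" for u, g in portions)


def _entry_from_record(rec: dict, where: str) -> FoodEntry:
    try:
        nutrients = {}
        for name in NUTRIENT_FIELDS:
            raw = rec.get(name, "")
            raw = "" if raw is None else str(raw).strip()
            try:
                nutrients[name] = float(raw) if raw else 0.0
            except ValueError as exc:
                raise FoodDBError(f"{where}: field {name} is not a number: {raw!r}") from exc
        portions = rec.get("portions", ())
        if isinstance(portions, str):
            portions = _parse_portions(portions, where)
        else:
            portions = tuple((str(u), float(g)) for u, g in portions)
        brand = rec.get("brand") or None
        return FoodEntry(
            code=str(rec.get("code", "")).strip(),
            source=str(rec.get("source", "")).strip(),
            description=str(rec.get("description", "")).strip(),
            brand=str(brand).strip() if brand else None,
            nutrients_per_100g=NutrientVector(**nutrients),
            portions=portions,
        )
    except FoodDBError as exc:
        # re-anchor invariant violations to the offending row
        raise FoodDBError(f"{where}: {exc}") if where not in str(exc) else exc


def load_food_db(
    paths: str | Path | Sequence[str | Path], fmt: str | None = None
) -> list[FoodEntry]:
    """Load one or more CSV/JSON food databases into a single collection.

    Format is inferred from the file suffix unless ``fmt`` ("csv" or "json")
    is given.  Duplicate ``(code, source)`` keys — within one file or across
    files — are rejected; the same code under different sources is kept.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    entries: list[FoodEntry] = []
    seen: dict[tuple[str, str], str] = {}
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"food database not found: {path}")
        use_fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
        if use_fmt == "csv":
            with path.open(newline="", encoding="utf-8") as fh:
                reader = csv.DictReader(fh)
                missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
                if missing:
                    raise FoodDBError(
                        f"{path}: missing columns: {', '.join(sorted(missing))}"
                    )
                rows = [(f"{path} row {i}", rec) for i, rec in enumerate(reader, start=2)]
        elif use_fmt == "json":
            data = json.loads(path.read_text(encoding="utf-8"))
            if not isinstance(data, list):
                raise FoodDBError(f"{path}: JSON food DB must be a list of objects")
            rows = [(f"{path} item {i}", rec) for i, rec in enumerate(data)]
        else:
            raise ValueError(f"unknown format {use_fmt!r} (expected csv or json)")
        for where, rec in rows:
            entry = _entry_from_record(rec, where)
            if entry.key in seen:
                raise FoodDBError(
                    f"{where}: duplicate key code={entry.code!r} source={entry.source!r} "
                    f"(first seen at {seen[entry.key]})"
                )
            seen[entry.key] = where
            entries.append(entry)
    return entries


def write_food_db(
    entries: Iterable[FoodEntry], path: str | Path, fmt: str | None = None
) -> Path:
    """Write entries to CSV or JSON (round-trips with :func:`load_food_db`)."""
    path = Path(path)
    use_fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    records = [
        {
            "code": e.code,
            "source": e.source,
            "description": e.description,
            "brand": e.brand or "",
            **{n: getattr(e.nutrients_per_100g, n) for n in NUTRIENT_FIELDS},
            "portions": _format_portions(e.portions),
        }
        for e in entries
    ]
    if use_fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            writer.writerows(records)
    elif use_fmt == "json":
        for rec in records:
            rec["portions"] = [
                [u, g] for u, g in _parse_portions(rec["portions"], str(path))
            ]
        path.write_text(json.dumps(records, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {use_fmt!r} (expected csv or json)")
    return path


def index_entries(entries: Iterable[FoodEntry]) -> dict[tuple[str, str], FoodEntry]:
    return {e.key: e for e in entries}


def load_fixture_db() -> list[FoodEntry]:
    """The bundled 50-entry synthetic fixture database (two sources)."""
    return load_food_db(Path(__file__).parent / "data" / "fixture_db.csv")
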