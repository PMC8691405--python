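"""Per-user food diaries: confirm/revise workflow, persistence, aggregation.

A diary is an append-only JSON-lines event log of confirmed
:class:`LogRecord` entries — one per logged food — replayable to rebuild
all state (personalization history, unit popularity, reports).  Daily
intakes aggregate records into energy and percent-of-energy macronutrient
shares using the general Atwater factors (protein 4, carbohydrate 4,
fat 9, alcohol 7 kcal/g).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .food_db import ATWATER_KCAL_PER_G, NutrientVector, scale_nutrients
from .food_matcher import CandidateRanking
from .unit_resolver import UnitRanking

__all__ = [
    "LogRecord",
    "DailyIntake",
    "DiaryStore",
    "confirm_or_revise",
    "daily_intake",
    "DAILY_COLUMNS",
]

INPUT_MODES = ("spoken", "written")

DAILY_COLUMNS = (
    "user_id",
    "day",
    "energy_kcal",
    "pct_protein",
    "pct_fat",
    "pct_carbohydrate",
    "pct_alcohol",
    "n_eating_events",
)


@dataclass(frozen=True)
class LogRecord:
    """One confirmed food item in a user's diary.

    ``revised_food`` is set when the user picked a candidate other than the
    proposed top-1 food code; ``revised_unit`` / ``revised_amount`` when the
    confirmed unit or amount differs from the proposed defaults.
    """

    user_id: str
    day: dt.date
    food_code: str
    source: str
    unit_name: str
    amount: float
    nutrients: NutrientVector
    item_text: str = ""
    meal_label: str | None = None
    input_mode: str = "written"
    revised_food: bool = False
    revised_unit: bool = False
    revised_amount: bool = False
    had_brand_or_prep: bool = False
    had_quantity: bool = False

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if self.amount < 0:
            raise ValueError("amount must be non-negative")

    @property
    def revised_unit_amount(self) -> bool:
        return self.revised_unit or self.revised_amount

    def to_dict(self) -> dict:
        d = {
            "user_id": self.user_id,
            "day": self.day.isoformat(),
            "food_code": self.food_code,
            "source": self.source,
            "unit_name": self.unit_name,
            "amount": self.amount,
            "nutrients": self.nutrients.as_dict(),
            "item_text": self.item_text,
            "meal_label": self.meal_label,
            "input_mode": self.input_mode,
            "revised_food": self.revised_food,
            "revised_unit": self.revised_unit,
            "revised_amount": self.revised_amount,
            "had_brand_or_prep": self.had_brand_or_prep,
            "had_quantity": self.had_quantity,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LogRecord":
        d = dict(d)
        d["day"] = dt.date.fromisoformat(d["day"])
        d["nutrients"] = NutrientVector.from_dict(d["nutrients"])
        return cls(**d)


def confirm_or_revise(
    ranking: CandidateRanking,
    unit_ranking: UnitRanking,
    user_choice: tuple[int | None, int | None, float | None] | None = None,
    *,
    user_id: str,
    day: dt.date,
    meal_label: str | None = None,
    input_mode: str = "written",
) -> LogRecord | None:
    """Turn a candidate+unit ranking into a confirmed LogRecord.

    With no ``user_choice`` the top-1 candidate, top-ranked unit and
    predicted amount are implicitly confirmed and all revision flags stay
    false.  A choice tuple ``(candidate_index, unit_index, amount)`` (None
    components mean "keep default") sets revision flags where it differs
    from the defaults.  A candidate index at/after the end of the list
    signals delete-and-retry: ``None`` is returned and nothing is logged.
    """
    if not ranking.candidates:
        raise ValueError("cannot confirm an empty candidate ranking")
    cand_idx, unit_idx, amount = (None, None, None) if user_choice is None else user_choice
    cand_idx = 0 if cand_idx is None else cand_idx
    unit_idx = 0 if unit_idx is None else unit_idx
    if cand_idx < 0 or unit_idx < 0:
        raise IndexError("candidate/unit indices must be non-negative")
    if cand_idx >= len(ranking.candidates):
        return None  # delete-and-retry
    if unit_idx >= len(unit_ranking.units):
        raise IndexError(
            f"unit index {unit_idx} out of range for {len(unit_ranking.units)} units"
        )
    entry = ranking.candidates[cand_idx][0]
    unit = unit_ranking.units[unit_idx]
    final_amount = unit_ranking.amount if amount is None else float(amount)
    item = ranking.item
    return LogRecord(
        user_id=user_id,
        day=day,
        food_code=entry.code,
        source=entry.source,
        unit_name=unit,
        amount=final_amount,
        nutrients=scale_nutrients(entry, unit, final_amount),
        item_text=item.food_text,
        meal_label=meal_label,
        input_mode=input_mode,
        revised_food=cand_idx != 0,
        revised_unit=unit_idx != 0,
        revised_amount=final_amount != unit_ranking.amount,
        had_brand_or_prep=bool(item.brand_text or item.descriptors),
        had_quantity=item.quantity_text is not None,
    )


@dataclass(frozen=True)
class DailyIntake:
    """One user-day: total energy, percent energy by macronutrient, events."""

    user_id: str
    day: dt.date
    energy_kcal: float
    pct_protein: float
    pct_fat: float
    pct_carbohydrate: float
    pct_alcohol: float
    n_eating_events: int


def daily_intake(records: Sequence[LogRecord]) -> DailyIntake:
    """Aggregate one user-day of records.

    Percent energy uses Atwater factors; a zero-energy day reports all
    percentages as 0.  Eating events count distinct meal labels, with each
    unlabeled record counting as its own event.
    """
    if not records:
        raise ValueError("daily_intake needs at least one record; aggregate empty "
                         "days with DiaryStore.daily_table instead")
    users = {r.user_id for r in records}
    days = {r.day for r in records}
    if len(users) > 1 or len(days) > 1:
        raise ValueError(f"records span users {users} and days {days}; expected one user-day")

    total = NutrientVector()
    for r in records:
        total = total + r.nutrients
    energy = total.energy_kcal
    if energy > 0:
        pct = {
            n: 100.0 * getattr(total, n) * f / energy
            for n, f in ATWATER_KCAL_PER_G.items()
        }
    else:
        pct = {n: 0.0 for n in ATWATER_KCAL_PER_G}
    labels = {r.meal_label for r in records if r.meal_label is not None}
    n_events = len(labels) + sum(1 for r in records if r.meal_label is None)
    return DailyIntake(
        user_id=users.pop(),
        day=days.pop(),
        energy_kcal=energy,
        pct_protein=pct["protein_g"],
        pct_fat=pct["fat_g"],
        pct_carbohydrate=pct["carbohydrate_g"],
        pct_alcohol=pct["alcohol_g"],
        n_eating_events=n_events,
    )


class DiaryStore:
    """Append-only diary of LogRecords with JSON-lines persistence."""

    def __init__(self, records: Iterable[LogRecord] = ()) -> None:
        self._records: list[LogRecord] = list(records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    @property
    def records(self) -> list[LogRecord]:
        return list(self._records)

    def append(self, record: LogRecord) -> None:
        self._records.append(record)

    def extend(self, records: Iterable[LogRecord]) -> None:
        self._records.extend(records)

    def user_history(self, user_id: str) -> list[LogRecord]:
        """Chronological confirmed records for one user (personalization key)."""
        return [r for r in self._records if r.user_id == user_id]

    def all_history(self) -> list[LogRecord]:
        return list(self._records)

    def users(self) -> list[str]:
        seen = dict.fromkeys(r.user_id for r in self._records)
        return list(seen)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for r in self._records:
                fh.write(json.dumps(r.to_dict()) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DiaryStore":
        records = []
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(LogRecord.from_dict(json.loads(line)))
        return cls(records)

    # -- aggregation --------------------------------------------------------

    def daily_table(self, user_id: str | None = None) -> pd.DataFrame:
        """DailyIntake rows (one per user-day) as a DataFrame."""
        by_day: dict[tuple[str, dt.date], list[LogRecord]] = {}
        for r in self._records:
            if user_id is not None and r.user_id != user_id:
                continue
            by_day.setdefault((r.user_id, r.day), []).append(r)
        rows = [daily_intake(recs) for _, recs in sorted(by_day.items())]
        return pd.DataFrame(
            [vars(r) for r in rows], columns=list(DAILY_COLUMNS)
        )

    def export_daily_csv(self, path: str | Path, user_id: str | None = None) -> Path:
        path = Path(path)
        self.daily_table(user_id).to_csv(path, index=False)
        return path
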