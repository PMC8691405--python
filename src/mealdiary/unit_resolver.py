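"""Measuring-unit ranking with a four-tier fallback hierarchy.

For a chosen food entry the portion units are ordered by:

1. **exact_match** — the uttered unit string (case-folded, singular/plural
   normalized) equals one of the entry's portion units; that unit ranks
   first ("cup" puts "cup" on top).
2. **user_history** — otherwise, the unit this user has confirmed most
   often for this food code.
3. **global_popularity** — otherwise, the unit confirmed most often by all
   users for this food code.
4. **entry_default** — otherwise, the entry's first-listed portion unit.

History frequency ties break by most recent confirmation.  The remaining
units always follow in entry order, so the output is a permutation of the
entry's unit list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .food_db import FoodEntry
from .meal_nlu import _singular, parse_amount_detail

__all__ = ["UnitRanking", "rank_units"]

TIERS = ("exact_match", "user_history", "global_popularity", "entry_default")


@dataclass
class UnitRanking:
    """Ordered portion units for one entry, plus the predicted amount."""

    units: list[str]
    amount: float
    tier_used: str
    amount_assumed: bool = False

    def __post_init__(self) -> None:
        if self.tier_used not in TIERS:
            raise ValueError(f"unknown tier {self.tier_used!r}")

    @property
    def top(self) -> str:
        return self.units[0]


def _unit_key(name: str) -> str:
    return _singular(name.strip())


def _history_argmax(
    entry: FoodEntry, history: Iterable, unit_keys: dict[str, str]
) -> str | None:
    """Most frequently confirmed portion unit for this food code.

    ``history`` is chronological; ties break by most recent confirmation.
    Only units the entry actually offers are candidates.
    """
    counts: dict[str, int] = {}
    last_seen: dict[str, int] = {}
    for pos, rec in enumerate(history):
        if (rec.food_code, rec.source) != entry.key:
            continue
        key = _unit_key(rec.unit_name)
        if key not in unit_keys:
            continue
        counts[key] = counts.get(key, 0) + 1
        last_seen[key] = pos
    if not counts:
        return None
    best = max(counts, key=lambda u: (counts[u], last_seen[u]))
    return unit_keys[best]


def rank_units(
    entry: FoodEntry,
    unit_text: str | None = None,
    user_history: Iterable = (),
    global_history: Iterable = (),
    quantity_text: str | None = None,
) -> UnitRanking:
    """Rank the entry's portion units through the fallback hierarchy.

    ``user_history`` / ``global_history`` are chronological sequences of
    confirmed log records (anything with ``food_code``, ``source`` and
    ``unit_name`` attributes).  The predicted amount comes from the item's
    quantity text (default 1 when absent or unparseable).
    """
    unit_names = list(entry.unit_names)
    unit_keys = {_unit_key(u): u for u in unit_names}

    top: str | None = None
    tier = "entry_default"
    if unit_text:
        wanted = _unit_key(unit_text)
        if wanted in unit_keys:
            top, tier = unit_keys[wanted], "exact_match"
    if top is None:
        top = _history_argmax(entry, user_history, unit_keys)
        if top is not None:
            tier = "user_history"
    if top is None:
        top = _history_argmax(entry, global_history, unit_keys)
        if top is not None:
            tier = "global_popularity"
    if top is None:
        top, tier = unit_names[0], "entry_default"

    ordered = [top] + [u for u in unit_names if u != top]
    amount, assumed = parse_amount_detail(quantity_text)
    return UnitRanking(units=ordered, amount=amount, tier_used=tier, amount_assumed=assumed)
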