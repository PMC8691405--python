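"""Diary: confirm/revise semantics, daily aggregation, persistence."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mealdiary.diary_store import DiaryStore, LogRecord, confirm_or_revise, daily_intake
from mealdiary.food_db import FoodEntry, NutrientVector
from mealdiary.food_matcher import CandidateRanking
from mealdiary.meal_nlu import FoodItem
from mealdiary.unit_resolver import UnitRanking

DAY = dt.date(2021, 3, 1)


def _entry(code, energy=100.0, protein=0.0, fat=0.0, carb=0.0):
    return FoodEntry(
        code=code,
        source="reference",
        description=f"food {code}",
        nutrients_per_100g=NutrientVector(energy, protein, fat, carb, 0),
        portions=(("serving", 100.0), ("cup", 240.0)),
    )


@pytest.fixture
def ranking():
    item = FoodItem(food_text="some food", quantity_text="a", unit_text="serving")
    entries = [_entry(f"F{i}") for i in range(6)]
    return CandidateRanking(item=item, candidates=[(e, 1.0 - 0.1 * i) for i, e in enumerate(entries)])


@pytest.fixture
def unit_ranking():
    return UnitRanking(units=["serving", "cup", "gram"], amount=1.0, tier_used="exact_match")


def _confirm(ranking, unit_ranking, choice=None):
    return confirm_or_revise(
        ranking, unit_ranking, choice, user_id="U1", day=DAY, input_mode="written"
    )


def test_implicit_confirmation_accepts_all_defaults(ranking, unit_ranking):
    rec = _confirm(ranking, unit_ranking)
    assert rec.food_code == "F0"
    assert rec.unit_name == "serving" and rec.amount == 1.0
    assert not rec.revised_food and not rec.revised_unit_amount
    assert rec.had_quantity and not rec.had_brand_or_prep
    assert rec.nutrients.energy_kcal == pytest.approx(100.0)


def test_choosing_other_candidate_sets_food_flag_only(ranking, unit_ranking):
    rec = _confirm(ranking, unit_ranking, (4, None, None))
    assert rec.food_code == "F4"
    assert rec.revised_food and not rec.revised_unit_amount


def test_changing_amount_sets_unit_amount_flag(ranking, unit_ranking):
    rec = _confirm(ranking, unit_ranking, (None, None, 2.0))
    assert rec.amount == 2.0
    assert rec.revised_unit_amount and not rec.revised_food


def test_changing_unit_sets_unit_amount_flag(ranking, unit_ranking):
    rec = _confirm(ranking, unit_ranking, (None, 1, None))
    assert rec.unit_name == "cup"
    assert rec.revised_unit and rec.revised_unit_amount


def test_out_of_range_candidate_means_delete_and_retry(ranking, unit_ranking):
    assert _confirm(ranking, unit_ranking, (99, None, None)) is None


def test_negative_index_is_an_error(ranking, unit_ranking):
    with pytest.raises(IndexError):
        _confirm(ranking, unit_ranking, (-1, None, None))


# -- daily aggregation ------------------------------------------------------

def _record(energy, protein=0.0, fat=0.0, carb=0.0, alcohol=0.0, user="U1",
            day=DAY, meal_label=None, amount=1.0):
    return LogRecord(
        user_id=user,
        day=day,
        food_code="F1",
        source="reference",
        unit_name="serving",
        amount=amount,
        nutrients=NutrientVector(energy, protein, fat, carb, alcohol),
        meal_label=meal_label,
    )


def test_percent_energy_arithmetic():
    day = daily_intake([_record(200, protein=25, carb=25)])
    assert day.energy_kcal == 200
    assert day.pct_protein == pytest.approx(50.0)
    assert day.pct_carbohydrate == pytest.approx(50.0)
    assert day.pct_fat == 0.0


def test_energy_is_additive():
    day = daily_intake([_record(300), _record(500)])
    assert day.energy_kcal == 800


def test_zero_energy_day_reports_zero_percentages():
    day = daily_intake([_record(0)])
    assert day.energy_kcal == 0
    assert day.pct_protein == day.pct_fat == day.pct_carbohydrate == 0.0


def test_eating_events_count_distinct_meal_labels():
    records = [
        _record(100, meal_label="meal1"),
        _record(100, meal_label="meal1"),
        _record(100, meal_label="meal2"),
        _record(100),  # unlabeled records each count once
        _record(100),
    ]
    assert daily_intake(records).n_eating_events == 4


def test_mixed_user_days_rejected():
    with pytest.raises(ValueError):
        daily_intake([_record(100), _record(100, user="U2")])
    with pytest.raises(ValueError):
        daily_intake([_record(100), _record(100, day=DAY + dt.timedelta(days=1))])


@given(
    energies=st.lists(st.floats(min_value=0, max_value=2000, allow_nan=False),
                      min_size=1, max_size=8),
    order_seed=st.integers(0, 1000),
)
def test_daily_energy_order_invariant_and_split_additive(energies, order_seed):
    import random

    records = [_record(e, protein=e / 20, fat=e / 40, carb=e / 10) for e in energies]
    base = daily_intake(records)
    shuffled = records[:]
    random.Random(order_seed).shuffle(shuffled)
    assert daily_intake(shuffled).energy_kcal == pytest.approx(base.energy_kcal)
    # splitting any record into two half-amount records conserves totals
    split = []
    for r in records:
        half = NutrientVector(**{k: v / 2 for k, v in r.nutrients.as_dict().items()})
        for _ in range(2):
            split.append(
                LogRecord(
                    user_id=r.user_id, day=r.day, food_code=r.food_code,
                    source=r.source, unit_name=r.unit_name, amount=r.amount / 2,
                    nutrients=half,
                )
            )
    after = daily_intake(split)
    assert after.energy_kcal == pytest.approx(base.energy_kcal, rel=1e-9, abs=1e-9)
    assert after.pct_protein == pytest.approx(base.pct_protein, rel=1e-9, abs=1e-9)


def test_jsonl_round_trip(tmp_path):
    store = DiaryStore([
        _record(300, meal_label="meal1"),
        _record(200, user="U2", day=DAY + dt.timedelta(days=1)),
    ])
    path = store.save(tmp_path / "diary.jsonl")
    loaded = DiaryStore.load(path)
    assert loaded.records == store.records


def test_daily_table_shape_and_empty():
    assert len(DiaryStore().daily_table()) == 0
    store = DiaryStore([_record(300), _record(200, day=DAY + dt.timedelta(days=1))])
    table = store.daily_table("U1")
    assert len(table) == 2
    assert list(table["energy_kcal"]) == [300.0, 200.0]
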