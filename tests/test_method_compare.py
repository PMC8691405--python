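"""Statistical battery: elementary tests against hand/brute-force oracles."""

import datetime as dt
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mealdiary.diary_store import LogRecord
from mealdiary.food_db import NutrientVector
from mealdiary.method_compare import (
    bonferroni_pairwise,
    build_table1,
    energy_trend,
    mode_summary,
    paired_t,
    pearson_with_r2,
    plausibility_filter,
    table1_from_cohort,
    two_day_averages,
)
from mealdiary.synthetic_data import CohortSpec, generate_cohort


# -- paired t ---------------------------------------------------------------

def test_paired_t_hand_computed_example():
    # differences [-1, 0, -2]: mean -1, sd 1, se 1/sqrt(3) -> t = -sqrt(3)
    res = paired_t([1, 2, 3], [2, 2, 5])
    assert res.t_statistic == pytest.approx(-1.7321, abs=1e-4)
    assert res.df == 2


def test_paired_t_identical_vectors():
    res = paired_t([3.2, 4.8, 9.1], [3.2, 4.8, 9.1])
    assert res.t_statistic == 0.0
    assert res.p_value == 1.0


def test_paired_t_constant_nonzero_difference_is_degenerate():
    res = paired_t([2, 3, 4], [1, 2, 3])
    assert res.p_value == 0.0
    assert res.degenerate


def test_paired_t_needs_two_pairs():
    with pytest.raises(ValueError):
        paired_t([1], [2])


# -- pearson ----------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, rho",
    [
        ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
        ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
        ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),  # hand-computed: cov 1, sds sqrt(5/3)
    ],
)
def test_pearson_known_values(x, y, rho):
    res = pearson_with_r2(x, y)
    assert res.rho == pytest.approx(rho, abs=1e-12)
    assert res.r_squared == pytest.approx(rho**2, abs=1e-12)


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValueError):
        pearson_with_r2([1, 1, 1], [1, 2, 3])


def _oracle_paired_t(a, b):
    """Explicit-sum paired t (no vectorized library calls)."""
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t, 2 * stats.t.sf(abs(t), n - 1)


def _oracle_pearson(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    sa = math.sqrt(sum((x - ma) ** 2 for x in a))
    sb = math.sqrt(sum((y - mb) ** 2 for y in b))
    r = cov / (sa * sb)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * stats.t.sf(abs(t), n - 2)


def test_agreement_with_explicit_formula_oracles():
    rng = np.random.default_rng(12)
    for _ in range(200):
        n = int(rng.integers(4, 30))
        a = list(rng.normal(size=n))
        b = list(rng.normal(size=n))
        res = paired_t(a, b)
        t, p = _oracle_paired_t(a, b)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        corr = pearson_with_r2(a, b)
        r, pr = _oracle_pearson(a, b)
        assert corr.rho == pytest.approx(r, abs=1e-10)
        assert corr.p_value == pytest.approx(pr, abs=1e-10)


# -- bonferroni -------------------------------------------------------------

def test_bonferroni_multiplies_by_pair_count():
    rng = np.random.default_rng(3)
    groups = {k: rng.normal(loc=k, size=10) for k in range(3)}
    out = bonferroni_pairwise(groups)
    assert len(out) == 3
    assert np.allclose(out["p_adjusted"], np.minimum(1.0, out["p_raw"] * 3))
    assert (out["p_adjusted"] >= out["p_raw"]).all()


def test_bonferroni_caps_at_one():
    groups = {"a": [1.0, 1.1, 0.9], "b": [1.0, 1.05, 0.95], "c": [5.0, 5.1, 4.9]}
    out = bonferroni_pairwise(groups)
    pair_ab = out[(out.level_a == "a") & (out.level_b == "b")].iloc[0]
    assert pair_ab.p_adjusted <= 1.0
    assert (out["p_adjusted"] <= 1.0).all()


def test_bonferroni_identical_groups_all_one():
    g = [1.0, 2.0, 3.0]
    out = bonferroni_pairwise({"a": g, "b": list(g), "c": list(g)})
    assert (out["p_adjusted"] == 1.0).all()


def test_bonferroni_small_level_flagged_not_computed():
    out = bonferroni_pairwise({"a": [1.0], "b": [1.0, 2.0, 3.0]})
    row = out.iloc[0]
    assert not row.computed
    assert np.isnan(row.p_raw)


# -- plausibility filter ----------------------------------------------------

def _tiny_cohort(energies_by_pid):
    rows = []
    for pid, (e1, e2) in energies_by_pid.items():
        for day, e in ((2, e1), (3, e2)):
            for method in ("app", "recall"):
                rows.append(
                    dict(participant_id=pid, day=day, weekend=False, method=method,
                         energy_kcal=e, pct_protein=17.0, pct_fat=36.0,
                         pct_carbohydrate=47.0, pct_alcohol=0.0, n_events=4)
                )
    return pd.DataFrame(rows)


def test_filter_excludes_5300_average():
    cohort = _tiny_cohort({"P1": (5200, 5400), "P2": (2000, 2100)})
    retained, excluded = plausibility_filter(cohort)
    assert excluded == ["P1"]
    assert set(retained["participant_id"]) == {"P2"}


def test_filter_boundary_is_strictly_below():
    cohort = _tiny_cohort({"P1": (4999, 4999), "P2": (5000, 5000)})
    retained, excluded = plausibility_filter(cohort)
    assert excluded == ["P2"]
    assert "P1" in set(retained["participant_id"])


def test_filter_is_idempotent():
    cohort = generate_cohort(CohortSpec(seed=2))
    once, _ = plausibility_filter(cohort)
    twice, excluded_again = plausibility_filter(once)
    assert excluded_again == []
    assert once.equals(twice)


def test_filter_requires_overlap_days():
    cohort = _tiny_cohort({"P1": (2000, 2000)})
    broken = cohort[cohort["method"] == "app"]
    with pytest.raises(ValueError, match="P1"):
        plausibility_filter(broken)


# -- trend ------------------------------------------------------------------

def _flat_cohort(n=20, days=5, energy=2000.0):
    rows = []
    for i in range(n):
        for d in range(1, days + 1):
            rows.append(
                dict(participant_id=f"P{i}", day=d, weekend=(d >= 4), method="app",
                     energy_kcal=energy, pct_protein=17.0, pct_fat=36.0,
                     pct_carbohydrate=47.0, pct_alcohol=0.0, n_events=4)
            )
    return pd.DataFrame(rows)


def test_flat_series_has_zero_slope():
    res = energy_trend(_flat_cohort())
    assert res.slope == pytest.approx(0.0, abs=1e-9)
    assert res.slope_adjusted == pytest.approx(0.0, abs=1e-9)


def test_single_day_rejected():
    cohort = _flat_cohort(days=1)
    with pytest.raises(ValueError):
        energy_trend(cohort)


def test_injected_drift_recovered():
    cohort = generate_cohort(
        CohortSpec(n_participants=200, trend_kcal_per_day=-50.0, n_implausible=0, seed=21)
    )
    res = energy_trend(cohort)
    lo, hi = res.slope_ci
    assert lo <= -50.0 <= hi


# -- table 1 ----------------------------------------------------------------

def test_table1_self_comparison_is_null():
    cohort = generate_cohort(CohortSpec(n_participants=20, n_implausible=0, seed=13))
    avg = two_day_averages(cohort)
    app = avg[avg["method"] == "app"].drop(columns="method")
    table = build_table1(app, app.copy())
    assert len(table) == 5
    assert (table["p_value"] == 1.0).all()
    assert np.allclose(table["mean_app"], table["mean_recall"])


def test_table1_variable_list_and_counts():
    cohort = generate_cohort(CohortSpec(seed=3))
    retained, _ = plausibility_filter(cohort)
    table = table1_from_cohort(retained)
    assert list(table["variable"]) == [
        "energy_kcal", "pct_protein", "pct_fat", "pct_carbohydrate", "n_events"
    ]
    assert (table["n"] == 34).all()
    assert table["p_value"].between(0, 1).all()


# -- mode summary -----------------------------------------------------------

def _mode_record(mode="written", revised_food=False, revised_unit=False,
                 revised_amount=False, brand=False, qty=False, user="U1"):
    return LogRecord(
        user_id=user,
        day=dt.date(2021, 3, 1),
        food_code="F1",
        source="reference",
        unit_name="cup",
        amount=1,
        nutrients=NutrientVector(100, 5, 3, 12, 0),
        input_mode=mode,
        revised_food=revised_food,
        revised_unit=revised_unit,
        revised_amount=revised_amount,
        had_brand_or_prep=brand,
        had_quantity=qty,
    )


def test_all_defaults_accepted_when_nothing_revised():
    summary = mode_summary([_mode_record() for _ in range(5)])
    written = summary.per_mode.set_index("input_mode").loc["written"]
    assert written["pct_default_food_accepted"] == 100.0
    assert written["pct_default_unit_accepted"] == 100.0
    assert written["pct_default_amount_accepted"] == 100.0
    assert summary.revision_rate_food == 0.0


def test_amount_revisions_counted():
    records = [_mode_record(revised_amount=(i < 2)) for i in range(10)]
    summary = mode_summary(records)
    written = summary.per_mode.set_index("input_mode").loc["written"]
    assert written["pct_default_amount_accepted"] == pytest.approx(80.0)
    assert summary.revision_rate_unit_amount == pytest.approx(20.0)


def test_mode_shares():
    records = [_mode_record("spoken")] * 3 + [_mode_record("written")] * 7
    summary = mode_summary(records)
    per = summary.per_mode.set_index("input_mode")
    assert per.loc["spoken", "pct_of_all_foods"] == pytest.approx(30.0)
    assert per.loc["written", "pct_of_all_foods"] == pytest.approx(70.0)


def test_empty_diary_zero_filled():
    summary = mode_summary([])
    assert (summary.per_mode["n_foods"] == 0).all()
    assert summary.revision_rate_food == 0.0
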