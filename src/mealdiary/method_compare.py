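"""Method-comparison statistics for paired dietary-assessment cohorts.

Implements the full evaluation battery used to compare an app-logged
diary against an interviewer-administered recall comparator:

* an a-priori plausibility filter (participants with a 2-day average
  energy intake >= 5000 kcal are excluded);
* paired-samples t tests and Pearson correlations (with R^2) on the
  2-day averages of energy, percent energy by macronutrient and number
  of eating events — the "Table 1" analogue;
* simple linear time-trend regression of energy over study days, with
  and without a weekend adjustment (statsmodels OLS), plus a
  multiplicative weekend-effect estimate from a log-energy fit;
* Bonferroni-corrected pairwise comparisons of means across levels
  (day of week, recall sequence number) using Welch two-sample t tests;
* logging-mode summaries of spoken vs written entries and default
  acceptance rates — the "Table 2" analogue.

The significance level defaults to alpha = .05 throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diary_store import LogRecord

__all__ = [
    "ALPHA",
    "PairedComparison",
    "CorrelationResult",
    "TrendResult",
    "ModeSummary",
    "plausibility_filter",
    "paired_t",
    "pearson_with_r2",
    "energy_trend",
    "bonferroni_pairwise",
    "mode_summary",
    "two_day_averages",
    "build_table1",
    "table1_from_cohort",
    "build_table2",
    "figure1_table",
    "null_rejection_rate",
    "power_curve",
    "TABLE1_VARIABLES",
]

ALPHA = 0.05

TABLE1_VARIABLES = (
    "energy_kcal",
    "pct_protein",
    "pct_fat",
    "pct_carbohydrate",
    "n_events",
)


@dataclass(frozen=True)
class PairedComparison:
    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    rho: float
    p_value: float

    @property
    def r_squared(self) -> float:
        return self.rho**2


@dataclass(frozen=True)
class TrendResult:
    """Energy-over-days regression, unadjusted and weekend-adjusted."""

    slope: float
    p_unadjusted: float
    slope_ci: tuple[float, float]
    slope_adjusted: float
    p_adjusted: float
    slope_adjusted_ci: tuple[float, float]
    weekend_coef_kcal: float
    weekend_ratio: float
    weekend_ratio_ci: tuple[float, float]


# ---------------------------------------------------------------------------
# Plausibility filter
# ---------------------------------------------------------------------------

def plausibility_filter(
    cohort: pd.DataFrame,
    threshold_kcal: float = 5000.0,
    method: str = "app",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop participants whose 2-day average energy is not plausibly low.

    The 2-day average uses ``method`` rows (app by default) on each
    participant's overlap days — the days on which recall rows exist.
    Strictly-below the threshold is retained.  Idempotent.
    """
    required = {"participant_id", "day", "method", "energy_kcal"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    overlap = cohort.loc[
        cohort["method"] == "recall", ["participant_id", "day"]
    ].drop_duplicates()
    no_overlap = set(cohort["participant_id"]) - set(overlap["participant_id"])
    if no_overlap:
        raise ValueError(
            f"participant {sorted(no_overlap)[0]} has no overlap (recall) days"
        )
    rows = overlap.merge(
        cohort[cohort["method"] == method], on=["participant_id", "day"], how="left"
    )
    short = rows.loc[rows["energy_kcal"].isna(), "participant_id"]
    if len(short):
        raise ValueError(
            f"participant {short.iloc[0]} is missing {method} rows on overlap days"
        )
    avg = rows.groupby("participant_id")["energy_kcal"].mean()
    excluded = sorted(avg.index[avg >= threshold_kcal])
    retained = cohort[~cohort["participant_id"].isin(excluded)].reset_index(drop=True)
    return retained, excluded


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def paired_t(values_a: Sequence[float], values_b: Sequence[float], variable: str = "") -> PairedComparison:
    """Classic paired-samples t test on the differences, two-sided.

    Degenerate inputs follow fixed conventions: all-zero differences give
    t = 0, p = 1; zero-variance differences with nonzero mean give p = 0
    with the ``degenerate`` flag set.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("paired_t needs at least 2 pairs")
    d = a - b
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        if mean_d == 0:
            return PairedComparison(variable, a.mean(), a.std(ddof=1), b.mean(),
                                    b.std(ddof=1), 0.0, n - 1, 1.0)
        return PairedComparison(variable, a.mean(), a.std(ddof=1), b.mean(),
                                b.std(ddof=1), math.copysign(math.inf, mean_d),
                                n - 1, 0.0, degenerate=True)
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedComparison(
        variable, a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1), t, n - 1, float(p)
    )


def pearson_with_r2(
    values_a: Sequence[float], values_b: Sequence[float], variable: str = ""
) -> CorrelationResult:
    """Pearson correlation with two-sided p (t transform) and R^2."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("pearson_with_r2 needs two equal-length sequences, n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("pearson_with_r2: zero variance in an input vector")
    rho, p = stats.pearsonr(a, b)
    return CorrelationResult(variable, float(rho), float(p))


def bonferroni_pairwise(
    groups: Mapping[object, Sequence[float]]
) -> pd.DataFrame:
    """All pairwise Welch comparisons of means, Bonferroni-adjusted.

    Adjusted p = min(1, raw p * m) with m the number of pairs.  A pair in
    which either level has fewer than 2 observations is flagged
    (``computed`` False) and carries NaN statistics.
    """
    levels = list(groups)
    if len(levels) < 2:
        raise ValueError("bonferroni_pairwise needs >= 2 levels")
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for la, lb in pairs:
        a = np.asarray(groups[la], dtype=float)
        b = np.asarray(groups[lb], dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append((la, lb, np.nan, np.nan, np.nan, False))
            continue
        if np.array_equal(a, b) or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
            # identical/constant groups: no evidence of a difference
            p_raw = 1.0 if a.mean() == b.mean() else 0.0
            t = 0.0 if a.mean() == b.mean() else math.copysign(math.inf, a.mean() - b.mean())
        else:
            t, p_raw = stats.ttest_ind(a, b, equal_var=False)
        rows.append((la, lb, float(t), float(p_raw), min(1.0, float(p_raw) * m), True))
    return pd.DataFrame(
        rows, columns=["level_a", "level_b", "t_statistic", "p_raw", "p_adjusted", "computed"]
    )


# ---------------------------------------------------------------------------
# Time trend
# ---------------------------------------------------------------------------

def energy_trend(cohort: pd.DataFrame, method: str = "app") -> TrendResult:
    """Linear trend of energy over study days, with a weekend adjustment.

    Fits OLS of participant-day energy on the day index (unadjusted) and on
    day index + weekend indicator (adjusted).  A companion log-energy fit
    expresses the weekend effect as a multiplicative ratio with its 95% CI.
    """
    import statsmodels.api as sm

    rows = cohort[cohort["method"] == method]
    if rows["day"].nunique() < 2:
        raise ValueError("energy_trend needs >= 2 distinct days")
    y = rows["energy_kcal"].to_numpy(dtype=float)
    day = rows["day"].to_numpy(dtype=float)
    weekend = rows["weekend"].to_numpy(dtype=float)

    X0 = sm.add_constant(day)
    fit0 = sm.OLS(y, X0).fit()
    X1 = sm.add_constant(np.column_stack([day, weekend]))
    fit1 = sm.OLS(y, X1).fit()
    logfit = sm.OLS(np.log(y), X1).fit()
    ci0 = fit0.conf_int()[1]
    ci1 = fit1.conf_int()[1]
    ci_w = logfit.conf_int()[2]
    return TrendResult(
        slope=float(fit0.params[1]),
        p_unadjusted=float(fit0.pvalues[1]),
        slope_ci=(float(ci0[0]), float(ci0[1])),
        slope_adjusted=float(fit1.params[1]),
        p_adjusted=float(fit1.pvalues[1]),
        slope_adjusted_ci=(float(ci1[0]), float(ci1[1])),
        weekend_coef_kcal=float(fit1.params[2]),
        weekend_ratio=float(np.exp(logfit.params[2])),
        weekend_ratio_ci=(float(np.exp(ci_w[0])), float(np.exp(ci_w[1]))),
    )


# ---------------------------------------------------------------------------
# Table 1: paired method comparison on overlap-day averages
# ---------------------------------------------------------------------------

def two_day_averages(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-participant per-method averages over the overlap days.

    Overlap days are the days with recall rows for that participant; both
    methods are averaged over those same days.  Returns a tidy frame with
    one row per (participant, method).
    """
    overlap = cohort.loc[
        cohort["method"] == "recall", ["participant_id", "day"]
    ].drop_duplicates()
    if overlap.empty:
        raise ValueError("cohort has no recall rows; overlap days undefined")
    sub = cohort.merge(overlap, on=["participant_id", "day"])
    cols = [c for c in TABLE1_VARIABLES if c in sub.columns]
    return (
        sub.groupby(["participant_id", "method"], as_index=False)[cols]
        .mean()
        .sort_values(["participant_id", "method"], ignore_index=True)
    )


def build_table1(
    averages_app: pd.DataFrame,
    averages_recall: pd.DataFrame,
    variables: Sequence[str] = TABLE1_VARIABLES,
) -> pd.DataFrame:
    """Paired t + Pearson per variable on aligned per-participant averages.

    Inputs are per-participant average tables (indexed or keyed by
    ``participant_id``) for each method; participants are aligned by id.
    """
    a = averages_app.set_index("participant_id") if "participant_id" in averages_app else averages_app
    b = averages_recall.set_index("participant_id") if "participant_id" in averages_recall else averages_recall
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("need >= 2 participants present for both methods")
    a, b = a.loc[common], b.loc[common]
    rows = []
    for var in variables:
        pc = paired_t(a[var], b[var], variable=var)
        try:
            corr = pearson_with_r2(a[var], b[var], variable=var)
            rho, p_rho, r2 = corr.rho, corr.p_value, corr.r_squared
        except ValueError:
            rho = p_rho = r2 = np.nan
        rows.append(
            {
                "variable": var,
                "mean_app": pc.mean_a,
                "sd_app": pc.sd_a,
                "mean_recall": pc.mean_b,
                "sd_recall": pc.sd_b,
                "t_statistic": pc.t_statistic,
                "df": pc.df,
                "p_value": pc.p_value,
                "rho": rho,
                "p_rho": p_rho,
                "r_squared": r2,
                "n": len(common),
            }
        )
    return pd.DataFrame(rows)


def table1_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Overlap-day averages + paired comparison in one step (post-filter)."""
    avg = two_day_averages(cohort)
    return build_table1(
        avg[avg["method"] == "app"].drop(columns="method"),
        avg[avg["method"] == "recall"].drop(columns="method"),
    )


def figure1_table(cohort: pd.DataFrame, method: str = "app") -> pd.DataFrame:
    """Per-day mean +/- SD of energy (the figure-style trend summary)."""
    rows = cohort[cohort["method"] == method]
    g = rows.groupby("day")["energy_kcal"]
    return pd.DataFrame(
        {"day": g.mean().index, "mean_kcal": g.mean().values, "sd_kcal": g.std(ddof=1).values,
         "n": g.size().values}
    )


# ---------------------------------------------------------------------------
# Table 2: logging-mode summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeSummary:
    """Spoken-vs-written usage and default-acceptance rates."""

    per_mode: pd.DataFrame
    revision_rate_food: float
    revision_rate_unit_amount: float


def mode_summary(records: Iterable[LogRecord]) -> ModeSummary:
    """Summarize a diary by input mode.

    Per mode: mean foods per user-day, share of all logged foods, share
    with brand/preparation detail, share with an explicit quantity, and the
    default-acceptance rates for food code, measuring unit and amount
    (a default is "accepted" when the corresponding revision flag is
    false).  Overall revision rates cover food name/description/brand and
    unit amount.  An empty diary yields a zero-filled summary.
    """
    records = list(records)
    modes = ("spoken", "written")
    user_days = {(r.user_id, r.day) for r in records}
    n_days = max(len(user_days), 1)
    total = len(records)
    rows = []
    for mode in modes:
        sub = [r for r in records if r.input_mode == mode]
        n = len(sub)
        pct = lambda flag: 100.0 * sum(flag(r) for r in sub) / n if n else 0.0
        rows.append(
            {
                "input_mode": mode,
                "n_foods": n,
                "foods_per_person_day": n / n_days,
                "pct_of_all_foods": 100.0 * n / total if total else 0.0,
                "pct_with_brand_or_prep": pct(lambda r: r.had_brand_or_prep),
                "pct_with_quantity": pct(lambda r: r.had_quantity),
                "pct_default_food_accepted": pct(lambda r: not r.revised_food),
                "pct_default_unit_accepted": pct(lambda r: not r.revised_unit),
                "pct_default_amount_accepted": pct(lambda r: not r.revised_amount),
            }
        )
    rate = lambda flag: 100.0 * sum(flag(r) for r in records) / total if total else 0.0
    return ModeSummary(
        per_mode=pd.DataFrame(rows),
        revision_rate_food=rate(lambda r: r.revised_food),
        revision_rate_unit_amount=rate(lambda r: r.revised_unit_amount),
    )


def build_table2(records: Iterable[LogRecord]) -> pd.DataFrame:
    """The per-mode summary as a CSV-ready table."""
    return mode_summary(records).per_mode


# ---------------------------------------------------------------------------
# Simulation currencies: type-I error and power of the table-1 pipeline
# ---------------------------------------------------------------------------

def _pipeline_energy_p(cohort: pd.DataFrame) -> float:
    retained, _ = plausibility_filter(cohort)
    avg = two_day_averages(retained)
    a = avg[avg["method"] == "app"].set_index("participant_id")["energy_kcal"]
    b = avg[avg["method"] == "recall"].set_index("participant_id")["energy_kcal"]
    common = a.index.intersection(b.index)
    return paired_t(a.loc[common], b.loc[common]).p_value


def null_rejection_rate(
    n_replicates: int,
    seed: int,
    n_participants: int = 34,
    alpha: float = ALPHA,
    bias_app_kcal: float = 0.0,
    **spec_kwargs,
) -> float:
    """Rejection rate of the table-1 paired energy t test over replicates.

    Each replicate generates a cohort (no forced implausible reporter, zero
    between-method bias unless ``bias_app_kcal`` is given), runs the
    plausibility filter and the 2-day-average paired t test on energy, and
    records whether p < alpha.  With zero bias this estimates the type-I
    error; with bias it estimates power.
    """
    from .synthetic_data import CohortSpec, generate_cohort

    rng = np.random.default_rng(seed)
    rejections = 0
    for rep_seed in rng.integers(0, 2**31 - 1, size=n_replicates):
        spec = CohortSpec(
            n_participants=n_participants,
            n_implausible=0,
            bias_app_kcal=bias_app_kcal,
            seed=int(rep_seed),
            **spec_kwargs,
        )
        if _pipeline_energy_p(generate_cohort(spec)) < alpha:
            rejections += 1
    return rejections / n_replicates


def power_curve(
    biases_kcal: Sequence[float],
    n_replicates: int,
    seed: int,
    n_participants: int = 34,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Rejection rate as a function of injected between-method bias."""
    rows = [
        {
            "bias_kcal": delta,
            "rejection_rate": null_rejection_rate(
                n_replicates, seed, n_participants, alpha, bias_app_kcal=delta
            ),
        }
        for delta in biases_kcal
    ]
    return pd.DataFrame(rows)
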