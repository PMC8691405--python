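"""Synthetic inputs for the whole pipeline.

Everything the system consumes can be generated here, reproducibly from a
seed: multi-source food-composition databases, grammar-based annotated
meal descriptions (with ground-truth BIO labels), user diaries driven
through the real tag→rank→confirm pipeline, and paired per-participant
daily-intake cohorts for the method-comparison statistics.

The cohort error model is stated explicitly so downstream statistics are
interpretable: participant habitual energy is lognormal (mean 2000 kcal,
CV 0.25 by default), day-to-day intake varies multiplicatively around it,
and each assessment method observes a day's true intake through
multiplicative lognormal error (mean 1) that may be correlated between
methods, plus an optional additive bias per method.  Macronutrient energy
shares are Dirichlet around a configurable mean split.  One participant
(by default) is forced to an implausibly high 2-day average (>= 5000 kcal)
to exercise the a-priori plausibility filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .food_db import FoodEntry, NutrientVector
from .meal_nlu import (
    DESC_WORDS,
    FoodLexicon,
    TaggedMeal,
    group_items,
    tokenize,
)

__all__ = [
    "AnnotatedMeal",
    "CohortSpec",
    "COHORT_COLUMNS",
    "generate_food_db",
    "generate_annotated_meals",
    "generate_cohort",
    "generate_diary",
]

COHORT_COLUMNS = (
    "participant_id",
    "day",
    "weekend",
    "method",
    "energy_kcal",
    "pct_protein",
    "pct_fat",
    "pct_carbohydrate",
    "pct_alcohol",
    "n_events",
)

# ---------------------------------------------------------------------------
# Food database generator
# ---------------------------------------------------------------------------

_BASE_FOODS = """bread milk cheese chicken rice pasta salad soup chili yogurt
oatmeal coffee tea juice apple banana eggs bacon salmon beef tofu beans
lentils granola pancakes waffles burrito pizza sandwich smoothie cereal
muffin bagel cookie steak shrimp soda wine beer butter noodles quinoa
turkey hummus crackers almonds potatoes broccoli carrots spinach""".split()

_MODIFIERS = [
    "cheddar", "swiss", "whole wheat", "wheat", "skim", "greek", "vanilla",
    "chocolate", "strawberry", "brown", "white", "green", "spicy", "garlic",
    "honey", "lemon", "peanut", "blueberry", "cinnamon", "maple",
    "sourdough", "veggie", "tomato", "mushroom", "onion", "herb", "sesame",
    "coconut", "mixed", "berry",
]

_BRANDS = [
    "acme", "goldcrest", "sunnyvale", "bluebird", "harvest hill",
    "mornington", "silver oak", "redbarn",
]

_ALCOHOLIC = {"wine", "beer"}

_UNIT_GRAMS = {
    "cup": 240.0, "bowl": 350.0, "glass": 250.0, "slice": 30.0,
    "piece": 50.0, "tablespoon": 15.0, "serving": 150.0, "can": 355.0,
    "bottle": 500.0, "scoop": 35.0, "plate": 300.0, "handful": 30.0,
}

SOURCES = ("reference", "branded")


def _nutrients_for(base: str, rng: np.random.Generator) -> NutrientVector:
    energy = float(rng.uniform(30, 400))
    if base in _ALCOHOLIC:
        alcohol_frac = float(rng.uniform(0.5, 0.9))
        alcohol_g = energy * alcohol_frac / 7.0
        rest = energy * (1 - alcohol_frac)
        shares = rng.dirichlet((1.0, 1.0, 4.0))
        return NutrientVector(
            energy_kcal=energy,
            protein_g=rest * shares[0] / 4.0,
            fat_g=rest * shares[1] / 9.0,
            carbohydrate_g=rest * shares[2] / 4.0,
            alcohol_g=alcohol_g,
        )
    shares = rng.dirichlet((2.0, 3.0, 4.0))
    return NutrientVector(
        energy_kcal=energy,
        protein_g=energy * shares[0] / 4.0,
        fat_g=energy * shares[1] / 9.0,
        carbohydrate_g=energy * shares[2] / 4.0,
    )


def generate_food_db(n_entries: int, seed: int) -> list[FoodEntry]:
    """A deterministic multi-source food database.

    Descriptions compose a modifier and a base food from bundled lexicons.
    Entries split across a reference-style and a branded source (for
    ``n_entries >= 2``); at least one description is shared verbatim by
    both sources when ``n_entries >= 20``, exercising the cross-source
    duplicate behaviour.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    rng = np.random.default_rng(seed)
    pool = [f"{m} {b}" for m in _MODIFIERS for b in _BASE_FOODS]
    pool = list(rng.permutation(pool))
    bases = list(rng.permutation(_BASE_FOODS))
    descriptions = (bases[:10] + pool)[:n_entries]

    n_branded = 0 if n_entries < 2 else max(1, int(round(n_entries * 0.4)))
    entries: list[FoodEntry] = []
    for i, desc in enumerate(descriptions):
        branded = i >= n_entries - n_branded
        source = SOURCES[1] if branded else SOURCES[0]
        if branded and n_entries >= 20 and i == n_entries - 1:
            desc = descriptions[0]  # cross-source duplicate guarantee
        base = desc.split()[-1]
        n_units = int(rng.integers(1, 4))
        units = list(rng.choice(list(_UNIT_GRAMS), size=n_units, replace=False))
        brand = None
        if branded and rng.random() < 0.8:
            brand = str(rng.choice(_BRANDS))
        entries.append(
            FoodEntry(
                code=f"{source[:3].upper()}{i + 1:05d}",
                source=source,
                description=desc,
                brand=brand,
                nutrients_per_100g=_nutrients_for(base, rng),
                portions=tuple((u, _UNIT_GRAMS[u]) for u in units),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Annotated meal-description grammar
# ---------------------------------------------------------------------------

_PREAMBLES = [
    ["for", "breakfast", ",", "i", "had"],
    ["for", "lunch", ",", "i", "had"],
    ["for", "dinner", ",", "i", "had"],
    ["i", "had"],
    ["i", "ate"],
]

_QTY_CHOICES = ["a", "2", "3", "one", "two", "half"]
_PREP_WORDS = sorted(DESC_WORDS)


@dataclass
class AnnotatedMeal:
    """A grammar-generated meal with ground-truth labels and entry keys."""

    meal: TaggedMeal
    entry_keys: list[tuple[str, str]]

    @property
    def tokens(self) -> list[str]:
        return self.meal.tokens

    @property
    def labels(self) -> list[str]:
        return self.meal.labels


def generate_annotated_meals(
    db: Sequence[FoodEntry],
    n_meals: int,
    seed: int,
    modifier_prob: float = 0.15,
) -> list[AnnotatedMeal]:
    """Sample annotated meal descriptions from a context-free grammar.

    Pattern: optional meal-time preamble, then one to three food items
    joined by "with"/"and"; each item optionally carries "QTY UNIT of" and,
    with probability ``modifier_prob``, a brand or preparation-method
    modifier before the food phrase.  Food phrases are verbatim database
    descriptions, so a lexicon built from ``db`` covers every food span.
    """
    if not db:
        raise ValueError("db must be non-empty")
    rng = np.random.default_rng(seed)
    meals: list[AnnotatedMeal] = []
    for _ in range(n_meals):
        tokens: list[str] = []
        labels: list[str] = []
        keys: list[tuple[str, str]] = []
        pre = _PREAMBLES[rng.integers(len(_PREAMBLES))]
        tokens += pre
        labels += ["O"] * len(pre)
        n_items = int(rng.choice([1, 2, 3], p=[0.55, 0.35, 0.10]))
        for j in range(n_items):
            if j > 0:
                tokens.append("with" if rng.random() < 0.6 else "and")
                labels.append("O")
            entry = db[int(rng.integers(len(db)))]
            food_tokens = tokenize(entry.description_norm)
            household = [u for u in entry.unit_names if u != "gram"]
            if household and rng.random() < 0.5:
                qty = _QTY_CHOICES[rng.integers(len(_QTY_CHOICES))]
                unit = household[int(rng.integers(len(household)))]
                tokens += [qty, unit, "of"]
                labels += ["B-QTY", "B-UNIT", "O"]
            if rng.random() < modifier_prob:
                if entry.brand and rng.random() < 0.5:
                    brand_tokens = tokenize(entry.brand)
                    tokens += brand_tokens
                    labels += ["B-BRAND"] + ["I-BRAND"] * (len(brand_tokens) - 1)
                else:
                    tokens.append(_PREP_WORDS[rng.integers(len(_PREP_WORDS))])
                    labels.append("B-DESC")
            tokens += food_tokens
            labels += ["B-FOOD"] + ["I-FOOD"] * (len(food_tokens) - 1)
            keys.append(entry.key)
        meal = TaggedMeal(
            raw_text=" ".join(tokens),
            tokens=tokens,
            labels=labels,
            items=group_items(tokens, labels),
        )
        meals.append(AnnotatedMeal(meal=meal, entry_keys=keys))
    return meals


# ---------------------------------------------------------------------------
# Paired-cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-design and error-model parameters for a paired cohort.

    The app method logs all ``days``; the comparator (recall) method covers
    only ``overlap_days``.  Observed energy for method m on day d is

        (habitual_i + trend*(d-1)) * weekend^w * day_noise * method_noise_m
        + bias_m

    with lognormal mean-1 day and method noise; method noise is correlated
    ``method_rho`` between the two methods within a day and independent
    across days.  ``n_implausible`` participants are forced to a 2-day
    average app energy of at least ``implausible_kcal``; all others are
    guaranteed below it (resampled if a random draw lands above).
    """

    n_participants: int = 35
    days: int = 5
    overlap_days: tuple[int, int] = (2, 3)
    energy_mean_kcal: float = 2000.0
    energy_cv: float = 0.25
    macro_mean: tuple[float, float, float, float] = (0.17, 0.36, 0.47, 0.00)
    macro_conc_between: float = 60.0
    macro_conc_within: float = 150.0
    day_cv: float = 0.15
    method_cv: float = 0.30
    method_rho: float = 0.5
    bias_app_kcal: float = 0.0
    bias_recall_kcal: float = 0.0
    weekend_effect: float = 1.0
    trend_kcal_per_day: float = 0.0
    events_mean: float = 4.0
    events_sd: float = 1.0
    n_implausible: int = 1
    implausible_kcal: float = 5000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not all(1 <= d <= self.days for d in self.overlap_days):
            raise ValueError(f"overlap_days {self.overlap_days} outside 1..{self.days}")
        for name in ("energy_cv", "day_cv", "method_cv", "events_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.method_rho <= 1.0:
            raise ValueError("method_rho must be in [-1, 1]")
        if any(m < 0 for m in self.macro_mean):
            raise ValueError("macro_mean components must be >= 0")
        if not math.isclose(sum(self.macro_mean), 1.0, abs_tol=1e-9):
            raise ValueError(f"macro_mean must sum to 1, got {sum(self.macro_mean)}")
        if self.weekend_effect <= 0:
            raise ValueError("weekend_effect must be > 0")
        if not 0 <= self.n_implausible <= self.n_participants:
            raise ValueError("n_implausible must be in [0, n_participants]")


def _lognormal_sigma_mu(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    return math.sqrt(sigma2), math.log(mean) - sigma2 / 2.0


def _mean_one_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size=size))


def _dirichlet_shares(
    rng: np.random.Generator, mean: np.ndarray, conc: float, size: tuple
) -> np.ndarray:
    """Dirichlet draws with arbitrary leading shape; zero-mean components stay 0."""
    alpha = mean * conc
    out = np.zeros(size + (len(mean),))
    pos = alpha > 0
    g = rng.gamma(np.broadcast_to(alpha[pos], size + (int(pos.sum()),)))
    out[..., pos] = g / g.sum(axis=-1, keepdims=True)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a paired per-participant per-day cohort table.

    Returns a DataFrame with :data:`COHORT_COLUMNS`; app rows cover every
    day, recall rows only the overlap days.  Pure function of the spec
    (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, D = spec.n_participants, spec.days
    overlap_idx = np.array([d - 1 for d in spec.overlap_days])
    sigma_e, mu_e = _lognormal_sigma_mu(spec.energy_mean_kcal, spec.energy_cv)

    def draw_energy_block(rows: int):
        """(habitual, day_noise, z_app, z_recall) for `rows` participants."""
        habitual = np.exp(rng.normal(mu_e, sigma_e, size=rows))
        day_noise = _mean_one_noise(rng, spec.day_cv, (rows, D))
        sigma2_m = math.log1p(spec.method_cv**2)
        sd = math.sqrt(sigma2_m)
        z1 = rng.normal(size=(rows, D))
        z2 = spec.method_rho * z1 + math.sqrt(1 - spec.method_rho**2) * rng.normal(
            size=(rows, D)
        )
        app_noise = np.exp(-sigma2_m / 2 + sd * z1)
        recall_noise = np.exp(-sigma2_m / 2 + sd * z2)
        return habitual, day_noise, app_noise, recall_noise

    habitual, day_noise, app_noise, recall_noise = draw_energy_block(n)
    start_dow = rng.integers(0, 7, size=n)
    day_idx = np.arange(D)
    dow = (start_dow[:, None] + day_idx[None, :]) % 7
    weekend = dow >= 5

    def observed(habitual_vec: np.ndarray, dn, an, rn, wk):
        base = habitual_vec[:, None] + spec.trend_kcal_per_day * day_idx[None, :]
        base = np.maximum(base, 1.0)
        true = base * np.where(wk, spec.weekend_effect, 1.0) * dn
        app = true * an + spec.bias_app_kcal
        recall = true * rn + spec.bias_recall_kcal
        return np.maximum(app, 1.0), np.maximum(recall, 1.0)

    app_energy, recall_energy = observed(habitual, day_noise, app_noise, recall_noise, weekend)

    # Enforce exactly n_implausible participants at/above the threshold on
    # the app 2-day average: resample natural offenders, rescale forced ones.
    forced = set(range(spec.n_implausible))
    for i in range(n):
        if i in forced:
            continue
        for _ in range(200):
            if app_energy[i, overlap_idx].mean() < spec.implausible_kcal:
                break
            h, dn, an, rn = draw_energy_block(1)
            habitual[i] = h[0]
            day_noise[i], app_noise[i], recall_noise[i] = dn[0], an[0], rn[0]
            a, r = observed(h, dn, an, rn, weekend[i : i + 1])
            app_energy[i], recall_energy[i] = a[0], r[0]
    for i in sorted(forced):
        avg = app_energy[i, overlap_idx].mean()
        if avg < spec.implausible_kcal:
            scale = 1.08 * spec.implausible_kcal / avg
            habitual[i] *= scale
            a, r = observed(
                habitual[i : i + 1],
                day_noise[i : i + 1],
                app_noise[i : i + 1],
                recall_noise[i : i + 1],
                weekend[i : i + 1],
            )
            app_energy[i], recall_energy[i] = a[0], r[0]

    # Macronutrient energy shares: participant-level mean, then per
    # (day, method) variation around it.
    macro_mean = np.asarray(spec.macro_mean, dtype=float)
    p_base = _dirichlet_shares(rng, macro_mean, spec.macro_conc_between, (n,))
    shares = np.zeros((n, D, 2, 4))
    for i in range(n):
        shares[i] = _dirichlet_shares(
            rng, p_base[i], spec.macro_conc_within, (D, 2)
        ) if p_base[i].sum() > 0 else 0.0

    lam = np.clip(rng.normal(spec.events_mean, spec.events_sd, size=n), 1.0, None)
    events = np.maximum(rng.poisson(lam[:, None, None], size=(n, D, 2)), 1)

    pids = np.array([f"P{i + 1:03d}" for i in range(n)])
    frames = []
    for m_idx, (method, energy) in enumerate(
        (("app", app_energy), ("recall", recall_energy))
    ):
        days_used = day_idx if method == "app" else overlap_idx
        ii, dd = np.meshgrid(np.arange(n), days_used, indexing="ij")
        ii, dd = ii.ravel(), dd.ravel()
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pids[ii],
                    "day": dd + 1,
                    "weekend": weekend[ii, dd],
                    "method": method,
                    "energy_kcal": energy[ii, dd],
                    "pct_protein": 100 * shares[ii, dd, m_idx, 0],
                    "pct_fat": 100 * shares[ii, dd, m_idx, 1],
                    "pct_carbohydrate": 100 * shares[ii, dd, m_idx, 2],
                    "pct_alcohol": 100 * shares[ii, dd, m_idx, 3],
                    "n_events": events[ii, dd, m_idx],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "method", "day"], ignore_index=True)


# ---------------------------------------------------------------------------
# Synthetic diaries through the real pipeline
# ---------------------------------------------------------------------------

def generate_diary(
    db: Sequence[FoodEntry],
    n_users: int = 5,
    days: int = 5,
    seed: int = 0,
    meals_per_day: tuple[int, int] = (3, 6),
    p_spoken: float = 0.284,
    p_revise_food: float = 0.081,
    p_revise_unit: float = 0.10,
    p_revise_amount: float = 0.20,
    modifier_prob: float = 0.15,
    start_date: str = "2021-03-01",
):
    """Simulate users logging grammar-generated meals through the pipeline.

    Each utterance is tagged (rules backend), candidates and units are
    ranked against the live diary history, and the proposal is confirmed or
    revised with the given probabilities.  Default usage rates emulate the
    observed mix of spoken entries and revision frequencies in app-based
    logging.  Returns a :class:`~mealdiary.diary_store.DiaryStore`.
    """
    import datetime as dt

    from .diary_store import DiaryStore, confirm_or_revise
    from .food_matcher import fit_vectorizer, rank_candidates
    from .unit_resolver import rank_units

    if not db:
        raise ValueError("db must be non-empty")
    rng = np.random.default_rng(seed)
    lexicon = FoodLexicon.from_entries(db)
    vectorizer = fit_vectorizer(db)
    entry_matrix = vectorizer.transform_entries(db)
    store = DiaryStore()
    day0 = dt.date.fromisoformat(start_date)
    meal_seed = int(rng.integers(2**31 - 1))
    meal_iter = iter(
        generate_annotated_meals(
            db, n_meals=n_users * days * meals_per_day[1], seed=meal_seed,
            modifier_prob=modifier_prob,
        )
    )
    for u in range(n_users):
        user_id = f"U{u + 1:03d}"
        for d in range(days):
            day = day0 + dt.timedelta(days=d)
            n_meals = int(rng.integers(meals_per_day[0], meals_per_day[1] + 1))
            for k in range(n_meals):
                annotated = next(meal_iter)
                mode = "spoken" if rng.random() < p_spoken else "written"
                history = store.user_history(user_id)
                for item in annotated.meal.items:
                    ranking = rank_candidates(
                        item, vectorizer, db, history=history,
                        entry_matrix=entry_matrix,
                    )
                    unit_ranking = rank_units(
                        ranking.top,
                        unit_text=item.unit_text,
                        user_history=history,
                        global_history=store.all_history(),
                        quantity_text=item.quantity_text,
                    )
                    cand_idx = (
                        int(rng.integers(1, min(4, len(ranking.candidates))))
                        if len(ranking.candidates) > 1 and rng.random() < p_revise_food
                        else 0
                    )
                    entry = ranking.candidates[cand_idx][0]
                    unit_rk = unit_ranking
                    if entry is not ranking.top:
                        unit_rk = rank_units(
                            entry, unit_text=item.unit_text,
                            user_history=history,
                            global_history=store.all_history(),
                            quantity_text=item.quantity_text,
                        )
                    unit_idx = (
                        1 if len(unit_rk.units) > 1 and rng.random() < p_revise_unit else 0
                    )
                    amount = (
                        unit_rk.amount + 1.0
                        if rng.random() < p_revise_amount
                        else None
                    )
                    rec = confirm_or_revise(
                        ranking,
                        unit_rk,
                        user_choice=(cand_idx, unit_idx, amount),
                        user_id=user_id,
                        day=day,
                        meal_label=f"meal{k + 1}",
                        input_mode=mode,
                    )
                    if rec is not None:
                        store.append(rec)
    return store
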