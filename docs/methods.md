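# Methods

This note documents the models, parameters and design choices behind
`mealdiary`, and what the synthetic-data experiments do and do not show.

## Meal tagging

Meal descriptions are tokenized on whitespace/punctuation (decimals and
simple fractions kept whole) and labeled with BIO tags over five span
classes: FOOD, QTY, UNIT, BRAND, DESC. Grouping attaches each
QTY/UNIT/BRAND/DESC span to the nearest *following* food span, falling
back to the nearest preceding one — English meal descriptions are
overwhelmingly "QTY UNIT of FOOD" ("a bowl of chili"), which this rule
captures; the "of" between unit and food is left outside every span.
Meal-time phrases ("for dinner") are labeled O.

Two backends share the contract:

* **Rules.** Longest-match against a food-phrase lexicon built from the
  loaded database (USDA-style inverted descriptions such as
  "Cheese, cheddar" also contribute their natural reading "cheddar
  cheese"), then brand phrases, then closed classes for quantities
  (digits, fractions, "a"/"an", spelled numbers one–twenty, "half"),
  measuring units (singular/plural-folded household units) and
  preparation words. Deterministic by construction.
* **Learned.** Per-token multinomial logistic regression
  (scikit-learn) over lexical identity, neighbors, suffix, shape flags
  and lexicon-membership features (including whether a lexicon phrase
  starts at or covers the position), with predictions coerced to BIO
  well-formedness (dangling I-X becomes B-X). A linear per-token model
  with phrase-positional lexicon features is enough for this task's
  local structure; training is deterministic given the seed. It is a
  stand-in with the identical interface for heavier sequence models, so
  downstream modules are backend-agnostic.

Unparseable quantity text defaults to amount 1 with an `assumed` flag:
the confirm-by-default workflow must always propose some amount.

## Candidate retrieval

Entries and queries are embedded as sparse term-weighted vectors:
sublinear TF-IDF over word 1–2-grams plus character 3–5-grams (character
block down-weighted ×0.5), concatenated and L2-normalized; the ranking
operator is the dot product. Character n-grams buy tolerance to
misspellings and inflection without a fuzzy-matching dependency. The
top-K list (K = 15 by default — one screenful of options — configurable)
is the first K of the full score ordering; ties break by source priority
then lexicographic food code so rankings are reproducible. Duplicate
foods across source databases are scored independently and may both
appear.

Personalization uses the case-folded, whitespace-normalized food item
text as the key: when the user's history contains a confirmed food code
for exactly that text, the code is hard-promoted to rank 1 (the most
conservative reading of "ranked higher or at the top") and the ranking
is flagged `personalized`. Promotion only reorders; nothing is dropped
except by truncation at K.

## Unit and amount resolution

Four tiers, in order: exact string match of the uttered unit against the
entry's portion units (singular/plural folding counts as exact — spoken
quantities are routinely plural); the unit this user confirmed most
often for this food code; the unit all users confirmed most often for
this food code (read as per-food-code popularity, not global across
foods); the entry's first-listed unit. Frequency ties break toward the
most recent confirmation. The fourth tier covers the cold-start state
with zero history, which a self-contained system must handle. The output
is always a permutation of the entry's units.

## Diary and daily intake

Confirmed records carry the revision flags used by the logging-mode
summary: `revised_food` (a non-top candidate was picked),
`revised_unit`, `revised_amount` (reported jointly as
`revised_unit_amount`), plus `had_brand_or_prep` and `had_quantity`
observed from the tagged item. Storage is an append-only JSON-lines
event log, replayable to rebuild all state.

Daily energy is the sum over records; percent energy from protein, fat,
carbohydrate and alcohol uses the general Atwater factors (4, 9, 4,
7 kcal/g). A zero-energy day reports zero percentages. An eating event
is one logging utterance: records sharing a meal label count once,
unlabeled records count individually.

## Method-comparison statistics

All tests run on biologically plausible participants only: the a-priori
filter drops anyone whose 2-day average energy (app method, on the days
the recall method also covers) is ≥ 5000 kcal; the threshold and method
are configurable. Per participant and method, the overlap days are
averaged; energy, the three macronutrient percentages and the number of
eating events are compared across methods with classic paired *t* tests
and Pearson correlations (R² = ρ²). Degenerate inputs follow fixed
conventions: all-zero differences give t = 0, p = 1; zero-variance
differences with nonzero mean give p = 0 with a flag.

Time trends fit OLS of participant-day energy on the day index, with and
without a weekend indicator; a companion log-energy fit expresses the
weekend effect as a multiplicative ratio with its 95% CI. Pairwise
comparisons across levels (day of week, recall sequence) use Welch
two-sample *t* tests with Bonferroni adjustment p_adj = min(1, p·m) over
the m pairs; a level with fewer than two observations flags its pairs as
not computed. α = .05 throughout, exposed in the call signatures.

## Synthetic cohort generator

The generator emulates a 35-participant, 5-day paired design in which
the comparator covers days 2–3. Observed energy for method m on day d is

    (E_i + τ·(d−1)) · w^{weekend} · u_{id} · v_{idm} + δ_m

with participant habitual energy E_i lognormal (mean 2000 kcal,
CV 0.25), day-level lognormal noise u (mean 1, CV 0.15) shared by both
methods, method-level lognormal noise v (mean 1, CV 0.30) correlated
ρ = 0.5 between methods within a day and independent across days,
optional linear drift τ, multiplicative weekend effect w (each
participant starts on a uniformly random weekday), and additive bias δ_m
per method. Macronutrient energy shares are Dirichlet: a participant
mean around (0.17, 0.36, 0.47, 0.00) for protein/fat/carbohydrate/
alcohol (concentration 60), then per day-and-method draws around it
(concentration 150); a zero-mean component stays exactly zero. Eating
events are Poisson around a participant rate drawn near 4/day. The
macro means and event rate were set near values typical of app-based
intake reports so synthetic report tables look realistic; all are
configurable.

Exactly `n_implausible` participants (default 1) end with a 2-day
average app energy ≥ 5000 kcal: forced participants are rescaled up,
and any other participant landing above the threshold by chance is
resampled. This makes "35 enrolled → 34 analyzed" a construction
guarantee; the tail truncation it imposes on the remaining participants
affects ~0.2% of draws and is negligible for the calibration results.

This error model is a stated invention: it captures paired multiplicative
measurement error with shared day-level variation, but not item-level
phenomena (composite-food decomposition differences between methods,
forgotten foods, database coverage gaps) or behavioural reactivity to
logging. Null-calibration and power results under this model therefore
validate the statistical pipeline, not the field accuracy of any app.

Under the null (δ = 0) the two methods' errors are exchangeable, so the
paired differences are symmetric and the paired *t* test holds its
nominal level despite the skewed lognormal errors — the 5,000-replicate
simulation (`scripts/acceptance.py`, about a minute on one CPU) checks
exactly this, and power against injected bias δ ∈ {0, 100, 200, 400}
kcal rises monotonically (~0.05, ~0.26, ~0.7, ~1.0 at n = 34).

## Annotated-meal grammar

Meals are sampled from a small context-free grammar: optional meal-time
preamble, one to three items joined by "with"/"and", each item
optionally "QTY UNIT of" and, with probability 0.15 (matching the ~15%
brand/preparation mention rate typical of such logs), a brand or
preparation modifier before the food phrase. Food phrases are verbatim
database descriptions, so a lexicon built from the same database covers
every food span by construction; the rules backend's ≥ 95% item
recovery on this corpus is a consistency check of tagger and grammar,
not an estimate of accuracy on real speech. The generator's word lists
deliberately avoid collisions between food-description words and the
closed quantity/unit/preparation classes.

## Problem sizes

Defaults used by the test suite and the acceptance script: 5,000
replicate cohorts of n = 34 for null calibration; 150 replicates per
bias level for the power curve; a 2,000/500 train/held-out split for the
learned tagger; n = 200 cohorts for trend and weekend-effect recovery
(95% CIs). These sizes give Monte-Carlo standard errors comfortably
inside the assertion tolerances (e.g. ±0.003 on the null rejection
proportion).

## Known limitations

* English only; tokenizer and grammar assume Latin-script text.
* The matcher has no semantic generalization: a food described with
  words absent from the database text can rank poorly; character n-grams
  mitigate misspellings only.
* Personalization requires an exact normalized-text repeat of the item
  description.
* Unit resolution never converts between volume and mass beyond the
  entry's own portion list.
* Item-level cross-method matching (which foods one method captured and
  the other missed) is out of scope; the statistics operate on daily
  aggregates.
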