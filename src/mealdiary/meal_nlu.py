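"""Meal-description understanding: tokenize, BIO-tag, group into food items.

A meal description ("For dinner, I had a bowl of chili with cheddar cheese")
is tokenized and every token is labeled with a BIO tag over five span
classes — FOOD, QTY (quantity), UNIT (measuring unit), BRAND and DESC
(preparation/descriptor) — plus O.  Contiguous spans are then grouped into
:class:`FoodItem` structures: each quantity/unit/brand/descriptor span
attaches to the nearest following food span (nearest preceding if none
follows), matching the dominant English "QTY UNIT of FOOD" pattern.

Two interchangeable tagging backends honor the same contract:

* a deterministic longest-match lexicon tagger (:class:`RuleTagger`), whose
  food lexicon is derived from the loaded food database, with closed-class
  grammars for quantities, units and preparation words; and
* a trainable discriminative sequence labeler (:class:`LearnedTagger`,
  :func:`train_labeler`) — per-token multinomial logistic regression over
  lexical, shape, context and lexicon-membership features, with BIO repair.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .food_db import FoodEntry, normalize_text

__all__ = [
    "LABELS",
    "SPAN_CLASSES",
    "FoodItem",
    "TaggedMeal",
    "FoodLexicon",
    "RuleTagger",
    "LearnedTagger",
    "tokenize",
    "tag_meal",
    "train_labeler",
    "parse_amount",
    "parse_amount_detail",
    "group_items",
    "repair_bio",
    "token_f1",
    "read_corpus",
    "write_corpus",
    "UNIT_WORDS",
    "QTY_WORDS",
    "DESC_WORDS",
    "MEAL_WORDS",
]

SPAN_CLASSES = ("FOOD", "QTY", "UNIT", "BRAND", "DESC")
LABELS = tuple(f"{p}-{c}" for c in SPAN_CLASSES for p in ("B", "I")) + ("O",)

_TOKEN_RE = re.compile(r"\d+\.\d+|\w+(?:/\w+)?|[^\w\s]", re.UNICODE)

#: Closed class of household measuring units (singular forms).
UNIT_WORDS = frozenset(
    """gram grams g cup bowl glass slice piece tablespoon tbsp teaspoon tsp
    ounce oz serving can bottle bar scoop plate handful stick packet pint
    liter ml""".split()
)

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11, "twelve": 12,
    "thirteen": 13, "fourteen": 14, "fifteen": 15, "sixteen": 16,
    "seventeen": 17, "eighteen": 18, "nineteen": 19, "twenty": 20,
}

#: Words that open or continue a quantity span.
QTY_WORDS = frozenset({"a", "an", "half", "couple", "few", "some"} | set(_NUMBER_WORDS))

#: Preparation-method / descriptor closed class.
DESC_WORDS = frozenset(
    """toasted grilled fried baked roasted steamed scrambled boiled poached
    raw fresh melted smoked homemade leftover crispy warm cold iced
    unsweetened sweetened plain light diet""".split()
)

#: Meal-time words kept outside food spans ("for dinner", "at breakfast").
MEAL_WORDS = frozenset("breakfast lunch dinner brunch snack supper".split())

_FRACTION_RE = re.compile(r"^(\d+)/(\d+)$")
_NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?$")


def tokenize(raw_text: str) -> list[str]:
    """Whitespace/punctuation tokenization; deterministic; empty-safe.

    Simple fractions ("1/2") stay single tokens so quantities survive.
    """
    return _TOKEN_RE.findall(raw_text)


# ---------------------------------------------------------------------------
# Quantity parsing
# ---------------------------------------------------------------------------

def parse_amount_detail(quantity_text: str | None) -> tuple[float, bool]:
    """Parse a quantity span into a number; returns ``(value, assumed)``.

    ``assumed`` is True when the text could not be parsed and the default
    amount of 1 was substituted (the confirm-by-default workflow always
    needs some proposed amount).  Total: never raises.
    """
    if quantity_text is None:
        return 1.0, True
    tokens = [t.casefold() for t in tokenize(quantity_text)]
    if not tokens:
        return 1.0, True
    # "a half" / "half a" -> 0.5
    if tokens in (["a", "half"], ["half", "a"], ["half"]):
        return 0.5, False
    if len(tokens) == 1:
        tok = tokens[0]
        if tok in ("a", "an"):
            return 1.0, False
        if tok in _NUMBER_WORDS:
            return float(_NUMBER_WORDS[tok]), False
        if _NUMBER_RE.match(tok):
            return float(tok), False
        m = _FRACTION_RE.match(tok)
        if m and int(m.group(2)) != 0:
            return int(m.group(1)) / int(m.group(2)), False
    # "two and a half", "1 1/2"
    if len(tokens) >= 2:
        head, _ = parse_amount_detail(tokens[0])
        tail = tokens[1:]
        if tail == ["and", "a", "half"] or tail == ["and", "half"]:
            return head + 0.5, False
        if len(tail) == 1 and _FRACTION_RE.match(tail[0]):
            frac, assumed = parse_amount_detail(tail[0])
            if not assumed and _NUMBER_RE.match(tokens[0]):
                return head + frac, False
    return 1.0, True


def parse_amount(quantity_text: str | None) -> float:
    """Numeric amount for a quantity span; 1 when unparseable."""
    return parse_amount_detail(quantity_text)[0]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FoodItem:
    """One food mention with its attached quantity/unit/brand/descriptors."""

    food_text: str
    quantity_text: str | None = None
    unit_text: str | None = None
    brand_text: str | None = None
    descriptors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.food_text:
            raise ValueError("FoodItem.food_text must be non-empty")

    @property
    def amount(self) -> float:
        return parse_amount(self.quantity_text)

    @property
    def query_text(self) -> str:
        """Text used to query the food database (food + brand + descriptors)."""
        parts = [self.food_text]
        if self.brand_text:
            parts.append(self.brand_text)
        parts.extend(self.descriptors)
        return " ".join(parts)


@dataclass
class TaggedMeal:
    """Tokenized meal description with aligned BIO labels and grouped items."""

    raw_text: str
    tokens: list[str]
    labels: list[str]
    items: list[FoodItem]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.tokens)} tokens"
            )
        check_bio(self.labels)


def check_bio(labels: Sequence[str]) -> None:
    """Raise ValueError unless the label sequence is BIO well-formed."""
    prev = "O"
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
        if lab.startswith("I-"):
            cls = lab[2:]
            if prev not in (f"B-{cls}", f"I-{cls}"):
                raise ValueError(f"dangling {lab} after {prev}")
        prev = lab


def repair_bio(labels: Sequence[str]) -> list[str]:
    """Coerce an arbitrary label sequence into BIO well-formedness.

    An I- tag without a compatible left neighbour becomes the B- tag of the
    same class; unknown labels become O.
    """
    out: list[str] = []
    prev = "O"
    for lab in labels:
        if lab not in LABELS:
            lab = "O"
        if lab.startswith("I-"):
            cls = lab[2:]
            if prev not in (f"B-{cls}", f"I-{cls}"):
                lab = f"B-{cls}"
        out.append(lab)
        prev = lab
    return out


def _spans(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    """(class, start, end-exclusive) for each maximal span."""
    spans = []
    i = 0
    while i < len(labels):
        lab = labels[i]
        if lab == "O":
            i += 1
            continue
        cls = lab[2:]
        j = i + 1
        while j < len(labels) and labels[j] == f"I-{cls}":
            j += 1
        spans.append((cls, i, j))
        i = j
    return spans


def group_items(tokens: Sequence[str], labels: Sequence[str]) -> list[FoodItem]:
    """Group BIO spans into FoodItems.

    Each QTY/UNIT/BRAND/DESC span attaches to the nearest following FOOD
    span, or the nearest preceding one when no food span follows.  The
    first quantity/unit/brand attached to an item wins; descriptors
    accumulate.
    """
    spans = _spans(labels)
    food_spans = [(s, e) for cls, s, e in spans if cls == "FOOD"]
    if not food_spans:
        return []
    text = lambda s, e: " ".join(tokens[s:e])
    items = [FoodItem(food_text=text(s, e)) for s, e in food_spans]
    starts = [s for s, _ in food_spans]
    for cls, s, e in spans:
        if cls == "FOOD":
            continue
        # nearest food span starting at/after the modifier's end, else last before
        idx = next((k for k, fs in enumerate(starts) if fs >= e), None)
        if idx is None:
            idx = len(starts) - 1
        item = items[idx]
        if cls == "QTY" and item.quantity_text is None:
            item.quantity_text = text(s, e)
        elif cls == "UNIT" and item.unit_text is None:
            item.unit_text = text(s, e)
        elif cls == "BRAND" and item.brand_text is None:
            item.brand_text = text(s, e)
        elif cls == "DESC":
            item.descriptors.append(text(s, e))
    return items


# ---------------------------------------------------------------------------
# Lexicon and the rules backend
# ---------------------------------------------------------------------------

class FoodLexicon:
    """Food-name and brand phrase lexicon derived from a food database.

    Phrases are stored as case-folded token tuples.  USDA-style inverted
    descriptions ("Cheese, cheddar") additionally contribute their natural
    reading ("cheddar cheese") so spoken-order mentions match.
    """

    def __init__(
        self,
        food_phrases: Iterable[Sequence[str]] = (),
        brand_phrases: Iterable[Sequence[str]] = (),
    ) -> None:
        self.food_phrases: set[tuple[str, ...]] = {tuple(p) for p in food_phrases if p}
        self.brand_phrases: set[tuple[str, ...]] = {tuple(p) for p in brand_phrases if p}
        self._rebuild()

    def _rebuild(self) -> None:
        self.max_food_len = max((len(p) for p in self.food_phrases), default=0)
        self.max_brand_len = max((len(p) for p in self.brand_phrases), default=0)
        self.food_tokens = {t for p in self.food_phrases for t in p}
        self.food_starts = {p[0] for p in self.food_phrases}

    @staticmethod
    def _phrase_variants(description: str) -> list[tuple[str, ...]]:
        norm = normalize_text(description)
        variants = [tuple(tokenize(norm))]
        if "," in description:
            parts = [p.strip() for p in norm.split(",") if p.strip()]
            if len(parts) > 1:
                natural = " ".join(reversed(parts))
                variants.append(tuple(tokenize(natural)))
        return [v for v in variants if v]

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[FoodEntry],
        extra_phrases: Iterable[str] = (),
    ) -> "FoodLexicon":
        foods: set[tuple[str, ...]] = set()
        brands: set[tuple[str, ...]] = set()
        for e in entries:
            foods.update(cls._phrase_variants(e.description))
            if e.brand:
                brands.add(tuple(tokenize(normalize_text(e.brand))))
        for phrase in extra_phrases:
            foods.update(cls._phrase_variants(phrase))
        lex = cls()
        lex.food_phrases = foods
        lex.brand_phrases = brands
        lex._rebuild()
        return lex

    def add_phrase(self, phrase: str) -> None:
        self.food_phrases.update(self._phrase_variants(phrase))
        self._rebuild()


class RuleTagger:
    """Deterministic longest-match lexicon tagger with closed-class grammar."""

    def __init__(self, lexicon: FoodLexicon) -> None:
        self.lexicon = lexicon

    def label_tokens(self, tokens: Sequence[str]) -> list[str]:
        folded = [t.casefold() for t in tokens]
        n = len(tokens)
        labels = ["O"] * n

        def claim(start: int, end: int, cls: str) -> None:
            labels[start] = f"B-{cls}"
            for k in range(start + 1, end):
                labels[k] = f"I-{cls}"

        # Pass 1: longest-match food phrases (left to right, greedy).
        i = 0
        while i < n:
            matched = 0
            if folded[i] in self.lexicon.food_starts:
                top = min(self.lexicon.max_food_len, n - i)
                for ln in range(top, 0, -1):
                    if tuple(folded[i : i + ln]) in self.lexicon.food_phrases:
                        matched = ln
                        break
            if matched:
                claim(i, i + matched, "FOOD")
                i += matched
            else:
                i += 1
        # Pass 2: brands on unclaimed tokens.
        i = 0
        while i < n:
            matched = 0
            if labels[i] == "O" and self.lexicon.brand_phrases:
                top = min(self.lexicon.max_brand_len, n - i)
                for ln in range(top, 0, -1):
                    if all(labels[k] == "O" for k in range(i, i + ln)) and tuple(
                        folded[i : i + ln]
                    ) in self.lexicon.brand_phrases:
                        matched = ln
                        break
            if matched:
                claim(i, i + matched, "BRAND")
                i += matched
            else:
                i += 1
        # Pass 3: closed classes on remaining tokens.
        for i, tok in enumerate(folded):
            if labels[i] != "O":
                continue
            if tok in MEAL_WORDS:
                continue  # "for dinner" stays O
            if _NUMBER_RE.match(tok) or _FRACTION_RE.match(tok):
                labels[i] = "B-QTY"
            elif tok in QTY_WORDS:
                # "a"/"an" count as quantities only before a unit, a food
                # mention, or a modifier that precedes one
                if tok in ("a", "an"):
                    nxt = folded[i + 1] if i + 1 < n else ""
                    nxt_attaches = (
                        _singular(nxt) in UNIT_WORDS
                        or nxt in self.lexicon.food_starts
                        or nxt in DESC_WORDS
                        or nxt == "half"
                        or (i + 1 < n and labels[i + 1] != "O")
                    )
                    if nxt_attaches:
                        labels[i] = "B-QTY"
                else:
                    labels[i] = "B-QTY"
            elif _singular(tok) in UNIT_WORDS:
                labels[i] = "B-UNIT"
            elif tok in DESC_WORDS:
                labels[i] = "B-DESC"
        # Merge adjacent quantity tokens ("a half", "two and a half" minus "and").
        for i in range(1, n):
            if labels[i] == "B-QTY" and labels[i - 1] in ("B-QTY", "I-QTY"):
                labels[i] = "I-QTY"
        return repair_bio(labels)


def _singular(token: str) -> str:
    """Naive singularization for unit matching ("cups" -> "cup")."""
    t = token.casefold()
    if len(t) > 3 and t.endswith("ies"):
        return t[:-3] + "y"
    if len(t) > 3 and t.endswith("es") and t[-3] in "shxz":
        return t[:-2]
    if len(t) > 2 and t.endswith("s") and not t.endswith("ss"):
        return t[:-1]
    return t


def tag_meal(
    raw_text: str,
    backend: "str | RuleTagger | LearnedTagger" = "rules",
    lexicon: FoodLexicon | None = None,
) -> TaggedMeal:
    """Tokenize, label and group a meal description into a TaggedMeal.

    ``backend`` is either the string ``"rules"`` (requires ``lexicon``) or a
    tagger object exposing ``label_tokens``.  Text with no recognizable food
    yields zero items.
    """
    tokens = tokenize(raw_text)
    if isinstance(backend, str):
        if backend != "rules":
            raise ValueError(f"unknown backend {backend!r}; pass a tagger object")
        if lexicon is None:
            raise ValueError("rules backend requires a lexicon")
        tagger: RuleTagger | LearnedTagger = RuleTagger(lexicon)
    else:
        tagger = backend
    labels = repair_bio(tagger.label_tokens(tokens)) if tokens else []
    return TaggedMeal(raw_text=raw_text, tokens=tokens, labels=labels, items=group_items(tokens, labels))


# ---------------------------------------------------------------------------
# Learned backend
# ---------------------------------------------------------------------------

def _token_features(
    tokens: Sequence[str], i: int, lexicon: FoodLexicon | None
) -> dict[str, float]:
    tok = tokens[i].casefold()
    prev = tokens[i - 1].casefold() if i > 0 else "<s>"
    nxt = tokens[i + 1].casefold() if i + 1 < len(tokens) else "</s>"
    feats = {
        f"w={tok}": 1.0,
        f"w-1={prev}": 1.0,
        f"w+1={nxt}": 1.0,
        f"suf3={tok[-3:]}": 1.0,
        "isnum": float(bool(_NUMBER_RE.match(tok) or _FRACTION_RE.match(tok))),
        "isunit": float(_singular(tok) in UNIT_WORDS),
        "isqty": float(tok in QTY_WORDS),
        "isdesc": float(tok in DESC_WORDS),
        "ismeal": float(tok in MEAL_WORDS),
        "ispunct": float(not tok[:1].isalnum()) if tok else 0.0,
        "first": float(i == 0),
    }
    if lexicon is not None:
        folded = [t.casefold() for t in tokens]
        feats["inlex"] = float(tok in lexicon.food_tokens)
        # does a lexicon phrase start here / cover this position?
        starts = 0.0
        covered = 0.0
        lo = max(0, i - lexicon.max_food_len + 1)
        for s in range(lo, i + 1):
            top = min(lexicon.max_food_len, len(tokens) - s)
            for ln in range(1, top + 1):
                if s + ln <= i:
                    continue
                if tuple(folded[s : s + ln]) in lexicon.food_phrases:
                    covered = 1.0
                    if s == i:
                        starts = 1.0
        feats["lexstart"] = starts
        feats["lexcover"] = covered
        feats["nextlexstart"] = float(nxt in lexicon.food_starts)
    return feats


class LearnedTagger:
    """Feature-based discriminative token labeler (sklearn conventions).

    Per-token multinomial logistic regression over lexical/shape/context/
    lexicon features; predictions are BIO-repaired.  Deterministic given
    the ``random_state`` used at fit time.
    """

    def __init__(self, lexicon: FoodLexicon | None = None, random_state: int = 0, C: float = 10.0):
        self.lexicon = lexicon
        self.random_state = random_state
        self.C = C

    def fit(self, meals: Sequence["TaggedMeal | dict"]) -> "LearnedTagger":
        from sklearn.feature_extraction import DictVectorizer
        from sklearn.linear_model import LogisticRegression

        X_dicts: list[dict] = []
        y: list[str] = []
        if not meals:
            raise ValueError("training corpus is empty")
        for meal in meals:
            tokens, labels = _meal_tokens_labels(meal)
            if len(tokens) != len(labels):
                raise ValueError(
                    f"corpus example has {len(labels)} labels for {len(tokens)} tokens"
                )
            for i in range(len(tokens)):
                X_dicts.append(_token_features(tokens, i, self.lexicon))
                y.append(labels[i])
        self.vectorizer_ = DictVectorizer(sparse=True)
        X = self.vectorizer_.fit_transform(X_dicts)
        self.classifier_ = LogisticRegression(
            C=self.C, max_iter=300, random_state=self.random_state
        )
        self.classifier_.fit(X, y)
        return self

    def label_tokens(self, tokens: Sequence[str]) -> list[str]:
        if not tokens:
            return []
        X = self.vectorizer_.transform(
            [_token_features(tokens, i, self.lexicon) for i in range(len(tokens))]
        )
        return repair_bio(list(self.classifier_.predict(X)))


def _meal_tokens_labels(meal: "TaggedMeal | dict") -> tuple[list[str], list[str]]:
    if isinstance(meal, TaggedMeal):
        return meal.tokens, meal.labels
    return list(meal["tokens"]), list(meal["labels"])


def train_labeler(
    corpus: Sequence["TaggedMeal | dict"],
    seed: int = 0,
    lexicon: FoodLexicon | None = None,
) -> LearnedTagger:
    """Train the learned labeler on an annotated corpus; deterministic per seed."""
    return LearnedTagger(lexicon=lexicon, random_state=seed).fit(corpus)


def token_f1(
    gold: Sequence[Sequence[str]], predicted: Sequence[Sequence[str]]
) -> float:
    """Micro-averaged token-level F1 over non-O labels."""
    tp = fp = fn = 0
    for g_seq, p_seq in zip(gold, predicted, strict=True):
        for g, p in zip(g_seq, p_seq, strict=True):
            if p != "O" and p == g:
                tp += 1
            else:
                if p != "O":
                    fp += 1
                if g != "O":
                    fn += 1
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


# ---------------------------------------------------------------------------
# Annotated-corpus I/O: JSON lines, one meal per line
# ---------------------------------------------------------------------------

def write_corpus(meals: Iterable["TaggedMeal | dict"], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for meal in meals:
            tokens, labels = _meal_tokens_labels(meal)
            text = meal.raw_text if isinstance(meal, TaggedMeal) else meal.get("text", " ".join(tokens))
            fh.write(json.dumps({"text": text, "tokens": tokens, "labels": labels}) + "\n")
    return path


def read_corpus(path: str | Path) -> list[dict]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
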