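"""Candidate food-code retrieval by vector dot-product similarity.

Each database entry and each tagged food item is embedded as a sparse
term-weighted vector (sublinear TF-IDF over word 1–2-grams plus character
3–5-grams; the character block buys robustness to misspellings), L2
normalized so that the ranking dot product is a cosine.  For a tagged food
item, all entries are scored and the top-K (default 15, the list length a
user scrolls) are returned in descending score order.

Personalization: when the user has previously confirmed a food code for
the same (case-folded, whitespace-normalized) item text, that code is
promoted to rank 1 and the ranking is flagged as personalized.  Duplicate
foods across source databases are all scored and may all appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.preprocessing import normalize as l2_normalize

from .food_db import FoodEntry, normalize_text
from .meal_nlu import FoodItem

__all__ = ["FoodVectorizer", "CandidateRanking", "fit_vectorizer", "rank_candidates"]

DEFAULT_TOP_K = 15


def _entry_document(entry: FoodEntry) -> str:
    doc = entry.description_norm
    if entry.brand:
        doc += " " + normalize_text(entry.brand)
    return doc


class FoodVectorizer:
    """Sparse word+character TF-IDF embedding of food texts (sklearn-style).

    Deterministic: fitting twice on the same entries yields identical
    vocabularies and vectors.
    """

    def __init__(
        self,
        word_ngram_range: tuple[int, int] = (1, 2),
        char_ngram_range: tuple[int, int] = (3, 5),
        char_weight: float = 0.5,
    ) -> None:
        self.word_ngram_range = word_ngram_range
        self.char_ngram_range = char_ngram_range
        self.char_weight = char_weight

    def fit(self, entries: Sequence[FoodEntry]) -> "FoodVectorizer":
        if not entries:
            raise ValueError("cannot fit vectorizer on an empty entry collection")
        docs = [_entry_document(e) for e in entries]
        self.word_ = TfidfVectorizer(
            ngram_range=self.word_ngram_range, sublinear_tf=True, norm=None
        )
        self.char_ = TfidfVectorizer(
            analyzer="char_wb",
            ngram_range=self.char_ngram_range,
            sublinear_tf=True,
            norm=None,
        )
        self.word_.fit(docs)
        self.char_.fit(docs)
        self.n_features_ = len(self.word_.vocabulary_) + len(self.char_.vocabulary_)
        return self

    def transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        texts = [normalize_text(t) for t in texts]
        blocks = sp.hstack(
            [self.word_.transform(texts), self.char_weight * self.char_.transform(texts)],
            format="csr",
        )
        return l2_normalize(blocks, norm="l2", copy=False)

    def transform_entries(self, entries: Sequence[FoodEntry]) -> sp.csr_matrix:
        return self.transform([_entry_document(e) for e in entries])

    def fit_transform_entries(self, entries: Sequence[FoodEntry]) -> sp.csr_matrix:
        return self.fit(entries).transform_entries(entries)


def fit_vectorizer(entries: Sequence[FoodEntry], **kwargs) -> FoodVectorizer:
    """Fit the deterministic TF-IDF food vectorizer over entry descriptions+brands."""
    return FoodVectorizer(**kwargs).fit(entries)


@dataclass
class CandidateRanking:
    """Top-K database candidates for one tagged food item."""

    item: FoodItem
    candidates: list[tuple[FoodEntry, float]]
    personalized: bool = False

    def __post_init__(self) -> None:
        scores = [s for _, s in self.candidates]
        if any(not np.isfinite(s) for s in scores):
            raise ValueError("candidate scores must be finite")

    @property
    def entries(self) -> list[FoodEntry]:
        return [e for e, _ in self.candidates]

    @property
    def top(self) -> FoodEntry:
        return self.candidates[0][0]


def _history_code(
    item: FoodItem, history: Iterable
) -> tuple[str, str] | None:
    """Most recently confirmed (code, source) for this exact item text, if any."""
    key = normalize_text(item.food_text)
    found = None
    for rec in history:  # chronological; last match wins
        if normalize_text(getattr(rec, "item_text", "") or "") == key:
            found = (rec.food_code, rec.source)
    return found


def rank_candidates(
    item: FoodItem,
    vectorizer: FoodVectorizer,
    entries: Sequence[FoodEntry],
    history: Iterable = (),
    k: int = DEFAULT_TOP_K,
    source_priority: Sequence[str] = (),
    entry_matrix: sp.csr_matrix | None = None,
) -> CandidateRanking:
    """Score every entry against the item and return the top-K ranking.

    Scores are dot products between the item's text vector and each entry
    vector.  Ties break by source priority (position in ``source_priority``,
    unknown sources last) then lexicographic code.  A confirmed history
    pairing for the identical normalized item text promotes that entry to
    rank 1.  ``entry_matrix`` may carry precomputed entry vectors (rows
    aligned with ``entries``) to avoid re-transforming a large database.
    """
    if not entries:
        raise ValueError("food database is empty")
    if entry_matrix is None:
        entry_matrix = vectorizer.transform_entries(entries)
    query = vectorizer.transform([item.query_text])
    scores = np.asarray((entry_matrix @ query.T).todense()).ravel()

    prio = {s: i for i, s in enumerate(source_priority)}
    order = sorted(
        range(len(entries)),
        key=lambda i: (
            -scores[i],
            prio.get(entries[i].source, len(prio)),
            entries[i].code,
        ),
    )

    personalized = False
    promoted = _history_code(item, history)
    if promoted is not None:
        pos = next((r for r, i in enumerate(order) if entries[i].key == promoted), None)
        if pos is not None:
            order.insert(0, order.pop(pos))
            personalized = True

    top = order[: max(0, k)]
    return CandidateRanking(
        item=item,
        candidates=[(entries[i], float(scores[i])) for i in top],
        personalized=personalized,
    )
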