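"""Windowed collocation counting, mutual information, and filtering.

The span rule: for each node occurrence, up to ``span`` window positions are
collected on each side.  Articles never consume a window position.  Other
stop words consume a position but are not emitted as collocates (they were
removed in preprocessing), unless ``skip_stopwords`` is set, in which case
they behave like articles.  The window never crosses a sentence boundary,
and node words are never counted as their own collocates.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .corpus_io import RatingLexicon, TokenizedSentence

__all__ = [
    "CollocationCounts",
    "CollocateRecord",
    "count_collocates",
    "mutual_information",
    "filter_collocates",
]

DEFAULT_SPAN = 6
DEFAULT_MI_THRESHOLD = 1.5


class CountInconsistencyError(ValueError):
    """Raised when co-occurrence counts contradict corpus frequencies."""


@dataclass
class CollocationCounts:
    """Per-year co-occurrence and frequency counts for one node-word set.

    ``n_tokens_all`` counts every token (stop words and articles included);
    ``n_tokens_content`` counts non-stop-word tokens only.  Both denominators
    are kept because the normalization unit is ambiguous; ``n_tokens``
    selects one.
    """

    span: int = DEFAULT_SPAN
    n_tokens_all: Counter = field(default_factory=Counter)
    n_tokens_content: Counter = field(default_factory=Counter)
    f_node: Counter = field(default_factory=Counter)
    f_near: Counter = field(default_factory=Counter)  # (year, word) -> count
    f_colloc: Counter = field(default_factory=Counter)  # (year, word) -> count

    @property
    def years(self) -> list[int]:
        return sorted(self.n_tokens_all)

    def n_tokens(self, year: int, denominator: Literal["all", "content"] = "all") -> int:
        if denominator == "all":
            return self.n_tokens_all[year]
        if denominator == "content":
            return self.n_tokens_content[year]
        raise ValueError(f"unknown denominator {denominator!r}")

    def node_rate_per_million(self, year: int) -> dict[str, float]:
        """Node occurrences per million tokens, under both denominators."""
        out = {}
        for denom in ("all", "content"):
            n = self.n_tokens(year, denom)
            out[denom] = 1e6 * self.f_node[year] / n if n else float("nan")
        return out


@dataclass(frozen=True)
class CollocateRecord:
    word: str
    year: int
    f_near: int
    mi: float
    relevant: bool
    retained: bool


def count_collocates(
    sentences: Iterable[TokenizedSentence],
    node_words: frozenset[str] | set[str],
    span: int = DEFAULT_SPAN,
    skip_stopwords: bool = False,
) -> CollocationCounts:
    """Count collocates of the node word(s) under the span rules.

    Parameters
    ----------
    sentences : iterable of TokenizedSentence
    node_words : lowercase node-word surface forms (exact match)
    span : content-word window positions on each side of a node occurrence
    skip_stopwords : if True, non-article stop words do not consume window
        positions (alternative reading of the span rule); default False.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    counts = CollocationCounts(span=span)
    node_words = frozenset(node_words)
    for sent in sentences:
        year = sent.year
        tokens = sent.tokens
        counts.n_tokens_all[year] += len(tokens)
        node_positions = []
        for i, tok in enumerate(tokens):
            if not tok.is_stopword:
                counts.n_tokens_content[year] += 1
            counts.f_colloc[(year, tok.surface)] += 1
            if tok.surface in node_words:
                node_positions.append(i)
        counts.f_node[year] += len(node_positions)
        # a token occurrence within the windows of several node occurrences
        # still counts once (keeps F_near <= F_colloc)
        emitted: set[int] = set()
        for i in node_positions:
            for direction in (-1, 1):
                consumed = 0
                j = i + direction
                while 0 <= j < len(tokens) and consumed < span:
                    tok = tokens[j]
                    skip = tok.is_article or (skip_stopwords and tok.is_stopword)
                    if not skip:
                        consumed += 1
                        if not tok.is_stopword and tok.surface not in node_words:
                            emitted.add(j)
                    j += direction
        for j in emitted:
            counts.f_near[(year, tokens[j].surface)] += 1
    return counts


def mutual_information(
    counts: CollocationCounts,
    pooling: Literal["per_year", "pooled"] = "per_year",
    denominator: Literal["all", "content"] = "all",
) -> dict[tuple[int, str], float]:
    """Span-adjusted pointwise mutual information (bits) per (year, word).

    mi = log2( F_near * N / (F_node * F_colloc * S) ),  S = 2 * span.

    Collocates with F_near = 0 are absent from the result (no -inf values).
    Under ``pooled`` all years share summed counts; the result is keyed by
    (0, word).
    """
    s_total = 2 * counts.span
    out: dict[tuple[int, str], float] = {}
    if pooling == "pooled":
        n = sum(counts.n_tokens(y, denominator) for y in counts.years)
        f_node = sum(counts.f_node.values())
        near: Counter = Counter()
        colloc: Counter = Counter()
        for (y, w), c in counts.f_near.items():
            near[w] += c
        for (y, w), c in counts.f_colloc.items():
            colloc[w] += c
        if near and (n <= 0 or f_node <= 0):
            raise ValueError("pooled MI requires N_tokens > 0 and F_node > 0")
        for w, f_near in near.items():
            if f_near == 0:
                continue
            f_colloc = colloc[w]
            if f_colloc == 0:
                raise CountInconsistencyError(
                    f"word {w!r}: F_near={f_near} but F_colloc=0"
                )
            out[(0, w)] = math.log2(f_near * n / (f_node * f_colloc * s_total))
        return out
    if pooling != "per_year":
        raise ValueError(f"unknown pooling {pooling!r}")
    for (year, w), f_near in counts.f_near.items():
        if f_near == 0:
            continue
        n = counts.n_tokens(year, denominator)
        f_node = counts.f_node[year]
        if n <= 0 or f_node <= 0:
            raise ValueError(f"year {year}: MI requires N_tokens > 0 and F_node > 0")
        f_colloc = counts.f_colloc[(year, w)]
        if f_colloc == 0:
            raise CountInconsistencyError(
                f"year {year}, word {w!r}: F_near={f_near} but F_colloc=0"
            )
        out[(year, w)] = math.log2(f_near * n / (f_node * f_colloc * s_total))
    return out


def filter_collocates(
    mi_scores: Mapping[tuple[int, str], float],
    lexicon: RatingLexicon,
    threshold: float = DEFAULT_MI_THRESHOLD,
    counts: CollocationCounts | None = None,
) -> tuple[list[CollocateRecord], list[tuple[int, str]]]:
    """Apply the MI-and-relevance filter.

    Returns ``(records, needs_rating)``.  ``records`` contains one
    :class:`CollocateRecord` per scored (year, word) present in the lexicon,
    with ``retained`` = (mi >= threshold and relevant).  Words that clear the
    MI threshold but are absent from the lexicon are routed to
    ``needs_rating`` rather than silently dropped.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    records: list[CollocateRecord] = []
    needs_rating: list[tuple[int, str]] = []
    for (year, word), mi in sorted(mi_scores.items()):
        f_near = counts.f_near[(year, word)] if counts is not None else 0
        if word in lexicon:
            entry = lexicon[word]
            records.append(
                CollocateRecord(
                    word=word,
                    year=year,
                    f_near=f_near,
                    mi=mi,
                    relevant=entry.relevant,
                    retained=(mi >= threshold and entry.relevant),
                )
            )
        elif mi >= threshold:
            needs_rating.append((year, word))
    return records, needs_rating
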