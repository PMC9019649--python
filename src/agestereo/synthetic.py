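"""Synthetic data with planted effects.

Two generators:

* :func:`generate_panel` draws score-level annual panels from a known
  first-stage-moderated structural model, for parameter-recovery and
  bootstrap-coverage tests.
* :func:`generate_corpus` assembles document-level corpora with planted
  collocation structure: a node word occurring at a controlled rate,
  vocabulary words sampled near it proportionally to an association
  strength, and a policy-year regime shift that up-weights medical
  (low-sentiment) collocates.  The true rating lexicon is emitted alongside,
  so the scoring stage needs no human raters in tests.

Background text is token soup from a Zipf-weighted filler vocabulary —
windows and counts, not syntax, drive every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import Document, LexiconEntry, RatingLexicon
from .scoring import AnnualPanel, PANEL_COLUMNS

__all__ = [
    "PanelGenConfig",
    "VocabWord",
    "CorpusGenConfig",
    "generate_panel",
    "generate_corpus",
    "default_vocabulary",
]


@dataclass(frozen=True)
class PanelGenConfig:
    """Structural model for score-level panels.

    X is a step at ``policy_year``; W declines linearly from
    ``support_start`` to ``support_end``; with Wc = W - mean(W):

        M = i_m + a1*X + a2*Wc + a3*X*Wc + N(0, sd_m)
        Y = i_y + c_prime*X + b*M + N(0, sd_y)
    """

    n_years: int = 8
    start_year: int = 2010
    policy_year: int = 2014
    a1: float = -0.5
    a2: float = 0.0
    a3: float = 0.0
    b: float = 2.0
    c_prime: float = 0.1
    i_m: float = 0.0
    i_y: float = 0.0
    sd_m: float = 1.0
    sd_y: float = 1.0
    support_start: float = 7.4
    support_end: float = 5.1

    def __post_init__(self) -> None:
        if self.n_years < 4:
            raise ValueError("n_years must be >= 4")
        if self.sd_m < 0 or self.sd_y < 0:
            raise ValueError("noise SDs must be >= 0")


def generate_panel(
    config: PanelGenConfig, seed: int
) -> tuple[AnnualPanel, dict]:
    """Draw one panel from the structural model; returns (panel, truth).

    The panel is a pure function of (config, seed).  Score bounds are not
    enforced (structural-equation values are unbounded).
    """
    rng = np.random.default_rng(seed)
    years = config.start_year + np.arange(config.n_years)
    x = (years >= config.policy_year).astype(float)
    w = np.linspace(config.support_start, config.support_end, config.n_years)
    wc = w - w.mean()
    m = (
        config.i_m
        + config.a1 * x
        + config.a2 * wc
        + config.a3 * x * wc
        + rng.normal(0.0, config.sd_m, config.n_years)
    )
    y = (
        config.i_y
        + config.c_prime * x
        + config.b * m
        + rng.normal(0.0, config.sd_y, config.n_years)
    )
    df = pd.DataFrame(
        {
            "year": years,
            "sas": y,
            "med": m,
            "n_collocates": 0,
            "policy": x.astype(int),
            "support_ratio": w,
        }
    )[PANEL_COLUMNS]
    truth = {
        "a1": config.a1,
        "a2": config.a2,
        "a3": config.a3,
        "b": config.b,
        "c_prime": config.c_prime,
        "indirect": config.a1 * config.b,
        "index_modmed": config.a3 * config.b,
        "seed": seed,
    }
    return AnnualPanel(df, check_bounds=False), truth


@dataclass(frozen=True)
class VocabWord:
    word: str
    sentiment: int  # true rating 1-5
    medical: int  # 0/1
    association: float  # sampling weight near the node word; 0 = never near

    def __post_init__(self) -> None:
        if self.sentiment not in (1, 2, 3, 4, 5):
            raise ValueError(f"{self.word!r}: sentiment must be 1-5")
        if self.medical not in (0, 1):
            raise ValueError(f"{self.word!r}: medical must be 0/1")
        if self.association < 0:
            raise ValueError(f"{self.word!r}: association must be >= 0")


def default_vocabulary() -> list[VocabWord]:
    """A vocabulary mixing low-sentiment medical words, positive
    non-medical words, neutral words, and chance-level distractors."""
    vocab = []
    for i in range(8):
        vocab.append(VocabWord(f"ailment{i}", sentiment=1 + (i % 2), medical=1, association=4.0))
    for i in range(8):
        vocab.append(VocabWord(f"praise{i}", sentiment=5 - (i % 2), medical=0, association=4.0))
    for i in range(4):
        vocab.append(VocabWord(f"neutral{i}", sentiment=3, medical=0, association=4.0))
    for i in range(6):
        vocab.append(VocabWord(f"chance{i}", sentiment=3, medical=0, association=0.02))
    return vocab


@dataclass(frozen=True)
class CorpusGenConfig:
    years: tuple[int, ...] = tuple(range(2010, 2018))
    articles_per_year: int = 20
    tokens_per_article: int = 240
    sentence_length: int = 12
    node_word: str = "elderly"
    node_rate: float = 8.0  # node occurrences per 1,000 tokens
    collocates_per_node: int = 4
    vocabulary: tuple[VocabWord, ...] = field(default_factory=lambda: tuple(default_vocabulary()))
    policy_year: int = 2014
    medical_boost: float = 3.0
    n_filler_words: int = 400
    vocab_background_rate: float = 0.02  # per-token prob. of a vocab word in background text

    def __post_init__(self) -> None:
        if self.medical_boost <= 0:
            raise ValueError("medical_boost must be > 0")
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")
        words = [v.word for v in self.vocabulary]
        if len(set(words)) != len(words):
            raise ValueError("vocabulary words must be unique")
        expected_node = (
            self.node_rate / 1000 * self.articles_per_year * self.tokens_per_article
        )
        if expected_node < 20:
            raise ValueError(
                f"config yields expected F_node ~ {expected_node:.1f} < 20 per year; "
                "MI would not be estimable"
            )


def _truth_lexicon(vocabulary) -> RatingLexicon:
    lex = RatingLexicon()
    for v in vocabulary:
        lex.add(
            LexiconEntry(
                word=v.word,
                sentiment_ratings=(v.sentiment, v.sentiment),
                medical_flags=(v.medical, v.medical),
                relevant=True,
            )
        )
    return lex


def generate_corpus(
    config: CorpusGenConfig, seed: int
) -> tuple[list[Document], RatingLexicon, dict]:
    """Generate year-stamped documents with planted collocation structure.

    Returns ``(documents, truth_lexicon, truth)``.  Sentences are either
    background (Zipf filler plus vocabulary words at a base rate — never the
    node word) or node sentences (exactly one node occurrence with
    ``collocates_per_node`` vocabulary words sampled by association strength
    placed adjacent to it, filler elsewhere).  From ``policy_year`` onward,
    medical-word association is multiplied by ``medical_boost``.
    """
    rng = np.random.default_rng(seed)
    vocab = list(config.vocabulary)
    vocab_words = [v.word for v in vocab]
    filler = [f"w{i:05d}" for i in range(config.n_filler_words)]
    overlap = set(filler) & set(vocab_words) | {config.node_word} & set(filler)
    if config.node_word in vocab_words:
        raise ValueError("node word must not be in the vocabulary")
    zipf = 1.0 / np.arange(1, config.n_filler_words + 1)
    zipf /= zipf.sum()

    sent_len = config.sentence_length
    sents_per_article = max(1, config.tokens_per_article // sent_len)
    p_node_sentence = min(1.0, config.node_rate / 1000 * sent_len)
    base_assoc = np.array([v.association for v in vocab])
    is_medical = np.array([v.medical for v in vocab], dtype=bool)

    documents: list[Document] = []
    for year in config.years:
        assoc = base_assoc.copy()
        if year >= config.policy_year:
            assoc[is_medical] *= config.medical_boost
        assoc_p = assoc / assoc.sum() if assoc.sum() > 0 else assoc
        for art in range(config.articles_per_year):
            sentences = []
            for _ in range(sents_per_article):
                if rng.random() < p_node_sentence:
                    sentences.append(
                        _node_sentence(rng, config, vocab_words, assoc_p, filler, zipf)
                    )
                else:
                    sentences.append(
                        _background_sentence(rng, config, vocab_words, filler, zipf)
                    )
            text = " ".join(" ".join(s) + "." for s in sentences)
            documents.append(
                Document(
                    doc_id=f"y{year}a{art:03d}",
                    year=int(year),
                    source="synthetic",
                    text=text,
                )
            )
    truth = {
        "seed": seed,
        "policy_year": config.policy_year,
        "medical_boost": config.medical_boost,
        "node_word": config.node_word,
        "vocabulary": [
            {
                "word": v.word,
                "sentiment": v.sentiment,
                "medical": v.medical,
                "association": v.association,
            }
            for v in vocab
        ],
    }
    return documents, _truth_lexicon(vocab), truth


def _background_sentence(rng, config, vocab_words, filler, zipf) -> list[str]:
    n = config.sentence_length
    tokens = [filler[i] for i in rng.choice(len(filler), size=n, p=zipf)]
    vocab_mask = rng.random(n) < config.vocab_background_rate
    for pos in np.nonzero(vocab_mask)[0]:
        tokens[pos] = vocab_words[rng.integers(len(vocab_words))]
    return tokens


def _node_sentence(rng, config, vocab_words, assoc_p, filler, zipf) -> list[str]:
    n = config.sentence_length
    tokens = [filler[i] for i in rng.choice(len(filler), size=n, p=zipf)]
    node_pos = int(rng.integers(0, n))
    tokens[node_pos] = config.node_word
    k = config.collocates_per_node
    if assoc_p.sum() > 0 and k > 0:
        chosen = rng.choice(len(vocab_words), size=k, p=assoc_p)
        # alternate positions immediately around the node so every planted
        # collocate stays inside the span window
        offsets = []
        d = 1
        while len(offsets) < k:
            for sign in (-1, 1):
                pos = node_pos + sign * d
                if 0 <= pos < n and len(offsets) < k:
                    offsets.append(pos)
            d += 1
            if d > n:
                break
        for pos, vi in zip(offsets, chosen):
            tokens[pos] = vocab_words[vi]
    return tokens
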