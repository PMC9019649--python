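"""Corpus and lexicon I/O plus tokenization.

Reads year-stamped document collections (TSV manifest pointing at plain-text
files, or a single JSONL record file), multi-rater rating lexicons, and
per-year covariate tables.  Tokenization is deliberately rule-based and
deterministic: sentences split on terminal punctuation, tokens lowercased,
stop words *flagged* rather than removed so that downstream windowing rules
can treat them consistently.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "Document",
    "Token",
    "TokenizedSentence",
    "RatingLexicon",
    "LexiconEntry",
    "read_corpus",
    "read_jsonl_corpus",
    "tokenize",
    "read_lexicon",
    "write_lexicon",
    "read_covariates",
    "default_stopwords",
    "DEFAULT_ARTICLES",
]

DEFAULT_ARTICLES = frozenset({"a", "an", "the"})

_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")
# word-internal hyphens and apostrophes are kept; everything else is stripped
_TOKEN = re.compile(r"[A-Za-z0-9]+(?:['\-][A-Za-z0-9]+)*")


class CorpusError(ValueError):
    """Raised on malformed manifests, unreadable files or invalid lexicons."""


@dataclass(frozen=True)
class Document:
    """A year-stamped raw-text corpus unit."""

    doc_id: str
    year: int
    source: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise CorpusError(f"document {self.doc_id!r}: empty text")


@dataclass(frozen=True)
class Token:
    surface: str
    is_stopword: bool
    is_article: bool


@dataclass(frozen=True)
class TokenizedSentence:
    doc_id: str
    year: int
    tokens: tuple[Token, ...]


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    sentiment_ratings: tuple[int, ...]
    medical_flags: tuple[int, ...]
    relevant: bool

    @property
    def mean_sentiment(self) -> float:
        return sum(self.sentiment_ratings) / len(self.sentiment_ratings)

    @property
    def mean_medical(self) -> float:
        return sum(self.medical_flags) / len(self.medical_flags)


@dataclass
class RatingLexicon:
    """Per-collocate multi-rater sentiment (1-5) and medical (0/1) ratings."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)

    @property
    def n_raters(self) -> int:
        if not self.entries:
            return 0
        return len(next(iter(self.entries.values())).sentiment_ratings)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __getitem__(self, word: str) -> LexiconEntry:
        return self.entries[word]

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, entry: LexiconEntry) -> None:
        if self.entries:
            k = self.n_raters
            if len(entry.sentiment_ratings) != k or len(entry.medical_flags) != k:
                raise CorpusError(
                    f"entry {entry.word!r}: rater count differs from previous entries"
                )
        for r in entry.sentiment_ratings:
            if r not in (1, 2, 3, 4, 5):
                raise CorpusError(f"entry {entry.word!r}: sentiment rating {r} not in 1-5")
        for m in entry.medical_flags:
            if m not in (0, 1):
                raise CorpusError(f"entry {entry.word!r}: medical flag {m} not in {{0,1}}")
        self.entries[entry.word] = entry


def default_stopwords() -> frozenset[str]:
    """Packaged stop-word list (function words: prepositions, conjunctions,
    pronouns, auxiliaries, determiners)."""
    text = resources.files("agestereo.data").joinpath("stopwords.txt").read_text()
    return frozenset(
        w.strip().lower() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


def read_corpus(
    manifest_path: str | Path, text_encoding: str = "utf-8"
) -> Iterator[Document]:
    """Yield one :class:`Document` per manifest row.

    The manifest is a TSV with columns ``doc_id, year, source, path``; paths
    are resolved relative to the manifest's directory.  Rows with an
    unparseable year and missing files raise :class:`CorpusError` naming the
    offending row, as do duplicate ``doc_id`` values.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CorpusError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"doc_id", "year", "source", "path"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusError(f"manifest missing columns: {sorted(missing)}")
    seen: set[str] = set()
    base = manifest_path.parent
    for i, row in df.iterrows():
        doc_id = str(row["doc_id"])
        if doc_id in seen:
            raise CorpusError(f"duplicate doc_id {doc_id!r} at manifest row {i}")
        seen.add(doc_id)
        try:
            year = int(row["year"])
        except (TypeError, ValueError):
            raise CorpusError(
                f"manifest row {i} (doc_id {doc_id!r}): unparseable year {row['year']!r}"
            ) from None
        path = base / str(row["path"])
        if not path.exists():
            raise CorpusError(f"manifest row {i} (doc_id {doc_id!r}): file not found {path}")
        text = path.read_text(encoding=text_encoding)
        yield Document(doc_id=doc_id, year=year, source=str(row["source"]), text=text)


def read_jsonl_corpus(path: str | Path) -> Iterator[Document]:
    """Yield Documents from a newline-delimited JSON file with fields
    ``id, year, source, text``."""
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus file not found: {path}")
    with path.open() as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            try:
                year = int(rec["year"])
            except (TypeError, ValueError, KeyError):
                raise CorpusError(f"record {i}: unparseable year") from None
            yield Document(
                doc_id=str(rec["id"]),
                year=year,
                source=str(rec.get("source", "")),
                text=str(rec["text"]),
            )


def _normalize_token(raw: str) -> str:
    word = raw.lower()
    if word.endswith("'s"):
        word = word[:-2]
    return word


def tokenize(
    document: Document,
    stopwords: frozenset[str] | set[str] | None = None,
    articles: frozenset[str] | set[str] = DEFAULT_ARTICLES,
) -> list[TokenizedSentence]:
    """Split a document into sentences and lowercased, punctuation-stripped
    tokens, flagging stop words and articles.

    Stop-word tokens are retained in the stream (flagged, not deleted) so the
    collocation span rule can skip them deterministically.  An empty document
    yields an empty list.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    sentences: list[TokenizedSentence] = []
    for raw_sentence in _SENTENCE_SPLIT.split(document.text):
        tokens = []
        for match in _TOKEN.finditer(raw_sentence):
            word = _normalize_token(match.group(0))
            if not word:
                continue
            is_article = word in articles
            tokens.append(
                Token(
                    surface=word,
                    is_stopword=is_article or word in stopwords,
                    is_article=is_article,
                )
            )
        if tokens:
            sentences.append(
                TokenizedSentence(doc_id=document.doc_id, year=document.year, tokens=tuple(tokens))
            )
    return sentences


_S_COL = re.compile(r"^s_(.+)$")
_M_COL = re.compile(r"^m_(.+)$")


def read_lexicon(path: str | Path) -> RatingLexicon:
    """Read a rating lexicon TSV with columns
    ``word, relevant, s_<rater>..., m_<rater>...``.

    Sentiment ratings outside 1-5, medical flags outside {0,1}, and rows with
    missing cells are hard errors reporting the row number.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"lexicon not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    s_cols = [c for c in df.columns if _S_COL.match(c)]
    m_cols = [c for c in df.columns if _M_COL.match(c)]
    if "word" not in df.columns or "relevant" not in df.columns:
        raise CorpusError("lexicon must have 'word' and 'relevant' columns")
    if len(s_cols) < 2:
        raise CorpusError(f"lexicon needs >= 2 sentiment rater columns, found {len(s_cols)}")
    if len(m_cols) != len(s_cols):
        raise CorpusError(
            f"lexicon has {len(s_cols)} sentiment but {len(m_cols)} medical rater columns"
        )
    lexicon = RatingLexicon()
    for i, row in df.iterrows():
        word = str(row["word"]).lower()
        try:
            sentiments = tuple(int(row[c]) for c in s_cols)
            flags = tuple(int(row[c]) for c in m_cols)
        except (TypeError, ValueError):
            raise CorpusError(f"lexicon row {i} ({word!r}): non-integer rating") from None
        for r in sentiments:
            if not 1 <= r <= 5:
                raise CorpusError(f"lexicon row {i} ({word!r}): sentiment {r} outside 1-5")
        for m in flags:
            if m not in (0, 1):
                raise CorpusError(f"lexicon row {i} ({word!r}): medical flag {m} not 0/1")
        relevant = str(row["relevant"]).strip().lower() in ("1", "true", "yes", "y")
        lexicon.add(
            LexiconEntry(
                word=word,
                sentiment_ratings=sentiments,
                medical_flags=flags,
                relevant=relevant,
            )
        )
    return lexicon


def write_lexicon(lexicon: RatingLexicon, path: str | Path) -> None:
    """Write a lexicon back to TSV; inverse of :func:`read_lexicon`."""
    k = lexicon.n_raters
    cols = ["word", "relevant"] + [f"s_rater{j + 1}" for j in range(k)] + [
        f"m_rater{j + 1}" for j in range(k)
    ]
    rows = []
    for entry in lexicon.entries.values():
        rows.append(
            [entry.word, int(entry.relevant), *entry.sentiment_ratings, *entry.medical_flags]
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the per-year covariate table (TSV: year, policy_indicator
    optional, support_ratio)."""
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"covariate table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if "year" not in df.columns or "support_ratio" not in df.columns:
        raise CorpusError("covariate table must have 'year' and 'support_ratio' columns")
    df["year"] = df["year"].astype(int)
    if df["year"].duplicated().any():
        raise CorpusError("covariate table has duplicate years")
    if (df["support_ratio"] <= 0).any():
        raise CorpusError("support_ratio must be positive")
    return df.sort_values("year").reset_index(drop=True)
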