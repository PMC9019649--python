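import math
import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from agestereo.collocation import (
    CollocationCounts,
    CountInconsistencyError,
    count_collocates,
    filter_collocates,
    mutual_information,
)
from agestereo.corpus_io import Document, LexiconEntry, RatingLexicon, tokenize

from _oracles import HANDCRAFTED_TEXTS, brute_force_f_near, brute_force_mi

NODE = frozenset({"elderly"})


def sentences_from(texts, stopwords, year=2010):
    sents = []
    for i, text in enumerate(texts):
        sents.extend(tokenize(Document(f"d{i}", year, "t", text), stopwords=stopwords))
    return sents


class TestCountCollocates:
    def test_article_excluded_content_counted(self, stopwords):
        sents = sentences_from(["the elderly suffer dementia"], stopwords)
        counts = count_collocates(sents, NODE, span=6)
        assert counts.f_near[(2010, "suffer")] == 1
        assert counts.f_near[(2010, "dementia")] == 1
        assert counts.f_near[(2010, "the")] == 0

    def test_sentence_boundary_excludes_prior_sentence(self, stopwords):
        sents = sentences_from(["He left. Elderly thrive."], stopwords)
        counts = count_collocates(sents, NODE, span=6)
        assert counts.f_near[(2010, "thrive")] == 1
        assert counts.f_near[(2010, "he")] == 0
        assert counts.f_near[(2010, "left")] == 0

    def test_zero_node_occurrences(self, stopwords):
        sents = sentences_from(["Nothing relevant here at all."], stopwords)
        counts = count_collocates(sents, NODE, span=6)
        assert counts.f_node[2010] == 0
        assert sum(counts.f_near.values()) == 0

    def test_span_truncation(self, stopwords):
        text = "one two three four five six seven elderly"
        sents = sentences_from([text], stopwords.union({"one"}) - {"one"}, year=2011)
        counts = count_collocates(sents, NODE, span=6)
        # six content words before the node fit; "one" (7 positions away) does not
        assert counts.f_near[(2011, "seven")] == 1
        assert counts.f_near[(2011, "two")] == 1
        assert counts.f_near[(2011, "one")] == 0

    def test_articles_do_not_consume_positions(self, stopwords):
        # with span 1, an article between node and content word is skipped over
        sents = sentences_from(["elderly the gardener slept"], stopwords)
        counts = count_collocates(sents, NODE, span=1)
        assert counts.f_near[(2010, "gardener")] == 1
        assert counts.f_near[(2010, "slept")] == 0

    def test_node_not_own_collocate(self, stopwords):
        sents = sentences_from(["elderly met elderly"], stopwords)
        counts = count_collocates(sents, NODE, span=6)
        # "met" sits in both node windows but its single occurrence counts once
        assert counts.f_near[(2010, "elderly")] == 0
        assert counts.f_near[(2010, "met")] == 1
        assert counts.f_node[2010] == 2

    @pytest.mark.parametrize("skip_stopwords", [False, True])
    def test_matches_brute_force_on_handcrafted(self, stopwords, skip_stopwords):
        sents = sentences_from(HANDCRAFTED_TEXTS, stopwords)
        counts = count_collocates(sents, NODE, span=6, skip_stopwords=skip_stopwords)
        oracle = brute_force_f_near(sents, NODE, span=6, skip_stopwords=skip_stopwords)
        observed = Counter({k: v for k, v in counts.f_near.items() if v})
        assert observed == oracle

    @pytest.mark.parametrize("span", [1, 2, 6])
    @pytest.mark.parametrize("skip_stopwords", [False, True])
    def test_matches_brute_force_on_random_small_corpora(
        self, stopwords, span, skip_stopwords
    ):
        rng = random.Random(42)
        vocab = ["elderly", "the", "a", "and", "with", "cat", "dog", "ran", "sat",
                 "frail", "spry", "home"]
        for trial in range(30):
            n_sents = rng.randint(1, 6)
            texts = [
                " ".join(rng.choices(vocab, k=rng.randint(1, 12))) + "."
                for _ in range(n_sents)
            ]
            sents = sentences_from(texts, stopwords, year=2000 + trial)
            counts = count_collocates(sents, NODE, span=span, skip_stopwords=skip_stopwords)
            oracle = brute_force_f_near(sents, NODE, span=span, skip_stopwords=skip_stopwords)
            assert Counter({k: v for k, v in counts.f_near.items() if v}) == oracle

    def test_sum_conservation(self, stopwords):
        sents = sentences_from(HANDCRAFTED_TEXTS, stopwords)
        counts = count_collocates(sents, NODE, span=6)
        per_year_near = Counter()
        for (year, _), v in counts.f_near.items():
            per_year_near[year] += v
        for year, total in per_year_near.items():
            assert total <= counts.f_node[year] * 2 * counts.span

    def test_f_near_bounded_by_f_colloc(self, stopwords):
        sents = sentences_from(HANDCRAFTED_TEXTS, stopwords)
        counts = count_collocates(sents, NODE, span=6)
        for key, v in counts.f_near.items():
            assert v <= counts.f_colloc[key]

    def test_document_order_invariance(self, fixture_documents, stopwords):
        fwd = []
        for d in fixture_documents:
            fwd.extend(tokenize(d, stopwords=stopwords))
        rev = []
        for d in reversed(fixture_documents):
            rev.extend(tokenize(d, stopwords=stopwords))
        c1 = count_collocates(fwd, NODE, span=6)
        c2 = count_collocates(rev, NODE, span=6)
        assert c1.f_near == c2.f_near
        assert c1.f_colloc == c2.f_colloc
        assert c1.f_node == c2.f_node

    def test_span_below_one_rejected(self, stopwords):
        with pytest.raises(ValueError):
            count_collocates([], NODE, span=0)


def make_counts(f_near, n, f_node, f_colloc, span=6, year=2015, word="w"):
    counts = CollocationCounts(span=span)
    counts.n_tokens_all[year] = n
    counts.n_tokens_content[year] = n
    counts.f_node[year] = f_node
    counts.f_near[(year, word)] = f_near
    counts.f_colloc[(year, word)] = f_colloc
    return counts


class TestMutualInformation:
    def test_direct_formula_example(self):
        counts = make_counts(f_near=8, n=100_000, f_node=10, f_colloc=50, span=6)
        mi = mutual_information(counts)[(2015, "w")]
        assert mi == pytest.approx(math.log2(8 * 100_000 / (10 * 50 * 12)))
        assert mi == pytest.approx(7.06, abs=0.005)
        assert mi == pytest.approx(brute_force_mi(8, 100_000, 10, 50, 6))

    def test_independence_gives_zero(self):
        # F_near/(F_node*S) == F_colloc/N  ->  mi = 0
        counts = make_counts(f_near=1, n=1200, f_node=1, f_colloc=100, span=6)
        assert mutual_information(counts)[(2015, "w")] == pytest.approx(0.0, abs=1e-12)

    def test_doubling_f_near_adds_one_bit(self):
        base = make_counts(f_near=4, n=50_000, f_node=10, f_colloc=40)
        double = make_counts(f_near=8, n=50_000, f_node=10, f_colloc=40)
        mi1 = mutual_information(base)[(2015, "w")]
        mi2 = mutual_information(double)[(2015, "w")]
        assert mi2 - mi1 == pytest.approx(1.0, abs=1e-12)

    @given(
        f_near=st.integers(1, 50),
        f_colloc=st.integers(51, 500),
        bump=st.integers(1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, f_near, f_colloc, bump):
        lo = mutual_information(make_counts(f_near, 10_000, 20, f_colloc))[(2015, "w")]
        hi = mutual_information(make_counts(f_near + bump, 10_000, 20, f_colloc))[(2015, "w")]
        assert hi > lo
        worse = mutual_information(make_counts(f_near, 10_000, 20, f_colloc + bump))[(2015, "w")]
        assert worse < lo

    def test_zero_f_near_absent(self):
        counts = make_counts(f_near=0, n=1000, f_node=5, f_colloc=10)
        assert (2015, "w") not in mutual_information(counts)

    def test_inconsistent_counts_error(self):
        counts = make_counts(f_near=3, n=1000, f_node=5, f_colloc=0)
        with pytest.raises(CountInconsistencyError):
            mutual_information(counts)

    def test_pooled_mode(self):
        counts = CollocationCounts(span=6)
        for year in (2010, 2011):
            counts.n_tokens_all[year] = 500
            counts.n_tokens_content[year] = 500
            counts.f_node[year] = 5
            counts.f_near[(year, "w")] = 2
            counts.f_colloc[(year, "w")] = 4
        pooled = mutual_information(counts, pooling="pooled")
        assert pooled[(0, "w")] == pytest.approx(math.log2(4 * 1000 / (10 * 8 * 12)))


def tiny_lexicon():
    lex = RatingLexicon()
    lex.add(LexiconEntry("kept", (4, 4), (0, 0), relevant=True))
    lex.add(LexiconEntry("lowmi", (2, 2), (0, 0), relevant=True))
    lex.add(LexiconEntry("irrelevant", (3, 3), (0, 0), relevant=False))
    return lex


class TestFilterCollocates:
    def test_threshold_inclusive_at_boundary(self):
        scores = {(2010, "kept"): 1.5, (2010, "lowmi"): 1.49}
        records, needs = filter_collocates(scores, tiny_lexicon())
        by_word = {r.word: r for r in records}
        assert by_word["kept"].retained
        assert not by_word["lowmi"].retained
        assert needs == []

    def test_irrelevant_excluded(self):
        scores = {(2010, "irrelevant"): 3.0}
        records, _ = filter_collocates(scores, tiny_lexicon())
        assert not records[0].retained
        assert records[0].relevant is False

    def test_unrated_routed_to_needs_rating(self):
        scores = {(2010, "mystery"): 2.0, (2010, "faint"): 0.2}
        records, needs = filter_collocates(scores, tiny_lexicon())
        assert records == []
        assert needs == [(2010, "mystery")]

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_collocates({}, tiny_lexicon(), threshold=float("nan"))

    def test_retained_implies_relevant_and_above_threshold(self):
        scores = {(2010, "kept"): 2.0, (2011, "kept"): 0.3, (2010, "irrelevant"): 9.0}
        records, _ = filter_collocates(scores, tiny_lexicon())
        for r in records:
            if r.retained:
                assert r.relevant and r.mi >= 1.5
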