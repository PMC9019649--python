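# agestereo

Corpus-based measurement of societal age stereotypes and the medicalization
of aging, with downstream trend and path-model inference — packaged as a
reusable, fully testable pipeline that runs on any year-stamped document
corpus.

The pipeline has two halves, joined by a year-level panel TSV:

1. **Measurement.** Documents are tokenized into sentences (stop words and
   articles flagged, not deleted). Collocates of a node word (default
   `elderly`) are counted in a six-content-word window on each side —
   articles never consume window positions, windows never cross sentence
   boundaries. Each (year, word) pair gets a span-adjusted pointwise mutual
   information score, `log2(F_near·N / (F_node·F_colloc·S))` with
   `S = 2·span`; pairs with MI ≥ 1.5 whose word a rating lexicon marks
   relevant are retained (unrated high-MI words go to a needs-rating
   report). Retained collocates plus multi-rater lexicon ratings yield an
   annual stereotype score (mean 1–5 sentiment) and an annual medicalization
   score (mean 0/1 medical flag, a proportion), with Cronbach's alpha
   (Feldt CI) for rater reliability.
2. **Inference.** On the panel (year, sas, med, n_collocates, policy,
   support_ratio): polynomial trend fits on centered years; single-mediator
   mediation (total / direct / indirect effects, `c = c' + a·b` exactly);
   first-stage moderated mediation with a mean-centered moderator,
   conditional indirect effects at mean ± SD, the index of moderated
   mediation `a₃·b`, and seeded percentile-bootstrap CIs; simple-slopes
   probing of the interaction.

A synthetic-data module generates (a) score-level panels from a known
structural model and (b) document-level corpora with planted collocation
structure — a policy-year regime shift that boosts low-sentiment medical
collocates — so every stage is testable end to end without external data.

## CLI

```sh
# synthetic corpus with planted effects (writes manifest, docs/, truth lexicon)
agestereo generate --seed 11 --out corpus/

# full pipeline: collocates → panel → trend → mediation → moderated mediation
agestereo run-all --manifest corpus/manifest.tsv \
    --lexicon corpus/truth_lexicon.tsv \
    --covariates tests/data/covariates.tsv \
    --out results/ --seed 17

# individual stages
agestereo collocate --manifest M.tsv --lexicon L.tsv --node elderly --out col/
agestereo score --collocates col/collocates.tsv --lexicon L.tsv \
    --covariates C.tsv --out panel.tsv
agestereo trend --panel panel.tsv --outcome sas --degree 2
agestereo pathmodel --panel panel.tsv --boot 5000 --seed 17
```

All outputs are TSV/JSON; rerunning with an identical configuration (and
seed) reproduces them byte for byte.

### Input formats

- **Corpus manifest** — TSV `doc_id, year, source, path` (paths relative to
  the manifest), or a JSONL file with `{id, year, source, text}` records.
- **Rating lexicon** — TSV `word, relevant, s_rater1..s_raterK,
  m_rater1..m_raterK` with sentiments in 1–5 and medical flags in {0, 1}.
- **Covariates** — TSV `year, support_ratio`. A 2010–2017 old-age
  support-ratio fixture ships with the package
  (`agestereo.scoring.packaged_support_ratio()`).

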