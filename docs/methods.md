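# Methods

## The analysis model

The package estimates the thematic composition of news narratives around a
target keyword in a multi-country corpus. The chain has five stages, each
with an explicit contract.

**Article selection.** An article is retained iff it contains a target term
as a whole surface token, case-insensitively. Selection runs on surface
forms, not lemmas, because it precedes lemmatization in the processing
order; consequently inflected variants ("pregnancies") do not trigger
selection by themselves, and semantically adjacent words ("maternity",
"motherhood") never do.

**Content filtering.** Tokens are words (maximal alphanumeric runs with
internal hyphens/apostrophes); tagging uses a coarse tagset
{ADJ, NOUN, PROPN, VERB, AUX, ADV, PRON, DET, CONJ, NUM, OTHER}. A token is
a *content word* iff its tag is in {ADJ, NOUN, VERB, ADV} and its lemma is
not *have*/*be*. Removal of proper nouns is tag-driven (every PROPN), not
gazetteer-driven, so the rule is reproducible without a name list. Digit
cardinals are tagged NUM and removed; number *words* ("two", "sixteen") are
tagged ADJ and retained as attributive quantifiers — in illustrative news
snippets a small count next to the keyword ("two pregnant women") is
exactly the kind of collocational signal the window stage should see. The
retained POS set is configurable (`keep_pos`).

The default tagger is the shipped rule-based backend: closed-class lexicons
(determiners, pronouns, conjunctions, adpositions, modals, *have*/*be*
forms), an irregular-lemma table, and suffix heuristics (-ed/-ing/-s
stripping with silent-e restoration; -ly → ADV; capitalized open-class
tokens → PROPN). It is deterministic, dependency-free, and bit-reproducible
across runs — properties the test suite relies on. Its known weaknesses:
sentence-initial capitalized content words are mis-tagged PROPN, unknown
lowercase words default to NOUN (harmless for content filtering, which
keeps NOUN anyway), and suffix lemmatization is approximate outside the
irregular table ("abortion-related" → "abortion-relate"). A statistical
backend (spaCy, when installed) is the documented alternative for real
corpora; selecting it without spaCy raises an error naming the fallback.

**Windowed collocates.** For each occurrence of a target lemma at content
position p, every content token at positions [p−6, p+6] \ {p} counts one
co-occurrence (Span = 2·6 = 12). Windows are counted on the *content*
stream by default: function words do not consume window slots, which is
what makes a collocate seven raw tokens away still "within six words" after
cleaning. The raw stream is available via `WindowSpec(stream="raw")`.
Windows never cross article boundaries; a target is never its own
collocate; both target terms pool into a single count table. Each
(target occurrence, collocate occurrence) pair counts once, so a token
between two nearby targets legitimately counts twice — the `C ≤ B`
inequality therefore holds only when target occurrences are at least a span
apart.

The association score is the base-2 log of the observed-to-expected
co-occurrence ratio, MI = log2((C·Size)/(A·B·Span)), with Size the total
content-token count. MI is undefined (an error, never a silent 0) when any
count is non-positive. The shortlist keeps MI ≥ 3 (inclusive), sorted by MI
descending with lexicographic tie-breaks. A useful structural fact: a
collocate that occurs *only* inside windows has C = B, so its MI equals the
ceiling log2(Size/(A·Span)); with one target per selected article this is
log2(L̄/Span) where L̄ is the mean content length of selected articles. The
threshold of 3 is thus only attainable at all when articles average more
than 2³·Span = 96 content tokens — true of real news articles and of the
synthetic defaults, and worth checking before applying the pipeline to
corpora of very short texts.

**Topic model.** LDA on per-article bags of shortlisted window collocates
(the document unit is the article — the only unit the metadata supports).
The estimator is collapsed Gibbs sampling: θ and φ are integrated out and
each token's topic is resampled from
p(z=k|·) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ) with the token's own count removed.
The point estimate is the final state (no averaging); the collapsed joint
log-likelihood is traced every sweep as a convergence diagnostic.
Implementation choices that matter:

- *Determinism.* One PCG64 stream, consumed in a canonical document order
  (sorted by `doc_id`), drives initialization and all sweeps: a fixed seed
  gives a bit-identical state, and permuting the input document order
  changes nothing but the row order of document-indexed outputs.
- *Label switching* is handled by a deterministic presentation order:
  topics are relabeled by descending token count after fitting.
- *Restarts.* `fit(n_restarts=r)` runs r independently seeded chains and
  keeps the best final log-likelihood. Single chains occasionally settle in
  a topic-merged local mode; three restarts removed every such case in the
  recovery experiments.
- *Defaults*: K = 10 per stratum (ten topics per region), α = 50/K,
  β = 0.01, 1000 sweeps with 500 burn-in — conventional values for long
  documents. For the short bags this pipeline produces (a handful of window
  collocates per article), a much sparser document prior is appropriate;
  the recovery experiments use α = 0.1. All are configurable.
- The inner sweep is numba-compiled; uniforms are pre-drawn per sweep from
  the numpy generator so the RNG remains outside the kernel.

Empty bags (articles whose windows contain no shortlisted lemma) are
recorded, logged, excluded from fitting, and never appear as exemplars.
States serialize to a flat JSON document (counts, assignments, config,
seed) for exact inspection and byte-level comparison; JSON is deliberately
chosen over a binary format — states at this scale are small and a text
artifact diffs cleanly.

**Themes.** A theme is a human label over one or more topics. The package
never auto-labels real corpora: `labeling_report()` emits, per topic, the
top-20 smoothed word probabilities ((n_kw+β)/(n_k+Vβ)) and the ten
articles with the highest estimated topic share, and the resulting
topic→theme mapping is read from an editable YAML file; unlabeled topics
fall to "other". Prevalence of a theme in a stratum is the share of fitted
collocate tokens whose final assignment carries the theme (a document-level
alternative — dominant theme per article — is available via
`unit="documents"` for sensitivity analysis). Shares are percentages and
sum to 100 per stratum by construction. Strata are the five regions plus a
pooled "ALL"; pooling concatenated per-stratum assignments equals the
token-count-weighted mean of stratum shares.

## The synthetic corpus generator

Real multi-country news corpora are licensed; the generator produces
ground-truthed stand-ins that exercise every pipeline stage.

Per document: a region determines a theme (by default via stratified quota
allocation — largest-remainder rounding of the region's theme weights,
shuffled — so a region's realized composition equals its weights by design,
as in fixed-arm simulation studies; iid per-document sampling is available
with `quota_themes=False`); a topic mixture θ is drawn Dirichlet(α) over
the theme's topics; content tokens are drawn from per-topic word
distributions φ over a synthetic vocabulary (`w0000`…). With probability
`target_insertion_rate` a target term is inserted with `n_planted`
collocates from the theme's signature vocabulary (readable words like
*miscarriage*, *murder*, *announce*, *duchess*, *abortion*) placed
contiguously around it — guaranteeing every planted collocate lies within
±6 content positions. Function words from the shipped closed-class list are
interleaved at `function_word_rate`. Country, ISO date (2019), title and
source metadata are attached; a fixed seed yields a byte-identical corpus.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `K` | 10 | ten topics per stratum, two per theme |
| `V_content` | 200 | enough vocabulary for sparse, distinct topics |
| `doc_length_mean` | 150 | news-article scale; puts the MI ceiling log2(L̄/12) ≈ 3.6 above the shortlist threshold |
| `alpha` | 0.1 | sparse per-document topic mixtures |
| `phi_concentration` | 0.05 | sparse, well-separated topic-word rows |
| `signature_mass` | 0.0 | signature words occur *only* as planted window collocates, the constructive meaning of "planted"; raising it blends them into general topic vocabulary (and, at news scale, below the MI threshold) |
| `target_insertion_rate` | 0.4 | a realistic minority of articles mention the keyword, so selection has work to do |
| `function_word_rate` | 0.45 | the approximate function-word share of running English text |
| region theme weights | cyclic shifts of (0.33, 0.27, 0.20, 0.13, 0.07) | every adjacent gap ≥ 6 points → each region has an unambiguous theme ranking |

The `GroundTruth` object records φ, θ, per-region weights, seeded document
ids, planted pairs, and each document's exact content-token sequence, so
tests can compare pipeline output against generator bookkeeping rather than
re-deriving it. `sample_lda_corpus` additionally draws bag corpora straight
from the LDA generative model (no documents, no windows) for
estimator-recovery experiments. `signature_theme_mapping` maps fitted
topics to themes by signature-word probability mass — a ground-truth
evaluation shortcut for synthetic corpora, not an auto-labeler.

What the generator does *not* emulate: natural-language syntax and word
order, topical drift within an article, named entities, country-level
(rather than region-level) variation in theme weights, bursty word usage,
and the heavy-tailed source/length distributions of real news. Passing
tests therefore certify the *mechanics* of the pipeline — counting,
scoring, sampling, stratification, determinism — and its statistical
behavior under the assumed generative model; they do not certify tagger
accuracy or topic interpretability on real prose.

## Verification experiments and problem sizes

The acceptance suite (and `scripts/acceptance.py`) runs five experiments,
sized to finish in a few minutes on one CPU:

- *MI oracle*: 25 random toy corpora (≤ ~1000 tokens each) against a naive
  O(n²) position-pair reference; agreement to 1e-12.
- *Gibbs kernel*: a frozen 2-document, 3-word instance; 50,000 single-site
  draws against the enumerated full conditional (chi-square).
- *Topic recovery*: K = 5, V = 200, D = 500, mean length 100, α = 0.1;
  10 corpora, 300 sweeps, 3 restarts; Hungarian-matched mean cosine ≥ 0.8.
- *Theme recovery*: five regions × 300 articles, every article seeded
  (`target_insertion_rate=1`, matching a post-selection corpus), K = 10,
  α = 0.1, 200 sweeps; rank order and share error per region. The sample
  size follows a power argument: for rankings with 6-point gaps to be
  stable, the share s.e. (≈ √(w(1−w)/n)) must stay well under 2 points.
- *Determinism*: two identical-seed end-to-end runs compared byte-for-byte
  (collocate CSV, serialized state, prevalence table).

## Known limitations

- The rule-based tagger is built for reproducibility, not accuracy; real
  corpora should use a statistical backend and expect small shifts in the
  content stream.
- MI with threshold 3 is the only association measure; low-frequency
  collocates (B = C = 1) can tie the MI ceiling and enter the shortlist —
  a minimum-frequency cut is deliberately not applied.
- Topic count K is fixed per stratum, not selected; no hyperparameter
  optimization; no statistical testing of between-region share differences
  (the pipeline reports descriptive shares only).
- English-only; article-level documents; one pooled shortlist for both
  target terms.
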