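# Methods

This note documents the models, conventions and design choices behind
`nerprompt`, what the synthetic benchmark does and does not emulate, and
the numerical details a user reproducing or extending the results needs.

## Data model and tagging conventions

A `Sentence` is a tuple of non-empty tokens with one IOB2 tag per token
(`O`, `B-<type>`, `I-<type>`); entity type names are word characters
(letters, digits, underscore — hyphens are reserved as the tag
separator). Entities are maximal `B`/`I` runs of a single type,
represented as 0-based half-open token spans `[start, end)`; half-open
spans make lengths and adjacency arithmetic unambiguous. An `I-` tag
whose predecessor is not a same-type `B-`/`I-` is an IOB2 violation; the
default policy rewrites it to `B-` with a logged warning (the
conventional IOB2 repair), and a strict mode rejects the input instead.
CoNLL reading validates every label against the tag grammar and reports
hard errors with line numbers.

## The token–label codec

Prompts instruct the model to return a JSON array with one
`token-label` string per input token (`codeine-B-Clinical_Impacts`).
Decoding splits each item at the **last** position whose suffix is a
valid IOB2 tag: because the tag grammar is a suffix language and type
names exclude hyphens, the rightmost match is unique, which resolves
hyphen-bearing tokens (`co-codamol-B-Drug`) and both separator dialects
seen in model output — with a separating hyphen and with the tag
appended directly (`addict.I-Clinical_Impacts`). Encoding always emits
the hyphenated form; decoding accepts both without claiming either is
canonical upstream.

Decoding is total. Unparseable items become `O`; when the item count
differs from the token count, items are aligned to tokens by greedy
left-to-right exact text match, gaps are filled with `O`, and excess
items are dropped; orphaned `I-` tags are repaired to `B-`. Every
intervention is counted in a repair log, and the repair count is zero
iff the output is well-formed and length-matched — the property the
round-trip tests pin down.

## Prompt structure

A prompt is a fixed-order document: baseline block (task description,
entity definitions, output format) → dataset description →
high-frequency instances → background knowledge → error feedback →
examples → input. Rendering is a pure function of its arguments, so
identical configurations produce byte-identical prompts (hashable, hence
cacheable and replayable). Optional blocks render only when set; the
ablation conditions (`BP`, `BP+<component>`, `BP+All`) are masks over a
fully-populated component set.

High-frequency instances are the top-6 most frequent tokens inside
spans of each class, lowercased, ties broken lexicographically for
determinism. Unigram tokens are counted; whole sub-phrases can be
included via the `ngram` flag, but the unigram reading is the default.
Background knowledge is an opaque text slot — the package performs no
terminology-base extraction (licensing, and the component is the one
most often observed to *hurt* performance).

Retrieved examples are ordered most-similar-**last**, so the closest
example sits adjacent to the input; context windows weight recent
content, and no upstream convention dictates an order. Static example
selection supports both global uniform draws and per-label stratified
draws (k sentences containing each type); the static ablation defaults
to per-label, the dynamic designs count shots in total.

## Retrieval engines

Retrieval text is the lowercased, whitespace-joined gold tokens —
corpora are pre-tokenized, so no second tokenizer is introduced.

* **tfidf** — raw within-sentence term counts weighted by smoothed
  inverse document frequency `idf(t) = ln((1+N)/(1+df(t))) + 1`,
  L2-normalized, cosine similarity. The variant is *declared*, not
  inferred: some fixed choice is required for testability, and this one
  is the common smoothed default. scikit-learn's vectorizer provides
  exactly this weighting; a hand-rolled matrix serves as the independent
  oracle in tests.
* **dual_encoder** — one vector per sentence from separate query and
  document encoder calls, inner product (cosine under the default
  normalization), the dense-passage-retrieval scoring scheme.
* **late_interaction** — per-token vectors, scored by MaxSim:
  `Σ_i max_j q_i·d_j`, the ColBERT-style interaction.
* **lexical** — Jaccard overlap of token sets; the floor any semantic
  engine should beat.

Ties are broken by pool order (stable sort), so retrieval is
deterministic; subsampled pools preserve the original sentence order so
tie-breaking stays stable under the pool-size ablation. Query
self-exclusion is off by default (test inputs are unseen at inference)
and available for leave-one-out diagnostics. Pools are small by design;
scoring is exhaustive, with no approximate-nearest-neighbor structure.

No pretrained encoder ships with the package. Dense engines accept any
object with `sentence_vector(text)` and `token_vectors(tokens)`; the
built-in `HashingEncoder` maps each token to a fixed unit vector drawn
from a generator seeded by a stable content hash — deterministic across
processes and platforms, with no semantic structure. It exists to make
dense-engine *mechanics* exactly testable; it does not emulate semantic
similarity, so conclusions about semantic encoders' advantages on
paraphrased text do not follow from these tests.

## The mock annotator

`MockBackend` parses the structured prompt (the `Input:` lines), looks
up the gold labels of the input from a registry (a privilege a test
double is allowed), and labels each token correctly with probability
`p = clamp(p0 + α·rel, 0, 1)`, otherwise drawing a uniformly random
wrong label; with probability `q` an item is dropped or emitted without
a tag, exercising codec repair. `rel` is the maximum Jaccard overlap of
lowercased token sets between the input and the prompt's examples —
deliberately engine-independent and sharing no code with any retrieval
engine under test, yet positively correlated with every engine's notion
of similarity. Expected accuracy is therefore monotone in example
relevance, which turns "retrieval beats random example selection" into
a quantitative, seeded, offline property.

Randomness derives from the oracle seed *and* the content of the input
and example sets (hashed): fully deterministic per seed, while two
experimental arms that show the same input with different examples draw
independent noise. This matters for the null control — with `α = 0` the
arms must be statistically indistinguishable but not byte-identical,
otherwise "within two standard errors" is vacuous.

Default noise levels for the benchmark experiments are `p0 = 0.5`,
`α = 0.4`, `q = 0.05`: a weak-but-usable annotator whose ceiling
(`rel = 1`) is 90% token accuracy, with enough format noise to keep the
repair path honest. Because wrong labels are drawn uniformly (including
spurious `B-`/`I-` tags on background tokens), strict entity-level
precision is low in absolute terms; the designs compare arms under
identical noise, so the quantity of interest is the gap, not the level.

## Evaluation

Scoring is strict and micro-averaged: a predicted entity is correct only
if `(start, end, type)` all match a gold entity; tp/fp/fn are pooled
over sentences and types before the ratios. Confidence intervals use a
percentile bootstrap with 1000 resamples at the 95% level; the
resampling unit is the **sentence**, respecting within-sentence
dependence between entities (neither the resampling unit nor the
interval method is dictated upstream; sentence-level percentile is the
defensible default). Resampling operates on precomputed per-sentence
(tp, fp, fn) triples, so 1000 resamples of hundreds of sentences are a
single vectorized pass. With fewer than two sentences the interval is
degenerate and flagged. Multi-run results are arithmetic means of
P/R/F1 across runs with per-run values retained; every aggregate row in
an experiment table is checked against the mean of its stored per-run
rows at write time.

A coverage simulation (each sentence carrying one gold span, predicted
correctly with probability a = 0.7, else with shifted boundaries, so the
asymptotic micro-F1 equals a; 100 sentences per dataset, 500 datasets)
puts empirical coverage of the 95% interval at ~95%.

## Synthetic corpora

The generator emulates the statistical skeleton real annotated corpora
share: sparse entities (each sentence carries one mention with
probability `entity_rate`, giving a binomial corpus total), per-type
lexicons whose entries are used with Zipf-skewed frequency (exponent
1.2 — a few canonical mentions dominate), multi-token mentions labeled
`B, I, …`, and a diversity knob: with probability `diversity` a mention
surfaces as one of its paraphrases instead of its canonical form, which
lowers token overlap between same-type mentions
(`mention_overlap_statistic` measures this directly). Background tokens
come from a vocabulary disjoint from all entity lexicons, so
entity/background confusion is controlled and retrieval-relevance
effects are isolated.

Defaults (3 types, 8 entries per lexicon, mentions of 1–2 tokens, 3
paraphrases per entry, sentence lengths 6–14, background vocabulary
200, `entity_rate = 0.7`, `diversity = 0.3`) describe a small,
moderately redundant annotation project. What the generator does *not*
emulate: real clinical language, ambiguous mention boundaries, nested
or overlapping entities, type confusability, and any semantic
relationship between paraphrases that a real encoder could exploit.
Passing end-to-end tests therefore demonstrate the pipeline's
correctness and the direction of retrieval effects under a controlled
noise model — not performance on clinical text.

## Experiment designs and problem sizes

The three designs mirror the standard protocol for this kind of study:
component ablation with examples redrawn per run (4 runs), engine × shot
dynamic comparison with a random-example comparator arm, and the
pool-size ablation (50/100/200/ALL, two independent subsamples each,
means reported). `pool = ALL` reduces to the plain dynamic design by
construction and is asserted to be identical under fixed seeds.

The benchmark experiments in the test suite and acceptance script run on
a 1000-sentence corpus split evenly into a 500-sentence retrieval pool
and a 500-sentence test set, with 20 replicate seeds for the
retrieval-benefit and pool-size comparisons — sizes at which every
quantity of interest is stable (the TF-IDF-vs-random gap is roughly
eight standard errors) while a full run completes in minutes on one
CPU.

Every experiment emits a tidy long-format table and a `RunLedger`
(config snapshot, per-run reports, request hashes). Tables regenerate
bit-identically from the ledger with the mock backend and the same
seeds, or from a recorded response cache in replay mode with zero
backend calls — the audit trail for any reported number.

## Known limitations

* The fixture encoder has no semantics; claims about dense retrievers on
  linguistically diverse data cannot be established with it.
* Sentence-mode prompting still evaluates against the dataset's gold
  tokenization; no re-tokenization of model free text is attempted.
* The greedy length-mismatch alignment assumes the model mostly echoes
  tokens verbatim; heavily hallucinated outputs decay to all-`O`.
* Per-type score breakdowns are available via the span sets but the
  reported metric is the single pooled micro-F1.
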