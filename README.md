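# nerprompt

Few-shot biomedical named entity recognition (NER) with structured and
retrieval-augmented prompts.

Generative LLMs can extract typed entity mentions — drugs, diseases,
clinical impacts — from biomedical text with only a handful of annotated
examples in the prompt, but their performance depends heavily on *how*
the prompt is built and *which* examples it carries. `nerprompt`
implements that pipeline end to end for people studying or deploying
prompt-based NER:

* **Structured static prompts** assembled from six composable blocks:
  task description + entity definitions + output-format specification
  (the baseline), dataset description, per-class high-frequency
  instances (the top-6 most frequent entity tokens per class from the
  training data), background domain knowledge, error-analysis feedback,
  and k annotated in-context examples.
* **Dynamic (retrieval-augmented) prompts** whose example slot is filled
  per input with the top-n most similar annotated sentences, under four
  retrieval engines: sparse TF-IDF cosine, a dual-encoder inner product
  (DPR-style), late-interaction MaxSim over token vectors
  (ColBERT-style), and a Jaccard lexical-overlap baseline.
* **A token–label codec**: the model is asked to echo each input token
  concatenated with its IOB2 tag (`codeine-B-Clinical_Impacts`), which
  pins the number of predicted labels to the number of tokens; decoding
  is total and repairs malformed output instead of failing.
* **Strict entity-level evaluation**: a prediction counts only when span
  boundaries *and* type exactly match; micro-averaged precision / recall
  / F1 with percentile-bootstrap 95% confidence intervals (1000
  resamples of sentences) and multi-run averaging.
* **Offline testability**: a seeded synthetic BIO-corpus generator and a
  deterministic, relevance-sensitive mock LLM whose per-token accuracy is
  `p = clamp(p0 + α·rel, 0, 1)`, where `rel` is the best Jaccard token
  overlap between the input and the in-context examples — so "relevant
  examples help" is a measurable, reproducible effect with no API access.

No pretrained weights, datasets, or network access are required; real
models and encoders plug in through small contracts
(`llm_interface.Backend`, `retrieval.EncoderContract`).

## The statistic at the core

For gold span set *G* and predicted span set *P*, pooled over all test
sentences (micro-averaging):

    tp = |G ∩ P|   (exact (start, end, type) equality)
    Precision = tp / |P|,  Recall = tp / |G|,  F1 = 2PR / (P + R)

TF-IDF similarity is fixed to raw term counts with smoothed inverse
document frequency `idf(t) = ln((1+N)/(1+df(t))) + 1` and L2-normalized
cosine; MaxSim is `Σ_i max_j q_i · d_j` over query/document token
vectors.

## Worked example

Generate a synthetic corpus, split it into a retrieval pool and a test
set, and compare TF-IDF dynamic 5-shot prompting against a
random-example static arm under the relevance-sensitive mock:

```python
from nerprompt import (
    MockOracleConfig, baseline_components, generate_corpus, make_default_spec,
    mock_client_factory, run_dynamic, split_train_test,
)

corpus = generate_corpus(make_default_spec(n_sentences=400, seed=0))
train, test = split_train_test(corpus, seed=0)
components = baseline_components(sorted(corpus.entity_types))
oracle = MockOracleConfig(base_accuracy=0.5, relevance_gain=0.4, format_noise=0.05)
clients = mock_client_factory(oracle, [train, test])
table, ledger = run_dynamic(
    train, test, components, clients,
    engines=("tfidf",), shots=(5,), runs=4, seeds=[0, 1, 2, 3],
)
print(table[table.run == "mean"].to_string(index=False))
```

which prints

```
condition  run    metric    value
  tfidf@5 mean precision 0.078215
  tfidf@5 mean    recall 0.471698
  tfidf@5 mean        f1 0.134174
 random@5 mean precision 0.072463
 random@5 mean    recall 0.476415
 random@5 mean        f1 0.125772
```

Each row is the mean over the four seeded runs. The mock annotator is
deliberately noisy (50% base token accuracy plus a relevance bonus), so
absolute scores are low; the point is the *gap*: TF-IDF retrieval lifts
mean F1 over random example selection because retrieved examples share
entity vocabulary with the input, raising the mock's per-token accuracy
— the same mechanism by which real LLMs benefit from relevant in-context
examples. With `relevance_gain=0` the gap vanishes (a built-in null
control).

The same experiments are available from the shell:

```bash
nerprompt generate --n-sentences 400 --seed 0 --out corpus.conll
nerprompt dynamic corpus.conll --engines tfidf,lexical --shots 5,10
nerprompt pool-ablation corpus.conll --sizes 50,100,200,ALL
nerprompt score gold.conll predictions.conll
```

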