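"""Seeded synthetic BIO corpora for offline testing.

The generator emulates the statistical skeleton of an annotated
biomedical NER corpus: sentences of variable length drawn from a
background vocabulary, sparse entity mentions whose surface forms come
from per-type lexicons with Zipf-skewed usage (a few canonical mentions
dominate, a long tail is rare), multi-token mentions, and a *lexical
diversity* knob — the probability that a mention appears as one of its
paraphrases rather than its canonical form.  At ``diversity=0`` every
mention of a lexicon entry is its canonical surface form, so lexical
retrieval finds same-entity examples trivially; as ``diversity`` rises,
token overlap between same-type mentions falls, the regime where
semantic encoders are claimed to help.

Background tokens are drawn from a vocabulary disjoint from every entity
lexicon, so entity/background confusion is controlled and retrieval
relevance effects are isolated.  Everything is deterministic per seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, Sentence


@dataclass(frozen=True)
class LexiconEntry:
    """One concept: a canonical surface form plus optional paraphrases.

    Surface forms are token tuples; multi-token forms become B,I,…
    mention spans.
    """

    canonical: tuple[str, ...]
    paraphrases: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValueError("canonical form must be non-empty")


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to (re)generate a corpus deterministically."""

    n_sentences: int = 200
    length_range: tuple[int, int] = (6, 14)
    lexicons: Mapping[str, tuple[LexiconEntry, ...]] = field(default_factory=dict)
    entity_rate: float = 0.7
    zipf_exponent: float = 1.2
    diversity: float = 0.3
    background_vocab_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.entity_rate <= 1.0):
            raise ValueError("entity_rate must be in [0, 1]")
        if not (0.0 <= self.diversity <= 1.0):
            raise ValueError("diversity must be in [0, 1]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        if self.background_vocab_size < 1:
            raise ValueError("background_vocab_size must be >= 1")
        for etype, entries in self.lexicons.items():
            if not entries:
                raise ValueError(f"empty lexicon for type {etype!r}")

    @property
    def entity_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.lexicons))


def make_default_spec(
    n_sentences: int = 200,
    n_types: int = 3,
    lexicon_size: int = 8,
    n_paraphrases: int = 3,
    max_mention_tokens: int = 2,
    **overrides,
) -> GeneratorSpec:
    """A ready-made spec with programmatically built disjoint lexicons.

    Entity tokens are synthetic words like ``t0e2a`` (type 0, entry 2,
    first token), paraphrase tokens like ``t0e2p1a`` — all disjoint from
    the background vocabulary (``w0``, ``w1``, …).
    """
    lexicons: dict[str, tuple[LexiconEntry, ...]] = {}
    for t in range(n_types):
        entries = []
        for e in range(lexicon_size):
            width = 1 + (e % max_mention_tokens)
            canonical = tuple(f"t{t}e{e}{chr(97 + w)}" for w in range(width))
            paraphrases = tuple(
                tuple(f"t{t}e{e}p{p}{chr(97 + w)}" for w in range(width))
                for p in range(n_paraphrases)
            )
            entries.append(LexiconEntry(canonical, paraphrases))
        lexicons[f"TYPE{t}"] = tuple(entries)
    return GeneratorSpec(n_sentences=n_sentences, lexicons=lexicons, **overrides)


def zipf_weights(n: int, exponent: float) -> np.ndarray:
    """Normalized Zipf rank weights ``1/rank**exponent``."""
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def generate_corpus(spec: GeneratorSpec) -> Corpus:
    """Generate a valid BIO corpus; deterministic per ``spec.seed``.

    Each sentence independently carries one entity mention with
    probability ``entity_rate`` (type uniform, lexicon entry Zipf-skewed
    by rank, surface form canonical or a uniform paraphrase per
    ``diversity``), inserted at a random position among background
    tokens.
    """
    rng = np.random.default_rng(spec.seed)
    background = [f"w{i}" for i in range(spec.background_vocab_size)]
    types = spec.entity_types
    max_mention = max(
        (
            len(form)
            for entries in spec.lexicons.values()
            for entry in entries
            for form in (entry.canonical, *entry.paraphrases)
        ),
        default=0,
    )
    if types and max_mention > spec.length_range[1]:
        raise ValueError(
            f"longest mention ({max_mention} tokens) exceeds max sentence "
            f"length {spec.length_range[1]}"
        )
    weights = {
        etype: zipf_weights(len(entries), spec.zipf_exponent)
        for etype, entries in spec.lexicons.items()
    }
    lo, hi = spec.length_range
    sentences: list[Sentence] = []
    for i in range(spec.n_sentences):
        length = int(rng.integers(lo, hi + 1))
        tokens = [background[j] for j in rng.integers(0, len(background), size=length)]
        labels = ["O"] * length
        if types and rng.random() < spec.entity_rate:
            etype = types[rng.integers(len(types))]
            entries = spec.lexicons[etype]
            entry = entries[rng.choice(len(entries), p=weights[etype])]
            if entry.paraphrases and rng.random() < spec.diversity:
                form = entry.paraphrases[rng.integers(len(entry.paraphrases))]
            else:
                form = entry.canonical
            # ensure the mention fits, growing the sentence if needed
            if len(form) > length:
                extra = [
                    background[j]
                    for j in rng.integers(0, len(background), size=len(form) - length)
                ]
                tokens += extra
                labels += ["O"] * len(extra)
                length = len(tokens)
            pos = int(rng.integers(0, length - len(form) + 1))
            tokens[pos : pos + len(form)] = list(form)
            labels[pos : pos + len(form)] = [f"B-{etype}"] + [
                f"I-{etype}"
            ] * (len(form) - 1)
        sentences.append(Sentence(f"g{spec.seed}_{i}", tuple(tokens), tuple(labels)))
    return Corpus(tuple(sentences), provenance=f"synthetic(seed={spec.seed})")


def split_train_test(
    corpus: Corpus, fractions: tuple[float, float] = (0.8, 0.2), seed: int = 0
) -> tuple[Corpus, Corpus]:
    """Disjoint, exhaustive, seeded random split of a corpus."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(corpus)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    train_idx = sorted(perm[:n_train])
    test_idx = sorted(perm[n_train:])
    prov = corpus.provenance
    return (
        Corpus(tuple(corpus[i] for i in train_idx), provenance=f"{prov}[train]"),
        Corpus(tuple(corpus[i] for i in test_idx), provenance=f"{prov}[test]"),
    )


def mention_overlap_statistic(corpus: Corpus, max_pairs: int = 5000, seed: int = 0) -> float:
    """Mean pairwise Jaccard token overlap between same-type mentions.

    The diagnostic behind the diversity knob: near 1 at ``diversity=0``
    for single-entry comparisons, falling as paraphrase use rises.
    Subsamples pairs when there are more than ``max_pairs``.
    """
    from .corpus_io import extract_entities

    mentions: dict[str, list[frozenset[str]]] = {}
    for s in corpus:
        for sp in extract_entities(s):
            mentions.setdefault(sp.etype, []).append(
                frozenset(t.lower() for t in s.tokens[sp.start : sp.end])
            )
    pairs = [
        (a, b)
        for forms in mentions.values()
        for a, b in itertools.combinations(forms, 2)
    ]
    if not pairs:
        return float("nan")
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    return float(
        np.mean([len(a & b) / len(a | b) for a, b in pairs])
    )
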