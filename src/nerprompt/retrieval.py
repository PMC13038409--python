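"""Similarity search over annotated sentences for dynamic prompting.

Four engines are provided:

* ``tfidf`` — sparse term weighting with L2-normalized cosine similarity.
  The variant is fixed for testability: raw within-sentence term counts,
  smoothed inverse document frequency ``idf(t) = ln((1+N)/(1+df(t))) + 1``.
* ``dual_encoder`` — one vector per sentence from separate query/document
  encoders, compared by inner product (cosine when normalized, the
  default), in the style of dense passage retrieval.
* ``late_interaction`` — per-token vectors compared by MaxSim: the sum
  over query tokens of each token's best dot product against any document
  token, in the style of ColBERT.
* ``lexical`` — Jaccard overlap of lowercased token sets; the trivial
  overlap baseline.

Retrieval text is the lowercased whitespace-joined gold tokens (corpora
are pre-tokenized).  Ties are broken by pool order, so retrieval is
deterministic.  No pretrained weights ship with the package: dense
engines take any object satisfying :class:`EncoderContract`, and the
deterministic :class:`HashingEncoder` serves as the built-in fixture.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus_io import Corpus, Sentence

logger = logging.getLogger("nerprompt")

ENGINES = ("tfidf", "dual_encoder", "late_interaction", "lexical")


class EncoderContract(Protocol):
    """What a dense engine needs from an encoder.

    Real pretrained sentence/token encoders can be plugged in by
    implementing these two methods; the package itself ships only the
    deterministic hashing fixture.
    """

    def sentence_vector(self, text: str) -> np.ndarray:  # (dim,)
        ...

    def token_vectors(self, tokens: Sequence[str]) -> np.ndarray:  # (n, dim)
        ...


class HashingEncoder:
    """Deterministic hash-to-vector encoder (test fixture, no downloads).

    Each distinct token maps to a fixed unit vector drawn from a RNG
    seeded by a stable hash of ``(seed, token)``; a sentence vector is
    the L2-normalized mean of its token vectors.  Identical texts always
    encode identically, across processes and platforms.
    """

    def __init__(self, dim: int = 64, seed: int = 0) -> None:
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _token_vec(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.sha256(f"{self.seed}\x00{token}".encode()).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
            vec = rng.standard_normal(self.dim)
            vec /= np.linalg.norm(vec)
            self._cache[token] = vec
        return vec

    def token_vectors(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            raise ValueError("empty token sequence")
        return np.stack([self._token_vec(t.lower()) for t in tokens])

    def sentence_vector(self, text: str) -> np.ndarray:
        vecs = self.token_vectors(text.lower().split())
        mean = vecs.mean(axis=0)
        norm = np.linalg.norm(mean)
        return mean / norm if norm > 0 else mean


def sentence_text(sentence: Sentence) -> str:
    """Canonical retrieval text: lowercased whitespace-joined gold tokens."""
    return " ".join(t.lower() for t in sentence.tokens)


# ---------------------------------------------------------------------------
# Pairwise scoring primitives
# ---------------------------------------------------------------------------

def score_dual_encoder(
    query_vec: np.ndarray, doc_vec: np.ndarray, normalize: bool = True
) -> float:
    """Inner product of the two sentence vectors (cosine if normalized)."""
    q = np.asarray(query_vec, dtype=float)
    d = np.asarray(doc_vec, dtype=float)
    if q.shape != d.shape:
        raise ValueError(f"dimension mismatch: {q.shape} vs {d.shape}")
    if normalize:
        qn, dn = np.linalg.norm(q), np.linalg.norm(d)
        if qn > 0:
            q = q / qn
        if dn > 0:
            d = d / dn
    return float(q @ d)


def score_late_interaction(
    query_token_vecs: np.ndarray, doc_token_vecs: np.ndarray
) -> float:
    """MaxSim: sum over query tokens of the best dot product in the doc."""
    q = np.atleast_2d(np.asarray(query_token_vecs, dtype=float))
    d = np.atleast_2d(np.asarray(doc_token_vecs, dtype=float))
    if q.size == 0 or d.size == 0:
        raise ValueError("token vector sets must be non-empty")
    if q.shape[1] != d.shape[1]:
        raise ValueError(f"dimension mismatch: {q.shape[1]} vs {d.shape[1]}")
    return float((q @ d.T).max(axis=1).sum())


def score_lexical(query_tokens: Sequence[str], doc_tokens: Sequence[str]) -> float:
    """Jaccard overlap of lowercased token sets."""
    a = {t.lower() for t in query_tokens}
    b = {t.lower() for t in doc_tokens}
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------

@dataclass
class RetrievalIndex:
    """Precomputed engine state over a pool of annotated sentences."""

    pool: tuple[Sentence, ...]
    engine: str
    encoder: EncoderContract | None = None
    vectorizer: TfidfVectorizer | None = field(default=None, repr=False)
    doc_matrix: np.ndarray | None = field(default=None, repr=False)  # tfidf / dual
    doc_token_vecs: tuple[np.ndarray, ...] | None = field(default=None, repr=False)
    doc_token_sets: tuple[frozenset[str], ...] | None = field(default=None, repr=False)

    @property
    def vocab(self) -> dict[str, int] | None:
        """Term → column mapping (sparse engines only)."""
        if self.vectorizer is None:
            return None
        return dict(self.vectorizer.vocabulary_)


@dataclass(frozen=True)
class ScoredExample:
    """One retrieved sentence with its similarity score and 1-based rank."""

    sentence: Sentence
    score: float
    rank: int


def build_index(
    pool: Sequence[Sentence] | Corpus,
    engine: str = "tfidf",
    encoder: EncoderContract | None = None,
) -> RetrievalIndex:
    """Index a pool of annotated sentences for one engine.

    The state is deterministic given ``(pool, engine, encoder)`` and
    covers exactly the pool; rebuild after any pool change.
    """
    sentences = tuple(pool)
    if not sentences:
        raise ValueError("retrieval pool must be non-empty")
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    texts = [sentence_text(s) for s in sentences]

    if engine == "tfidf":
        vectorizer = TfidfVectorizer(
            analyzer=str.split,  # corpora are pre-tokenized; split on whitespace
            lowercase=False,  # texts are already lowercased
            norm="l2",
            smooth_idf=True,  # idf = ln((1+N)/(1+df)) + 1
            sublinear_tf=False,
        )
        matrix = vectorizer.fit_transform(texts).toarray()
        return RetrievalIndex(sentences, engine, vectorizer=vectorizer, doc_matrix=matrix)

    if engine == "dual_encoder":
        if encoder is None:
            raise ValueError("dual_encoder engine requires an encoder")
        vecs = np.stack([encoder.sentence_vector(t) for t in texts])
        return RetrievalIndex(sentences, engine, encoder=encoder, doc_matrix=vecs)

    if engine == "late_interaction":
        if encoder is None:
            raise ValueError("late_interaction engine requires an encoder")
        tok_vecs = tuple(encoder.token_vectors(t.split()) for t in texts)
        return RetrievalIndex(sentences, engine, encoder=encoder, doc_token_vecs=tok_vecs)

    # lexical
    sets = tuple(frozenset(t.split()) for t in texts)
    return RetrievalIndex(sentences, engine, doc_token_sets=sets)


def score_tfidf(query_terms: Sequence[str], doc_index: int, index: RetrievalIndex) -> float:
    """Cosine similarity between a query and one indexed document."""
    if index.engine != "tfidf" or index.vectorizer is None or index.doc_matrix is None:
        raise ValueError("index is not a tfidf index")
    text = " ".join(t.lower() for t in query_terms)
    qvec = index.vectorizer.transform([text]).toarray()[0]
    return float(qvec @ index.doc_matrix[doc_index])


def score_all(index: RetrievalIndex, query: Sentence) -> np.ndarray:
    """Engine score of the query against every pool document."""
    text = sentence_text(query)
    if index.engine == "tfidf":
        qvec = index.vectorizer.transform([text]).toarray()[0]
        return index.doc_matrix @ qvec
    if index.engine == "dual_encoder":
        qvec = index.encoder.sentence_vector(text)
        return np.array(
            [score_dual_encoder(qvec, d, normalize=True) for d in index.doc_matrix]
        )
    if index.engine == "late_interaction":
        qvecs = index.encoder.token_vectors(text.split())
        return np.array(
            [score_late_interaction(qvecs, d) for d in index.doc_token_vecs]
        )
    # lexical
    qset = set(text.split())
    return np.array(
        [
            len(qset & s) / len(qset | s) if (qset or s) else 0.0
            for s in index.doc_token_sets
        ]
    )


def retrieve(
    index: RetrievalIndex,
    query_sentence: Sentence,
    n: int,
    exclude_self: bool = False,
) -> tuple[ScoredExample, ...]:
    """Top-``n`` pool sentences by engine score, most similar first.

    Ties break by pool order.  ``exclude_self`` drops pool sentences whose
    tokens equal the query's exactly (leave-one-out diagnostics); ``n``
    larger than the pool is clamped with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scores = score_all(index, query_sentence)
    candidates = np.arange(len(index.pool))
    if exclude_self:
        keep = np.array(
            [index.pool[i].tokens != query_sentence.tokens for i in candidates]
        )
        candidates = candidates[keep]
        scores = scores[keep]
    if n > len(candidates):
        logger.warning(
            "requested n=%d > pool of %d; clamping", n, len(candidates)
        )
        n = len(candidates)
    # stable argsort on -score preserves pool order for equal scores
    order = np.argsort(-scores, kind="stable")[:n]
    return tuple(
        ScoredExample(index.pool[candidates[i]], float(scores[i]), rank)
        for rank, i in enumerate(order, start=1)
    )


def subsample_pool(corpus: Corpus, size: int | None, seed: int) -> Corpus:
    """Seeded uniform subsample of the training corpus, without replacement.

    ``size=None`` (ALL) returns the full corpus unchanged.  Selected
    sentences keep their original relative order so pool-order tie-breaks
    stay stable under subsampling.
    """
    if size is None or size == len(corpus):
        return corpus
    if size > len(corpus):
        raise ValueError(f"pool size {size} exceeds corpus size {len(corpus)}")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(corpus), size=size, replace=False))
    return Corpus(tuple(corpus[i] for i in idx), provenance=f"{corpus.provenance}[subsample {size}]")


# ---------------------------------------------------------------------------
# Persistence (sparse engines; JSON, text-only)
# ---------------------------------------------------------------------------

INDEX_FORMAT_VERSION = 1


def save_index(index: RetrievalIndex, path: str | Path) -> None:
    """Persist a tfidf or lexical index as versioned JSON."""
    if index.engine not in ("tfidf", "lexical"):
        raise ValueError("only sparse engines persist; dense state is encoder-derived")
    payload: dict = {
        "version": INDEX_FORMAT_VERSION,
        "engine": index.engine,
        "pool": [
            {"id": s.id, "tokens": list(s.tokens), "labels": list(s.labels)}
            for s in index.pool
        ],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_index(path: str | Path) -> RetrievalIndex:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("version") != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index version {payload.get('version')!r}")
    pool = tuple(
        Sentence(r["id"], tuple(r["tokens"]), tuple(r["labels"]))
        for r in payload["pool"]
    )
    return build_index(pool, payload["engine"])
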