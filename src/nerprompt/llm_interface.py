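"""LLM completion contract, response caching, and a deterministic mock.

Any chat model is reached through a :class:`Backend` with a single
``complete(prompt, config) -> text`` method.  Three sampling presets
mirror the configurations used for proprietary GPT models, an
instruction-tuned 70B LLaMA, and an open-weight GPT-OSS model.

The :class:`MockBackend` is a seeded test double with *relevance-
sensitive* accuracy: the probability that it labels a token correctly is
``p = clamp(p0 + alpha * rel, 0, 1)`` where ``rel`` is the maximum
Jaccard token overlap between the input and the in-context examples in
the prompt.  With ``alpha > 0`` prompts carrying closer examples yield
better annotations, which makes "retrieval beats random examples" a
property testable entirely offline.  Relevance is deliberately measured
by Jaccard overlap — engine-independent and sharing no code with any
retrieval engine under test.

A content-addressed JSON cache supports record/replay: a recorded
experiment regenerates bit-identically offline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .corpus_io import Corpus, Sentence

logger = logging.getLogger("nerprompt")


@dataclass(frozen=True)
class LLMConfig:
    """Sampling configuration sent with every completion request."""

    model_name: str = "mock"
    temperature: float = 0.0
    top_p: float = 1.0
    max_tokens: int = 2048
    endpoint: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.top_p <= 1.0):
            raise ValueError("top_p must be in [0, 1]")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


#: named sampling presets for the model families evaluated in few-shot NER
PRESETS: dict[str, LLMConfig] = {
    "gpt": LLMConfig(model_name="gpt", temperature=0.2, top_p=0.1),
    "llama3": LLMConfig(model_name="llama3", temperature=0.5, top_p=0.95),
    "gpt-oss": LLMConfig(model_name="gpt-oss", temperature=1.0, top_p=1.0),
    "mock": LLMConfig(model_name="mock", temperature=0.0, top_p=1.0),
}


class TransportError(RuntimeError):
    """A completion request failed at the transport level."""


class ReplayMissError(KeyError):
    """Replay-only mode saw a prompt absent from the cache."""


class Backend(Protocol):
    def complete(self, prompt: str, config: LLMConfig) -> str: ...


def request_key(prompt: str, config: LLMConfig) -> str:
    """Content address of one completion request."""
    blob = json.dumps(
        {
            "prompt": prompt,
            "model": config.model_name,
            "temperature": config.temperature,
            "top_p": config.top_p,
            "max_tokens": config.max_tokens,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


class ResponseCache:
    """Content-addressed prompt→response store, persisted as JSON."""

    def __init__(self, path: str | Path | None = None) -> None:
        self.path = Path(path) if path is not None else None
        self._store: dict[str, str] = {}
        if self.path is not None and self.path.exists():
            self._store = json.loads(self.path.read_text(encoding="utf-8"))

    def get(self, key: str) -> str | None:
        return self._store.get(key)

    def put(self, key: str, response: str) -> None:
        self._store[key] = response

    def save(self) -> None:
        if self.path is None:
            raise ValueError("cache has no backing path")
        self.path.write_text(json.dumps(self._store, sort_keys=True), encoding="utf-8")

    def __len__(self) -> int:
        return len(self._store)


class CachingClient:
    """Wraps a backend with record/replay semantics.

    ``mode="record"`` calls through on cache miss and stores the
    response; ``mode="replay"`` never calls through and raises
    :class:`ReplayMissError` on unseen prompts; ``mode="live"`` bypasses
    the cache entirely.
    """

    def __init__(
        self,
        backend: Backend | None,
        cache: ResponseCache | None = None,
        mode: str = "record",
        max_retries: int = 2,
    ) -> None:
        if mode not in ("record", "replay", "live"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode != "replay" and backend is None:
            raise ValueError(f"mode {mode!r} requires a backend")
        if mode != "live" and cache is None:
            cache = ResponseCache()
        self.backend = backend
        self.cache = cache
        self.mode = mode
        self.max_retries = max_retries
        self.n_calls = 0  # backend calls actually made

    def complete(self, prompt: str, config: LLMConfig) -> str:
        key = request_key(prompt, config)
        if self.mode != "live":
            hit = self.cache.get(key)
            if hit is not None:
                return hit
            if self.mode == "replay":
                raise ReplayMissError(f"no cached response for request {key[:12]}…")
        last_exc: Exception | None = None
        for _ in range(self.max_retries + 1):
            try:
                response = self.backend.complete(prompt, config)
                break
            except TransportError as exc:  # pragma: no cover - retry path
                last_exc = exc
        else:  # pragma: no cover
            raise TransportError(f"completion failed after retries: {last_exc}")
        self.n_calls += 1
        if self.mode == "record":
            self.cache.put(key, response)
        return response


# ---------------------------------------------------------------------------
# Mock oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MockOracleConfig:
    """Noise model of the mock annotator.

    ``base_accuracy`` (p0) is the per-token probability of emitting the
    gold label with no useful examples; ``relevance_gain`` (alpha) scales
    how much the best in-context example's Jaccard overlap with the input
    raises that probability (clamped to 1); ``format_noise`` (q) is the
    per-item probability of dropping or mangling the output item, which
    exercises codec repair.
    """

    base_accuracy: float = 0.5
    relevance_gain: float = 0.4
    format_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_accuracy", "format_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.relevance_gain < 0:
            raise ValueError("relevance_gain must be >= 0")


def max_jaccard_relevance(
    example_token_sets: Sequence[frozenset[str]], input_tokens: Sequence[str]
) -> float:
    """Max Jaccard overlap of lowercased token sets, examples vs input."""
    q = frozenset(t.lower() for t in input_tokens)
    best = 0.0
    for s in example_token_sets:
        union = len(q | s)
        if union:
            best = max(best, len(q & s) / union)
    return best


def _derived_rng(
    seed: int, input_tokens: Sequence[str], example_token_sets: Sequence[frozenset[str]]
) -> np.random.Generator:
    # independent noise per (seed, input, example set): two arms of an
    # experiment that show a sentence with different examples draw
    # different corruption, so a null effect is genuinely stochastic
    h = hashlib.sha256()
    h.update(str(seed).encode())
    for t in input_tokens:
        h.update(b"\x00" + t.encode())
    for s in sorted(example_token_sets, key=sorted):
        h.update(b"\x01" + "\x02".join(sorted(s)).encode())
    return np.random.default_rng(int.from_bytes(h.digest()[:8], "little") % (2**63))


def mock_annotate(
    prompt_examples: Sequence[Sequence[str]],
    input_sentence: Sentence,
    oracle_config: MockOracleConfig,
    label_space: Sequence[str],
) -> list[str]:
    """Simulated LLM output items for one input sentence.

    The oracle sees the gold labels (test-harness privilege).  Each token
    is labeled correctly with probability ``clamp(p0 + alpha*rel, 0, 1)``
    and otherwise gets a uniformly random *wrong* label from
    ``label_space``; with probability ``format_noise`` an item is dropped
    or mangled.  All randomness derives from the oracle seed, the input
    tokens, and the example token sets.
    """
    sets = [frozenset(t.lower() for t in ex) for ex in prompt_examples]
    rel = max_jaccard_relevance(sets, input_sentence.tokens)
    p = min(1.0, max(0.0, oracle_config.base_accuracy + oracle_config.relevance_gain * rel))
    rng = _derived_rng(oracle_config.seed, input_sentence.tokens, sets)
    labels = list(label_space)
    items: list[str] = []
    for tok, gold in zip(input_sentence.tokens, input_sentence.labels):
        if rng.random() < p:
            lab = gold
        else:
            wrong = [l for l in labels if l != gold]
            lab = wrong[rng.integers(len(wrong))] if wrong else gold
        if oracle_config.format_noise > 0 and rng.random() < oracle_config.format_noise:
            if rng.random() < 0.5:
                continue  # drop the item entirely
            items.append(tok)  # mangled: token with no label
        else:
            items.append(f"{tok}-{lab}")
    return items


def label_space_for(entity_types: Sequence[str]) -> list[str]:
    """Full IOB2 label inventory for a set of entity types."""
    out = ["O"]
    for t in sorted(entity_types):
        out += [f"B-{t}", f"I-{t}"]
    return out


class MockBackend:
    """Backend that parses structured prompts and answers via the oracle.

    The backend holds a registry of gold sentences (keyed by token
    sequence).  ``complete`` recovers the input tokens and example token
    lists from the prompt's ``Input:``/``Output:`` lines, looks up the
    gold labels, and returns the oracle's items as a JSON array — the
    exact contract a real model is instructed to follow.
    """

    def __init__(self, oracle_config: MockOracleConfig) -> None:
        self.oracle_config = oracle_config
        self._gold: dict[tuple[str, ...], Sentence] = {}
        self._types: set[str] = set()

    def register(self, corpus: Corpus | Sequence[Sentence]) -> None:
        sentences = corpus.sentences if isinstance(corpus, Corpus) else corpus
        for s in sentences:
            self._gold[s.tokens] = s
            self._types.update(lab[2:] for lab in s.labels if lab != "O")

    @staticmethod
    def _parse_prompt(prompt: str) -> tuple[list[list[str]], tuple[str, ...]]:
        examples: list[list[str]] = []
        inputs: list[list[str]] = []
        for line in prompt.splitlines():
            if line.startswith("Input: "):
                inputs.append(json.loads(line[len("Input: "):]))
        if not inputs:
            raise ValueError("prompt has no Input line")
        *example_inputs, final = inputs
        return example_inputs, tuple(final)

    def complete(self, prompt: str, config: LLMConfig) -> str:
        example_inputs, input_tokens = self._parse_prompt(prompt)
        gold = self._gold.get(input_tokens)
        if gold is None and len(input_tokens) == 1:
            # sentence-mode input: single raw string; match on its tokens
            gold = self._gold.get(tuple(input_tokens[0].split()))
        if gold is None:
            raise ValueError(f"mock backend has no gold for input {input_tokens!r}")
        # sentence-mode examples arrive as one raw string; split to tokens
        norm_examples = [
            ex[0].split() if len(ex) == 1 and " " in ex[0] else ex
            for ex in example_inputs
        ]
        items = mock_annotate(
            norm_examples,
            gold,
            self.oracle_config,
            label_space_for(sorted(self._types)),
        )
        return json.dumps(items)
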