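"""Assembly of structured NER prompts.

A prompt is an ordered document of up to six components: (1) the baseline
block — task description, entity definitions and output-format
specification — which is always present; (2) a dataset description;
(3) high-frequency instances per class; (4) background domain knowledge;
(5) error-analysis feedback; (6) annotated in-context examples.  Static
prompts fix the example slot once (random selection); dynamic prompts
refill it per input from a retrieval index.

Rendering is a pure function of its arguments: identical inputs yield
byte-identical text, which makes prompts hashable and cacheable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .codec import EncodedExample, Mode, encode
from .corpus_io import Corpus, Sentence, extract_entities
from .retrieval import RetrievalIndex, retrieve

logger = logging.getLogger("nerprompt")

#: block headers, in rendering order
_HEADERS = {
    "task": "## Task",
    "definitions": "## Entity definitions",
    "format": "## Output format",
    "dataset": "## Dataset description",
    "high_freq": "## High-frequency instances",
    "background": "## Background knowledge",
    "feedback": "## Error-analysis feedback",
    "examples": "## Examples",
    "input": "## Input",
}

DEFAULT_FORMAT_SPEC = (
    "Return a JSON array of strings, one per input token, in order. Each "
    "string is the token concatenated with its BIO label using a hyphen, "
    'e.g. "codeine-B-Drug" for an entity token and "was-O" for a '
    "non-entity token. The array must contain exactly one item per input "
    "token."
)


@dataclass(frozen=True)
class PromptComponents:
    """The configurable blocks of a structured prompt.

    ``task_description``, ``entity_definitions`` and ``format_spec`` form
    the baseline prompt and are always rendered; the optional blocks
    render only when set.
    """

    task_description: str
    entity_definitions: Mapping[str, str]
    format_spec: str = DEFAULT_FORMAT_SPEC
    dataset_description: str | None = None
    high_freq_lexicon: Mapping[str, Sequence[str]] | None = None
    background_knowledge: str | None = None
    error_feedback: str | None = None
    examples: tuple[EncodedExample, ...] = ()
    mode: Mode = "tokenized"

    def with_examples(self, examples: Sequence[EncodedExample]) -> "PromptComponents":
        return replace(self, examples=tuple(examples))


@dataclass(frozen=True)
class ExperimentConfig:
    """Shot count, retrieval settings and replication plan for one run."""

    k_shots: int = 5
    n_retrieved: int | None = None  # defaults to k_shots in dynamic mode
    pool_size: int | None = None  # None = ALL
    engine: str = "tfidf"
    seeds: tuple[int, ...] = (0, 1, 2, 3)
    runs: int = 4

    def __post_init__(self) -> None:
        if self.k_shots < 0:
            raise ValueError("k_shots must be >= 0")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


def baseline_components(
    entity_types: Sequence[str],
    definitions: Mapping[str, str] | None = None,
    mode: Mode = "tokenized",
) -> PromptComponents:
    """A generic baseline prompt for the given entity-type inventory."""
    types = sorted(entity_types)
    defs = {
        t: (definitions or {}).get(t, f"A mention of an entity of type '{t}'.")
        for t in types
    }
    task = (
        "You are a biomedical named-entity recognition system. Label every "
        "token of the input with a BIO tag: B-<type> opens an entity, "
        "I-<type> continues it, O marks a non-entity token. The entity "
        "types are: " + ", ".join(types) + "."
    )
    return PromptComponents(task_description=task, entity_definitions=defs, mode=mode)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_example(ex: EncodedExample) -> str:
    return (
        f"Input: {json.dumps(list(ex.input_repr))}\n"
        f"Output: {json.dumps(list(ex.output_repr))}"
    )


def build_prompt(components: PromptComponents, input_sentence: Sentence) -> str:
    """Render the full prompt for one input sentence.

    Blocks appear in a fixed order — baseline, dataset description,
    high-frequency instances, background knowledge, error feedback,
    examples, input — and the result is byte-identical across calls with
    equal arguments.
    """
    c = components
    parts: list[str] = [_HEADERS["task"], c.task_description, _HEADERS["definitions"]]
    for etype in sorted(c.entity_definitions):
        parts.append(f"- {etype}: {c.entity_definitions[etype]}")
    parts += [_HEADERS["format"], c.format_spec]
    if c.dataset_description is not None:
        parts += [_HEADERS["dataset"], c.dataset_description]
    if c.high_freq_lexicon is not None:
        parts.append(_HEADERS["high_freq"])
        for etype in sorted(c.high_freq_lexicon):
            words = ", ".join(c.high_freq_lexicon[etype])
            parts.append(f"- {etype}: {words}")
    if c.background_knowledge is not None:
        parts += [_HEADERS["background"], c.background_knowledge]
    if c.error_feedback is not None:
        parts += [_HEADERS["feedback"], c.error_feedback]
    if c.examples:
        parts.append(_HEADERS["examples"])
        parts += [_render_example(ex) for ex in c.examples]
    parts.append(_HEADERS["input"])
    if c.mode == "sentence":
        if input_sentence.raw_text is None:
            raise ValueError(
                f"sentence mode requires raw_text (sentence {input_sentence.id!r})"
            )
        parts.append(f"Input: {json.dumps([input_sentence.raw_text])}")
    else:
        parts.append(f"Input: {json.dumps(list(input_sentence.tokens))}")
    parts.append("Output:")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# Example selection
# ---------------------------------------------------------------------------

def select_static_examples(
    corpus: Corpus,
    k: int,
    seed: int,
    strategy: Literal["uniform", "per_label"] = "uniform",
    mode: Mode = "tokenized",
) -> tuple[EncodedExample, ...]:
    """Seeded random in-context examples.

    ``uniform`` draws ``k`` sentences without replacement from the whole
    corpus; ``per_label`` draws ``k`` per entity type from the stratum of
    sentences containing at least one entity of that type (so a prompt
    carries k examples per label).
    """
    rng = np.random.default_rng(seed)
    if strategy == "uniform":
        if k > len(corpus):
            raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
        idx = sorted(rng.choice(len(corpus), size=k, replace=False))
        chosen = [corpus[i] for i in idx]
    elif strategy == "per_label":
        chosen = []
        for etype in sorted(corpus.entity_types):
            stratum = [
                i
                for i, s in enumerate(corpus)
                if any(sp.etype == etype for sp in extract_entities(s))
            ]
            if k > len(stratum):
                raise ValueError(
                    f"k={k} exceeds stratum size {len(stratum)} for type {etype!r}"
                )
            idx = sorted(rng.choice(len(stratum), size=k, replace=False))
            chosen.extend(corpus[stratum[i]] for i in idx)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return tuple(encode(s, mode) for s in chosen)


def build_dynamic_prompt(
    components: PromptComponents,
    index: RetrievalIndex,
    input_sentence: Sentence,
    n: int,
    exclude_self: bool = False,
) -> str:
    """Prompt whose example slot holds the top-``n`` retrieved sentences.

    Retrieved examples are ordered most-similar-*last* so the closest
    example sits nearest the input in the context window.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scored = retrieve(index, input_sentence, n, exclude_self=exclude_self)
    examples = tuple(
        encode(se.sentence, components.mode) for se in reversed(scored)
    )
    return build_prompt(components.with_examples(examples), input_sentence)
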