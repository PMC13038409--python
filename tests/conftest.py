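"""Shared fixtures: the worked-example sentence and small random corpora."""

from __future__ import annotations

import numpy as np
import pytest

from nerprompt import Corpus, Sentence, generate_corpus, make_default_spec


@pytest.fixture
def worked_sentence() -> Sentence:
    """The canonical opioid-report example used throughout the docs."""
    return Sentence(
        "w0",
        ("I", "was", "a", "codeine", "addict."),
        ("O", "O", "O", "B-Clinical_Impacts", "I-Clinical_Impacts"),
    )


@pytest.fixture
def tiny_corpus(worked_sentence) -> Corpus:
    return Corpus(
        (
            worked_sentence,
            Sentence("w1", ("no", "entities", "here"), ("O", "O", "O")),
            Sentence(
                "w2",
                ("took", "codeine", "daily"),
                ("O", "B-Drug", "O"),
            ),
        )
    )


@pytest.fixture
def synthetic_corpus() -> Corpus:
    return generate_corpus(make_default_spec(n_sentences=120, seed=11))


def random_labels(rng: np.random.Generator, length: int, types=("X", "Y")) -> tuple[str, ...]:
    """A random *valid* IOB2 sequence (for oracle-equivalence tests)."""
    labels = []
    prev_type = None
    for _ in range(length):
        choices = ["O", "B"]
        if prev_type is not None:
            choices.append("I")
        c = choices[rng.integers(len(choices))]
        if c == "O":
            labels.append("O")
            prev_type = None
        elif c == "B":
            t = types[rng.integers(len(types))]
            labels.append(f"B-{t}")
            prev_type = t
        else:
            labels.append(f"I-{prev_type}")
    return tuple(labels)
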