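"""Token–label codec for LLM-based NER.

Generative models are asked to echo each input token concatenated with its
IOB2 tag (``codeine-B-Clinical_Impacts``), which pins the number of output
labels to the number of input tokens.  Real model output is messy, so
:func:`decode` is *total*: any list of strings yields a full-length valid
IOB2 sequence, with every deviation recorded as a repair rather than
raised.

Two separator dialects occur in the wild — ``token-B-X`` (hyphen
separator) and ``token.I-X`` (label appended directly) — and both are
accepted on decode.  Encoding always emits the hyphenated canonical form.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .corpus_io import LABEL_RE, Sentence, repair_iob2

Mode = Literal["tokenized", "sentence"]

#: repair kinds recorded by :func:`decode`
PAD = "pad"
TRUNCATE = "truncate"
TOKEN_MISMATCH = "token_mismatch"
UNPARSEABLE = "unparseable"
IOB2_FIX = "iob2_fix"


@dataclass(frozen=True)
class EncodedExample:
    """One sentence in prompt form.

    ``input_repr`` is the token list (tokenized mode) or the raw sentence
    (sentence mode); ``output_repr`` is one ``token-label`` string per
    token.
    """

    input_repr: tuple[str, ...]
    output_repr: tuple[str, ...]
    mode: Mode = "tokenized"


@dataclass
class DecodeResult:
    """A repaired, full-length IOB2 sequence plus the repair log."""

    labels: tuple[str, ...]
    repairs: dict[str, int] = field(default_factory=dict)

    @property
    def n_repairs(self) -> int:
        return sum(self.repairs.values())


def encode(sentence: Sentence, mode: Mode = "tokenized") -> EncodedExample:
    """Render a sentence as an LLM input/output pair.

    Output items are always ``token + "-" + label``; the input is either
    the token list or the untokenized sentence depending on ``mode``.
    """
    items = tuple(f"{tok}-{lab}" for tok, lab in zip(sentence.tokens, sentence.labels))
    if mode == "tokenized":
        return EncodedExample(sentence.tokens, items, mode)
    if mode == "sentence":
        return EncodedExample((sentence.text,), items, mode)
    raise ValueError(f"unknown mode {mode!r}")


def split_item(item: str) -> tuple[str, str] | None:
    """Split one output item into ``(token, label)``, or ``None``.

    The label grammar is a suffix language, so the item is split at the
    *last* position whose suffix is a valid IOB2 tag; an immediately
    preceding hyphen is treated as the separator and dropped.  This
    resolves hyphen-bearing tokens (``co-codamol-B-Drug``) and both
    separator dialects unambiguously.
    """
    for i in range(len(item) - 1, 0, -1):
        if LABEL_RE.match(item[i:]):
            if item[i - 1] == "-" and i >= 2:
                return item[: i - 1], item[i:]
            return item[:i], item[i:]
    return None


def decode(output_items: Sequence[str], expected_tokens: Sequence[str]) -> DecodeResult:
    """Recover an IOB2 sequence aligned to ``expected_tokens``.

    Never raises: unparseable items become ``O``; a length mismatch is
    resolved by greedy left-to-right alignment on exact token text with
    ``O``-fill for gaps; orphaned ``I-`` tags are rewritten to ``B-``.
    Every intervention increments a counter in ``repairs``.
    """
    if not expected_tokens:
        raise ValueError("expected_tokens must be non-empty")
    repairs: dict[str, int] = {}

    def bump(kind: str, n: int = 1) -> None:
        if n:
            repairs[kind] = repairs.get(kind, 0) + n

    parsed: list[tuple[str | None, str]] = []
    for item in output_items:
        split = split_item(str(item))
        if split is None:
            bump(UNPARSEABLE)
            parsed.append((None, "O"))
        else:
            parsed.append(split)

    m, n = len(parsed), len(expected_tokens)
    if m == n:
        labels = []
        for (tok, lab), expected in zip(parsed, expected_tokens):
            if tok is not None and tok != expected:
                bump(TOKEN_MISMATCH)
            labels.append(lab)
    else:
        # greedy alignment on exact token text; unmatched positions get O
        labels = ["O"] * n
        j = 0
        matched = 0
        for tok, lab in parsed:
            if tok is None:
                continue
            for k in range(j, n):
                if expected_tokens[k] == tok:
                    labels[k] = lab
                    j = k + 1
                    matched += 1
                    break
        if m < n:
            bump(PAD, n - m)
        else:
            bump(TRUNCATE, m - n)
        # items whose token never matched are effectively dropped
        bump(TOKEN_MISMATCH, sum(1 for t, _ in parsed if t is not None) - matched)

    fixed, n_fix = repair_iob2(labels)
    bump(IOB2_FIX, n_fix)
    return DecodeResult(tuple(fixed), repairs)


def roundtrip_check(sentence: Sentence) -> bool:
    """True iff encode→decode reproduces the labels with zero repairs."""
    enc = encode(sentence, "tokenized")
    res = decode(enc.output_repr, sentence.tokens)
    return res.labels == sentence.labels and res.n_repairs == 0


# ---------------------------------------------------------------------------
# Extracting the item array from raw LLM text
# ---------------------------------------------------------------------------

_FENCE_RE = re.compile(r"```(?:\w+)?\n(.*?)```", re.DOTALL)
_ARRAY_RE = re.compile(r"\[.*?\]", re.DOTALL)


def extract_output_items(response_text: str) -> list[str]:
    """Pull the JSON array of ``token-label`` strings out of a response.

    Tries, in order: fenced code blocks, the first bracketed array in the
    text, then line-per-item fallback.  Returns ``[]`` when nothing
    usable is found — downstream :func:`decode` turns that into an all-O
    prediction with pad repairs.
    """
    candidates = _FENCE_RE.findall(response_text)
    candidates.append(response_text)
    for cand in candidates:
        m = _ARRAY_RE.search(cand)
        if not m:
            continue
        blob = m.group(0)
        for attempt in (blob, blob.replace("'", '"'), blob.replace("‘", '"').replace("’", '"')):
            try:
                arr = json.loads(attempt)
            except json.JSONDecodeError:
                continue
            if isinstance(arr, list):
                return [str(x) for x in arr]
    lines = [ln.strip() for ln in response_text.splitlines() if ln.strip()]
    if lines and all(split_item(ln) is not None for ln in lines):
        return lines
    return []
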