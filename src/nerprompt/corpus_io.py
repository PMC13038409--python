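"""Reading, writing and validating BIO-annotated NER corpora.

The atomic unit is a :class:`Sentence`: a sequence of tokens with one IOB2
tag per token (``O``, ``B-<type>`` or ``I-<type>``).  Entities are maximal
``B``/``I`` runs of a single type and are represented as half-open token
spans (:class:`EntitySpan`).  The on-disk format is CoNLL-style
token-per-line text with blank-line sentence separators; a JSON dialect is
provided for round-tripping sentence ids.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger("nerprompt")

#: grammar of a single IOB2 tag; entity type names are word characters
#: (letters, digits, underscore) — hyphens are reserved as the B/I separator.
LABEL_RE = re.compile(r"^(O|[BI]-\w+)$")


class CorpusFormatError(ValueError):
    """Raised for unreadable or grammatically invalid corpus files."""


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity occupying tokens ``[start, end)`` of a sentence."""

    start: int
    end: int
    etype: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class Sentence:
    """A tokenized sentence with aligned IOB2 labels.

    Parameters
    ----------
    id:
        Opaque identifier, unique within a corpus.
    tokens:
        Non-empty text tokens.
    labels:
        IOB2 tags, one per token.
    raw_text:
        Optional untokenized surface form (used by sentence-mode prompts).
    """

    id: str
    tokens: tuple[str, ...]
    labels: tuple[str, ...]
    raw_text: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"sentence {self.id!r}: {len(self.tokens)} tokens but "
                f"{len(self.labels)} labels"
            )
        for tok in self.tokens:
            if not tok:
                raise ValueError(f"sentence {self.id!r}: empty token")
        for lab in self.labels:
            if not LABEL_RE.match(lab):
                raise ValueError(f"sentence {self.id!r}: bad label {lab!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        """Surface form: ``raw_text`` if set, else space-joined tokens."""
        return self.raw_text if self.raw_text is not None else " ".join(self.tokens)


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of sentences plus its entity-type inventory."""

    sentences: tuple[Sentence, ...]
    provenance: str = ""
    entity_types: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sentences", tuple(self.sentences))
        observed = frozenset(
            lab[2:] for s in self.sentences for lab in s.labels if lab != "O"
        )
        # the inventory always reflects the labels actually present
        object.__setattr__(self, "entity_types", observed)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    def __getitem__(self, i: int) -> Sentence:
        return self.sentences[i]


# ---------------------------------------------------------------------------
# IOB2 validation and repair
# ---------------------------------------------------------------------------

def iob2_violations(labels: Sequence[str]) -> list[int]:
    """Indices where an ``I-<type>`` tag has no matching predecessor.

    An ``I-X`` is valid only immediately after ``B-X`` or ``I-X``.
    """
    bad = []
    prev = "O"
    for i, lab in enumerate(labels):
        if lab.startswith("I-"):
            if not (prev == "B-" + lab[2:] or prev == "I-" + lab[2:]):
                bad.append(i)
        prev = lab
    return bad


def repair_iob2(labels: Sequence[str]) -> tuple[tuple[str, ...], int]:
    """Rewrite orphaned ``I-X`` tags to ``B-X`` (conventional IOB2 fixing).

    Returns the repaired sequence and the number of rewrites.
    """
    out = list(labels)
    n = 0
    prev = "O"
    for i, lab in enumerate(out):
        if lab.startswith("I-"):
            if not (prev == "B-" + lab[2:] or prev == "I-" + lab[2:]):
                out[i] = "B-" + lab[2:]
                n += 1
        prev = out[i]
    return tuple(out), n


def validate_sentence(sentence: Sentence, repair: bool = True) -> Sentence:
    """Validate IOB2 transitions; repair or raise depending on ``repair``."""
    bad = iob2_violations(sentence.labels)
    if not bad:
        return sentence
    if not repair:
        raise CorpusFormatError(
            f"sentence {sentence.id!r}: orphaned I- tag at positions {bad}"
        )
    fixed, n = repair_iob2(sentence.labels)
    logger.warning(
        "sentence %r: repaired %d orphaned I- tag(s) to B-", sentence.id, n
    )
    return replace(sentence, labels=fixed)


# ---------------------------------------------------------------------------
# CoNLL reader / writer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    """Which whitespace/tab-delimited columns hold the token and the label."""

    token: int = 0
    label: int = 1
    delimiter: str | None = None  # None = any whitespace


def read_conll(
    path: str | Path,
    column_spec: ColumnSpec = ColumnSpec(),
    repair: bool = True,
    id_prefix: str = "s",
) -> Corpus:
    """Read a token-per-line BIO corpus.

    Blank lines separate sentences; ``-DOCSTART-`` lines are ignored.
    Labels violating the IOB2 grammar raise :class:`CorpusFormatError` with
    the offending line number; orphaned ``I-`` transitions are repaired (or
    rejected when ``repair=False``).
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise CorpusFormatError(f"cannot read {path}: {exc}") from exc

    sentences: list[Sentence] = []
    tokens: list[str] = []
    labels: list[str] = []

    def flush() -> None:
        if tokens:
            s = Sentence(f"{id_prefix}{len(sentences)}", tuple(tokens), tuple(labels))
            sentences.append(validate_sentence(s, repair=repair))
            tokens.clear()
            labels.clear()

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            flush()
            continue
        if stripped.startswith("-DOCSTART-"):
            continue
        cols = line.split(column_spec.delimiter)
        try:
            tok = cols[column_spec.token]
            lab = cols[column_spec.label]
        except IndexError:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected >= "
                f"{max(column_spec.token, column_spec.label) + 1} columns"
            ) from None
        if not LABEL_RE.match(lab):
            raise CorpusFormatError(f"{path}:{lineno}: bad label {lab!r}")
        tokens.append(tok)
        labels.append(lab)
    flush()
    return Corpus(tuple(sentences), provenance=str(path))


def write_conll(corpus: Corpus, path: str | Path, delimiter: str = "\t") -> None:
    """Write ``corpus`` in two-column CoNLL format (round-trips with
    :func:`read_conll`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in corpus:
            for tok, lab in zip(sent.tokens, sent.labels):
                fh.write(f"{tok}{delimiter}{lab}\n")
            fh.write("\n")


def read_json_corpus(path: str | Path) -> Corpus:
    """Read the JSON dialect: a list of ``{id, tokens, labels[, raw_text]}``."""
    with Path(path).open(encoding="utf-8") as fh:
        payload = json.load(fh)
    sentences = tuple(
        validate_sentence(
            Sentence(
                str(rec["id"]),
                tuple(rec["tokens"]),
                tuple(rec["labels"]),
                rec.get("raw_text"),
            )
        )
        for rec in payload["sentences"]
    )
    return Corpus(sentences, provenance=payload.get("provenance", str(path)))


def write_json_corpus(corpus: Corpus, path: str | Path) -> None:
    payload = {
        "provenance": corpus.provenance,
        "sentences": [
            {
                "id": s.id,
                "tokens": list(s.tokens),
                "labels": list(s.labels),
                **({"raw_text": s.raw_text} if s.raw_text is not None else {}),
            }
            for s in corpus
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# Entity extraction and per-class statistics
# ---------------------------------------------------------------------------

def extract_entities(sentence: Sentence) -> tuple[EntitySpan, ...]:
    """Maximal ``B``/``I`` runs as half-open spans, ordered by start index."""
    spans: list[EntitySpan] = []
    start = -1
    etype = ""
    for i, lab in enumerate(sentence.labels):
        if lab.startswith("B-"):
            if start >= 0:
                spans.append(EntitySpan(start, i, etype))
            start, etype = i, lab[2:]
        elif lab.startswith("I-") and start >= 0 and lab[2:] == etype:
            continue
        else:  # "O" (or an orphaned I-, which validation has removed upstream)
            if start >= 0:
                spans.append(EntitySpan(start, i, etype))
            start = -1
    if start >= 0:
        spans.append(EntitySpan(start, len(sentence), etype))
    return tuple(spans)


def spans_to_labels(spans: Iterable[EntitySpan], length: int) -> tuple[str, ...]:
    """Inverse of :func:`extract_entities` for non-overlapping spans."""
    labels = ["O"] * length
    for sp in spans:
        if sp.end > length:
            raise ValueError(f"span {sp} exceeds sentence length {length}")
        labels[sp.start] = "B-" + sp.etype
        for i in range(sp.start + 1, sp.end):
            labels[i] = "I-" + sp.etype
    return tuple(labels)


def high_frequency_instances(
    corpus: Corpus,
    per_class_cap: int = 6,
    lowercase: bool = True,
    ngram: int = 1,
    entity_types: Iterable[str] | None = None,
) -> dict[str, list[str]]:
    """Top-``per_class_cap`` most frequent entity tokens per class.

    For each entity type, every unigram token inside a span of that type is
    counted (lowercased by default) and the tokens are ranked by descending
    count with lexicographic tie-breaking.  These "label words" give an LLM
    a cheap lexicon of what each class looks like in the training data.

    ``ngram > 1`` additionally counts whole n-token sub-phrases of each
    span; this is an extension, disabled by default.
    """
    if per_class_cap < 1:
        raise ValueError("per_class_cap must be >= 1")
    types = set(corpus.entity_types)
    if entity_types is not None:
        types |= set(entity_types)
    counts: dict[str, Counter[str]] = {t: Counter() for t in sorted(types)}
    for sent in corpus:
        for sp in extract_entities(sent):
            toks = sent.tokens[sp.start : sp.end]
            if lowercase:
                toks = tuple(t.lower() for t in toks)
            counts[sp.etype].update(toks)
            if ngram > 1:
                for size in range(2, ngram + 1):
                    for i in range(len(toks) - size + 1):
                        counts[sp.etype][" ".join(toks[i : i + size])] += 1
    lexicon: dict[str, list[str]] = {}
    for etype, ctr in counts.items():
        ranked = sorted(ctr.items(), key=lambda kv: (-kv[1], kv[0]))
        lexicon[etype] = [tok for tok, _ in ranked[:per_class_cap]]
    return lexicon
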