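"""Strict entity-level evaluation with bootstrap confidence intervals.

A predicted entity counts as a true positive only when its token span
*and* type exactly equal a gold entity.  Precision, recall and F1 are
micro-averaged: true/false positives and false negatives are pooled over
all sentences and entity types before the ratios are taken.

Uncertainty is quantified by a percentile bootstrap that resamples
*sentences* with replacement (the sentence is the natural exchangeable
unit; entities within a sentence are dependent) and recomputes micro-F1
on each resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import EntitySpan, Sentence, extract_entities


@dataclass(frozen=True)
class PredictionRecord:
    """Gold and predicted span sets for one sentence."""

    sentence_id: str
    gold_spans: frozenset[EntitySpan]
    pred_spans: frozenset[EntitySpan]
    n_repairs: int = 0

    @property
    def counts(self) -> tuple[int, int, int]:
        """(tp, fp, fn) for this sentence under strict matching."""
        tp = len(self.gold_spans & self.pred_spans)
        return tp, len(self.pred_spans) - tp, len(self.gold_spans) - tp


def record_from_labels(
    sentence: Sentence, pred_labels: Sequence[str], n_repairs: int = 0
) -> PredictionRecord:
    """Build a record by extracting entities from gold and predicted tags."""
    from dataclasses import replace

    pred_sentence = replace(sentence, labels=tuple(pred_labels))
    return PredictionRecord(
        sentence.id,
        frozenset(extract_entities(sentence)),
        frozenset(extract_entities(pred_sentence)),
        n_repairs,
    )


@dataclass
class EvalReport:
    """Micro-averaged precision/recall/F1 with optional CI bounds."""

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    n_sentences: int
    ci_low: float | None = None
    ci_high: float | None = None
    ci_degenerate: bool = False
    per_run: list["EvalReport"] = field(default_factory=list)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def count_matrix(records: Sequence[PredictionRecord]) -> np.ndarray:
    """Per-sentence (tp, fp, fn) as an ``(n, 3)`` integer array."""
    return np.array([r.counts for r in records], dtype=np.int64)


def score_strict(records: Sequence[PredictionRecord]) -> EvalReport:
    """Micro P/R/F1 over all sentences under strict span+type matching."""
    if not records:
        raise ValueError("records must be non-empty")
    counts = count_matrix(records).sum(axis=0)
    tp, fp, fn = (int(x) for x in counts)
    p, r, f1 = _prf(tp, fp, fn)
    return EvalReport(p, r, f1, tp, fp, fn, n_sentences=len(records))


def bootstrap_ci(
    records: Sequence[PredictionRecord],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for micro-F1.

    Sentences are resampled with replacement ``n_boot`` times and micro-F1
    recomputed on each resample; the interval is the
    ``((1-level)/2, 1-(1-level)/2)`` empirical quantile pair.  With fewer
    than two sentences there is nothing to resample and the degenerate
    point interval is returned (flagged on the report by callers).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    counts = count_matrix(records)
    n = counts.shape[0]
    point = score_strict(records).f1
    if n < 2:
        return point, point
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    resampled = counts[idx].sum(axis=1)  # (n_boot, 3)
    tp = resampled[:, 0].astype(float)
    denom_p = tp + resampled[:, 1]
    denom_r = tp + resampled[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom_p > 0, tp / denom_p, 0.0)
        r = np.where(denom_r > 0, tp / denom_r, 0.0)
        f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(f1, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate(
    records: Sequence[PredictionRecord],
    n_boot: int | None = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EvalReport:
    """Point estimates plus (optionally) a bootstrap CI on micro-F1."""
    report = score_strict(records)
    if n_boot:
        report.ci_low, report.ci_high = bootstrap_ci(records, n_boot, level, seed)
        report.ci_degenerate = len(records) < 2
    return report


def aggregate_runs(reports: Sequence[EvalReport]) -> EvalReport:
    """Arithmetic mean of P/R/F1 across replicate runs, per-run detail kept."""
    if not reports:
        raise ValueError("need at least one report")
    mean = EvalReport(
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        tp=int(sum(r.tp for r in reports)),
        fp=int(sum(r.fp for r in reports)),
        fn=int(sum(r.fn for r in reports)),
        n_sentences=sum(r.n_sentences for r in reports),
        per_run=list(reports),
    )
    return mean
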