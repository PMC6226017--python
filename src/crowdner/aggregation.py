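"""Minimum-percent-agreement aggregation of multi-annotator span markings.

For each distinct span marked in a document, the *agreement* is m/n: the
number of distinct annotators who marked that exact span divided by the
total number of distinct annotators who processed the document.  Keeping
spans whose agreement meets a threshold t interpolates between the union of
all markings (t = 0, maximal recall) and their intersection (t = 100,
maximal precision); sweeping t against a gold standard traces the
precision/recall/F trade-off, whose F-maximizing threshold is the usual
operating point.

n is the actual number of distinct annotators for the document, not a
nominal target — documents may be processed by more or fewer users than
planned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .annotation_model import AnnotationSet, Corpus, Span, SubmissionLog
from .scoring import Mode, ScoreTriple, score

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(range(0, 101, 10))

__all__ = [
    "SpanSupport",
    "AgreementCurvePoint",
    "AgreementCurve",
    "DEFAULT_THRESHOLDS",
    "span_support",
    "aggregate_at_threshold",
    "agreement_curve",
]


@dataclass(frozen=True)
class SpanSupport:
    """A span's vote count m out of n annotators for one document."""

    span: Span
    m: int
    n: int

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.n):
            raise ValueError(f"need 1 <= m <= n, got m={self.m}, n={self.n}")

    @property
    def agreement(self) -> float:
        return self.m / self.n


def _spans_by_annotator(
    doc_submissions: Sequence[AnnotationSet],
) -> tuple[str, dict[str, frozenset[Span]]]:
    if not doc_submissions:
        raise ValueError("no submissions: agreement undefined for n = 0")
    doc_ids = {sub.doc_id for sub in doc_submissions}
    if len(doc_ids) > 1:
        raise ValueError(f"submissions span multiple documents: {sorted(doc_ids)}")
    (doc_id,) = doc_ids
    per_annotator: dict[str, frozenset[Span]] = {}
    for sub in doc_submissions:
        prev = per_annotator.get(sub.annotator_id, frozenset())
        per_annotator[sub.annotator_id] = prev | sub.spans
    return doc_id, per_annotator


def span_support(doc_submissions: Sequence[AnnotationSet]) -> list[SpanSupport]:
    """Vote counts for every distinct span marked in one document.

    Multiple submissions by the same annotator are unioned and counted as
    one voter.  Returned in (start, end, entity_type) order.
    """
    _, per_annotator = _spans_by_annotator(doc_submissions)
    n = len(per_annotator)
    votes: dict[Span, int] = {}
    for spans in per_annotator.values():
        for span in spans:
            votes[span] = votes.get(span, 0) + 1
    return [
        SpanSupport(span, m, n)
        for span, m in sorted(votes.items(), key=lambda kv: kv[0].key)
    ]


def aggregate_at_threshold(
    doc_submissions: Sequence[AnnotationSet], t: float
) -> AnnotationSet:
    """Keep spans whose agreement is at least t percent.

    t = 0 keeps every span marked by at least one annotator (union);
    t = 100 keeps only spans marked by every annotator (intersection).
    """
    if not (0 <= t <= 100):
        raise ValueError(f"threshold must be in [0, 100], got {t}")
    supports = span_support(doc_submissions)
    if t == 0:
        kept = [s.span for s in supports]
    else:
        kept = [s.span for s in supports if s.agreement >= t / 100]
    return AnnotationSet(
        doc_id=doc_submissions[0].doc_id,
        annotator_id=f"aggregate@{t:g}",
        spans=frozenset(kept),
    )


@dataclass(frozen=True)
class AgreementCurvePoint:
    threshold: float
    scores: ScoreTriple
    macro_f1: float | None = None  # set only when average="macro"


@dataclass
class AgreementCurve:
    points: list[AgreementCurvePoint]

    @property
    def best(self) -> AgreementCurvePoint:
        """The F-maximizing point (lowest threshold on ties)."""
        return max(self.points, key=lambda p: (p.scores.f1, -p.threshold))

    def to_records(self) -> list[dict]:
        return [
            {
                "threshold": p.threshold,
                "tp": p.scores.tp,
                "fp": p.scores.fp,
                "fn": p.scores.fn,
                "precision": p.scores.precision,
                "recall": p.scores.recall,
                "f1": p.scores.f1,
            }
            for p in self.points
        ]


def agreement_curve(
    log: SubmissionLog,
    corpus: Corpus,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    mode: Mode = "exact",
    average: Literal["micro", "macro"] = "micro",
) -> AgreementCurve:
    """Corpus-level P/R/F at each agreement threshold.

    Each document is aggregated at the threshold and scored against gold;
    counts are micro-pooled across documents (``average="macro"`` instead
    averages per-document F).  Documents without submissions or without
    gold are skipped with a warning.
    """
    thresholds = sorted(set(thresholds))
    if not thresholds:
        raise ValueError("no thresholds given")
    by_doc = log.by_document()
    scorable = [doc_id for doc_id in by_doc if doc_id in corpus.gold]
    missing_gold = set(by_doc) - set(scorable)
    if missing_gold:
        logger.warning(
            "skipping %d document(s) without gold annotations", len(missing_gold)
        )
    unannotated = set(corpus.gold) - set(by_doc)
    if unannotated:
        logger.warning(
            "skipping %d gold document(s) with zero submissions", len(unannotated)
        )
    # support counts are threshold-independent: compute once per document
    doc_supports = {doc_id: span_support(by_doc[doc_id]) for doc_id in scorable}
    points: list[AgreementCurvePoint] = []
    for t in thresholds:
        doc_scores = [
            score(
                (
                    [s.span for s in doc_supports[doc_id]]
                    if t == 0
                    else [
                        s.span
                        for s in doc_supports[doc_id]
                        if s.agreement >= t / 100
                    ]
                ),
                corpus.gold[doc_id].spans,
                mode,
            )
            for doc_id in scorable
        ]
        pooled = sum(doc_scores, ScoreTriple(0, 0, 0))
        if average == "micro":
            points.append(AgreementCurvePoint(t, pooled))
        elif average == "macro":
            mean_f = (
                sum(s.f1 for s in doc_scores) / len(doc_scores)
                if doc_scores
                else math.nan
            )
            points.append(AgreementCurvePoint(t, pooled, macro_f1=mean_f))
        else:
            raise ValueError(f"unknown average {average!r}")
    return AgreementCurve(points)
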