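"""Span matching and precision/recall/F computation.

Scoring follows the exact-match NER evaluation tradition: a predicted span
is a true positive only if a reference span with the identical ``(start,
end, entity_type)`` triple exists.  An ``overlap`` mode is also provided
(greedy one-to-one pairing of spans sharing at least one character), since
two characteristic crowd errors — splitting a conjunction into its word
pieces, and including or dropping a modifier token — produce spans that
overlap the reference without matching it exactly.

Zero-denominator convention: precision, recall and F are all defined as 0
when their denominators vanish, so pooled statistics are total functions.
Per-user scores are micro-pooled: tp/fp/fn are summed over all of a user's
documents before a single P/R/F is computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .annotation_model import AnnotationSet, Corpus, Span, SubmissionLog

logger = logging.getLogger(__name__)

Mode = Literal["exact", "overlap"]

__all__ = [
    "ScoreTriple",
    "UserScore",
    "PerUserScores",
    "match_spans",
    "score",
    "per_user_scores",
    "feedback_score",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 → 1), unlike banker's rounding."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScoreTriple:
    """tp/fp/fn counts with derived precision, recall and F1."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def __add__(self, other: "ScoreTriple") -> "ScoreTriple":
        return ScoreTriple(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def match_spans(
    pred: Iterable[Span], ref: Iterable[Span], mode: Mode = "exact"
) -> tuple[int, int, int]:
    """Count (tp, fp, fn) between predicted and reference span sets.

    ``exact``: tp = spans sharing the identical (start, end, entity_type)
    triple.  ``overlap``: greedy one-to-one pairing of pred/ref spans of
    equal entity_type sharing ≥1 character; candidate pairs are taken in
    order of larger character overlap, then smaller start offset.
    """
    pred_set = frozenset(pred)
    ref_set = frozenset(ref)
    if mode == "exact":
        tp = len(pred_set & ref_set)
    elif mode == "overlap":
        candidates = sorted(
            (
                (-p.overlap(r), p.start, r.start, p, r)
                for p in pred_set
                for r in ref_set
                if p.entity_type == r.entity_type and p.overlap(r) > 0
            ),
            key=lambda c: (c[0], c[1], c[2]),
        )
        used_pred: set[Span] = set()
        used_ref: set[Span] = set()
        tp = 0
        for _, _, _, p, r in candidates:
            if p not in used_pred and r not in used_ref:
                used_pred.add(p)
                used_ref.add(r)
                tp += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return tp, len(pred_set) - tp, len(ref_set) - tp


def score(
    pred: Iterable[Span], ref: Iterable[Span], mode: Mode = "exact"
) -> ScoreTriple:
    """Score a predicted span set against a reference span set."""
    tp, fp, fn = match_spans(pred, ref, mode)
    return ScoreTriple(tp, fp, fn)


@dataclass(frozen=True)
class UserScore:
    annotator_id: str
    n_docs: int
    counts: ScoreTriple


@dataclass
class PerUserScores:
    """Micro-pooled per-user scores plus the mean and sd of user F values."""

    per_user: dict[str, UserScore]
    mean_f: float
    sd_f: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "annotator_id": us.annotator_id,
                "n_docs": us.n_docs,
                "tp": us.counts.tp,
                "fp": us.counts.fp,
                "fn": us.counts.fn,
                "precision": us.counts.precision,
                "recall": us.counts.recall,
                "f1": us.counts.f1,
            }
            for us in self.per_user.values()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "annotator_id", "n_docs", "tp", "fp", "fn",
                "precision", "recall", "f1",
            ],
        ).sort_values("annotator_id", ignore_index=True)


def per_user_scores(
    log: SubmissionLog, corpus: Corpus, mode: Mode = "exact"
) -> PerUserScores:
    """Score each annotator against gold, pooling counts over their documents.

    Only documents with gold annotations contribute; users with no scorable
    submissions are excluded rather than scored 0.  The summary sd is the
    population standard deviation of per-user F values.
    """
    per_user: dict[str, UserScore] = {}
    for annotator_id in log.annotator_ids():
        pooled = ScoreTriple(0, 0, 0)
        docs: dict[str, set[Span]] = {}
        for sub in log.submissions:
            if sub.annotator_id != annotator_id or sub.doc_id not in corpus.gold:
                continue
            docs.setdefault(sub.doc_id, set()).update(sub.spans)
        for doc_id, spans in docs.items():
            pooled = pooled + score(spans, corpus.gold[doc_id].spans, mode)
        if docs:
            per_user[annotator_id] = UserScore(annotator_id, len(docs), pooled)
    if not per_user:
        return PerUserScores({}, math.nan, math.nan)
    f_values = np.array([us.counts.f1 for us in per_user.values()])
    return PerUserScores(per_user, float(f_values.mean()), float(f_values.std()))


def feedback_score(
    user: AnnotationSet, partner: AnnotationSet | None, mode: Mode = "exact"
) -> int:
    """Gamified document score: F against the partner's markings × 1000.

    A user with no partner (first to annotate a non-gold document) receives
    the full allotment of 1000 points.  Points are rounded half-up.
    """
    if partner is None:
        return 1000
    if partner.doc_id != user.doc_id:
        raise ValueError(
            f"partner annotated document {partner.doc_id}, user annotated "
            f"{user.doc_id}"
        )
    return int(round_half_up(score(user.spans, partner.spans, mode).f1 * 1000))
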