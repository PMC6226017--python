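"""Synthetic corpora and simulated citizen-science annotation studies.

The simulator produces the three objects a full analysis needs — a gold
corpus, a multi-annotator submission log, and an engagement log — with the
error structure characteristic of crowd span-marking:

* *missed detections*: each gold entity is marked with probability
  ``p_detect``, independently per annotator and per span;
* *conjunction splitting*: a detected multi-token entity is emitted as its
  word pieces ("colorectal cancer" → "colorectal" + "cancer");
* *boundary modifiers*: a detected entity is extended or truncated by one
  adjacent token ("ovarian cancer" ↔ "premenopausal ovarian cancer");
* *spurious marks*: a Poisson number of single-token marks on non-entity
  tokens, placed independently per annotator — so high-agreement spurious
  spans are rare, which is exactly why agreement thresholding raises
  precision.

Documents are sequences of random pseudo-words with non-overlapping entity
token runs planted and recorded as gold.  Workloads across annotators are
heavy-tailed (Pareto weights), and each annotator works in one contiguous
burst of days, so the median account-to-last-submission period is short —
most volunteers participate once.

``expected_recall`` gives the closed-form aggregate recall under the pure
detection model (no boundary/split errors): a gold span survives threshold
t when at least ``ceil(n·t/100)`` of n annotators mark it, so recall is a
binomial tail probability.  It is the independent oracle against which the
simulator's output is checked.

All randomness flows from named seeds via ``numpy.random.SeedSequence``;
there is no global random state.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np
from scipy import stats

from .annotation_model import (
    AnnotationSet,
    Corpus,
    Document,
    Span,
    SubmissionLog,
    UserActivity,
)
from .success_metrics import EngagementLog

logger = logging.getLogger(__name__)

__all__ = [
    "CorpusParams",
    "AnnotatorProfile",
    "StudyParams",
    "generate_corpus",
    "simulate_annotator",
    "simulate_study",
    "expected_recall",
]


@dataclass
class CorpusParams:
    """Shape of a synthetic gold corpus.

    ``entity_length_weights`` is an (unnormalized) distribution over entity
    lengths in tokens; entities are planted without overlap and separated
    by at least one non-entity token.
    """

    n_docs: int = 20
    tokens_per_doc: tuple[int, int] = (40, 80)
    entities_per_doc: tuple[int, int] = (1, 4)
    entity_length_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.15, 4: 0.05}
    )
    vocabulary_size: int = 500
    title_tokens: int = 6
    gold_feedback_fraction: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 1 or self.vocabulary_size < 2:
            raise ValueError("n_docs and vocabulary_size must be positive")
        lo_tok, hi_tok = self.tokens_per_doc
        lo_ent, hi_ent = self.entities_per_doc
        if not (1 <= lo_tok <= hi_tok) or not (0 <= lo_ent <= hi_ent):
            raise ValueError("ranges must satisfy low <= high")
        if not self.entity_length_weights:
            raise ValueError("entity_length_weights must be non-empty")
        if any(k < 1 or w < 0 for k, w in self.entity_length_weights.items()):
            raise ValueError("entity lengths >= 1 and weights >= 0 required")
        max_len = max(self.entity_length_weights)
        # entities must fit with >=1 separating token
        if hi_ent * max_len + max(hi_ent - 1, 0) > lo_tok:
            raise ValueError(
                f"cannot pack up to {hi_ent} entities of up to {max_len} "
                f"tokens into a {lo_tok}-token document"
            )


@dataclass
class AnnotatorProfile:
    """Error model of one simulated annotator."""

    annotator_id: str
    p_detect: float = 0.8
    p_boundary: float = 0.1
    p_split: float = 0.05
    spurious_rate: float = 1.0
    n_docs_target: int | None = None

    def validate(self) -> None:
        for name in ("p_detect", "p_boundary", "p_split"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")


@dataclass
class StudyParams:
    """A full simulated study: corpus, cohort, replication, and calendar."""

    corpus: CorpusParams = field(default_factory=CorpusParams)
    annotators: list[AnnotatorProfile] = field(default_factory=list)
    annotators_per_doc: int = 15
    workload_alpha: float = 1.1  # Pareto shape; smaller = heavier tail
    start_date: date = date(2015, 1, 19)
    active_period_days: int = 28
    project_age_days: int | None = None
    rng_seed: int = 0

    @classmethod
    def uniform_cohort(
        cls,
        n_annotators: int,
        profile: AnnotatorProfile | None = None,
        **kwargs,
    ) -> "StudyParams":
        """Cohort of n annotators sharing one error profile."""
        base = profile or AnnotatorProfile(annotator_id="")
        annotators = [
            AnnotatorProfile(
                annotator_id=f"user{i:04d}",
                p_detect=base.p_detect,
                p_boundary=base.p_boundary,
                p_split=base.p_split,
                spurious_rate=base.spurious_rate,
            )
            for i in range(n_annotators)
        ]
        return cls(annotators=annotators, **kwargs)

    def validate(self) -> None:
        self.corpus.validate()
        if self.annotators_per_doc < 1:
            raise ValueError("annotators_per_doc must be >= 1")
        if len(self.annotators) < self.annotators_per_doc:
            raise ValueError(
                f"{len(self.annotators)} annotator(s) cannot provide "
                f"{self.annotators_per_doc} per document"
            )
        ids = [a.annotator_id for a in self.annotators]
        if len(set(ids)) != len(ids):
            raise ValueError("annotator ids must be unique")
        for profile in self.annotators:
            profile.validate()
        if self.active_period_days < 1:
            raise ValueError("active_period_days must be >= 1")


def _make_vocabulary(size: int, rng: np.random.Generator) -> list[str]:
    letters = np.array(list(string.ascii_lowercase))
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < size:
        length = int(rng.integers(3, 9))
        word = "".join(rng.choice(letters, size=length))
        if word not in seen:
            seen.add(word)
            vocab.append(word)
    return vocab


def _token_offsets(tokens: Sequence[str]) -> list[tuple[int, int]]:
    """Character (start, end) of each token in the space-joined text."""
    offsets = []
    pos = 0
    for tok in tokens:
        offsets.append((pos, pos + len(tok)))
        pos += len(tok) + 1
    return offsets


def generate_corpus(params: CorpusParams) -> Corpus:
    """Generate documents of random tokens with planted gold entity spans."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed))
    vocab = _make_vocabulary(params.vocabulary_size, rng)
    lengths = sorted(params.entity_length_weights)
    weights = np.array([params.entity_length_weights[k] for k in lengths], float)
    weights = weights / weights.sum()

    documents: dict[str, Document] = {}
    gold: dict[str, AnnotationSet] = {}
    n_feedback = math.ceil(params.gold_feedback_fraction * params.n_docs)
    feedback_ids = set(
        rng.choice(params.n_docs, size=n_feedback, replace=False).tolist()
    )
    for i in range(params.n_docs):
        doc_id = f"D{i:05d}"
        n_tokens = int(rng.integers(params.tokens_per_doc[0],
                                    params.tokens_per_doc[1] + 1))
        tokens = [vocab[j] for j in rng.integers(0, len(vocab), size=n_tokens)]
        n_ent = int(rng.integers(params.entities_per_doc[0],
                                 params.entities_per_doc[1] + 1))
        ent_lengths = [
            lengths[j] for j in rng.choice(len(lengths), size=n_ent, p=weights)
        ]
        total_ent = sum(ent_lengths)
        # place entities left-to-right with random gaps; reserve 1 token
        # between consecutive entities so gold runs never touch
        reserved = max(n_ent - 1, 0)
        free = n_tokens - total_ent - reserved
        if free < 0:
            raise ValueError(
                f"cannot pack {n_ent} entities ({total_ent} tokens) into "
                f"{n_tokens} tokens in document {doc_id}"
            )
        gaps = rng.multinomial(free, [1.0 / (n_ent + 1)] * (n_ent + 1))
        starts = []
        pos = 0
        for j, ent_len in enumerate(ent_lengths):
            pos += int(gaps[j]) + (1 if j > 0 else 0)
            starts.append(pos)
            pos += ent_len

        title_n = min(params.title_tokens, n_tokens)
        title = " ".join(tokens[:title_n])
        abstract = " ".join(tokens[title_n:])
        doc = Document(
            doc_id=doc_id,
            title=title,
            abstract=abstract,
            is_gold_feedback=i in feedback_ids,
        )
        text = doc.text
        offsets = _token_offsets(tokens)
        spans = []
        for start_tok, ent_len in zip(starts, ent_lengths):
            c_start = offsets[start_tok][0]
            c_end = offsets[start_tok + ent_len - 1][1]
            spans.append(Span(c_start, c_end, text[c_start:c_end]))
        documents[doc_id] = doc
        gold[doc_id] = AnnotationSet(doc_id, "expert", frozenset(spans))
    corpus = Corpus(documents=documents, gold=gold)
    corpus.validate()
    return corpus


def _gold_token_indices(
    gold_spans: Sequence[Span], offsets: Sequence[tuple[int, int]]
) -> set[int]:
    covered = set()
    for span in gold_spans:
        for idx, (s, e) in enumerate(offsets):
            if s >= span.start and e <= span.end:
                covered.add(idx)
    return covered


def simulate_annotator(
    profile: AnnotatorProfile,
    doc: Document,
    gold: AnnotationSet,
    rng: np.random.Generator,
    submitted_at: datetime | None = None,
) -> AnnotationSet:
    """One annotator's noisy marking of one document.

    Each gold span is detected with ``p_detect``; a detected multi-token
    span is split into word pieces with ``p_split``, otherwise its boundary
    is shifted by one token with ``p_boundary`` (extend or truncate, equal
    probability, when feasible).  ``Poisson(spurious_rate)`` single-token
    spurious marks land on distinct non-gold token positions.
    """
    profile.validate()
    text = doc.text
    tokens = text.split(" ")
    offsets = _token_offsets(tokens)
    gold_sorted = sorted(gold.spans, key=lambda s: s.key)
    marked: set[Span] = set()

    for span in gold_sorted:
        if rng.random() >= profile.p_detect:
            continue
        tok_idx = [
            i for i, (s, e) in enumerate(offsets)
            if s >= span.start and e <= span.end
        ]
        multi_token = len(tok_idx) > 1
        if multi_token and rng.random() < profile.p_split:
            for i in tok_idx:
                s, e = offsets[i]
                marked.add(Span(s, e, text[s:e], span.entity_type))
            continue
        if rng.random() < profile.p_boundary:
            moves = []
            first, last = tok_idx[0], tok_idx[-1]
            if first > 0:
                moves.append(("extend_left", first - 1))
            if last < len(tokens) - 1:
                moves.append(("extend_right", last + 1))
            if multi_token:
                moves.append(("trunc_left", first + 1))
                moves.append(("trunc_right", last - 1))
            if moves:
                move, pivot = moves[int(rng.integers(len(moves)))]
                if move == "extend_left":
                    s, e = offsets[pivot][0], span.end
                elif move == "extend_right":
                    s, e = span.start, offsets[pivot][1]
                elif move == "trunc_left":
                    s, e = offsets[pivot][0], span.end
                else:
                    s, e = span.start, offsets[pivot][1]
                marked.add(Span(s, e, text[s:e], span.entity_type))
                continue
        marked.add(Span(span.start, span.end, span.surface, span.entity_type))

    non_gold = sorted(set(range(len(tokens))) - _gold_token_indices(gold_sorted, offsets))
    if non_gold and profile.spurious_rate > 0:
        n_spurious = min(int(rng.poisson(profile.spurious_rate)), len(non_gold))
        if n_spurious:
            picks = rng.choice(len(non_gold), size=n_spurious, replace=False)
            for p in picks:
                s, e = offsets[non_gold[int(p)]]
                marked.add(Span(s, e, text[s:e]))

    result = AnnotationSet(
        doc_id=doc.doc_id,
        annotator_id=profile.annotator_id,
        spans=frozenset(marked),
        submitted_at=submitted_at,
    )
    result.validate(doc)
    return result


def simulate_study(
    params: StudyParams,
) -> tuple[Corpus, SubmissionLog, EngagementLog]:
    """Simulate a complete study: corpus, submissions, engagement counts.

    Documents are each assigned ``annotators_per_doc`` distinct annotators,
    drawn without replacement with probability proportional to heavy-tailed
    Pareto workload weights.  Each annotator executes their workload in one
    contiguous burst of days inside the study calendar.  The engagement log
    is derived from the resulting submission log, so its counts are
    consistent with it by construction.
    """
    params.validate()
    corpus = generate_corpus(params.corpus)
    root = np.random.SeedSequence(params.rng_seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])

    profiles = list(params.annotators)
    n_annot = len(profiles)
    weights = assign_rng.pareto(params.workload_alpha, size=n_annot) + 1.0
    doc_ids = sorted(corpus.documents)
    assignment: dict[int, list[str]] = {i: [] for i in range(n_annot)}
    for doc_id in doc_ids:
        chosen = assign_rng.choice(
            n_annot,
            size=params.annotators_per_doc,
            replace=False,
            p=weights / weights.sum(),
        )
        for a_idx in sorted(int(c) for c in chosen):
            assignment[a_idx].append(doc_id)

    calendar_rng = np.random.default_rng(
        np.random.SeedSequence(params.rng_seed, spawn_key=(1,))
    )
    submissions: list[AnnotationSet] = []
    users: dict[str, UserActivity] = {}
    for a_idx, profile in enumerate(profiles):
        docs = assignment[a_idx]
        # burst length: mostly a single day, occasionally a few
        burst_days = 1 + int(calendar_rng.geometric(0.8)) - 1
        burst_days = min(burst_days, params.active_period_days)
        start_offset = int(
            calendar_rng.integers(0, params.active_period_days - burst_days + 1)
        )
        day0 = params.start_date + timedelta(days=start_offset)
        stamps: list[datetime] = []
        for j, doc_id in enumerate(docs):
            day = min(
                j * burst_days // max(len(docs), 1), burst_days - 1
            )
            stamp = datetime.combine(
                day0 + timedelta(days=day), datetime.min.time()
            ) + timedelta(minutes=9 * 60 + 2 * j)
            stamps.append(stamp)
            ann_rng = np.random.default_rng(
                np.random.SeedSequence(
                    params.rng_seed, spawn_key=(2, a_idx, doc_ids.index(doc_id))
                )
            )
            submissions.append(
                simulate_annotator(
                    profile,
                    corpus.documents[doc_id],
                    corpus.gold[doc_id],
                    ann_rng,
                    submitted_at=stamp,
                )
            )
        if stamps:
            users[profile.annotator_id] = UserActivity(day0, max(stamps))

    log = SubmissionLog(submissions=submissions, users=users)
    engagement = EngagementLog.from_submission_log(
        log,
        target_classifications=len(doc_ids) * params.annotators_per_doc,
        active_period_days=params.active_period_days,
        project_age_days=params.project_age_days,
    )
    return corpus, log, engagement


def expected_recall(n: int, p: float, t: float) -> float:
    """Closed-form aggregate recall under the pure detection model.

    With n independent annotators each marking a gold span with probability
    p, the span survives agreement threshold t when the number of markers
    X ~ Binomial(n, p) reaches k = 1 for t = 0, else k = ceil(n·t/100).
    Returns P(X ≥ k).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if not 0 <= t <= 100:
        raise ValueError("t must be in [0, 100]")
    k = 1 if t == 0 else math.ceil(n * t / 100)
    return float(stats.binom.sf(k - 1, n, p))
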