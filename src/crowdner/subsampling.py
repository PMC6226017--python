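"""Contributors-per-abstract experiment: aggregate F as a function of k.

The question: how many independent annotators per document does an
agreement-voted aggregate need before quality saturates?  We answer it by
subsampling — for each k, draw k annotators per document uniformly without
replacement from the full log, aggregate, score against gold, and repeat
over replicates.

Seeds are derived per (k, replicate, document) from the root seed with
``numpy.random.SeedSequence`` spawn keys, so results do not depend on
iteration order and any single cell of the experiment can be reproduced in
isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .annotation_model import AnnotationSet, Corpus, SubmissionLog
from .aggregation import DEFAULT_THRESHOLDS, agreement_curve
from .scoring import Mode

logger = logging.getLogger(__name__)

ThresholdPolicy = Literal["sweep_max", "fixed"]

__all__ = ["SubsampleResult", "sample_annotators", "f_vs_k"]


@dataclass
class SubsampleResult:
    """Replicate F values for one k, with their mean/sd and the policy used."""

    k: int
    replicate_f: list[float]
    thresholds_used: list[float]
    threshold_policy: str

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.replicate_f))

    @property
    def sd_f(self) -> float:
        return float(np.std(self.replicate_f))


def sample_annotators(
    doc_submissions: Sequence[AnnotationSet],
    k: int,
    rng: np.random.Generator | int,
) -> list[AnnotationSet]:
    """Uniformly sample the submissions of k distinct annotators of one doc."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    annotators = sorted({sub.annotator_id for sub in doc_submissions})
    doc_id = doc_submissions[0].doc_id if doc_submissions else "?"
    if not 1 <= k <= len(annotators):
        raise ValueError(
            f"cannot sample k={k} from {len(annotators)} annotator(s) "
            f"of document {doc_id}"
        )
    chosen = set(rng.choice(annotators, size=k, replace=False))
    return [sub for sub in doc_submissions if sub.annotator_id in chosen]


def f_vs_k(
    log: SubmissionLog,
    corpus: Corpus,
    ks: Sequence[int],
    replicates: int = 25,
    rng_seed: int = 0,
    threshold_policy: ThresholdPolicy = "sweep_max",
    fixed_t: float = 40.0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    mode: Mode = "exact",
) -> list[SubsampleResult]:
    """Estimate aggregate F at each annotator count k over random subsamples.

    Per replicate, k annotators are drawn per document and the agreement
    curve recomputed on the subsampled log; F is taken at the curve's
    F-maximizing threshold (``sweep_max``) or at ``fixed_t`` (``fixed``).
    Documents with fewer than k annotators are skipped with a warning.
    """
    if not ks:
        raise ValueError("ks must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    by_doc = log.by_document()
    doc_order = sorted(by_doc)
    results: list[SubsampleResult] = []
    for k in sorted(ks):
        eligible = [
            doc_id
            for doc_id in doc_order
            if len({s.annotator_id for s in by_doc[doc_id]}) >= k
        ]
        skipped = len(doc_order) - len(eligible)
        if skipped:
            logger.warning(
                "k=%d: skipping %d document(s) with fewer than %d annotators",
                k, skipped, k,
            )
        if not eligible:
            raise ValueError(f"no document has {k} annotators")
        replicate_f: list[float] = []
        thresholds_used: list[float] = []
        for rep in range(replicates):
            subsampled: list[AnnotationSet] = []
            for doc_idx, doc_id in enumerate(eligible):
                seq = np.random.SeedSequence(
                    entropy=rng_seed, spawn_key=(k, rep, doc_idx)
                )
                subsampled.extend(
                    sample_annotators(
                        by_doc[doc_id], k, np.random.default_rng(seq)
                    )
                )
            sub_log = SubmissionLog(submissions=subsampled, users=log.users)
            curve = agreement_curve(sub_log, corpus, thresholds, mode)
            if threshold_policy == "sweep_max":
                point = curve.best
            elif threshold_policy == "fixed":
                matches = [p for p in curve.points if p.threshold == fixed_t]
                if not matches:
                    raise ValueError(
                        f"fixed threshold {fixed_t} not in threshold grid"
                    )
                point = matches[0]
            else:
                raise ValueError(f"unknown threshold policy {threshold_policy!r}")
            replicate_f.append(point.scores.f1)
            thresholds_used.append(point.threshold)
        results.append(
            SubsampleResult(
                k=k,
                replicate_f=replicate_f,
                thresholds_used=thresholds_used,
                threshold_policy=(
                    "sweep_max"
                    if threshold_policy == "sweep_max"
                    else f"fixed@{fixed_t:g}"
                ),
            )
        )
    return results
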