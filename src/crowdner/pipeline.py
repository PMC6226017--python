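"""End-to-end experiment orchestration: quests, points, and report bundles.

``run_experiment`` executes the full analysis — read corpus and
submissions, per-user scores, agreement threshold sweep, annotator
subsampling, success-metric matrix — and writes one TSV per stage plus a
JSON run manifest (config echo, seeds, library versions, wall time).
Outputs are deterministic given identical config and inputs, so a rerun
produces byte-identical TSVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation_model import (
    Corpus,
    SubmissionLog,
    read_pubtator,
    read_submissions,
    read_users,
)
from .aggregation import DEFAULT_THRESHOLDS, agreement_curve
from .scoring import Mode, feedback_score, per_user_scores
from .subsampling import f_vs_k
from .success_metrics import CostModel, EngagementLog, success_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "make_quests", "run_experiment",
           "quest_points"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def make_quests(
    doc_ids: Sequence[str], quest_size: int = 5
) -> list[list[str]]:
    """Bin documents into order-preserving quests of up to ``quest_size``."""
    if quest_size < 1:
        raise ValueError("quest_size must be >= 1")
    doc_ids = list(doc_ids)
    return [
        doc_ids[i : i + quest_size] for i in range(0, len(doc_ids), quest_size)
    ]


def quest_points(
    log: SubmissionLog,
    corpus: Corpus,
    quests: Sequence[Sequence[str]] | None = None,
    quest_bonus: int = 5000,
    mode: Mode = "exact",
) -> pd.DataFrame:
    """Per-user gamification points ledger.

    Per document: the feedback score against the expert gold when the
    document is flagged for gold feedback, against the prior annotator of
    the document otherwise, and the full 1000 points when the user was
    first.  Completing every document of a quest earns ``quest_bonus``.
    """
    if quests is None:
        quests = make_quests(sorted(corpus.documents))
    ordered = sorted(
        log.submissions,
        key=lambda s: (s.submitted_at or pd.Timestamp.min, s.annotator_id),
    )
    seen_by_doc: dict[str, list] = {}
    doc_points: dict[str, int] = {}
    docs_done: dict[str, set[str]] = {}
    for sub in ordered:
        doc = corpus.documents[sub.doc_id]
        if doc.is_gold_feedback and sub.doc_id in corpus.gold:
            partner = corpus.gold[sub.doc_id]
        else:
            prior = seen_by_doc.get(sub.doc_id)
            partner = prior[-1] if prior else None
        pts = feedback_score(sub, partner, mode)
        doc_points[sub.annotator_id] = doc_points.get(sub.annotator_id, 0) + pts
        docs_done.setdefault(sub.annotator_id, set()).add(sub.doc_id)
        seen_by_doc.setdefault(sub.doc_id, []).append(sub)
    rows = []
    for uid in sorted(doc_points):
        bonuses = sum(
            quest_bonus
            for quest in quests
            if quest and set(quest) <= docs_done[uid]
        )
        rows.append(
            {
                "annotator_id": uid,
                "n_docs": len(docs_done[uid]),
                "document_points": doc_points[uid],
                "quest_bonus_points": bonuses,
                "total_points": doc_points[uid] + bonuses,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["annotator_id", "n_docs", "document_points",
                 "quest_bonus_points", "total_points"],
    )


@dataclass
class RunConfig:
    """Everything a full experiment run needs; loadable from YAML."""

    corpus_path: str
    submissions_path: str
    out_dir: str
    users_path: str | None = None
    event_log_path: str | None = None
    mode: Mode = "exact"
    thresholds: list[float] = field(
        default_factory=lambda: list(DEFAULT_THRESHOLDS)
    )
    ks: list[int] = field(default_factory=lambda: [2, 3, 5, 10, 15])
    replicates: int = 25
    threshold_policy: str = "sweep_max"
    fixed_t: float = 40.0
    seed: int = 0
    annotators_per_doc_target: int = 15
    quest_size: int = 5
    unit_cost: float | None = None
    fee_rate: float = 0.0
    lenient: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_experiment(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write the report bundle.

    Returns a mapping of artifact name to written path.  Any stage failure
    raises :class:`PipelineStageError` naming the stage.
    """
    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            result = fn()
            logger.info("stage %s complete", name)
            return result
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineStageError(name, exc) from exc

    def _read():
        corpus = read_pubtator(config.corpus_path, lenient=config.lenient)
        log = read_submissions(
            config.submissions_path, corpus, lenient=config.lenient
        )
        if config.users_path:
            log.users = read_users(config.users_path)
        return corpus, log

    corpus, log = stage("read", _read)

    def _scores():
        scores = per_user_scores(log, corpus, config.mode)
        path = out_dir / "per_user_scores.tsv"
        _write_tsv(scores.to_frame(), path)
        artifacts["per_user_scores"] = path
        return scores

    scores = stage("per_user_scores", _scores)

    def _curve():
        curve = agreement_curve(log, corpus, config.thresholds, config.mode)
        frame = pd.DataFrame(curve.to_records())
        path = out_dir / "agreement_curve.tsv"
        _write_tsv(frame, path)
        artifacts["agreement_curve"] = path
        return curve

    curve = stage("agreement_curve", _curve)

    def _subsample():
        results = f_vs_k(
            log,
            corpus,
            ks=config.ks,
            replicates=config.replicates,
            rng_seed=config.seed,
            threshold_policy=config.threshold_policy,  # type: ignore[arg-type]
            fixed_t=config.fixed_t,
            thresholds=config.thresholds,
            mode=config.mode,
        )
        detail = pd.DataFrame(
            [
                {
                    "k": r.k,
                    "replicate": i,
                    "threshold_used": t,
                    "f1": f,
                }
                for r in results
                for i, (f, t) in enumerate(zip(r.replicate_f, r.thresholds_used))
            ]
        )
        summary = pd.DataFrame(
            [
                {
                    "k": r.k,
                    "mean_f": r.mean_f,
                    "sd_f": r.sd_f,
                    "threshold_policy": r.threshold_policy,
                }
                for r in results
            ]
        )
        detail_path = out_dir / "subsample.tsv"
        summary_path = out_dir / "subsample_summary.tsv"
        _write_tsv(detail, detail_path)
        _write_tsv(summary, summary_path)
        artifacts["subsample"] = detail_path
        artifacts["subsample_summary"] = summary_path
        return results

    stage("subsampling", _subsample)

    def _metrics():
        if config.event_log_path:
            with Path(config.event_log_path).open(encoding="utf-8") as fh:
                raw = yaml.safe_load(fh) or {}
            engagement = EngagementLog(**raw)
        else:
            n_target = len(corpus.documents) * config.annotators_per_doc_target
            engagement = EngagementLog.from_submission_log(
                log, target_classifications=n_target
            )
        cost = (
            CostModel(config.unit_cost, config.fee_rate)
            if config.unit_cost is not None
            else None
        )
        report = success_report(engagement, cost)
        path = out_dir / "success_report.tsv"
        _write_tsv(report.to_frame(), path)
        artifacts["success_report"] = path
        return report

    stage("success_metrics", _metrics)

    def _points():
        quests = make_quests(sorted(corpus.documents), config.quest_size)
        frame = quest_points(log, corpus, quests, mode=config.mode)
        path = out_dir / "points.tsv"
        _write_tsv(frame, path)
        artifacts["points"] = path

    stage("points", _points)

    def _manifest():
        import numpy
        import scipy

        manifest = {
            "config": asdict(config),
            "seed": config.seed,
            "versions": {
                "crowdner": __version__,
                "numpy": numpy.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
            },
            "n_documents": len(corpus.documents),
            "n_submissions": len(log.submissions),
            "n_annotators": len(log.annotator_ids()),
            "mean_user_f": scores.mean_f,
            "best_threshold": curve.best.threshold,
            "best_f1": curve.best.scores.f1,
            "wall_time_s": round(time.monotonic() - t0, 3),
        }
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
        artifacts["manifest"] = path

    stage("manifest", _manifest)
    return artifacts
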