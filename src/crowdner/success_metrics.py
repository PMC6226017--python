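"""Citizen-science success metrics: the contribution/engagement matrix.

Beyond data quality, the success of a volunteer project is usually judged
on a matrix of proxies split into two panels — *Contribution to Science*
(publication rate, completeness of analysis, academic impact, resource
savings, distribution of effort, effective training) and *Public
Engagement* (collaboration, communication, interaction, project appeal,
sustained engagement, public contribution).  Each proxy is a simple ratio:
publication-linked metrics are normalized by the squared project age in
days, engagement metrics by the squared active period in days, and the
distribution of effort is one minus the Gini coefficient of per-volunteer
task counts.

The Gini coefficient used here is the population relative mean absolute
difference, G = Σᵢⱼ|xᵢ−xⱼ| / (2 n² x̄), without small-sample correction.
Medians use the lower-median convention for even n.  Values are carried at
full precision; printing rounds half-up to three decimals (two for
completeness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import SubmissionLog, UserActivity
from .scoring import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "EngagementLog",
    "MetricValue",
    "SuccessReport",
    "CostModel",
    "gini",
    "distribution_of_effort",
    "rate_metric",
    "effective_training",
    "completeness",
    "median_active_period",
    "lower_median",
    "retention_rate",
    "survey_response_rate",
    "success_report",
]


def gini(counts: Sequence[float]) -> float:
    """Population Gini coefficient of a non-negative count distribution.

    G = Σᵢⱼ|xᵢ−xⱼ| / (2 n² x̄); 0 for perfect equality, bounded above by
    (n−1)/n.  Computed via the sorted-rank identity rather than the O(n²)
    pairwise sum.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("gini of an empty sequence is undefined")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("gini of an all-zero sequence is undefined")
    x = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2 * (ranks * x).sum() - (n + 1) * total) / (n * total))


def distribution_of_effort(counts: Sequence[float]) -> float:
    """1 − Gini: 1 when every volunteer contributed equally."""
    return 1.0 - gini(counts)


def rate_metric(count: float, period_days: float) -> float:
    """count / period_days² — the matrix's per-period normalization."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if period_days <= 0:
        raise ValueError("period_days must be positive")
    return count / period_days**2


def effective_training(n_tutorial_only: int, n_contributors: int) -> float:
    """1 − tutorial-only completions / total contributors."""
    if n_contributors <= 0:
        raise ValueError("n_contributors must be positive")
    if n_tutorial_only < 0:
        raise ValueError("n_tutorial_only must be non-negative")
    return 1.0 - n_tutorial_only / n_contributors


def completeness(n_classifications: int, target_classifications: int) -> float:
    """Classifications done over the target; may exceed 1 (overshoot)."""
    if target_classifications <= 0:
        raise ValueError("target_classifications must be positive")
    if n_classifications < 0:
        raise ValueError("n_classifications must be non-negative")
    return n_classifications / target_classifications


def lower_median(values: Sequence[float]) -> float:
    """Median with the lower of the two central values for even n."""
    if not values:
        raise ValueError("median of an empty sequence is undefined")
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def median_active_period(per_user_active: Mapping[str, UserActivity]) -> float:
    """Median per-user active period in whole days (same-day activity = 1)."""
    if not per_user_active:
        raise ValueError("no user activity records")
    periods = [
        (act.last_submission.date() - act.account_created).days + 1
        for act in per_user_active.values()
    ]
    return lower_median(periods)


def retention_rate(n_completed_next: int, n_completed_prev: int) -> float:
    """Percent of users finishing one training step who finish the next."""
    if n_completed_prev <= 0:
        raise ValueError("n_completed_prev must be positive")
    return 100.0 * n_completed_next / n_completed_prev


def survey_response_rate(n_responses: int, n_surveyed: int) -> float:
    """Percent response rate, truncated (not rounded) to one decimal."""
    if n_surveyed <= 0:
        raise ValueError("n_surveyed must be positive")
    return int(1000.0 * n_responses / n_surveyed) / 10.0


@dataclass
class EngagementLog:
    """Event-log counts feeding the success matrix.

    Optional quantities left as ``None`` cause the dependent metric to be
    reported as absent, never as zero.
    """

    per_user_classifications: dict[str, int] | None = None
    per_user_active: dict[str, UserActivity] | None = None
    median_active_period_days: float | None = None  # overrides per_user_active
    n_publications: int | None = None
    n_citations: int | None = None
    n_citsci_coauthor_papers: int | None = None
    n_communications: int | None = None
    n_interactions: int | None = None
    n_volunteers: int | None = None
    n_tutorial_only: int | None = None
    n_contributors: int | None = None
    active_period_days: float | None = None
    project_age_days: float | None = None
    n_classifications: int | None = None
    target_classifications: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_publications", "n_citations", "n_citsci_coauthor_papers",
            "n_communications", "n_interactions", "n_volunteers",
            "n_tutorial_only", "n_contributors", "n_classifications",
            "target_classifications",
        ):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.active_period_days is not None and self.active_period_days < 1:
            raise ValueError("active_period_days must be >= 1")
        if (
            self.n_volunteers is not None
            and self.n_tutorial_only is not None
            and self.n_contributors is not None
            and self.n_tutorial_only + self.n_contributors != self.n_volunteers
        ):
            logger.warning(
                "tutorial-only (%d) + contributors (%d) != volunteers (%d)",
                self.n_tutorial_only, self.n_contributors, self.n_volunteers,
            )

    @classmethod
    def from_submission_log(
        cls,
        log: SubmissionLog,
        target_classifications: int,
        active_period_days: float | None = None,
        project_age_days: float | None = None,
        **extra_counts: int,
    ) -> "EngagementLog":
        """Derive per-user and total counts from a submission log.

        ``active_period_days`` defaults to the span of submission dates.
        Counts not derivable from the log (communications, publications,
        tutorial-only completions, …) are passed through ``extra_counts``.
        """
        per_user: dict[str, int] = {}
        for sub in log.submissions:
            per_user[sub.annotator_id] = per_user.get(sub.annotator_id, 0) + 1
        if active_period_days is None:
            stamps = [
                s.submitted_at for s in log.submissions if s.submitted_at
            ]
            if not stamps:
                raise ValueError(
                    "active_period_days not given and no timestamps to infer it"
                )
            active_period_days = (max(stamps).date() - min(stamps).date()).days + 1
        n_contributors = len(per_user)
        defaults = dict(
            n_publications=0,
            n_citations=0,
            n_citsci_coauthor_papers=0,
            n_tutorial_only=0,
        )
        defaults.update(extra_counts)
        n_volunteers = defaults.pop(
            "n_volunteers", n_contributors + defaults["n_tutorial_only"]
        )
        return cls(
            per_user_classifications=per_user,
            per_user_active=dict(log.users) or None,
            n_volunteers=n_volunteers,
            n_contributors=n_contributors,
            active_period_days=active_period_days,
            project_age_days=project_age_days,
            n_classifications=len(log.submissions),
            target_classifications=target_classifications,
            **defaults,
        )


@dataclass(frozen=True)
class MetricValue:
    """A reported metric with its raw numerator and denominator."""

    value: float
    numerator: float
    denominator: float

    def rounded(self, ndigits: int = 3) -> float:
        return round_half_up(self.value, ndigits)


@dataclass
class CostModel:
    """Resource-savings model: tasks × unit cost × (1 + platform fee)."""

    unit_cost: float
    fee_rate: float = 0.0


_PANELS: dict[str, str] = {
    "publication_rate": "Contribution to Science",
    "completeness": "Contribution to Science",
    "academic_impact": "Contribution to Science",
    "resource_savings": "Contribution to Science",
    "distribution_of_effort": "Contribution to Science",
    "effective_training": "Contribution to Science",
    "collaboration": "Public Engagement",
    "communication": "Public Engagement",
    "interaction": "Public Engagement",
    "project_appeal": "Public Engagement",
    "sustained_engagement": "Public Engagement",
    "public_contribution": "Public Engagement",
}


@dataclass
class SuccessReport:
    """The twelve-proxy success matrix; absent inputs yield ``None``."""

    publication_rate: MetricValue | None = None
    completeness: MetricValue | None = None
    academic_impact: MetricValue | None = None
    resource_savings: MetricValue | None = None
    distribution_of_effort: MetricValue | None = None
    effective_training: MetricValue | None = None
    collaboration: MetricValue | None = None
    communication: MetricValue | None = None
    interaction: MetricValue | None = None
    project_appeal: MetricValue | None = None
    sustained_engagement: MetricValue | None = None
    public_contribution: MetricValue | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, panel in _PANELS.items():
            mv: MetricValue | None = getattr(self, name)
            if mv is None:
                continue
            ndigits = 2 if name == "completeness" else 3
            rows.append(
                {
                    "panel": panel,
                    "metric": name,
                    "numerator": mv.numerator,
                    "denominator": mv.denominator,
                    "value": mv.value,
                    "printed": mv.rounded(ndigits),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["panel", "metric", "numerator", "denominator", "value", "printed"],
        )

    def pretty(self) -> str:
        frame = self.to_frame()
        lines = []
        for panel in ("Contribution to Science", "Public Engagement"):
            lines.append(f"=== {panel} ===")
            sub = frame[frame["panel"] == panel]
            for _, row in sub.iterrows():
                lines.append(
                    f"  {row['metric']:<24s} {row['printed']:g}"
                    f"  (components: {row['numerator']:g}, {row['denominator']:g})"
                )
        return "\n".join(lines)


def success_report(
    log: EngagementLog, cost_model: CostModel | None = None
) -> SuccessReport:
    """Compute every matrix proxy available from an engagement log."""
    report = SuccessReport()
    age = log.project_age_days
    period = log.active_period_days

    def age_rate(count: int | None) -> MetricValue | None:
        if count is None or age is None:
            return None
        return MetricValue(rate_metric(count, age), count, age)

    report.publication_rate = age_rate(log.n_publications)
    report.academic_impact = age_rate(log.n_citations)
    report.collaboration = age_rate(log.n_citsci_coauthor_papers)

    def period_rate(count: float | None) -> MetricValue | None:
        if count is None or period is None:
            return None
        return MetricValue(rate_metric(count, period), count, period)

    report.communication = period_rate(log.n_communications)
    report.interaction = period_rate(log.n_interactions)
    report.project_appeal = period_rate(log.n_volunteers)

    median_period: float | None = log.median_active_period_days
    if median_period is None and log.per_user_active:
        median_period = median_active_period(log.per_user_active)
    report.sustained_engagement = period_rate(median_period)

    if log.per_user_classifications:
        median_cls = lower_median(list(log.per_user_classifications.values()))
        report.public_contribution = period_rate(median_cls)
        counts = list(log.per_user_classifications.values())
        # numerator field records the Gini itself; denominator the user count
        report.distribution_of_effort = MetricValue(
            distribution_of_effort(counts), gini(counts), len(counts)
        )

    if log.n_classifications is not None and log.target_classifications:
        report.completeness = MetricValue(
            completeness(log.n_classifications, log.target_classifications),
            log.n_classifications,
            log.target_classifications,
        )
    if log.n_tutorial_only is not None and log.n_contributors:
        report.effective_training = MetricValue(
            effective_training(log.n_tutorial_only, log.n_contributors),
            log.n_tutorial_only,
            log.n_contributors,
        )
    if cost_model is not None and log.n_classifications is not None:
        savings = (
            log.n_classifications * cost_model.unit_cost * (1 + cost_model.fee_rate)
        )
        report.resource_savings = MetricValue(
            savings, log.n_classifications, cost_model.unit_cost
        )
    return report
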