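"""Data model and I/O for documents, gold annotations, and crowd submissions.

The coordinate frame for every annotation is the concatenation
``title + " " + abstract`` of a document, addressed by 0-based, half-open
character offsets (the PubTator convention; the single joining space is part
of the frame).  A :class:`Span` is identified by its ``(start, end,
entity_type)`` triple; the surface string is carried for validation and
display but does not participate in identity.

Supported formats:

* PubTator: ``PMID|t|title``, ``PMID|a|abstract``, tab-separated annotation
  rows ``PMID<TAB>start<TAB>end<TAB>surface<TAB>type[<TAB>concept]``.
* Submission JSONL: one annotation set per line,
  ``{"doc_id", "annotator_id", "submitted_at", "spans": [...]}``.
* Submission CSV (long form): one span per row with columns ``doc_id,
  annotator_id, start, end, surface, entity_type, submitted_at``; a
  column-name mapping can adapt the reader to foreign exports.
* Users sidecar CSV: ``annotator_id, account_created, last_submission``.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Span",
    "Document",
    "AnnotationSet",
    "Corpus",
    "UserActivity",
    "SubmissionLog",
    "PubtatorParseError",
    "SpanValidationError",
    "SubmissionReadError",
    "read_pubtator",
    "write_pubtator",
    "read_submissions",
    "write_annotations",
    "read_users",
    "write_users",
]


class PubtatorParseError(ValueError):
    """A PubTator line could not be parsed (message names the line number)."""


class SpanValidationError(ValueError):
    """A span is inconsistent with its document (offsets or surface text)."""


class SubmissionReadError(ValueError):
    """A submission file is malformed or references unknown documents."""


@dataclass(frozen=True)
class Span:
    """A typed character-offset interval.

    Identity (equality / hashing) is the ``(start, end, entity_type)``
    triple; ``surface`` and ``concept`` are carried as metadata.
    """

    start: int
    end: int
    surface: str = field(compare=False)
    entity_type: str = "Disease"
    concept: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SpanValidationError(
                f"invalid span offsets: start={self.start}, end={self.end}"
            )

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.entity_type)

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Span") -> int:
        """Number of characters shared with ``other``."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def validate(self, doc: "Document", lenient: bool = False) -> None:
        """Check bounds and surface-slice equality against ``doc``.

        With ``lenient=True`` a surface mismatch is logged, not raised;
        out-of-bounds offsets are always errors.
        """
        text = doc.text
        if self.end > len(text):
            raise SpanValidationError(
                f"span ({self.start},{self.end}) exceeds text length "
                f"{len(text)} in document {doc.doc_id}"
            )
        actual = text[self.start : self.end]
        if actual != self.surface:
            msg = (
                f"surface mismatch in document {doc.doc_id} at "
                f"({self.start},{self.end}): expected {self.surface!r}, "
                f"text has {actual!r}"
            )
            if lenient:
                logger.warning(msg)
            else:
                raise SpanValidationError(msg)


@dataclass(frozen=True)
class Document:
    """A title+abstract unit; offsets address ``title + ' ' + abstract``."""

    doc_id: str
    title: str
    abstract: str
    is_gold_feedback: bool = False

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract


@dataclass
class AnnotationSet:
    """One annotator's complete marking of one document.

    ``spans`` is a frozenset — a user cannot mark the same (start, end,
    type) twice, so agreement later counts users, not marks.
    """

    doc_id: str
    annotator_id: str
    spans: frozenset[Span] = frozenset()
    submitted_at: datetime | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.spans, frozenset):
            self.spans = frozenset(self.spans)

    def validate(self, doc: Document, lenient: bool = False) -> None:
        if doc.doc_id != self.doc_id:
            raise SpanValidationError(
                f"annotation set for {self.doc_id} checked against "
                f"document {doc.doc_id}"
            )
        for span in self.spans:
            span.validate(doc, lenient=lenient)


@dataclass
class Corpus:
    """Documents plus expert gold annotations (annotator_id ``"expert"``)."""

    documents: dict[str, Document] = field(default_factory=dict)
    gold: dict[str, AnnotationSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for doc_id in self.gold:
            if doc_id not in self.documents:
                raise ValueError(f"gold annotations for unknown document {doc_id}")

    def __len__(self) -> int:
        return len(self.documents)

    def doc_ids(self) -> list[str]:
        return list(self.documents)

    def validate(self, lenient: bool = False) -> None:
        for doc_id, gold_set in self.gold.items():
            gold_set.validate(self.documents[doc_id], lenient=lenient)


@dataclass(frozen=True)
class UserActivity:
    """Account-creation date and last-submission timestamp for one user."""

    account_created: date
    last_submission: datetime

    def __post_init__(self) -> None:
        if self.last_submission.date() < self.account_created:
            raise ValueError(
                f"last submission {self.last_submission} precedes account "
                f"creation {self.account_created}"
            )


@dataclass
class SubmissionLog:
    """All annotation sets of a study plus per-user activity records."""

    submissions: list[AnnotationSet] = field(default_factory=list)
    users: dict[str, UserActivity] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        submissions: Sequence[AnnotationSet],
        users: Mapping[str, UserActivity] | None = None,
    ) -> "SubmissionLog":
        """Assemble a log, deriving user activity from timestamps if absent."""
        if users is None:
            users = derive_user_activity(submissions)
        missing = {s.annotator_id for s in submissions} - set(users)
        if missing and users:
            logger.warning(
                "no activity record for %d annotator(s): %s",
                len(missing),
                sorted(missing)[:5],
            )
        return cls(submissions=list(submissions), users=dict(users))

    def by_document(self) -> dict[str, list[AnnotationSet]]:
        grouped: dict[str, list[AnnotationSet]] = defaultdict(list)
        for sub in self.submissions:
            grouped[sub.doc_id].append(sub)
        return dict(grouped)

    def by_annotator(self) -> dict[str, list[AnnotationSet]]:
        grouped: dict[str, list[AnnotationSet]] = defaultdict(list)
        for sub in self.submissions:
            grouped[sub.annotator_id].append(sub)
        return dict(grouped)

    def annotator_ids(self) -> list[str]:
        return sorted({s.annotator_id for s in self.submissions})


def derive_user_activity(
    submissions: Sequence[AnnotationSet],
) -> dict[str, UserActivity]:
    """Infer (account_created, last_submission) from submission timestamps.

    Users whose submissions all lack timestamps are omitted with a warning.
    """
    stamps: dict[str, list[datetime]] = defaultdict(list)
    for sub in submissions:
        if sub.submitted_at is not None:
            stamps[sub.annotator_id].append(sub.submitted_at)
    users = {
        uid: UserActivity(min(ts).date(), max(ts)) for uid, ts in stamps.items()
    }
    untimed = {s.annotator_id for s in submissions} - set(users)
    if untimed:
        logger.warning(
            "cannot derive activity for %d annotator(s) without timestamps",
            len(untimed),
        )
    return users


# ---------------------------------------------------------------------------
# PubTator corpus I/O


def read_pubtator(path: str | Path, lenient: bool = False) -> Corpus:
    """Read a PubTator-format corpus (title/abstract lines + annotation rows).

    Every document receives a gold :class:`AnnotationSet` (possibly empty)
    attributed to the single ``"expert"`` annotator.  Offsets are validated
    against the reconstructed ``title + " " + abstract`` text; a surface
    mismatch is an error unless ``lenient``.
    """
    path = Path(path)
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    ann_rows: list[tuple[int, str, int, int, str, str, str | None]] = []

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if "\t" in line:
                fields = line.split("\t")
                if len(fields) < 5:
                    raise PubtatorParseError(
                        f"line {lineno}: annotation row has {len(fields)} "
                        f"fields, expected at least 5"
                    )
                doc_id, start_s, end_s, surface, ent_type = fields[:5]
                concept = fields[5] if len(fields) > 5 else None
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise PubtatorParseError(
                        f"line {lineno}: non-integer offsets "
                        f"{start_s!r}, {end_s!r}"
                    ) from exc
                ann_rows.append(
                    (lineno, doc_id, start, end, surface, ent_type, concept)
                )
                continue
            parts = line.split("|", 2)
            if len(parts) != 3 or parts[1] not in ("t", "a"):
                raise PubtatorParseError(
                    f"line {lineno}: expected 'id|t|…', 'id|a|…' or a "
                    f"tab-separated annotation row, got {line[:60]!r}"
                )
            doc_id, kind, text = parts
            target = titles if kind == "t" else abstracts
            if doc_id in target:
                raise PubtatorParseError(
                    f"line {lineno}: duplicate {kind!r} line for document "
                    f"{doc_id}"
                )
            target[doc_id] = text

    documents: dict[str, Document] = {}
    for doc_id, title in titles.items():
        documents[doc_id] = Document(
            doc_id=doc_id, title=title, abstract=abstracts.get(doc_id, "")
        )
    orphans = set(abstracts) - set(titles)
    for doc_id in sorted(orphans):
        documents[doc_id] = Document(
            doc_id=doc_id, title="", abstract=abstracts[doc_id]
        )

    gold_spans: dict[str, list[Span]] = {doc_id: [] for doc_id in documents}
    for lineno, doc_id, start, end, surface, ent_type, concept in ann_rows:
        if doc_id not in documents:
            raise PubtatorParseError(
                f"line {lineno}: annotation for unknown document {doc_id}"
            )
        span = Span(start, end, surface, ent_type, concept)
        span.validate(documents[doc_id], lenient=lenient)
        gold_spans[doc_id].append(span)

    gold = {
        doc_id: AnnotationSet(doc_id, "expert", frozenset(spans))
        for doc_id, spans in gold_spans.items()
    }
    return Corpus(documents=documents, gold=gold)


def write_pubtator(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus (documents + gold annotations) in PubTator format."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc_id in corpus.documents:
            doc = corpus.documents[doc_id]
            fh.write(f"{doc_id}|t|{doc.title}\n")
            fh.write(f"{doc_id}|a|{doc.abstract}\n")
            gold = corpus.gold.get(doc_id)
            if gold is not None:
                for span in sorted(gold.spans, key=lambda s: s.key):
                    concept = span.concept if span.concept is not None else ""
                    fh.write(
                        f"{doc_id}\t{span.start}\t{span.end}\t{span.surface}"
                        f"\t{span.entity_type}\t{concept}\n"
                    )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Submission I/O

#: canonical CSV column names; a column_map may rename any of them
CSV_COLUMNS = (
    "doc_id",
    "annotator_id",
    "start",
    "end",
    "surface",
    "entity_type",
    "submitted_at",
)


def _parse_timestamp(value: str | None, where: str) -> datetime | None:
    if value is None or value == "":
        return None
    try:
        return datetime.fromisoformat(value)
    except ValueError as exc:
        raise SubmissionReadError(
            f"{where}: unparseable timestamp {value!r}"
        ) from exc


def _dedup_spans(
    spans: Iterable[Span], doc_id: str, annotator_id: str
) -> frozenset[Span]:
    spans = list(spans)
    unique = frozenset(spans)
    if len(unique) < len(spans):
        logger.warning(
            "collapsed %d duplicate span(s) for annotator %s on document %s",
            len(spans) - len(unique),
            annotator_id,
            doc_id,
        )
    return unique


def read_submissions(
    path: str | Path,
    corpus: Corpus,
    lenient: bool = False,
    column_map: Mapping[str, str] | None = None,
) -> SubmissionLog:
    """Read a multi-annotator submission file (JSONL or long-form CSV).

    Duplicate identical spans within one annotator's set are collapsed with
    a warning.  Spans referencing documents absent from ``corpus`` raise a
    :class:`SubmissionReadError` listing the offending ids.  ``column_map``
    maps canonical CSV column names to the names used in a foreign export.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".json", ".ndjson"):
        sets = _read_submissions_jsonl(path)
    elif suffix in (".csv", ".tsv"):
        sets = _read_submissions_csv(path, column_map, delimiter="\t" if suffix == ".tsv" else ",")
    else:
        raise SubmissionReadError(f"unrecognized submission format: {path.name}")

    unknown = sorted({s.doc_id for s in sets} - set(corpus.documents))
    if unknown:
        raise SubmissionReadError(
            f"submissions reference {len(unknown)} unknown document id(s): "
            f"{', '.join(unknown[:10])}"
        )
    for sub in sets:
        sub.validate(corpus.documents[sub.doc_id], lenient=lenient)
    return SubmissionLog.build(sets)


def _read_submissions_jsonl(path: Path) -> list[AnnotationSet]:
    sets: list[AnnotationSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SubmissionReadError(
                    f"line {lineno}: invalid JSON"
                ) from exc
            try:
                spans = [
                    Span(
                        int(s["start"]),
                        int(s["end"]),
                        s["surface"],
                        s.get("entity_type", "Disease"),
                    )
                    for s in record["spans"]
                ]
                doc_id = record["doc_id"]
                annotator_id = record["annotator_id"]
            except (KeyError, TypeError, ValueError) as exc:
                raise SubmissionReadError(
                    f"line {lineno}: malformed record ({exc})"
                ) from exc
            sets.append(
                AnnotationSet(
                    doc_id=doc_id,
                    annotator_id=annotator_id,
                    spans=_dedup_spans(spans, doc_id, annotator_id),
                    submitted_at=_parse_timestamp(
                        record.get("submitted_at"), f"line {lineno}"
                    ),
                )
            )
    return sets


def _read_submissions_csv(
    path: Path, column_map: Mapping[str, str] | None, delimiter: str = ","
) -> list[AnnotationSet]:
    colmap = {name: name for name in CSV_COLUMNS}
    if column_map:
        colmap.update(column_map)
    grouped: dict[tuple[str, str], list[Span]] = defaultdict(list)
    stamps: dict[tuple[str, str], datetime] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return []
        for required in ("doc_id", "annotator_id", "start", "end"):
            if colmap[required] not in reader.fieldnames:
                raise SubmissionReadError(
                    f"missing required column {colmap[required]!r}"
                )
        for rowno, row in enumerate(reader, start=2):
            where = f"row {rowno}"
            try:
                doc_id = row[colmap["doc_id"]]
                annotator_id = row[colmap["annotator_id"]]
                span = Span(
                    int(row[colmap["start"]]),
                    int(row[colmap["end"]]),
                    row.get(colmap["surface"], "") or "",
                    row.get(colmap["entity_type"]) or "Disease",
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise SubmissionReadError(f"{where}: malformed row ({exc})") from exc
            key = (doc_id, annotator_id)
            grouped[key].append(span)
            ts = _parse_timestamp(row.get(colmap["submitted_at"]), where)
            if ts is not None and (key not in stamps or ts > stamps[key]):
                stamps[key] = ts
    return [
        AnnotationSet(
            doc_id=doc_id,
            annotator_id=annotator_id,
            spans=_dedup_spans(spans, doc_id, annotator_id),
            submitted_at=stamps.get((doc_id, annotator_id)),
        )
        for (doc_id, annotator_id), spans in grouped.items()
    ]


def write_annotations(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    """Write annotation sets as JSONL; ``read_submissions`` round-trips it."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sub in sets:
            record = {
                "doc_id": sub.doc_id,
                "annotator_id": sub.annotator_id,
                "submitted_at": (
                    sub.submitted_at.isoformat() if sub.submitted_at else None
                ),
                "spans": [
                    {
                        "start": s.start,
                        "end": s.end,
                        "surface": s.surface,
                        "entity_type": s.entity_type,
                    }
                    for s in sorted(sub.spans, key=lambda s: s.key)
                ],
            }
            fh.write(json.dumps(record) + "\n")


def read_users(path: str | Path) -> dict[str, UserActivity]:
    """Read the users sidecar CSV (annotator_id, account_created, last_submission)."""
    path = Path(path)
    users: dict[str, UserActivity] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for rowno, row in enumerate(reader, start=2):
            try:
                created = date.fromisoformat(row["account_created"])
            except (KeyError, ValueError) as exc:
                raise SubmissionReadError(
                    f"row {rowno}: bad account_created"
                ) from exc
            last = _parse_timestamp(row.get("last_submission"), f"row {rowno}")
            if last is None:
                raise SubmissionReadError(f"row {rowno}: missing last_submission")
            users[row["annotator_id"]] = UserActivity(created, last)
    return users


def write_users(users: Mapping[str, UserActivity], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["annotator_id", "account_created", "last_submission"])
        for uid in sorted(users):
            act = users[uid]
            writer.writerow(
                [uid, act.account_created.isoformat(), act.last_submission.isoformat()]
            )
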