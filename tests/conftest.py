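"""Shared fixtures: a tiny hand-built corpus and a toy three-annotator log."""

from __future__ import annotations

from datetime import datetime

import pytest
from hypothesis import settings

from crowdner import AnnotationSet, Corpus, Document, Span, SubmissionLog

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_doc() -> Document:
    # title is 23 characters; "Colorectal cancer" occupies [0, 17)
    return Document(
        doc_id="123",
        title="Colorectal cancer study",
        abstract="We studied families.",
    )


@pytest.fixture
def toy_corpus(toy_doc: Document) -> Corpus:
    gold = AnnotationSet(
        "123", "expert", frozenset({Span(0, 17, "Colorectal cancer")})
    )
    return Corpus(documents={"123": toy_doc}, gold={"123": gold})


def make_set(doc_id: str, annotator_id: str, pairs, text: str) -> AnnotationSet:
    spans = frozenset(Span(s, e, text[s:e]) for s, e in pairs)
    return AnnotationSet(
        doc_id, annotator_id, spans, submitted_at=datetime(2015, 1, 20, 9, 0)
    )


@pytest.fixture
def toy_submissions(toy_doc: Document) -> list[AnnotationSet]:
    """u1:{(0,5)}, u2:{(0,5),(7,9)}, u3:{(0,5)} over the toy document."""
    text = toy_doc.text
    return [
        make_set("123", "u1", [(0, 5)], text),
        make_set("123", "u2", [(0, 5), (7, 9)], text),
        make_set("123", "u3", [(0, 5)], text),
    ]


@pytest.fixture
def toy_log(toy_submissions) -> SubmissionLog:
    return SubmissionLog.build(toy_submissions)
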