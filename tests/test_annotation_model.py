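"""I/O and invariants of the document / span / submission data model."""

from __future__ import annotations

from datetime import date, datetime

import pytest

from crowdner import (
    AnnotationSet,
    Span,
    UserActivity,
    read_pubtator,
    read_submissions,
    read_users,
    write_annotations,
    write_pubtator,
    write_users,
)
from crowdner.annotation_model import (
    PubtatorParseError,
    SpanValidationError,
    SubmissionReadError,
)

PUBTATOR = (
    "123|t|Colorectal cancer study\n"
    "123|a|We studied families.\n"
    "123\t0\t17\tColorectal cancer\tDisease\tD015179\n"
)


class TestSpan:
    def test_identity_is_offset_type_triple(self):
        assert Span(0, 5, "aaaaa") == Span(0, 5, "bbbbb")
        assert Span(0, 5, "x" * 5) != Span(0, 5, "x" * 5, entity_type="Gene")
        assert len({Span(0, 5, "aaaaa"), Span(0, 5, "bbbbb")}) == 1

    @pytest.mark.parametrize("start,end", [(5, 5), (6, 5), (-1, 3)])
    def test_degenerate_offsets_rejected(self, start, end):
        with pytest.raises(SpanValidationError):
            Span(start, end, "x")

    def test_document_text_is_title_space_abstract(self, toy_doc):
        assert toy_doc.text == "Colorectal cancer study We studied families."
        assert len(toy_doc.text) == len(toy_doc.title) + 1 + len(toy_doc.abstract)


class TestReadPubtator:
    def test_parses_document_and_gold_span(self, tmp_path):
        path = tmp_path / "corpus.txt"
        path.write_text(PUBTATOR)
        corpus = read_pubtator(path)
        assert len(corpus) == 1
        (span,) = corpus.gold["123"].spans
        assert span == Span(0, 17, "Colorectal cancer")
        assert span.surface == corpus.documents["123"].text[0:17]
        assert span.concept == "D015179"
        assert corpus.gold["123"].annotator_id == "expert"

    def test_document_without_annotations_gets_empty_gold(self, tmp_path):
        path = tmp_path / "corpus.txt"
        path.write_text("9|t|A title\n9|a|An abstract.\n")
        corpus = read_pubtator(path)
        assert corpus.gold["9"].spans == frozenset()

    def test_out_of_bounds_annotation_rejected(self, tmp_path):
        path = tmp_path / "corpus.txt"
        path.write_text("9|t|Tiny\n9|a|Text\n9\t0\t999\tTiny\tDisease\n")
        with pytest.raises(SpanValidationError, match="9"):
            read_pubtator(path)

    def test_surface_mismatch_error_names_doc_and_offsets(self, tmp_path):
        path = tmp_path / "corpus.txt"
        path.write_text("9|t|Tiny\n9|a|Text\n9\t0\t4\tWRNG\tDisease\n")
        with pytest.raises(SpanValidationError, match=r"9.*\(0,4\)"):
            read_pubtator(path)
        # lenient mode downgrades the mismatch to a warning
        corpus = read_pubtator(path, lenient=True)
        assert len(corpus.gold["9"].spans) == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "corpus.txt"
        path.write_text("9|t|Tiny\nnot a valid line\n")
        with pytest.raises(PubtatorParseError, match="line 2"):
            read_pubtator(path)

    def test_pubtator_round_trip(self, tmp_path, toy_corpus):
        path = tmp_path / "corpus.txt"
        write_pubtator(toy_corpus, path)
        again = read_pubtator(path)
        assert again.documents["123"].text == toy_corpus.documents["123"].text
        assert again.gold["123"].spans == toy_corpus.gold["123"].spans


class TestSubmissionsIO:
    def test_jsonl_round_trip_up_to_ordering(self, tmp_path, toy_corpus, toy_submissions):
        path = tmp_path / "subs.jsonl"
        write_annotations(toy_submissions, path)
        log = read_submissions(path, toy_corpus)
        original = {(s.doc_id, s.annotator_id): s.spans for s in toy_submissions}
        reread = {(s.doc_id, s.annotator_id): s.spans for s in log.submissions}
        assert reread == original
        assert all(
            s.submitted_at == datetime(2015, 1, 20, 9, 0) for s in log.submissions
        )

    def test_duplicate_spans_collapsed_with_warning(self, tmp_path, toy_corpus, caplog):
        path = tmp_path / "subs.jsonl"
        record = (
            '{"doc_id": "123", "annotator_id": "u1", "submitted_at": null,'
            ' "spans": [{"start": 0, "end": 5, "surface": "Color"},'
            ' {"start": 0, "end": 5, "surface": "Color"}]}'
        )
        path.write_text(record + "\n")
        with caplog.at_level("WARNING"):
            log = read_submissions(path, toy_corpus)
        assert len(log.submissions[0].spans) == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_file_gives_empty_log(self, tmp_path, toy_corpus):
        path = tmp_path / "subs.jsonl"
        path.write_text("")
        assert read_submissions(path, toy_corpus).submissions == []

    def test_unknown_doc_id_listed_in_error(self, tmp_path, toy_corpus):
        path = tmp_path / "subs.jsonl"
        path.write_text(
            '{"doc_id": "999", "annotator_id": "u1", "spans": []}\n'
        )
        with pytest.raises(SubmissionReadError, match="999"):
            read_submissions(path, toy_corpus)

    def test_unparseable_timestamp_names_line(self, tmp_path, toy_corpus):
        path = tmp_path / "subs.jsonl"
        path.write_text(
            '{"doc_id": "123", "annotator_id": "u1",'
            ' "submitted_at": "yesterday", "spans": []}\n'
        )
        with pytest.raises(SubmissionReadError, match="line 1"):
            read_submissions(path, toy_corpus)

    def test_csv_long_form_with_column_mapping(self, tmp_path, toy_corpus):
        path = tmp_path / "subs.csv"
        path.write_text(
            "pmid,user,begin,stop,surface,entity_type,submitted_at\n"
            "123,u1,0,5,Color,Disease,2015-01-20T09:00:00\n"
            "123,u1,7,9,ta,Disease,2015-01-20T09:05:00\n"
        )
        log = read_submissions(
            path,
            toy_corpus,
            column_map={"doc_id": "pmid", "annotator_id": "user",
                        "start": "begin", "end": "stop"},
        )
        (sub,) = log.submissions
        assert sub.spans == frozenset({Span(0, 5, "Color"), Span(7, 9, "ta")})
        assert sub.submitted_at == datetime(2015, 1, 20, 9, 5)

    def test_users_sidecar_round_trip(self, tmp_path):
        users = {
            "u1": UserActivity(date(2015, 1, 19), datetime(2015, 1, 20, 10)),
            "u2": UserActivity(date(2015, 2, 1), datetime(2015, 2, 1, 23, 59)),
        }
        path = tmp_path / "users.csv"
        write_users(users, path)
        assert read_users(path) == users

    def test_last_submission_before_creation_rejected(self):
        with pytest.raises(ValueError):
            UserActivity(date(2015, 2, 1), datetime(2015, 1, 1))


class TestSubmissionLog:
    def test_user_activity_derived_from_timestamps(self, toy_log):
        assert set(toy_log.users) == {"u1", "u2", "u3"}
        act = toy_log.users["u1"]
        assert act.account_created == date(2015, 1, 20)
        assert act.last_submission == datetime(2015, 1, 20, 9, 0)

    def test_grouping_views(self, toy_log):
        assert set(toy_log.by_document()) == {"123"}
        assert len(toy_log.by_document()["123"]) == 3
        assert toy_log.annotator_ids() == ["u1", "u2", "u3"]

    def test_annotation_set_coerces_and_dedups_spans(self):
        s = AnnotationSet("d", "u", [Span(0, 2, "ab"), Span(0, 2, "ab")])
        assert isinstance(s.spans, frozenset)
        assert len(s.spans) == 1

    def test_gold_for_unknown_document_rejected(self, toy_doc):
        from crowdner import Corpus

        with pytest.raises(ValueError):
            Corpus(
                documents={},
                gold={"123": AnnotationSet("123", "expert", frozenset())},
            )
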