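"""The study simulator: corpus construction, error modes, closed-form recall."""

from __future__ import annotations

import numpy as np
import pytest

from crowdner import (
    expected_recall,
    generate_corpus,
    simulate_annotator,
    simulate_study,
)
from crowdner.synthetic_data import AnnotatorProfile, CorpusParams, StudyParams


def small_corpus_params(**overrides) -> CorpusParams:
    defaults = dict(n_docs=5, tokens_per_doc=(30, 40), entities_per_doc=(1, 3),
                    rng_seed=0)
    defaults.update(overrides)
    return CorpusParams(**defaults)


class TestGenerateCorpus:
    def test_two_token_entity_has_internal_space(self):
        params = CorpusParams(
            n_docs=1, tokens_per_doc=(20, 20), entities_per_doc=(1, 1),
            entity_length_weights={2: 1.0}, rng_seed=4,
        )
        corpus = generate_corpus(params)
        (doc_id,) = corpus.documents
        (span,) = corpus.gold[doc_id].spans
        assert span.surface.count(" ") == 1
        assert span.surface == corpus.documents[doc_id].text[span.start:span.end]

    def test_same_seed_identical_corpus(self):
        a = generate_corpus(small_corpus_params())
        b = generate_corpus(small_corpus_params())
        assert a.documents == b.documents
        assert {d: s.spans for d, s in a.gold.items()} == {
            d: s.spans for d, s in b.gold.items()
        }

    def test_different_seed_differs(self):
        a = generate_corpus(small_corpus_params(rng_seed=0))
        b = generate_corpus(small_corpus_params(rng_seed=1))
        assert a.documents != b.documents

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            CorpusParams(
                n_docs=1, tokens_per_doc=(5, 10), entities_per_doc=(3, 3),
                entity_length_weights={4: 1.0},
            ).validate()

    def test_gold_feedback_fraction_flagged(self):
        corpus = generate_corpus(small_corpus_params(n_docs=10))
        flagged = sum(d.is_gold_feedback for d in corpus.documents.values())
        assert flagged == 1  # ceil(0.1 * 10)

    def test_gold_spans_do_not_overlap(self):
        corpus = generate_corpus(small_corpus_params(n_docs=10, rng_seed=9))
        for gold in corpus.gold.values():
            spans = sorted(gold.spans, key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                assert a.end < b.start  # separated by >= 1 token


class TestSimulateAnnotator:
    @pytest.fixture
    def doc_and_gold(self):
        corpus = generate_corpus(small_corpus_params(n_docs=1, rng_seed=8))
        (doc_id,) = corpus.documents
        return corpus.documents[doc_id], corpus.gold[doc_id]

    def test_noiseless_recovers_gold_exactly(self, doc_and_gold):
        doc, gold = doc_and_gold
        profile = AnnotatorProfile("u", p_detect=1.0, p_boundary=0.0,
                                   p_split=0.0, spurious_rate=0.0)
        result = simulate_annotator(profile, doc, gold, np.random.default_rng(0))
        assert result.spans == gold.spans

    def test_zero_detection_gives_empty_set(self, doc_and_gold):
        doc, gold = doc_and_gold
        profile = AnnotatorProfile("u", p_detect=0.0, spurious_rate=0.0)
        result = simulate_annotator(profile, doc, gold, np.random.default_rng(0))
        assert result.spans == frozenset()

    def test_split_emits_word_pieces_not_matching_gold(self):
        params = CorpusParams(
            n_docs=1, tokens_per_doc=(20, 20), entities_per_doc=(1, 1),
            entity_length_weights={2: 1.0}, rng_seed=4,
        )
        corpus = generate_corpus(params)
        (doc_id,) = corpus.documents
        doc, gold = corpus.documents[doc_id], corpus.gold[doc_id]
        profile = AnnotatorProfile("u", p_detect=1.0, p_boundary=0.0,
                                   p_split=1.0, spurious_rate=0.0)
        result = simulate_annotator(profile, doc, gold, np.random.default_rng(0))
        (gold_span,) = gold.spans
        assert len(result.spans) == 2
        assert gold_span not in result.spans
        for piece in result.spans:
            assert gold_span.start <= piece.start < piece.end <= gold_span.end
            assert " " not in piece.surface

    def test_boundary_shift_moves_one_token_edge(self, doc_and_gold):
        doc, gold = doc_and_gold
        profile = AnnotatorProfile("u", p_detect=1.0, p_boundary=1.0,
                                   p_split=0.0, spurious_rate=0.0)
        result = simulate_annotator(profile, doc, gold, np.random.default_rng(3))
        assert len(result.spans) == len(gold.spans)
        for span in result.spans:
            # each emitted span overlaps exactly one gold span, differs at
            # most by one token on one side
            overlapping = [g for g in gold.spans if g.overlap(span) > 0]
            assert len(overlapping) == 1

    def test_spurious_marks_avoid_gold_tokens(self, doc_and_gold):
        doc, gold = doc_and_gold
        profile = AnnotatorProfile("u", p_detect=0.0, spurious_rate=5.0)
        result = simulate_annotator(profile, doc, gold, np.random.default_rng(1))
        for span in result.spans:
            assert all(g.overlap(span) == 0 for g in gold.spans)
            assert " " not in span.surface


class TestSimulateStudy:
    def test_replication_and_perfect_aggregate(self):
        from crowdner import agreement_curve

        params = StudyParams.uniform_cohort(
            15,
            AnnotatorProfile("", p_detect=1.0, p_boundary=0.0, p_split=0.0,
                             spurious_rate=0.0),
            corpus=CorpusParams(n_docs=4, rng_seed=1),
            annotators_per_doc=15,
            rng_seed=1,
        )
        corpus, log, _ = simulate_study(params)
        by_doc = log.by_document()
        assert all(len(subs) == 15 for subs in by_doc.values())
        curve = agreement_curve(log, corpus)
        assert all(p.scores.f1 == 1.0 for p in curve.points)

    def test_determinism(self):
        params = StudyParams.uniform_cohort(
            8, corpus=CorpusParams(n_docs=3, rng_seed=6),
            annotators_per_doc=5, rng_seed=6,
        )
        _, log_a, _ = simulate_study(params)
        _, log_b, _ = simulate_study(params)
        key = lambda s: (s.doc_id, s.annotator_id)
        assert sorted(
            [(key(s), s.spans, s.submitted_at) for s in log_a.submissions]
        ) == sorted([(key(s), s.spans, s.submitted_at) for s in log_b.submissions])

    def test_too_few_annotators_rejected(self):
        params = StudyParams.uniform_cohort(
            3, corpus=CorpusParams(n_docs=2), annotators_per_doc=5
        )
        with pytest.raises(ValueError):
            simulate_study(params)

    def test_heavy_tail_concentrates_workload(self):
        params = StudyParams.uniform_cohort(
            40, corpus=CorpusParams(n_docs=60, rng_seed=3),
            annotators_per_doc=10, workload_alpha=0.4, rng_seed=3,
        )
        _, log, _ = simulate_study(params)
        counts = sorted(
            (len(subs) for subs in log.by_annotator().values()), reverse=True
        )
        top_quartile = sum(counts[: max(1, len(counts) // 4)])
        assert top_quartile / sum(counts) > 0.5

    def test_engagement_log_consistent_with_submissions(self):
        params = StudyParams.uniform_cohort(
            8, corpus=CorpusParams(n_docs=4, rng_seed=2),
            annotators_per_doc=5, rng_seed=2,
        )
        _, log, engagement = simulate_study(params)
        assert engagement.n_classifications == len(log.submissions)
        assert engagement.n_contributors == len(log.annotator_ids())
        assert sum(engagement.per_user_classifications.values()) == len(
            log.submissions
        )
        assert engagement.target_classifications == 4 * 5
        for uid, act in engagement.per_user_active.items():
            assert act.last_submission.date() >= act.account_created


class TestExpectedRecall:
    @pytest.mark.parametrize(
        "n,p,t,expected",
        [
            (5, 1.0, 0, 1.0),
            (5, 1.0, 70, 1.0),
            (2, 0.5, 0, 0.75),       # 1 - (1/2)^2, enumeration of 4 outcomes
            (3, 0.5, 50, 0.5),       # k=2: P(X>=2) = 4/8
            (4, 0.5, 100, 0.0625),   # all four detect
        ],
    )
    def test_enumeration_values(self, n, p, t, expected):
        assert expected_recall(n, p, t) == pytest.approx(expected)

    def test_monotone_in_threshold_and_detection(self):
        grid_t = range(0, 101, 5)
        for n in (3, 10, 15):
            for p in (0.2, 0.5, 0.8):
                values = [expected_recall(n, p, t) for t in grid_t]
                assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
            for t in (0, 30, 60, 100):
                by_p = [expected_recall(n, p, t) for p in (0.1, 0.4, 0.7, 1.0)]
                assert all(a <= b + 1e-12 for a, b in zip(by_p, by_p[1:]))

    @pytest.mark.parametrize("n,p,t", [(0, 0.5, 10), (3, 1.5, 10), (3, 0.5, 101)])
    def test_out_of_range_rejected(self, n, p, t):
        with pytest.raises(ValueError):
            expected_recall(n, p, t)
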