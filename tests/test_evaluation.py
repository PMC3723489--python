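import random

import pytest
from sklearn.metrics import cohen_kappa_score

from hypofinder.errors import ConsistencyError
from hypofinder.evaluation import (
    adjudicate,
    cohen_kappa,
    prf_from_counts,
    sentence_labels_from_spans,
    sentence_prf,
    span_prf,
)
from hypofinder.types import AnnotationSpan, Document, Label, SentenceLabel


def span(doc_id, start, end, surface="x"):
    return AnnotationSpan(doc_id, start, end, surface)


def label(doc_id, idx, positive):
    return SentenceLabel(doc_id, idx, Label.POSITIVE if positive else Label.NEGATIVE)


class TestSpanPRF:
    def test_perfect_agreement(self):
        spans = [span("1", 0, 5), span("1", 10, 15), span("2", 3, 8)]
        rep = span_prf(spans, list(spans))
        assert (rep.precision, rep.recall, rep.f_score) == (1.0, 1.0, 1.0)

    def test_hand_computed_counts(self):
        gold = [span("1", 0, 5), span("1", 10, 15), span("1", 20, 25)]
        pred = [span("1", 0, 5), span("1", 10, 15), span("1", 30, 35)]
        rep = span_prf(pred, gold)
        assert (rep.tp, rep.fp, rep.fn) == (2, 1, 1)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f_score == pytest.approx(2 / 3)

    def test_partial_overlap_by_criterion(self):
        gold = [span("1", 0, 17, "might be involved")]
        pred = [span("1", 0, 8, "might be")]
        exact = span_prf(pred, gold, criterion="exact")
        assert (exact.tp, exact.fp, exact.fn) == (0, 1, 1)
        overlap = span_prf(pred, gold, criterion="overlap")
        assert (overlap.tp, overlap.fp, overlap.fn) == (1, 0, 0)

    def test_overlap_pairing_is_one_to_one(self):
        gold = [span("1", 0, 10)]
        pred = [span("1", 0, 4), span("1", 5, 9)]
        rep = span_prf(pred, gold, criterion="overlap")
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 0)

    def test_order_invariance_exact(self):
        gold = [span("1", 0, 5), span("1", 10, 15)]
        pred = [span("1", 10, 15), span("1", 0, 5)]
        assert span_prf(pred, gold).f_score == 1.0

    def test_unknown_document_rejected(self):
        with pytest.raises(ConsistencyError):
            span_prf([span("ghost", 0, 2)], [], documents=[Document("1", "ab c")])


class TestSentencePRF:
    def test_all_correct(self):
        gold = [label("1", i, i % 2 == 0) for i in range(6)]
        rep = sentence_prf(gold, gold)
        assert (rep.precision, rep.recall, rep.f_score) == (1.0, 1.0, 1.0)

    def test_all_negative_predictor_degenerates_to_zero(self):
        gold = [label("1", 0, True), label("1", 1, False)]
        pred = [label("1", 0, False), label("1", 1, False)]
        rep = sentence_prf(pred, gold)
        assert (rep.precision, rep.recall, rep.f_score) == (0.0, 0.0, 0.0)

    def test_hand_computed_confusion(self):
        gold, pred = [], []
        i = 0
        for tp in range(8):
            gold.append(label("1", i, True)); pred.append(label("1", i, True)); i += 1
        for fp in range(2):
            gold.append(label("1", i, False)); pred.append(label("1", i, True)); i += 1
        for fn in range(4):
            gold.append(label("1", i, True)); pred.append(label("1", i, False)); i += 1
        for tn in range(6):
            gold.append(label("1", i, False)); pred.append(label("1", i, False)); i += 1
        rep = sentence_prf(pred, gold)
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(2 / 3)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            sentence_prf([label("1", 0, True)], [label("2", 0, True)])


class TestCohenKappa:
    def test_identical_labelings(self):
        a = [label("1", i, i % 2 == 0) for i in range(10)]
        rep = cohen_kappa(a, a)
        assert rep.kappa == pytest.approx(1.0)

    def test_total_disagreement_nonpositive(self):
        a = [label("1", i, True) for i in range(10)]
        b = [label("1", i, False) for i in range(10)]
        assert cohen_kappa(a, b).kappa <= 0.0

    def test_hand_computed_2x2_table(self):
        # 20 pos/pos, 5 pos/neg, 5 neg/pos, 20 neg/neg:
        # po = 0.8, pe = 0.5, kappa = 0.6
        a, b = [], []
        i = 0
        for n, (la, lb) in [(20, (1, 1)), (5, (1, 0)), (5, (0, 1)), (20, (0, 0))]:
            for _ in range(n):
                a.append(label("1", i, la)); b.append(label("1", i, lb)); i += 1
        rep = cohen_kappa(a, b)
        assert rep.observed_agreement == pytest.approx(0.8)
        assert rep.expected_agreement == pytest.approx(0.5)
        assert rep.kappa == pytest.approx(0.6)

    def test_matches_sklearn_reference(self):
        rng = random.Random(17)
        va = [rng.random() < 0.4 for _ in range(80)]
        vb = [a if rng.random() < 0.7 else rng.random() < 0.4
              for a in va]
        a = [label("1", i, x) for i, x in enumerate(va)]
        b = [label("1", i, x) for i, x in enumerate(vb)]
        ours = cohen_kappa(a, b).kappa
        ref = cohen_kappa_score([int(x) for x in va], [int(x) for x in vb])
        assert ours == pytest.approx(ref)

    def test_empty_unit_set_rejected(self):
        with pytest.raises(ConsistencyError):
            cohen_kappa([], [])

    def test_random_labelings_concentrate_near_zero(self):
        rng = random.Random(2024)
        kappas = []
        for _ in range(200):
            a = [label("1", i, rng.random() < 0.5) for i in range(300)]
            b = [label("1", i, rng.random() < 0.5) for i in range(300)]
            kappas.append(cohen_kappa(a, b).kappa)
        mean_abs = sum(abs(k) for k in kappas) / len(kappas)
        assert mean_abs < 0.1


class TestSentenceLabelsFromSpans:
    def test_positive_where_span_overlaps(self):
        doc = Document("1", "Tau may be toxic. Plaques were counted.")
        labels = sentence_labels_from_spans([doc], [span("1", 4, 10, "may be")])
        assert [l.label for l in labels] == [Label.POSITIVE, Label.NEGATIVE]

    def test_orphan_span_rejected(self):
        doc = Document("1", "Short text here.")
        with pytest.raises(ConsistencyError):
            sentence_labels_from_spans([doc], [span("other", 0, 4)])


class TestAdjudicate:
    def test_partial_overlap_reduced_to_intersection(self):
        text = "The protein might be involved in transport."
        doc = Document("1", text)
        start = text.index("might")
        a = [span("1", start, start + len("might be involved"), "might be involved")]
        b = [span("1", start, start + len("might be"), "might be")]
        merged = adjudicate(a, b, documents=[doc])
        assert len(merged) == 1
        assert merged[0].surface == "might be"

    def test_identical_sets_need_no_decisions(self):
        a = [span("1", 0, 5), span("1", 10, 15)]
        assert adjudicate(a, list(a)) == sorted(a, key=lambda s: s.start)

    def test_single_annotator_span_rejected_by_decision(self):
        a = [span("1", 0, 5), span("1", 20, 25)]
        b = [span("1", 0, 5)]
        merged = adjudicate(a, b, decisions={("1", 20, 25): "reject"})
        assert merged == [span("1", 0, 5)]

    def test_single_annotator_span_accepted_by_decision(self):
        a = [span("1", 0, 5)]
        b = [span("1", 0, 5), span("1", 20, 25)]
        merged = adjudicate(a, b, decisions={("1", 20, 25): "accept"})
        assert merged == [span("1", 0, 5), span("1", 20, 25)]

    def test_missing_decision_lists_disputed_spans(self):
        a = [span("1", 0, 5), span("1", 20, 25)]
        b = [span("1", 0, 5)]
        with pytest.raises(ConsistencyError, match=r"1\[20:25\]"):
            adjudicate(a, b)

    def test_never_invents_and_never_deletes_agreements(self):
        rng = random.Random(5)
        for _ in range(100):
            def random_spans():
                out = {}
                for _ in range(rng.randint(0, 6)):
                    start = rng.randrange(0, 40) * 5
                    end = start + rng.choice([5, 10, 15])
                    out[("1", start, end)] = span("1", start, end)
                return list(out.values())

            a, b = random_spans(), random_spans()
            keys_a = {(s.doc_id, s.start, s.end) for s in a}
            keys_b = {(s.doc_id, s.start, s.end) for s in b}
            decisions = {}
            try:
                merged = adjudicate(a, b)
            except ConsistencyError:
                # supply decisions for every disputed span and retry
                decisions = {k: "accept" for k in (keys_a ^ keys_b)}
                merged = adjudicate(a, b, decisions=decisions)
            merged_keys = {(s.doc_id, s.start, s.end) for s in merged}
            union_cover = []
            for s in a + b:
                union_cover.append((s.start, s.end))
            # no invention: every merged span lies inside some input span pair
            for s in merged:
                assert any(us <= s.start and s.end <= ue for us, ue in union_cover)
            # no deletion of agreements
            assert keys_a & keys_b <= merged_keys
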