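import pytest

from hypofinder import ml
from hypofinder.errors import ConfigurationError, ConsistencyError
from hypofinder.evaluation import sentence_prf
from hypofinder.fixtures import FixtureSpec, generate_corpus
from hypofinder.pattern_dictionary import build_patterns, compile_index, seed_index
from hypofinder.types import AnnotationSpan, Document, Label

from conftest import make_dictionary, make_sentence

STUB_LEXICON = {
    "proteins": ("protein", True),
    "protein": ("protein", True),
    "regulate": ("regulate", False),
    "regulates": ("regulate", False),
    "may": ("may", False),
    "tau": ("tau", True),
}


@pytest.fixture
def provider():
    return ml.LexiconProvider(STUB_LEXICON)


class TestExtractFeatures:
    def test_base_features_are_folded_words(self):
        sent = make_sentence("proteins may regulate tau")
        feats = ml.extract_features(sent, "proteins may regulate tau", ["base"])
        assert feats == {
            "base:proteins": 1.0, "base:may": 1.0,
            "base:regulate": 1.0, "base:tau": 1.0,
        }

    def test_spec_features_from_dictionary_matches(self):
        text = "proteins may regulate tau"
        idx = compile_index(build_patterns(make_dictionary("may")))
        feats = ml.extract_features(make_sentence(text), text, ["spec"], index=idx)
        assert feats == {"spec:may": 1.0, "spec:__any__": 1.0}

    def test_noun_prefix_suffix_features(self, provider):
        text = "protein regulates"
        feats = ml.extract_features(make_sentence(text), text, ["lex"],
                                    provider=provider)
        for name in ["lex:p2:pr", "lex:p3:pro", "lex:p4:prot",
                     "lex:s2:in", "lex:s3:ein", "lex:s4:tein"]:
            assert feats[name] == 1.0
        # "regulates" lemmatizes to "regulate" and is not a noun
        assert "lex:p2:re" not in feats
        assert "lex:u:regulate" in feats

    def test_lemma_ngrams(self, provider):
        text = "proteins may regulate tau"
        feats = ml.extract_features(make_sentence(text), text, ["lex"],
                                    provider=provider)
        assert "lex:b:protein_may" in feats
        assert "lex:t:protein_may_regulate" in feats

    def test_lex_without_provider_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ml.extract_features(make_sentence("tau"), "tau", ["lex"])

    def test_namespace_separability(self, provider):
        text = "proteins may regulate tau"
        idx = compile_index(build_patterns(make_dictionary("may")))
        all_feats = ml.extract_features(make_sentence(text), text,
                                        ["base", "spec", "lex"],
                                        index=idx, provider=provider)
        no_spec = ml.extract_features(make_sentence(text), text, ["base", "lex"],
                                      index=idx, provider=provider)
        removed = set(all_feats) - set(no_spec)
        assert removed and all(name.startswith("spec:") for name in removed)


class TestBuildInstances:
    def _doc(self):
        return Document(
            "1",
            "Plaques formed early. Tau may be toxic here. Counts rose. Assays ran.",
        )

    def test_positive_where_span_overlaps_sentence(self):
        doc = self._doc()
        start = doc.text.index("may be")
        spans = [AnnotationSpan("1", start, start + 6, "may be")]
        instances = ml.build_instances([doc], spans)
        assert [i.gold_label for i in instances] == [
            Label.NEGATIVE, Label.POSITIVE, Label.NEGATIVE, Label.NEGATIVE]

    def test_straddling_span_rejected(self):
        from hypofinder.segmenter import segment

        doc = self._doc()
        segment(doc)
        boundary = doc.sentences[0].end
        spans = [AnnotationSpan("1", boundary - 4, boundary + 5, "xx")]
        with pytest.raises(ConsistencyError, match="straddles"):
            ml.build_instances([doc], spans)

    def test_empty_gold_all_negative(self):
        instances = ml.build_instances([self._doc()], [])
        assert all(i.gold_label is Label.NEGATIVE for i in instances)


def _split_fixture(seed, n_docs=100, train_frac=0.8, dictionary=None):
    spec = FixtureSpec(seed=seed, n_documents=n_docs, positive_rate=0.3,
                       distractor_rate=0.3, dictionary=dictionary)
    docs, spans, gold = generate_corpus(spec)
    cut = int(len(docs) * train_frac)
    train_docs, test_docs = docs[:cut], docs[cut:]
    train_ids = {d.doc_id for d in train_docs}
    train_spans = [s for s in spans if s.doc_id in train_ids]
    test_spans = [s for s in spans if s.doc_id not in train_ids]
    return (ml.build_instances(train_docs, train_spans),
            ml.build_instances(test_docs, test_spans))


def _f_score(model, instances):
    predicted = ml.predict(model, instances)
    gold = [l for l in _gold_labels(instances)]
    return sentence_prf(predicted, gold).f_score


def _gold_labels(instances):
    from hypofinder.types import SentenceLabel
    return [SentenceLabel(i.sentence.doc_id, i.sentence.index, i.gold_label)
            for i in instances]


class TestTrainPredict:
    def test_separable_instances_reach_training_accuracy_one(self):
        doc = Document("1", "Tau may be toxic. Plaques were counted.")
        start = doc.text.index("may be")
        instances = ml.build_instances(
            [doc], [AnnotationSpan("1", start, start + 6, "may be")])
        model = ml.train(instances, modes=["base"], seed=0)
        preds = ml.predict(model, instances)
        assert [p.label for p in preds] == [i.gold_label for i in instances]

    def test_single_class_training_rejected(self):
        doc = Document("1", "Tau rose. Plaques fell.")
        instances = ml.build_instances([doc], [])
        with pytest.raises(ValueError, match="single class"):
            ml.train(instances, modes=["base"])

    def test_same_seed_identical_predictions(self):
        train_inst, test_inst = _split_fixture(seed=21, n_docs=40)
        a = ml.train(train_inst, modes=["base"], seed=3)
        b = ml.train(train_inst, modes=["base"], seed=3)
        pa = [p.label for p in ml.predict(a, test_inst)]
        pb = [p.label for p in ml.predict(b, test_inst)]
        assert pa == pb

    def test_empty_sentence_gets_majority_fallback(self):
        train_inst, _ = _split_fixture(seed=22, n_docs=20)
        model = ml.train(train_inst, modes=["base"], seed=0)
        empty = ml.LabeledInstance(
            sentence=make_sentence("..."), text="...", gold_label=Label.NEGATIVE)
        (pred,) = ml.predict(model, [empty])
        assert pred.label is model.majority_label

    def test_spec_features_perfect_when_cues_determine_labels(self):
        """With cue features, cue-determined labels, and every pattern well
        represented in training, held-out F = 1."""
        from hypofinder.corpus_io import DictionaryFile
        from hypofinder.pattern_dictionary import build_patterns, compile_index, seed_dictionary

        small = DictionaryFile(seed_dictionary().entries[:15])
        idx = compile_index(build_patterns(small))
        train_inst, test_inst = _split_fixture(seed=23, n_docs=150,
                                               dictionary=small)
        model = ml.train(train_inst, modes=["spec"], seed=0, index=idx)
        assert _f_score(model, test_inst) == pytest.approx(1.0)

    def test_feature_family_ordering(self):
        """Speculative features lift MaxEnt above bag-of-words, and
        lexico-syntactic n-grams beat plain words.

        Needs the full study-scale corpus: bag-of-words errors come from
        the minority of cues whose every word also occurs in negatives,
        so small test splits may not sample any.
        """
        train_inst, test_inst = _split_fixture(seed=24, n_docs=500)
        idx = seed_index()
        provider = ml.LexiconProvider()
        f_base = _f_score(ml.train(train_inst, modes=["base"], seed=0), test_inst)
        f_both = _f_score(
            ml.train(train_inst, modes=["base", "spec"], seed=0, index=idx),
            test_inst)
        f_lex = _f_score(
            ml.train(train_inst, modes=["lex"], seed=0, provider=provider),
            test_inst)
        assert f_both > f_base
        assert f_lex > f_base

    def test_algorithm_switching(self):
        train_inst, test_inst = _split_fixture(seed=25, n_docs=30)
        for algo in ml.ALGORITHMS:
            model = ml.train(train_inst, algorithm=algo, modes=["base"], seed=0)
            preds = ml.predict(model, test_inst)
            assert len(preds) == len(test_inst)
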