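"""Machine-learning baseline for hypothetical-sentence classification.

Instances are sentences; the gold label is POSITIVE iff a gold speculative
span overlaps the sentence.  Three feature families are supported, kept in
separate namespaces so they can be switched on and off independently:

* ``base`` — one binary feature per case-folded word in the sentence;
* ``spec`` — one binary feature per dictionary pattern with at least one
  match in the sentence (the hand-crafted speculative cues);
* ``lex``  — lemma unigrams/bigrams/trigrams, 2/3/4-character prefixes and
  suffixes of noun tokens, and dependency triples when the configured
  linguistic provider supplies them.

The reference classifier is maximum entropy, i.e. L2-regularized
multinomial logistic regression (C = 1.0 by default); naive Bayes, k-NN,
decision trees and a linear SVM are available behind the same contract.
Linguistic analysis (lemmas, noun flags, dependencies) is pluggable: any
object with an ``analyze`` method works, and a deterministic lexicon-backed
provider is included so the family is usable without a parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, ConsistencyError
from .matcher import find_matches
from .pattern_dictionary import MatcherIndex
from .segmenter import segment
from .types import AnnotationSpan, Document, Label, Sentence, SentenceLabel

FEATURE_MODES = ("base", "spec", "lex")
ALGORITHMS = ("maxent", "naive_bayes", "knn", "decision_tree", "svm")


class LinguisticProvider(Protocol):
    """Supplies lemmas, noun flags and (optionally) dependency triples."""

    def analyze(self, tokens: Sequence[str]) -> list[tuple[str, bool]]:
        """Per word token: (lemma, is_noun)."""
        ...

    def dependencies(self, tokens: Sequence[str]) -> Optional[list[tuple[str, str, str]]]:
        """(head, relation, dependent) triples, or None when unavailable."""
        ...


class LexiconProvider:
    """Deterministic linguistic provider backed by a word -> (lemma, noun) table.

    Out-of-lexicon words fall back to a light suffix heuristic for the noun
    flag and to the folded surface as lemma.  Dependencies are never
    produced; a parser-backed provider can replace this object wholesale.
    """

    _NOUN_SUFFIXES = ("tion", "sion", "ment", "ness", "ity", "ism", "ase",
                      "ein", "eins", "osis", "emia", "oma")

    def __init__(self, lexicon: Optional[Mapping[str, tuple[str, bool]]] = None):
        self.lexicon = dict(lexicon or {})

    def analyze(self, tokens: Sequence[str]) -> list[tuple[str, bool]]:
        out = []
        for tok in tokens:
            folded = tok.casefold()
            if folded in self.lexicon:
                out.append(self.lexicon[folded])
            else:
                out.append((folded, folded.endswith(self._NOUN_SUFFIXES)))
        return out

    def dependencies(self, tokens: Sequence[str]) -> None:
        return None


def extract_features(
    sentence: Sentence,
    text: str,
    modes: Sequence[str],
    index: Optional[MatcherIndex] = None,
    provider: Optional[LinguisticProvider] = None,
) -> dict[str, float]:
    """Extract the requested feature families for one sentence."""
    modes = tuple(modes)
    for mode in modes:
        if mode not in FEATURE_MODES:
            raise ConfigurationError(f"unknown feature mode {mode!r}")
    features: dict[str, float] = {}
    words = [t for t in sentence.tokens if t.is_word]

    if "base" in modes:
        for t in words:
            features[f"base:{t.folded}"] = 1.0

    if "spec" in modes:
        if index is None:
            raise ConfigurationError("spec features need a compiled dictionary index")
        matches = find_matches(sentence, index, text)
        for m in matches:
            features[f"spec:{m.pattern_representative}"] = 1.0
        if matches:
            # aggregate indicator: some hand-crafted pattern occurred
            features["spec:__any__"] = 1.0

    if "lex" in modes:
        if provider is None:
            raise ConfigurationError("lex features need a linguistic provider")
        surfaces = [t.surface for t in words]
        analyses = provider.analyze(surfaces)
        lemmas = [lemma for lemma, _ in analyses]
        for lemma in lemmas:
            features[f"lex:u:{lemma}"] = 1.0
        for a, b in zip(lemmas, lemmas[1:]):
            features[f"lex:b:{a}_{b}"] = 1.0
        for a, b, c in zip(lemmas, lemmas[1:], lemmas[2:]):
            features[f"lex:t:{a}_{b}_{c}"] = 1.0
        for t, (_, is_noun) in zip(words, analyses):
            if not is_noun:
                continue
            for n in (2, 3, 4):
                if len(t.folded) >= n:
                    features[f"lex:p{n}:{t.folded[:n]}"] = 1.0
                    features[f"lex:s{n}:{t.folded[-n:]}"] = 1.0
        triples = provider.dependencies(surfaces)
        if triples:
            for head, rel, dep in triples:
                features[f"lex:d:{head}_{rel}_{dep}"] = 1.0
    return features


def build_instances(
    documents: Sequence[Document], gold_spans: Sequence[AnnotationSpan]
) -> list["LabeledInstance"]:
    """One labeled instance per sentence; POSITIVE iff a gold span overlaps it.

    A span that overlaps no sentence, or straddles a sentence boundary, is a
    consistency error (annotation and text disagree).
    """
    instances: list[LabeledInstance] = []
    covered = [0] * len(gold_spans)
    for doc in documents:
        if not doc.sentences:
            segment(doc)
        for sentence in doc.sentences:
            positive = False
            for i, span in enumerate(gold_spans):
                if span.doc_id != doc.doc_id:
                    continue
                if span.start < sentence.end and sentence.start < span.end:
                    covered[i] += 1
                    positive = True
            instances.append(
                LabeledInstance(
                    sentence=sentence,
                    text=doc.text,
                    gold_label=Label.POSITIVE if positive else Label.NEGATIVE,
                )
            )
    for i, count in enumerate(covered):
        span = gold_spans[i]
        if count == 0:
            raise ConsistencyError(
                f"gold span [{span.start}, {span.end}) of {span.doc_id!r} "
                "lies outside every sentence"
            )
        if count > 1:
            raise ConsistencyError(
                f"gold span [{span.start}, {span.end}) of {span.doc_id!r} "
                "straddles a sentence boundary"
            )
    return instances


@dataclass
class LabeledInstance:
    sentence: Sentence
    text: str  # document text the sentence offsets index into
    gold_label: Label


@dataclass
class TrainedModel:
    algorithm: str
    modes: tuple[str, ...]
    vectorizer: DictVectorizer
    estimator: object
    majority_label: Label
    index: Optional[MatcherIndex] = None
    provider: Optional[LinguisticProvider] = None
    metadata: dict = field(default_factory=dict)


def _as_int32_csr(X):
    # tree/neighbor estimators reject 64-bit sparse indices
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32, copy=False)
    X.indptr = X.indptr.astype(np.int32, copy=False)
    return X


def _make_estimator(algorithm: str, seed: int, C: float):
    if algorithm == "maxent":
        return LogisticRegression(C=C, max_iter=2000, random_state=seed)
    if algorithm == "naive_bayes":
        return BernoulliNB()
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "svm":
        return LinearSVC(C=C, random_state=seed)
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def train(
    instances: Sequence[LabeledInstance],
    algorithm: str = "maxent",
    modes: Sequence[str] = ("base",),
    seed: int = 0,
    index: Optional[MatcherIndex] = None,
    provider: Optional[LinguisticProvider] = None,
    C: float = 1.0,
) -> TrainedModel:
    """Train a sentence classifier on labeled instances.

    Deterministic given the seed; raises on a single-class training set.
    """
    if len(instances) < 2:
        raise ValueError("need at least 2 training instances")
    labels = [inst.gold_label for inst in instances]
    if len(set(labels)) < 2:
        raise ValueError("training set contains a single class")
    feats = [
        extract_features(inst.sentence, inst.text, modes, index=index, provider=provider)
        for inst in instances
    ]
    vectorizer = DictVectorizer(sparse=True)
    X = _as_int32_csr(vectorizer.fit_transform(feats))
    y = [l.value for l in labels]
    estimator = _make_estimator(algorithm, seed, C)
    estimator.fit(X, y)
    counts = {l: labels.count(l) for l in set(labels)}
    majority = max(sorted(counts, key=lambda l: l.value), key=lambda l: counts[l])
    return TrainedModel(
        algorithm=algorithm,
        modes=tuple(modes),
        vectorizer=vectorizer,
        estimator=estimator,
        majority_label=majority,
        index=index,
        provider=provider,
        metadata={
            "n_instances": len(instances),
            "n_positive": sum(1 for l in labels if l is Label.POSITIVE),
            "seed": seed,
            "C": C,
        },
    )


def predict(
    model: TrainedModel,
    instances: Sequence[LabeledInstance],
) -> list[SentenceLabel]:
    """Predict one label per sentence; featureless sentences fall back to
    the training majority class."""
    out: list[Optional[SentenceLabel]] = [None] * len(instances)
    feats: list[dict[str, float]] = []
    rows: list[int] = []
    for i, inst in enumerate(instances):
        f = extract_features(
            inst.sentence, inst.text, model.modes,
            index=model.index, provider=model.provider,
        )
        if not f:
            out[i] = SentenceLabel(inst.sentence.doc_id, inst.sentence.index,
                                   model.majority_label)
        else:
            feats.append(f)
            rows.append(i)
    if feats:
        X = _as_int32_csr(model.vectorizer.transform(feats))
        for i, pred in zip(rows, model.estimator.predict(X)):
            inst = instances[i]
            out[i] = SentenceLabel(inst.sentence.doc_id, inst.sentence.index,
                                   Label(pred))
    return out


def instances_from_documents(documents: Sequence[Document]) -> list[LabeledInstance]:
    """Unlabeled instances (label NEGATIVE placeholder) for prediction."""
    out = []
    for doc in documents:
        if not doc.sentences:
            segment(doc)
        for sentence in doc.sentences:
            out.append(LabeledInstance(sentence=sentence, text=doc.text,
                                       gold_label=Label.NEGATIVE))
    return out
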