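"""Synthetic labeled corpora with the statistical structure the detector assumes.

Every sentence is built from a shared scaffold of the form
``<framing> X <verb slot> Y <framing>``, where X is a biomedical agent, Y
an affected process, and the framing carries one of four discourse
flavors — inferences, results and conclusions, argumentative sentences,
and open questions.  Scaffolds and frames are drawn identically for both
classes, so neither content words nor discourse framing carry label
signal.  What differs is only the verb slot: a positive sentence plants
exactly one dictionary surface form there (at a recorded offset); a
negative sentence fills it with a factual connector.

The factual connectors deliberately re-use speculation-cue vocabulary in
non-cue arrangements — negated ability ("could not be linked to"),
reported past belief ("was long thought unrelated to"), factual relation
("was not related to", "is involved in") — and negatives can additionally
be salted with near-miss distractor clauses built around the bare weak
terms the seed dictionary excludes ("potential", "possibility", "should",
"would", "remains to be elucidated").  This reproduces the property of
real abstracts that cue *words* are class-ambiguous while cue *sequences*
are not: bag-of-words features degrade, exact sequence matching does not.

Every negative scaffold x connector x distractor combination is verified
against the planting dictionary at generation time, so gold labels are
correct by construction, and generation is fully deterministic per seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .classify import classify_corpus
from .corpus_io import DictionaryFile
from .errors import ConfigurationError, ConsistencyError
from .matcher import find_matches
from .pattern_dictionary import (
    MatcherIndex,
    build_patterns,
    compile_index,
    seed_dictionary,
)
from .segmenter import segment, segment_text
from .types import AnnotationSpan, Document, Label, SentenceLabel

CONTROL_CATEGORIES = (
    "inferences",
    "results_and_conclusions",
    "argumentative",
    "open_questions",
)

# shared content frames: an agent (X) and an affected process (Y); both
# pools are free of dictionary forms and of tokens that could extend a
# planted cue into a longer form
SUBJECTS = [
    "Elevated CSF tau",
    "Soluble amyloid oligomers",
    "Apolipoprotein E genotype",
    "Chronic microglial activation",
    "Loss of presenilin function",
    "Impaired insulin signaling",
    "Synaptic zinc release",
    "Aberrant complement activation",
]

OBJECTS = [
    "neurodegeneration in vulnerable circuits",
    "synaptic failure in the aging hippocampus",
    "tau phosphorylation in cortical neurons",
    "cognitive decline in risk-allele carriers",
    "axonal transport deficits",
    "hippocampal atrophy in prodromal disease",
    "microglial priming near plaques",
    "oxidative stress in aging neurons",
]

# discourse scaffolds, shared by both classes; {V} is the verb slot
SCAFFOLDS: dict[str, list[str]] = {
    "inferences": [
        "Taken together these data demonstrate that {X} {V} {Y}.",
        "These observations establish that {X} {V} {Y}.",
        "We conclude from these measurements that {X} {V} {Y}.",
        "On the combined evidence, {X} {V} {Y}.",
    ],
    "results_and_conclusions": [
        "{X} {V} {Y} in this cohort.",
        "In May 2012, {X} {V} {Y}.",
        "In the randomized arm, {X} {V} {Y}.",
        "Under the prespecified analysis, {X} {V} {Y}.",
    ],
    "argumentative": [
        "There is increasing evidence that {X} {V} {Y}.",
        "It is widely agreed that {X} {V} {Y}.",
        "The amyloid hypothesis notwithstanding, {X} {V} {Y}.",
        "Most reviews hold that {X} {V} {Y}.",
    ],
    "open_questions": [
        "Whether {X} {V} {Y} remains to be elucidated.",
        "To what extent {X} {V} {Y} remains unclear.",
        "Whether {X} {V} {Y} is not yet established.",
        "How far {X} {V} {Y} remains an open question.",
    ],
}

# factual verb-slot connectors for negatives, with draw weights.  The
# near-miss connectors (negated ability, negative results, reported prior
# belief) are weighted up: negative-result phrasing dominates real
# abstracts, and it is what makes cue vocabulary class-ambiguous.
FACTUAL_CONNECTORS: list[tuple[str, int]] = [
    ("drives", 1),
    ("robustly increases", 1),
    ("directly regulates", 1),
    ("strongly predicts", 1),
    ("does not alter", 2),
    ("fails to modify", 1),
    ("can cause", 1),
    ("can beneficially influence", 1),
    ("is involved in", 3),
    ("plays a central role in", 1),
    ("shows no association with", 1),
    ("could not be linked to", 3),
    ("has not been linked to", 2),
    ("was not related to", 3),
    ("was not associated with", 3),
    ("was not due to", 2),
    ("was long thought unrelated to", 2),
    ("appears at elevated levels alongside", 2),
    ("was suggested previously to track", 2),
]

# class-neutral adjunct clauses appended (comma-separated) to sentences of
# either class.  They keep the high-frequency function words (that, is,
# was, to, be, a, the, not, has, been, there, it, we, May) equally common
# in both classes, the way real abstracts do; a comma token separates them
# from the sentence core, so they can never extend or form a cue sequence.
NEUTRAL_ADJUNCTS: list[str] = [
    ", a pattern that held at both sites",
    ", and it was clear that the assays were stable",
    ", though it has to be said that numbers were small",
    ", with follow-up visits each May",
    ", and there was no blinding of raters",
    ", on data available up to May 2014",
    ", though not in every cohort",
    ", and this has been the case at every site",
    ", as we also saw in the pilot phase",
    ", an effect that was not due to attrition",
    ", and it is a matter of record that consent was obtained",
    ", to the extent that the records allow",
]

# fraction of sentences (both classes) receiving a neutral adjunct
ADJUNCT_RATE = 0.7

# near-miss clauses built around bare weak terms the dictionary excludes
DISTRACTOR_CLAUSES: list[str] = [
    ", which should be addressed in future work",
    ", a potential confounder in earlier cohorts",
    ", although the possibility of selection bias remains",
    ", as earlier trials would demonstrate",
    ", and the mechanism remains to be elucidated before clinical translation",
    ", as originally proposed in earlier work",
    ", controlling for age and sex",
]


def negative_control_templates(category: str) -> list[str]:
    """Sentence scaffolds for one of the four negative-control categories."""
    if category not in SCAFFOLDS:
        raise ValueError(
            f"unknown control category {category!r}; expected one of {CONTROL_CATEGORIES}"
        )
    return list(SCAFFOLDS[category])


@dataclass
class FixtureSpec:
    """Parameters of a generated corpus.

    ``positive_rate`` is the fraction of sentences that receive a planted
    cue (exact count by default, Bernoulli when ``exact_counts`` is off);
    ``distractor_rate`` is the fraction of negatives salted with a
    near-miss clause.  The seed is mandatory: generation is deterministic.
    """

    seed: int
    n_documents: int = 50
    sentences_per_document: int = 5
    positive_rate: float = 0.2
    distractor_rate: float = 0.0
    negative_control_mix: Optional[dict[str, float]] = None
    dictionary: Optional[DictionaryFile] = None
    exact_counts: bool = True

    def __post_init__(self) -> None:
        for name in ("positive_rate", "distractor_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.negative_control_mix:
            unknown = set(self.negative_control_mix) - set(CONTROL_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown control categories: {sorted(unknown)}")


def _render(scaffold: str, x: str, y: str, verb: str,
            clause: Optional[str] = None) -> str:
    text = scaffold.format(X=x, V=verb, Y=y)
    if clause:
        text = text[:-1] + clause + "."
    return text


def verify_negative_templates(index: MatcherIndex) -> None:
    """Assert that no rendered negative (salted or not) contains a dictionary form.

    Neutral adjuncts are checked standalone: they attach behind a comma
    token, and no dictionary form contains punctuation, so a form can
    never span the junction.
    """
    for adjunct in NEUTRAL_ADJUNCTS:
        text = "Control" + adjunct + "."
        for sent in segment_text(text, doc_id="check"):
            if find_matches(sent, index, text):
                raise ConsistencyError(
                    f"neutral adjunct contains a dictionary form: {adjunct!r}"
                )
    for scaffolds in SCAFFOLDS.values():
        for scaffold in scaffolds:
            for verb, _weight in FACTUAL_CONNECTORS:
                for clause in [None, *DISTRACTOR_CLAUSES]:
                    # frame pools are cue-free; one representative pair plus
                    # the full pools once (clause-free) keeps this exhaustive
                    for x in SUBJECTS:
                        for y in OBJECTS if clause is None else OBJECTS[:1]:
                            text = _render(scaffold, x, y, verb, clause)
                            for sent in segment_text(text, doc_id="check"):
                                if find_matches(sent, index, text):
                                    raise ConsistencyError(
                                        "negative template contains a "
                                        f"dictionary form: {text!r}"
                                    )


def _all_surfaces(dictionary: DictionaryFile) -> list[str]:
    return [surface for entry in dictionary for surface in entry.surfaces()]


_connector_names = [c for c, _ in FACTUAL_CONNECTORS]
_connector_weights = [w for _, w in FACTUAL_CONNECTORS]


def _flat_scaffolds() -> list[str]:
    return [s for category in CONTROL_CATEGORIES for s in SCAFFOLDS[category]]


def generate_corpus(
    spec: FixtureSpec,
) -> tuple[list[Document], list[AnnotationSpan], list[SentenceLabel]]:
    """Generate (documents, gold cue spans, gold sentence labels)."""
    dictionary = spec.dictionary if spec.dictionary is not None else seed_dictionary()
    if spec.positive_rate > 0 and dictionary.n_entries == 0:
        raise ConfigurationError("positive_rate > 0 requires a non-empty dictionary")
    index = compile_index(build_patterns(dictionary))
    verify_negative_templates(index)

    rng = random.Random(spec.seed)
    surfaces = _all_surfaces(dictionary)
    all_scaffolds = _flat_scaffolds()
    mix = spec.negative_control_mix or {c: 1.0 for c in CONTROL_CATEGORIES}
    categories = sorted(mix)
    weights = [mix[c] for c in categories]

    n_total = spec.n_documents * spec.sentences_per_document
    if spec.exact_counts:
        n_pos = round(spec.positive_rate * n_total)
        positive_slots = set(rng.sample(range(n_total), n_pos))
        is_positive = [i in positive_slots for i in range(n_total)]
    else:
        is_positive = [rng.random() < spec.positive_rate for _ in range(n_total)]

    documents: list[Document] = []
    spans: list[AnnotationSpan] = []
    labels: list[SentenceLabel] = []
    slot = 0
    for d in range(spec.n_documents):
        doc_id = f"SYN{d:05d}"
        parts: list[str] = []
        offset = 0
        for s in range(spec.sentences_per_document):
            if parts:
                offset += 1  # the joining space
            x = SUBJECTS[rng.randrange(len(SUBJECTS))]
            y = OBJECTS[rng.randrange(len(OBJECTS))]
            if is_positive[slot]:
                scaffold = all_scaffolds[rng.randrange(len(all_scaffolds))]
                cue = surfaces[rng.randrange(len(surfaces))]
                head, tail = scaffold.split("{V}")
                prefix = head.format(X=x, Y=y)
                sentence_text = prefix + cue + tail.format(X=x, Y=y)
                cue_start = offset + len(prefix)
                spans.append(
                    AnnotationSpan(doc_id, cue_start, cue_start + len(cue), cue)
                )
                labels.append(SentenceLabel(doc_id, s, Label.POSITIVE))
            else:
                category = rng.choices(categories, weights=weights)[0]
                scaffolds = SCAFFOLDS[category]
                scaffold = scaffolds[rng.randrange(len(scaffolds))]
                verb = rng.choices(_connector_names, weights=_connector_weights)[0]
                clause = None
                if spec.distractor_rate and rng.random() < spec.distractor_rate:
                    clause = DISTRACTOR_CLAUSES[rng.randrange(len(DISTRACTOR_CLAUSES))]
                sentence_text = _render(scaffold, x, y, verb, clause)
                labels.append(SentenceLabel(doc_id, s, Label.NEGATIVE))
            if rng.random() < ADJUNCT_RATE:
                adjunct = NEUTRAL_ADJUNCTS[rng.randrange(len(NEUTRAL_ADJUNCTS))]
                sentence_text = sentence_text[:-1] + adjunct + "."
            parts.append(sentence_text)
            offset += len(sentence_text)
            slot += 1
        documents.append(Document(doc_id=doc_id, text=" ".join(parts)))

    # generator integrity: the segmenter must reproduce the planted layout
    for doc in documents:
        segment(doc)
        if len(doc.sentences) != spec.sentences_per_document:
            raise ConsistencyError(
                f"{doc.doc_id}: segmenter found {len(doc.sentences)} sentences, "
                f"expected {spec.sentences_per_document}"
            )
    for span in spans:
        doc = documents[int(span.doc_id[3:])]
        if doc.text[span.start:span.end] != span.surface:
            raise ConsistencyError(f"planted span misaligned in {span.doc_id}")
    return documents, spans, labels


def perfect_recovery_check(
    spec: FixtureSpec,
) -> tuple[list[Document], list[AnnotationSpan], list[SentenceLabel], list[SentenceLabel]]:
    """Generate a corpus and classify it with its own planting dictionary."""
    documents, spans, gold_labels = generate_corpus(spec)
    dictionary = spec.dictionary if spec.dictionary is not None else seed_dictionary()
    index = compile_index(build_patterns(dictionary))
    predicted = classify_corpus(documents, index)
    return documents, spans, gold_labels, predicted
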