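"""Sentence-level hypothesis classification and pattern-efficacy profiling.

A sentence is POSITIVE (hypothetical) exactly when the matcher finds at
least one speculative pattern in it; the matches are carried along as
evidence.  ``profile_efficacy`` reproduces the pattern-strength procedure:
collect the sentences a single pattern matches, sample at most ``cap`` of
them, and report the fraction a curator judged truly speculative as the
pattern's percent efficacy.
"""

from __future__ import annotations

import random
from typing import Mapping, Optional, Sequence

from .errors import ConsistencyError
from .matcher import find_matches
from .pattern_dictionary import MatcherIndex, SpeculativePattern, compile_index
from .segmenter import segment
from .types import (
    Document,
    EfficacyRecord,
    Label,
    Match,
    Sentence,
    SentenceLabel,
    Strength,
)

DEFAULT_EFFICACY_CAP = 50
DEFAULT_THRESHOLDS = (90.0, 50.0)  # (t_strong, t_weak), percent


def classify_sentence(sentence: Sentence, matches: Sequence[Match]) -> SentenceLabel:
    """POSITIVE iff at least one speculative pattern was matched."""
    for m in matches:
        if m.doc_id != sentence.doc_id or m.sentence_index != sentence.index:
            raise ConsistencyError(
                f"match {m.pattern_representative!r}@{m.doc_id}:{m.sentence_index} "
                f"does not belong to sentence {sentence.doc_id}:{sentence.index}"
            )
    label = Label.POSITIVE if matches else Label.NEGATIVE
    return SentenceLabel(
        doc_id=sentence.doc_id,
        sentence_index=sentence.index,
        label=label,
        supporting_matches=list(matches),
    )


def classify_corpus(
    documents: Sequence[Document], index: MatcherIndex
) -> list[SentenceLabel]:
    """Segment (if needed), match, and label every sentence in order."""
    labels: list[SentenceLabel] = []
    for doc in documents:
        if not doc.sentences:
            segment(doc)
        for sentence in doc.sentences:
            matches = find_matches(sentence, index, doc.text)
            labels.append(classify_sentence(sentence, matches))
    return labels


def corpus_matches(documents: Sequence[Document], index: MatcherIndex) -> list[Match]:
    """All matches over a corpus, document order preserved."""
    out: list[Match] = []
    for doc in documents:
        if not doc.sentences:
            segment(doc)
        for sentence in doc.sentences:
            out.extend(find_matches(sentence, index, doc.text))
    return out


def profile_efficacy(
    pattern: SpeculativePattern,
    documents: Sequence[Document],
    curated_labels: Mapping[tuple[str, int], bool],
    cap: int = DEFAULT_EFFICACY_CAP,
    seed: int = 0,
) -> EfficacyRecord:
    """Profile one pattern's percent efficacy over a corpus.

    ``curated_labels`` maps ``(doc_id, sentence_index)`` to the curator's
    judgement (True = speculative) and must cover the sampled sentences.
    When more than ``cap`` sentences contain the pattern, a uniform sample
    without replacement of size ``cap`` is drawn with the given seed.
    """
    single = compile_index([pattern])
    matched: list[tuple[str, int]] = []
    for label in classify_corpus(list(documents), single):
        if label.label is Label.POSITIVE:
            matched.append(label.key())

    count = len(matched)
    if count == 0:
        return EfficacyRecord(
            pattern_representative=pattern.representative,
            sentence_count=0,
            sampled_count=0,
            speculative_count=0,
            percent_efficacy=None,
        )
    if count > cap:
        sample = random.Random(seed).sample(matched, cap)
    else:
        sample = matched
    missing = [k for k in sample if k not in curated_labels]
    if missing:
        raise ConsistencyError(
            f"curated labels missing for {len(missing)} sampled sentences, "
            f"e.g. {missing[0]}"
        )
    speculative = sum(1 for k in sample if curated_labels[k])
    return EfficacyRecord(
        pattern_representative=pattern.representative,
        sentence_count=count,
        sampled_count=len(sample),
        speculative_count=speculative,
        percent_efficacy=100.0 * speculative / len(sample),
    )


def assign_strength(
    percent_efficacy: Optional[float],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> Strength:
    """Map percent efficacy to a strength class.

    ``thresholds = (t_strong, t_weak)``: efficacy >= t_strong is strong,
    < t_weak is weak, anything between is moderate.  A non-computable
    efficacy (pattern never observed) stays unclassified.
    """
    t_strong, t_weak = thresholds
    if not (0 <= t_weak < t_strong <= 100):
        raise ValueError(f"invalid thresholds (t_strong={t_strong}, t_weak={t_weak})")
    if percent_efficacy is None:
        return Strength.UNCLASSIFIED
    if percent_efficacy >= t_strong:
        return Strength.STRONG
    if percent_efficacy < t_weak:
        return Strength.WEAK
    return Strength.MODERATE
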