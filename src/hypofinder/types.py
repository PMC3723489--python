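"""Core record types shared across the toolkit.

All character offsets are 0-based, half-open, and index into the *document*
text (the whitespace-normalized abstract), never into a sentence-local
string.  Every record that carries a ``surface`` field promises that the
surface equals the document slice it points at; readers and writers enforce
this invariant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Label(str, enum.Enum):
    """Sentence-level hypothesis label."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class Strength(str, enum.Enum):
    """Strength class of a speculative pattern (by percent efficacy)."""

    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Token:
    """A word or punctuation token anchored to document text."""

    surface: str
    start: int
    end: int
    folded: str

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"empty token span [{self.start}, {self.end})")

    @property
    def is_word(self) -> bool:
        return self.surface[0].isalnum()


@dataclass
class Sentence:
    """An offset-anchored sentence: the unit of matching and classification."""

    doc_id: str
    index: int
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)

    def key(self) -> tuple[str, int]:
        return (self.doc_id, self.index)


@dataclass
class Document:
    """An abstract (optionally title-prefixed) identified by e.g. a PMID."""

    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not self.text:
            raise ValueError(f"document {self.doc_id!r} has empty text")


@dataclass(frozen=True)
class AnnotationSpan:
    """A standoff annotation of one speculative pattern occurrence."""

    doc_id: str
    start: int
    end: int
    surface: str
    label: str = "speculative_pattern"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) in {self.doc_id!r}"
            )


@dataclass(frozen=True)
class Match:
    """A dictionary hit: a pattern surface form found in a sentence."""

    doc_id: str
    sentence_index: int
    start: int
    end: int
    pattern_representative: str
    surface: str

    def span(self) -> AnnotationSpan:
        return AnnotationSpan(self.doc_id, self.start, self.end, self.surface)


@dataclass
class SentenceLabel:
    """The classifier's verdict for one sentence, with supporting matches."""

    doc_id: str
    sentence_index: int
    label: Label
    supporting_matches: list[Match] = field(default_factory=list)

    def key(self) -> tuple[str, int]:
        return (self.doc_id, self.sentence_index)


@dataclass
class EfficacyRecord:
    """Per-pattern profile: how often its sentences are truly speculative.

    ``percent_efficacy`` is ``None`` (not 0) when the pattern matched no
    sentence, so an unobserved pattern is never mistaken for a useless one.
    """

    pattern_representative: str
    sentence_count: int
    sampled_count: int
    speculative_count: int
    percent_efficacy: Optional[float]
    strength: Strength = Strength.UNCLASSIFIED


@dataclass
class EvalReport:
    """Precision/recall/F over a span- or sentence-level comparison."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    level: str = "span"
    criterion: str = "exact"


@dataclass
class AgreementReport:
    """Two-rater agreement (Cohen's kappa) over a shared unit set."""

    observed_agreement: float
    expected_agreement: float
    kappa: float
    unit: str = "sentence"
    n_units: int = 0
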