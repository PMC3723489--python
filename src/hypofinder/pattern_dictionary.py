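"""Speculative-pattern dictionary: expansion, composition, and indexing.

A dictionary entry groups a representative cue ("appear to") with its
synonymous surface forms (inflections and recombinations such as "appears
to be").  Forms are tokenized with the same tokenizer the matcher uses and
stored case-folded, so matching is case-insensitive by construction.

Bare weak cues ("potential", "possibility", "should", "would") are kept out
of the shipped seed dictionary in their original form: they mark a sentence
as speculative too rarely on their own, and are useful only after
composition with auxiliary phrases — see :func:`strengthen_weak`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from .corpus_io import DictionaryFile, read_dictionary
from .errors import DictionaryParseError
from .segmenter import tokenize
from .types import Strength

logger = logging.getLogger(__name__)

SEED_DICTIONARY_RESOURCE = "seed_dictionary_synthetic.txt"


@dataclass
class SpeculativePattern:
    """One speculative cue with all of its matchable surface forms."""

    representative: str
    synonyms: list[str]
    strength: Strength
    forms: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def surface_forms(self) -> list[tuple[str, ...]]:
        return self.forms


class Placement(str, enum.Enum):
    PREFIX = "prefix"
    SUFFIX = "suffix"


@dataclass(frozen=True)
class IndexedForm:
    tokens: tuple[str, ...]
    pattern: SpeculativePattern
    order: int  # position in the flattened dictionary, for tie-breaking


@dataclass
class MatcherIndex:
    """Token-sequence lookup over all surface forms of all patterns.

    Forms are bucketed by their first (case-folded) token; the matcher
    enumerates every form whose first token matches the scan position.
    First entry wins when two entries carry the same form (logged).
    """

    by_first: dict[str, list[IndexedForm]]
    n_forms: int
    patterns: list[SpeculativePattern]

    def forms_starting_with(self, folded_token: str) -> Sequence[IndexedForm]:
        return self.by_first.get(folded_token, ())

    def all_forms(self) -> list[IndexedForm]:
        return [f for bucket in self.by_first.values() for f in bucket]


def build_patterns(dictionary: DictionaryFile) -> list[SpeculativePattern]:
    """Turn parsed dictionary entries into tokenized, case-folded patterns."""
    patterns = []
    for entry in dictionary:
        forms: list[tuple[str, ...]] = []
        seen: set[tuple[str, ...]] = set()
        for surface in entry.surfaces():
            tokens = tokenize(surface)
            if not any(t.is_word for t in tokens):
                raise DictionaryParseError(
                    f"entry {entry.representative!r}: surface {surface!r} "
                    "collapses to zero word tokens"
                )
            toks = tuple(t.folded for t in tokens)
            if toks not in seen:
                seen.add(toks)
                forms.append(toks)
        patterns.append(
            SpeculativePattern(
                representative=entry.representative,
                synonyms=list(entry.synonyms),
                strength=entry.strength or Strength.UNCLASSIFIED,
                forms=forms,
            )
        )
    return patterns


def strengthen_weak(
    weak_term: str,
    modifiers: Sequence[str],
    placement: Placement | str = Placement.PREFIX,
    trailing: str = "",
) -> list[str]:
    """Compose a weak cue with auxiliary phrases into stronger surface forms.

    ``("potential", ["could be a"], PREFIX)`` yields ``["could be a
    potential"]``; a ``trailing`` word is appended after the composition,
    so ``("possibility", ["raising the"], PREFIX, trailing="that")`` yields
    ``["raising the possibility that"]``.  The bare weak term itself is
    never part of the result; with no modifiers the composition is empty
    and the term stays excluded.
    """
    if not weak_term or not weak_term.strip():
        raise ValueError("weak_term must be non-empty")
    placement = Placement(placement)
    composed = []
    for modifier in modifiers:
        modifier = modifier.strip()
        if not modifier:
            continue
        if placement is Placement.PREFIX:
            phrase = f"{modifier} {weak_term.strip()}"
        else:
            phrase = f"{weak_term.strip()} {modifier}"
        if trailing:
            phrase = f"{phrase} {trailing.strip()}"
        composed.append(phrase)
    return composed


def compile_index(patterns: Sequence[SpeculativePattern]) -> MatcherIndex:
    """Compile patterns into a matcher index (deterministic, first-entry-wins)."""
    if not patterns:
        raise DictionaryParseError("cannot compile an empty pattern set")
    by_first: dict[str, list[IndexedForm]] = {}
    owner: dict[tuple[str, ...], str] = {}
    order = 0
    n_forms = 0
    for pattern in patterns:
        for form in pattern.forms:
            if form in owner:
                logger.warning(
                    "duplicate surface form %r: kept under %r, ignored under %r",
                    " ".join(form), owner[form], pattern.representative,
                )
                continue
            owner[form] = pattern.representative
            by_first.setdefault(form[0], []).append(
                IndexedForm(tokens=form, pattern=pattern, order=order)
            )
            order += 1
            n_forms += 1
    return MatcherIndex(by_first=by_first, n_forms=n_forms, patterns=list(patterns))


def seed_dictionary() -> DictionaryFile:
    """Load the seed speculative-pattern dictionary shipped with the package.

    This is a synthetic reconstruction: it contains every cue printed in the
    literature examples the toolkit's tests exercise, filled out with
    standard English hedging cues and their inflectional variants to the
    published dictionary size (156 representative, 392 synonymous patterns).
    """
    with resources.as_file(
        resources.files("hypofinder.data").joinpath(SEED_DICTIONARY_RESOURCE)
    ) as path:
        return read_dictionary(path)


def seed_patterns() -> list[SpeculativePattern]:
    return build_patterns(seed_dictionary())


def seed_index() -> MatcherIndex:
    return compile_index(seed_patterns())


def dictionary_stats(dictionary: DictionaryFile) -> dict[str, int]:
    patterns = build_patterns(dictionary)
    distinct_forms = {form for p in patterns for form in p.forms}
    return {
        "representative_patterns": dictionary.n_entries,
        "synonymous_patterns": dictionary.n_synonyms,
        "distinct_surface_forms": len(distinct_forms),
    }
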