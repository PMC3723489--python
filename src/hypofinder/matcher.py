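"""Dictionary matching under case-insensitive, word-order-sensitive,
longest-exact-match semantics.

The scan is greedy left-to-right over sentence tokens: at each position the
longest dictionary form (counted in tokens) that matches the case-folded
token sequence exactly and contiguously is taken, the scan resumes after
it, and matches therefore never overlap.  Ties in token length are broken
by the longer character span, then by dictionary entry order.  Matching
never crosses sentence boundaries.

:func:`brute_force_matches` re-derives the same output by exhaustive
candidate enumeration and is used as the independent oracle in tests.
"""

from __future__ import annotations

from typing import Sequence

from .pattern_dictionary import MatcherIndex, SpeculativePattern
from .types import Match, Sentence


def find_matches(sentence: Sentence, index: MatcherIndex, text: str) -> list[Match]:
    """Find all non-overlapping longest matches in one sentence.

    ``text`` is the full document text the sentence's token offsets index
    into; matched surfaces are slices of it.
    """
    tokens = sentence.tokens
    n = len(tokens)
    matches: list[Match] = []
    i = 0
    while i < n:
        best = None  # (n_tokens, char_span, -order, form)
        for form in index.forms_starting_with(tokens[i].folded):
            length = len(form.tokens)
            if i + length > n:
                continue
            if any(tokens[i + k].folded != form.tokens[k] for k in range(1, length)):
                continue
            span = tokens[i + length - 1].end - tokens[i].start
            key = (length, span, -form.order)
            if best is None or key > best[0]:
                best = (key, form)
        if best is None:
            i += 1
            continue
        (length, _, _), form = best
        start = tokens[i].start
        end = tokens[i + length - 1].end
        matches.append(
            Match(
                doc_id=sentence.doc_id,
                sentence_index=sentence.index,
                start=start,
                end=end,
                pattern_representative=form.pattern.representative,
                surface=text[start:end],
            )
        )
        i += length
    return matches


def brute_force_matches(
    sentence: Sentence, patterns: Sequence[SpeculativePattern], text: str
) -> list[Match]:
    """Oracle: enumerate every (position, form) candidate directly, then
    apply the leftmost-longest non-overlapping selection.

    Works from the uncompiled pattern list and shares no code with
    :func:`find_matches` beyond the token representation.
    """
    tokens = sentence.tokens
    n = len(tokens)

    # global entry order mirrors compile_index's flattened ordering
    candidates = []  # (start_tok, n_tokens, char_span, order, pattern)
    order = 0
    seen_forms: set[tuple[str, ...]] = set()
    for pattern in patterns:
        for form in pattern.forms:
            if form in seen_forms:
                continue  # duplicate form: first entry owns it
            seen_forms.add(form)
            length = len(form)
            for start_tok in range(n - length + 1):
                if tuple(t.folded for t in tokens[start_tok:start_tok + length]) == form:
                    span = tokens[start_tok + length - 1].end - tokens[start_tok].start
                    candidates.append((start_tok, length, span, order, pattern))
            order += 1

    # leftmost first; at one position prefer more tokens, then a longer
    # character span, then earlier dictionary order.  Sweeping the sorted
    # list and accepting every candidate that starts at or past the free
    # cursor realises exactly the greedy non-overlapping selection.
    candidates.sort(key=lambda c: (c[0], -c[1], -c[2], c[3]))
    matches: list[Match] = []
    next_free = 0
    for start_tok, length, _span, _order, pattern in candidates:
        if start_tok < next_free:
            continue
        start = tokens[start_tok].start
        end = tokens[start_tok + length - 1].end
        matches.append(
            Match(
                doc_id=sentence.doc_id,
                sentence_index=sentence.index,
                start=start,
                end=end,
                pattern_representative=pattern.representative,
                surface=text[start:end],
            )
        )
        next_free = start_tok + length
    return matches
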