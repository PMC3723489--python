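"""Rule-based sentence segmentation and tokenization for abstracts.

The splitter is deliberately deterministic and dependency-free: abstracts
are short, well-punctuated text, and the downstream matcher only needs
stable, offset-faithful word units.  Sentence boundaries are sentence-final
punctuation followed by whitespace and an uppercase or opening character;
a fixed abbreviation list (shipped as package data) is protected from
splitting.
"""

from __future__ import annotations

import re
from importlib import resources

from .types import Document, Sentence, Token

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")
# characters a new sentence may start with
_SENTENCE_OPENERS = set('"“‘\'([')
# a single capitalised initial ("J. Smith") never ends a sentence
_INITIAL_RE = re.compile(r"(?:^|[\s(])[A-Za-z]\.$")


def _load_abbreviations() -> frozenset[str]:
    text = (
        resources.files("hypofinder.data").joinpath("abbreviations.txt").read_text()
    )
    out = set()
    for line in text.splitlines():
        line = line.strip().casefold()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


ABBREVIATIONS: frozenset[str] = _load_abbreviations()


def tokenize(text: str, base_offset: int = 0) -> list[Token]:
    """Split ``text`` into word and single-character punctuation tokens.

    Runs of letters/digits form word tokens; every other non-space character
    is emitted as its own token, so hyphens and parentheses are always token
    boundaries ("Abeta(1-42)" -> Abeta ( 1 - 42 )).  Offsets are relative to
    the enclosing document when ``base_offset`` is the slice start.
    """
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        surface = m.group(0)
        tokens.append(
            Token(
                surface=surface,
                start=base_offset + m.start(),
                end=base_offset + m.end(),
                folded=surface.casefold(),
            )
        )
    return tokens


def _is_boundary(text: str, punct_end: int) -> bool:
    """Decide whether the punctuation run ending at ``punct_end`` closes a sentence."""
    rest = text[punct_end:]
    stripped = rest.lstrip()
    if not stripped:
        return True
    nxt = stripped[0]
    if not (nxt.isupper() or nxt in _SENTENCE_OPENERS):
        return False
    head = text[:punct_end]
    folded = head.casefold()
    for abbr in ABBREVIATIONS:
        if folded.endswith(abbr):
            # require the abbreviation to start at a word boundary
            pre = folded[: len(folded) - len(abbr)]
            if not pre or not pre[-1].isalnum():
                return False
    if _INITIAL_RE.search(head):
        return False
    return True


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences in ``text`` (whitespace-trimmed)."""
    cuts = [0]
    for m in _BOUNDARY_RE.finditer(text):
        if _is_boundary(text, m.end()):
            cuts.append(m.end())
    cuts.append(len(text))
    spans = []
    for a, b in zip(cuts, cuts[1:]):
        chunk = text[a:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if a + lead < b - trail:
            spans.append((a + lead, b - trail))
    return spans


def segment_text(text: str, doc_id: str = "") -> list[Sentence]:
    sentences = []
    for i, (a, b) in enumerate(sentence_spans(text)):
        sentences.append(
            Sentence(
                doc_id=doc_id,
                index=i,
                start=a,
                end=b,
                tokens=tokenize(text[a:b], base_offset=a),
            )
        )
    return sentences


def segment(document: Document) -> list[Sentence]:
    """Segment a document in place and return its sentences."""
    document.sentences = segment_text(document.text, document.doc_id)
    return document.sentences
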