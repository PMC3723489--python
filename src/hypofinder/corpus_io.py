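"""Readers and writers for every external format the toolkit touches.

Formats
-------
* PMID-tagged plain text corpora: blocks separated by blank lines, each
  block starting with a ``PMID<TAB>id`` line followed by the abstract text
  (line breaks are normalized to single spaces, after which offsets are
  stable).  A directory of one-document files is also accepted.
* Pattern dictionary: one entry per line —
  ``representative<TAB>syn|syn|...<TAB>strength`` with both tab-separated
  fields optional.  Lines starting with ``#`` and blank lines are ignored.
* BioScope-dialect XML: ``<sentence>`` elements with nested ``<cue
  type="speculation">`` elements; negation cues and scope markup are read
  through but not extracted.
* Standoff TSV annotations and matches.
"""

from __future__ import annotations

import csv
import io
import os
from typing import Iterable, Optional, Sequence

from lxml import etree

from .errors import ConsistencyError, CorpusParseError, DictionaryParseError
from .types import AnnotationSpan, Document, Match, Strength

# ---------------------------------------------------------------------------
# plain-text corpora
# ---------------------------------------------------------------------------

_ID_PREFIX = "PMID"


def _parse_block(lines: list[str], block_no: int) -> Document:
    header = lines[0]
    parts = header.split("\t", 1)
    if parts[0].strip() != _ID_PREFIX or len(parts) < 2 or not parts[1].strip():
        raise CorpusParseError(
            f"block {block_no}: expected 'PMID<TAB>id' header, got {header!r}"
        )
    doc_id = parts[1].strip()
    text = " ".join(line.strip() for line in lines[1:] if line.strip())
    if not text:
        raise CorpusParseError(f"block {block_no} ({doc_id}): no abstract text")
    return Document(doc_id=doc_id, text=text)


def _read_blocks(handle: io.TextIOBase) -> list[Document]:
    documents: list[Document] = []
    block: list[str] = []
    block_no = 0
    seen: set[str] = set()

    def flush() -> None:
        nonlocal block_no
        if block:
            block_no += 1
            doc = _parse_block(block, block_no)
            if doc.doc_id in seen:
                raise CorpusParseError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            documents.append(doc)
            block.clear()

    for raw in handle:
        line = raw.rstrip("\n")
        if line.strip():
            block.append(line)
        else:
            flush()
    flush()
    return documents


def read_plain_corpus(path: str | os.PathLike) -> list[Document]:
    """Read a PMID-tagged plain-text corpus file or directory.

    An empty file yields an empty list; a block without a valid id line is a
    :class:`CorpusParseError` naming the block.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        documents = []
        for name in sorted(os.listdir(path)):
            full = os.path.join(path, name)
            if os.path.isfile(full):
                with open(full, encoding="utf-8") as fh:
                    documents.extend(_read_blocks(fh))
        return documents
    with open(path, encoding="utf-8") as fh:
        return _read_blocks(fh)


def write_plain_corpus(documents: Iterable[Document], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(f"{_ID_PREFIX}\t{doc.doc_id}\n{doc.text}\n\n")


# ---------------------------------------------------------------------------
# pattern dictionary
# ---------------------------------------------------------------------------

_STRENGTH_TOKENS = {s.value for s in Strength}


class DictionaryEntry:
    """One dictionary line: a representative cue plus synonymous forms."""

    __slots__ = ("representative", "synonyms", "strength")

    def __init__(
        self,
        representative: str,
        synonyms: Sequence[str] = (),
        strength: Optional[Strength] = None,
    ):
        if not representative or not representative.strip():
            raise DictionaryParseError("empty representative pattern")
        self.representative = representative.strip()
        # de-duplicate after case folding, preserving order
        seen = {self.representative.casefold()}
        kept = []
        for syn in synonyms:
            syn = syn.strip()
            if syn and syn.casefold() not in seen:
                seen.add(syn.casefold())
                kept.append(syn)
        self.synonyms = kept
        self.strength = strength

    def surfaces(self) -> list[str]:
        return [self.representative, *self.synonyms]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DictionaryEntry)
            and self.representative == other.representative
            and self.synonyms == other.synonyms
            and self.strength == other.strength
        )

    def __repr__(self) -> str:
        return (
            f"DictionaryEntry({self.representative!r}, {len(self.synonyms)} synonyms,"
            f" strength={self.strength})"
        )


class DictionaryFile:
    """An ordered collection of dictionary entries."""

    def __init__(self, entries: Sequence[DictionaryEntry]):
        self.entries = list(entries)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def n_synonyms(self) -> int:
        return sum(len(e.synonyms) for e in self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _parse_dictionary_line(line: str, lineno: int) -> DictionaryEntry:
    fields = line.split("\t")
    representative = fields[0].strip()
    if not representative:
        raise DictionaryParseError(f"line {lineno}: empty representative")
    synonyms: list[str] = []
    strength: Optional[Strength] = None
    if len(fields) == 2:
        second = fields[1].strip()
        # a lone strength token is a strength, anything else is synonyms
        if second.casefold() in _STRENGTH_TOKENS and "|" not in second:
            strength = Strength(second.casefold())
        else:
            synonyms = second.split("|")
    elif len(fields) >= 3:
        synonyms = fields[1].split("|") if fields[1].strip() else []
        token = fields[2].strip().casefold()
        if token:
            if token not in _STRENGTH_TOKENS:
                raise DictionaryParseError(
                    f"line {lineno}: unknown strength token {fields[2].strip()!r}"
                )
            strength = Strength(token)
    return DictionaryEntry(representative, synonyms, strength)


def read_dictionary(path: str | os.PathLike) -> DictionaryFile:
    """Parse a UTF-8 pattern-dictionary file."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            entries.append(_parse_dictionary_line(line, lineno))
    return DictionaryFile(entries)


def write_dictionary(dictionary: DictionaryFile, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entry in dictionary:
            fields = [entry.representative]
            if entry.synonyms or entry.strength is not None:
                fields.append("|".join(entry.synonyms))
            if entry.strength is not None:
                fields.append(entry.strength.value)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BioScope XML (speculation cues only)
# ---------------------------------------------------------------------------


def _collect_sentence(elem: etree._Element, buf: list[str], cues: list[tuple[int, int]]):
    """Walk a <sentence> subtree, appending text and recording speculation cues."""

    def walk(node: etree._Element) -> None:
        if node.text:
            buf.append(node.text)
        for child in node:
            is_spec_cue = (
                etree.QName(child).localname == "cue"
                and child.get("type", "").casefold() == "speculation"
            )
            start = sum(len(s) for s in buf)
            walk(child)
            end = sum(len(s) for s in buf)
            if is_spec_cue and end > start:
                cues.append((start, end))
            if child.tail:
                buf.append(child.tail)

    walk(elem)


def read_bioscope(path: str | os.PathLike) -> tuple[list[Document], list[AnnotationSpan]]:
    """Read a BioScope-dialect XML file.

    Returns the reconstructed documents (sentence texts joined with single
    spaces) and the speculation-cue annotation spans.  Negation cues and
    scope elements are ignored.
    """
    try:
        tree = etree.parse(os.fspath(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed BioScope XML: {exc}") from exc
    root = tree.getroot()

    doc_elems = root.findall(".//Document")
    if not doc_elems and etree.QName(root).localname == "Document":
        doc_elems = [root]
    if not doc_elems:
        # treat the whole file as one document of sentences
        doc_elems = [root]

    documents: list[Document] = []
    spans: list[AnnotationSpan] = []
    for i, doc_elem in enumerate(doc_elems):
        doc_id = doc_elem.get("id") or ""
        docid_child = doc_elem.find(".//DocID")
        if not doc_id and docid_child is not None and docid_child.text:
            doc_id = docid_child.text.strip()
        if not doc_id:
            doc_id = f"bioscope-{i + 1}"

        parts: list[str] = []
        doc_spans: list[tuple[int, int]] = []
        offset = 0
        for sent in doc_elem.iter():
            if etree.QName(sent).localname != "sentence":
                continue
            buf: list[str] = []
            cues: list[tuple[int, int]] = []
            _collect_sentence(sent, buf, cues)
            sent_text = "".join(buf).strip()
            lead = len("".join(buf)) - len("".join(buf).lstrip())
            if not sent_text:
                continue
            if parts:
                offset += 1  # joining space
            for a, b in cues:
                doc_spans.append((offset + a - lead, offset + b - lead))
            parts.append(sent_text)
            offset += len(sent_text)
        if not parts:
            continue
        text = " ".join(parts)
        doc = Document(doc_id=doc_id, text=text)
        documents.append(doc)
        for a, b in doc_spans:
            if not (0 <= a < b <= len(text)):
                raise ConsistencyError(
                    f"cue span [{a}, {b}) outside text of {doc_id!r}"
                )
            spans.append(AnnotationSpan(doc_id, a, b, text[a:b]))
    return documents, spans


# ---------------------------------------------------------------------------
# standoff TSV (matches and annotations)
# ---------------------------------------------------------------------------

_MATCH_COLUMNS = ["doc_id", "sentence_index", "start", "end", "pattern_representative", "surface"]


def write_matches(matches: Iterable[Match], path: str | os.PathLike) -> None:
    """Write matches as standoff TSV (header always present)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MATCH_COLUMNS)
        for m in matches:
            writer.writerow(
                [m.doc_id, m.sentence_index, m.start, m.end, m.pattern_representative, m.surface]
            )


def read_matches(path: str | os.PathLike,
                 documents: Optional[Sequence[Document]] = None) -> list[Match]:
    """Inverse of :func:`write_matches`; validates offsets when documents given."""
    by_id = {d.doc_id: d for d in documents} if documents is not None else None
    out: list[Match] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return out
        if [h.strip() for h in header] != _MATCH_COLUMNS:
            raise CorpusParseError(f"unexpected match header: {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != len(_MATCH_COLUMNS):
                raise CorpusParseError(f"line {lineno}: expected {len(_MATCH_COLUMNS)} columns")
            doc_id, sent_idx, start, end, rep, surface = row
            m = Match(doc_id, int(sent_idx), int(start), int(end), rep, surface)
            _validate_surface(by_id, m.doc_id, m.start, m.end, m.surface)
            out.append(m)
    return out


def _validate_surface(by_id, doc_id: str, start: int, end: int, surface: str) -> None:
    if by_id is None:
        return
    if doc_id not in by_id:
        raise ConsistencyError(f"annotation references unknown document {doc_id!r}")
    text = by_id[doc_id].text
    if not (0 <= start < end <= len(text)) or text[start:end] != surface:
        raise ConsistencyError(
            f"span [{start}, {end}) of {doc_id!r}: surface {surface!r} "
            f"!= document slice {text[start:end]!r}"
        )


def write_annotations(spans: Iterable[AnnotationSpan], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "start", "end", "surface", "label"])
        for s in spans:
            writer.writerow([s.doc_id, s.start, s.end, s.surface, s.label])


def read_annotations(path: str | os.PathLike,
                     documents: Optional[Sequence[Document]] = None) -> list[AnnotationSpan]:
    """Read standoff annotation TSV.

    Accepts either the annotation layout (doc_id, start, end, surface,
    label) or the richer match layout written by :func:`write_matches`
    (the pattern column is then dropped).
    """
    by_id = {d.doc_id: d for d in documents} if documents is not None else None
    out: list[AnnotationSpan] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return out
        header = [h.strip() for h in header]
        if header == _MATCH_COLUMNS:
            layout = "match"
        elif header[:4] == ["doc_id", "start", "end", "surface"]:
            layout = "span"
        else:
            raise CorpusParseError(f"unexpected annotation header: {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if layout == "match":
                doc_id, _, start, end, _, surface = row
                label = "speculative_pattern"
            else:
                doc_id, start, end, surface = row[:4]
                label = row[4] if len(row) > 4 else "speculative_pattern"
            start_i, end_i = int(start), int(end)
            _validate_surface(by_id, doc_id, start_i, end_i, surface)
            out.append(AnnotationSpan(doc_id, start_i, end_i, surface, label))
    return out
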