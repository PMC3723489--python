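"""Scoring, inter-annotator agreement, and annotation adjudication.

Precision, recall and F-score follow the usual information-extraction
definitions: P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R), computed over
spans (pattern recognition) or over the POSITIVE class of sentence labels
(hypothesis classification).  Degenerate 0/0 ratios are reported as 0 with
a warning rather than leaving the report undefined.

Adjudication merges two annotators' span sets under four rules: agreed
spans are kept unconditionally; partially overlapping spans are reduced to
their character intersection (snapped to token boundaries, i.e. only the
conflicting words are removed); spans marked by a single annotator need an
explicit accept/reject decision; nothing absent from both inputs is ever
introduced.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Optional, Sequence

from .errors import ConsistencyError
from .segmenter import segment, tokenize
from .types import AgreementReport, AnnotationSpan, Document, EvalReport, Label, SentenceLabel

logger = logging.getLogger(__name__)


def _prf(tp: int, fp: int, fn: int, level: str, criterion: str) -> EvalReport:
    if tp + fp == 0 or tp + fn == 0:
        logger.warning("degenerate confusion counts (tp=%d fp=%d fn=%d): "
                       "undefined ratios reported as 0", tp, fp, fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_score = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                      f_score=f_score, level=level, criterion=criterion)


def prf_from_counts(tp: int, fp: int, fn: int,
                    level: str = "sentence", criterion: str = "exact") -> EvalReport:
    """Report P/R/F for explicit confusion counts."""
    return _prf(tp, fp, fn, level, criterion)


def _check_docs(spans: Sequence[AnnotationSpan],
                documents: Optional[Sequence[Document]]) -> None:
    if documents is None:
        return
    known = {d.doc_id for d in documents}
    for s in spans:
        if s.doc_id not in known:
            raise ConsistencyError(f"span references unknown document {s.doc_id!r}")


def span_prf(
    predicted: Sequence[AnnotationSpan],
    gold: Sequence[AnnotationSpan],
    criterion: str = "exact",
    documents: Optional[Sequence[Document]] = None,
) -> EvalReport:
    """Span-level P/R/F.

    ``exact``: a predicted span is a TP iff an unconsumed gold span has the
    identical (doc_id, start, end).  ``overlap``: a TP iff it shares at
    least one character with an unconsumed gold span; pairing is greedy
    one-to-one in positional order.
    """
    if criterion not in ("exact", "overlap"):
        raise ValueError(f"unknown criterion {criterion!r}")
    _check_docs(predicted, documents)
    _check_docs(gold, documents)

    if criterion == "exact":
        pred_keys = Counter((s.doc_id, s.start, s.end) for s in predicted)
        gold_keys = Counter((s.doc_id, s.start, s.end) for s in gold)
        tp = sum((pred_keys & gold_keys).values())
        fp = sum(pred_keys.values()) - tp
        fn = sum(gold_keys.values()) - tp
        return _prf(tp, fp, fn, "span", criterion)

    pred_sorted = sorted(predicted, key=lambda s: (s.doc_id, s.start, s.end))
    gold_sorted = sorted(gold, key=lambda s: (s.doc_id, s.start, s.end))
    used = [False] * len(gold_sorted)
    tp = 0
    for p in pred_sorted:
        for j, g in enumerate(gold_sorted):
            if used[j] or g.doc_id != p.doc_id:
                continue
            if p.start < g.end and g.start < p.end:
                used[j] = True
                tp += 1
                break
    return _prf(tp, len(pred_sorted) - tp, used.count(False), "span", criterion)


def sentence_prf(
    predicted: Sequence[SentenceLabel], gold: Sequence[SentenceLabel]
) -> EvalReport:
    """Sentence-level P/R/F over the POSITIVE class."""
    pred_map = {p.key(): p.label for p in predicted}
    gold_map = {g.key(): g.label for g in gold}
    if len(pred_map) != len(predicted) or len(gold_map) != len(gold):
        raise ConsistencyError("duplicate sentence keys in labeling")
    if set(pred_map) != set(gold_map):
        raise ConsistencyError("predicted and gold label different sentence sets")
    tp = fp = fn = 0
    for key, plabel in pred_map.items():
        glabel = gold_map[key]
        if plabel is Label.POSITIVE and glabel is Label.POSITIVE:
            tp += 1
        elif plabel is Label.POSITIVE:
            fp += 1
        elif glabel is Label.POSITIVE:
            fn += 1
    return _prf(tp, fp, fn, "sentence", "exact")


# ---------------------------------------------------------------------------
# inter-annotator agreement
# ---------------------------------------------------------------------------


def _as_label_map(labels) -> dict:
    if isinstance(labels, Mapping):
        return dict(labels)
    return {l.key(): l.label for l in labels}


def cohen_kappa(labels_a, labels_b, unit: str = "sentence") -> AgreementReport:
    """Two-rater Cohen's kappa over a shared unit set.

    Accepts sequences of :class:`SentenceLabel` or mappings unit -> label.
    When chance agreement is 1 (both raters constant and identical), kappa
    is reported as 1 for perfect agreement and 0 otherwise.
    """
    a = _as_label_map(labels_a)
    b = _as_label_map(labels_b)
    if not a or set(a) != set(b):
        raise ConsistencyError("annotators must label the same non-empty unit set")
    n = len(a)
    observed = sum(1 for k in a if a[k] == b[k]) / n
    cats = set(a.values()) | set(b.values())
    expected = sum(
        (sum(1 for v in a.values() if v == c) / n)
        * (sum(1 for v in b.values() if v == c) / n)
        for c in cats
    )
    if expected >= 1.0:
        kappa = 1.0 if observed == 1.0 else 0.0
    else:
        kappa = (observed - expected) / (1.0 - expected)
    return AgreementReport(
        observed_agreement=observed,
        expected_agreement=expected,
        kappa=kappa,
        unit=unit,
        n_units=n,
    )


def sentence_labels_from_spans(
    documents: Sequence[Document], spans: Sequence[AnnotationSpan]
) -> list[SentenceLabel]:
    """Derive per-sentence speculative/not labels from annotated spans.

    A sentence is POSITIVE iff at least one span overlaps its character
    range; a span overlapping no sentence is a consistency error.
    """
    labels: list[SentenceLabel] = []
    covered = [False] * len(spans)
    for doc in documents:
        if not doc.sentences:
            segment(doc)
        for sentence in doc.sentences:
            positive = False
            for i, s in enumerate(spans):
                if s.doc_id == doc.doc_id and s.start < sentence.end and sentence.start < s.end:
                    positive = True
                    covered[i] = True
            labels.append(
                SentenceLabel(
                    doc_id=doc.doc_id,
                    sentence_index=sentence.index,
                    label=Label.POSITIVE if positive else Label.NEGATIVE,
                )
            )
    if not all(covered):
        missing = spans[covered.index(False)]
        raise ConsistencyError(
            f"span [{missing.start}, {missing.end}) of {missing.doc_id!r} "
            "overlaps no sentence"
        )
    return labels


# ---------------------------------------------------------------------------
# adjudication
# ---------------------------------------------------------------------------


def _snap_to_tokens(doc: Optional[Document], doc_id: str,
                    start: int, end: int) -> Optional[tuple[int, int]]:
    """Shrink a raw character intersection to whole tokens."""
    if doc is None:
        return (start, end) if start < end else None
    toks = [t for t in tokenize(doc.text) if t.is_word or not t.surface.isspace()]
    inside = [t for t in toks if t.start >= start and t.end <= end]
    if not inside:
        return None
    return (inside[0].start, inside[-1].end)


def adjudicate(
    spans_a: Sequence[AnnotationSpan],
    spans_b: Sequence[AnnotationSpan],
    decisions: Optional[Mapping[tuple[str, int, int], str]] = None,
    documents: Optional[Sequence[Document]] = None,
) -> list[AnnotationSpan]:
    """Merge two annotators' span sets under the four adjudication rules.

    ``decisions`` maps (doc_id, start, end) of each disputed span — marked
    by exactly one annotator and overlapping nothing in the other set — to
    "accept" or "reject".  Missing decisions raise an error listing the
    disputed spans.  When ``documents`` are provided, partial-overlap
    intersections are snapped to token boundaries and surfaces re-sliced.
    """
    decisions = dict(decisions or {})
    by_doc = {d.doc_id: d for d in documents} if documents else {}

    keys_a = {(s.doc_id, s.start, s.end): s for s in spans_a}
    keys_b = {(s.doc_id, s.start, s.end): s for s in spans_b}

    merged: dict[tuple[str, int, int], AnnotationSpan] = {}
    # rule 2: identical annotations are kept unconditionally
    for key in keys_a.keys() & keys_b.keys():
        merged[key] = keys_a[key]

    rest_a = [s for k, s in keys_a.items() if k not in merged]
    rest_b = [s for k, s in keys_b.items() if k not in merged]

    # rule 4: partially overlapping pairs -> intersection, greedy by position
    used_b = set()
    disputed: list[AnnotationSpan] = []
    for sa in sorted(rest_a, key=lambda s: (s.doc_id, s.start, s.end)):
        partner = None
        for j, sb in enumerate(sorted(rest_b, key=lambda s: (s.doc_id, s.start, s.end))):
            if j in used_b or sb.doc_id != sa.doc_id:
                continue
            if sa.start < sb.end and sb.start < sa.end:
                partner = (j, sb)
                break
        if partner is None:
            disputed.append(sa)
            continue
        j, sb = partner
        used_b.add(j)
        doc = by_doc.get(sa.doc_id)
        snapped = _snap_to_tokens(doc, sa.doc_id, max(sa.start, sb.start),
                                  min(sa.end, sb.end))
        if snapped is None:
            continue
        start, end = snapped
        surface = doc.text[start:end] if doc else sa.surface[
            start - sa.start:end - sa.start]
        merged[(sa.doc_id, start, end)] = AnnotationSpan(sa.doc_id, start, end, surface)
    for j, sb in enumerate(sorted(rest_b, key=lambda s: (s.doc_id, s.start, s.end))):
        if j not in used_b:
            disputed.append(sb)

    # rule 3: single-annotator spans need an explicit consensus decision
    missing = [s for s in disputed if (s.doc_id, s.start, s.end) not in decisions]
    if missing:
        listing = ", ".join(f"{s.doc_id}[{s.start}:{s.end}]" for s in missing)
        raise ConsistencyError(f"missing adjudication decisions for: {listing}")
    for s in disputed:
        verdict = decisions[(s.doc_id, s.start, s.end)].strip().casefold()
        if verdict not in ("accept", "reject"):
            raise ValueError(f"unknown adjudication decision {verdict!r}")
        if verdict == "accept":
            merged.setdefault((s.doc_id, s.start, s.end), s)

    # rule 1 (no invention) holds by construction: every merged span derives
    # from an input span or an intersection of two input spans
    return sorted(merged.values(), key=lambda s: (s.doc_id, s.start, s.end))
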