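# hypofinder

Dictionary-based detection of speculative (hedged) statements in
biomedical abstracts, with evaluation tooling and a machine-learning
baseline for systematic comparison.

## The problem

Scientific abstracts mix established findings with *speculative*
statements — tentative claims marked by hedging cues such as "may be
involved", "seems to play", or "raising the possibility that".
Collected systematically, these statements are a map of a field's
emerging hypotheses (e.g., around the molecular etiology of Alzheimer's
disease), but they must first be separated from factual inferences,
results, arguments, and open questions that merely resemble them.
`hypofinder` is for text-mining practitioners who want a transparent,
auditable hedge detector plus the machinery to evaluate one.

## The method

A **speculative-pattern dictionary** groups each representative cue with
its synonymous surface forms (inflections and recombinations), annotated
with a strength class. Matching is **case-insensitive,
word-order-sensitive, longest exact match** over tokens: scanning each
sentence left to right, the longest dictionary form matching the
case-folded token sequence contiguously is taken, and the scan resumes
after it. A sentence is labeled

```
POSITIVE  iff  at least one speculative pattern matches, else NEGATIVE
```

Pattern quality is profiled by **percent efficacy**: for a pattern p
matched in a set S of sentences (sampled down to 50 when larger),

```
efficacy(p) = 100 · |curated speculative ∩ sample| / |sample|
```

which drives the strong (≥ 90%), moderate, weak (< 50%) classes. Bare
weak cues ("potential", "possibility", "should", "would") are excluded
standalone and admitted only in strengthened compositions ("could be a
potential", "raising the possibility that").

Around the detector the package provides: readers/writers for
PMID-tagged plain text, BioScope-style XML (speculation cues), the
dictionary format and standoff TSV; a rule-based sentence
segmenter/tokenizer with offset fidelity; span- and sentence-level
precision/recall/F-score (P = TP/(TP+FP), R = TP/(TP+FN),
F = 2PR/(P+R)); two-rater Cohen's kappa; a four-rule adjudicator that
merges dual annotations (agreed spans kept, partial overlaps reduced to
their token-snapped intersection, single-annotator spans decided
explicitly, nothing invented); a maximum-entropy sentence classifier
with three switchable feature families (`base` bag-of-words, `spec`
dictionary-pattern occurrences, `lex` lemma n-grams + noun affixes +
optional dependency triples); and a deterministic synthetic-corpus
generator for end-to-end testing.

The shipped seed dictionary (`src/hypofinder/data/seed_dictionary_synthetic.txt`)
is a synthetic reconstruction containing every cue from the worked
literature examples plus standard English hedging cues, sized at 156
representative and 392 synonymous patterns.

## Worked example

```
$ cat corpus.txt
PMID	14699432
Our findings support the notion that CSF tau and Abeta(1-42) may be
useful biomarkers in the early identification of AD in MCI subjects.

PMID	22433668
Whether T2D can cause late onset Alzheimer's disease (LOAD) remains to
be elucidated.

$ hypofinder classify corpus.txt
{"doc_id": "14699432", "sentence_index": 0, "label": "POSITIVE", "matches":
  [{"start": 13, "end": 36, "pattern": "supports the notion that",
    "surface": "support the notion that"},
   {"start": 61, "end": 67, "pattern": "may be", "surface": "may be"}]}
{"doc_id": "22433668", "sentence_index": 0, "label": "NEGATIVE", "matches": []}
```

The first abstract is flagged hypothetical with two supporting cue
matches at character offsets into the abstract text; the open question
("Whether … remains to be elucidated") stays NEGATIVE because the bare
phrasing is deliberately not a dictionary form. Other entry points:

```
hypofinder dict stats                 # 156 representatives, 392 synonyms, 548 forms
hypofinder gen-fixtures --n-docs 50 --pos-rate 0.2 --seed 7 --out fix/
hypofinder match --out pred.tsv fix/corpus.txt
hypofinder evaluate --level span --criterion exact pred.tsv fix/gold_spans.tsv
hypofinder train --features base,spec --algo maxent --seed 0 \
    --model-out model.pkl fix/corpus.txt fix/gold_spans.tsv
hypofinder iaa --corpus fix/corpus.txt annA.tsv annB.tsv
```

The same functionality is available as a library (`import hypofinder`).

## Layout

```
src/hypofinder/
  corpus_io.py            file formats (plain corpus, dictionary, BioScope, TSV)
  segmenter.py            sentence segmentation + tokenization
  pattern_dictionary.py   patterns, synonym expansion, composition, index
  matcher.py              longest-match scan + brute-force oracle
  classify.py             sentence labeling, efficacy profiling, strength classes
  ml.py                   feature families + MaxEnt and alternative classifiers
  evaluation.py           P/R/F, Cohen's kappa, four-rule adjudication
  fixtures.py             deterministic synthetic corpus generator
  cli.py                  `hypofinder` command-line interface
docs/methods.md           model, parameters, design choices, limitations
```
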