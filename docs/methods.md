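# Methods

## Detection model

The detector treats speculation as a lexical phenomenon: a sentence is
hypothetical exactly when it contains at least one cue from a curated
dictionary of speculative patterns. A dictionary entry groups a
representative cue ("appear to") with synonymous surface forms covering
inflections and recombinations ("appears to be", "appeared that", …) and
an optional strength class. All forms are tokenized with the package's
own tokenizer and case-folded, so matching semantics are fixed at
compile time:

* **case-insensitive** — comparison is over case-folded tokens;
* **word-order-sensitive** — a form matches only as an exact, contiguous,
  ordered token sequence (gapped patterns are out of scope);
* **longest exact match** — at each scan position the form with the most
  tokens wins; ties break by character span, then dictionary order; the
  scan resumes after a match, so matches never overlap and never cross
  sentence boundaries.

The assumption that cue presence implies speculation fails for weak
cues: bare "potential", "possibility", "should", "would" frequently
occur in non-speculative use. The seed dictionary therefore excludes
them standalone; `strengthen_weak` composes them with auxiliary phrases
("could be a" + "potential") and only those compositions are entries.

### Seed dictionary

Dataset-scale hedge lexicons for this task are not redistributable, so
the package ships a synthetic reconstruction
(`data/seed_dictionary_synthetic.txt`): every cue string that appears in
the worked literature examples the test suite exercises, filled out with
standard English hedging cue families — modal-verb phrases (may/might/
could + verb paradigms), seem/appear constructions, hedging performative
verbs (speculate, hypothesize, postulate, surmise, …), passive hedges
("is thought to"), hedging adverbs (presumably, conceivably, …), and
strengthened weak-term composites. It is sized at 156 representative and
392 synonymous patterns (548 distinct forms). Strength labels follow the
observation that modal-verb patterns are near-always speculative
(strong) while reportive/passive hedges and bare adverbs are moderate.

### Percent efficacy and strength classes

`profile_efficacy` reproduces the pattern-profiling procedure: collect
the sentences a single pattern matches; if more than `cap` (default 50),
draw a uniform sample without replacement of size `cap` with an explicit
seed; report `100 · speculative / sampled` against curator-supplied
labels. A pattern with no matching sentences gets efficacy `None`
("not computable"), never 0 — an unobserved pattern must not look like a
useless one. `assign_strength` maps efficacy to classes with
configurable thresholds defaulting to strong ≥ 90 %, weak < 50 %; the
numeric cut-offs are a design choice (no published values exist),
consistent with modal patterns profiling near 100 % and bare weak terms
well below 50 %.

## Segmentation and tokenization

A deterministic rule-based splitter is used: sentence-final punctuation
followed by whitespace and an uppercase/opening character ends a
sentence, with an abbreviation guard list (`data/abbreviations.txt`:
e.g., i.e., et al., Fig., vs., …) and a single-initial guard ("J.").
Abstracts are short and well punctuated; a statistical segmenter would
add a dependency without changing any downstream contract. Tokens are
maximal alphanumeric runs; every other non-space character is its own
token, so hyphens and parentheses are token boundaries
("Abeta(1-42)" → `Abeta ( 1 - 42 )`). Every token records character
offsets into the document text and its case-folded surface; all standoff
offsets in the package are 0-based half-open document coordinates.

## Evaluation stack

Span- and sentence-level precision, recall and F-score use the standard
definitions with the 0/0 convention "report 0 and warn". Span scoring
supports an `exact` criterion (identical doc/start/end; the default, as
the stricter reproducible reading) and an `overlap` criterion (≥ 1
shared character, greedy one-to-one pairing in positional order).
Sentence scoring is over the POSITIVE class. Inter-annotator agreement
is two-rater Cohen's kappa on sentence-level labels; the arithmetic is
implemented directly (observed and expected agreement are part of the
report) and cross-checked against scikit-learn in the tests. When
expected agreement is 1, kappa is reported as 1 for perfect agreement
and 0 otherwise.

Adjudication merges two annotators' span sets under four rules: (1)
nothing absent from both inputs is ever introduced; (2) spans identical
in both sets are kept unconditionally; (3) spans marked by one annotator
only and overlapping nothing in the other set require an explicit
accept/reject decision — a missing decision is an error listing the
disputed spans; (4) partially overlapping pairs are replaced by their
character intersection, snapped to token boundaries when documents are
available, so only the conflicting words are removed ("might be
involved" ∩ "might be" → "might be").

## ML baseline

Sentences become labeled instances (POSITIVE iff a gold span overlaps
the sentence; spans straddling sentence boundaries are data errors).
Three feature families live in separate namespaces:

* `base:` — binary feature per case-folded word;
* `spec:` — binary feature per dictionary pattern with ≥ 1 match, plus
  an aggregate indicator that some pattern matched. The aggregate is the
  simplest member of the "occurrences of hand-crafted patterns" family
  and lets a linear model use the dictionary signal at full strength
  even for patterns rare in training;
* `lex:` — lemma unigrams/bigrams/trigrams, 2/3/4-character prefixes and
  suffixes of noun tokens, and dependency triples when available.

Lemmas, noun flags and dependencies come from a pluggable
`LinguisticProvider`. The default `LexiconProvider` is a deterministic
word table with a suffix heuristic for the noun flag and no dependency
output; a parser-backed provider can replace it wholesale. This keeps
the core testable and dependency-free; with the default provider the
`lex` family simply has no dependency features.

The reference algorithm, maximum entropy, is L2-regularized multinomial
logistic regression with regularization strength C = 1.0 (configurable;
no published hyperparameters exist to copy). Naive Bayes, k-NN (k = 3),
decision trees and a linear SVM are available behind the same contract.
Training requires both classes; prediction is deterministic given the
training seed; sentences yielding no features fall back to the training
majority class.

A note on feature-family behavior: with per-pattern features alone,
logistic regression under C = 1.0 cannot lift patterns seen only once
or twice in training above the class-imbalance intercept, so a
spec-only model has structurally limited recall — speculative features
are not present in all sentences and do not carry a model alone. The
aggregate indicator restores the family's full signal in combined
models.

## Synthetic corpus generator

The generator emulates the statistical structure the detector assumes
about abstracts, not their surface realism. Every sentence is a shared
discourse scaffold (`<framing> X <verb slot> Y`) over pools of
biomedical agents X and affected processes Y; scaffolds realize four
non-speculative discourse categories — inferences, results and
conclusions, argumentative sentences, open questions. Positives plant
exactly one dictionary surface form, drawn uniformly, in the verb slot
at a recorded offset; negatives fill it with a factual connector.
Because scaffolds and frames are drawn identically for both classes,
content words and discourse framing carry no label signal.

Three deliberate properties mirror real abstracts:

* **near-miss connectors** — negated ability ("could not be linked to"),
  negative results ("was not associated with"), reported prior belief
  ("was long thought unrelated to") re-use cue vocabulary in non-cue
  arrangements and are weighted up, as negative-result phrasing is in
  real corpora;
* **distractor clauses** (at `distractor_rate`) salt negatives with the
  bare weak terms the dictionary excludes ("a potential confounder",
  "although the possibility of selection bias remains");
* **neutral adjuncts** (70 % of sentences, both classes) keep
  high-frequency function words (that, is, was, to, be, not, there, has,
  been, May, …) equally common in both classes.

Together these make cue *words* class-ambiguous while cue *sequences*
remain definitive — the property that separates sequence-aware matching
from bag-of-words models. Every negative scaffold x connector x
distractor combination is verified against the planting dictionary at
generation time (adjuncts are verified standalone; they attach behind a
comma token, and no form contains punctuation, so no form can span the
junction). Gold labels are therefore correct by construction, positives
are exactly recoverable by the pattern classifier, and generation is
byte-deterministic given the seed. Exact-count planting (default) fixes
the number of positives at `round(rate · n)` for test stability;
Bernoulli planting is available.

What passing tests on these corpora do **not** show: robustness to real
lexical diversity, misspellings, cue senses outside the planted
contexts, or cues absent from the dictionary. Scores on generated
corpora are properties of the construction, not estimates of real-world
accuracy.

## Problem sizes and defaults

* Matcher/oracle equivalence: 1,000 randomized dictionary/sentence pairs
  over a 15-word alphabet chosen to force nested and overlapping
  candidates.
* Recovery corpus: 50 documents × 5 sentences, positive rate 0.2,
  distractor rate 0.5.
* ML comparison corpus: 500 documents × 5 sentences (2,500 sentences),
  positive rate 0.3, distractor rate 0.3, 80/20 document-level split.
  The rate and split were chosen so each representative pattern is
  likely observed during training (expected unseen ≈ 2 %): the
  comparison is about feature families, not data sparsity.
* Agreement simulation: 200 independent random labelings of 300
  sentences at prevalence 0.5.

## Known limitations

* Gapped or discontinuous cues are not matched; every dictionary form is
  a contiguous token sequence.
* The greedy non-overlapping scan is a policy choice; a cue starting
  inside an accepted match is consumed (irrelevant for sentence-level
  labels, visible in span-level output).
* BioScope reading extracts speculation cues only; scope annotations and
  negation cues are ignored by design.
* The seed dictionary is a reconstruction: counts and structure follow
  the published description, but the exact published entry inventory is
  not reproducible.
* The default linguistic provider supplies no dependency triples, so the
  `lex` family is lemma/affix-based unless a parser-backed provider is
  configured.
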