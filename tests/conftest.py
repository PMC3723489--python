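import random

import pytest

from hypofinder.corpus_io import DictionaryEntry, DictionaryFile
from hypofinder.pattern_dictionary import build_patterns, compile_index, seed_dictionary
from hypofinder.segmenter import tokenize
from hypofinder.types import Sentence


@pytest.fixture(scope="session")
def seed_dict():
    return seed_dictionary()


@pytest.fixture(scope="session")
def seed_pats(seed_dict):
    return build_patterns(seed_dict)


@pytest.fixture(scope="session")
def seed_idx(seed_pats):
    return compile_index(seed_pats)


def make_sentence(text: str, doc_id: str = "doc", index: int = 0) -> Sentence:
    """One-sentence helper with document-coordinate tokens."""
    return Sentence(doc_id=doc_id, index=index, start=0, end=len(text),
                    tokens=tokenize(text))


def make_dictionary(*lines) -> DictionaryFile:
    """Build a dictionary from 'rep' or ('rep', [syns]) shorthand."""
    entries = []
    for line in lines:
        if isinstance(line, str):
            entries.append(DictionaryEntry(line))
        else:
            rep, syns = line
            entries.append(DictionaryEntry(rep, syns))
    return DictionaryFile(entries)


_ALPHABET = [
    "tau", "amyloid", "may", "be", "involved", "seems", "to", "play",
    "protein", "regulate", "might", "could", "that", "in", "signaling",
]


def random_matcher_instance(rng: random.Random):
    """A random (patterns, sentence, text) triple for oracle comparison.

    Dictionary forms and sentence tokens are drawn from one small shared
    alphabet so that overlapping and nested candidates are frequent; the
    sentence gets random per-character casing to exercise case folding.
    """
    n_entries = rng.randint(1, 6)
    entries = []
    used = set()
    for _ in range(n_entries):
        rep_tokens = [rng.choice(_ALPHABET) for _ in range(rng.randint(1, 3))]
        rep = " ".join(rep_tokens)
        syns = []
        for _ in range(rng.randint(0, 2)):
            syn = " ".join(rng.choice(_ALPHABET) for _ in range(rng.randint(1, 3)))
            syns.append(syn)
        key = rep.casefold()
        if key in used:
            continue
        used.add(key)
        entries.append(DictionaryEntry(rep, syns))
    if not entries:
        entries.append(DictionaryEntry(rng.choice(_ALPHABET)))
    patterns = build_patterns(DictionaryFile(entries))

    words = [rng.choice(_ALPHABET) for _ in range(rng.randint(3, 18))]
    cased = []
    for w in words:
        cased.append("".join(
            ch.upper() if rng.random() < 0.3 else ch for ch in w))
    text = " ".join(cased) + "."
    return patterns, make_sentence(text), text
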