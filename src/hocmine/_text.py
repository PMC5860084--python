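"""Tokenization, lemmatization and sentence segmentation.

The upstream pipeline that produced the original annotations used an external
POS tagger/lemmatizer; here both steps are pluggable so that a subprocess
adapter around such a tool can be dropped in.  The defaults are deliberately
simple and fully deterministic:

* ``RegexTokenizer`` — word tokens of letters/digits with internal hyphens,
  apostrophes and slashes (``"p53"``, ``"cell-cycle"``, ``"BRCA1/2"``).
* ``LowercaseLemmatizer`` — the identity lemmatizer: lemma = lowercased token.
* ``RegexSentenceSegmenter`` — splits on sentence-final ``.!?`` followed by
  whitespace and an upper-case letter or digit, protecting a fixed list of
  common scientific abbreviations ("i.e.", "e.g.", "et al.", "Fig." ...).

Every model artifact records the identity string of the segmenter and
lemmatizer that produced it, so predictions are reproducible.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import List, Protocol

__all__ = [
    "RegexTokenizer",
    "LowercaseLemmatizer",
    "RegexSentenceSegmenter",
    "load_stopwords",
    "STOPWORDS",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'/][A-Za-z0-9]+)*")

# Abbreviations after which a period never ends a sentence.
_ABBREVIATIONS = {
    "i.e", "e.g", "etc", "vs", "al", "fig", "figs", "eq", "eqs", "ref",
    "refs", "no", "approx", "ca", "cf", "resp", "dr", "prof", "inc", "st",
}


class Tokenizer(Protocol):
    def tokenize(self, text: str) -> List[str]: ...


class Lemmatizer(Protocol):
    def lemmatize(self, tokens: List[str]) -> List[str]: ...


class SentenceSegmenter(Protocol):
    identity: str

    def segment(self, text: str) -> List[str]: ...


class RegexTokenizer:
    identity = "hocmine-regex-tokenizer/1"

    def tokenize(self, text: str) -> List[str]:
        return _TOKEN_RE.findall(text)


class LowercaseLemmatizer:
    """Identity lemmatizer: lemmas are lowercased surface tokens."""

    identity = "hocmine-lowercase-lemmatizer/1"

    def lemmatize(self, tokens: List[str]) -> List[str]:
        return [t.lower() for t in tokens]


class RegexSentenceSegmenter:
    identity = "hocmine-regex-segmenter/1"

    _BOUNDARY = re.compile(r"([.!?])(\s+)(?=[A-Z0-9(\[])")

    def segment(self, text: str) -> List[str]:
        text = text.strip()
        if not text:
            return []
        sentences: List[str] = []
        start = 0
        for match in self._BOUNDARY.finditer(text):
            end = match.end(1)
            preceding = text[start:end]
            last_word = re.search(r"([A-Za-z][A-Za-z.]*)\.$", preceding)
            if last_word and last_word.group(1).lower().rstrip(".") in _ABBREVIATIONS:
                continue
            sentences.append(preceding.strip())
            start = match.end()
        tail = text[start:].strip()
        if tail:
            sentences.append(tail)
        return sentences


def load_stopwords() -> frozenset:
    """The shipped, version-stamped English stopword list."""
    ref = resources.files("hocmine.data").joinpath("stopwords.txt")
    words = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


STOPWORDS = load_stopwords()
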