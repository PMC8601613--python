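"""Small text primitives shared by the mining and matching modules.

Tokenization, sentence splitting, an English stop-word list for the
annotation-text frequency analysis, and the fuzzy string score used for
metabolite name matching.  The fuzzy score is the classic token-sort
Levenshtein-style ratio: both strings are lowercased, tokenized, the
tokens sorted and re-joined, and the similarity of the two normalized
strings is ``round(100 * 2M / (len(a) + len(b)))`` with ``M`` the number
of matched characters (``difflib.SequenceMatcher`` ratio), an integer in
[0, 100].  Token sorting makes the score robust to word-order variation
in metabolite synonyms ("acid, citric" vs "citric acid").
"""

from __future__ import annotations

import re
from difflib import SequenceMatcher
from typing import Iterable

__all__ = [
    "tokenize",
    "split_sentences",
    "ngrams",
    "STOP_WORDS",
    "simple_ratio",
    "token_sort_ratio",
]

_WORD_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9_'\-]*")
_SENTENCE_RE = re.compile(r"(?<=[.!?;])\s+")

#: Common English function words ignored by the frequency analysis.
STOP_WORDS = frozenset(
    """a an and are as at be been but by for from had has have if in into is it
    its more most no not of on or such that the their then there these they
    this to was were which while will with within without""".split()
)


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split free text into word tokens (letters, digits, -, _, ')."""
    tokens = _WORD_RE.findall(text)
    return [t.lower() for t in tokens] if lowercase else tokens


def split_sentences(text: str) -> list[str]:
    """Split text into sentences on ., !, ? and ; boundaries."""
    return [s.strip() for s in _SENTENCE_RE.split(text) if s.strip()]


def ngrams(tokens: Iterable[str], n: int) -> list[str]:
    """Space-joined n-grams of a token sequence."""
    toks = list(tokens)
    return [" ".join(toks[i : i + n]) for i in range(len(toks) - n + 1)]


def simple_ratio(a: str, b: str) -> int:
    """Similarity of two strings as an integer percentage in [0, 100]."""
    if not a and not b:
        return 100
    return int(round(100 * SequenceMatcher(None, a, b).ratio()))


def _token_sort(text: str) -> str:
    return " ".join(sorted(tokenize(text)))


def token_sort_ratio(a: str, b: str) -> int:
    """Word-order-insensitive similarity score in [0, 100]."""
    return simple_ratio(_token_sort(a), _token_sort(b))
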