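"""Nucleotide/word integer coding shared by counting and background modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i

__all__ = ["BASES", "encode", "word_to_index", "index_to_word", "check_word"]


def encode(sequence: str) -> np.ndarray:
    """Map a sanitized DNA string to int8 codes A,C,G,T -> 0..3; N -> -1."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if np.any((codes < 0) & (arr != ord("N"))):
        raise ValueError("sequence contains characters outside A,C,G,T,N")
    return codes


def check_word(word: str) -> None:
    if not word:
        raise ValueError("word must be non-empty")
    if set(word) - set(BASES):
        raise ValueError(f"word {word!r} contains characters outside A,C,G,T")


def word_to_index(word: str) -> int:
    """Base-4 index of a word (lexicographic rank among words of its length)."""
    check_word(word)
    idx = 0
    for ch in word:
        idx = idx * 4 + BASES.index(ch)
    return idx


def index_to_word(index: int, length: int) -> str:
    chars = []
    for _ in range(length):
        chars.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(chars))
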