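"""Word counting and per-sequence binomial over-representation scores.

For every word W and gene sequence s, the number of overlapping exact
matches m is compared against the background probability p = P_k(W) from
the gene's own Markov model.  With n = l_s - l_W + 1 possible match
positions, the over-representation p-value is the binomial upper tail

    P(q >= m | n, p) = sum_{i=m}^{n} C(n, i) p^i (1-p)^(n-i)

and each gene's p-value is mapped to a log-score ls = -ln(p + alpha),
with a small regularizer alpha (default 1e-5) bounding the score of
vanishingly small p-values.  Genes shorter than the word carry p = 1
(no information), keeping the gene count constant across word lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._seq import BASES, check_word, encode
from .background import MarkovBackground, word_probability
from .io import RankedDataset

__all__ = [
    "LogScoreSet",
    "count_occurrences",
    "count_all_words",
    "enumerate_words",
    "binomial_tail",
    "log_scores",
    "score_word_over_dataset",
]

DEFAULT_ALPHA = 1e-5


@dataclass(frozen=True)
class LogScoreSet:
    """Per-gene log-scores ``-ln(p_i + alpha)`` for one word, in rank order."""

    word: str
    scores: np.ndarray
    alpha: float = DEFAULT_ALPHA

    @property
    def u(self) -> int:
        return len(self.scores)


def count_occurrences(sequence: str, word: str) -> int:
    """Number of overlapping exact matches of ``word`` in ``sequence``.

    Windows containing N never match.
    """
    check_word(word)
    codes = encode(sequence)
    lw = len(word)
    n_win = len(codes) - lw + 1
    if n_win <= 0:
        return 0
    wcodes = encode(word)
    hit = np.ones(n_win, dtype=bool)
    for j in range(lw):
        hit &= codes[j : j + n_win] == wcodes[j]
    return int(hit.sum())


def count_all_words(codes: np.ndarray, length: int) -> np.ndarray:
    """Counts of every word of ``length`` in one encoded sequence.

    Returns a vector of 4**length counts in lexicographic word order.
    Single rolling pass; windows overlapping an N (code -1) are skipped,
    so the result equals :func:`count_occurrences` word by word.
    """
    n_win = len(codes) - length + 1
    size = 4**length
    if n_win <= 0:
        return np.zeros(size, dtype=np.int64)
    safe = np.where(codes >= 0, codes, 0).astype(np.int64)
    valid = codes >= 0
    idx = safe[:n_win].copy()
    ok = valid[:n_win].copy()
    for j in range(1, length):
        idx = idx * 4 + safe[j : j + n_win]
        ok &= valid[j : j + n_win]
    return np.bincount(idx[ok], minlength=size)


def enumerate_words(lengths: Iterable[int]) -> list[str]:
    """All 4**l DNA words for each length, lexicographic within each length."""
    out: list[str] = []
    for length in sorted(set(lengths)):
        if length < 1:
            raise ValueError(f"word length must be >= 1, got {length}")
        out.extend("".join(p) for p in product(BASES, repeat=length))
    return out


def binomial_tail(m: int, n: int, p: float) -> float:
    """Upper binomial tail P(q >= m | n, p).

    Stable for n up to 1e5 and p down to 1e-8 (regularized incomplete
    beta under the hood).
    """
    if not 0 <= m <= n:
        raise ValueError(f"need 0 <= m <= n, got m={m}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability p={p} outside [0, 1]")
    if m == 0:
        return 1.0
    return float(stats.binom.sf(m - 1, n, p))


def log_scores(pvals: Sequence[float] | np.ndarray, alpha: float = DEFAULT_ALPHA, word: str = "") -> LogScoreSet:
    """Transform p-values to log-scores ``ls_i = -ln(p_i + alpha)``."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return LogScoreSet(word=word, scores=-np.log(p + alpha), alpha=alpha)


def score_word_over_dataset(
    word: str,
    dataset: RankedDataset,
    backgrounds: Sequence[MarkovBackground],
    alpha: float = DEFAULT_ALPHA,
) -> LogScoreSet:
    """Per-gene binomial log-scores of one word across the ranked dataset.

    ``backgrounds`` must be aligned with the dataset's gene order.  A gene
    shorter than the word gets p = 1.  This is the reference (per-word)
    scoring path; the all-word engine in :mod:`wordbridge.model` matches
    it exactly.
    """
    check_word(word)
    if len(backgrounds) != dataset.u:
        raise ValueError("backgrounds must align with the dataset (one per gene)")
    lw = len(word)
    pvals = np.empty(dataset.u)
    for i, (rec, bg) in enumerate(zip(dataset.records, backgrounds)):
        n = len(rec.sequence) - lw + 1
        if n <= 0:
            pvals[i] = 1.0
            continue
        m = count_occurrences(rec.sequence, word)
        pvals[i] = binomial_tail(m, n, word_probability(bg, word))
    return log_scores(pvals, alpha=alpha, word=word)
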