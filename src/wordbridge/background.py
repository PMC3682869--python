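"""Per-sequence Markov background models for word probabilities.

Each gene sequence gets its own order-``k`` Markov model (``k`` in
{0, 1, 2}, i.e. mono-, di- or tri-nucleotide background), so composition
bias — GC content in UTRs, codon usage in CDS — is corrected gene by gene.
The background probability of a word W of length l is

    P_k(W) = mu(w_1..w_k) * prod_{i=1}^{l-k} pi(w_{i+k} | w_i..w_{i+k-1})

where ``mu`` is the marginal distribution of the first k letters
(estimated from the sequence's k-windows) and ``pi`` the conditional
next-letter distribution (estimated from its (k+1)-windows).  Counting is
over overlapping windows on the given strand only (mRNA motif search is
strand-specific); windows containing N are skipped.  A pseudocount ``c``
(default 1) on the (k+1)-mer counts keeps every word probability strictly
positive even on short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import BASES, check_word, encode, word_to_index

__all__ = ["MarkovBackground", "estimate_background", "word_probability"]


@dataclass(frozen=True)
class MarkovBackground:
    """An order-``k`` Markov model estimated from a single sequence.

    Attributes
    ----------
    order : int
        Model order k (0, 1 or 2).
    mu : np.ndarray, shape (4**k,)
        Marginal probability of each k-mer (``[1.0]`` for k=0: the empty
        word).  Sums to 1.
    pi : np.ndarray, shape (4**k, 4)
        ``pi[context, base]`` = conditional probability of the next base
        given the k-mer context.  Each defined row sums to 1; with a zero
        pseudocount a context never observed has a NaN row, and using it
        raises at lookup time.
    pseudocount : float
        The smoothing constant c applied to the window counts.
    """

    order: int
    mu: np.ndarray
    pi: np.ndarray
    pseudocount: float

    def mu_of(self, kmer: str) -> float:
        """Marginal probability of a k-mer (the empty string for k=0)."""
        if len(kmer) != self.order:
            raise ValueError(f"expected a {self.order}-mer, got {kmer!r}")
        return float(self.mu[word_to_index(kmer) if kmer else 0])

    def pi_of(self, base: str, context: str) -> float:
        """Conditional probability pi(base | context)."""
        if len(context) != self.order:
            raise ValueError(f"context must have length {self.order}")
        row = word_to_index(context) if context else 0
        val = self.pi[row, BASES.index(base)]
        if np.isnan(val):
            raise ValueError(
                f"context {context!r} was never observed and pseudocount is 0; "
                "re-estimate with pseudocount > 0"
            )
        return float(val)


def _window_index_and_validity(codes: np.ndarray, width: int):
    """Rolling base-4 indices of all ``width``-windows plus an N-free mask."""
    n_win = len(codes) - width + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    safe = np.where(codes >= 0, codes, 0).astype(np.int64)
    valid = codes >= 0
    idx = safe[:n_win].copy()
    ok = valid[:n_win].copy()
    for j in range(1, width):
        idx = idx * 4 + safe[j : j + n_win]
        ok &= valid[j : j + n_win]
    return idx, ok


def estimate_background(
    sequence: str, order: int, pseudocount: float = 1.0
) -> MarkovBackground:
    """Estimate an order-``k`` Markov background from one sequence.

    ``mu(a) = (#a among k-windows + c) / (#k-windows + c*4^k)`` and
    ``pi(x|a) = (#(a.x) among (k+1)-windows + c) / (#windows with prefix a + 4c)``.
    Windows containing N contribute to neither numerator nor denominator.

    Raises
    ------
    ValueError
        If the sequence is shorter than ``order + 1``, the order is outside
        {0, 1, 2}, or the pseudocount is negative.
    """
    if order not in (0, 1, 2):
        raise ValueError(f"order must be 0, 1 or 2, got {order}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    codes = encode(sequence)
    if len(codes) < order + 1:
        raise ValueError(
            f"sequence of length {len(codes)} is too short for order {order} "
            f"(need >= {order + 1})"
        )
    c = float(pseudocount)
    k = order
    n_ctx = 4**k

    # mu from k-windows (k=0: single empty word, probability 1)
    if k == 0:
        mu = np.array([1.0])
    else:
        idx, ok = _window_index_and_validity(codes, k)
        counts = np.bincount(idx[ok], minlength=n_ctx).astype(float)
        total = counts.sum()
        if total + c * n_ctx == 0:
            raise ValueError(
                "no valid k-windows (all contain N) and pseudocount is 0"
            )
        mu = (counts + c) / (total + c * n_ctx)

    # pi from (k+1)-windows
    idx, ok = _window_index_and_validity(codes, k + 1)
    joint = np.bincount(idx[ok], minlength=n_ctx * 4).astype(float)
    joint = joint.reshape(n_ctx, 4)
    row_tot = joint.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (joint + c) / (row_tot + 4 * c)[:, None]
    if c == 0:
        pi[row_tot == 0] = np.nan  # undefined contexts; error on use
    return MarkovBackground(order=k, mu=mu, pi=pi, pseudocount=c)


def word_probability(bg: MarkovBackground, word: str) -> float:
    """Background probability P_k(W) of a word under a per-sequence model.

    The word must be longer than the model order.  Strictly positive
    whenever the model was estimated with a positive pseudocount.
    """
    check_word(word)
    k = bg.order
    if len(word) <= k:
        raise ValueError(
            f"word length {len(word)} must exceed background order {k}"
        )
    p = bg.mu_of(word[:k])
    for i in range(k, len(word)):
        p *= bg.pi_of(word[i], word[i - k : i])
    return p


def all_word_log_probabilities(
    bg: MarkovBackground, max_length: int
) -> dict[int, np.ndarray]:
    """Log background probability of every word of each length up to ``max_length``.

    Returns ``{l: array of shape (4**l,)}`` for l = order+1 .. max_length,
    indexed lexicographically.  Built by the prefix recursion
    ``logP_l[w] = logP_{l-1}[w // 4] + log pi[ctx(w), w % 4]`` so all
    lengths share work; agrees elementwise with :func:`word_probability`.
    """
    k = bg.order
    if max_length <= k:
        raise ValueError("max_length must exceed the background order")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_mu = np.log(bg.mu)
        log_pi = np.log(bg.pi)
    out: dict[int, np.ndarray] = {}
    prev = log_mu  # length-k words (k=0: the empty word, logP = 0)
    n_ctx = 4**k
    for length in range(k + 1, max_length + 1):
        idx = np.arange(4**length, dtype=np.int64)
        prefix = idx >> 2
        ctx = prefix & (n_ctx - 1)
        prev = prev[prefix] + log_pi[ctx, idx & 3]
        out[length] = prev
    return out
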