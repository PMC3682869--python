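"""Grouping top-ranked words into degenerate motifs.

Regulatory signals rarely surface as a single word: seed-site variants
shifted by one position, or sub/superwords of a core site, all rank high
together.  Words are therefore clustered by sequence similarity: the best
ungapped local alignment of two words, scored matches minus mismatches,
normalized by the length of the shorter word (so a 6-mer nested in a
7-mer scores a full 1.0), and fed as distance 1 - similarity into UPGMA
(average-linkage) hierarchical clustering.  Cutting the tree (default
distance 0.5) yields flat motif labels used for display grouping — the
cut is a visualization aid, not an inferential threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._seq import check_word

__all__ = [
    "WordSimilarity",
    "MotifClustering",
    "best_ungapped_alignment",
    "normalized_similarity",
    "upgma_cluster",
]


@dataclass(frozen=True)
class WordSimilarity:
    word_a: str
    word_b: str
    raw_score: int
    normalized: float


@dataclass(frozen=True)
class MotifClustering:
    """UPGMA tree plus flat motif labels over a set of words.

    ``linkage`` is a scipy linkage matrix over the words sorted
    lexicographically (``None`` for a single word); ``labels`` maps each
    word to a cluster id, contiguous from 1, numbered by first appearance
    in lexicographic word order so labels are independent of input order.
    """

    words: tuple[str, ...]
    linkage: np.ndarray | None
    labels: dict[str, int]
    cut_distance: float

    @property
    def n_clusters(self) -> int:
        return max(self.labels.values())


def best_ungapped_alignment(word_a: str, word_b: str) -> int:
    """Score of the best ungapped local alignment of two words.

    Over every relative offset of the two words, the best contiguous
    segment of the overlap is scored +1 per match, -1 per mismatch
    (maximum-subarray on each diagonal); the empty segment scores 0, so
    the result is never negative.
    """
    check_word(word_a)
    check_word(word_b)
    la, lb = len(word_a), len(word_b)
    best = 0
    for offset in range(-(lb - 1), la):
        # overlap of word_a[i] with word_b[i - offset]
        start = max(0, offset)
        stop = min(la, lb + offset)
        run = 0
        for i in range(start, stop):
            s = 1 if word_a[i] == word_b[i - offset] else -1
            run = max(run + s, 0)  # Kadane with empty-segment floor
            best = max(best, run)
    return best


def normalized_similarity(word_a: str, word_b: str) -> float:
    """Alignment score normalized by the shorter word's length; in [0, 1].

    Shortest-length normalization removes the score bias between word
    lengths and makes a word identical to a nested sub-word score 1.0.
    """
    raw = best_ungapped_alignment(word_a, word_b)
    return raw / min(len(word_a), len(word_b))


def similarity(word_a: str, word_b: str) -> WordSimilarity:
    raw = best_ungapped_alignment(word_a, word_b)
    return WordSimilarity(word_a, word_b, raw, raw / min(len(word_a), len(word_b)))


def upgma_cluster(words, cut_distance: float = 0.5) -> MotifClustering:
    """UPGMA-cluster words on 1 - normalized ungapped-alignment similarity.

    Words are canonicalised (sorted lexicographically) before linkage, so
    the tree and the flat labels do not depend on input order.  The tree
    is cut at ``cut_distance``; labels are renumbered contiguously from 1
    by first appearance in lexicographic order.
    """
    words = list(words)
    if not words:
        raise ValueError("at least one word is required")
    if not 0.0 <= cut_distance <= 1.0:
        raise ValueError("cut_distance must lie in [0, 1]")
    order = sorted(words)  # duplicates allowed; they merge at height 0
    if len(order) == 1:
        return MotifClustering(
            words=tuple(words), linkage=None,
            labels={order[0]: 1}, cut_distance=cut_distance,
        )
    n = len(order)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - normalized_similarity(order[i], order[j])
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(Z, t=cut_distance, criterion="distance")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for w, c in zip(order, flat):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[w] = relabel[c]
    return MotifClustering(
        words=tuple(words), linkage=Z, labels=labels, cut_distance=cut_distance
    )
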