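"""Model/Results interface for the full ranked-list word-enrichment analysis.

:class:`WordEnrichment` holds a ranked dataset plus the analysis
parameters (word lengths, background order, regularizer alpha, smoothing
pseudocount); :meth:`WordEnrichment.fit` runs the exhaustive analysis —
every word of every requested length scored in every gene, running-sum
statistics, analytic bridge p-values, cross-length Z normalization and
pooled Benjamini-Hochberg FDR — and returns a
:class:`WordEnrichmentResults` carrying the per-word table, diagnostics,
profiles, clustering and plots.

The engine is a vectorized equivalent of the per-word reference path
(:func:`wordbridge.wordstats.score_word_over_dataset` followed by
:func:`wordbridge.rankstat.running_sum`): per gene it counts all words of
a length in one rolling pass and evaluates all background probabilities
by a shared prefix recursion, then evaluates binomial tails only where a
word actually occurs (a word with zero occurrences has p = 1 exactly, as
does a gene shorter than the word, so those entries collapse to a common
baseline log-score).  Work is partitioned over contiguous gene chunks
when ``workers > 1``; the reduction is order-preserving, so the output is
bit-identical for any worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from ._seq import encode, word_to_index
from .background import (
    MarkovBackground,
    all_word_log_probabilities,
    estimate_background,
)
from .io import RankedDataset, build_ranked_dataset, read_fasta, read_rank_table
from .rankstat import (
    DIRECTION_DOWN,
    DIRECTION_UP,
    EnrichmentProfile,
    _series_sf_vec,
    bridge_moments,
    running_sum,
)
from .wordstats import DEFAULT_ALPHA, count_all_words, enumerate_words, score_word_over_dataset

__all__ = ["WordEnrichment", "WordEnrichmentResults"]

RESULT_COLUMNS = [
    "word", "length", "total_occurrences", "n_genes_with_word",
    "D", "sigma", "es_index", "direction", "p_analytic", "z", "fdr", "rank",
]

_BLOCK_COLS = 8192  # words per cumsum block; caps peak memory


def _chunk_word_stats(
    sequences: Sequence[str],
    lengths: tuple[int, ...],
    order: int,
    pseudocount: float,
):
    """Sparse (gene, word, count, background-prob) triplets for a gene chunk.

    Returns ``{l: (gene_idx, word_idx, m, p0)}`` with gene indices local to
    the chunk, plus the chunk's sequence lengths.
    """
    max_len = max(lengths)
    acc: dict[int, list[list[np.ndarray]]] = {l: [[], [], [], []] for l in lengths}
    seq_lens = np.empty(len(sequences), dtype=np.int64)
    for gi, seq in enumerate(sequences):
        seq_lens[gi] = len(seq)
        codes = encode(seq)
        bg = estimate_background(seq, order, pseudocount)
        logp = all_word_log_probabilities(bg, max_len)
        for l in lengths:
            counts = count_all_words(codes, l)
            nz = np.flatnonzero(counts)
            if nz.size == 0:
                continue
            a = acc[l]
            a[0].append(np.full(nz.size, gi, dtype=np.int64))
            a[1].append(nz)
            a[2].append(counts[nz])
            a[3].append(np.exp(logp[l][nz]))
    out = {}
    for l in lengths:
        a = acc[l]
        if a[0]:
            out[l] = tuple(np.concatenate(x) for x in a)
        else:
            e = np.empty(0)
            out[l] = (e.astype(np.int64), e.astype(np.int64), e.astype(np.int64), e)
    return out, seq_lens


def _length_table(
    l: int,
    gene_idx: np.ndarray,
    word_idx: np.ndarray,
    m: np.ndarray,
    p0: np.ndarray,
    seq_lens: np.ndarray,
    alpha: float,
) -> tuple[pd.DataFrame, float]:
    """Per-word statistics for one word length from the sparse triplets."""
    u = len(seq_lens)
    size = 4**l
    n_per_gene = np.maximum(seq_lens - l + 1, 0)

    # binomial upper tail only where m > 0 (m = 0 or n <= 0 give p = 1)
    pv = _sps.binom.sf(m - 1, n_per_gene[gene_idx], p0)

    baseline = -math.log1p(alpha)
    ls = np.full((u, size), baseline)
    ls[gene_idx, word_idx] = -np.log(pv + alpha)

    total_occ = np.bincount(word_idx, weights=m, minlength=size).astype(np.int64)
    n_genes = np.bincount(word_idx, minlength=size).astype(np.int64)

    mean = ls.mean(axis=0)
    sigma = ls.std(axis=0)
    # an all-constant score column carries no signal; detect exactly rather
    # than via sigma, which picks up summation rounding (~1e-20)
    constant = ls.max(axis=0) == ls.min(axis=0)
    D = np.zeros(size)
    es = np.ones(size, dtype=np.int64)
    down = np.ones(size, dtype=bool)
    max_r_end = 0.0
    for start in range(0, size, _BLOCK_COLS):
        sl = slice(start, min(start + _BLOCK_COLS, size))
        cs = np.cumsum(ls[:, sl] - mean[sl], axis=0)
        abs_cs = np.abs(cs)
        row = np.argmax(abs_cs, axis=0)  # first row attaining the max
        cols = np.arange(cs.shape[1])
        D[sl] = abs_cs[row, cols]
        es[sl] = row + 1  # r_0 = 0 never exceeds a positive max
        down[sl] = cs[row, cols] > 0
        max_r_end = max(max_r_end, float(np.abs(cs[-1]).max(initial=0.0)))

    degenerate = constant | (sigma == 0.0)
    sigma = np.where(degenerate, 0.0, sigma)
    x = np.zeros(size)
    np.divide(D, sigma * math.sqrt(u), out=x, where=~degenerate)
    p_analytic = np.where(degenerate, 1.0, _series_sf_vec(x))
    mom_mean, mom_var = bridge_moments(u)
    z = np.zeros(size)
    np.divide(D, sigma, out=z, where=~degenerate)
    z = np.where(degenerate, 0.0, (z - mom_mean) / math.sqrt(mom_var))
    D = np.where(degenerate, 0.0, D)
    es = np.where(degenerate, 1, es)
    direction = np.where(degenerate | down, DIRECTION_DOWN, DIRECTION_UP)

    df = pd.DataFrame(
        {
            "word": enumerate_words([l]),
            "length": l,
            "total_occurrences": total_occ,
            "n_genes_with_word": n_genes,
            "D": D,
            "sigma": sigma,
            "es_index": es,
            "direction": direction,
            "p_analytic": p_analytic,
            "z": z,
        }
    )
    return df, max_r_end


class WordEnrichment:
    """Ranked-list word-enrichment model.

    Parameters
    ----------
    dataset : RankedDataset
        Genes with sequences, sorted by the ranking value (most
        down-regulated first).
    lengths : iterable of int, default (6, 7, 8)
        Word lengths analyzed exhaustively (all 4**l words per length).
    order : int, default 1
        Markov background order per sequence: 0/1/2 for mono-, di- or
        tri-nucleotide background.  2 is recommended for CDS input, where
        the tri-nucleotide background absorbs codon-usage bias.
    alpha : float, default 1e-5
        Regularizer in the log-score transform -ln(p + alpha).
    pseudocount : float, default 1.0
        Smoothing constant on per-sequence window counts; must be > 0 so
        every word probability is strictly positive.
    """

    def __init__(
        self,
        dataset: RankedDataset,
        lengths: Iterable[int] = (6, 7, 8),
        order: int = 1,
        alpha: float = DEFAULT_ALPHA,
        pseudocount: float = 1.0,
    ) -> None:
        lengths = tuple(sorted(set(int(l) for l in lengths)))
        if not lengths:
            raise ValueError("at least one word length is required")
        if lengths[0] < 1 or lengths[-1] > 10:
            raise ValueError(f"word lengths must lie in 1..10, got {lengths}")
        if order not in (0, 1, 2):
            raise ValueError(f"background order must be 0, 1 or 2, got {order}")
        if lengths[0] <= order:
            raise ValueError(
                f"all word lengths must exceed the background order {order}"
            )
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 for the full analysis")
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        self.dataset = dataset
        self.lengths = lengths
        self.order = int(order)
        self.alpha = float(alpha)
        self.pseudocount = float(pseudocount)
        self._backgrounds: list[MarkovBackground] | None = None

    @classmethod
    def from_files(
        cls,
        fasta_path,
        ranks_path,
        ascending: bool = True,
        **kwargs,
    ) -> "WordEnrichment":
        """Build the model from a FASTA file and a rank table."""
        seqs = read_fasta(fasta_path)
        ranks = read_rank_table(ranks_path)
        dataset = build_ranked_dataset(seqs, ranks, ascending=ascending)
        return cls(dataset, **kwargs)

    @property
    def backgrounds(self) -> list[MarkovBackground]:
        """Per-gene Markov background models, in ranked order (cached)."""
        if self._backgrounds is None:
            self._backgrounds = [
                estimate_background(s, self.order, self.pseudocount)
                for s in self.dataset.sequences
            ]
        return self._backgrounds

    def fit(self, workers: int = 1) -> "WordEnrichmentResults":
        """Run the exhaustive analysis and return the results object.

        ``workers`` only partitions the per-gene scoring stage; output is
        bit-identical for any value >= 1.
        """
        if workers < 1:
            raise ValueError("workers must be >= 1")
        seqs = self.dataset.sequences
        u = self.dataset.u
        if workers == 1 or u < 2 * workers:
            chunks = [
                _chunk_word_stats(seqs, self.lengths, self.order, self.pseudocount)
            ]
        else:
            from joblib import Parallel, delayed

            bounds = np.linspace(0, u, workers + 1).astype(int)
            chunks = Parallel(n_jobs=workers)(
                delayed(_chunk_word_stats)(
                    seqs[a:b], self.lengths, self.order, self.pseudocount
                )
                for a, b in zip(bounds[:-1], bounds[1:])
            )
        seq_lens = np.concatenate([c[1] for c in chunks])
        offsets = np.concatenate([[0], np.cumsum([len(c[1]) for c in chunks])])

        frames = []
        max_r_end = 0.0
        for l in self.lengths:
            gi = np.concatenate(
                [c[0][l][0] + off for c, off in zip(chunks, offsets)]
            )
            wi = np.concatenate([c[0][l][1] for c in chunks])
            m = np.concatenate([c[0][l][2] for c in chunks])
            p0 = np.concatenate([c[0][l][3] for c in chunks])
            df, r_end = _length_table(l, gi, wi, m, p0, seq_lens, self.alpha)
            frames.append(df)
            max_r_end = max(max_r_end, r_end)

        table = pd.concat(frames, ignore_index=True)
        table["fdr"] = _sps.false_discovery_control(
            table["p_analytic"].to_numpy(), method="bh"
        )
        table = table.sort_values(
            ["z", "word"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        table = table[RESULT_COLUMNS]
        diagnostics = {
            "max_abs_r_end": max_r_end,
            "n_words": len(table),
            "u": u,
        }
        return WordEnrichmentResults(self, table, diagnostics)


class WordEnrichmentResults:
    """Fitted results: the per-word table plus profiles, clustering, plots.

    ``results`` is a DataFrame with one row per analyzed word, sorted by
    Z descending (ties broken lexicographically), columns
    ``word, length, total_occurrences, n_genes_with_word, D, sigma,
    es_index, direction, p_analytic, z, fdr, rank``.
    """

    def __init__(
        self,
        model: WordEnrichment,
        results: pd.DataFrame,
        diagnostics: dict,
    ) -> None:
        self.model = model
        self.results = results
        self.diagnostics = diagnostics
        self._row_by_word = None

    def top_words(self, n: int = 100) -> list[str]:
        """The n highest-Z words across all analyzed lengths."""
        return self.results["word"].head(n).tolist()

    def word_row(self, word: str) -> pd.Series:
        if self._row_by_word is None:
            self._row_by_word = self.results.set_index("word")
        return self._row_by_word.loc[word]

    def profile(self, word: str) -> EnrichmentProfile:
        """Recompute the full running-sum profile of one word.

        Uses the per-word reference scoring path; its D, sigma, ES index
        and direction agree exactly with the fitted table.
        """
        scores = score_word_over_dataset(
            word, self.model.dataset, self.model.backgrounds,
            alpha=self.model.alpha,
        )
        return running_sum(scores)

    def cluster(self, top_n: int = 100, cut_distance: float = 0.5):
        """UPGMA-cluster the top words into motifs (see :mod:`wordbridge.cluster`)."""
        from .cluster import upgma_cluster

        return upgma_cluster(self.top_words(top_n), cut_distance=cut_distance)

    def plot_profiles(self, path, words: Sequence[str] | None = None, **kw):
        from .plotting import plot_enrichment_profiles

        words = list(words) if words is not None else self.top_words(10)
        profiles = [self.profile(w) for w in words]
        return plot_enrichment_profiles(profiles, path, **kw)

    def plot_word_cluster(self, path, clustering=None, top_n: int = 100, **kw):
        from .plotting import plot_word_cluster

        if clustering is None:
            clustering = self.cluster(top_n=top_n)
        return plot_word_cluster(self.results, clustering, path, **kw)

    def save(self, out_dir, **kw):
        """Write the full report (tables, plots, metadata); see :mod:`wordbridge.report`."""
        from .report import write_report

        return write_report(self, out_dir, **kw)

    def summary(self, top: int = 10) -> str:
        """Human-readable summary: parameters and the top-Z words."""
        m = self.model
        head = self.results.head(top).copy()
        for col in ("D", "sigma", "z"):
            head[col] = head[col].map("{:.3f}".format)
        for col in ("p_analytic", "fdr"):
            head[col] = head[col].map("{:.3g}".format)
        lines = [
            "Ranked-list word enrichment",
            "===========================",
            f"genes (u):            {m.dataset.u}",
            f"word lengths:         {', '.join(map(str, m.lengths))}"
            f"   ({self.diagnostics['n_words']} words)",
            f"background order (k): {m.order}",
            f"alpha:                {m.alpha:g}",
            f"sort:                 {'ascending' if m.dataset.ascending else 'descending'} rank value",
            "",
            f"Top {top} words by Z:",
            head.to_string(index=False),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<WordEnrichmentResults: {self.diagnostics['n_words']} words, "
            f"u={self.diagnostics['u']}, lengths={self.model.lengths}>"
        )
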