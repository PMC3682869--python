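"""Deterministic synthetic benchmark data with planted, rank-correlated motifs.

The generator emulates the structure the enrichment statistic assumes: a
ranked list of gene sequences of heterogeneous length and composition in
which one word is over-represented specifically among the most strongly
down-regulated genes.  Per gene, a GC fraction is drawn from a range
(composition heterogeneity the per-sequence background must absorb), a
sequence is drawn i.i.d. with that composition, and a ranking value is
formed from an equally spaced base grid in [-3, 3] plus Gaussian noise,
giving a realistic near-tie structure at the list center.  For genes
whose final rank falls in the top ``n_top``, the planted word overwrites
a uniformly chosen window with probability ``plant_probability`` —
overwriting rather than inserting keeps sequence lengths, and hence the
trial counts of the binomial model, unchanged.  Everything is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._seq import BASES, check_word
from .io import RankedDataset, build_ranked_dataset

__all__ = ["SyntheticSpec", "generate", "make_null", "generate_dataset", "ranked_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic planted-motif benchmark.

    Defaults: 500 genes of 400-1200 nt with per-gene GC drawn from
    [0.3, 0.6], the miR-9 7mer-m8 seed-match word ACCAAAG planted with
    probability 0.8 in the 100 most down-regulated genes, and ranking
    values on a [-3, 3] grid with N(0, 0.25 sd) noise.
    """

    n_genes: int = 500
    length_range: tuple[int, int] = (400, 1200)
    gc_range: tuple[float, float] = (0.3, 0.6)
    planted_word: str | None = "ACCAAAG"
    plant_probability: float | Callable[[int], float] = 0.8
    n_top: int = 100
    rank_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        g0, g1 = self.gc_range
        if not 0.0 < g0 <= g1 < 1.0:
            raise ValueError("gc fractions must lie strictly inside (0, 1)")
        if not 0 <= self.n_top <= self.n_genes:
            raise ValueError("n_top must lie in [0, n_genes]")
        if self.planted_word is not None:
            check_word(self.planted_word)
            if len(self.planted_word) > lo:
                raise ValueError(
                    f"planted word of length {len(self.planted_word)} exceeds "
                    f"the minimum sequence length {lo}"
                )

    def plant_prob_at(self, rank: int) -> float:
        """Planting probability as a function of (1-based) gene rank."""
        if callable(self.plant_probability):
            return float(self.plant_probability(rank))
        return float(self.plant_probability) if rank <= self.n_top else 0.0


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[dict[str, str], dict[str, float], pd.DataFrame]:
    """Generate sequences, rank values, and the planted-site truth record.

    Returns ``(seqs, ranks, truth)`` where ``truth`` has one row per
    planted occurrence: gene_id, position (0-based), word.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    width = len(str(n))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n)]

    gc = rng.uniform(*spec.gc_range, size=n)
    lengths = rng.integers(spec.length_range[0], spec.length_range[1] + 1, size=n)
    base = np.linspace(-3.0, 3.0, n)
    values = base + rng.normal(0.0, spec.rank_noise_sd, size=n)

    seqs: dict[str, str] = {}
    for gid, frac, length in zip(gene_ids, gc, lengths):
        probs = np.array(
            [(1 - frac) / 2, frac / 2, frac / 2, (1 - frac) / 2]
        )  # A, C, G, T
        codes = rng.choice(4, size=int(length), p=probs)
        seqs[gid] = "".join(BASES[c] for c in codes)

    ranks = dict(zip(gene_ids, values))
    truth_rows = []
    if spec.planted_word is not None:
        word = spec.planted_word
        lw = len(word)
        by_rank = sorted(gene_ids, key=lambda g: (ranks[g], g))
        for rank, gid in enumerate(by_rank, start=1):
            prob = spec.plant_prob_at(rank)
            if prob <= 0 or rng.random() >= prob:
                continue
            pos = int(rng.integers(0, len(seqs[gid]) - lw + 1))
            s = seqs[gid]
            seqs[gid] = s[:pos] + word + s[pos + lw:]
            truth_rows.append({"gene_id": gid, "position": pos, "word": word})
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "position", "word"])
    return seqs, ranks, truth


def generate(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Generate a fixture on disk: FASTA, rank TSV, and truth TSV.

    File contents are a pure function of the spec (same seed, same bytes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs, ranks, truth = generate_dataset(spec)
    fasta = out / "synthetic.fa"
    rank_tsv = out / "synthetic_ranks.tsv"
    truth_tsv = out / "synthetic_truth.tsv"
    with open(fasta, "w") as fh:
        for gid, seq in seqs.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(rank_tsv, "w") as fh:
        fh.write("gene_id\tlogFC\n")
        for gid in seqs:
            fh.write(f"{gid}\t{ranks[gid]:.6f}\n")
    truth.to_csv(truth_tsv, sep="\t", index=False)
    return fasta, rank_tsv, truth_tsv


def make_null(spec: SyntheticSpec) -> tuple[dict[str, str], dict[str, float]]:
    """The same generator with no planted word (calibration null)."""
    seqs, ranks, _ = generate_dataset(replace(spec, planted_word=None))
    return seqs, ranks


def ranked_dataset(spec: SyntheticSpec) -> RankedDataset:
    """Convenience: generate and join into a RankedDataset in memory."""
    seqs, ranks, _ = generate_dataset(spec)
    return build_ranked_dataset(seqs, ranks)
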