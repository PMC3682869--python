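"""Input handling: FASTA sequences, gene-ranking tables, and the ranked dataset.

The analysis consumes a :class:`RankedDataset`: one sequence per gene
(3'UTR or CDS, DNA alphabet, T in place of U) joined to a ranking value
(typically the log fold change of expression) and sorted ascending, so the
most down-regulated genes come first.  Genes with multiple transcript
isoforms must be collapsed to a single representative sequence upstream;
gene identifiers are matched by exact string equality.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneRecord",
    "RankedDataset",
    "read_fasta",
    "read_rank_table",
    "build_ranked_dataset",
]

_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneRecord:
    """A gene's identifier, ranking value and sanitized DNA sequence."""

    gene_id: str
    rank_value: float
    sequence: str

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence


@dataclass
class RankedDataset:
    """Genes joined to sequences, ordered by differential-expression value.

    ``records`` are sorted ascending by ``rank_value`` (most down-regulated
    first); ties are broken by lexicographic gene id.  ``dropped_sequences``
    and ``dropped_ranks`` count ids present in only one of the two inputs.
    """

    records: list[GeneRecord]
    dropped_sequences: int = 0
    dropped_ranks: int = 0
    ascending: bool = True

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(
                f"a ranked dataset needs at least 2 genes, got {len(self.records)}"
            )

    @property
    def u(self) -> int:
        """Number of genes in the ranked list."""
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def rank_values(self) -> list[float]:
        return [r.rank_value for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "rank_value": self.rank_values,
                "length": [len(r.sequence) for r in self.records],
            }
        )


def _sanitize(seq: str, gene_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"sequence for {gene_id!r} contains invalid characters: "
            f"{sorted(bad)} (allowed: A,C,G,T,N; U is mapped to T)"
        )
    if not s:
        raise ValueError(f"sequence for {gene_id!r} is empty")
    return s


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a mapping ``gene_id -> DNA sequence``.

    Headers are truncated at the first whitespace.  Sequences are
    upper-cased and U is mapped to T; characters outside {A,C,G,T,N} are
    rejected.  N-containing sequences are retained (windows overlapping an
    N are later excluded from both word counts and background counts).

    Raises
    ------
    ValueError
        On a duplicate gene id (named in the message) or an empty file.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if not gene_id:
            raise ValueError(f"empty FASTA header in {path}")
        if gene_id in seqs:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        seqs[gene_id] = _sanitize(str(rec.seq), gene_id)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def read_rank_table(path: str | Path) -> dict[str, float]:
    """Read a two-column tab-separated ``gene_id<TAB>rank_value`` table.

    A single header line is skipped when its second column is non-numeric.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        rest = fh.read()
    if not first.strip():
        raise ValueError(f"rank table {path} is empty")
    cols = first.rstrip("\n").split("\t")
    if len(cols) != 2:
        raise ValueError(
            f"rank table {path} must have exactly 2 tab-separated columns, "
            f"first line has {len(cols)}"
        )
    try:
        float(cols[1])
        body = first + rest
    except ValueError:
        body = rest  # header line
    df = pd.read_csv(
        _stdio.StringIO(body),
        sep="\t",
        header=None,
        names=["gene_id", "rank_value"],
        dtype={"gene_id": str},
    )
    if df["rank_value"].dtype == object:
        bad = df.loc[pd.to_numeric(df["rank_value"], errors="coerce").isna(), "gene_id"]
        raise ValueError(
            f"non-numeric rank values in {path} for gene(s): {list(bad)[:5]}"
        )
    if len(df) < 2:
        raise ValueError(f"rank table {path} has fewer than 2 data rows")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id {dup.iloc[0]!r} in rank table {path}")
    return dict(zip(df["gene_id"], df["rank_value"].astype(float)))


def build_ranked_dataset(
    seqs: Mapping[str, str],
    ranks: Mapping[str, float],
    ascending: bool = True,
) -> RankedDataset:
    """Inner-join sequences and ranks into a :class:`RankedDataset`.

    Sorted ascending by rank value (most down-regulated first) by default;
    ``ascending=False`` reverses the sort for datasets where high values
    mean "bound" (e.g. AGO-IP relative abundance).  Ties are broken by
    lexicographic gene id, so the ordering is deterministic and independent
    of input order.
    """
    common = set(seqs) & set(ranks)
    if len(common) < 2:
        raise ValueError(
            f"sequences and ranks share only {len(common)} gene id(s); need >= 2"
        )
    sign = 1.0 if ascending else -1.0
    ordered = sorted(common, key=lambda g: (sign * ranks[g], g))
    records = [GeneRecord(g, float(ranks[g]), seqs[g]) for g in ordered]
    return RankedDataset(
        records=records,
        dropped_sequences=len(set(seqs) - common),
        dropped_ranks=len(set(ranks) - common),
        ascending=ascending,
    )
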