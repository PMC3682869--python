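"""Summary visualizations: enrichment-profile plot and word-cluster plot.

Every figure has a machine-readable twin: the exact series behind the
plot is written next to it as TSV, so plots are views, never sources of
truth.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from ._seq import check_word
from .cluster import MotifClustering
from .rankstat import EnrichmentProfile

__all__ = ["plot_enrichment_profiles", "plot_word_cluster"]


def _backing_path(path: Path) -> Path:
    return path.with_suffix(".tsv")


def plot_enrichment_profiles(
    profiles: Sequence[EnrichmentProfile],
    path: str | Path,
    title: str = "Word enrichment profiles",
) -> tuple[Path, Path]:
    """Running-sum graph of one line per word over the ranked gene list.

    x-axis: gene rank (most down-regulated to most up-regulated);
    y-axis: cumulative enrichment score r_i.  Writes the image plus a
    long-format backing TSV (word, rank, r) and returns both paths.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    path = Path(path)
    rows = []
    fig, ax = plt.subplots(figsize=(8, 5))
    for prof in profiles:
        ranks = range(len(prof.r))
        ax.plot(list(ranks), prof.r, label=prof.word, linewidth=1.2)
        rows.append(
            pd.DataFrame({"word": prof.word, "rank": list(ranks), "r": prof.r})
        )
    ax.axhline(0.0, color="grey", linewidth=0.6)
    ax.set_xlabel("gene rank (most down-regulated → most up-regulated)")
    ax.set_ylabel("cumulative enrichment score $r_i$")
    ax.set_title(title)
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    backing = _backing_path(path)
    pd.concat(rows, ignore_index=True).to_csv(
        backing, sep="\t", index=False, float_format="%.6g"
    )
    return path, backing


def plot_word_cluster(
    results: pd.DataFrame,
    clustering: MotifClustering,
    path: str | Path,
    annotation_table: dict[str, str] | None = None,
    title: str = "Word cluster plot",
) -> tuple[Path, Path]:
    """Scatter of ES index (x) vs Z (y) for clustered words.

    Point color encodes the motif (cluster) a word belongs to; words
    present in ``annotation_table`` (seed-match word -> miRNA name) are
    drawn as triangles.  Writes image + backing TSV (word, es_index, z,
    cluster_id, annotation) and returns both paths.
    """
    path = Path(path)
    annotation_table = annotation_table or {}
    for w in annotation_table:
        check_word(w)
    words = [w for w in clustering.words]
    sub = results[results["word"].isin(words)].copy()
    missing = set(words) - set(sub["word"])
    if missing:
        raise ValueError(f"clustered words missing from results: {sorted(missing)[:5]}")
    sub["cluster_id"] = sub["word"].map(clustering.labels)
    sub["annotation"] = sub["word"].map(annotation_table).fillna("")

    fig, ax = plt.subplots(figsize=(8, 5))
    cmap = plt.get_cmap("tab20")
    annotated = sub["annotation"] != ""
    for is_tri, frame in sub.groupby(annotated):
        ax.scatter(
            frame["es_index"],
            frame["z"],
            c=[cmap((cid - 1) % 20) for cid in frame["cluster_id"]],
            marker="^" if is_tri else "o",
            s=48 if is_tri else 28,
            edgecolors="black" if is_tri else "none",
            linewidths=0.6,
            zorder=3 if is_tri else 2,
        )
    ax.set_xlabel("enrichment specificity (ES) index")
    ax.set_ylabel("Z-score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    backing = _backing_path(path)
    sub[["word", "es_index", "z", "cluster_id", "annotation"]].to_csv(
        backing, sep="\t", index=False, float_format="%.6g"
    )
    return path, backing
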