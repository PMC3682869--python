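"""Tabular and graphical report of a fitted analysis.

:func:`write_report` writes the documented output set of a run:

=======================  =====================================================
results.tsv              per-word statistics, one row per analyzed word
clusters.tsv             UPGMA linkage dump (merge pairs + heights)
enrichment_profiles.png  running-sum plot of the top words
enrichment_profiles.tsv  backing series of the profile plot (word, rank, r)
word_clusters.png        ES-index vs Z scatter colored by motif cluster
word_clusters.tsv        backing table of the scatter
run_metadata.json        parameters, input checksums, package version
=======================  =====================================================

Outputs are deterministic: identical inputs and parameters reproduce
byte-identical TSVs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .model import WordEnrichmentResults

__all__ = ["write_report", "REPORT_FILES"]

REPORT_FILES = (
    "results.tsv",
    "clusters.tsv",
    "enrichment_profiles.png",
    "enrichment_profiles.tsv",
    "word_clusters.png",
    "word_clusters.tsv",
    "run_metadata.json",
)


def _checksum(path: str | Path | None) -> str | None:
    if path is None:
        return None
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_report(
    results: WordEnrichmentResults,
    out_dir: str | Path,
    top_profiles: int = 10,
    top_cluster: int = 100,
    cut_distance: float = 0.5,
    annotation_table: dict[str, str] | None = None,
    inputs: dict[str, str | Path] | None = None,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the full report into ``out_dir``; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"not a writable directory: {out}")

    clustering = results.cluster(top_n=top_cluster, cut_distance=cut_distance)

    table = results.results.copy()
    table["cluster_id"] = (
        table["word"].map(clustering.labels).astype("Int64")
    )
    paths = {"results.tsv": out / "results.tsv"}
    table.to_csv(paths["results.tsv"], sep="\t", index=False, float_format="%.6g")

    lk = clustering.linkage
    sorted_words = sorted(clustering.words)
    if lk is None:
        link_df = pd.DataFrame(columns=["node_a", "node_b", "height", "size"])
    else:
        link_df = pd.DataFrame(
            {
                "node_a": lk[:, 0].astype(int),
                "node_b": lk[:, 1].astype(int),
                "height": lk[:, 2],
                "size": lk[:, 3].astype(int),
            }
        )
    paths["clusters.tsv"] = out / "clusters.tsv"
    with open(paths["clusters.tsv"], "w") as fh:
        fh.write("# leaves (lexicographic order): " + ",".join(sorted_words) + "\n")
        link_df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    png, tsv = results.plot_profiles(out / "enrichment_profiles.png",
                                     words=results.top_words(top_profiles))
    paths["enrichment_profiles.png"] = png
    paths["enrichment_profiles.tsv"] = tsv
    png, tsv = results.plot_word_cluster(
        out / "word_clusters.png", clustering=clustering,
        annotation_table=annotation_table,
    )
    paths["word_clusters.png"] = png
    paths["word_clusters.tsv"] = tsv

    m = results.model
    meta = {
        "package": "wordbridge",
        "version": __version__,
        "u": m.dataset.u,
        "word_lengths": list(m.lengths),
        "background_order": m.order,
        "alpha": m.alpha,
        "pseudocount": m.pseudocount,
        "sort_ascending": m.dataset.ascending,
        "top_profiles": top_profiles,
        "top_cluster": top_cluster,
        "cut_distance": cut_distance,
        "n_words": results.diagnostics["n_words"],
        "max_abs_r_end": results.diagnostics["max_abs_r_end"],
        "dropped_sequence_only_ids": m.dataset.dropped_sequences,
        "dropped_rank_only_ids": m.dataset.dropped_ranks,
        "inputs": {
            name: {"path": str(p), "sha256": _checksum(p)}
            for name, p in (inputs or {}).items()
        },
    }
    if extra_metadata:
        meta.update(extra_metadata)
    paths["run_metadata.json"] = out / "run_metadata.json"
    with open(paths["run_metadata.json"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
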