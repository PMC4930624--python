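"""End-to-end orchestration: filters -> Gini -> selection -> clustering -> DE.

The pipeline executes the five analysis steps in order — compute per-gene
Gini indices, normalize them against the expression trend and select
high-Gini genes, build a cell-cell distance on those genes, detect clusters
with DBSCAN, and characterize each rare cluster by differential expression
against the largest cluster.  t-SNE is attached for visualization only and
never feeds clustering.

Every run is reproducible from its config and seed; when an output directory
is given, all tables are written as TSV alongside a JSON manifest carrying
the package version, the full config, its hash, and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    SINGLETON,
    ClusterAssignment,
    correlation_distance,
    dbscan,
    jaccard_distance,
)
from .diffexpr import hurdle_lrt, t_test_de
from .gene_selection import compute_gini_table, select_high_gini
from .preprocess import ExpressionMatrix, filter_cells, filter_genes

logger = logging.getLogger("giniclust")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "tsne_embed"]


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults follow the published RNA-seq settings: gene filter at 3 cells,
    cell filter at 2000 detected genes, high-Gini selection at p < 1e-4,
    Jaccard distance with DBSCAN eps = 0.5 and MinPts = 3, and differential
    expression cutoffs p < 1e-5 with fold change > 2.  For qPCR data use
    ``mode='qpcr'`` with the correlation metric, eps = 0.25, MinPts = 5 and
    the normalized-Gini cutoff 0.05.  Synthetic count matrices are not
    subject to the empirical QC thresholds; pass ``min_genes=0`` there.
    """

    mode: str = "rnaseq"  # rnaseq | qpcr
    min_cells: int = 3
    min_genes: int = 2000
    loess_span: float = 0.9
    loess_degree: int = 2
    robust_pvalues: bool = True
    p_cutoff: float = 1e-4
    gini_cutoff: float = 0.05
    metric: str = "jaccard"  # jaccard | one_minus_correlation
    eps: float = 0.5
    min_pts: int = 3
    de: bool = True
    de_p_cut: float = 1e-5
    de_fc_cut: float = 2.0
    tsne: bool = False
    tsne_perplexity: float = 10.0
    tsne_max_iter: int = 3000
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def qpcr(cls, **kwargs) -> "RunConfig":
        """Published qPCR settings: correlation metric, eps 0.25, MinPts 5."""
        defaults = dict(
            mode="qpcr", metric="one_minus_correlation", eps=0.25, min_pts=5,
            min_cells=0, min_genes=0,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    gini_table: pd.DataFrame
    clusters: ClusterAssignment
    de_tables: dict[int, pd.DataFrame] = field(default_factory=dict)
    embedding: pd.DataFrame | None = None
    config: RunConfig | None = None


def run_pipeline(m: ExpressionMatrix, config: RunConfig | None = None) -> PipelineResult:
    """Run the full rare-cell detection pipeline on an expression matrix."""
    config = config or RunConfig()
    if config.mode == "qpcr" and m.modality != "qpcr_log2":
        raise ValueError("qpcr config requires a qpcr_log2 matrix")
    if config.mode == "rnaseq" and m.modality == "qpcr_log2":
        raise ValueError("rnaseq config requires a umi or read matrix")

    logger.info("input: %d genes x %d cells (%s)", m.n_genes, m.n_cells, m.modality)
    if config.min_cells > 0:
        m = filter_genes(m, config.min_cells)
    if config.min_genes > 0:
        m = filter_cells(m, config.min_genes)
    logger.info("after filters: %d genes x %d cells", m.n_genes, m.n_cells)

    table = compute_gini_table(
        m,
        mode=config.mode,
        span=config.loess_span,
        degree=config.loess_degree,
        robust_pvalues=config.robust_pvalues,
    )
    table = select_high_gini(
        table, mode=config.mode,
        p_cutoff=config.p_cutoff, gini_cutoff=config.gini_cutoff,
    )
    selected = table["selected"].to_numpy()
    logger.info("selected %d high Gini genes", int(selected.sum()))
    sub = m.subset_genes(selected)

    if config.metric == "jaccard":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dist = jaccard_distance(sub.values)
    elif config.metric == "one_minus_correlation":
        dist = correlation_distance(sub.values)
    else:
        raise ValueError(f"unknown metric {config.metric!r}")

    clusters = dbscan(dist, config.eps, config.min_pts, cell_names=m.cell_names)
    logger.info(
        "found %d clusters (%d rare), %d singletons",
        clusters.n_clusters, len(clusters.rare_ids), clusters.n_singletons,
    )
    if clusters.n_clusters == 0:
        raise RuntimeError(
            "DBSCAN found no clusters; consider increasing eps or decreasing "
            "min_pts"
        )

    de_tables: dict[int, pd.DataFrame] = {}
    if config.de:
        reference = clusters.members(1)
        for cid in sorted(clusters.rare_ids):
            if cid == 1 or len(reference) < 2 or len(clusters.members(cid)) < 2:
                continue
            if config.mode == "qpcr":
                de = t_test_de(
                    m, clusters.members(cid), reference,
                    p_cut=config.de_p_cut, fc_cut=config.de_fc_cut,
                )
            else:
                de = hurdle_lrt(
                    m, clusters.members(cid), reference,
                    p_cut=config.de_p_cut, fc_cut=config.de_fc_cut,
                )
            de_tables[cid] = de
            logger.info(
                "cluster %d vs 1: %d significant genes",
                cid, int(de["significant"].sum()),
            )

    embedding = None
    if config.tsne:
        embedding = tsne_embed(
            dist,
            cell_names=m.cell_names,
            perplexity=config.tsne_perplexity,
            max_iter=config.tsne_max_iter,
            seed=config.seed,
        )

    result = PipelineResult(m, table, clusters, de_tables, embedding, config)
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def tsne_embed(
    dist: np.ndarray,
    cell_names: list[str] | None = None,
    perplexity: float = 10.0,
    max_iter: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE of cells from a precomputed distance matrix.

    Random (non-PCA) initialization, fixed seed.  Perplexity is reduced with
    a warning when there are fewer than ``3 * perplexity + 1`` cells.
    """
    from sklearn.manifold import TSNE

    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 10:
        raise ValueError("need at least 10 cells for a t-SNE embedding")
    if cell_names is None:
        cell_names = [f"cell{i}" for i in range(n)]
    max_perp = (n - 1) / 3
    if perplexity > max_perp:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} cells; using {max_perp:.1f}",
            stacklevel=2,
        )
        perplexity = max_perp
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        max_iter=max_iter,
        random_state=seed,
    )
    coords = tsne.fit_transform(dist)
    return pd.DataFrame(coords, index=cell_names, columns=["tsne1", "tsne2"])


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.gini_table.to_csv(outdir / "gini_table.tsv", sep="\t", index=False)
    result.clusters.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    result.clusters.summary().to_csv(
        outdir / "cluster_summary.tsv", sep="\t", index=False
    )
    for cid, de in result.de_tables.items():
        de.to_csv(outdir / f"de_cluster{cid}_vs_1.tsv", sep="\t", index=False)
    if result.embedding is not None:
        result.embedding.to_csv(outdir / "tsne.tsv", sep="\t")
        _plot_embedding(result, outdir / "tsne.png")
    manifest = {
        "package": "giniclust",
        "version": __version__,
        "config": result.config.to_dict() if result.config else None,
        "config_hash": result.config.hash() if result.config else None,
        "seed": result.config.seed if result.config else None,
        "n_genes": result.matrix.n_genes,
        "n_cells": result.matrix.n_cells,
        "n_selected_genes": int(result.gini_table["selected"].sum()),
        "n_clusters": result.clusters.n_clusters,
        "rare_clusters": result.clusters.rare_ids,
        "n_singletons": result.clusters.n_singletons,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _plot_embedding(result: PipelineResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    emb = result.embedding
    labels = result.clusters.labels
    fig, ax = plt.subplots(figsize=(6, 5))
    single = labels == SINGLETON
    if single.any():
        ax.scatter(
            emb.iloc[single, 0], emb.iloc[single, 1],
            s=8, c="lightgrey", label="singleton",
        )
    for cid in sorted(result.clusters.sizes):
        mask = labels == cid
        ax.scatter(emb.iloc[mask, 0], emb.iloc[mask, 1], s=8, label=f"cluster {cid}")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(fontsize=7, markerscale=1.5, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
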