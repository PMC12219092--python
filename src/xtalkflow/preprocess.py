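"""Quality filtering, normalization/scaling and target-gene selection.

Filtering drops rare clusters (fewer than 20 cells by default) and genes
detected in less than 5% of the remaining cells.  Normalization is
counts-per-10k followed by log1p; scaling is a per-gene z-score clipped at
+/-10.  Target genes for a receiver cluster are either user-supplied or the
cluster's over-expressed genes by a one-vs-rest Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionData

logger = logging.getLogger("xtalkflow")

__all__ = ["filter_cells_and_genes", "normalize_and_scale", "select_targets",
           "qc_flags"]

CP10K_TOTAL = 10_000.0
SCALE_CLIP = 10.0


def filter_cells_and_genes(data: ExpressionData, min_cluster_size: int = 20,
                           min_gene_frac: float = 0.05) -> ExpressionData:
    """Drop rare clusters and rarely detected genes.

    Clusters with fewer than ``min_cluster_size`` cells are removed
    entirely; genes with nonzero expression in fewer than
    ``min_gene_frac`` of the remaining cells are removed.  Both "fewer
    than" comparisons are strict.
    """
    sizes: dict[str, int] = {}
    for c in data.cell_ids:
        sizes[data.cluster_of[c]] = sizes.get(data.cluster_of[c], 0) + 1
    keep_clusters = {k for k, n in sizes.items() if n >= min_cluster_size}
    cell_idx = np.array(
        [j for j, c in enumerate(data.cell_ids)
         if data.cluster_of[c] in keep_clusters], dtype=int)
    n_dropped_clusters = len(sizes) - len(keep_clusters)
    if n_dropped_clusters:
        logger.info("dropped %d clusters (< %d cells), %d cells removed",
                    n_dropped_clusters, min_cluster_size,
                    data.n_cells - cell_idx.size)
    if cell_idx.size == 0:
        raise ValueError("all cells removed by the cluster-size filter")

    sub = data.matrix[:, cell_idx]
    detected_frac = (sub > 0).mean(axis=1)
    gene_idx = np.flatnonzero(detected_frac >= min_gene_frac)
    n_dropped_genes = data.n_genes - gene_idx.size
    if n_dropped_genes:
        logger.info("dropped %d genes detected in < %.0f%% of cells",
                    n_dropped_genes, 100 * min_gene_frac)
    if gene_idx.size == 0:
        raise ValueError("all genes removed by the detection filter")

    return data.subset(gene_idx, cell_idx)


def normalize_and_scale(data: ExpressionData) -> ExpressionData:
    """Library-size normalize (CP10K + log1p) and z-score per gene.

    Cells with zero total counts are dropped with a warning.  Both the
    normalized and the scaled layer are retained; downstream operations
    state which one they consume.  Constant genes scale to all zeros.
    """
    totals = data.matrix.sum(axis=0)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        logger.warning("dropping %d cells with zero total counts", dead.size)
        data = data.subset(cell_idx=np.flatnonzero(totals > 0))
        totals = data.matrix.sum(axis=0)

    norm = np.log1p(data.matrix / totals * CP10K_TOTAL)
    mu = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)          # constant gene -> all zeros
    scaled = np.clip((norm - mu) / sd_safe, -SCALE_CLIP, SCALE_CLIP)

    out = data.subset()
    out.normalized = norm
    out.scaled = scaled
    out.state = "scaled"
    return out


def select_targets(data: ExpressionData, receiver: str,
                   user_targets: list[str] | None = None,
                   alpha: float = 0.05, min_logfc: float = 0.25) -> list[str]:
    """Target genes for the receiver cluster.

    A non-empty ``user_targets`` list overrides differential expression:
    it is intersected with the kept genes, order preserved.  Otherwise the
    genes over-expressed in the receiver versus all other cells (Wilcoxon
    rank-sum on the normalized layer, Benjamini-Hochberg adjusted p < alpha,
    log fold-change > ``min_logfc``) are returned sorted by decreasing
    fold-change.
    """
    if receiver not in data.clusters:
        raise ValueError(f"receiver cluster {receiver!r} not present")
    if user_targets:
        kept = [g for g in user_targets if data.has_gene(g)]
        missing = set(user_targets) - set(kept)
        if missing:
            logger.warning("%d user targets absent from the matrix: %s",
                           len(missing), sorted(missing))
        if not kept:
            raise ValueError("none of the user-specified targets survive filtering")
        return kept

    norm = data.layer("normalized")
    in_grp = data.cells_in(receiver)
    out_grp = np.setdiff1d(np.arange(data.n_cells), in_grp)
    if out_grp.size == 0:
        raise ValueError("receiver is the only cluster; cannot run one-vs-rest DE")

    pvals = np.ones(data.n_genes)
    logfc = np.zeros(data.n_genes)
    for i in range(data.n_genes):
        a, b = norm[i, in_grp], norm[i, out_grp]
        logfc[i] = a.mean() - b.mean()
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            continue
        pvals[i] = stats.mannwhitneyu(a, b, alternative="greater").pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    hits = np.flatnonzero((adj < alpha) & (logfc > min_logfc))
    if hits.size == 0:
        raise ValueError(
            "no differentially expressed targets found for the receiver; "
            "relax alpha/min_logfc or provide an explicit target list")
    order = hits[np.argsort(-logfc[hits], kind="stable")]
    return [data.gene_ids[i] for i in order]


def qc_flags(data: ExpressionData, count_percentile: float = 99.0,
             mito_frac: float = 0.2,
             mito_prefixes: tuple[str, ...] = ("MT-", "mt-")) -> np.ndarray:
    """Optional per-cell QC flags: abnormally high totals or mitochondrial load.

    Returns a boolean vector (True = flagged).  Off the default path; callers
    decide whether to drop flagged cells.
    """
    totals = data.matrix.sum(axis=0)
    high = totals > np.percentile(totals, count_percentile)
    mito_idx = [i for i, g in enumerate(data.gene_ids)
                if g.startswith(mito_prefixes)]
    if mito_idx:
        frac = data.matrix[mito_idx].sum(axis=0) / np.maximum(totals, 1e-12)
        high |= frac > mito_frac
    return high
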