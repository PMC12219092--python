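"""Ground-truthed synthetic benchmark data.

A random 3-layer regulatory network (receptors : TFs : targets = 1 : 4 : 15)
drives a chemical-Langevin simulation of single-cell expression: each
gene's production rate is a Hill function of the weighted sum of its
regulators, receptors carry cluster-specific basal rates (three clusters by
default), and stationary states become counts through Poisson sampling
followed by technical noise (per-entry dropout, per-gene log-normal
outlier scaling).  The composable receptor->TF->target edge pairs are the
ground-truth pathways against which recovery is scored by AUROC/AUPRC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import RunConfig
from .io import ExpressionData
from . import hgnn, hypergraph as hg, preprocess

logger = logging.getLogger("xtalkflow")

__all__ = ["SyntheticGRN", "SyntheticDataset", "generate_grn",
           "simulate_expression", "make_benchmark", "score_benchmark",
           "pairwise_score_product", "run_recovery_benchmark"]

DECAY = 1.0          # first-order degradation rate
HILL_COEF = 2.0      # Hill coefficient of regulated production
HILL_K = 1.0         # half-saturation of regulated production
BASAL_LOW = 0.1      # leak production of regulated genes
PROD_MAX = 2.0       # span of the regulated production term
COUNT_SCALE = 10.0   # Poisson rate per unit of stationary expression


@dataclass
class SyntheticGRN:
    receptors: list[str]
    tfs: list[str]
    targets: list[str]
    receptor_tf_edges: pd.DataFrame     # from, to, weight (signed)
    tf_target_edges: pd.DataFrame
    truth_pathways: set[tuple[str, str, str]] = field(default_factory=set)

    @property
    def n_genes(self) -> int:
        return len(self.receptors) + len(self.tfs) + len(self.targets)

    @property
    def gene_ids(self) -> list[str]:
        return self.receptors + self.tfs + self.targets


@dataclass
class SyntheticDataset:
    counts: np.ndarray                  # genes x cells
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_of: dict[str, str]
    grn: SyntheticGRN
    ligand_of: dict[str, str] = field(default_factory=dict)  # receptor -> ligand
    states: np.ndarray | None = None    # pre-noise stationary expression

    def to_expression_data(self) -> ExpressionData:
        return ExpressionData(
            matrix=self.counts, gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids), cluster_of=dict(self.cluster_of),
            state="raw")


def _role_counts(n_genes: int) -> tuple[int, int, int]:
    # 1:4:15 split, remainder to targets
    n_rec = max(1, round(n_genes * 1 / 20))
    n_tf = max(1, round(n_genes * 4 / 20))
    return n_rec, n_tf, n_genes - n_rec - n_tf


def generate_grn(n_genes: int = 200, density_rt: float = 0.2,
                 density_tt: float = 0.1,
                 strength_range: tuple[float, float] = (0.5, 2.0),
                 seed: int = 0) -> SyntheticGRN:
    """Random 3-layer GRN with Bernoulli edges and signed uniform strengths.

    Every TF is guaranteed at least one incoming receptor edge and every
    target at least one incoming TF edge (resampled when violated), so no
    downstream gene is orphaned.  Ground-truth pathways are exactly the
    composable edge pairs.
    """
    if not (0 < density_rt <= 1 and 0 < density_tt <= 1):
        raise ValueError("densities must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_rec, n_tf, n_tgt = _role_counts(n_genes)
    receptors = [f"R{i+1}" for i in range(n_rec)]
    tfs = [f"TF{i+1}" for i in range(n_tf)]
    targets = [f"T{i+1}" for i in range(n_tgt)]

    def layer_edges(sources: list[str], sinks: list[str],
                    density: float) -> pd.DataFrame:
        mask = rng.random((len(sources), len(sinks))) < density
        for j in range(len(sinks)):        # no orphaned sinks
            if not mask[:, j].any():
                mask[rng.integers(len(sources)), j] = True
        lo, hi = strength_range
        strength = rng.uniform(lo, hi, size=mask.shape)
        sign = rng.choice([-1.0, 1.0], size=mask.shape)
        rows = [(sources[i], sinks[j], float(strength[i, j] * sign[i, j]))
                for i, j in zip(*np.nonzero(mask))]
        return pd.DataFrame(rows, columns=["from", "to", "weight"])

    rt = layer_edges(receptors, tfs, density_rt)
    tt = layer_edges(tfs, targets, density_tt)

    rt_by_tf: dict[str, list[str]] = {}
    for r, c in zip(rt["from"], rt["to"]):
        rt_by_tf.setdefault(c, []).append(r)
    truth = {(r, c, t)
             for c, t in zip(tt["from"], tt["to"])
             for r in rt_by_tf.get(c, [])}
    return SyntheticGRN(receptors, tfs, targets, rt, tt, truth)


def simulate_expression(grn: SyntheticGRN, n_cells: int = 1500,
                        n_clusters: int = 3, dt: float = 0.05,
                        steps: int = 200, noise_scale: float = 0.3,
                        dropout: float = 0.3, outlier_prob: float = 0.01,
                        outlier_sigma: float = 1.0, seed: int = 0,
                        with_ligands: bool = False) -> SyntheticDataset:
    """Chemical-Langevin simulation of the GRN to stationarity, then counts.

    Cells are split into equal clusters differing in receptor basal
    production (drawn per cluster from Uniform(0.2, 2.0)).  Each cell is an
    independent Euler-Maruyama trajectory of

        dx_g = (prod_g(x) - DECAY * x_g) dt + noise_scale * sqrt(prod + x) dW,

    where a regulated gene's production is BASAL_LOW + PROD_MAX *
    Hill(max(sum_r w_r x_r, 0)).  Final states become Poisson counts with
    dropout and sporadic per-gene log-normal amplification as technical
    noise.  ``with_ligands`` appends one cluster-specific ligand gene per
    receptor (expressed in the non-receiver clusters) plus the mapping
    needed to exercise the communication stage end to end.
    """
    rng = np.random.default_rng(seed)
    genes = grn.gene_ids
    g_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    W = np.zeros((n_genes, n_genes))   # W[g, r]: effect of regulator r on g
    for df in (grn.receptor_tf_edges, grn.tf_target_edges):
        for u, v, w in zip(df["from"], df["to"], df["weight"]):
            W[g_index[v], g_index[u]] = w
    regulated = W.any(axis=1)
    rec_idx = np.array([g_index[r] for r in grn.receptors])

    sizes = np.full(n_clusters, n_cells // n_clusters)
    sizes[: n_cells % n_clusters] += 1
    cluster_labels = np.repeat(np.arange(n_clusters), sizes)
    basal = rng.uniform(0.2, 2.0, size=(n_clusters, rec_idx.size))

    prod0 = np.zeros((n_genes, n_cells))
    prod0[rec_idx] = basal[cluster_labels].T
    x = prod0 / DECAY + 0.0             # start at the unregulated fixed point
    sqrt_dt = np.sqrt(dt)
    for _ in range(steps):
        drive = np.maximum(W @ x, 0.0)
        hill = drive**HILL_COEF / (HILL_K**HILL_COEF + drive**HILL_COEF)
        prod = prod0 + np.where(regulated[:, None],
                                BASAL_LOW + PROD_MAX * hill, 0.0)
        noise = noise_scale * np.sqrt(np.maximum(prod + DECAY * x, 0.0))
        x = x + (prod - DECAY * x) * dt \
            + noise * sqrt_dt * rng.standard_normal(x.shape)
        x = np.maximum(x, 0.0)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite simulation state; reduce dt")

    gene_ids = list(genes)
    ligand_of: dict[str, str] = {}
    if with_ligands:
        # ligand L_i mirrors receptor i's communication: expressed in sender
        # clusters (all but cluster 0) with its own per-cluster level
        lig_rows = np.zeros((rec_idx.size, n_cells))
        lig_basal = rng.uniform(0.5, 2.0, size=(n_clusters, rec_idx.size))
        lig_basal[0] *= 0.05            # receiver cluster barely expresses ligands
        lig_mean = lig_basal[cluster_labels].T
        lig_rows = np.maximum(
            lig_mean + noise_scale * rng.standard_normal(lig_mean.shape), 0.0)
        for i, r in enumerate(grn.receptors):
            ligand_of[r] = f"L{i+1}"
        gene_ids = [f"L{i+1}" for i in range(rec_idx.size)] + gene_ids
        x = np.vstack([lig_rows, x])

    counts = rng.poisson(COUNT_SCALE * x).astype(float)
    if outlier_prob > 0:
        out_genes = rng.random(counts.shape[0]) < outlier_prob
        factors = rng.lognormal(0.0, outlier_sigma, size=counts.shape[0])
        counts[out_genes] = np.round(counts[out_genes]
                                     * factors[out_genes, None])
    if dropout > 0:
        counts[rng.random(counts.shape) < dropout] = 0.0

    cell_ids = [f"cell{j+1}" for j in range(n_cells)]
    cluster_of = {c: f"C{cluster_labels[j]+1}" for j, c in enumerate(cell_ids)}
    return SyntheticDataset(counts, gene_ids, cell_ids, cluster_of, grn,
                            ligand_of, states=x)


# ---------------------------------------------------------------------------
# benchmark harness


def make_benchmark(grn: SyntheticGRN, train_frac: float = 0.8,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balanced labelled triples split into train and test sets.

    Positives are the ground-truth pathways; negatives are role-respecting
    triples outside the truth, matched in number.  The split is seeded and
    class-balanced; train and test are disjoint.
    """
    rng = np.random.default_rng(seed)
    positives = sorted(grn.truth_pathways)
    n_pos = len(positives)
    negatives: list[tuple[str, str, str]] = []
    seen = set(grn.truth_pathways)
    while len(negatives) < n_pos:
        k = n_pos - len(negatives)
        cand = zip(rng.choice(grn.receptors, size=k),
                   rng.choice(grn.tfs, size=k),
                   rng.choice(grn.targets, size=k))
        for t in cand:
            t = (str(t[0]), str(t[1]), str(t[2]))
            if t not in seen:
                seen.add(t)
                negatives.append(t)

    def split(items: list[tuple[str, str, str]], label: int):
        perm = rng.permutation(len(items))
        n_train = int(round(train_frac * len(items)))
        rows = [(items[i][0], items[i][1], items[i][2], label,
                 bool(j < n_train)) for j, i in enumerate(perm)]
        return rows

    rows = split(positives, 1) + split(negatives, 0)
    df = pd.DataFrame(rows, columns=["Signal", "SSC", "Target", "label",
                                     "is_train"])
    return (df[df["is_train"]].drop(columns="is_train").reset_index(drop=True),
            df[~df["is_train"]].drop(columns="is_train").reset_index(drop=True))


def score_benchmark(pred_scores: np.ndarray,
                    labels: np.ndarray) -> tuple[float, float]:
    """(AUROC, AUPRC) of predicted triple scores against binary labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("test set must contain both classes")
    return (float(roc_auc_score(labels, pred_scores)),
            float(average_precision_score(labels, pred_scores)))


def pairwise_score_product(signal_tf_scores: dict[tuple[str, str], float],
                           tf_target_scores: dict[tuple[str, str], float],
                           triples: list[tuple[str, str, str]]) -> np.ndarray:
    """Adapter for pairwise scorers: |s(signal, SSC)| * |s(SSC, target)|,
    with missing edge scores counting as zero."""
    return np.array([
        abs(signal_tf_scores.get((s, c), 0.0))
        * abs(tf_target_scores.get((c, t), 0.0))
        for s, c, t in triples])


def run_recovery_benchmark(n_genes: int = 200, density_rt: float = 0.2,
                           density_tt: float = 0.1, n_cells: int = 1500,
                           n_clusters: int = 3, train_frac: float = 0.8,
                           receiver: str = "C1", seed: int = 0,
                           config: RunConfig | None = None,
                           ) -> dict[str, object]:
    """Simulate, train on the labelled split, and score held-out triples.

    The hypergraph skeleton is built from the training positives; node
    features are the receiver cluster's normalized expression.  Returns the
    AUROC/AUPRC on the test set together with the train log.
    """
    config = config or RunConfig(seed=seed)
    grn = generate_grn(n_genes, density_rt, density_tt, seed=seed)
    dataset = simulate_expression(grn, n_cells=n_cells, n_clusters=n_clusters,
                                  seed=seed + 1)
    expr = preprocess.normalize_and_scale(dataset.to_expression_data())
    train_df, test_df = make_benchmark(grn, train_frac=train_frac,
                                       seed=seed + 2)

    pos_train = [tuple(r) for r in train_df.loc[train_df["label"] == 1,
                 ["Signal", "SSC", "Target"]].itertuples(index=False)]
    graph = hg.build_hypergraph_from_triples(
        pos_train, signals=grn.receptors, sscs=grn.tfs, targets=grn.targets)
    X = hgnn.node_features(graph, expr, receiver, config)

    all_train = [tuple(r) for r in train_df[["Signal", "SSC", "Target"]]
                 .itertuples(index=False)]
    rng = config.spawn_rng("benchmark-valsplit")
    labels = train_df["label"].to_numpy()
    is_train = np.zeros(len(all_train), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        is_train[perm[: int(round(0.8 * idx.size))]] = True
    samples = hg.TrainingSamples(all_train, labels, is_train)

    state, log = hgnn.train(graph, X, samples, config)
    test_triples = [tuple(r) for r in test_df[["Signal", "SSC", "Target"]]
                    .itertuples(index=False)]
    scores = state.predict_pa(test_triples)
    auroc, auprc = score_benchmark(scores, test_df["label"].to_numpy())
    logger.info("recovery benchmark seed=%d train_frac=%.2f: AUROC=%.3f "
                "AUPRC=%.3f", seed, train_frac, auroc, auprc)
    return {"auroc": auroc, "auprc": auprc, "train_log": log,
            "state": state, "grn": grn, "dataset": dataset,
            "test_scores": scores, "test_labels": test_df["label"].to_numpy()}
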