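"""Cell-cell communication scoring and signal (receptor) selection.

The communication strength of a ligand-receptor pair between a sender and
a receiver cluster follows a mass-action Hill model on cluster-mean
normalized expression,

    P = [LR / (K_h + LR)] * (1 + AG_s/(K_h+AG_s)) * (1 + AG_r/(K_h+AG_r))
        * K_h/(K_h+AN_s) * K_h/(K_h+AN_r) * n_s n_r / n^2,

with multi-subunit ligand/receptor expression taken as the geometric mean
of subunit cluster means and agonist/antagonist terms at their neutral
value when the gene lists are empty.  Significance comes from a label
permutation test; receptors retained after the p-value filter whose total
strength reaches a fraction of the maximum become signal nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .io import ExpressionData, LRDatabase, LRRecord

logger = logging.getLogger("xtalkflow")

__all__ = ["LRScore", "SignalSet", "lr_strength", "lr_permutation_pvalue",
           "select_signals", "score_communication"]


@dataclass
class LRScore:
    sender: str
    receiver: str
    record: LRRecord
    strength: float
    pvalue: float = np.nan


@dataclass
class SignalSet:
    """Receptors retained as signal nodes, with their summed strengths."""

    receptors: list[str]
    total_strength: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.receptors)


def _cluster_mean(layer: np.ndarray, expr: ExpressionData, genes: list[str],
                  cols: np.ndarray, geometric: bool) -> float:
    """Mean expression of a gene list in a set of cells.

    ``geometric=True`` combines subunit cluster means geometrically (used
    for ligand/receptor complexes); otherwise the arithmetic mean over
    genes is used (agonists/antagonists).  Missing genes count as zero
    expression; an empty list returns 0.
    """
    if not genes:
        return 0.0
    means = np.array([
        layer[expr.gene_index(g), cols].mean() if expr.has_gene(g) else 0.0
        for g in genes
    ])
    if geometric:
        return float(np.prod(means) ** (1.0 / len(means)))
    return float(means.mean())


def _strength_for_labels(expr: ExpressionData, layer: np.ndarray, lr: LRRecord,
                         sender_cols: np.ndarray, receiver_cols: np.ndarray,
                         n_total: int, k_h: float) -> float:
    L = _cluster_mean(layer, expr, lr.ligand_subunits, sender_cols, geometric=True)
    R = _cluster_mean(layer, expr, lr.receptor_subunits, receiver_cols, geometric=True)
    lr_term = L * R / (k_h + L * R)
    ag_s = _cluster_mean(layer, expr, lr.agonists, sender_cols, geometric=False)
    ag_r = _cluster_mean(layer, expr, lr.agonists, receiver_cols, geometric=False)
    an_s = _cluster_mean(layer, expr, lr.antagonists, sender_cols, geometric=False)
    an_r = _cluster_mean(layer, expr, lr.antagonists, receiver_cols, geometric=False)
    pop = sender_cols.size * receiver_cols.size / n_total**2
    return (lr_term
            * (1.0 + ag_s / (k_h + ag_s)) * (1.0 + ag_r / (k_h + ag_r))
            * (k_h / (k_h + an_s)) * (k_h / (k_h + an_r))
            * pop)


def lr_strength(expr: ExpressionData, lr: LRRecord, sender: str, receiver: str,
                k_h: float = 0.5) -> float:
    """Communication strength of one LR pair between two clusters."""
    layer = expr.layer("normalized")
    return _strength_for_labels(
        expr, layer, lr, expr.cells_in(sender), expr.cells_in(receiver),
        expr.n_cells, k_h)


def lr_permutation_pvalue(expr: ExpressionData, lr: LRRecord, sender: str,
                          receiver: str, n_permutations: int = 100,
                          k_h: float = 0.5,
                          rng: np.random.Generator | None = None) -> float:
    """Permutation p-value: the fraction of label permutations whose
    recomputed strength is >= the observed one (ties inclusive)."""
    rng = rng or np.random.default_rng()
    layer = expr.layer("normalized")
    observed = lr_strength(expr, lr, sender, receiver, k_h)
    labels = np.array([expr.cluster_of[c] for c in expr.cell_ids])
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        s_cols = np.flatnonzero(perm == sender)
        r_cols = np.flatnonzero(perm == receiver)
        p = _strength_for_labels(expr, layer, lr, s_cols, r_cols,
                                 expr.n_cells, k_h)
        if p >= observed:
            count += 1
    return count / n_permutations


def score_communication(expr: ExpressionData, lrdb: LRDatabase, receiver: str,
                        senders: list[str] | None = None,
                        config: RunConfig | None = None) -> list[LRScore]:
    """Score every LR record from each sender cluster into the receiver."""
    config = config or RunConfig()
    senders = senders or [c for c in expr.clusters if c != receiver]
    rng = config.spawn_rng("ccc-permutation")
    scores: list[LRScore] = []
    for sender in senders:
        for rec in lrdb:
            s = lr_strength(expr, rec, sender, receiver, config.k_h)
            pv = 1.0 if s == 0 else lr_permutation_pvalue(
                expr, rec, sender, receiver, config.n_permutations,
                config.k_h, rng)
            scores.append(LRScore(sender, receiver, rec, s, pv))
    return scores


def select_signals(scores: list[LRScore], pvalue_cutoff: float = 0.1,
                   strength_frac: float = 0.10) -> SignalSet:
    """Filter by p-value, sum strengths per receptor, keep receptors whose
    total reaches ``strength_frac`` of the maximum total."""
    totals: dict[str, float] = {}
    for sc in scores:
        if sc.pvalue > pvalue_cutoff:
            continue
        name = sc.record.receptor_name
        totals[name] = totals.get(name, 0.0) + sc.strength
    totals = {k: v for k, v in totals.items() if v > 0}
    if not totals:
        raise ValueError("no significant communication into the receiver cluster")
    cutoff = strength_frac * max(totals.values())
    kept = sorted([r for r, t in totals.items() if t >= cutoff])
    logger.info("selected %d / %d receptors as signals", len(kept), len(totals))
    return SignalSet(receptors=kept,
                     total_strength={r: totals[r] for r in kept})
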