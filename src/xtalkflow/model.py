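"""Model/Results surface tying the pipeline stages together.

:class:`CrosstalkModel` is built from an expression matrix plus the prior
interaction tables and a receiver cluster; :meth:`CrosstalkModel.fit` runs
filtering, normalization, communication scoring, prior-hypergraph
construction, representation learning, Random-Forest pathway-strength
estimation and selectivity scoring, returning a
:class:`CrosstalkResults` that carries the pathway table, the trained
embedding state and a text ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccc, crosstalk, hgnn, hypergraph as hg, preprocess, prs
from .config import RunConfig
from .io import (ExpressionData, LRDatabase, PriorNetworks,
                 read_expression, read_priors, write_pathway_table)

logger = logging.getLogger("xtalkflow")

__all__ = ["CrosstalkModel", "CrosstalkResults"]


@dataclass
class CrosstalkResults:
    """Fit output: the scored pathway table plus per-stage artifacts."""

    pathways: pd.DataFrame              # Signal, SSC, Target, S_H, PA, PRS, Fid, Spe
    activated: pd.DataFrame
    totals: pd.DataFrame                # per signal-target TRS / total fid / spe
    signal_set: ccc.SignalSet
    targets: list[str]
    train_log: hgnn.TrainLog
    state: hgnn.EmbeddingState
    config: RunConfig
    receiver: str

    def summary(self) -> str:
        lines = [
            "Crosstalk pathway inference results",
            "=" * 43,
            f"receiver cluster:        {self.receiver}",
            f"signals (receptors):     {len(self.signal_set.receptors)}",
            f"scored triples:          {len(self.pathways)}",
            f"hyperedges (prior):      {int((self.pathways['S_H'].rank(ascending=False) <= max(1, len(self.pathways) * self.config.sh_top_frac)).sum())}",
            f"activated (PA > {self.config.pa_threshold:.2f}):  {len(self.activated)}",
            f"best validation loss:    {min(self.train_log.val_loss):.4f} "
            f"(epoch {self.train_log.best_epoch})",
            "",
            "Top pathways by PRS:",
        ]
        top = (self.activated.sort_values(["PRS", "Signal", "SSC", "Target"],
                                          ascending=[False, True, True, True])
               .head(10))
        lines.append(f"{'Signal':<12}{'SSC':<12}{'Target':<12}"
                     f"{'PA':>8}{'PRS':>10}{'Fid':>8}{'Spe':>8}")
        for r in top.itertuples(index=False):
            fid = getattr(r, "Fid_target_xmod", float("nan"))
            spe = getattr(r, "Spe_signal_xmod", float("nan"))
            lines.append(f"{r.Signal:<12}{r.SSC:<12}{r.Target:<12}"
                         f"{r.PA:>8.3f}{r.PRS:>10.4f}"
                         f"{fid:>8.3f}{spe:>8.3f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_pathway_table(self.pathways, out_dir / "pathways.tsv")
        self.totals.to_csv(out_dir / "signal_target_totals.tsv", sep="\t",
                           index=False, float_format="%.6g",
                           lineterminator="\n")
        self.config.to_file(out_dir / "config.txt")


@dataclass
class CrosstalkModel:
    """Crosstalk inference model for one receiver cluster.

    Parameters
    ----------
    expr
        Raw expression data (genes x cells with cluster labels).
    lr_db
        Ligand-receptor interaction records.
    priors
        Receptor->TF and TF->target prior edge tables.
    receiver
        Cluster receiving communication; its cells provide node features,
        targets and the PRS regressions.
    senders
        Sender clusters (default: every other cluster).
    user_targets
        Optional explicit target list overriding differential expression.
    config
        All tunable parameters and the master seed.
    """

    expr: ExpressionData
    lr_db: LRDatabase
    priors: PriorNetworks
    receiver: str
    senders: list[str] | None = None
    user_targets: list[str] | None = None
    config: RunConfig = field(default_factory=RunConfig)

    @classmethod
    def from_files(cls, expr_path: str | Path, annot_path: str | Path,
                   lr_path: str | Path, rt_path: str | Path,
                   tt_path: str | Path, receiver: str,
                   **kwargs) -> "CrosstalkModel":
        expr = read_expression(expr_path, annot_path)
        lr_db, priors = read_priors(lr_path, rt_path, tt_path)
        return cls(expr=expr, lr_db=lr_db, priors=priors, receiver=receiver,
                   **kwargs)

    def fit(self) -> CrosstalkResults:
        cfg = self.config
        data = preprocess.filter_cells_and_genes(self.expr)
        data = preprocess.normalize_and_scale(data)
        if self.receiver not in data.clusters:
            raise ValueError(
                f"receiver {self.receiver!r} was removed by filtering")

        scores = ccc.score_communication(data, self.lr_db, self.receiver,
                                         self.senders, cfg)
        signals = ccc.select_signals(scores, cfg.pvalue_cutoff,
                                     cfg.receptor_strength_frac)
        targets = preprocess.select_targets(data, self.receiver,
                                            self.user_targets)

        sscs = [t for t in self.priors.tfs if data.has_gene(t)]
        if not sscs:
            raise ValueError("no prior TF survives the expression filters")
        triples = hg.score_triples(signals, sscs, targets, self.priors, data,
                                   self.receiver, cfg.ppr_damping)
        graph = hg.binarize(triples, cfg.sh_top_frac)
        samples = hg.make_training_samples(
            triples, graph, cfg.spawn_rng("samples"))

        X = hgnn.node_features(graph, data, self.receiver, cfg)
        state, log = hgnn.train(graph, X, samples, cfg)

        all_triples = [tuple(r) for r in triples[["Signal", "SSC", "Target"]]
                       .itertuples(index=False)]
        triples = triples.assign(PA=state.predict_pa(all_triples))
        activated = hgnn.filter_activated(triples, cfg.pa_threshold)

        activated = prs.compute_prs_table(activated, data, self.receiver, cfg)
        activated = crosstalk.add_selectivity(activated)
        totals = crosstalk.pairwise_totals(activated)

        pathways = triples.merge(
            activated[["Signal", "SSC", "Target", "PRS",
                       "Fid_target_xmod", "Spe_signal_xmod"]],
            on=["Signal", "SSC", "Target"], how="left")
        logger.info("fit complete: %d scored, %d activated pathways",
                    len(pathways), len(activated))
        return CrosstalkResults(
            pathways=pathways, activated=activated, totals=totals,
            signal_set=signals, targets=targets, train_log=log, state=state,
            config=cfg, receiver=self.receiver)
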