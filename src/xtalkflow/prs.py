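"""Pathway regulatory strength (PRS) via Random-Forest permutation importance.

For an activated SSC-target pair, the per-cell activation strength
ACS = x_ssc * x_target (normalized layer) is regressed on the expression
of all signals whose activated pathways share that pair.  Each signal's
permutation importance (mean decrease in R^2 under feature shuffling,
negative values floored at zero) is its pathway regulatory strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .config import RunConfig
from .io import ExpressionData

logger = logging.getLogger("xtalkflow")

__all__ = ["ActivationProfile", "activation_strength", "fit_prs",
           "compute_prs_table"]

MIN_CELLS = 30


@dataclass
class ActivationProfile:
    ssc: str
    target: str
    acs_per_cell: np.ndarray


def activation_strength(expr: ExpressionData, ssc: str, target: str,
                        receiver: str | None = None) -> ActivationProfile:
    """Per-cell product of the SSC and target normalized expression."""
    for g in (ssc, target):
        if not expr.has_gene(g):
            raise KeyError(f"gene {g!r} absent from the expression matrix")
    layer = expr.layer("normalized")
    cols = (expr.cells_in(receiver) if receiver is not None
            else np.arange(expr.n_cells))
    acs = layer[expr.gene_index(ssc), cols] * layer[expr.gene_index(target), cols]
    return ActivationProfile(ssc, target, acs)


def fit_prs(profile: ActivationProfile, signal_exprs: pd.DataFrame,
            config: RunConfig | None = None,
            rng: np.random.Generator | None = None) -> dict[str, float]:
    """Permutation importance of each signal in predicting the ACS.

    ``signal_exprs`` is a cells x signals table.  Returns a signal -> PRS
    mapping; a constant ACS yields all-zero importances with a warning.
    """
    config = config or RunConfig()
    if signal_exprs.shape[1] < 1:
        raise ValueError("at least one signal column required")
    if signal_exprs.shape[0] != profile.acs_per_cell.size:
        raise ValueError("signal matrix and ACS profile disagree on cell count")
    if signal_exprs.shape[0] < MIN_CELLS:
        logger.warning("only %d cells for the PRS regression (>= %d advised)",
                       signal_exprs.shape[0], MIN_CELLS)
    y = profile.acs_per_cell
    if np.ptp(y) == 0:
        logger.warning("constant ACS for (%s, %s); PRS set to 0",
                       profile.ssc, profile.target)
        return {s: 0.0 for s in signal_exprs.columns}

    rng = rng or np.random.default_rng(config.stage_seed("prs"))
    rf_seed = int(rng.integers(2**31))
    perm_seed = int(rng.integers(2**31))
    model = RandomForestRegressor(
        n_estimators=config.rf_trees, max_features="sqrt",
        random_state=rf_seed, n_jobs=1)
    X = signal_exprs.to_numpy(dtype=float)
    model.fit(X, y)
    imp = permutation_importance(
        model, X, y, n_repeats=config.rf_perm_repeats,
        random_state=perm_seed, scoring="r2", n_jobs=1)
    return {s: float(max(v, 0.0))
            for s, v in zip(signal_exprs.columns, imp.importances_mean)}


def compute_prs_table(activated: pd.DataFrame, expr: ExpressionData,
                      receiver: str,
                      config: RunConfig | None = None) -> pd.DataFrame:
    """PRS for every activated pathway, grouped by (SSC, target) pair.

    The signal roster of each regression is exactly the signals of the
    activated pathways sharing that pair.  Multi-subunit signal expression
    is the geometric mean of subunit rows.
    """
    config = config or RunConfig()
    if activated.empty:
        return activated.assign(PRS=pd.Series(dtype=float))
    layer = expr.layer("normalized")
    cols = expr.cells_in(receiver)
    rng = config.spawn_rng("prs")

    def signal_vector(name: str) -> np.ndarray | None:
        parts = name.split("_") if not expr.has_gene(name) else [name]
        rows = [expr.gene_index(p) for p in parts if expr.has_gene(p)]
        if not rows:
            return None
        return np.exp(np.mean(np.log1p(layer[rows][:, cols]), axis=0)) - 1.0

    records = []
    for (ssc, target), group in activated.groupby(["SSC", "Target"], sort=True):
        profile = ActivationProfile(
            ssc, target,
            layer[expr.gene_index(ssc), cols] * layer[expr.gene_index(target), cols])
        sig_cols = {}
        for s in sorted(group["Signal"].unique()):
            v = signal_vector(s)
            if v is None:
                logger.warning("signal %r has no expressed subunit; PRS 0", s)
            else:
                sig_cols[s] = v
        prs = (fit_prs(profile, pd.DataFrame(sig_cols), config, rng)
               if sig_cols else {})
        for s in group["Signal"].unique():
            records.append((s, ssc, target, prs.get(s, 0.0)))
    prs_df = pd.DataFrame(records, columns=["Signal", "SSC", "Target", "PRS"])
    return activated.merge(prs_df, on=["Signal", "SSC", "Target"], how="left")
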