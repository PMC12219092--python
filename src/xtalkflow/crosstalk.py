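"""Crosstalk modules, fidelity/specificity, TRS, ACI and receiver subclustering.

Pathways sharing a component form a crosstalk module (Xmod): Signal-Xmod,
SSC-Xmod, Target-Xmod, or a compound module sharing two components.
Fidelity is a pathway's PRS share within its Target-Xmod; specificity its
share within its Signal-Xmod; both therefore sum to one per module.  The
total regulatory strength (TRS) of a signal-target pair sums PRS over
SSC routes, with total fidelity/specificity as the corresponding shares.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import ExpressionData

logger = logging.getLogger("xtalkflow")

__all__ = ["add_selectivity", "fidelity", "specificity", "trs_and_totals",
           "compound_selectivity", "activation_index", "subcluster_receivers"]


def _share(prs_table: pd.DataFrame, by: list[str]) -> pd.Series:
    """PRS share within groups; NaN where the group's PRS sum is zero."""
    sums = prs_table.groupby(by)["PRS"].transform("sum")
    return prs_table["PRS"].where(sums > 0).div(sums.where(sums > 0))


def add_selectivity(prs_table: pd.DataFrame) -> pd.DataFrame:
    """Append fidelity (Target-Xmod share) and specificity (Signal-Xmod
    share) columns; zero-sum modules yield missing values with a log note."""
    out = prs_table.copy()
    out["Fid_target_xmod"] = _share(out, ["Target"])
    out["Spe_signal_xmod"] = _share(out, ["Signal"])
    n_missing = int(out["Fid_target_xmod"].isna().sum()
                    + out["Spe_signal_xmod"].isna().sum())
    if n_missing:
        logger.info("%d selectivity values undefined (zero-sum modules)",
                    n_missing)
    return out


def fidelity(prs_table: pd.DataFrame, pathway: tuple[str, str, str]) -> float:
    """PRS share of one pathway within its Target-Xmod (NaN if undefined)."""
    return _single_share(prs_table, pathway, group_col="Target")


def specificity(prs_table: pd.DataFrame, pathway: tuple[str, str, str]) -> float:
    """PRS share of one pathway within its Signal-Xmod (NaN if undefined)."""
    return _single_share(prs_table, pathway, group_col="Signal")


def _single_share(prs_table: pd.DataFrame, pathway: tuple[str, str, str],
                  group_col: str) -> float:
    s, c, t = pathway
    row = prs_table[(prs_table["Signal"] == s) & (prs_table["SSC"] == c)
                    & (prs_table["Target"] == t)]
    if row.empty:
        raise KeyError(f"pathway {pathway} not in the PRS table")
    anchor = {"Target": t, "Signal": s}[group_col]
    denom = prs_table.loc[prs_table[group_col] == anchor, "PRS"].sum()
    if denom <= 0:
        return float("nan")
    return float(row["PRS"].iloc[0] / denom)


def trs_and_totals(prs_table: pd.DataFrame, signal: str,
                   target: str) -> tuple[float, float, float]:
    """(TRS, total fidelity, total specificity) of a signal-target pair.

    TRS sums PRS over SSC routes; total fidelity normalizes over signals
    reaching the target, total specificity over targets of the signal.
    Zero denominators yield NaN.
    """
    pair = prs_table[(prs_table["Signal"] == signal)
                     & (prs_table["Target"] == target)]
    trs = float(pair["PRS"].sum())
    fid_denom = float(prs_table.loc[prs_table["Target"] == target, "PRS"].sum())
    spe_denom = float(prs_table.loc[prs_table["Signal"] == signal, "PRS"].sum())
    total_fid = trs / fid_denom if fid_denom > 0 else float("nan")
    total_spe = trs / spe_denom if spe_denom > 0 else float("nan")
    return trs, total_fid, total_spe


def pairwise_totals(prs_table: pd.DataFrame) -> pd.DataFrame:
    """TRS and total fidelity/specificity for every signal-target pair."""
    trs = (prs_table.groupby(["Signal", "Target"], as_index=False)["PRS"]
           .sum().rename(columns={"PRS": "TRS"}))
    by_target = trs.groupby("Target")["TRS"].transform("sum")
    by_signal = trs.groupby("Signal")["TRS"].transform("sum")
    trs["total_fid"] = trs["TRS"].where(by_target > 0).div(by_target.where(by_target > 0))
    trs["total_spe"] = trs["TRS"].where(by_signal > 0).div(by_signal.where(by_signal > 0))
    return trs


def compound_selectivity(prs_table: pd.DataFrame,
                         shared: tuple[str, str]) -> pd.Series:
    """PRS shares within a compound module sharing two components.

    ``shared`` is either ("Signal", "SSC") or ("SSC", "Target"); the
    returned Series is indexed like the table rows of each module and sums
    to one per module (NaN in zero-sum modules).
    """
    allowed = {("Signal", "SSC"), ("SSC", "Target")}
    if tuple(shared) not in allowed:
        raise ValueError(f"shared must be one of {sorted(allowed)}")
    return _share(prs_table, list(shared))


def activation_index(expr: ExpressionData, signal: str, ssc: str,
                     cell: str, k_h: float = 0.5) -> float:
    """Hill-saturated per-cell product of a signal-SSC pair: xy/(K_h + xy)."""
    layer = expr.layer("normalized")
    j = expr.cell_ids.index(cell) if isinstance(cell, str) else int(cell)
    x = layer[expr.gene_index(signal), j]
    y = layer[expr.gene_index(ssc), j]
    return float(x * y / (k_h + x * y))


def subcluster_receivers(expr: ExpressionData, receiver: str, signal: str,
                         totals: pd.DataFrame, seed: int = 0,
                         n_markers: int = 10) -> pd.Series:
    """Binary weighted k-means split of receiver cells by the signal's most
    specific targets.

    The top ``n_markers`` targets by total specificity serve as markers,
    each weighted proportionally to its specificity (weights normalized to
    sum one); k-means runs on marker expression scaled by sqrt(weight),
    which realizes the weighted squared-error objective.  The cluster with
    the higher weighted mean marker expression is labelled ``interacted``.
    """
    cols = expr.cells_in(receiver)
    if cols.size < 2:
        raise ValueError("receiver cluster needs at least 2 cells")
    cand = (totals[(totals["Signal"] == signal) & totals["total_spe"].notna()]
            .sort_values(["total_spe", "Target"], ascending=[False, True]))
    cand = cand[cand["Target"].map(expr.has_gene)]
    if cand.empty:
        raise ValueError(f"no targets with defined specificity for {signal!r}")
    if len(cand) < n_markers:
        logger.warning("only %d specific targets available (wanted %d)",
                       len(cand), n_markers)
    markers = cand["Target"].head(n_markers).tolist()
    w = cand["total_spe"].head(n_markers).to_numpy(dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()

    layer = expr.layer("normalized")
    M = np.stack([layer[expr.gene_index(g), cols] for g in markers], axis=1)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(M * np.sqrt(w))
    means = [float(np.average(M[raw_labels == k].mean(axis=0), weights=w))
             for k in (0, 1)]
    interacted = int(np.argmax(means))
    cells = [expr.cell_ids[j] for j in cols]
    return pd.Series(
        ["interacted" if l == interacted else "not-interacted"
         for l in raw_labels],
        index=cells, name=f"{signal}_interaction")
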