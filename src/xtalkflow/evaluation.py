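"""Shared-component evaluation: coverage, Fisher's exact and chi-square
tests over predicted versus reference shared-TF gene lists."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("xtalkflow")

__all__ = ["coverage", "fisher_exact_two_sided", "point_probability",
           "chi_square_test", "shared_tf_lists", "contingency_from_sets"]


def coverage(predicted: set[str], truth: set[str]) -> float:
    """|predicted & truth| / |truth|; NaN for an empty truth set."""
    if not truth:
        logger.warning("empty reference set; coverage undefined")
        return float("nan")
    return len(set(predicted) & set(truth)) / len(truth)


def contingency_from_sets(predicted: set[str], truth: set[str],
                          universe: int | None = None) -> tuple[int, int, int, int]:
    """2x2 counts (a, b, c, d) from two gene sets.

    a = shared, b = predicted only, c = truth only, d = the remainder of a
    universe of size n (default: the union size, giving d = 0).
    """
    predicted, truth = set(predicted), set(truth)
    a = len(predicted & truth)
    b = len(predicted) - a
    c = len(truth) - a
    n = len(predicted | truth) if universe is None else universe
    d = n - a - b - c
    if d < 0:
        raise ValueError("universe smaller than the union of the two sets")
    return a, b, c, d


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: total hypergeometric mass of tables (same
    margins) no more probable than the observed one.  All-zero -> 1."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


def point_probability(a: int, b: int, c: int, d: int) -> float:
    """Hypergeometric probability of the observed table itself (the
    single-table quantity, not a two-sided sum)."""
    n = a + b + c + d
    return float(stats.hypergeom.pmf(a, n, a + b, a + c))


def chi_square_test(observed: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df.

    Returns (statistic, p-value); a zero margin makes both NaN.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        logger.warning("zero margin; chi-square undefined")
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def shared_tf_lists(pathway_table: pd.DataFrame,
                    receptor_pair: tuple[str, str],
                    pa_threshold: float = 0.75) -> set[str]:
    """TFs on activated pathways downstream of BOTH receptors of a pair.

    Activated means PA strictly above the threshold.  A receptor with no
    activated pathways yields an empty set with a warning.
    """
    act = pathway_table[pathway_table["PA"] > pa_threshold]
    sets = []
    for r in receptor_pair:
        tfs = set(act.loc[act["Signal"] == r, "SSC"])
        if not tfs:
            logger.warning("receptor %r has no activated pathways", r)
        sets.append(tfs)
    return sets[0] & sets[1]
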