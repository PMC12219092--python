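"""Prior regulatory hypergraph construction.

Every candidate (signal, SSC, target) triple is scored by

    S_H = | PPR(signal -> SSC) * Spearman(SSC, target) |,

where PPR is personalized PageRank on the directed receptor->TF prior
graph seeded at the signal, and the rank correlation is computed over the
receiver cells.  The top fraction of triples by S_H (10% by default)
become the hyperedges of a 3-uniform hypergraph; the remainder supply
negative training material.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats

from .ccc import SignalSet
from .io import ExpressionData, PriorNetworks

logger = logging.getLogger("xtalkflow")

__all__ = ["Hypergraph", "TrainingSamples", "personalized_pagerank",
           "spearman_cor", "score_triples", "binarize",
           "make_training_samples", "build_hypergraph_from_triples"]

PPR_TOL = 1e-12


@dataclass
class Hypergraph:
    """A 3-uniform hypergraph over genes with role tags.

    ``edges`` holds (signal, SSC, target) name triples; ``H`` is the
    node x hyperedge incidence matrix.  Node roles may overlap (a gene can
    be both SSC and target).
    """

    node_names: list[str]
    roles: dict[str, set[str]]
    edges: list[tuple[str, str, str]]
    H: scipy.sparse.csr_matrix

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.node_names)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, gene: str) -> int:
        return self._index[gene]

    @property
    def node_degrees(self) -> np.ndarray:
        return np.asarray(self.H.sum(axis=1)).ravel()

    @property
    def edge_degrees(self) -> np.ndarray:
        return np.asarray(self.H.sum(axis=0)).ravel()

    def nodes_with_role(self, role: str) -> list[str]:
        return [g for g in self.node_names if role in self.roles.get(g, set())]


@dataclass
class TrainingSamples:
    """Class-balanced labelled triples with a train/validation partition."""

    triples: list[tuple[str, str, str]]
    labels: np.ndarray          # 1 = hyperedge, 0 = negative
    is_train: np.ndarray        # boolean mask

    def __len__(self) -> int:
        return len(self.triples)


# ---------------------------------------------------------------------------
# scoring primitives


def personalized_pagerank(edges: pd.DataFrame, seed_gene: str,
                          damping: float = 0.85) -> dict[str, float]:
    """Personalized PageRank with restart at ``seed_gene`` on a directed
    weighted edge table.  Scores sum to 1; dangling mass returns to the
    seed; an absent seed yields an empty result with a warning."""
    G = nx.DiGraph()
    weights = edges["weight"] if "weight" in edges.columns else np.ones(len(edges))
    for u, v, w in zip(edges["from"], edges["to"], weights):
        G.add_edge(u, v, weight=abs(float(w)))
    G.add_nodes_from(edges["from"])
    G.add_nodes_from(edges["to"])
    if seed_gene not in G:
        logger.warning("PPR seed %r absent from the prior graph", seed_gene)
        return {}
    personalization = {seed_gene: 1.0}
    scores = nx.pagerank(G, alpha=damping, personalization=personalization,
                         dangling=personalization, weight="weight",
                         tol=PPR_TOL, max_iter=10_000)
    return dict(scores)


def spearman_cor(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties; a
    zero-variance vector yields 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must share a length of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance vector in rank correlation; returning 0")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


# ---------------------------------------------------------------------------
# triple scoring and binarization


def score_triples(signals: SignalSet | list[str], sscs: list[str],
                  targets: list[str], priors: PriorNetworks,
                  expr: ExpressionData, receiver: str,
                  damping: float = 0.85) -> pd.DataFrame:
    """Score every candidate triple; zero-scoring triples are omitted.

    Returns a DataFrame with columns Signal, SSC, Target, S_H sorted
    lexicographically.  The rank correlation uses the normalized layer
    restricted to receiver cells (ranks are invariant to the monotone
    per-gene scaling, so the scaled layer would give identical values).
    """
    receptor_list = signals.receptors if isinstance(signals, SignalSet) else signals
    layer = expr.layer("normalized")
    cols = expr.cells_in(receiver)
    if cols.size < 3:
        raise ValueError("receiver cluster has fewer than 3 cells")

    # rank-correlate every (ssc, target) pair at once on ranked rows
    genes_needed = [g for g in set(sscs) | set(targets) if expr.has_gene(g)]
    ranked = {g: stats.rankdata(layer[expr.gene_index(g), cols])
              for g in genes_needed}

    def cor(a: str, b: str) -> float:
        ra, rb = ranked[a], ranked[b]
        if np.ptp(ra) == 0 or np.ptp(rb) == 0:
            return 0.0
        return float(np.corrcoef(ra, rb)[0, 1])

    rows = []
    for sig in receptor_list:
        ppr = _seed_ppr(priors.receptor_tf_edges, sig, damping)
        if not ppr:
            continue
        for ssc in sscs:
            p = ppr.get(ssc, 0.0)
            if p <= 0 or ssc not in ranked:
                continue
            for tgt in targets:
                if tgt == ssc or tgt not in ranked:
                    continue
                s_h = abs(p * cor(ssc, tgt))
                if s_h > 0:
                    rows.append((sig, ssc, tgt, s_h))
    if not rows:
        raise ValueError("no positive-scoring (signal, SSC, target) triple")
    df = pd.DataFrame(rows, columns=["Signal", "SSC", "Target", "S_H"])
    return df.sort_values(["Signal", "SSC", "Target"], ignore_index=True)


def _seed_ppr(edges: pd.DataFrame, signal: str,
              damping: float) -> dict[str, float]:
    """PPR from a signal; a multi-subunit receptor absent from the graph is
    averaged over the subunits that are present."""
    node_set = set(edges["from"]) | set(edges["to"])
    if signal in node_set:
        return personalized_pagerank(edges, signal, damping)
    if "_" in signal:
        parts = [p for p in signal.split("_") if p in node_set]
        if parts:
            acc: dict[str, float] = {}
            for p in parts:
                for g, v in personalized_pagerank(edges, p, damping).items():
                    acc[g] = acc.get(g, 0.0) + v / len(parts)
            return acc
    logger.warning("signal %r not in the receptor-TF prior graph", signal)
    return {}


def binarize(triples: pd.DataFrame, top_frac: float = 0.10) -> Hypergraph:
    """Keep the top fraction of triples by S_H as hyperedges.

    Exactly ``ceil(top_frac * N)`` triples become hyperedges; ties at the
    threshold are broken by lexicographic (Signal, SSC, Target) order and
    truncated.  Fewer than 10 scored triples promote everything, with a
    warning.
    """
    n = len(triples)
    if n < 10:
        logger.warning("only %d scored triples; all become hyperedges", n)
        n_keep = n
    else:
        n_keep = int(np.ceil(top_frac * n))
    df = triples.sort_values(
        ["S_H", "Signal", "SSC", "Target"],
        ascending=[False, True, True, True], kind="stable",
        ignore_index=True)
    kept = df.iloc[:n_keep]
    edges = [tuple(r) for r in kept[["Signal", "SSC", "Target"]].itertuples(index=False)]
    return build_hypergraph_from_triples(
        edges,
        signals=sorted(set(triples["Signal"])),
        sscs=sorted(set(triples["SSC"])),
        targets=sorted(set(triples["Target"])),
    )


def build_hypergraph_from_triples(edges: list[tuple[str, str, str]],
                                  signals: list[str], sscs: list[str],
                                  targets: list[str]) -> Hypergraph:
    """Assemble incidence structure from explicit hyperedge triples.

    The node roster is the union of the role lists, so genes that end up in
    no hyperedge are still nodes (they receive pass-through features in the
    convolution).
    """
    roles: dict[str, set[str]] = {}
    for g in signals:
        roles.setdefault(g, set()).add("signal")
    for g in sscs:
        roles.setdefault(g, set()).add("ssc")
    for g in targets:
        roles.setdefault(g, set()).add("target")
    node_names = sorted(roles)
    index = {g: i for i, g in enumerate(node_names)}
    rows, cols = [], []
    for q, (s, c, t) in enumerate(edges):
        for g in (s, c, t):
            rows.append(index[g])
            cols.append(q)
    H = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(node_names), len(edges)))
    # a node may appear twice in a conceptual triple if roles overlap;
    # incidence entries are clipped to {0, 1}
    H.data = np.minimum(H.data, 1.0)
    return Hypergraph(node_names=node_names, roles=roles, edges=list(edges), H=H)


# ---------------------------------------------------------------------------
# training samples


def make_training_samples(triples: pd.DataFrame, hypergraph: Hypergraph,
                          rng: np.random.Generator,
                          train_frac: float = 0.8,
                          hard_negative_frac: float = 0.5) -> TrainingSamples:
    """Positive samples are the hyperedges; an equal number of negatives is
    drawn half from the lowest-scoring non-hyperedge triples and half from
    role-respecting random triples absent from the scored set.  A seeded
    class-balanced split assigns ``train_frac`` of each class to training.
    """
    positives = list(hypergraph.edges)
    pos_set = set(positives)
    n_pos = len(positives)
    if n_pos == 0:
        raise ValueError("hypergraph has no hyperedges")

    scored = triples.sort_values(
        ["S_H", "Signal", "SSC", "Target"],
        ascending=[True, True, True, True], kind="stable")
    low = [t for t in scored[["Signal", "SSC", "Target"]]
           .itertuples(index=False, name=None) if t not in pos_set]
    n_hard = min(int(round(n_pos * hard_negative_frac)), len(low))
    hard_negatives = low[:n_hard]

    scored_set = pos_set | set(
        triples[["Signal", "SSC", "Target"]].itertuples(index=False, name=None))
    n_random = n_pos - n_hard
    random_negatives = _sample_random_triples(
        hypergraph, scored_set | set(hard_negatives), n_random, rng)
    negatives = hard_negatives + random_negatives
    if len(negatives) < n_pos:
        logger.warning("insufficient distinct negatives; sampling with replacement")
        extra = rng.choice(len(negatives), size=n_pos - len(negatives))
        negatives = negatives + [negatives[i] for i in extra]

    all_triples = positives + negatives
    labels = np.array([1] * n_pos + [0] * len(negatives))
    is_train = np.zeros(len(all_triples), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        is_train[perm[:n_train]] = True
    return TrainingSamples(all_triples, labels, is_train)


def _sample_random_triples(hypergraph: Hypergraph, forbidden: set,
                           n: int, rng: np.random.Generator,
                           max_tries: int = 50) -> list[tuple[str, str, str]]:
    signals = hypergraph.nodes_with_role("signal")
    sscs = hypergraph.nodes_with_role("ssc")
    targets = hypergraph.nodes_with_role("target")
    out: list[tuple[str, str, str]] = []
    seen = set(forbidden)
    for _ in range(max_tries):
        if len(out) >= n:
            break
        k = max(n - len(out), 1)
        cand = zip(rng.choice(signals, size=k), rng.choice(sscs, size=k),
                   rng.choice(targets, size=k))
        for t in cand:
            t = (str(t[0]), str(t[1]), str(t[2]))
            if t[1] != t[2] and t not in seen:
                seen.add(t)
                out.append(t)
                if len(out) >= n:
                    break
    return out
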