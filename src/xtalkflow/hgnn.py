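"""Hypergraph representation learning for pathway-activity prediction.

Two hypergraph convolution layers embed gene nodes by mean aggregation
node -> hyperedge -> node,

    Z^{k+1} = ELU( D_v^{-1} H D_e^{-1} H^T Z^k Theta^k ),

followed by an independent two-layer MLP head per role (signal, SSC,
target).  The activity of a candidate pathway (v_s, v_c, v_t) is

    PA = | cos(y_s, y_c) * cos(y_c, y_t) |  in [0, 1],

trained against binary hyperedge labels with a clamped binary
cross-entropy, Adam updates and an exponentially decaying learning rate.
The whole network, including backpropagation, is implemented in NumPy;
an optional ``raw_de`` flag replaces D_e^{-1} with D_e (sum instead of
mean aggregation over hyperedge members).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .hypergraph import Hypergraph, TrainingSamples
from .io import ExpressionData

logger = logging.getLogger("xtalkflow")

__all__ = ["EmbeddingState", "TrainLog", "hgnn_conv", "role_head",
           "pathway_activity", "train", "filter_activated", "node_features"]

EPS = 1e-7
ROLES = ("signal", "ssc", "target")


# ---------------------------------------------------------------------------
# activations


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# spec operations (stand-alone, used by the trainer below)


def aggregation_matrix(H: np.ndarray, raw_de: bool = False) -> np.ndarray:
    """Node-to-node propagation matrix D_v^{-1} H D_e^{+/-1} H^T.

    Zero-degree nodes get an identity row so their transformed features
    pass through the layer unchanged.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ValueError("incidence must be 2-D")
    dv = H.sum(axis=1)
    de = H.sum(axis=0)
    de_scale = de if raw_de else np.divide(1.0, de, out=np.zeros_like(de),
                                           where=de > 0)
    inner = (H * de_scale) @ H.T
    dv_inv = np.divide(1.0, dv, out=np.zeros_like(dv), where=dv > 0)
    A = dv_inv[:, None] * inner
    isolated = np.flatnonzero(dv == 0)
    A[isolated, isolated] = 1.0
    return A


def hgnn_conv(Z: np.ndarray, H: np.ndarray, theta: np.ndarray,
              raw_de: bool = False) -> np.ndarray:
    """One hypergraph convolution: ELU(D_v^-1 H D_e^-1 H^T Z Theta)."""
    Z = np.asarray(Z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if Z.shape[1] != theta.shape[0]:
        raise ValueError(
            f"feature dim {Z.shape[1]} does not match theta rows {theta.shape[0]}")
    return _elu(aggregation_matrix(H, raw_de) @ Z @ theta)


def role_head(z: np.ndarray, W1: np.ndarray, b1: np.ndarray,
              W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Two-layer MLP head: ReLU(W2^T ELU(W1^T z + b1) + b2)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    out = _relu(_elu(z @ W1 + b1) @ W2 + b2)
    return out[0] if out.shape[0] == 1 else out


def pathway_activity(y_s: np.ndarray, y_c: np.ndarray,
                     y_t: np.ndarray) -> float:
    """PA = |cos(y_s, y_c) * cos(y_c, y_t)|; a zero-norm embedding gives 0."""
    ns, nc, nt = (np.linalg.norm(v) for v in (y_s, y_c, y_t))
    if ns == 0 or nc == 0 or nt == 0:
        return 0.0
    c1 = float(np.dot(y_s, y_c) / (ns * nc))
    c2 = float(np.dot(y_c, y_t) / (nc * nt))
    return abs(c1 * c2)


# ---------------------------------------------------------------------------
# trainable state


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class EmbeddingState:
    """Trained network parameters bound to a hypergraph and node features."""

    hypergraph: Hypergraph
    A: np.ndarray                     # propagation matrix, fixed
    X: np.ndarray                     # node features, fixed
    params: dict[str, np.ndarray]

    def forward(self) -> dict[str, np.ndarray]:
        """Full forward pass; returns all cached pre/post activations."""
        p = self.params
        AX = self.A @ self.X
        P1 = AX @ p["theta1"]
        Z2 = _elu(P1)
        AZ2 = self.A @ Z2
        P2 = AZ2 @ p["theta2"]
        Z3 = _elu(P2)
        cache = {"AX": AX, "P1": P1, "Z2": Z2, "AZ2": AZ2, "P2": P2, "Z3": Z3}
        for r in ROLES:
            Q = Z3 @ p[f"{r}_W1"] + p[f"{r}_b1"]
            U = _elu(Q)
            V = U @ p[f"{r}_W2"] + p[f"{r}_b2"]
            cache[f"{r}_Q"], cache[f"{r}_U"] = Q, U
            cache[f"{r}_V"], cache[f"{r}_Y"] = V, _relu(V)
        return cache

    def embeddings(self) -> dict[str, np.ndarray]:
        cache = self.forward()
        return {r: cache[f"{r}_Y"] for r in ROLES}

    def predict_pa(self, triples: list[tuple[str, str, str]]) -> np.ndarray:
        """PA scores for (signal, SSC, target) name triples."""
        Y = self.embeddings()
        idx = self.hypergraph.node_index
        I = np.array([idx(t[0]) for t in triples])
        J = np.array([idx(t[1]) for t in triples])
        K = np.array([idx(t[2]) for t in triples])
        c1 = _cosine_rows(Y["signal"][I], Y["ssc"][J])[0]
        c2 = _cosine_rows(Y["ssc"][J], Y["target"][K])[0]
        return np.abs(c1 * c2)


def _cosine_rows(X: np.ndarray, Y: np.ndarray):
    nx_ = np.linalg.norm(X, axis=1)
    ny_ = np.linalg.norm(Y, axis=1)
    denom = nx_ * ny_
    safe = denom > 0
    c = np.zeros(X.shape[0])
    c[safe] = np.einsum("ij,ij->i", X[safe], Y[safe]) / denom[safe]
    return c, nx_, ny_, safe


def _cos_grads(X, Y, c, nx_, ny_, safe):
    """d cos(x,y)/dx and /dy, row-wise, zero where a norm vanishes."""
    gX = np.zeros_like(X)
    gY = np.zeros_like(Y)
    d = (nx_ * ny_)[safe, None]
    gX[safe] = Y[safe] / d - c[safe, None] * X[safe] / (nx_[safe, None] ** 2)
    gY[safe] = X[safe] / d - c[safe, None] * Y[safe] / (ny_[safe, None] ** 2)
    return gX, gY


# ---------------------------------------------------------------------------
# loss + gradients


def _batch_loss_and_grads(state: EmbeddingState, cache: dict,
                          I: np.ndarray, J: np.ndarray, K: np.ndarray,
                          labels: np.ndarray,
                          compute_grads: bool = True):
    p = state.params
    Ys, Yc, Yt = cache["signal_Y"], cache["ssc_Y"], cache["target_Y"]
    ys, yc, yt = Ys[I], Yc[J], Yt[K]
    c1, ns, nc1, safe1 = _cosine_rows(ys, yc)
    c2, nc2, nt, safe2 = _cosine_rows(yc, yt)
    pa = np.abs(c1 * c2)
    pac = np.clip(pa, EPS, 1.0 - EPS)
    B = labels.size
    loss = float(-np.mean(labels * np.log(pac) + (1 - labels) * np.log(1 - pac)))
    if not compute_grads:
        return loss, None

    dpa = (pac - labels) / (pac * (1.0 - pac)) / B
    sign = np.sign(c1 * c2)
    dc1 = dpa * sign * c2
    dc2 = dpa * sign * c1
    g1s, g1c = _cos_grads(ys, yc, c1, ns, nc1, safe1)
    g2c, g2t = _cos_grads(yc, yt, c2, nc2, nt, safe2)

    dYs = np.zeros_like(Ys)
    dYc = np.zeros_like(Yc)
    dYt = np.zeros_like(Yt)
    np.add.at(dYs, I, dc1[:, None] * g1s)
    np.add.at(dYc, J, dc1[:, None] * g1c + dc2[:, None] * g2c)
    np.add.at(dYt, K, dc2[:, None] * g2t)

    grads: dict[str, np.ndarray] = {}
    Z3 = cache["Z3"]
    dZ3 = np.zeros_like(Z3)
    for r, dY in zip(ROLES, (dYs, dYc, dYt)):
        dV = dY * (cache[f"{r}_V"] > 0)
        grads[f"{r}_W2"] = cache[f"{r}_U"].T @ dV
        grads[f"{r}_b2"] = dV.sum(axis=0)
        dU = dV @ p[f"{r}_W2"].T
        dQ = dU * _elu_grad(cache[f"{r}_Q"])
        grads[f"{r}_W1"] = Z3.T @ dQ
        grads[f"{r}_b1"] = dQ.sum(axis=0)
        dZ3 += dQ @ p[f"{r}_W1"].T

    dP2 = dZ3 * _elu_grad(cache["P2"])
    grads["theta2"] = cache["AZ2"].T @ dP2
    dZ2 = state.A.T @ (dP2 @ p["theta2"].T)
    dP1 = dZ2 * _elu_grad(cache["P1"])
    grads["theta1"] = cache["AX"].T @ dP1
    return loss, grads


# ---------------------------------------------------------------------------
# training


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _init_params(rng: np.random.Generator, n_features: int,
                 config: RunConfig) -> dict[str, np.ndarray]:
    d1, d2 = config.embed_dims
    h1, h2 = config.head_dims
    params = {
        "theta1": _glorot(rng, n_features, d1),
        "theta2": _glorot(rng, d1, d2),
    }
    for r in ROLES:
        params[f"{r}_W1"] = _glorot(rng, d2, h1)
        params[f"{r}_b1"] = np.zeros(h1)
        params[f"{r}_W2"] = _glorot(rng, h1, h2)
        params[f"{r}_b2"] = np.zeros(h2)
    return params


def node_features(hypergraph: Hypergraph, expr: ExpressionData, receiver: str,
                  config: RunConfig) -> np.ndarray:
    """Node feature matrix: each gene node's scaled (z-scored) expression
    across receiver cells; genes absent from the matrix get zero rows;
    cells are subsampled (seeded) to bound the feature width.

    The scaled layer is used because the raw-normalized layer's strictly
    non-negative, library-size-dominated rows make the initial role-head
    embeddings nearly collinear, which parks the cosine-product activity
    score at an uninformative saddle early in training; z-scoring spreads
    the initial cosines and training descends immediately.
    """
    layer = expr.layer("scaled")
    cols = expr.cells_in(receiver)
    if cols.size > config.max_feature_cells:
        rng = config.spawn_rng("feature-subsample")
        cols = np.sort(rng.choice(cols, size=config.max_feature_cells,
                                  replace=False))
    X = np.zeros((hypergraph.n_nodes, cols.size))
    for i, g in enumerate(hypergraph.node_names):
        if expr.has_gene(g):
            X[i] = layer[expr.gene_index(g), cols]
    return X


def train(hypergraph: Hypergraph, features: np.ndarray,
          samples: TrainingSamples,
          config: RunConfig | None = None) -> tuple[EmbeddingState, TrainLog]:
    """Fit the network on labelled triples; returns the best-validation state.

    Mini-batches are class-balanced by construction of the sample set;
    Adam with exponential learning-rate decay; early stopping on the
    validation loss with the configured patience.
    """
    config = config or RunConfig()
    rng_init = config.spawn_rng("hgnn-init")
    rng_batch = config.spawn_rng("hgnn-batches")
    A = aggregation_matrix(hypergraph.H.toarray(), raw_de=config.raw_de)
    state = EmbeddingState(hypergraph, A, np.asarray(features, dtype=float),
                           _init_params(rng_init, features.shape[1], config))

    idx = {True: np.flatnonzero(samples.is_train),
           False: np.flatnonzero(~samples.is_train)}
    node_idx = hypergraph.node_index
    I = np.array([node_idx(t[0]) for t in samples.triples])
    J = np.array([node_idx(t[1]) for t in samples.triples])
    K = np.array([node_idx(t[2]) for t in samples.triples])
    labels = samples.labels.astype(float)

    adam_m = {k: np.zeros_like(v) for k, v in state.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in state.params.items()}
    beta1, beta2, adam_eps, t = 0.9, 0.999, 1e-8, 0

    log = TrainLog()
    best_val = np.inf
    best_params = {k: v.copy() for k, v in state.params.items()}
    stall = 0

    for epoch in range(config.epochs):
        lr = config.learning_rate * config.scheduler_decay**epoch
        order = rng_batch.permutation(idx[True])
        epoch_losses = []
        for start in range(0, order.size, config.batch_size):
            batch = order[start:start + config.batch_size]
            cache = state.forward()
            loss, grads = _batch_loss_and_grads(
                state, cache, I[batch], J[batch], K[batch], labels[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            epoch_losses.append(loss)
            t += 1
            for k, g in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                m_hat = adam_m[k] / (1 - beta1**t)
                v_hat = adam_v[k] / (1 - beta2**t)
                state.params[k] -= lr * m_hat / (np.sqrt(v_hat) + adam_eps)

        cache = state.forward()
        vi = idx[False]
        val_loss, _ = _batch_loss_and_grads(
            state, cache, I[vi], J[vi], K[vi], labels[vi],
            compute_grads=False) if vi.size else (float(np.mean(epoch_losses)), None)
        log.train_loss.append(float(np.mean(epoch_losses)))
        log.val_loss.append(val_loss)
        log.learning_rate.append(lr)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in state.params.items()}
            log.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                logger.info("early stop at epoch %d (best %d)", epoch,
                            log.best_epoch)
                break

    state.params = best_params
    return state, log


def filter_activated(triples: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
    """Retain pathways with PA strictly above the threshold."""
    if triples.empty:
        return triples.copy()
    out = triples[triples["PA"] > threshold].reset_index(drop=True)
    if out.empty:
        logger.warning("no pathway exceeds PA > %.2f", threshold)
    return out
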