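"""Semi-supervised graph convolutional classifier.

Two graph-convolution layers followed by one dense softmax layer:

    H1  = ReLU(A_hat @ H0 @ W0)
    H2  = ReLU(A_hat @ H1 @ W1)
    Out = softmax(H2 @ W2)

with ``A_hat = D~^(-1/2) (G + I) D~^(-1/2)`` the symmetrically normalised
adjacency (self-loops added).  Training is transductive: every node —
labeled reference or unlabeled contig — participates in the forward
pass, but only labeled nodes contribute to the loss (squared error
between the softmax row and the one-hot label).  After training, the
parameters are frozen and unlabeled nodes take the argmax of their
softmax row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import KnowledgeGraph

__all__ = [
    "GCNModel",
    "Prediction",
    "normalize_adjacency",
    "gcn_forward",
    "train_gcn",
    "predict",
]


@dataclass
class GCNModel:
    w0: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    a_hat: np.ndarray
    class_names: list[str]
    history: list[float] = field(default_factory=list)

    @property
    def n_label(self) -> int:
        return self.w2.shape[1]


@dataclass(frozen=True)
class Prediction:
    seq_id: str
    label: str
    scores: np.ndarray | None  # probability vector over classes; None if rejected
    is_reference: bool = False
    tie: bool = False


def normalize_adjacency(G: np.ndarray, literal: bool = False) -> np.ndarray:
    """Normalised adjacency with self-loops.

    Default is the symmetric form ``D~^(-1/2) (G+I) D~^(-1/2)``; with
    ``literal=True`` the right-hand exponent is +1/2 instead (an
    alternative normalisation; the result is then similar to, but not
    equal to, the symmetric operator).
    """
    G = np.asarray(G, dtype=np.float64)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(G, G.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(G) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    gt = G + np.eye(len(G))
    deg = gt.sum(axis=1)
    d_neg = np.diag(deg ** -0.5)
    d_right = np.diag(deg ** (0.5 if literal else -0.5))
    return d_neg @ gt @ d_right


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_cache(a_hat: np.ndarray, h0: np.ndarray, model: GCNModel) -> dict[str, np.ndarray]:
    ah0 = a_hat @ h0
    h1 = np.maximum(ah0 @ model.w0, 0.0)
    ah1 = a_hat @ h1
    h2 = np.maximum(ah1 @ model.w1, 0.0)
    logits = h2 @ model.w2
    return {"ah0": ah0, "h1": h1, "ah1": ah1, "h2": h2, "probs": _softmax(logits)}


def gcn_forward(a_hat: np.ndarray, h0: np.ndarray, model: GCNModel) -> np.ndarray:
    """Per-node class probabilities for node features ``h0``."""
    a_hat = np.asarray(a_hat, dtype=np.float64)
    h0 = np.asarray(h0, dtype=np.float64)
    if a_hat.shape[0] != a_hat.shape[1] or a_hat.shape[0] != h0.shape[0]:
        raise ValueError("a_hat and features have inconsistent shapes")
    if h0.shape[1] != model.w0.shape[0]:
        raise ValueError("feature dimension does not match W0")
    return _forward_cache(a_hat, h0, model)["probs"]


class _Adam:
    def __init__(self, params, lr):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        c1, c2 = 1 - self.b1 ** self.t, 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def train_gcn(
    graph: KnowledgeGraph,
    hidden_dims: Sequence[int] = (128, 32),
    epochs: int = 200,
    lr: float = 1e-2,
    seed: int = 0,
    patience: int = 20,
    literal_normalization: bool = False,
    class_names: Sequence[str] | None = None,
    n_restarts: int = 3,
) -> GCNModel:
    """Fit the GCN on a knowledge graph (L2 loss on labeled nodes, Adam).

    Early-stops when the training loss has not improved for ``patience``
    epochs and restores the best parameters.  The squared error of a
    softmax has vanishing gradients once an unlucky initialisation
    saturates, so the fit is restarted ``n_restarts`` times from
    derived seeds and the run with the lowest training loss is kept.
    Deterministic per seed.
    """
    init_seeds = [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_restarts)]
    best = None
    for s in init_seeds:
        model = _train_gcn_once(
            graph,
            hidden_dims=hidden_dims,
            epochs=epochs,
            lr=lr,
            seed=s,
            patience=patience,
            literal_normalization=literal_normalization,
            class_names=class_names,
        )
        if best is None or min(model.history) < min(best.history):
            best = model
    return best


def _train_gcn_once(
    graph: KnowledgeGraph,
    hidden_dims: Sequence[int],
    epochs: int,
    lr: float,
    seed: int,
    patience: int,
    literal_normalization: bool,
    class_names: Sequence[str] | None,
) -> GCNModel:
    classes = sorted(class_names) if class_names is not None else graph.class_names
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    present = {l for l in graph.labels if l is not None}
    missing = sorted(set(classes) - present)
    if missing:
        raise ValueError(f"classes absent from labeled nodes: {missing}")

    labeled = np.array([l is not None for l in graph.labels])
    y = np.zeros((graph.n_nodes, len(classes)))
    for i, l in enumerate(graph.labels):
        if l is not None:
            y[i, classes.index(l)] = 1.0

    a_hat = normalize_adjacency(graph.adjacency, literal=literal_normalization)
    h0 = np.asarray(graph.features, dtype=np.float64)
    # scale features so layer activations start in a sane range
    scale = np.abs(h0).max()
    if scale > 0:
        h0 = h0 / scale

    rng = np.random.default_rng(seed)
    dims = [h0.shape[1], *hidden_dims, len(classes)]

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    model = GCNModel(
        w0=glorot(dims[0], dims[1]),
        w1=glorot(dims[1], dims[2]),
        w2=glorot(dims[2], dims[3]),
        a_hat=a_hat,
        class_names=list(classes),
    )
    params = [model.w0, model.w1, model.w2]
    opt = _Adam(params, lr)
    n_lab = int(labeled.sum())
    best_loss, best_params, since_best = np.inf, [p.copy() for p in params], 0

    for _ in range(epochs):
        cache = _forward_cache(a_hat, h0, model)
        probs = cache["probs"]
        diff = (probs - y) * labeled[:, None]
        loss = float(np.square(diff).sum() / n_lab)
        model.history.append(loss)

        dprobs = 2.0 * diff / n_lab
        # softmax Jacobian applied rowwise
        dlogits = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
        g_w2 = cache["h2"].T @ dlogits
        dh2 = (dlogits @ model.w2.T) * (cache["h2"] > 0)
        g_w1 = cache["ah1"].T @ dh2
        dh1 = (a_hat.T @ (dh2 @ model.w1.T)) * (cache["h1"] > 0)
        g_w0 = cache["ah0"].T @ dh1
        opt.step(params, [g_w0, g_w1, g_w2])

        if loss < best_loss - 1e-9:
            best_loss, since_best = loss, 0
            best_params = [p.copy() for p in params]
        else:
            since_best += 1
            if since_best >= patience:
                break
    model.w0, model.w1, model.w2 = best_params
    model._h0 = h0  # cached scaled features for prediction on this graph
    return model


def predict(graph: KnowledgeGraph, model: GCNModel) -> list[Prediction]:
    """Predictions for every sequence: references keep their label,
    in-graph contigs get the argmax family, rejected contigs are
    reported as ``unclassified``."""
    h0 = getattr(model, "_h0", None)
    if h0 is None or h0.shape[0] != graph.n_nodes:
        h0 = np.asarray(graph.features, dtype=np.float64)
        scale = np.abs(h0).max()
        if scale > 0:
            h0 = h0 / scale
    probs = gcn_forward(model.a_hat, h0, model)
    out: list[Prediction] = []
    for i, (sid, label) in enumerate(zip(graph.node_ids, graph.labels)):
        if label is not None:
            out.append(Prediction(sid, label, probs[i], is_reference=True))
        else:
            row = probs[i]
            best = row.max()
            ties = np.nonzero(row == best)[0]
            out.append(
                Prediction(
                    sid,
                    model.class_names[int(ties[0])],
                    row,
                    tie=len(ties) > 1,
                )
            )
    for sid in graph.rejected:
        out.append(Prediction(sid, "unclassified", None))
    return out
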