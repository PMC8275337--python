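"""Skip-gram 3-mer embedding and CNN node encoder.

A contig is cut into 2 kbp windows; each window becomes an embedded
matrix ``M`` (one 100-dimensional skip-gram vector per 3-mer position,
zero-padded to the window length), which a small CNN maps to a feature
vector.  In train mode the CNN ends in a softmax over families and is
fit with cross-entropy on labeled reference segments; in encoding mode
the ReLU output of the first dense layer (512 units by default) is the
node feature, averaged over a contig's windows so contigs of any length
map to vectors of the same size.

Implemented directly in numpy with explicit gradients: the architecture
is small and fixed (one convolution with positional max-pooling, two
dense layers, softmax), and the training sets are desk-scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import Contig, Segment, segment_contig

__all__ = [
    "KmerEmbedding",
    "CNNEncoder",
    "ContigTooShortError",
    "train_embedding",
    "embed_segment",
    "cnn_forward",
    "train_cnn",
    "encode_contig",
    "cnn_predict_contig",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ContigTooShortError(ValueError):
    """Contig shorter than one encoder window: no feature can be produced."""


def kmer_ids(seq: str, k: int = 3) -> np.ndarray:
    """Integer ids (base-4) of the k-mers of ``seq``; -1 marks k-mers
    containing anything outside {A, C, G, T}."""
    codes = np.array([_BASE_INDEX.get(ch, -1) for ch in seq], dtype=np.int64)
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    n = len(codes) - k + 1
    ids = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for off in range(k):
        seg = codes[off : off + n]
        ids = ids * 4 + np.maximum(seg, 0)
        ok &= seg >= 0
    ids[~ok] = -1
    return ids


@dataclass
class KmerEmbedding:
    """Skip-gram embedding table over the 4^k canonical k-mers."""

    k: int
    dim: int
    m: int
    table: np.ndarray  # (4^k, dim) float32

    def __post_init__(self) -> None:
        if self.table.shape != (4 ** self.k, self.dim):
            raise ValueError("embedding table shape mismatch")

    def lookup_table(self) -> np.ndarray:
        """Table with an extra all-zero row at index 4^k for unknown k-mers."""
        return np.vstack([self.table, np.zeros((1, self.dim), dtype=self.table.dtype)])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def train_embedding(
    corpus: Iterable[str],
    m: int = 2,
    dim: int = 100,
    seed: int = 0,
    k: int = 3,
    epochs: int = 3,
    lr: float = 0.05,
    batch_size: int = 4096,
) -> KmerEmbedding:
    """Train the skip-gram k-mer embedding on a DNA corpus.

    Training pairs are (center k-mer at i, context k-mer at i + j) for
    1 <= |j| <= m.  With only 4^k words the objective is the exact
    softmax cross-entropy, optimised by minibatch SGD; deterministic for
    a fixed seed.
    """
    if m < 1:
        raise ValueError("context half-width m must be >= 1")
    centers_list, contexts_list = [], []
    for seq in corpus:
        ids = kmer_ids(seq, k)
        for j in range(1, m + 1):
            if len(ids) <= j:
                continue
            a, b = ids[:-j], ids[j:]
            ok = (a >= 0) & (b >= 0)
            centers_list.append(np.concatenate([a[ok], b[ok]]))
            contexts_list.append(np.concatenate([b[ok], a[ok]]))
    if not centers_list or not any(len(c) for c in centers_list):
        raise ValueError("corpus too short to form any skip-gram pair")
    centers = np.concatenate(centers_list)
    contexts = np.concatenate(contexts_list)

    rng = np.random.default_rng(seed)
    vocab = 4 ** k
    w_in = ((rng.random((vocab, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((dim, vocab), dtype=np.float32)
    n = len(centers)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            c, t = centers[idx], contexts[idx]
            h = w_in[c]  # (B, dim)
            probs = _softmax(h @ w_out)  # (B, vocab)
            probs[np.arange(len(t)), t] -= 1.0
            probs /= len(t)
            g_out = h.T @ probs
            g_h = probs @ w_out.T
            w_out -= lr * g_out
            np.subtract.at(w_in, c, lr * g_h)
    return KmerEmbedding(k=k, dim=dim, m=m, table=w_in)


def embed_segment(segment: Segment | str, emb: KmerEmbedding, window: int = 2000) -> np.ndarray:
    """Embedded matrix of one window: row t is the embedding of the k-mer
    starting at t; rows for N-containing k-mers are zero, and the matrix
    is zero-padded to ``window`` rows."""
    seq = segment.seq if isinstance(segment, Segment) else segment
    if len(seq) != window:
        raise ValueError(f"segment length {len(seq)} != window {window}")
    ids = kmer_ids(seq, emb.k)
    ids = np.where(ids < 0, 4 ** emb.k, ids)
    mat = np.zeros((window, emb.dim), dtype=np.float32)
    mat[: len(ids)] = emb.lookup_table()[ids]
    return mat


@dataclass
class CNNEncoder:
    """Convolutional node encoder with a softmax training head.

    ``w_conv`` holds ``n_conv`` filters of shape ``d1 x d2`` (d2 = the
    embedding dimension); the first dense layer's width is the node
    feature dimension.
    """

    embedding: KmerEmbedding
    w_conv: np.ndarray  # (d1, d2, n_conv)
    b_conv: np.ndarray  # (n_conv,)
    w0: np.ndarray  # (n_conv, feature_dim)
    b0: np.ndarray
    w1: np.ndarray  # (feature_dim, hidden2)
    b1: np.ndarray
    w2: np.ndarray  # (hidden2, n_label)
    b2: np.ndarray
    class_names: list[str]
    window: int = 2000
    history: list[float] = field(default_factory=list)

    @property
    def d1(self) -> int:
        return self.w_conv.shape[0]

    @property
    def n_conv(self) -> int:
        return self.w_conv.shape[2]

    @property
    def feature_dim(self) -> int:
        return self.w0.shape[1]

    @property
    def n_label(self) -> int:
        return self.w2.shape[1]

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            emb_table=self.embedding.table,
            w_conv=self.w_conv,
            b_conv=self.b_conv,
            w0=self.w0,
            b0=self.b0,
            w1=self.w1,
            b1=self.b1,
            w2=self.w2,
            b2=self.b2,
            meta=np.frombuffer(
                json.dumps(
                    {
                        "k": self.embedding.k,
                        "dim": self.embedding.dim,
                        "m": self.embedding.m,
                        "window": self.window,
                        "class_names": self.class_names,
                    }
                ).encode(),
                dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CNNEncoder":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        emb = KmerEmbedding(k=meta["k"], dim=meta["dim"], m=meta["m"], table=data["emb_table"])
        return cls(
            embedding=emb,
            w_conv=data["w_conv"],
            b_conv=data["b_conv"],
            w0=data["w0"],
            b0=data["b0"],
            w1=data["w1"],
            b1=data["b1"],
            w2=data["w2"],
            b2=data["b2"],
            class_names=list(meta["class_names"]),
            window=meta["window"],
        )


def _conv_pool(mats: np.ndarray, model: CNNEncoder) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convolution + ReLU + positional max-pool for a batch.

    Returns (pooled (B, n_conv), argmax positions (B, n_conv),
    pre-activation at the argmax (B, n_conv)).
    """
    B, L, d2 = mats.shape
    d1 = model.d1
    T = L - d1 + 1
    pre = np.broadcast_to(model.b_conv, (B, T, model.n_conv)).copy()
    for off in range(d1):
        sl = mats[:, off : off + T, :].reshape(B * T, d2)
        pre += (sl @ model.w_conv[off]).reshape(B, T, model.n_conv)
    z = np.maximum(pre, 0.0)
    argmax = z.argmax(axis=1)  # (B, n_conv)
    b_idx = np.arange(B)[:, None]
    pooled = z[b_idx, argmax, np.arange(model.n_conv)[None, :]]
    pre_at = pre[b_idx, argmax, np.arange(model.n_conv)[None, :]]
    return pooled, argmax, pre_at


def _dense_forward(pooled: np.ndarray, model: CNNEncoder) -> dict[str, np.ndarray]:
    h1 = np.maximum(pooled @ model.w0 + model.b0, 0.0)
    h2 = np.maximum(h1 @ model.w1 + model.b1, 0.0)
    logits = h2 @ model.w2 + model.b2
    return {"h1": h1, "h2": h2, "logits": logits, "probs": _softmax(logits)}


def cnn_forward(M: np.ndarray, model: CNNEncoder) -> np.ndarray:
    """Train-mode forward pass of one embedded matrix: class probabilities."""
    M = np.asarray(M, dtype=np.float32)
    if M.ndim != 2 or M.shape[1] != model.w_conv.shape[1]:
        raise ValueError(
            f"embedded matrix width {M.shape} incompatible with filters {model.w_conv.shape}"
        )
    if M.shape[0] < model.d1:
        raise ValueError("embedded matrix has fewer rows than the filter height")
    pooled, _, _ = _conv_pool(M[None], model)
    return _dense_forward(pooled, model)["probs"][0]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def _segments_to_ids(segments: Sequence[Segment | str], emb: KmerEmbedding, window: int) -> np.ndarray:
    ids = np.empty((len(segments), window - emb.k + 1), dtype=np.int32)
    for i, seg in enumerate(segments):
        seq = seg.seq if isinstance(seg, Segment) else seg
        if len(seq) != window:
            raise ValueError(f"segment length {len(seq)} != window {window}")
        arr = kmer_ids(seq, emb.k)
        ids[i] = np.where(arr < 0, 4 ** emb.k, arr)
    return ids


def _embed_ids(ids: np.ndarray, table: np.ndarray, window: int) -> np.ndarray:
    B, n = ids.shape
    mats = np.zeros((B, window, table.shape[1]), dtype=np.float32)
    mats[:, :n, :] = table[ids]
    return mats


def train_cnn(
    segments: Sequence[Segment | str],
    labels: Sequence[str],
    emb: KmerEmbedding,
    window: int = 2000,
    d1: int = 8,
    n_conv: int = 64,
    feature_dim: int = 512,
    hidden2: int = 256,
    epochs: int = 10,
    lr: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> CNNEncoder:
    """Fit the CNN on labeled segments with cross-entropy loss (Adam).

    Deterministic for a fixed seed.  ``model.history[0]`` is the loss at
    initialisation; subsequent entries are per-epoch mean losses.
    """
    if len(segments) != len(labels):
        raise ValueError("segments and labels length mismatch")
    class_names = sorted(set(labels))
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes to train the softmax head")
    y = np.array([class_names.index(l) for l in labels], dtype=np.int64)

    rng = np.random.default_rng(seed)
    d2 = emb.dim

    def glorot(shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return (rng.uniform(-limit, limit, size=shape)).astype(np.float32)

    model = CNNEncoder(
        embedding=emb,
        w_conv=glorot((d1, d2, n_conv)) / d1,
        b_conv=np.zeros(n_conv, dtype=np.float32),
        w0=glorot((n_conv, feature_dim)),
        b0=np.zeros(feature_dim, dtype=np.float32),
        w1=glorot((feature_dim, hidden2)),
        b1=np.zeros(hidden2, dtype=np.float32),
        w2=glorot((hidden2, len(class_names))),
        b2=np.zeros(len(class_names), dtype=np.float32),
        class_names=class_names,
        window=window,
    )
    ids_all = _segments_to_ids(segments, emb, window)
    table = emb.lookup_table()
    params = [model.w_conv, model.b_conv, model.w0, model.b0, model.w1, model.b1, model.w2, model.b2]
    opt = _Adam(params, lr)
    n = len(segments)

    def epoch_loss() -> float:
        total = 0.0
        for s in range(0, n, 256):
            mats = _embed_ids(ids_all[s : s + 256], table, window)
            pooled, _, _ = _conv_pool(mats, model)
            probs = _dense_forward(pooled, model)["probs"]
            total += -np.log(np.maximum(probs[np.arange(len(probs)), y[s : s + 256]], 1e-12)).sum()
        return total / n

    model.history.append(epoch_loss())
    f_idx = np.arange(n_conv)[None, :]
    for _ in range(epochs):
        order = rng.permutation(n)
        running = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            mats = _embed_ids(ids_all[idx], table, window)
            B = len(idx)
            pooled, argmax, pre_at = _conv_pool(mats, model)
            cache = _dense_forward(pooled, model)
            probs = cache["probs"]
            yb = y[idx]
            running += -np.log(np.maximum(probs[np.arange(B), yb], 1e-12)).sum()

            dlogits = probs.copy()
            dlogits[np.arange(B), yb] -= 1.0
            dlogits /= B
            g_w2 = cache["h2"].T @ dlogits
            g_b2 = dlogits.sum(0)
            dh2 = (dlogits @ model.w2.T) * (cache["h2"] > 0)
            g_w1 = cache["h1"].T @ dh2
            g_b1 = dh2.sum(0)
            dh1 = (dh2 @ model.w1.T) * (cache["h1"] > 0)
            g_w0 = pooled.T @ dh1
            g_b0 = dh1.sum(0)
            dpooled = dh1 @ model.w0.T  # (B, n_conv)
            # gradient flows only through the argmax window of each filter
            dpre = dpooled * (pre_at > 0)
            g_bc = dpre.sum(0)
            rows = argmax[:, :, None] + np.arange(model.d1)[None, None, :]  # (B, F, d1)
            gathered = mats[np.arange(B)[:, None, None], rows, :]  # (B, F, d1, d2)
            g_wc = np.einsum("bf,bfod->odf", dpre, gathered)
            opt.step(params, [g_wc, g_bc, g_w0, g_b0, g_w1, g_b1, g_w2, g_b2])
        model.history.append(running / n)
    return model


def _contig_windows(contig: Contig, model: CNNEncoder, stride: int | None) -> list[str]:
    if contig.length < model.window:
        raise ContigTooShortError(
            f"contig {contig.id!r} ({contig.length} nt) shorter than window {model.window}"
        )
    stride = stride or model.window  # non-overlapping in encoding mode
    segs = segment_contig(contig, window=model.window, stride=stride)
    return [s.seq for s in segs]


def encode_contig(contig: Contig, model: CNNEncoder, stride: int | None = None) -> np.ndarray:
    """Encoding-mode feature: first-dense-layer ReLU output averaged over
    the contig's windows (non-overlapping windows by default)."""
    seqs = _contig_windows(contig, model, stride)
    ids = _segments_to_ids(seqs, model.embedding, model.window)
    mats = _embed_ids(ids, model.embedding.lookup_table(), model.window)
    pooled, _, _ = _conv_pool(mats, model)
    h1 = np.maximum(pooled @ model.w0 + model.b0, 0.0)
    return h1.mean(axis=0).astype(np.float64)


def cnn_predict_contig(contig: Contig, model: CNNEncoder, stride: int | None = None) -> np.ndarray:
    """Diagnostic CNN-only prediction: softmax averaged over windows."""
    seqs = _contig_windows(contig, model, stride)
    ids = _segments_to_ids(seqs, model.embedding, model.window)
    mats = _embed_ids(ids, model.embedding.lookup_table(), model.window)
    pooled, _, _ = _conv_pool(mats, model)
    return _dense_forward(pooled, model)["probs"].mean(axis=0)
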