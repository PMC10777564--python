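"""Graph-convolutional classifier over sequence feature graphs.

The network stacks graph convolutions (symmetric degree-normalized neighbor
aggregation, linear map, ReLU), reads the node representations out into a
fixed-shape 1-D signal over the lexicographic k-mer universe, applies three
one-dimensional convolutions, and classifies with a two-layer fully connected
softmax head:

    Z_i = sum_{j in N(i)} a_ij / sqrt(d_i d_j) . h_j . W      (aggregation)
    H_i = ReLU(Z_i)                                           (transform)
    y_hat = softmax(ReLU(W1 . x + b1) . W2 + b2)              (head)

trained by mini-batch gradient descent on (optionally class-weighted) binary
cross-entropy. In the default weighted mode a_ij is the edge weight and the
degrees are weighted degrees; with ``use_edge_weights=False`` a_ij = 1 for
every edge, the literal unweighted form. No self term is added unless a
self-loop edge exists. All forward and backward passes are explicit NumPy;
gradients are exact and are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gkmgraph.encoding import (
    EncoderConfig,
    SequenceFeatureGraph,
    build_sequence_feature_graph,
    full_kmer_universe,
)
from gkmgraph.sequence_io import Dataset

logger = logging.getLogger(__name__)

_EPS = 1e-12
CHECKPOINT_FORMAT = "gkmgraph-checkpoint-1"


# ---------------------------------------------------------------------------
# configuration


def default_hidden_dims(n_layers: int) -> list[int]:
    """Default per-layer GCN widths; [16, 32, 32, 16] at the default depth 4.

    Shallower stacks take a prefix; deeper stacks repeat the final width.
    """
    base = [16, 32, 32, 16]
    if n_layers <= len(base):
        return base[:n_layers]
    return base + [base[-1]] * (n_layers - len(base))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the classifier.

    ``n_gcn_layers`` graph convolutions (default 4), three 1-D convolutional
    layers with ``conv_channels`` output channels, a fully connected hidden
    layer of width ``fc_hidden_dim`` and a two-class softmax output. ``seed``
    drives the deterministic parameter initialization.

    ``input_scale`` multiplies the node features entering the network; the
    default (None) uses the node count 4^k, so a uniform relative-frequency
    profile maps to unit features — without it the ~1/4^k-scale inputs shrink
    activations toward zero and gradient descent stalls near the uniform
    predictor.
    """

    n_gcn_layers: int = 4
    gcn_hidden_dims: tuple[int, ...] | None = None
    conv_channels: tuple[int, int, int] = (16, 32, 16)
    conv_kernel_size: int = 3
    fc_hidden_dim: int = 64
    use_edge_weights: bool = True
    input_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gcn_layers < 1:
            raise ValueError("n_gcn_layers must be >= 1")
        if self.gcn_hidden_dims is not None and len(self.gcn_hidden_dims) != self.n_gcn_layers:
            raise ValueError(
                f"gcn_hidden_dims has {len(self.gcn_hidden_dims)} entries "
                f"for {self.n_gcn_layers} layers"
            )
        if len(self.conv_channels) != 3:
            raise ValueError("conv_channels must list exactly 3 channel counts")
        if self.conv_kernel_size < 1 or self.conv_kernel_size % 2 == 0:
            raise ValueError("conv_kernel_size must be a positive odd integer")

    @property
    def hidden_dims(self) -> list[int]:
        if self.gcn_hidden_dims is not None:
            return list(self.gcn_hidden_dims)
        return default_hidden_dims(self.n_gcn_layers)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: plain mini-batch SGD on weighted cross-entropy."""

    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 32
    class_weights: str | tuple[float, float] = "balanced"
    early_stopping_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if isinstance(self.class_weights, str) and self.class_weights not in ("balanced", "none"):
            raise ValueError("class_weights must be 'balanced', 'none' or an explicit pair")


@dataclass
class ModelParams:
    """All trainable tensors, plus the architecture and encoder k they assume."""

    gcn_weights: list[np.ndarray]
    conv_kernels: list[np.ndarray]  # each (C_out, C_in, kernel_size)
    conv_biases: list[np.ndarray]
    W1: np.ndarray  # (fc_hidden, flattened conv output)
    b1: np.ndarray
    W2: np.ndarray  # (fc_hidden, 2)
    b2: np.ndarray
    config: ModelConfig = field(default_factory=ModelConfig)
    k: int = 3

    @classmethod
    def initialize(cls, config: ModelConfig, k: int, seed: int | None = None) -> "ModelParams":
        """Symmetric uniform fan-in initialization; biases start at zero.

        The bound sqrt(6 / fan_in) preserves activation variance through the
        ReLU stacks (He-style scaling for uniform draws).
        """
        rng = np.random.default_rng(config.seed if seed is None else seed)

        def uniform(shape: tuple[int, ...], fan_in: int) -> np.ndarray:
            bound = np.sqrt(6.0 / fan_in)
            return rng.uniform(-bound, bound, size=shape)

        dims = [1] + config.hidden_dims
        gcn_weights = [uniform((dims[i], dims[i + 1]), dims[i]) for i in range(len(dims) - 1)]

        ks = config.conv_kernel_size
        chans = [config.hidden_dims[-1], *config.conv_channels]
        conv_kernels = [
            uniform((chans[i + 1], chans[i], ks), chans[i] * ks) for i in range(3)
        ]
        conv_biases = [np.zeros(chans[i + 1]) for i in range(3)]

        flat_dim = config.conv_channels[-1] * 4**k
        W1 = uniform((config.fc_hidden_dim, flat_dim), flat_dim)
        b1 = np.zeros(config.fc_hidden_dim)
        W2 = uniform((config.fc_hidden_dim, 2), config.fc_hidden_dim)
        b2 = np.zeros(2)
        return cls(gcn_weights, conv_kernels, conv_biases, W1, b1, W2, b2, config, k)

    # -- flat-vector view (used by the finite-difference gradient check) ----

    def _tensors(self) -> list[np.ndarray]:
        return [
            *self.gcn_weights,
            *self.conv_kernels,
            *self.conv_biases,
            self.W1,
            self.b1,
            self.W2,
            self.b2,
        ]

    def to_vector(self) -> np.ndarray:
        return np.concatenate([t.ravel() for t in self._tensors()])

    def from_vector(self, vec: np.ndarray) -> "ModelParams":
        """Rebuild parameters of identical shapes from a flat vector."""
        out = self.copy()
        pos = 0
        for t in out._tensors():
            t[...] = vec[pos : pos + t.size].reshape(t.shape)
            pos += t.size
        if pos != vec.size:
            raise ValueError(f"vector has {vec.size} entries, expected {pos}")
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            [w.copy() for w in self.gcn_weights],
            [k.copy() for k in self.conv_kernels],
            [b.copy() for b in self.conv_biases],
            self.W1.copy(),
            self.b1.copy(),
            self.W2.copy(),
            self.b2.copy(),
            self.config,
            self.k,
        )


# ---------------------------------------------------------------------------
# elementary operations


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, x)


def graph_convolution_layer(
    H_prev: np.ndarray,
    graph: SequenceFeatureGraph,
    W: np.ndarray,
    use_edge_weights: bool = True,
) -> np.ndarray:
    """One graph convolution on a single graph: ReLU(D^{-1/2} A D^{-1/2} H W).

    Isolated nodes (degree 0) produce zero rows; there is no self term unless
    the graph contains a self-loop edge.
    """
    if any(w < 0 for w in graph.edges.values()):
        raise ValueError("negative edge weight")
    if H_prev.shape != (graph.n_nodes, W.shape[0]):
        raise ValueError(
            f"H_prev shape {H_prev.shape} incompatible with "
            f"{graph.n_nodes} nodes and W input dim {W.shape[0]}"
        )
    a_hat = graph.normalized_adjacency(use_edge_weights)
    return relu(a_hat @ H_prev @ W)


def readout_to_tensor(
    H_final: np.ndarray,
    node_labels: Sequence[str],
    canonical_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Arrange node representations as a (channels, 4^k) 1-D signal.

    Nodes are placed in lexicographic k-mer order regardless of storage order,
    so the readout is deterministic under node permutations. Graphs built on
    an observed (variable-size) universe are rejected.
    """
    k = len(node_labels[0])
    canonical = list(canonical_order) if canonical_order is not None else full_kmer_universe(k)
    if sorted(node_labels) != sorted(canonical):
        raise ValueError(
            "readout requires the full fixed k-mer universe; "
            "observed-universe graphs have variable node sets"
        )
    if H_final.shape[0] != len(node_labels):
        raise ValueError("row count of H_final must equal the node count")
    order = {kmer: i for i, kmer in enumerate(node_labels)}
    idx = [order[kmer] for kmer in canonical]
    return H_final[idx].T.copy()


def _conv1d_same(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Length-preserving 1-D cross-correlation. x: (..., C_in, L) -> (..., C_out, L)."""
    ks = kernel.shape[-1]
    pad = (ks - 1) // 2
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    if xb.shape[1] != kernel.shape[1]:
        raise ValueError(
            f"input has {xb.shape[1]} channels, kernel expects {kernel.shape[1]}"
        )
    xp = np.pad(xb, ((0, 0), (0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, ks, axis=2)
    y = np.einsum("oct,bcmt->bom", kernel, windows) + bias[None, :, None]
    return y[0] if squeeze else y


def conv_stack(
    x: np.ndarray,
    kernels: Sequence[np.ndarray],
    biases: Sequence[np.ndarray],
) -> np.ndarray:
    """Three sequential same-padding 1-D convolutions with ReLU, then flatten."""
    if len(kernels) != 3 or len(biases) != 3:
        raise ValueError("conv_stack expects exactly 3 kernels and 3 biases")
    h = x
    for kernel, bias in zip(kernels, biases):
        h = relu(_conv1d_same(h, kernel, bias))
    return h.reshape(-1) if x.ndim == 2 else h.reshape(h.shape[0], -1)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def head_forward(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """softmax(ReLU(W1.x + b1).W2 + b2) -> (p_negative, p_positive)."""
    hidden = relu(params.W1 @ x + params.b1)
    logits = hidden @ params.W2 + params.b2
    return _softmax(logits)


def cross_entropy_loss(
    labels: np.ndarray,
    probs: np.ndarray,
    class_weights: tuple[float, float] | None = None,
) -> float:
    """Mean binary cross-entropy of positive-class probabilities.

    L = -(1/N) sum_n w_n [ y_n log p_n + (1 - y_n) log(1 - p_n) ], with p
    clipped to [eps, 1 - eps] and w_n the weight of sample n's class (1 when
    weighting is disabled).
    """
    labels = np.asarray(labels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {probs.shape} probs")
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    terms = labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)
    if class_weights is not None:
        w = np.where(labels == 1, class_weights[1], class_weights[0])
        terms = w * terms
    return float(-np.mean(terms))


# ---------------------------------------------------------------------------
# batched forward / backward engine


def _stack_graphs(graphs: Sequence[SequenceFeatureGraph], config: ModelConfig):
    """(B, M, M) normalized adjacencies and (B, M, 1) scaled input features."""
    a = np.stack([g.normalized_adjacency(config.use_edge_weights) for g in graphs])
    h0 = np.stack([g.node_features[:, None] for g in graphs])
    scale = config.input_scale if config.input_scale is not None else graphs[0].n_nodes
    return a, h0 * scale


def _forward_batch(a: np.ndarray, h0: np.ndarray, params: ModelParams) -> dict:
    """Full forward pass on a stacked batch; returns probabilities and caches.

    All contractions are phrased as matrix products so they hit BLAS.
    """
    cache: dict = {"a": a, "gcn": []}
    h = h0
    for w in params.gcn_weights:
        msg = a @ h  # batched neighbor aggregation
        z = msg @ w
        h_next = relu(z)
        cache["gcn"].append({"msg": msg, "z": z})
        h = h_next
    x = np.transpose(h, (0, 2, 1))  # (B, C, M) signal over the k-mer universe
    cache["conv"] = []
    for kernel, bias in zip(params.conv_kernels, params.conv_biases):
        c_out, c_in, ks = kernel.shape
        pad = (ks - 1) // 2
        b, _, m = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, ks, axis=2)
        # im2col: (B*M, C_in*ks) @ (C_in*ks, C_out)
        wmat = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(b * m, c_in * ks)
        y = (wmat @ kernel.reshape(c_out, c_in * ks).T).reshape(b, m, c_out)
        y = np.transpose(y, (0, 2, 1)) + bias[None, :, None]
        cache["conv"].append({"wmat": wmat, "y": y})
        x = relu(y)
    v = x.reshape(x.shape[0], -1)
    pre1 = v @ params.W1.T + params.b1
    hidden = relu(pre1)
    logits = hidden @ params.W2 + params.b2
    probs = _softmax(logits)
    cache.update(v=v, pre1=pre1, hidden=hidden, probs=probs, x_shape=x.shape)
    return cache


def _zero_grads(params: ModelParams) -> ModelParams:
    g = params.copy()
    for t in g._tensors():
        t[...] = 0.0
    return g


def loss_and_gradients(
    graphs: Sequence[SequenceFeatureGraph],
    labels: np.ndarray,
    params: ModelParams,
    class_weights: tuple[float, float] | None = None,
) -> tuple[float, ModelParams]:
    """Weighted cross-entropy loss and its exact gradients on a batch.

    Returns the scalar loss and a ModelParams holding dL/d(theta) for every
    trainable tensor.
    """
    labels = np.asarray(labels, dtype=int)
    a, h0 = _stack_graphs(graphs, params.config)
    return _loss_and_gradients_arrays(a, h0, labels, params, class_weights)


def _loss_and_gradients_arrays(
    a: np.ndarray,
    h0: np.ndarray,
    labels: np.ndarray,
    params: ModelParams,
    class_weights: tuple[float, float] | None,
) -> tuple[float, ModelParams]:
    cache = _forward_batch(a, h0, params)
    probs = cache["probs"]
    n = len(labels)

    loss = cross_entropy_loss(labels, probs[:, 1], class_weights)

    w = np.ones(n)
    if class_weights is not None:
        w = np.where(labels == 1, class_weights[1], class_weights[0])
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), labels] = 1.0
    dlogits = (probs - onehot) * w[:, None] / n

    grads = _zero_grads(params)
    grads.W2[...] = cache["hidden"].T @ dlogits
    grads.b2[...] = dlogits.sum(axis=0)
    dhidden = dlogits @ params.W2.T
    dpre1 = dhidden * (cache["pre1"] > 0)
    grads.W1[...] = dpre1.T @ cache["v"]
    grads.b1[...] = dpre1.sum(axis=0)
    dv = dpre1 @ params.W1
    dx = dv.reshape(cache["x_shape"])

    for li in range(2, -1, -1):
        c = cache["conv"][li]
        kernel = params.conv_kernels[li]
        c_out, c_in, ks = kernel.shape
        pad = (ks - 1) // 2
        b, _, m = dx.shape
        dy = dx * (c["y"] > 0)
        dymat = np.ascontiguousarray(np.transpose(dy, (0, 2, 1))).reshape(b * m, c_out)
        grads.conv_kernels[li][...] = (dymat.T @ c["wmat"]).reshape(c_out, c_in, ks)
        grads.conv_biases[li][...] = dy.sum(axis=(0, 2))
        dxp = np.zeros((b, c_in, m + 2 * pad))
        for t in range(ks):
            dxp[:, :, t : t + m] += np.matmul(kernel[:, :, t].T[None], dy)
        dx = dxp[:, :, pad : pad + m]

    dh = np.transpose(dx, (0, 2, 1))  # back to (B, M, C)
    for li in range(len(params.gcn_weights) - 1, -1, -1):
        c = cache["gcn"][li]
        w_l = params.gcn_weights[li]
        dz = dh * (c["z"] > 0)
        p_dim, d_dim = grads.gcn_weights[li].shape
        grads.gcn_weights[li][...] = (
            c["msg"].reshape(-1, p_dim).T @ dz.reshape(-1, d_dim)
        )
        # normalized adjacency is symmetric, so A^T = A
        dh = a @ (dz @ w_l.T)

    return loss, grads


def batch_loss(
    graphs: Sequence[SequenceFeatureGraph],
    labels: np.ndarray,
    params: ModelParams,
    class_weights: tuple[float, float] | None = None,
) -> float:
    """Forward-only loss (used for logging and gradient checking)."""
    a, h0 = _stack_graphs(graphs, params.config)
    cache = _forward_batch(a, h0, params)
    return cross_entropy_loss(np.asarray(labels, dtype=int), cache["probs"][:, 1], class_weights)


# ---------------------------------------------------------------------------
# training and prediction


def encode_dataset(ds: Dataset, enc: EncoderConfig) -> list[SequenceFeatureGraph]:
    """Encode every record of a dataset as a sequence feature graph."""
    return [build_sequence_feature_graph(rec, enc) for rec in ds]


def resolve_class_weights(
    spec: str | tuple[float, float], labels: np.ndarray
) -> tuple[float, float] | None:
    """Materialize a class-weight setting against training labels.

    'balanced' uses inverse class frequencies normalized so that balanced
    classes recover unit weights: w_c = N / (2 N_c).
    """
    if spec == "none":
        return None
    if spec == "balanced":
        n = len(labels)
        n_pos = int(np.sum(labels == 1))
        n_neg = n - n_pos
        if n_pos == 0 or n_neg == 0:
            raise ValueError("balanced class weights require both classes present")
        return (n / (2.0 * n_neg), n / (2.0 * n_pos))
    w0, w1 = spec  # explicit pair
    return (float(w0), float(w1))


def train_model(
    train: Dataset,
    validation: Dataset | None,
    enc: EncoderConfig,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
) -> tuple[ModelParams, pd.DataFrame]:
    """Train the classifier by mini-batch SGD on weighted cross-entropy.

    Returns the fitted parameters and a per-epoch log (epoch, train_loss,
    val_loss, val_acc). Identical seeds and data give identical trajectories.
    With ``early_stopping_patience`` set, training stops once validation loss
    has not improved for that many epochs and the best parameters are
    restored.
    """
    y_train = train.labels
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    if enc.node_universe != "full":
        raise ValueError("training requires the full fixed node universe")

    weights = resolve_class_weights(tcfg.class_weights, y_train)
    params = ModelParams.initialize(mcfg, enc.k)
    rng = np.random.default_rng(tcfg.seed)

    # stack adjacency/feature tensors once; mini-batches index into them
    a_train, h_train = _stack_graphs(encode_dataset(train, enc), mcfg)
    have_val = validation is not None and len(validation) > 0
    if have_val:
        a_val, h_val = _stack_graphs(encode_dataset(validation, enc), mcfg)
        y_val = validation.labels

    log_rows: list[dict] = []
    best_val = np.inf
    best_params = None
    stall = 0

    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(y_train))
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            loss, grads = _loss_and_gradients_arrays(
                a_train[idx], h_train[idx], y_train[idx], params, weights
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss!r} at epoch {epoch}, batch offset {start}"
                )
            for p_t, g_t in zip(params._tensors(), grads._tensors()):
                p_t -= tcfg.learning_rate * g_t

        row: dict = {
            "epoch": epoch,
            "train_loss": cross_entropy_loss(
                y_train, _forward_batch(a_train, h_train, params)["probs"][:, 1], weights
            ),
        }
        if have_val:
            val_scores = _forward_batch(a_val, h_val, params)["probs"][:, 1]
            row["val_loss"] = cross_entropy_loss(y_val, val_scores, weights)
            row["val_acc"] = float(np.mean((val_scores > 0.5).astype(int) == y_val))
        log_rows.append(row)

        if tcfg.early_stopping_patience is not None and have_val:
            if row["val_loss"] < best_val - 1e-12:
                best_val = row["val_loss"]
                best_params = params.copy()
                stall = 0
            else:
                stall += 1
                if stall >= tcfg.early_stopping_patience:
                    logger.info("early stop at epoch %d (patience %d)", epoch,
                                tcfg.early_stopping_patience)
                    params = best_params if best_params is not None else params
                    break

    return params, pd.DataFrame(log_rows)


def _score_graphs(graphs: Sequence[SequenceFeatureGraph], params: ModelParams) -> np.ndarray:
    if not graphs:
        return np.zeros(0)
    a, h0 = _stack_graphs(graphs, params.config)
    return _forward_batch(a, h0, params)["probs"][:, 1]


def predict(
    ds: Dataset, enc: EncoderConfig, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class scores and hard labels for every record.

    The hard label is the argmax class with ties (score exactly 0.5) broken
    toward the negative class.
    """
    if enc.k != params.k:
        raise ValueError(f"encoder k={enc.k} does not match model k={params.k}")
    graphs = encode_dataset(ds, enc)
    scores = _score_graphs(graphs, params)
    hard = (scores > 0.5).astype(int)
    return scores, hard


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path: str | Path, params: ModelParams, enc: EncoderConfig) -> None:
    """Self-describing .npz archive: format tag, configs, seed and all tensors."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "encoder": {"k": enc.k, "d": enc.d, "count_mode": enc.count_mode,
                    "node_universe": enc.node_universe},
        "model_config": {
            "n_gcn_layers": params.config.n_gcn_layers,
            "gcn_hidden_dims": params.config.hidden_dims,
            "conv_channels": list(params.config.conv_channels),
            "conv_kernel_size": params.config.conv_kernel_size,
            "fc_hidden_dim": params.config.fc_hidden_dim,
            "use_edge_weights": params.config.use_edge_weights,
            "input_scale": params.config.input_scale,
            "seed": params.config.seed,
        },
    }
    arrays = {"meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, w in enumerate(params.gcn_weights):
        arrays[f"gcn_w_{i}"] = w
    for i, (kk, bb) in enumerate(zip(params.conv_kernels, params.conv_biases)):
        arrays[f"conv_k_{i}"] = kk
        arrays[f"conv_b_{i}"] = bb
    arrays.update(W1=params.W1, b1=params.b1, W2=params.W2, b2=params.b2)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, EncoderConfig]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format {meta.get('format')!r}")
        mc = meta["model_config"]
        config = ModelConfig(
            n_gcn_layers=mc["n_gcn_layers"],
            gcn_hidden_dims=tuple(mc["gcn_hidden_dims"]),
            conv_channels=tuple(mc["conv_channels"]),
            conv_kernel_size=mc["conv_kernel_size"],
            fc_hidden_dim=mc["fc_hidden_dim"],
            use_edge_weights=mc["use_edge_weights"],
            input_scale=mc.get("input_scale"),
            seed=mc["seed"],
        )
        ec = meta["encoder"]
        enc = EncoderConfig(k=ec["k"], d=ec["d"], count_mode=ec["count_mode"],
                            node_universe=ec["node_universe"])
        n_layers = config.n_gcn_layers
        params = ModelParams(
            gcn_weights=[z[f"gcn_w_{i}"].copy() for i in range(n_layers)],
            conv_kernels=[z[f"conv_k_{i}"].copy() for i in range(3)],
            conv_biases=[z[f"conv_b_{i}"].copy() for i in range(3)],
            W1=z["W1"].copy(),
            b1=z["b1"].copy(),
            W2=z["W2"].copy(),
            b2=z["b2"].copy(),
            config=config,
            k=enc.k,
        )
    return params, enc
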