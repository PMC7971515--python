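"""MLP and edge-inferring GNN models for classification and forecasting.

Both tasks share one framework: a function ``f`` maps the N×2 node-feature
slice of one timestep (trace value and derivative per neuron) to an output
``H``.  For behavioral-state classification ``H`` is a length-k score vector
fed through a softmax; for trajectory forecasting ``H`` is an N×2 residual
added to the current features, i.e. a Markovian one-step predictor
``X_{t+1} = X_t + H``.

Two families of ``f``:

* **MLP** — graph-agnostic: aggregate node features (concatenation by
  default, summation optional) and apply a two-layer perceptron.
* **GNN** — infer a weighted adjacency from the data itself.  A per-node
  perceptron embeds each node's features; for every ordered pair the
  concatenated embeddings pass through an edge perceptron whose sigmoid
  output is the edge weight ``A[i, j] ∈ (0, 1)`` (self edges included).
  One round of message passing ``M = A X`` mixes node features along the
  inferred edges before aggregation and a final perceptron.  Edge weights
  are re-inferred every timestep (``dynamic``), inferred once from the whole
  recording with time-averaged node embeddings (``static``), or supplied by
  the user, e.g. from the physical connectome (``provided``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat
from .data_model import EdgeWeights
from .nn import Perceptron2

__all__ = [
    "ModelConfig",
    "MLPModel",
    "GNNModel",
    "build_model",
    "mlp_forward",
    "gnn_forward",
    "encode_edges",
    "message_pass",
    "classify",
    "predict_step",
    "rollout",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The source studies leave the approximator's internals open; defaults are
    the smallest round sizes that comfortably overfit a single individual.
    """

    n_neurons: int
    head: str = "classifier"  # "classifier" or "predictor"
    n_states: int = 4  # classifier output size k
    model_kind: str = "gnn"  # "mlp" or "gnn"
    edge_mode: str = "dynamic"  # "dynamic", "static", or "provided"
    hidden_width: int = 64
    node_embed_dim: int = 16
    aggregation: str = "concat"  # "concat" or "sum"
    message_passing_steps: int = 1
    feature_norm: bool = True
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 256  # timesteps per optimizer step (classification)
    train_window: int = 8  # rollout window length (prediction)
    shuffle_individuals: bool = False

    def __post_init__(self):
        if self.model_kind not in {"mlp", "gnn"}:
            raise ValueError(f"unknown model_kind: {self.model_kind!r}")
        if self.head not in {"classifier", "predictor"}:
            raise ValueError(f"unknown head: {self.head!r}")
        if self.aggregation not in {"concat", "sum"}:
            raise ValueError(f"unknown aggregation: {self.aggregation!r}")
        if self.edge_mode not in {"dynamic", "static", "provided"}:
            raise ValueError(f"unknown edge_mode: {self.edge_mode!r}")
        if self.hidden_width < 1 or self.node_embed_dim < 1:
            raise ValueError("hidden_width and node_embed_dim must be positive")
        if self.message_passing_steps < 1:
            raise ValueError("message_passing_steps must be >= 1")
        if self.head == "classifier" and self.n_states < 2:
            raise ValueError("classifier needs at least 2 states")

    @property
    def out_dim(self) -> int:
        return self.n_states if self.head == "classifier" else 2 * self.n_neurons

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_batch(X) -> tuple[Tensor, bool]:
    """Coerce (N,2) or (B,N,2) input to a (B,N,2) Tensor."""
    t = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
    if t.ndim == 2:
        return t.reshape(1, *t.shape), True
    if t.ndim != 3:
        raise ValueError(f"expected (N,2) or (B,N,2) features, got {t.shape}")
    return t, False


class MLPModel:
    """Graph-agnostic baseline: aggregate node features, apply a 2-layer MLP."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        if cfg.model_kind != "mlp":
            raise ValueError("config is not an MLP config")
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        in_dim = 2 * cfg.n_neurons if cfg.aggregation == "concat" else 2
        self.g_graph = Perceptron2(in_dim, cfg.hidden_width, cfg.out_dim, rng,
                                   feature_norm=cfg.feature_norm,
                                   zero_output=cfg.head == "predictor")

    def forward(self, X, A=None) -> Tensor:
        Xb, squeeze = _as_batch(X)
        if Xb.shape[1] != self.cfg.n_neurons or Xb.shape[2] != 2:
            raise ValueError(
                f"expected ({self.cfg.n_neurons}, 2) node features, "
                f"got {Xb.shape[1:]}"
            )
        if self.cfg.aggregation == "concat":
            agg = Xb.reshape(Xb.shape[0], 2 * self.cfg.n_neurons)
        else:
            agg = Xb.sum(axis=1)
        out = self.g_graph(agg)
        return out.reshape(out.shape[1]) if squeeze else out

    def parameters(self) -> list[Tensor]:
        return self.g_graph.parameters()


class GNNModel:
    """Edge-inferring graph network: embed nodes, score ordered pairs,
    message-pass along the sigmoid edge weights, aggregate, read out."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        if cfg.model_kind != "gnn":
            raise ValueError("config is not a GNN config")
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        d = cfg.node_embed_dim
        self.g_node = Perceptron2(2, cfg.hidden_width, d, rng,
                                  feature_norm=cfg.feature_norm)
        self.g_edge = Perceptron2(2 * d, cfg.hidden_width, 1, rng)
        in_dim = 2 * cfg.n_neurons if cfg.aggregation == "concat" else 2
        self.g_graph = Perceptron2(in_dim, cfg.hidden_width, cfg.out_dim, rng,
                                   feature_norm=cfg.feature_norm,
                                   zero_output=cfg.head == "predictor")

    # ------------------------------------------------------------ edge encoder
    def _embed_nodes(self, Xb: Tensor) -> Tensor:
        B, N, _ = Xb.shape
        flat = Xb.reshape(B * N, 2)
        return self.g_node(flat).reshape(B, N, self.cfg.node_embed_dim)

    def _pairs_to_edges(self, V: Tensor) -> Tensor:
        """Ordered-pair scores: A[..., i, j] from (v_i, v_j).

        The first edge-perceptron layer on the concatenated pair
        (v_i, v_j) is linear, so it is evaluated as two per-node
        projections broadcast-added over pairs — identical math, O(N·d·h)
        instead of O(N²·d·h) in the first layer.
        """
        *lead, N, d = V.shape
        W1, b1 = self.g_edge.fc1.W, self.g_edge.fc1.b
        h = W1.shape[1]
        P = V @ W1[:d]  # contribution of v_i
        Q = V @ W1[d:]  # contribution of v_j
        H1 = P.reshape(*lead, N, 1, h) + Q.reshape(*lead, 1, N, h) + b1
        E = self.g_edge.fc2(H1.relu())
        return E.reshape(*lead, N, N).sigmoid()

    def encode_edges_tensor(self, X) -> Tensor:
        """Infer edge weights; dynamic from one slice, static from all of X.

        Dynamic mode expects (B,N,2) (one A per timestep); static mode
        expects the full recording (T,N,2) and averages node embeddings over
        time before scoring pairs, so A is one (N,N) matrix fixed for the
        whole recording.
        """
        if self.cfg.edge_mode == "provided":
            raise RuntimeError("edge_mode='provided' bypasses the edge encoder")
        Xb, squeeze = _as_batch(X)
        V = self._embed_nodes(Xb)
        if self.cfg.edge_mode == "static":
            V = V.mean(axis=0)  # time-average of per-timestep embeddings
            return self._pairs_to_edges(V)
        A = self._pairs_to_edges(V)
        return A.reshape(*A.shape[1:]) if squeeze else A

    # ----------------------------------------------------------------- forward
    def forward(self, X, A) -> Tensor:
        """Apply message passing with edge weights ``A`` and read out.

        ``A`` may be a Tensor/array of shape (N,N) (static/provided) or
        (B,N,N) (dynamic, aligned with the batch).
        """
        Xb, squeeze = _as_batch(X)
        if Xb.shape[1] != self.cfg.n_neurons or Xb.shape[2] != 2:
            raise ValueError(
                f"expected ({self.cfg.n_neurons}, 2) node features, "
                f"got {Xb.shape[1:]}"
            )
        At = A if isinstance(A, Tensor) else Tensor(np.asarray(A, dtype=np.float64))
        if At.shape[-1] != self.cfg.n_neurons or At.shape[-2] != self.cfg.n_neurons:
            raise ValueError("adjacency does not match the model's neuron count")
        M = Xb
        for _ in range(self.cfg.message_passing_steps):
            M = At @ M
        if self.cfg.aggregation == "concat":
            agg = M.reshape(M.shape[0], 2 * self.cfg.n_neurons)
        else:
            agg = M.sum(axis=1)
        out = self.g_graph(agg)
        return out.reshape(out.shape[1]) if squeeze else out

    def parameters(self) -> list[Tensor]:
        return (self.g_node.parameters() + self.g_edge.parameters()
                + self.g_graph.parameters())


def build_model(cfg: ModelConfig):
    rng = np.random.default_rng(cfg.seed)
    return MLPModel(cfg, rng) if cfg.model_kind == "mlp" else GNNModel(cfg, rng)


# ------------------------------------------------------------------ functional

def mlp_forward(X, cfg: ModelConfig) -> np.ndarray:
    """Forward pass of a freshly initialized (seeded) MLP — functional form."""
    model = MLPModel(cfg)
    return model.forward(X).data


def gnn_forward(X, A, cfg: ModelConfig) -> np.ndarray:
    """Forward pass of a freshly initialized (seeded) GNN — functional form."""
    model = GNNModel(cfg)
    mat = A.matrix if isinstance(A, EdgeWeights) else A
    return model.forward(X, mat).data


def encode_edges(X, cfg: ModelConfig) -> EdgeWeights:
    """Infer edge weights with a freshly initialized (seeded) GNN encoder."""
    model = GNNModel(cfg)
    A = model.encode_edges_tensor(X).data
    return EdgeWeights(matrix=A, mode=cfg.edge_mode)


def message_pass(A, X, steps: int = 1) -> np.ndarray:
    """Message passing M = A·X: M_i = Σ_j A[i, j]·x_j, applied ``steps`` times."""
    mat = np.asarray(A.matrix if isinstance(A, EdgeWeights) else A,
                     dtype=np.float64)
    M = np.asarray(X, dtype=np.float64)
    if mat.shape[-1] != M.shape[-2]:
        raise ValueError(
            f"adjacency {mat.shape} does not match features {M.shape}"
        )
    for _ in range(steps):
        M = mat @ M
    return M


def classify(H) -> tuple[np.ndarray, np.ndarray | int]:
    """Softmax probabilities and argmax state (ties to the lowest code)."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape[-1] < 2:
        raise ValueError("need at least 2 states to classify")
    z = H - H.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    pred = p.argmax(axis=-1)
    if H.ndim == 1:
        return p, int(pred)
    return p, pred


def predict_step(X_t, H) -> np.ndarray:
    """Markovian residual update: X̂_{t+1} = X_t + H."""
    X_t = np.asarray(X_t, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    if X_t.shape != H.shape:
        raise ValueError(f"shape mismatch: X {X_t.shape} vs H {H.shape}")
    return X_t + H


def rollout(model, X0, n_steps: int, A=None) -> np.ndarray:
    """Autoregressive forecast: feed each prediction back as the next input.

    ``X0`` is (N,2) or (B,N,2).  For a dynamic-edge GNN the adjacency is
    re-inferred from each predicted slice; for static/provided modes pass
    the fixed ``A``.  Returns (n_steps, ...) stacked predictions.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    X = np.asarray(X0, dtype=np.float64)
    cfg = model.cfg
    fixed_A = None
    if cfg.model_kind == "gnn" and cfg.edge_mode != "dynamic":
        if A is None:
            raise ValueError(f"edge_mode={cfg.edge_mode!r} requires a fixed A")
        fixed_A = A.matrix if isinstance(A, EdgeWeights) else np.asarray(A)
    preds = []
    for _ in range(n_steps):
        if cfg.model_kind == "mlp":
            H = model.forward(X).data
        elif cfg.edge_mode == "dynamic":
            At = model.encode_edges_tensor(X)
            H = model.forward(X, At).data
        else:
            H = model.forward(X, fixed_A).data
        if cfg.head == "predictor":
            H = H.reshape(X.shape)
        X = X + H
        preds.append(X)
    return np.stack(preds, axis=0)


# ----------------------------------------------------------------- checkpoints

def save_checkpoint(model, path) -> None:
    """Save model weights plus the serialized config and its hash."""
    cfg = model.cfg
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    meta = json.dumps({"config": asdict(cfg), "hash": cfg.hash()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Load a checkpoint; refuses to load if the config hash mismatches."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ModelConfig(**meta["config"])
        if cfg.hash() != meta["hash"]:
            raise ValueError("checkpoint config hash mismatch; refusing to load")
        model = build_model(cfg)
        for i, p in enumerate(model.parameters()):
            stored = data[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError("checkpoint parameter shapes do not match config")
            p.data = stored.astype(np.float64)
    return model
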