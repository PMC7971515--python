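"""Scikit-learn-style estimators for state decoding and trajectory forecasting.

:class:`StateClassifier` decodes the behavioral state from one timestep of
per-neuron features; :class:`TrajectoryPredictor` forecasts each neuron's
trace and derivative with a Markovian residual model trained on short
rollouts with scheduled sampling.

Both estimators implement the dataset-enlargement scheme used for pooling
individuals: every epoch iterates the individuals one at a time and
optimizes the loss on that individual's data alone, so feature-normalization
statistics are always computed within one worm.  Pass ``individuals`` (an
array of per-timestep individual ids, contiguous per individual) to
``fit``/``predict`` to enable this; with a single individual the scheme
reduces exactly to plain training.

Inputs ``X`` are (T, N, 2) arrays: per-timestep node features (normalized
trace value, normalized derivative) for N neurons.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .autodiff import Tensor
from .data_model import EdgeWeights
from .models import ModelConfig, build_model, rollout
from .nn import Adam

__all__ = ["StateClassifier", "TrajectoryPredictor", "sampling_schedule"]


def sampling_schedule(epoch: int, total_epochs: int) -> float:
    """Teacher-forcing probability: linear decay from 1 at epoch 0 to 0 at the end."""
    if total_epochs < 1:
        raise ValueError("total_epochs must be >= 1")
    if epoch < 0 or epoch >= total_epochs:
        raise ValueError(f"epoch {epoch} out of range [0, {total_epochs})")
    if total_epochs == 1:
        return 0.0
    return 1.0 - epoch / (total_epochs - 1)


def _validate_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3 or X.shape[2] != 2:
        raise ValueError(f"X must be (T, N, 2) node features, got {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    return X


def _group_indices(individuals, n: int) -> dict:
    """Per-individual row indices, ordered by first appearance."""
    if individuals is None:
        return {"_all": np.arange(n)}
    individuals = np.asarray(individuals)
    if individuals.shape != (n,):
        raise ValueError("individuals must have one entry per timestep")
    groups: dict = {}
    for ind in individuals:
        key = ind.item() if hasattr(ind, "item") else ind
        if key not in groups:
            groups[key] = None
    return {key: np.flatnonzero(individuals == key) for key in groups}


def _cross_entropy(logits: Tensor, y_idx: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (B, k) logits against integer labels."""
    m = logits.max_detached(axis=1, keepdims=True)
    z = logits - m
    lse = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(y_idx)), y_idx] = 1.0
    nll = lse - (z * Tensor(onehot)).sum(axis=1, keepdims=True)
    return nll.mean()


class _FittedMixin:
    """Shared forward plumbing for the two estimators."""

    def _adjacency_matrix(self) -> np.ndarray:
        adj = self.adjacency
        if adj is None:
            raise ValueError("edge_mode='provided' requires an adjacency")
        mat = adj.matrix if isinstance(adj, EdgeWeights) else np.asarray(adj)
        return mat

    def _model_output(self, Xb: Tensor, X_full: Tensor | None) -> Tensor:
        """Forward a batch; X_full is the worm's whole recording (static mode)."""
        model = self.model_
        cfg = model.cfg
        if cfg.model_kind == "mlp":
            return model.forward(Xb)
        if cfg.edge_mode == "dynamic":
            A = model.encode_edges_tensor(Xb)
        elif cfg.edge_mode == "static":
            A = model.encode_edges_tensor(X_full)
        else:
            A = self._adjacency_matrix()
        return model.forward(Xb, A)

    def _check_loss(self, value: float, epoch: int, individual) -> None:
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite training loss ({value}) at epoch {epoch}, "
                f"individual {individual!r}; lower the learning rate"
            )


class StateClassifier(_FittedMixin, ClassifierMixin, BaseEstimator):
    """Behavioral-state decoder operating on one timestep of node features.

    Parameters mirror :class:`~wormgnn.models.ModelConfig`; ``model_kind``
    selects the graph-agnostic MLP or the edge-inferring GNN, ``edge_mode``
    how the GNN obtains its adjacency.  ``stop_train_accuracy`` optionally
    halts training once the training-set accuracy (checked every
    ``check_interval`` epochs) reaches the given level — a convergence
    criterion, not validation-based early stopping.
    """

    def __init__(self, model_kind: str = "gnn", edge_mode: str = "dynamic",
                 adjacency=None, hidden_width: int = 64,
                 node_embed_dim: int = 16, aggregation: str = "concat",
                 message_passing_steps: int = 1, feature_norm: bool = True,
                 learning_rate: float = 1e-3, epochs: int = 200,
                 batch_size: int = 256, shuffle_individuals: bool = False,
                 stop_train_accuracy: float | None = None,
                 check_interval: int = 10, random_state: int = 0):
        self.model_kind = model_kind
        self.edge_mode = edge_mode
        self.adjacency = adjacency
        self.hidden_width = hidden_width
        self.node_embed_dim = node_embed_dim
        self.aggregation = aggregation
        self.message_passing_steps = message_passing_steps
        self.feature_norm = feature_norm
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.shuffle_individuals = shuffle_individuals
        self.stop_train_accuracy = stop_train_accuracy
        self.check_interval = check_interval
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, individuals=None):
        X = _validate_features(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],):
            raise ValueError("y must have one label per timestep")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.n_neurons_ = X.shape[1]
        cfg = ModelConfig(
            n_neurons=self.n_neurons_, head="classifier",
            n_states=len(self.classes_), model_kind=self.model_kind,
            edge_mode=self.edge_mode, hidden_width=self.hidden_width,
            node_embed_dim=self.node_embed_dim, aggregation=self.aggregation,
            message_passing_steps=self.message_passing_steps,
            feature_norm=self.feature_norm, seed=self.random_state,
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size,
            shuffle_individuals=self.shuffle_individuals,
        )
        self.config_ = cfg
        self.model_ = build_model(cfg)
        opt = Adam(self.model_.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state)
        groups = _group_indices(individuals, X.shape[0])
        log: list[dict] = []
        for epoch in range(self.epochs):
            order = list(groups)
            if self.shuffle_individuals:
                rng.shuffle(order)
            for ind in order:
                idx = groups[ind]
                X_full = Tensor(X[idx]) if cfg.edge_mode == "static" else None
                perm = rng.permutation(idx)
                losses = []
                for lo in range(0, len(perm), self.batch_size):
                    sel = perm[lo:lo + self.batch_size]
                    opt.zero_grad()
                    logits = self._model_output(Tensor(X[sel]), X_full)
                    loss = _cross_entropy(logits, y_idx[sel])
                    value = float(loss.data)
                    self._check_loss(value, epoch, ind)
                    loss.backward()
                    opt.step()
                    losses.append(value)
                log.append({"epoch": epoch, "individual": ind,
                            "loss": float(np.mean(losses))})
            if (self.stop_train_accuracy is not None
                    and (epoch + 1) % self.check_interval == 0):
                acc = float(np.mean(
                    self.predict(X, individuals=individuals) == y))
                if acc >= self.stop_train_accuracy:
                    break
        self.train_log_ = log
        return self

    # -------------------------------------------------------------- predict
    def decision_function(self, X, individuals=None) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _validate_features(X)
        if X.shape[1] != self.n_neurons_:
            raise ValueError(
                f"model was fitted on {self.n_neurons_} neurons, "
                f"got {X.shape[1]}"
            )
        groups = _group_indices(individuals, X.shape[0])
        out = np.empty((X.shape[0], len(self.classes_)))
        for ind, idx in groups.items():
            Xg = Tensor(X[idx])
            X_full = Xg if self.config_.edge_mode == "static" else None
            out[idx] = self._model_output(Xg, X_full).data
        return out

    def predict_proba(self, X, individuals=None) -> np.ndarray:
        H = self.decision_function(X, individuals)
        z = H - H.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X, individuals=None) -> np.ndarray:
        scores = self.decision_function(X, individuals)
        return self.classes_[scores.argmax(axis=1)]


class TrajectoryPredictor(_FittedMixin, BaseEstimator):
    """Markovian forecaster of per-neuron features, trained on rollouts.

    Training cuts each individual's recording into windows of
    ``train_window`` timesteps, takes the first timestep of each window as
    the initial condition, and minimizes the mean squared error of the
    remaining ``train_window - 1`` predicted steps.  With scheduled sampling
    the input of each step is the ground truth with probability p(epoch)
    (linear decay 1 -> 0), otherwise the model's own prediction — the coin
    is flipped per window per step.
    """

    def __init__(self, model_kind: str = "gnn", edge_mode: str = "dynamic",
                 adjacency=None, hidden_width: int = 64,
                 node_embed_dim: int = 16, aggregation: str = "concat",
                 message_passing_steps: int = 1, feature_norm: bool = True,
                 learning_rate: float = 1e-3, epochs: int = 200,
                 train_window: int = 8, scheduled_sampling: bool = True,
                 batch_windows: int = 32,
                 shuffle_individuals: bool = False, random_state: int = 0):
        self.model_kind = model_kind
        self.edge_mode = edge_mode
        self.adjacency = adjacency
        self.hidden_width = hidden_width
        self.node_embed_dim = node_embed_dim
        self.aggregation = aggregation
        self.message_passing_steps = message_passing_steps
        self.feature_norm = feature_norm
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.train_window = train_window
        self.scheduled_sampling = scheduled_sampling
        self.batch_windows = batch_windows
        self.shuffle_individuals = shuffle_individuals
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None, individuals=None):
        X = _validate_features(X)
        if self.train_window < 2:
            raise ValueError("train_window must be >= 2")
        self.n_neurons_ = X.shape[1]
        cfg = ModelConfig(
            n_neurons=self.n_neurons_, head="predictor",
            model_kind=self.model_kind, edge_mode=self.edge_mode,
            hidden_width=self.hidden_width,
            node_embed_dim=self.node_embed_dim, aggregation=self.aggregation,
            message_passing_steps=self.message_passing_steps,
            feature_norm=self.feature_norm, seed=self.random_state,
            learning_rate=self.learning_rate, epochs=self.epochs,
            train_window=self.train_window,
            shuffle_individuals=self.shuffle_individuals,
        )
        self.config_ = cfg
        self.model_ = build_model(cfg)
        opt = Adam(self.model_.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state)
        groups = _group_indices(individuals, X.shape[0])
        W = self.train_window
        windows = {}
        for ind, idx in groups.items():
            if len(idx) < W:
                raise ValueError(
                    f"individual {ind!r} has fewer than train_window timesteps"
                )
            n_win = len(idx) // W
            windows[ind] = X[idx[: n_win * W]].reshape(
                n_win, W, self.n_neurons_, 2)
        log: list[dict] = []
        schedule: list[float] = []
        for epoch in range(self.epochs):
            p_truth = (sampling_schedule(epoch, self.epochs)
                       if self.scheduled_sampling else 1.0)
            schedule.append(p_truth)
            order = list(groups)
            if self.shuffle_individuals:
                rng.shuffle(order)
            for ind in order:
                wins = windows[ind]
                X_full = (Tensor(X[groups[ind]])
                          if cfg.edge_mode == "static" else None)
                perm = rng.permutation(wins.shape[0])
                losses = []
                for lo in range(0, len(perm), self.batch_windows):
                    sel = perm[lo:lo + self.batch_windows]
                    opt.zero_grad()
                    loss = self._rollout_loss(wins[sel], X_full, p_truth, rng)
                    value = float(loss.data)
                    self._check_loss(value, epoch, ind)
                    loss.backward()
                    opt.step()
                    losses.append(value)
                log.append({"epoch": epoch, "individual": ind,
                            "loss": float(np.mean(losses))})
        self.train_log_ = log
        self.sampling_trace_ = schedule
        return self

    def _rollout_loss(self, wins: np.ndarray, X_full: Tensor | None,
                      p_truth: float, rng: np.random.Generator) -> Tensor:
        model = self.model_
        cfg = model.cfg
        B, W = wins.shape[0], wins.shape[1]
        cur = Tensor(wins[:, 0])
        fixed_A = None
        if cfg.model_kind == "gnn" and cfg.edge_mode == "static":
            fixed_A = model.encode_edges_tensor(X_full)
        elif cfg.model_kind == "gnn" and cfg.edge_mode == "provided":
            fixed_A = Tensor(self._adjacency_matrix())
        terms = []
        for s in range(1, W):
            if cfg.model_kind == "mlp":
                H = model.forward(cur)
            elif cfg.edge_mode == "dynamic":
                H = model.forward(cur, model.encode_edges_tensor(cur))
            else:
                H = model.forward(cur, fixed_A)
            pred = cur + H.reshape(*cur.shape)
            target = wins[:, s]
            diff = pred - Tensor(target)
            terms.append((diff * diff).mean())
            if s < W - 1:
                mask = (rng.random(B) < p_truth).astype(np.float64)
                mask = mask[:, None, None]
                cur = pred * Tensor(1.0 - mask) + Tensor(target * mask)
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total * (1.0 / len(terms))

    # -------------------------------------------------------------- forecast
    def forecast(self, X0, n_steps: int, context=None) -> np.ndarray:
        """Autoregressive forecast from initial condition(s) ``X0``.

        ``X0`` is (N,2) or (B,N,2).  Static edge mode infers the adjacency
        from ``context`` — the full (T,N,2) recording of the evaluated
        individual, no labels involved; provided mode uses the estimator's
        adjacency; dynamic mode re-infers edges from each predicted slice.
        """
        check_is_fitted(self, "model_")
        cfg = self.config_
        A = None
        if cfg.model_kind == "gnn" and cfg.edge_mode == "static":
            if context is None:
                raise ValueError("static edge mode requires context=full recording")
            A = self.model_.encode_edges_tensor(
                Tensor(_validate_features(context))).data
        elif cfg.model_kind == "gnn" and cfg.edge_mode == "provided":
            A = self._adjacency_matrix()
        return rollout(self.model_, X0, n_steps, A)

    def infer_edges(self, X) -> EdgeWeights:
        """Edge weights the fitted GNN assigns on a recording (static: one A)."""
        check_is_fitted(self, "model_")
        if self.config_.model_kind != "gnn" or self.config_.edge_mode == "provided":
            raise ValueError("edge inference requires a GNN with learned edges")
        A = self.model_.encode_edges_tensor(Tensor(_validate_features(X))).data
        return EdgeWeights(matrix=A, mode=self.config_.edge_mode)
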