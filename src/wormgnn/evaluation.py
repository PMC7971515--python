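"""Measurement protocols: k-fold CV, unseen-individual decoding, rollout MSE.

Three protocols:

* **Seen population** — shuffled 10-fold cross-validation over 8-timestep
  windows of one labeled recording; a fresh model is trained per fold.
* **Unseen population** — a fitted classifier is run on every timestep of a
  recording from an individual never seen in training; reported as accuracy
  and a row-percentage confusion matrix (rows = labeled states).
* **Trajectory** — the recording is cut into evaluation windows; the model
  receives the first timestep of each window as the initial condition and
  autoregressively predicts ``horizon`` steps; the per-step MSE (averaged
  over windows, neurons and channels) is compared against the persistence
  baseline that repeats the initial condition.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import confusion_matrix

from .data_model import EvalReport, TraceSet
from .estimators import StateClassifier, TrajectoryPredictor
from .models import ModelConfig
from .preprocess import make_folds, make_windows
from .training import _estimator_params

__all__ = [
    "cross_validate_seen",
    "evaluate_unseen_classification",
    "evaluate_unseen_population",
    "evaluate_trajectory",
    "persistence_baseline_mse",
]


def cross_validate_seen(ts: TraceSet, cfg: ModelConfig, kfold: int = 10,
                        seed: int = 0, window: int = 8) -> EvalReport:
    """Shuffled k-fold cross-validation on one labeled recording.

    The recording is cut into ``window``-timestep windows, windows are
    shuffled and dealt into ``kfold`` folds; each fold is held out once
    while a fresh model trains on the rest.  Reports the per-fold, mean and
    spread (standard deviation) of accuracy.
    """
    if ts.labels is None:
        raise ValueError("cross-validation requires labels")
    batches = make_windows(ts, window)
    split = make_folds(batches, kfold, seed)
    feats = np.stack([b.features for b in batches])  # n_win x W x N x 2
    labs = np.stack([b.labels for b in batches])
    template = StateClassifier(batch_size=cfg.batch_size,
                               **_estimator_params(cfg))
    accs = []
    for fold in range(kfold):
        test = split.fold_indices(fold)
        train = np.flatnonzero(split.fold_of != fold)
        Xtr = feats[train].reshape(-1, ts.n_neurons, 2)
        ytr = labs[train].reshape(-1)
        clf = clone(template)
        clf.fit(Xtr, ytr)
        Xte = feats[test].reshape(-1, ts.n_neurons, 2)
        yte = labs[test].reshape(-1)
        accs.append(float(np.mean(clf.predict(Xte) == yte)))
    accs = np.asarray(accs)
    return EvalReport(
        accuracy=float(accs.mean()),
        fold_accuracies=accs,
        metadata={
            "protocol": "seen_population_cv",
            "individual": ts.individual_id,
            "kfold": kfold,
            "seed": seed,
            "accuracy_sd": float(accs.std(ddof=1)) if kfold > 1 else 0.0,
        },
    )


def _row_percent_confusion(y_true, y_pred, k: int) -> np.ndarray:
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(k)).astype(float)
    totals = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(totals > 0, 100.0 * cm / totals, 0.0)
    return out


def evaluate_unseen_classification(clf: StateClassifier, ts: TraceSet
                                   ) -> EvalReport:
    """Per-timestep decoding of an individual unseen during training.

    One prediction per timestep; with static edge mode the adjacency is
    inferred from the unseen recording itself (no labels used).  The
    confusion matrix follows the row-percentage convention: each row is a
    labeled state, its entries the percent occurrence of predicted states.
    """
    if ts.labels is None:
        raise ValueError("scoring requires labels on the evaluated recording")
    k = len(clf.classes_)
    if ts.vocabulary is not None and ts.vocabulary.size != k:
        raise ValueError(
            f"vocabulary mismatch: model has {k} states, recording has "
            f"{ts.vocabulary.size}; map the states first"
        )
    X = ts.features()
    pred = clf.predict(X, individuals=np.full(ts.n_timesteps, ts.individual_id,
                                              dtype=object))
    acc = float(np.mean(pred == ts.labels))
    return EvalReport(
        accuracy=acc,
        confusion=_row_percent_confusion(ts.labels, pred, k),
        metadata={"protocol": "unseen_individual",
                  "individual": ts.individual_id,
                  "n_timesteps": ts.n_timesteps},
    )


def evaluate_unseen_population(clf: StateClassifier,
                               population: Sequence[TraceSet]) -> EvalReport:
    """Average unseen accuracy with equal weight per individual."""
    reports = [evaluate_unseen_classification(clf, ts) for ts in population]
    accs = np.array([r.accuracy for r in reports])
    pooled_true = np.concatenate([ts.labels for ts in population])
    pooled_pred_conf = sum(
        r.confusion * ts.n_timesteps
        for r, ts in zip(reports, population)
    ) / sum(ts.n_timesteps for ts in population)
    return EvalReport(
        accuracy=float(accs.mean()),
        fold_accuracies=accs,
        confusion=pooled_pred_conf,
        metadata={
            "protocol": "unseen_population",
            "individuals": [ts.individual_id for ts in population],
            "accuracy_sd": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
            "n_states": int(len(np.unique(pooled_true))),
        },
    )


def _evaluation_windows(ts: TraceSet, horizon: int) -> np.ndarray:
    """Non-overlapping windows of horizon+1 timesteps: IC + horizon targets."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if horizon + 1 > ts.n_timesteps:
        raise ValueError(
            f"horizon {horizon} needs at least {horizon + 1} timesteps, "
            f"recording has {ts.n_timesteps}"
        )
    X = ts.features()
    n_win = ts.n_timesteps // (horizon + 1)
    return X[: n_win * (horizon + 1)].reshape(n_win, horizon + 1,
                                              ts.n_neurons, 2)


def evaluate_trajectory(pred: TrajectoryPredictor, ts: TraceSet,
                        horizon: int = 16) -> EvalReport:
    """Per-step MSE of autoregressive forecasts on one recording.

    The model is given the first timestep of each window as the initial
    condition and predicts ``horizon`` steps; MSE at step s averages the
    squared error over windows, neurons and both feature channels.
    """
    wins = _evaluation_windows(ts, horizon)
    X0 = wins[:, 0]
    context = ts.features() if pred.config_.edge_mode == "static" else None
    preds = pred.forecast(X0, horizon, context=context)  # horizon x B x N x 2
    truth = np.moveaxis(wins[:, 1:], 0, 1)  # horizon x B x N x 2
    mse = ((preds - truth) ** 2).mean(axis=(1, 2, 3))
    return EvalReport(
        per_step_mse=mse,
        metadata={"protocol": "trajectory", "individual": ts.individual_id,
                  "horizon": horizon, "n_windows": int(wins.shape[0])},
    )


def persistence_baseline_mse(ts: TraceSet, horizon: int = 16) -> np.ndarray:
    """Per-step MSE of repeating the initial condition: X̂_{t+s} = X_t.

    The reference a learned one-step map must beat at step 1.
    """
    wins = _evaluation_windows(ts, horizon)
    # evaluated exactly like a zero-residual forecast so the oracle identity
    # with evaluate_trajectory holds bitwise
    preds = np.stack([wins[:, 0]] * horizon, axis=0)
    truth = np.moveaxis(wins[:, 1:], 0, 1)
    return ((preds - truth) ** 2).mean(axis=(1, 2, 3))
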