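"""Training entry points operating on populations of TraceSets.

These are thin wrappers around the estimators in
:mod:`wormgnn.estimators`: they stack the recordings of a population into
one feature array with per-timestep individual ids (so dataset enlargement
iterates worms one at a time) and return the fitted estimator together with
a :class:`TrainLog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import TraceSet
from .estimators import StateClassifier, TrajectoryPredictor, sampling_schedule
from .models import ModelConfig

__all__ = [
    "TrainLog",
    "train_classifier",
    "train_predictor",
    "sampling_schedule",
    "stack_population",
]


@dataclass
class TrainLog:
    """Per-(epoch, individual) losses plus the sampling-probability trace."""

    entries: list[dict] = field(default_factory=list)
    sampling_probabilities: list[float] = field(default_factory=list)
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def stack_population(population: Sequence[TraceSet]
                     ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Stack recordings into (X, labels, individuals) arrays.

    All recordings must share neuron names (same order) and, when labeled,
    the same state vocabulary.
    """
    if not population:
        raise ValueError("population is empty")
    names = population[0].neuron_names
    for ts in population[1:]:
        if ts.neuron_names != names:
            raise ValueError(
                f"inconsistent neuron sets: {ts.individual_id} has "
                f"{ts.neuron_names}, expected {names}"
            )
    vocabs = {ts.vocabulary.names for ts in population
              if ts.vocabulary is not None}
    if len(vocabs) > 1:
        raise ValueError("individuals use different state vocabularies")
    X = np.concatenate([ts.features() for ts in population], axis=0)
    individuals = np.concatenate([
        np.full(ts.n_timesteps, ts.individual_id, dtype=object)
        for ts in population
    ])
    if all(ts.labels is not None for ts in population):
        y = np.concatenate([ts.labels for ts in population])
    else:
        y = None
    return X, y, individuals


def _estimator_params(cfg: ModelConfig) -> dict:
    return dict(
        model_kind=cfg.model_kind, edge_mode=cfg.edge_mode,
        hidden_width=cfg.hidden_width, node_embed_dim=cfg.node_embed_dim,
        aggregation=cfg.aggregation,
        message_passing_steps=cfg.message_passing_steps,
        feature_norm=cfg.feature_norm, learning_rate=cfg.learning_rate,
        epochs=cfg.epochs, shuffle_individuals=cfg.shuffle_individuals,
        random_state=cfg.seed,
    )


def train_classifier(population: Sequence[TraceSet], cfg: ModelConfig,
                     adjacency=None) -> tuple[StateClassifier, TrainLog]:
    """Fit a behavioral-state classifier on a (possibly pooled) population."""
    X, y, individuals = stack_population(population)
    if y is None:
        raise ValueError("classification requires labels on every individual")
    clf = StateClassifier(adjacency=adjacency,
                          batch_size=cfg.batch_size,
                          **_estimator_params(cfg))
    clf.fit(X, y, individuals=individuals)
    return clf, TrainLog(entries=clf.train_log_, seed=cfg.seed)


def train_predictor(population: Sequence[TraceSet], cfg: ModelConfig,
                    adjacency=None) -> tuple[TrajectoryPredictor, TrainLog]:
    """Fit a Markovian trajectory predictor with scheduled sampling."""
    X, _, individuals = stack_population(population)
    pred = TrajectoryPredictor(adjacency=adjacency,
                               train_window=cfg.train_window,
                               **_estimator_params(cfg))
    pred.fit(X, individuals=individuals)
    return pred, TrainLog(entries=pred.train_log_,
                          sampling_probabilities=pred.sampling_trace_,
                          seed=cfg.seed)
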