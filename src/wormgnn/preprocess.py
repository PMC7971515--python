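"""Feature construction and dataset partitioning.

The pipeline mirrors standard practice for behavioral decoding from
calcium traces: compute time derivatives, rescale each neuron's trace and
derivative to [0,1] over the *entire* recording (relative trace magnitude
carries graded behavioral information, so per-window normalization would
destroy it), cut the recording into fixed-length windows of consecutive
timesteps, and deal shuffled windows into k folds for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .data_model import StateVocabulary, TraceSet

__all__ = [
    "WindowBatch",
    "FoldSplit",
    "compute_derivative",
    "normalize_unit_interval",
    "prepare_traceset",
    "make_windows",
    "make_folds",
    "map_states",
    "map_traceset_states",
    "DEFAULT_7_TO_4_MAP",
]

# Default mapping from the 7-state vocabulary of the larger study to the
# 4-state vocabulary of the extended evaluation study.  The slowing phase of
# forward locomotion is folded into forward crawling; the three reversal
# sub-states collapse into a single reverse-crawling state.  Overridable via
# any Mapping (e.g. loaded from YAML).
DEFAULT_7_TO_4_MAP: dict[str, str] = {
    "Forward Crawling": "forward crawling",
    "Forward Slowing": "forward crawling",
    "Reverse 1": "reverse crawling",
    "Reverse 2": "reverse crawling",
    "Sustained Reverse Crawling": "reverse crawling",
    "Dorsal Turn": "dorsal turn",
    "Ventral Turn": "ventral turn",
}


@dataclass
class WindowBatch:
    """W consecutive timesteps of one individual's features."""

    features: np.ndarray  # W x N x 2
    labels: np.ndarray | None  # length W or None
    individual_id: str
    start: int

    @property
    def width(self) -> int:
        return self.features.shape[0]


@dataclass
class FoldSplit:
    """Assignment of every window to exactly one of ``kfold`` folds."""

    fold_of: np.ndarray  # length n_batches, values in 0..kfold-1
    kfold: int
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


def compute_derivative(traces: np.ndarray, dt: float) -> np.ndarray:
    """Finite-difference time derivative, columnwise.

    Central differences on interior points, one-sided at both ends.  The
    original studies used regularized differentiation; since both channels
    are subsequently rescaled to [0,1], the scheme's scale factor is
    immaterial and plain finite differences suffice.
    """
    traces = np.asarray(traces, dtype=np.float64)
    if traces.ndim == 1:
        traces = traces[:, None]
    if traces.shape[0] < 2:
        raise ValueError("need at least 2 timesteps to differentiate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(traces, dt, axis=0)


def normalize_unit_interval(matrix: np.ndarray) -> np.ndarray:
    """Rescale each column to [0,1] over the full recording.

    Constant columns map to all-zeros.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    lo = matrix.min(axis=0, keepdims=True)
    hi = matrix.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.zeros_like(matrix)
    np.divide(matrix - lo, span, out=out, where=span > 0)
    return out


def prepare_traceset(ts: TraceSet) -> TraceSet:
    """Derivatives (unless loader-provided) + per-neuron [0,1] normalization."""
    deriv = ts.derivatives
    if deriv is None:
        deriv = compute_derivative(ts.traces, ts.dt)
    return replace(
        ts,
        traces=normalize_unit_interval(ts.traces),
        derivatives=normalize_unit_interval(deriv),
    )


def make_windows(ts: TraceSet, width: int) -> list[WindowBatch]:
    """Cut a recording into floor(T/width) non-overlapping windows.

    A trailing remainder shorter than ``width`` is dropped, not padded.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    if width > ts.n_timesteps:
        raise ValueError(
            f"window width {width} exceeds recording length {ts.n_timesteps}"
        )
    X = ts.features()
    n = ts.n_timesteps // width
    return [
        WindowBatch(
            features=X[i * width:(i + 1) * width],
            labels=None if ts.labels is None else ts.labels[i * width:(i + 1) * width],
            individual_id=ts.individual_id,
            start=i * width,
        )
        for i in range(n)
    ]


def make_folds(batches: Sequence[WindowBatch], kfold: int, seed: int) -> FoldSplit:
    """Shuffle windows with a seeded permutation and deal them into folds.

    Fold sizes differ by at most one; the assignment is deterministic for a
    given seed.
    """
    n = len(batches)
    if kfold < 1 or kfold > n:
        raise ValueError(f"kfold must be in [1, {n}], got {kfold}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    # deal shuffled batches round-robin so sizes differ by at most 1
    fold_of[perm] = np.arange(n) % kfold
    return FoldSplit(fold_of=fold_of, kfold=kfold, seed=seed)


def map_states(labels: Sequence[int] | np.ndarray,
               source: StateVocabulary,
               mapping: Mapping[str, str] | None = None,
               target: StateVocabulary | None = None,
               ) -> tuple[np.ndarray, StateVocabulary]:
    """Relabel state codes through a name-level vocabulary map.

    ``mapping`` defaults to :data:`DEFAULT_7_TO_4_MAP`.  The target
    vocabulary is built from the mapping image in first-appearance order
    unless given explicitly.  Raises ``KeyError`` on an unmapped label.
    """
    if mapping is None:
        mapping = DEFAULT_7_TO_4_MAP
    labels = np.asarray(labels, dtype=np.int64)
    missing = [n for n in source.names if n not in mapping]
    if any(int(c) in set(labels.tolist()) for c, n in enumerate(source.names)
           if n in set(missing)):
        present_missing = sorted(
            {source.names[int(c)] for c in np.unique(labels)} - set(mapping)
        )
        raise KeyError(f"labels without a mapping entry: {present_missing}")
    if target is None:
        image = tuple(dict.fromkeys(mapping[n] for n in source.names
                                    if n in mapping))
        target = StateVocabulary(image)
    lut = np.array(
        [target.code(mapping[n]) if n in mapping else -1 for n in source.names],
        dtype=np.int64,
    )
    return lut[labels], target


def map_traceset_states(ts: TraceSet,
                        mapping: Mapping[str, str] | None = None,
                        target: StateVocabulary | None = None) -> TraceSet:
    """Apply :func:`map_states` to a labeled TraceSet."""
    if ts.labels is None or ts.vocabulary is None:
        raise ValueError("traceset has no labels/vocabulary to map")
    new_labels, new_vocab = map_states(ts.labels, ts.vocabulary, mapping, target)
    return replace(ts, labels=new_labels, vocabulary=new_vocab)
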