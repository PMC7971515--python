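"""Domain types and file I/O for whole-brain calcium-imaging recordings.

A recording of one individual is a :class:`TraceSet`: a T×N matrix of
normalized fluorescence traces for N named neurons over T timesteps
(~1/3 s each), the matching matrix of time derivatives, and optionally a
per-timestep behavioral-state label.  Trace tables are read and written as
CSV (one ``time`` column, one column per neuron, optional ``d_<name>``
derivative columns, optional ``state`` column) or as an HDF5 mirror of the
same layout.  Adjacency matrices — e.g. synapse counts from the physical
connectome — load from a square CSV with named header row/column or from a
``source,target,weight`` edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TraceSet",
    "StateVocabulary",
    "EdgeWeights",
    "EvalReport",
    "load_trace_table",
    "write_trace_table",
    "select_neurons",
    "load_adjacency",
    "KATO_SHARED_NEURONS",
    "CROSS_STUDY_SHARED_NEURONS",
]

# Neurons uniquely identified in all five individuals of the larger study,
# and the three-neuron subset shared across both studies.
KATO_SHARED_NEURONS: tuple[str, ...] = (
    "AIBL", "AIBR", "ALA", "AVAL", "AVAR", "AVBL", "AVER", "RID",
    "RIML", "RIMR", "RMED", "RMEL", "RMER", "VB01", "VB02",
)
CROSS_STUDY_SHARED_NEURONS: tuple[str, ...] = ("AIBR", "AVAL", "VB02")


@dataclass(frozen=True)
class StateVocabulary:
    """Bijective mapping between behavioral-state names and codes 0..k-1."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("state names must be unique")

    @property
    def size(self) -> int:
        return len(self.names)

    def code(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown state name: {name!r}") from None

    def encode(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.code(n) for n in names], dtype=np.int64)

    def decode(self, codes: Sequence[int]) -> list[str]:
        return [self.names[int(c)] for c in codes]


@dataclass
class TraceSet:
    """One individual's recording: traces, derivatives, names, labels."""

    individual_id: str
    neuron_names: tuple[str, ...]
    traces: np.ndarray  # T x N
    derivatives: np.ndarray | None = None  # T x N, None if not yet computed
    dt: float = 1.0 / 3.0  # seconds per timestep
    labels: np.ndarray | None = None  # length T, integer state codes
    vocabulary: StateVocabulary | None = None

    def __post_init__(self):
        self.neuron_names = tuple(self.neuron_names)
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if len(set(self.neuron_names)) != len(self.neuron_names):
            raise ValueError("neuron names must be unique")
        if self.traces.ndim != 2 or self.traces.shape[1] != len(self.neuron_names):
            raise ValueError("traces must be T x N matching neuron_names")
        if not np.isfinite(self.traces).all():
            raise ValueError("traces contain non-finite values")
        if self.derivatives is not None:
            self.derivatives = np.asarray(self.derivatives, dtype=np.float64)
            if self.derivatives.shape != self.traces.shape:
                raise ValueError("derivatives must share the traces' shape")
            if not np.isfinite(self.derivatives).all():
                raise ValueError("derivatives contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.traces.shape[0],):
                raise ValueError("labels must have one entry per timestep")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_timesteps(self) -> int:
        return self.traces.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[1]

    def features(self) -> np.ndarray:
        """T x N x 2 array: channel 0 trace, channel 1 derivative."""
        if self.derivatives is None:
            raise ValueError(
                "derivatives not computed; run preprocess.compute_derivative"
            )
        return np.stack([self.traces, self.derivatives], axis=-1)


@dataclass
class EdgeWeights:
    """Weighted adjacency A with entries in [0,1]; A[i, j] gates j -> i."""

    matrix: np.ndarray
    mode: str  # one of {"dynamic", "static", "provided"}

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        m = self.matrix
        if m.ndim < 2 or m.shape[-1] != m.shape[-2]:
            raise ValueError("adjacency must be square on its last two axes")
        if self.mode not in {"dynamic", "static", "provided"}:
            raise ValueError(f"unknown edge mode: {self.mode!r}")
        if m.min() < 0.0 or m.max() > 1.0:
            raise ValueError("edge weights must lie in [0, 1]")


@dataclass
class EvalReport:
    """Evaluation results: accuracies, confusion matrix, per-step MSE."""

    accuracy: float | None = None
    fold_accuracies: np.ndarray | None = None
    confusion: np.ndarray | None = None  # k x k, rows = true state, in percent
    per_step_mse: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = dict(self.metadata)
        if self.accuracy is not None:
            out["accuracy"] = float(self.accuracy)
        if self.fold_accuracies is not None:
            out["fold_accuracies"] = [float(a) for a in self.fold_accuracies]
        if self.confusion is not None:
            out["confusion_percent"] = self.confusion.tolist()
        if self.per_step_mse is not None:
            out["per_step_mse"] = [float(m) for m in self.per_step_mse]
        return out


# --------------------------------------------------------------------- loaders

def load_trace_table(path, dialect: str | None = None, *,
                     individual_id: str | None = None,
                     vocabulary: StateVocabulary | None = None,
                     dt: float = 1.0 / 3.0) -> TraceSet:
    """Load one individual's trace table from CSV or HDF5.

    Columns named ``d_<neuron>`` are treated as precomputed derivatives,
    ``state`` as the behavioral-state label, ``time`` is ignored beyond
    ordering.  ``dialect`` defaults from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace table not found: {path}")
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if dialect == "csv":
        return _load_csv(path, individual_id, vocabulary, dt)
    if dialect == "hdf5":
        return _load_hdf5(path, individual_id, vocabulary)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _load_csv(path: Path, individual_id, vocabulary, dt) -> TraceSet:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trace table {path}: {exc}") from exc
    reserved = {"time", "state"}
    neuron_cols = [c for c in df.columns
                   if c not in reserved and not c.startswith("d_")]
    if len(set(neuron_cols)) != len(neuron_cols):
        raise ValueError(f"duplicate neuron columns in {path}")
    if not neuron_cols:
        raise ValueError(f"no neuron columns found in {path}")
    traces = df[neuron_cols].to_numpy(dtype=np.float64)
    bad = np.argwhere(~np.isfinite(traces))
    if bad.size:
        row, col = bad[0]
        raise ValueError(
            f"non-numeric or missing trace value at data row {row}, "
            f"neuron {neuron_cols[col]!r} in {path}"
        )
    deriv_cols = [f"d_{c}" for c in neuron_cols]
    derivatives = None
    if all(c in df.columns for c in deriv_cols):
        derivatives = df[deriv_cols].to_numpy(dtype=np.float64)
        bad = np.argwhere(~np.isfinite(derivatives))
        if bad.size:
            row, col = bad[0]
            raise ValueError(
                f"non-numeric derivative value at data row {row}, "
                f"neuron {neuron_cols[col]!r} in {path}"
            )
    labels = None
    if "state" in df.columns:
        state_names = df["state"].astype(str).tolist()
        if vocabulary is None:
            vocabulary = StateVocabulary(tuple(dict.fromkeys(state_names)))
        labels = vocabulary.encode(state_names)
    return TraceSet(
        individual_id=individual_id or path.stem,
        neuron_names=tuple(neuron_cols),
        traces=traces,
        derivatives=derivatives,
        dt=dt,
        labels=labels,
        vocabulary=vocabulary,
    )


def _load_hdf5(path: Path, individual_id, vocabulary) -> TraceSet:
    with h5py.File(path, "r") as f:
        neuron_names = tuple(n.decode() if isinstance(n, bytes) else str(n)
                             for n in f.attrs["neuron_names"])
        traces = np.asarray(f["traces"], dtype=np.float64)
        derivatives = (np.asarray(f["derivatives"], dtype=np.float64)
                       if "derivatives" in f else None)
        labels = np.asarray(f["state"], dtype=np.int64) if "state" in f else None
        dt = float(f.attrs.get("dt", 1.0 / 3.0))
        iid = individual_id or str(f.attrs.get("individual_id", path.stem))
        if vocabulary is None and "state_names" in f.attrs:
            vocabulary = StateVocabulary(tuple(
                n.decode() if isinstance(n, bytes) else str(n)
                for n in f.attrs["state_names"]))
    return TraceSet(individual_id=iid, neuron_names=neuron_names,
                    traces=traces, derivatives=derivatives, dt=dt,
                    labels=labels, vocabulary=vocabulary)


def write_trace_table(ts: TraceSet, path, dialect: str | None = None) -> None:
    """Write a TraceSet to CSV or HDF5 (inverse of :func:`load_trace_table`)."""
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if dialect == "csv":
        data = {"time": np.arange(ts.n_timesteps) * ts.dt}
        for j, name in enumerate(ts.neuron_names):
            data[name] = ts.traces[:, j]
        if ts.derivatives is not None:
            for j, name in enumerate(ts.neuron_names):
                data[f"d_{name}"] = ts.derivatives[:, j]
        if ts.labels is not None:
            if ts.vocabulary is not None:
                data["state"] = ts.vocabulary.decode(ts.labels)
            else:
                data["state"] = ts.labels
        pd.DataFrame(data).to_csv(path, index=False)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=np.arange(ts.n_timesteps) * ts.dt)
            f.create_dataset("traces", data=ts.traces)
            if ts.derivatives is not None:
                f.create_dataset("derivatives", data=ts.derivatives)
            if ts.labels is not None:
                f.create_dataset("state", data=ts.labels)
                if ts.vocabulary is not None:
                    f.attrs["state_names"] = list(ts.vocabulary.names)
            f.attrs["neuron_names"] = list(ts.neuron_names)
            f.attrs["dt"] = ts.dt
            f.attrs["individual_id"] = ts.individual_id
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def select_neurons(ts: TraceSet, names: Sequence[str]) -> TraceSet:
    """Restrict a recording to the named neurons, in the requested order.

    Used to subset to the shared identified-neuron sets so recordings from
    different individuals (and studies) align on a common node set.
    Matching is case-sensitive and exact.
    """
    missing = [n for n in names if n not in ts.neuron_names]
    if missing:
        raise KeyError(f"neurons not in recording: {missing}")
    idx = [ts.neuron_names.index(n) for n in names]
    return replace(
        ts,
        neuron_names=tuple(names),
        traces=ts.traces[:, idx],
        derivatives=None if ts.derivatives is None else ts.derivatives[:, idx],
    )


def load_adjacency(path, neuron_names: Sequence[str], *,
                   normalize: bool = False) -> EdgeWeights:
    """Load a provided adjacency (e.g. connectome synapse counts).

    Accepts a square matrix CSV whose header row and first column carry
    neuron names, or a ``source,target,weight`` edge list.  The result is
    aligned to ``neuron_names`` order.  With ``normalize`` the matrix is
    divided by its maximum entry; otherwise entries must already lie in
    [0,1].  The matrix may be directed; no symmetrization is applied.
    Convention: entry (i, j) is the weight of the edge from j into i.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"adjacency file not found: {path}")
    names = list(neuron_names)
    df = pd.read_csv(path)
    cols = [str(c) for c in df.columns]
    if cols[:3] == ["source", "target", "weight"] and len(cols) == 3:
        mat = np.zeros((len(names), len(names)))
        index = {n: i for i, n in enumerate(names)}
        for _, row in df.iterrows():
            s, t = str(row["source"]), str(row["target"])
            if s not in index or t not in index:
                missing = [n for n in (s, t) if n not in index]
                raise ValueError(f"edge endpoint(s) not in neuron_names: {missing}")
            # edge source -> target lands in row target, column source
            mat[index[t], index[s]] = float(row["weight"])
    else:
        df = pd.read_csv(path, index_col=0)
        row_names = [str(r) for r in df.index]
        col_names = [str(c) for c in df.columns]
        if set(row_names) != set(names) or set(col_names) != set(names):
            raise ValueError(
                "adjacency header does not match the requested neuron names"
            )
        df = df.loc[names, names]
        mat = df.to_numpy(dtype=np.float64)
    if normalize:
        peak = np.abs(mat).max()
        if peak > 0:
            mat = mat / peak
    if mat.min() < 0.0 or mat.max() > 1.0:
        raise ValueError(
            "adjacency entries outside [0,1]; pass normalize=True to rescale"
        )
    return EdgeWeights(matrix=mat, mode="provided")
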