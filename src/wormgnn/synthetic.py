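"""Synthetic populations emulating whole-brain calcium-imaging studies.

Real recordings of freely moving nematodes show a shared low-dimensional
cyclic latent process — the pirouette motor sequence traces a loop in
neural state space — while each individual expresses that process through
its own mixing of neurons.  The generator reproduces exactly this
structure:

* a phase variable moves around a circle with state-dependent speed and a
  little diffusion; behavioral states are contiguous arcs of the circle,
  visited in a fixed cyclic order (forward -> reverse -> turn -> forward);
* the latent trajectory embeds the phase with decaying harmonics (three
  effective dimensions by default);
* each individual observes the shared latent through its own random linear
  readout followed by a softplus (fluorescence is nonnegative), first-order
  exponential smoothing (a calcium-indicator proxy) and additive noise;
* traces and derivatives are then normalized to [0,1] per neuron, as in the
  real pipeline.

Because readouts are individual-specific, a decoder trained on one
individual's neurons does not transfer to another, while the latent process
itself is perfectly decodable — the dissociation that makes
cross-individual generalization a meaningful test.

For trajectory-prediction and edge-recovery tests the module also provides
ground-truth coupled systems ``X_{t+1} = X_t + eps * tanh(W X_t + u) + noise``
with a known sparse coupling matrix ``W``.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from .data_model import KATO_SHARED_NEURONS, StateVocabulary, TraceSet
from .preprocess import prepare_traceset

__all__ = [
    "SyntheticPopulationConfig",
    "GroundTruthSystem",
    "generate_latent_cycle",
    "generate_individual",
    "generate_population",
    "make_random_system",
    "generate_coupled_system",
    "FOUR_STATES",
    "SEVEN_STATES",
]

# Cyclic state orders (the order in which arcs of the loop are visited).
FOUR_STATES: tuple[str, ...] = (
    "forward crawling", "reverse crawling", "dorsal turn", "ventral turn",
)
SEVEN_STATES: tuple[str, ...] = (
    "Forward Crawling", "Forward Slowing", "Reverse 1", "Reverse 2",
    "Sustained Reverse Crawling", "Dorsal Turn", "Ventral Turn",
)

# Relative dwell fractions and angular speeds: worms spend most time
# crawling forward; turns are brief and fast.
_DWELL_4 = (0.45, 0.30, 0.125, 0.125)
_SPEED_4 = (0.7, 1.0, 1.4, 1.9)
_DWELL_7 = (0.30, 0.15, 0.10, 0.10, 0.10, 0.125, 0.125)
_SPEED_7 = (0.7, 0.8, 1.0, 1.1, 1.2, 1.4, 1.9)


@dataclass
class SyntheticPopulationConfig:
    """Study conditions for the synthetic population.

    Defaults mirror the real studies: ~3,000-4,000 timesteps per individual
    at dt ~ 1/3 s, 15 shared named neurons, a three-dimensional cyclic
    latent process and 4 (or 7) cyclically ordered behavioral states.
    """

    n_individuals: int = 5
    n_neurons: int = 15
    n_timesteps: int = 3200
    latent_dim: int = 3
    n_states: int = 4
    dt: float = 1.0 / 3.0
    cycle_length: float = 150.0  # mean timesteps per full behavioral cycle
    dwell_fractions: tuple[float, ...] | None = None
    state_speeds: tuple[float, ...] | None = None
    phase_diffusion: float = 0.04  # rad per sqrt(step)
    noise_sd: float = 0.03  # observation noise on the smoothed trace
    smoothing_tau: float = 1.0  # calcium smoothing time constant, seconds
    readout_scale: float = 0.8
    readout_bias_mean: float = 2.5
    readout_bias_sd: float = 0.3
    # Fraction of readout variance shared across the population.  Identified
    # neurons keep partially conserved, "loosely related" tunings between
    # individuals; 0 makes every readout fully independent.
    readout_shared_fraction: float = 0.6

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if not 0.0 <= self.readout_shared_fraction <= 1.0:
            raise ValueError("readout_shared_fraction must be in [0, 1]")
        if self.dwell_fractions is None:
            self.dwell_fractions = (_DWELL_4 if self.n_states == 4 else
                                    _DWELL_7 if self.n_states == 7 else
                                    tuple([1.0 / self.n_states] * self.n_states))
        if self.state_speeds is None:
            self.state_speeds = (_SPEED_4 if self.n_states == 4 else
                                 _SPEED_7 if self.n_states == 7 else
                                 tuple([1.0] * self.n_states))
        if len(self.dwell_fractions) != self.n_states:
            raise ValueError("dwell_fractions must have one entry per state")
        if len(self.state_speeds) != self.n_states:
            raise ValueError("state_speeds must have one entry per state")

    @property
    def state_names(self) -> tuple[str, ...]:
        if self.n_states == 4:
            return FOUR_STATES
        if self.n_states == 7:
            return SEVEN_STATES
        return tuple(f"state_{i}" for i in range(self.n_states))

    def neuron_names(self) -> tuple[str, ...]:
        if self.n_neurons <= len(KATO_SHARED_NEURONS):
            return KATO_SHARED_NEURONS[: self.n_neurons]
        extra = tuple(f"N{i:03d}" for i in range(
            self.n_neurons - len(KATO_SHARED_NEURONS)))
        return KATO_SHARED_NEURONS + extra


def _arc_edges(cfg: SyntheticPopulationConfig) -> np.ndarray:
    """Upper phase boundaries of each state's arc on [0, 2*pi)."""
    dwell = np.asarray(cfg.dwell_fractions, dtype=np.float64)
    speed = np.asarray(cfg.state_speeds, dtype=np.float64)
    widths = dwell * speed  # dwell time ~ width / speed
    widths = widths / widths.sum() * 2.0 * np.pi
    return np.cumsum(widths)


def generate_latent_cycle(cfg: SyntheticPopulationConfig, seed: int
                          ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate the shared cyclic latent process and its state labels.

    Returns ``(latent, labels, info)`` where latent is T x latent_dim,
    labels is length T, and ``info`` flags whether all states were visited.
    Phase increments are clipped to be nonnegative so the cyclic state order
    is never traversed backwards.
    """
    rng = np.random.default_rng(seed)
    T = cfg.n_timesteps
    edges = _arc_edges(cfg)
    speeds = np.asarray(cfg.state_speeds, dtype=np.float64)
    base = 2.0 * np.pi / cfg.cycle_length
    theta = np.empty(T)
    th = rng.uniform(0.0, 2.0 * np.pi)
    noise = rng.normal(0.0, cfg.phase_diffusion, size=T)
    for t in range(T):
        theta[t] = th
        state = int(np.searchsorted(edges, th % (2.0 * np.pi), side="right"))
        state = min(state, cfg.n_states - 1)
        inc = base * speeds[state] + noise[t]
        th += max(inc, 0.0)
    wrapped = theta % (2.0 * np.pi)
    labels = np.minimum(np.searchsorted(edges, wrapped, side="right"),
                        cfg.n_states - 1).astype(np.int64)
    # harmonic embedding: (cos m*theta, sin m*theta) pairs, decaying amplitude
    cols = []
    m, amp = 1, 1.0
    while len(cols) < cfg.latent_dim:
        cols.append(amp * np.cos(m * theta))
        if len(cols) < cfg.latent_dim:
            cols.append(amp * np.sin(m * theta))
        m += 1
        amp *= 0.5
    latent = np.stack(cols[: cfg.latent_dim], axis=1)
    info = {"all_states_visited": bool(len(np.unique(labels)) == cfg.n_states)}
    return latent, labels, info


def _exp_smooth(x: np.ndarray, alpha: float) -> np.ndarray:
    out = np.empty_like(x)
    out[0] = x[0]
    for t in range(1, x.shape[0]):
        out[t] = (1.0 - alpha) * out[t - 1] + alpha * x[t]
    return out


def generate_individual(latent: np.ndarray, labels: np.ndarray,
                        cfg: SyntheticPopulationConfig, individual_seed: int,
                        individual_id: str | None = None,
                        shared_readout: np.ndarray | None = None) -> TraceSet:
    """Observe the shared latent through an individual-specific readout.

    traces = smooth(softplus(R @ latent + b)) + noise, then both channels
    are normalized to [0,1] per neuron.  The readout mixes a population-wide
    component (``shared_readout``, weight ``readout_shared_fraction``) with
    an independently drawn individual component, so neuron tunings are
    loosely related between individuals but never identical.  Without a
    ``shared_readout`` the readout is fully individual.
    """
    rng = np.random.default_rng(individual_seed)
    R_ind = rng.normal(0.0, cfg.readout_scale,
                       size=(cfg.n_neurons, latent.shape[1]))
    f = cfg.readout_shared_fraction if shared_readout is not None else 0.0
    if shared_readout is not None and shared_readout.shape != R_ind.shape:
        raise ValueError("shared_readout shape does not match (n_neurons, latent_dim)")
    R = (np.sqrt(f) * shared_readout if shared_readout is not None else 0.0) \
        + np.sqrt(1.0 - f) * R_ind
    b = rng.normal(cfg.readout_bias_mean, cfg.readout_bias_sd,
                   size=cfg.n_neurons)
    drive = latent @ R.T + b
    raw = np.logaddexp(0.0, drive)  # softplus
    alpha = 1.0 - np.exp(-cfg.dt / cfg.smoothing_tau)
    smoothed = _exp_smooth(raw, alpha)
    noisy = smoothed + rng.normal(0.0, cfg.noise_sd, size=smoothed.shape)
    ts = TraceSet(
        individual_id=individual_id or f"synthetic_{individual_seed}",
        neuron_names=cfg.neuron_names(),
        traces=noisy,
        dt=cfg.dt,
        labels=np.asarray(labels, dtype=np.int64),
        vocabulary=StateVocabulary(cfg.state_names),
    )
    return prepare_traceset(ts)


def generate_population(cfg: SyntheticPopulationConfig, master_seed: int,
                        with_ground_truth: bool = False):
    """Generate ``cfg.n_individuals`` individuals.

    Each individual gets a fresh realization of the same latent process and
    its own readout, reproducible from the master seed.  With
    ``with_ground_truth`` also returns a sidecar dict holding, per
    individual, the latent trajectory, labels and the seeds that generated
    them (for test oracles).
    """
    ss = np.random.SeedSequence(master_seed)
    shared_child, *children = ss.spawn(cfg.n_individuals + 1)
    shared_rng = np.random.default_rng(shared_child)
    shared_readout = shared_rng.normal(
        0.0, cfg.readout_scale, size=(cfg.n_neurons, cfg.latent_dim))
    population = []
    ground_truth = {"master_seed": int(master_seed), "individuals": []}
    for i, child in enumerate(children):
        lat_seed, read_seed = child.generate_state(2) >> 1  # keep below 2^31
        latent, labels, info = generate_latent_cycle(cfg, int(lat_seed))
        ts = generate_individual(latent, labels, cfg, int(read_seed),
                                 individual_id=f"worm_{i:02d}",
                                 shared_readout=shared_readout)
        population.append(ts)
        if with_ground_truth:
            ground_truth["individuals"].append({
                "id": ts.individual_id,
                "latent_seed": int(lat_seed),
                "readout_seed": int(read_seed),
                "latent": np.round(latent, 5).tolist(),
                "labels": labels.tolist(),
                **info,
            })
    if with_ground_truth:
        return population, ground_truth
    return population


# --------------------------------------------------------- coupled systems

@dataclass
class GroundTruthSystem:
    """Known coupled dynamical system used as an edge-recovery oracle.

    Update rule (``rule='tanh'``):  X_{t+1} = X_t + eps*tanh(W X_t + u) + noise
    Update rule (``rule='linear'``): X_{t+1} = X_t + eps*(W X_t + u) + noise
    """

    W: np.ndarray
    epsilon: float = 0.1
    noise_sd: float = 0.0
    drive: np.ndarray | None = None  # u; default zeros
    rule: str = "tanh"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if self.rule not in {"tanh", "linear"}:
            raise ValueError(f"unknown rule: {self.rule!r}")
        radius = np.abs(np.linalg.eigvals(self.epsilon * self.W)).max()
        if radius > 0.9 + 1e-9:
            raise ValueError(
                f"spectral radius of eps*W is {radius:.3f} > 0.9; "
                "trajectories may be unbounded"
            )
        if self.drive is not None:
            self.drive = np.asarray(self.drive, dtype=np.float64)

    @property
    def n_neurons(self) -> int:
        return self.W.shape[0]


def make_random_system(n_neurons: int = 10, density: float = 0.1,
                       seed: int = 0, epsilon: float = 0.1,
                       noise_sd: float = 0.02, self_decay: float = 1.2,
                       coupling_scale: float = 1.5) -> GroundTruthSystem:
    """Sample a sparse coupled system with an interior equilibrium.

    Off-diagonal couplings are nonzero with probability ``density`` with
    random sign; the diagonal carries self-decay so trajectories fluctuate
    around the equilibrium x* = 0.5, which the drive term places inside
    [0,1].  W is rescaled if needed to keep the spectral-radius bound.
    """
    rng = np.random.default_rng(seed)
    N = n_neurons
    mask = rng.random((N, N)) < density
    np.fill_diagonal(mask, False)
    signs = rng.choice([-1.0, 1.0], size=(N, N))
    magn = rng.uniform(0.6, 1.0, size=(N, N)) * coupling_scale
    W = np.where(mask, signs * magn, 0.0)
    np.fill_diagonal(W, -self_decay)
    radius = np.abs(np.linalg.eigvals(epsilon * W)).max()
    if radius > 0.9:
        W *= 0.9 / radius
    drive = -W @ np.full(N, 0.5)
    return GroundTruthSystem(W=W, epsilon=epsilon, noise_sd=noise_sd,
                             drive=drive, rule="tanh")


def generate_coupled_system(gt: GroundTruthSystem, T: int, seed: int,
                            x0: np.ndarray | None = None,
                            neuron_names=None, normalize: bool = True) -> TraceSet:
    """Simulate the coupled system and package it as an unlabeled TraceSet.

    Raw states are clipped to [0,1]; with ``normalize`` (default) traces and
    derivatives are then normalized per neuron like any other recording,
    otherwise the raw clipped states are returned (useful when checking the
    update rule itself).  Aborts if the trajectory becomes non-finite.
    """
    if T < 2:
        raise ValueError("need at least 2 timesteps")
    rng = np.random.default_rng(seed)
    N = gt.n_neurons
    u = gt.drive if gt.drive is not None else np.zeros(N)
    x = np.full(N, 0.5) if x0 is None else np.asarray(x0, dtype=np.float64)
    X = np.empty((T, N))
    X[0] = np.clip(x, 0.0, 1.0)
    for t in range(1, T):
        z = gt.W @ X[t - 1] + u
        inc = gt.epsilon * (np.tanh(z) if gt.rule == "tanh" else z)
        nxt = X[t - 1] + inc + rng.normal(0.0, gt.noise_sd, size=N)
        if not np.isfinite(nxt).all():
            raise RuntimeError(f"coupled system diverged at step {t}")
        X[t] = np.clip(nxt, 0.0, 1.0)
    names = (tuple(neuron_names) if neuron_names is not None
             else tuple(f"N{i:03d}" for i in range(N)))
    ts = TraceSet(individual_id=f"coupled_{seed}", neuron_names=names,
                  traces=X, dt=1.0)
    return prepare_traceset(ts) if normalize else ts
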