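# Methods

## The problem

Whole-brain calcium imaging of *C. elegans* yields, per animal, a matrix of
normalized fluorescence traces for a set of identified neurons sampled
roughly every 1/3 s, together with a per-timestep behavioral-state label
(forward crawling, reversal, dorsal/ventral turn, and finer sub-states).
Two tasks are addressed:

1. **Behavioral-state classification** — decode the state from the N×2
   node-feature slice of a *single* timestep (per-neuron trace value and
   derivative);
2. **Trajectory prediction** — forecast every neuron's trace and derivative
   over a short horizon from one initial timestep.

The scientific question behind both tasks is generalization across
individuals: neuron-level dynamics differ between animals even for
unambiguously identified neurons, so a decoder fit to one worm's neurons
typically fails on another. The models here are evaluated primarily on
*unseen* individuals.

## Models

Both tasks share one functional form, `H = f(X_t)` with `X_t ∈ R^{N×2}`.

* **Classifier head**: `p = softmax(H)`, `â = argmax p`, `H ∈ R^k`.
  Argmax ties break to the lowest state code for reproducibility.
* **Predictor head** (Markovian, residual): `X̂_{t+1} = X_t + H`,
  `H ∈ R^{N×2}`. Multi-step forecasts feed each prediction back as the next
  input.

Two families of `f`:

* **MLP** — node features are aggregated (concatenation by default;
  summation optional) and passed through a two-layer perceptron
  (`g_graph`). The model is agnostic to any graph structure.
* **Edge-inferring GNN** — a per-node perceptron `g_node: R² → R^d` embeds
  each node; for every ordered pair `(i, j)` the concatenation `(v_i, v_j)`
  passes through `g_edge` and a sigmoid, giving edge weights
  `A_ij ∈ (0,1)` (self edges included; A may be asymmetric because the
  pair is ordered). One message-passing step `M = A·X` mixes node features
  along the inferred edges, then aggregation and `g_graph` produce `H`.
  More passing steps are available behind a config flag but default to one.

Edge modes:

* `dynamic` — A is re-inferred from each timestep's features (and, during
  rollouts, from each predicted slice);
* `static` — per-timestep node embeddings are averaged over the whole
  recording, so one A is fixed per individual; on an unseen individual A is
  inferred from its recording without using labels;
* `provided` — A is supplied by the user (e.g. synapse counts from the
  physical connectome, max-normalized into [0,1]); the edge encoder is
  bypassed.

### Architecture defaults and numerical choices

The source protocol leaves the approximator's internals open. Defaults:
two-layer perceptrons with 64 hidden units and ReLU for `g_node`, `g_edge`
and `g_graph`; node embedding dimension 16; Adam with learning rate 1e-3;
200 epochs. A per-batch feature-normalization layer (learned gain/shift
after the first dense layer of `g_node` and `g_graph`) standardizes
activations with the statistics of the current batch; because training
iterates one individual at a time and evaluation passes one individual's
recording at a time, these are per-worm statistics by construction, with no
running averages. Consequently a prediction depends (weakly) on the batch
it is evaluated in; passing whole recordings is the intended use, and
single-timestep batches are degenerate for this layer.

Predictor heads zero-initialize the output layer of `g_graph`, so a fresh
residual model is exactly the persistence map `X̂_{t+1} = X_t`. This makes
the zero-model identities exact and avoids early-training rollout
divergence, since true per-step increments (~1e-2 on the [0,1] scale) are
far smaller than the output of a randomly initialized layer.

The models are implemented on a small reverse-mode automatic-
differentiation core (`wormgnn.autodiff`) operating on numpy arrays in
float64; gradients are verified against central finite differences in the
test suite. The edge encoder's first layer is evaluated as two per-node
projections broadcast-added over ordered pairs — algebraically identical to
scoring concatenated pairs, but O(N·d·h) instead of O(N²·d·h).

## Training protocols

**Dataset enlargement.** When a population is pooled, every epoch visits
the individuals one at a time (fixed input order by default; a seeded
shuffle is available) and optimizes the loss on that individual's
minibatches only, so feature-normalization statistics never mix worms.
With one individual this reduces exactly to plain training.

**Classification** minimizes softmax cross-entropy on minibatches of 256
timesteps (timesteps of one worm, shuffled per epoch). An optional
convergence stop halts training once the training-set accuracy reaches a
configured level (checked every few epochs); no validation data is used.

**Trajectory prediction** cuts each recording into windows of 8 timesteps,
uses the first timestep as the initial condition and minimizes the mean
squared error of the remaining 7 predicted steps. Scheduled sampling: at
rollout step `s` the input is the ground truth with probability `p(epoch)`,
otherwise the model's own prediction; the coin is flipped per window per
step with a seeded generator, and `p` decays linearly from 1 at the first
epoch to 0 at the last. Windows are minibatched (32 per optimizer step).

## Evaluation protocols

* **Seen population** — 10-fold cross-validation over the 8-timestep
  windows of one recording: windows are shuffled with a seeded permutation
  and dealt round-robin into folds (sizes differ by at most one); a fresh
  model trains on 9 folds and is scored on the held-out one. Mean and
  standard deviation over folds are reported.
* **Unseen individuals** — one prediction per timestep of the unseen
  recording; population accuracy averages per-individual accuracies with
  equal weight per worm. The confusion matrix is row-percentage: each row a
  labeled state, entries the percent occurrence of predicted states.
* **Trajectory** — the recording is split into non-overlapping windows of
  `horizon + 1` timesteps: one initial condition plus `horizon` targets, so
  the reported per-step MSE vector has exactly `horizon` entries (the
  16-step protocol thus consumes 17-timestep windows). MSE at step `s`
  averages over windows, neurons and both channels. The persistence
  baseline repeats the initial condition and is computed with the same
  reduction, making "zero-residual model equals persistence" an exact
  identity.
* **State-vocabulary mapping** — recordings labeled with the 7-state
  vocabulary are mapped to the 4-state vocabulary by a name-level table
  (forward slowing folds into forward crawling; the three reversal
  sub-states collapse into reverse crawling; turns map to themselves). The
  table is overridable; the default choice of where "Forward Slowing"
  lands cannot be pinned down from the source material.

## Synthetic populations

Real data for these protocols are per-animal recordings of ~3,000–4,000
timesteps; the package instead ships a generator that emulates their
statistical structure, so every protocol is testable offline.

* **Latent process** — a phase variable moves around a circle with
  state-dependent angular speed plus a small non-negative-increment
  diffusion (0.04 rad/step); behavioral states are contiguous arcs visited
  in a fixed cyclic order, mirroring the forward → reverse → turn cycle.
  Defaults: 4 states with dwell fractions (0.45, 0.30, 0.125, 0.125) and
  relative speeds (0.7, 1.0, 1.4, 1.9) — worms spend most time crawling
  forward, turns are brief and fast, and each state carries a distinct
  speed signature; ~150 timesteps per cycle (≈50 s at dt = 1/3 s). The
  latent embeds the phase with decaying harmonics (3 dimensions by
  default), so a noiseless individual's traces are ≥95% explained by three
  principal components.
* **Individuals** — `traces = smooth(softplus(R_α · latent + b_α)) + noise`
  with first-order exponential smoothing (τ = 1 s, a calcium-indicator
  proxy), observation noise sd 0.03, and per-neuron [0,1] normalization of
  traces and derivatives. The readout `R_α` mixes a population-shared
  component (fraction 0.6 of variance) with an independently drawn
  per-individual component: identified neurons keep loosely related — but
  never identical — tunings across animals. At shared fraction 0 the
  generator reproduces the dissociation the cross-individual question rests
  on: a linear decoder fit to one worm's neurons transfers to another at
  chance level on average, while the shared latent is decodable across
  worms almost perfectly.
* **Coupled systems** (ground-truth oracles for forecasting and edge
  recovery) — `X_{t+1} = clip(X_t + ε·tanh(W X_t + u) + noise)` with
  ε = 0.1, sparse random W (10% of off-diagonal entries, random sign,
  self-decay on the diagonal), drive `u = −W·0.5` placing the equilibrium
  at 0.5, spectral radius of εW capped at 0.9, process noise sd 0.02. A
  `linear` rule variant (`X_{t+1} = X_t + ε(W X_t + u) + noise`) provides
  exactly learnable linear dynamics.

What the generator does **not** emulate: real indicator kinetics and
photobleaching, recording artifacts, non-stationary behavior (e.g.
quiescence), neuron misidentification, and any biophysical coupling between
the latent cycle and single-neuron dynamics. Passing tests on this data
shows the protocols and models behave as designed under the stated
population structure — not that the accuracy levels transfer to real
recordings.

## Problem sizes used in the shipped test suite and acceptance script

Multi-seed experiments run at reduced sizes chosen once as this package's
study conditions: populations of 5 individuals with 500 timesteps each
(train 3 / evaluate 2 unseen), classifier hidden width 32 and embedding 16
at 60 epochs, predictor at 25–30 epochs, 10 master seeds for the
generalization and enlargement comparisons, 5 seeds for edge recovery
(100 epochs, teacher-forced), and the single-individual overfit check at
T = 1000 with up to 200 epochs. The acceptance script uses 3 populations
and 2 coupled systems per run. Larger recordings (the default T = 3200)
behave the same way but proportionally slower.

## Known limitations

* **Functional-edge recovery is weakly identified.** On coupled systems
  whose couplings are plainly recoverable from the data (least-squares
  regression of increments ranks true edges perfectly), the static-mode
  inferred A ranks true edges only slightly above chance (AUROC ~0.5–0.7
  depending on seed). The cause is architectural: static edges are scored
  from time-averaged per-node embeddings (marginal fingerprints, blind to
  pairwise temporal structure), and the graph-level readout is a full MLP
  over concatenated messages, so many (A, readout) factorizations achieve
  the same predictive loss and training has no reason to prefer the one
  aligned with the true couplings. Relational-inference architectures that
  do recover edges constrain the decoder to act per node through the
  sampled edges; the aggregation-plus-graph-MLP readout used here does
  not. The inferred A should therefore be read as functional, not
  structural, connectivity.
* The GNN's advantage over the MLP on unseen individuals is modest on
  synthetic populations and varies with the seed; on some draws the GNN
  finds worm-specific optima (high training accuracy, weaker transfer).
* Scheduled sampling uses a linear schedule only; no optimizer schedules,
  early stopping on validation data, or hyperparameter search.
* Recordings are assumed contiguous per individual; windows never span
  individuals, and trailing remainders shorter than one window are dropped.
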