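import numpy as np
import pytest

import wormgnn as wg
from wormgnn import (
    EdgeWeights,
    GNNModel,
    MLPModel,
    ModelConfig,
    classify,
    load_checkpoint,
    message_pass,
    predict_step,
    rollout,
    save_checkpoint,
)
from wormgnn.autodiff import Tensor


def _zero_params(model):
    for p in model.parameters():
        p.data[...] = 0.0


# ----------------------------------------------------------------- MLP

def test_mlp_zero_weights_give_zero_output(rng):
    cfg = ModelConfig(n_neurons=4, n_states=3, model_kind="mlp")
    m = MLPModel(cfg)
    _zero_params(m)
    out = m.forward(rng.random((4, 2)))
    np.testing.assert_array_equal(out.data, np.zeros(3))


def test_mlp_concat_input_width_is_two_per_neuron():
    cfg = ModelConfig(n_neurons=15, n_states=7, model_kind="mlp")
    m = MLPModel(cfg)
    assert m.g_graph.fc1.W.shape[0] == 30
    cfg_sum = ModelConfig(n_neurons=15, n_states=7, model_kind="mlp",
                          aggregation="sum")
    assert MLPModel(cfg_sum).g_graph.fc1.W.shape[0] == 2


def test_mlp_forward_deterministic_per_seed(rng):
    X = rng.random((5, 4, 2))
    cfg = ModelConfig(n_neurons=4, n_states=3, model_kind="mlp", seed=9)
    a = wg.mlp_forward(X, cfg)
    b = wg.mlp_forward(X, cfg)
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------- edge encoder

def test_zero_edge_encoder_outputs_half(rng):
    cfg = ModelConfig(n_neurons=5, model_kind="gnn")
    m = GNNModel(cfg)
    for p in m.g_edge.parameters():
        p.data[...] = 0.0
    A = m.encode_edges_tensor(Tensor(rng.random((3, 5, 2)))).data
    np.testing.assert_array_equal(A, np.full((3, 5, 5), 0.5))


def test_edge_weights_strictly_inside_unit_interval(rng):
    cfg = ModelConfig(n_neurons=6, model_kind="gnn")
    A = wg.encode_edges(rng.random((4, 6, 2)), cfg)
    assert isinstance(A, EdgeWeights)
    assert A.matrix.min() > 0.0 and A.matrix.max() < 1.0


def test_static_edges_invariant_to_timestep_permutation(rng):
    cfg = ModelConfig(n_neurons=4, model_kind="gnn", edge_mode="static")
    m = GNNModel(cfg)
    X = rng.random((5, 4, 2))
    A1 = m.encode_edges_tensor(Tensor(X)).data
    A2 = m.encode_edges_tensor(Tensor(X[[3, 1, 4, 0, 2]])).data
    np.testing.assert_allclose(A1, A2, atol=1e-12)
    assert A1.shape == (4, 4)


def test_provided_mode_bypasses_encoder(rng):
    cfg = ModelConfig(n_neurons=3, model_kind="gnn", edge_mode="provided")
    m = GNNModel(cfg)
    with pytest.raises(RuntimeError):
        m.encode_edges_tensor(Tensor(rng.random((2, 3, 2))))


# --------------------------------------------------------- message passing

def test_message_pass_identity_and_sum(rng):
    X = rng.random((4, 2))
    np.testing.assert_array_equal(message_pass(np.eye(4), X), X)
    x = rng.random((2, 2))
    M = message_pass(np.ones((2, 2)), x)
    np.testing.assert_allclose(M[0], x[0] + x[1])
    np.testing.assert_allclose(M[1], x[0] + x[1])


def test_message_pass_matches_double_loop(rng):
    A = rng.random((6, 6))
    X = rng.random((6, 2))
    oracle = np.array(
        [[sum(A[i, j] * X[j, c] for j in range(6)) for c in range(2)]
         for i in range(6)]
    )
    np.testing.assert_allclose(message_pass(A, X), oracle, atol=1e-10)
    with pytest.raises(ValueError):
        message_pass(np.eye(3), X)


def test_message_pass_repeated_steps(rng):
    A = rng.random((4, 4)) * 0.3
    X = rng.random((4, 2))
    np.testing.assert_allclose(message_pass(A, X, steps=2), A @ (A @ X))


# ------------------------------------------------------------ GNN forward

def test_gnn_zero_readout_is_zero_regardless_of_edges(rng):
    cfg = ModelConfig(n_neurons=4, n_states=3, model_kind="gnn")
    m = GNNModel(cfg)
    for p in m.g_graph.parameters():
        p.data[...] = 0.0
    out = m.forward(rng.random((4, 2)), rng.random((4, 4)))
    np.testing.assert_array_equal(out.data, np.zeros(3))


def test_gnn_identity_edges_pass_features_through(rng):
    cfg = ModelConfig(n_neurons=4, n_states=3, model_kind="gnn",
                      feature_norm=False)
    m = GNNModel(cfg)
    X = rng.random((2, 4, 2))
    out = m.forward(X, np.eye(4)).data
    direct = m.g_graph(Tensor(X.reshape(2, 8))).data
    np.testing.assert_allclose(out, direct, atol=1e-12)


def test_classifier_head_size_matches_vocabulary(rng):
    cfg = ModelConfig(n_neurons=15, n_states=7, model_kind="gnn")
    m = GNNModel(cfg)
    out = m.forward(rng.random((15, 2)), np.eye(15))
    assert out.shape == (7,)


def test_gnn_neuron_count_mismatch_raises(rng):
    cfg = ModelConfig(n_neurons=4, n_states=3, model_kind="gnn")
    m = GNNModel(cfg)
    with pytest.raises(ValueError):
        m.forward(rng.random((5, 2)), np.eye(5))
    with pytest.raises(ValueError):
        m.forward(rng.random((4, 2)), np.eye(3))


def test_gnn_with_identity_edges_and_sum_equals_mlp(rng):
    """With A = I and sum aggregation the GNN reduces to the MLP."""
    gnn_cfg = ModelConfig(n_neurons=5, n_states=4, model_kind="gnn",
                          aggregation="sum", feature_norm=False, seed=3)
    mlp_cfg = ModelConfig(n_neurons=5, n_states=4, model_kind="mlp",
                          aggregation="sum", feature_norm=False, seed=3)
    g, m = GNNModel(gnn_cfg), MLPModel(mlp_cfg)
    for pg, pm in zip(g.g_graph.parameters(), m.g_graph.parameters()):
        pg.data = pm.data.copy()
    X = rng.random((6, 5, 2))
    np.testing.assert_allclose(
        g.forward(X, np.eye(5)).data, m.forward(X).data, atol=1e-12
    )


# ------------------------------------------------------------------ heads

def test_classify_uniform_and_closed_form():
    p, a = classify(np.zeros(4))
    np.testing.assert_allclose(p, 0.25)
    assert a == 0  # tie broken toward the lowest code
    p, a = classify(np.array([1.0, 0.0]))
    np.testing.assert_allclose(p, [0.73105857863, 0.26894142137], atol=1e-9)
    assert a == 0
    with pytest.raises(ValueError):
        classify(np.array([1.0]))


def test_classify_normalized_and_shift_invariant(rng):
    H = rng.normal(size=(10, 5))
    p, _ = classify(H)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()
    p2, a2 = classify(H + 7.3)
    np.testing.assert_allclose(p, p2, atol=1e-9)


def test_predict_step_residual_update(rng):
    X = rng.random((4, 2))
    np.testing.assert_array_equal(predict_step(X, np.zeros_like(X)), X)
    np.testing.assert_allclose(
        predict_step(np.full((3, 2), 0.5), np.full((3, 2), 0.1)), 0.6
    )
    two = predict_step(predict_step(X, np.full_like(X, 0.2)), np.full_like(X, 0.2))
    np.testing.assert_allclose(two, X + 0.4)
    with pytest.raises(ValueError):
        predict_step(X, np.zeros((5, 2)))


# ---------------------------------------------------------------- rollout

def test_rollout_of_zero_model_is_constant(rng):
    cfg = ModelConfig(n_neurons=4, head="predictor", model_kind="gnn",
                      edge_mode="dynamic")
    m = GNNModel(cfg)  # predictor head: readout starts as the zero map
    X0 = rng.random((4, 2))
    seq = rollout(m, X0, n_steps=16)
    assert seq.shape == (16, 4, 2)
    for s in range(16):
        np.testing.assert_array_equal(seq[s], X0)


def test_rollout_composes_predict_steps(rng):
    cfg = ModelConfig(n_neurons=3, head="predictor", model_kind="mlp",
                      feature_norm=False, seed=1)
    m = MLPModel(cfg)
    m.g_graph.fc2.W.data = np.random.default_rng(5).normal(
        scale=0.05, size=m.g_graph.fc2.W.shape)
    X0 = rng.random((3, 2))
    seq = rollout(m, X0, n_steps=2)
    step1 = predict_step(X0, m.forward(X0).data.reshape(3, 2))
    step2 = predict_step(step1, m.forward(step1).data.reshape(3, 2))
    np.testing.assert_allclose(seq[0], step1, atol=1e-12)
    np.testing.assert_allclose(seq[1], step2, atol=1e-12)


def test_rollout_requires_fixed_adjacency_for_static(rng):
    cfg = ModelConfig(n_neurons=3, head="predictor", model_kind="gnn",
                      edge_mode="static")
    m = GNNModel(cfg)
    with pytest.raises(ValueError):
        rollout(m, rng.random((3, 2)), n_steps=2)


# -------------------------------------------------------------- checkpoints

def test_checkpoint_round_trip(tmp_path, rng):
    cfg = ModelConfig(n_neurons=4, n_states=3, model_kind="gnn", seed=11)
    m = GNNModel(cfg)
    X = rng.random((5, 4, 2))
    A = m.encode_edges_tensor(Tensor(X))
    before = m.forward(X, A).data
    path = tmp_path / "ckpt.npz"
    save_checkpoint(m, path)
    m2 = load_checkpoint(path)
    A2 = m2.encode_edges_tensor(Tensor(X))
    np.testing.assert_array_equal(m2.forward(X, A2).data, before)


def test_checkpoint_refuses_tampered_config(tmp_path):
    import json
    import numpy as np

    cfg = ModelConfig(n_neurons=4, n_states=3, model_kind="gnn")
    m = GNNModel(cfg)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(m, path)
    with np.load(path) as data:
        payload = {k: data[k] for k in data.files}
    meta = json.loads(bytes(payload["__meta__"]).decode())
    meta["config"]["hidden_width"] = 999  # stale hash
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)
    with pytest.raises(ValueError, match="hash"):
        load_checkpoint(path)
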