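import numpy as np
import pytest
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from wormgnn import (
    GroundTruthSystem,
    SyntheticPopulationConfig,
    generate_coupled_system,
    generate_individual,
    generate_latent_cycle,
    generate_population,
    make_random_system,
)


def test_latent_cycle_deterministic_and_labeled():
    cfg = SyntheticPopulationConfig(n_timesteps=1000)
    lat1, lab1, info1 = generate_latent_cycle(cfg, seed=4)
    lat2, lab2, _ = generate_latent_cycle(cfg, seed=4)
    np.testing.assert_array_equal(lat1, lat2)
    np.testing.assert_array_equal(lab1, lab2)
    assert lat1.shape == (1000, 3) and lab1.shape == (1000,)
    assert set(np.unique(lab1)) == {0, 1, 2, 3}
    assert info1["all_states_visited"]


def test_zero_diffusion_constant_speed_gives_linear_phase():
    cfg = SyntheticPopulationConfig(n_timesteps=300, phase_diffusion=0.0,
                                    state_speeds=(1.0, 1.0, 1.0, 1.0))
    lat, _, _ = generate_latent_cycle(cfg, seed=0)
    theta = np.unwrap(np.arctan2(lat[:, 1], lat[:, 0]))
    np.testing.assert_allclose(np.diff(theta), 2 * np.pi / cfg.cycle_length,
                               atol=1e-9)


def test_labels_follow_cyclic_state_order():
    """Transitions only stay in a state or advance to the next arc."""
    cfg = SyntheticPopulationConfig(n_timesteps=3000)
    _, lab, _ = generate_latent_cycle(cfg, seed=8)
    k = cfg.n_states
    trans = set(zip(lab[:-1], lab[1:]))
    allowed = {(s, s) for s in range(k)} | {(s, (s + 1) % k) for s in range(k)}
    assert trans <= allowed


def test_individual_is_deterministic_and_normalized():
    cfg = SyntheticPopulationConfig(n_timesteps=300, noise_sd=0.0)
    lat, lab, _ = generate_latent_cycle(cfg, seed=1)
    a = generate_individual(lat, lab, cfg, individual_seed=2)
    b = generate_individual(lat, lab, cfg, individual_seed=2)
    np.testing.assert_array_equal(a.traces, b.traces)
    assert a.traces.min() >= 0 and a.traces.max() <= 1
    assert a.derivatives.min() >= 0 and a.derivatives.max() <= 1
    assert a.traces.shape == (300, 15)
    np.testing.assert_array_equal(a.labels, lab)

    c = generate_individual(lat, lab, cfg, individual_seed=3)
    assert not np.allclose(a.traces, c.traces)  # different readout
    np.testing.assert_array_equal(a.labels, c.labels)  # shared latent labels


@pytest.mark.parametrize("n", [5, 21])
def test_population_sizes_mirror_the_studies(n):
    cfg = SyntheticPopulationConfig(n_individuals=n, n_timesteps=120)
    pop = generate_population(cfg, master_seed=1)
    assert len(pop) == n
    assert len({ts.individual_id for ts in pop}) == n


def test_population_reproducible_from_master_seed():
    cfg = SyntheticPopulationConfig(n_individuals=3, n_timesteps=150)
    p1 = generate_population(cfg, master_seed=9)
    p2 = generate_population(cfg, master_seed=9)
    for a, b in zip(p1, p2):
        np.testing.assert_array_equal(a.traces, b.traces)
        np.testing.assert_array_equal(a.labels, b.labels)


def test_noiseless_individual_is_three_dimensional():
    """Top-3 principal components carry >= 95% of trace variance."""
    cfg = SyntheticPopulationConfig(n_timesteps=1500, noise_sd=0.0)
    lat, lab, _ = generate_latent_cycle(cfg, seed=3)
    ts = generate_individual(lat, lab, cfg, individual_seed=4)
    ev = PCA().fit(ts.traces).explained_variance_ratio_
    assert ev[:3].sum() >= 0.95


def test_decoder_dissociation_between_neurons_and_latent():
    """With fully independent readouts a linear decoder on one worm's
    neurons transfers to another near chance, while the shared latent is
    decodable across worms — the structure cross-individual
    generalization claims rest on."""
    cfg = SyntheticPopulationConfig(n_individuals=2, n_timesteps=1000,
                                    readout_shared_fraction=0.0)
    neuron_acc, latent_acc = [], []
    for k in range(8):
        lat_a, lab_a, _ = generate_latent_cycle(cfg, 500 + k)
        lat_b, lab_b, _ = generate_latent_cycle(cfg, 600 + k)
        a = generate_individual(lat_a, lab_a, cfg, 700 + k)
        b = generate_individual(lat_b, lab_b, cfg, 800 + k)
        neuron_acc.append(
            LogisticRegression(max_iter=1000).fit(a.traces, lab_a)
            .score(b.traces, lab_b))
        latent_acc.append(
            LogisticRegression(max_iter=1000).fit(lat_a, lab_a)
            .score(lat_b, lab_b))
    assert np.mean(latent_acc) > 0.9
    assert np.mean(neuron_acc) < 0.45  # near the ~0.42 majority-class rate


# ------------------------------------------------------------ coupled systems

def test_coupled_system_zero_coupling_is_constant():
    gt = GroundTruthSystem(W=np.zeros((3, 3)), noise_sd=0.0)
    ts = generate_coupled_system(gt, T=50, seed=0, normalize=False)
    np.testing.assert_array_equal(ts.traces, 0.5)


def test_coupled_system_single_coupling_increment():
    """One step from x = (0.5, 0.5) with a single coupling w21 moves x2 by
    exactly eps * tanh(w21 * 0.5)."""
    w21 = 0.8
    W = np.array([[0.0, 0.0], [w21, 0.0]])
    gt = GroundTruthSystem(W=W, epsilon=0.1, noise_sd=0.0)
    ts = generate_coupled_system(gt, T=2, seed=0, normalize=False)
    inc = ts.traces[1] - ts.traces[0]
    assert inc[0] == 0.0
    assert inc[1] == pytest.approx(0.1 * np.tanh(w21 * 0.5), abs=1e-15)


def test_coupled_system_deterministic_and_bounded():
    gt = make_random_system(n_neurons=6, density=0.2, seed=3)
    a = generate_coupled_system(gt, T=200, seed=5)
    b = generate_coupled_system(gt, T=200, seed=5)
    np.testing.assert_array_equal(a.traces, b.traces)
    assert a.traces.min() >= 0 and a.traces.max() <= 1


def test_unstable_system_is_rejected():
    with pytest.raises(ValueError, match="spectral radius"):
        GroundTruthSystem(W=np.eye(3) * 100.0, epsilon=0.1)


def test_random_system_has_interior_equilibrium():
    gt = make_random_system(n_neurons=8, density=0.1, seed=0)
    x_star = np.full(8, 0.5)
    np.testing.assert_allclose(gt.W @ x_star + gt.drive, 0.0, atol=1e-12)
    radius = np.abs(np.linalg.eigvals(gt.epsilon * gt.W)).max()
    assert radius <= 0.9 + 1e-12
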