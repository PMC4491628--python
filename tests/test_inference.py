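import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from biomotion import (
    GaitParams, MotionModel, PatternLayer, ViewTransform, generate_motion,
    orientation_difference, random_rotation,
)
from biomotion.inference import (
    exclusiveness, perspective_gradient, prediction_error, proprio_inference_error,
)
from biomotion.patterns import WinnerRecord
from biomotion.perspective import euler_rotation_matrix
from biomotion.population import PopulationConfig, encode_all


def _random_subthreshold_directions(rng, n=12):
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d * rng.uniform(0.2, 1.0, (n, 1))


# ------------------------------------------------------------ prediction error

def test_error_is_zero_when_activation_matches_instar(rng):
    cfg = PopulationConfig(12, 8)
    act = encode_all(_random_subthreshold_directions(rng), rng.uniform(-1, 1, 8), cfg)
    layer = PatternLayer(cfg.total_dim)
    layer.instar = np.vstack([act.vector, np.zeros(cfg.total_dim)])
    layer.instar_norms = np.linalg.norm(layer.instar, axis=1)
    layer.lateral = np.full((2, 2), 0.5)
    err = prediction_error(act, layer, winner=0)
    np.testing.assert_array_equal(err.delta, 0.0)
    assert err.energy == 0.0


def test_error_energy_contracts_under_winner_training(rng):
    cfg = PopulationConfig(12, 8)
    act = encode_all(_random_subthreshold_directions(rng), rng.uniform(-1, 1, 8), cfg)
    layer = PatternLayer(cfg.total_dim, seed=1)
    layer.step(act.vector, learn=True)
    for _ in range(10):
        before = prediction_error(act, layer, winner=0).energy
        layer.train_winner(0, act.vector)
        after = prediction_error(act, layer, winner=0).energy
        assert after < before


def test_masked_slices_contribute_nothing(rng):
    gains = np.ones(20)
    gains[12:] = 0.0  # proprioception unavailable
    cfg = PopulationConfig(12, 8, gains=gains)
    act = encode_all(_random_subthreshold_directions(rng), rng.uniform(-1, 1, 8), cfg)
    layer = PatternLayer(cfg.total_dim, seed=1)
    layer.instar = np.vstack([rng.normal(size=cfg.total_dim), np.zeros(cfg.total_dim)])
    layer.instar_norms = np.linalg.norm(layer.instar, axis=1)
    layer.lateral = np.full((2, 2), 0.5)
    err = prediction_error(act, layer, winner=0)
    np.testing.assert_array_equal(err.delta[12 * 27:], 0.0)


# ------------------------------------------------------------------- gradient

def test_gradient_matches_central_finite_differences(rng):
    """The backprop gradient of 1/2 ||delta||^2 equals finite differences
    within 1e-4 relative error on random states."""
    cfg = PopulationConfig(12, 8)
    for _ in range(100):
        d = _random_subthreshold_directions(rng)
        dpro = rng.uniform(-1, 1, 8)
        mu = rng.uniform(-2, 2, 3)
        target = rng.normal(size=cfg.total_dim)
        target /= np.linalg.norm(target)

        def energy(m):
            O = encode_all(d @ euler_rotation_matrix(m).T, dpro, cfg).vector
            return 0.5 * np.sum((target - O) ** 2)

        O = encode_all(d @ euler_rotation_matrix(mu).T, dpro, cfg).vector
        grad = perspective_gradient(target - O, d, mu, cfg)
        h = 1e-6
        fd = np.array([(energy(mu + h * e) - energy(mu - h * e)) / (2 * h)
                       for e in np.eye(3)])
        np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-9)


def test_zero_error_gives_zero_gradient(rng):
    cfg = PopulationConfig(12, 8)
    grad = perspective_gradient(np.zeros(cfg.total_dim),
                                _random_subthreshold_directions(rng),
                                rng.uniform(-2, 2, 3), cfg)
    np.testing.assert_array_equal(grad, 0.0)


def test_small_rotation_offsets_produce_descent_directions(rng):
    """For a stimulus that is a slightly rotated stored pattern, a small
    step along the negative gradient reduces the error energy."""
    cfg = PopulationConfig(12, 8)
    wins = 0
    trials = 60
    for _ in range(trials):
        d = _random_subthreshold_directions(rng)
        dpro = rng.uniform(-1, 1, 8)
        target = encode_all(d, dpro, cfg).vector  # stored pattern at mu = 0
        mu = rng.uniform(-0.1, 0.1, 3)            # small offset

        def energy(m):
            O = encode_all(d @ euler_rotation_matrix(m).T, dpro, cfg).vector
            return 0.5 * np.sum((target - O) ** 2)

        O = encode_all(d @ euler_rotation_matrix(mu).T, dpro, cfg).vector
        grad = perspective_gradient(target - O, d, mu, cfg)
        if energy(mu - 1e-3 * grad) < energy(mu):
            wins += 1
    assert wins >= int(0.95 * trials)


# ------------------------------------------------------- orientation difference

def test_perfect_compensation_gives_zero_od():
    P = random_rotation(1)
    R_nu = random_rotation(2)
    R_mu = P @ R_nu.T
    assert orientation_difference(P, R_nu, R_mu) == pytest.approx(0.0, abs=1e-9)


def test_antipodal_orientations_give_pi():
    P = np.eye(3)
    R_nu = np.eye(3)
    R_mu = Rotation.from_rotvec([0, np.pi, 0]).as_matrix()
    assert orientation_difference(P, R_nu, R_mu) == pytest.approx(np.pi, abs=1e-9)


def test_od_matches_quaternion_axis_angle_oracle(rng):
    for i in range(50):
        P, R_nu, R_mu = (random_rotation(3 * i + k) for k in range(3))
        od = orientation_difference(P, R_nu, R_mu)
        expected = Rotation.from_matrix(P.T @ R_mu @ R_nu).magnitude()
        assert od == pytest.approx(expected, abs=1e-9)
        assert 0.0 <= od <= np.pi


def test_od_rejects_non_rotations():
    with pytest.raises(ValueError):
        orientation_difference(np.eye(3) * 2, np.eye(3), np.eye(3))


# --------------------------------------------------------------- exclusiveness

def test_exclusiveness_scores():
    winners = np.array([0] * 10 + [1] * 12 + [2] * 4)
    labels = np.array([3] * 10 + list(range(12)) + [0, 0, 0, 1])
    rec = WinnerRecord(winners, labels)
    scores = exclusiveness(rec)
    assert scores[0] == 1.0          # single-condition winner
    assert scores[1] == pytest.approx(1 / 12)  # uniform over 12 conditions
    assert scores[2] == pytest.approx(0.75)    # 3:1 split


def test_exclusiveness_requires_labels():
    with pytest.raises(ValueError):
        exclusiveness(WinnerRecord(np.array([0, 1])))


# --------------------------------------------------------- proprioceptive RMS

def test_proprio_rms_zero_when_prediction_matches_truth(rng):
    cfg = PopulationConfig(12, 8)
    truth = encode_all(_random_subthreshold_directions(rng), rng.uniform(-1, 1, 8), cfg).vector
    assert proprio_inference_error(truth, truth, cfg) == pytest.approx(0.0)


def test_wrong_winner_has_larger_proprio_error(walk_trained_model):
    """On a trained gait, forcing an incorrect winner increases the
    proprioceptive prediction error relative to the recognized winner."""
    model = walk_trained_model
    layer = model.layer
    seq = generate_motion("gaitA", GaitParams(seed=777), T=240)
    dvis, dpro = model.preprocess(seq)
    O = model.encode_stream(dvis, dpro)
    model.layer.reset_sequence_state()
    worse = 0
    total = 0
    trained_idx = np.flatnonzero(layer.trained)
    for t in range(60, 240, 10):
        nets = layer.net_inputs(O[t], include_lateral=False)
        nets = np.where(layer.trained, nets, -np.inf)
        best = int(np.argmax(nets))
        worst = int(trained_idx[np.argmin(nets[trained_idx])])
        e_best = proprio_inference_error(layer.instar[best], O[t], model.pop)
        e_worst = proprio_inference_error(layer.instar[worst], O[t], model.pop)
        worse += e_worst > e_best
        total += 1
    assert worse >= 0.9 * total
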