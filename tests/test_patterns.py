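import numpy as np
import pytest

from biomotion import (
    PatternLayer, free_run, gamma_from, lateral_inhibition_term, recruitment_probability,
)

DIM = 8


def _unit(rng, dim=DIM):
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


def _layer(**kw):
    kw.setdefault("seed", 0)
    return PatternLayer(DIM, **kw)


def _layer_with_trained(vectors, **kw):
    layer = _layer(**kw)
    for v in vectors:
        layer.instar = np.vstack([layer.instar[:-1], v, np.zeros(DIM)])
        layer.instar_norms = np.append(np.linalg.norm(layer.instar[:-1], axis=1), 0.0)
    P = layer.n_patterns
    layer.lateral = np.full((P, P), 0.5)
    return layer


# ---------------------------------------------------------------- gamma / law

def test_gamma_quarter_remainder_gives_half_breadth():
    assert gamma_from(0.25, 0.08) == pytest.approx(0.04)


def test_gamma_round_trips_through_the_recruitment_law():
    eps, b, theta = 0.001, 0.034, 0.5
    g = gamma_from(eps, b)
    assert recruitment_probability(theta + b, theta=theta, gamma=g) == pytest.approx(eps, abs=1e-12)
    assert recruitment_probability(theta - b, theta=theta, gamma=g) == pytest.approx(1 - eps, abs=1e-12)
    assert recruitment_probability(theta, theta=theta, gamma=g) == pytest.approx(0.5, abs=1e-15)


def test_gamma_diverges_toward_half_remainder():
    assert gamma_from(0.4999999, 1.0) > 1e5


@pytest.mark.parametrize("eps,b", [(0.0, 0.1), (0.6, 0.1), (0.1, 0.0), (0.1, -1.0)])
def test_gamma_rejects_out_of_range_arguments(eps, b):
    with pytest.raises(ValueError):
        gamma_from(eps, b)


# ----------------------------------------------------------------- net inputs

def test_net_input_is_cosine_similarity(rng):
    w = _unit(rng)
    layer = _layer_with_trained([w])
    assert layer.net_input(0, w) == pytest.approx(1.0, abs=1e-12)
    # orthogonal activation
    o = _unit(rng)
    o -= (o @ w) * w
    o /= np.linalg.norm(o)
    assert layer.net_input(0, o) == pytest.approx(0.0, abs=1e-12)
    for _ in range(50):
        a = rng.normal(size=DIM) * rng.uniform(0.2, 3)
        w2 = rng.normal(size=DIM)
        layer.instar[0] = w2
        layer.instar_norms[0] = np.linalg.norm(w2)
        expected = a @ w2 / (np.linalg.norm(a) * np.linalg.norm(w2))
        got = layer.net_input(0, a / np.linalg.norm(a))
        assert got == pytest.approx(expected, abs=1e-12)


def test_noiseless_limit_winner_is_argmax(rng):
    layer = _layer_with_trained([_unit(rng) for _ in range(4)], gamma=0.0)
    o = layer.instar[2] / np.linalg.norm(layer.instar[2])
    nets = layer.net_inputs(o)
    _, winner, _ = layer.activate(o)
    assert winner == np.argmax(nets) and winner == 2


# --------------------------------------------------------- recruitment by MC

def test_free_beats_trained_half_the_time_at_threshold(rng):
    """A stimulus exactly at the recruitment threshold spawns a new pattern
    with probability one half."""
    g = gamma_from(0.001, 0.034)
    theta = 0.5
    n = 100_000
    of = theta + g * rng.standard_cauchy(n)
    og = theta + g * rng.standard_cauchy(n)
    freq = np.mean(of >= og)
    se = np.sqrt(0.25 / n)
    assert freq == pytest.approx(0.5, abs=3 * se)


def test_empirical_recruitment_matches_closed_form_sweep(rng):
    g = gamma_from(0.05, 0.1)
    theta = 0.5
    n = 100_000
    for net_g in (0.3, 0.45, 0.5, 0.55, 0.7):
        of = theta + g * rng.standard_cauchy(n)
        og = net_g + g * rng.standard_cauchy(n)
        freq = np.mean(of >= og)
        p = recruitment_probability(net_g, theta=theta, gamma=g)
        se = max(np.sqrt(p * (1 - p) / n), 1e-4)
        assert freq == pytest.approx(p, abs=3 * se)


# ------------------------------------------------------------------ learning

def test_instar_fixed_point_and_geometric_convergence(rng):
    o = _unit(rng)
    layer = _layer_with_trained([o.copy()])
    layer.train_winner(0, o)
    np.testing.assert_allclose(layer.instar[0], o, atol=1e-12)
    layer.instar[0] = np.zeros(DIM)
    layer.instar[0][0] = 1.0
    layer.instar_norms[0] = 1.0
    for k in range(1, 30):
        layer.train_winner(0, o)
    expected = o + (1 - layer.eta) ** 29 * (np.eye(DIM)[0] - o)
    np.testing.assert_allclose(layer.instar[0], expected, atol=1e-12)


def test_free_pattern_recruited_after_a_single_update(rng):
    layer = _layer()
    assert layer.n_trained == 0 and layer.n_patterns == 1
    o = _unit(rng)
    layer.train_winner(0, o)
    assert layer.instar_norms[0] == pytest.approx(layer.eta)
    assert layer.trained[0]
    # a fresh free pattern was appended
    assert layer.n_patterns == 2 and not layer.trained[1]


def test_exactly_one_free_pattern_and_monotone_growth(rng):
    layer = _layer(seed=3)
    counts = []
    for t in range(300):
        o = _unit(rng)
        layer.step(o, learn=True)
        assert np.count_nonzero(~layer.trained) == 1
        counts.append(layer.n_patterns)
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_orthogonal_stimuli_recruit_exactly_two_patterns():
    """With theta = cos 60 deg and no noise, two alternating orthogonal
    activations force exactly two recruitments."""
    layer = _layer(gamma=1e-15)
    a, b = np.zeros(DIM), np.zeros(DIM)
    a[0] = 1.0
    b[1] = 1.0
    for _ in range(100):
        layer.step(a, learn=True)
        layer.step(b, learn=True)
    assert layer.n_trained == 2


# ----------------------------------------------------------- lateral dynamics

def test_lateral_term_anchors():
    g = gamma_from(0.001, 0.034)
    assert lateral_inhibition_term(0.5, g) == 0.0
    assert lateral_inhibition_term(0.9, g) == 0.0  # no facilitation
    assert lateral_inhibition_term(1e-12, g) == pytest.approx(-1.0, abs=1e-6)
    assert -1.0 < lateral_inhibition_term(0.2, g) < 0.0


def test_printed_form_flag_reproduces_the_historical_variant():
    g = 0.01
    w = 0.3
    assert lateral_inhibition_term(w, g, printed_form=True) == pytest.approx(
        np.tanh(-2 * g * np.tan(w * np.pi))
    )
    # the historical variant inhibits maximally at the 0.5 initialization
    assert lateral_inhibition_term(0.5, g, printed_form=True) < -0.9


def test_noise_only_transition_probability_equals_lateral_weight(rng):
    """Under noise-only drive, p(o_j > o_k) ~= w_kj."""
    g = gamma_from(0.001, 0.034)
    n = 100_000
    for w in (0.5, 0.2, 0.35):
        inh = lateral_inhibition_term(w, g)
        o_k = g * rng.standard_cauchy(n)
        o_j = inh + g * rng.standard_cauchy(n)
        freq = np.mean(o_j > o_k)
        se = np.sqrt(w * (1 - w) / n)
        assert freq == pytest.approx(w, abs=3 * se)


def test_equilibrium_lateral_update_is_zero(rng):
    layer = _layer_with_trained([_unit(rng), _unit(rng)])
    nets = np.array([0.7, 0.7, layer.theta])
    for _ in range(5):
        layer.buffer_nets(nets)
    layer.update_lateral(0)
    assert layer.lateral[0, 1] == pytest.approx(0.5)


def test_strict_alternation_drives_successor_weight_up(rng):
    a, b = np.zeros(DIM), np.zeros(DIM)
    a[0] = 1.0
    b[1] = 1.0
    layer = _layer(gamma=1e-6)
    for _ in range(40):
        layer.step(a, learn=True)
        layer.step(b, learn=True)
    ia = int(np.argmax(layer.instar[:, 0]))
    ib = int(np.argmax(layer.instar[:, 1]))
    assert layer.lateral[ia, ib] > 0.9
    assert layer.lateral[ib, ia] > 0.9
    # all other outgoing weights decay
    others = [j for j in range(layer.n_patterns) if j not in (ia, ib)]
    for j in others:
        if layer.trained[j]:
            assert layer.lateral[ia, j] < 0.5


# -------------------------------------------------------------------- free run

def test_free_run_histogram_uniform_with_untrained_laterals(rng):
    layer = _layer_with_trained([_unit(rng) for _ in range(5)], seed=9)
    rec = free_run(layer, steps=20_000, reset_sequence=True)
    hist = rec.histogram(layer.n_patterns)[:5]
    assert hist.sum() == 20_000
    np.testing.assert_allclose(hist / hist.sum(), 0.2, atol=0.02)


def test_free_run_requires_trained_patterns():
    with pytest.raises(ValueError):
        free_run(_layer(), steps=10)


# --------------------------------------------------------------- persistence

def test_snapshot_round_trip(tmp_path, rng):
    layer = _layer(seed=4)
    for _ in range(50):
        layer.step(_unit(rng), learn=True)
    path = tmp_path / "layer.npz"
    layer.save(path)
    back = PatternLayer.load(path)
    np.testing.assert_array_equal(back.instar, layer.instar)
    np.testing.assert_array_equal(back.lateral, layer.lateral)
    assert back.theta == layer.theta and back.gamma == layer.gamma
    assert back.prev_winner == layer.prev_winner
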