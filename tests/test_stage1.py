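import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biomotion import StageIConfig, StageIState, scale_and_smooth, directional_velocity
from biomotion.pipeline import MotionModel
from biomotion.synthetic import GaitParams, generate_motion

N, M = 2, 2
DIM = 3 * N + M


def _state():
    return StageIState(n_visual=N, n_proprio=M)


def test_constant_input_converges_to_alpha_x(rng):
    cfg = StageIConfig(alpha=100.0, lam=0.9)
    state = _state()
    x = rng.uniform(-1, 1, DIM)
    for _ in range(500):
        out = scale_and_smooth(x, state, cfg)
    np.testing.assert_allclose(out, cfg.alpha * x, rtol=1e-10)


def test_step_response_follows_geometric_series(rng):
    cfg = StageIConfig(alpha=50.0, lam=0.8)
    state = _state()
    scale_and_smooth(np.zeros(DIM), state, cfg)  # seed at zero
    x = rng.uniform(-1, 1, DIM)
    for k in range(1, 20):
        out = scale_and_smooth(x, state, cfg)
        np.testing.assert_allclose(out, cfg.alpha * x * (1 - cfg.lam ** k), rtol=1e-12)


def test_lam_zero_passes_scaled_input_through(rng):
    cfg = StageIConfig(alpha=7.0, lam=0.0)
    state = _state()
    scale_and_smooth(np.zeros(DIM), state, cfg)
    x = rng.uniform(-1, 1, DIM)
    np.testing.assert_allclose(scale_and_smooth(x, state, cfg), 7.0 * x)


def test_static_feature_yields_zero_direction():
    cfg = StageIConfig()
    state = _state()
    x = np.ones(DIM)
    scale_and_smooth(x, state, cfg)
    s = scale_and_smooth(x, state, cfg)
    dvis, dpro = directional_velocity(s, state)
    np.testing.assert_array_equal(dvis, 0.0)
    np.testing.assert_array_equal(dpro, 0.0)


def test_first_frame_seeding_gives_zero_initial_velocity(rng):
    cfg = StageIConfig()
    state = _state()
    s = scale_and_smooth(rng.uniform(-1, 1, DIM), state, cfg)
    dvis, dpro = directional_velocity(s, state)
    np.testing.assert_array_equal(dvis, 0.0)
    np.testing.assert_array_equal(dpro, 0.0)


@pytest.mark.parametrize("speed", [0.5, 1.0, 3.0])
def test_soft_normalization_magnitudes(speed):
    """|output| = min(|v|, 1): sub-threshold velocities pass untouched,
    larger ones are normalized to exactly 1."""
    cfg = StageIConfig(alpha=1.0, lam=0.0)
    state = _state()
    v = np.zeros(DIM)
    scale_and_smooth(v, state, cfg)
    step = np.full(DIM, speed / np.sqrt(3))
    step[3 * N:] = speed
    s = scale_and_smooth(step, state, cfg)
    dvis, dpro = directional_velocity(s, state)
    expected = min(speed, 1.0)
    np.testing.assert_allclose(np.linalg.norm(dvis, axis=-1), expected, rtol=1e-12)
    np.testing.assert_allclose(np.abs(dpro), expected, rtol=1e-12)
    if speed >= 1.0:
        np.testing.assert_allclose(np.linalg.norm(dvis, axis=-1), 1.0, rtol=1e-12)


def test_raw_velocity_of_one_over_alpha_saturates():
    """A raw feature velocity of 1/alpha is the saturation threshold."""
    cfg = StageIConfig(alpha=5000.0, lam=0.0)
    state = _state()
    x0 = np.zeros(DIM)
    scale_and_smooth(x0, state, cfg)
    x1 = x0.copy()
    x1[0] = 1.0 / cfg.alpha  # one visual coordinate moves by exactly 1/alpha
    s = scale_and_smooth(x1, state, cfg)
    dvis, _ = directional_velocity(s, state)
    assert np.linalg.norm(dvis[0]) == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_output_magnitude_always_within_unit_ball(seed):
    cfg = StageIConfig()
    state = _state()
    r = np.random.default_rng(seed)
    s = scale_and_smooth(r.normal(size=DIM) * 1e-3, state, cfg)
    for _ in range(5):
        s = scale_and_smooth(r.normal(size=DIM) * 1e-3, state, cfg)
        dvis, dpro = directional_velocity(s, state)
        assert np.all(np.linalg.norm(dvis, axis=-1) <= 1 + 1e-12)
        assert np.all(np.abs(dpro) <= 1 + 1e-12)


def test_translation_invariance_of_direction_stream():
    model = MotionModel(seed=0)
    seq = generate_motion("gaitA", GaitParams(seed=1), T=60)
    da, pa = model.preprocess(seq)
    seq.frames += np.array([5.0, -2.0, 11.0])
    db, pb = model.preprocess(seq)
    np.testing.assert_allclose(da, db, atol=1e-9)
    np.testing.assert_allclose(pa, pb, atol=1e-9)


def test_speed_covariance_for_saturated_directions():
    """Doubling playback speed (frame skipping) leaves saturated directions
    unchanged. The invariance is exact modulo the smoothing memory, which is
    counted in steps rather than seconds, so it is asserted tightly without
    smoothing and loosely at the default smoothing factor."""
    seq = generate_motion("gaitA", GaitParams(seed=2, posture_noise_sd=0.0), T=240)
    seq2 = type(seq)(seq.frames[::2], seq.sample_rate / 2, list(seq.landmark_names))

    def compare(lam):
        model = MotionModel(seed=0, params={"lam": lam})
        d1, _ = model.preprocess(seq)
        d2, _ = model.preprocess(seq2)
        n1 = np.linalg.norm(d1[::2], axis=-1)
        n2 = np.linalg.norm(d2, axis=-1)
        sat = (n1 > 0.9999) & (n2 > 0.9999)
        assert sat.mean() > 0.3
        return np.einsum("ij,ij->i", d1[::2][sat], d2[sat])

    assert np.quantile(compare(0.0), 0.05) > 0.999
    assert np.median(compare(0.95)) > 0.99


def test_pipeline_filter_matches_stepwise_api():
    """The vectorized IIR preprocessing equals the stepwise Stage I API."""
    model = MotionModel(seed=0)
    seq = generate_motion("gaitB", GaitParams(seed=3), T=40)
    dvis, dpro = model.preprocess(seq)

    from biomotion.features import extract_feature_streams

    vis, pro = extract_feature_streams(seq, model.spec)
    x = np.concatenate([vis.reshape(40, -1), pro], axis=1)
    state = StageIState(n_visual=12, n_proprio=8)
    for t in range(40):
        s = scale_and_smooth(x[t], state, model.stage1)
        dv, dp = directional_velocity(s, state)
        np.testing.assert_allclose(dv, dvis[t], atol=1e-9)
        np.testing.assert_allclose(dp, dpro[t], atol=1e-9)


def test_dimension_mismatch_raises():
    with pytest.raises(ValueError):
        scale_and_smooth(np.zeros(DIM + 1), _state(), StageIConfig())
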