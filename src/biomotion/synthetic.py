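"""Synthetic articulated periodic motion with gait-like statistics.

Real full-body motion-capture recordings are not bundled with the package;
instead, a two-level kinematic chain (torso -> upper limbs -> lower limbs,
15 landmarks) driven by sinusoidal joint angles emulates periodic
biological motion. Three motion kinds are provided that differ in cycle
frequency, amplitude pattern, and an asymmetric arm component (left/right
arms swing with different amplitude — the asymmetry is what disambiguates
a 2D-projected walker's heading):

* ``gaitA`` — walk-like: ~6 cycles per 360 frames, moderate amplitudes;
* ``gaitB`` — run-like: ~8 cycles, large hip/knee excursions;
* ``gaitC`` — dribble-like: ~5 leg cycles with a double-frequency,
  strongly asymmetric arm action.

Coordinates are right-handed with **y vertical**, x the walking direction,
z lateral. "Subjects" are emulated through per-segment morphology scaling
plus per-frame Gaussian posture-control noise on the joint angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .io import MotionSequence

__all__ = [
    "GaitParams", "ViewTransform", "generate_motion", "apply_view",
    "random_rotation", "canonical_views", "LANDMARKS", "MOTION_KINDS",
]

LANDMARKS = [
    "pelvis", "neck", "head",
    "l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_hand", "r_hand",
    "l_hip", "r_hip", "l_knee", "r_knee", "l_foot", "r_foot",
]

#: baseline segment lengths in meters (adult-scale stick body)
_SEGMENTS = {
    "torso": 0.55, "head": 0.25, "shoulder_w": 0.20, "hip_w": 0.11,
    "upper_arm": 0.30, "forearm": 0.27, "thigh": 0.44, "shank": 0.43,
}

MOTION_KINDS = ("gaitA", "gaitB", "gaitC")

# amplitude presets per kind: (cycles/360, hip, knee, arm, elbow, arm_asym,
#                              arm_freq_mult, bob, sway)
_KIND_PRESETS = {
    "gaitA": (6.0, 0.50, 0.60, 0.45, 0.35, 0.70, 1.0, 0.020, 0.05),
    "gaitB": (8.0, 0.80, 1.00, 0.60, 0.70, 0.80, 1.0, 0.050, 0.04),
    "gaitC": (5.0, 0.35, 0.45, 0.90, 0.80, 0.25, 2.0, 0.060, 0.08),
}


@dataclass
class GaitParams:
    """Generator parameters for one synthetic trial.

    ``morphology_scale`` multiplies segment lengths (scalar, or a mapping
    from segment name to multiplier) and emulates body-size differences
    between subjects; ``posture_noise_sd`` (radians) adds white Gaussian
    noise to every joint angle each frame, emulating posture-control
    variability. Identical seeds give identical output.
    """

    n_cycles_per_360_frames: float | None = None  # None -> kind preset
    joint_amplitude_scale: float = 1.0
    phase_offset: float = 0.0
    morphology_scale: float | dict[str, float] = 1.0
    posture_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.joint_amplitude_scale < 0:
            raise ValueError("joint_amplitude_scale must be >= 0")
        scales = (
            self.morphology_scale.values()
            if isinstance(self.morphology_scale, dict)
            else [self.morphology_scale]
        )
        if any(s <= 0 for s in scales):
            raise ValueError("morphology scales must be positive")
        if self.posture_noise_sd < 0:
            raise ValueError("posture_noise_sd must be >= 0")


@dataclass
class ViewTransform:
    """An exogenous view: rotation, optional 2D projection, optional mirror.

    The rotation must be orthonormal with determinant +1 (within 1e-9).
    ``project_2d`` zeroes the depth (z) coordinate, modelling a parallel
    projection onto the screen plane; ``mirror_horizontal`` negates the
    horizontal screen (x) coordinate.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    project_2d: bool = False
    mirror_horizontal: bool = False

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("rotation must be orthonormal with det = 1")
        self.rotation = R


def _seg(params: GaitParams, name: str) -> float:
    base = _SEGMENTS[name]
    ms = params.morphology_scale
    if isinstance(ms, dict):
        return base * ms.get(name, 1.0)
    return base * ms


def generate_motion(kind: str, params: GaitParams | None = None, T: int = 360,
                    sample_rate: float = 120.0) -> MotionSequence:
    """Forward-kinematic synthesis of ``T`` frames of the given motion kind."""
    if kind not in _KIND_PRESETS:
        raise ValueError(f"unknown motion kind {kind!r}; choose from {MOTION_KINDS}")
    if T < 2:
        raise ValueError("T must be >= 2")
    params = params or GaitParams()
    (cyc, a_hip, a_knee, a_arm, a_elb, asym, arm_fm, a_bob, a_sway) = _KIND_PRESETS[kind]
    if params.n_cycles_per_360_frames is not None:
        cyc = params.n_cycles_per_360_frames
    amp = params.joint_amplitude_scale
    rng = np.random.default_rng(params.seed)

    t = np.arange(T)
    w = 2.0 * np.pi * cyc / 360.0
    ph = w * t + params.phase_offset
    pha = arm_fm * w * t + params.phase_offset

    sd = params.posture_noise_sd

    def noisy(x: np.ndarray) -> np.ndarray:
        return x + rng.normal(0.0, sd, size=x.shape) if sd > 0 else x

    # joint angle time courses (radians); left/right legs in antiphase
    hip_l = noisy(amp * a_hip * np.sin(ph))
    hip_r = noisy(amp * a_hip * np.sin(ph + np.pi))
    knee_l = noisy(amp * a_knee * 0.5 * (1.0 + np.sin(ph - 0.5 * np.pi)))
    knee_r = noisy(amp * a_knee * 0.5 * (1.0 + np.sin(ph + 0.5 * np.pi)))
    # arms antiphase to ipsilateral legs; right arm scaled by the asymmetry
    sho_l = noisy(amp * a_arm * np.sin(pha + np.pi))
    sho_r = noisy(amp * a_arm * asym * np.sin(pha))
    elb_l = noisy(amp * a_elb * 0.5 * (1.0 + np.sin(pha + np.pi)))
    elb_r = noisy(amp * a_elb * asym * 0.5 * (1.0 + np.sin(pha)))
    sway = noisy(amp * a_sway * np.sin(ph))
    bob = a_bob * np.sin(2.0 * ph)

    torso = _seg(params, "torso")
    head_l = _seg(params, "head")
    sh_w = _seg(params, "shoulder_w")
    hp_w = _seg(params, "hip_w")
    ua = _seg(params, "upper_arm")
    fa = _seg(params, "forearm")
    th = _seg(params, "thigh")
    sk = _seg(params, "shank")

    def sagittal(theta: np.ndarray) -> np.ndarray:
        """Unit direction in the x-y plane: 0 -> straight down, + -> forward."""
        return np.stack([np.sin(theta), -np.cos(theta), np.zeros_like(theta)], axis=-1)

    z = np.array([0.0, 0.0, 1.0])
    pelvis = np.stack([np.zeros(T), (th + sk) * 0.98 + bob, np.zeros(T)], axis=-1)
    up = np.stack([np.zeros(T), np.cos(sway), np.sin(sway)], axis=-1)
    neck = pelvis + torso * up
    head = neck + head_l * up
    l_sho = neck - sh_w * z
    r_sho = neck + sh_w * z
    l_elbow = l_sho + ua * sagittal(sho_l)
    r_elbow = r_sho + ua * sagittal(sho_r)
    l_hand = l_elbow + fa * sagittal(sho_l + elb_l)
    r_hand = r_elbow + fa * sagittal(sho_r + elb_r)
    l_hip = pelvis - hp_w * z
    r_hip = pelvis + hp_w * z
    l_knee = l_hip + th * sagittal(hip_l)
    r_knee = r_hip + th * sagittal(hip_r)
    l_foot = l_knee + sk * sagittal(hip_l - knee_l)
    r_foot = r_knee + sk * sagittal(hip_r - knee_r)

    frames = np.stack(
        [pelvis, neck, head, l_sho, r_sho, l_elbow, r_elbow, l_hand, r_hand,
         l_hip, r_hip, l_knee, r_knee, l_foot, r_foot],
        axis=1,
    )
    return MotionSequence(frames, sample_rate, list(LANDMARKS))


def apply_view(seq: MotionSequence, view: ViewTransform) -> MotionSequence:
    """Apply an exogenous view transform to every landmark of ``seq``.

    Order: rotate, then (optionally) project to 2D by zeroing depth, then
    (optionally) mirror the horizontal coordinate. Projection and mirroring
    act on different coordinates, so their order is immaterial.
    """
    frames = seq.frames @ view.rotation.T
    if view.project_2d:
        frames = frames.copy()
        frames[..., 2] = 0.0
    if view.mirror_horizontal:
        frames = frames.copy()
        frames[..., 0] = -frames[..., 0]
    return MotionSequence(frames, seq.sample_rate, list(seq.landmark_names))


def random_rotation(seed: int | np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn Haar-uniformly from SO(3)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Rotation.random(rng=rng).as_matrix()


def rotation_about_vertical(angle: float) -> np.ndarray:
    """Rotation by ``angle`` radians about the vertical (y) axis."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def canonical_views() -> list[ViewTransform]:
    """The four training views: 0, 90, 180, 270 degrees about the vertical axis.

    Index 0 is the egocentric view, index 2 the facing view; 1 and 3 are the
    right and left profile views.
    """
    return [
        ViewTransform(rotation=rotation_about_vertical(k * np.pi / 2.0))
        for k in range(4)
    ]


def subject_params(subject: int, base: GaitParams | None = None) -> GaitParams:
    """Emulate a different 'subject' by deterministic morphology scaling.

    Subject 0 is the baseline body; other indices scale limb segments by
    +-15% in a fixed pseudo-random pattern derived from the index.
    """
    base = base or GaitParams()
    rng = np.random.default_rng(900_000 + subject)
    if subject == 0:
        return base
    scale = {name: float(1.0 + 0.15 * rng.uniform(-1, 1)) for name in _SEGMENTS}
    return replace(base, morphology_scale=scale)
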