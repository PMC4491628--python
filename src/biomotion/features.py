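"""Relative visual and angular proprioceptive body features.

The model is driven by ``N`` relative 3D positions (visual pathway) and ``M``
inter-segment angles (proprioceptive pathway) per frame. A visual feature is
the difference ``p_a - p_b`` between two landmark positions; a proprioceptive
feature is the angle between two such segment vectors, computed via the
arccos of the normalized inner product and hence confined to ``[0, pi]``.

Feature-to-input assignment is static: a :class:`BodyFeatureSpec` names the
landmark pairs and angle definitions, and can be round-tripped through YAML
as part of a run configuration. Automatic feature assignment is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import MotionSequence

__all__ = ["BodyFeatureSpec", "FeatureFrame", "extract_features", "extract_feature_streams"]

Pair = tuple[str, str]
# an angle is defined between segments (a - b) and (c - d)
AngleDef = tuple[str, str, str, str]


@dataclass
class BodyFeatureSpec:
    """Static assignment of landmarks to the model's input neurons.

    ``visual_pairs`` lists ``N`` ordered landmark pairs ``(a, b)`` defining
    the relative positions ``p_a - p_b``. ``angle_defs`` lists ``M`` angle
    definitions; each is either a triple ``(a, b, c)`` — the angle at ``b``
    between segments ``a-b`` and ``c-b`` — or a quadruple ``(a, b, c, d)``
    for the angle between segments ``a-b`` and ``c-d``.
    """

    visual_pairs: list[Pair] = field(default_factory=list)
    angle_defs: list[AngleDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.visual_pairs) < 1:
            raise ValueError("at least one visual pair is required")
        norm: list[AngleDef] = []
        for d in self.angle_defs:
            d = tuple(d)
            if len(d) == 3:  # angle at the middle landmark
                a, b, c = d
                d = (a, b, c, b)
            elif len(d) != 4:
                raise ValueError(f"angle definition must have 3 or 4 landmarks, got {d}")
            norm.append(d)
        self.angle_defs = norm

    @property
    def n_visual(self) -> int:
        return len(self.visual_pairs)

    @property
    def n_proprio(self) -> int:
        return len(self.angle_defs)

    @property
    def input_dim(self) -> int:
        """Total scalar input count, 3N + M (44 in the default configuration)."""
        return 3 * self.n_visual + self.n_proprio

    def referenced_landmarks(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.visual_pairs:
            out |= {a, b}
        for a, b, c, d in self.angle_defs:
            out |= {a, b, c, d}
        return out

    def validate_against(self, seq: MotionSequence) -> None:
        missing = self.referenced_landmarks() - set(seq.landmark_names)
        if missing:
            raise KeyError(f"feature spec references unknown landmarks: {sorted(missing)}")

    # ---- serialization -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "visual_pairs": [list(p) for p in self.visual_pairs],
            "angle_defs": [list(d) for d in self.angle_defs],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BodyFeatureSpec":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            visual_pairs=[tuple(p) for p in payload["visual_pairs"]],
            angle_defs=[tuple(d) for d in payload["angle_defs"]],
        )


@dataclass
class FeatureFrame:
    """One time step of model input: N relative positions and M angles.

    ``availability`` flags features whose value is defined this frame; an
    angle whose defining segment has zero length is flagged unavailable
    rather than raising.
    """

    visual: np.ndarray        # (N, 3)
    proprio: np.ndarray       # (M,) radians in [0, pi]
    availability: np.ndarray  # (N + M,) bool, visual features first

    def concatenated(self) -> np.ndarray:
        """Flat input vector of length 3N + M (visual first)."""
        return np.concatenate([self.visual.ravel(), self.proprio])


def _segment_angle(u: np.ndarray, v: np.ndarray) -> tuple[float, bool]:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0, False
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(c)), True


def extract_features(seq: MotionSequence, spec: BodyFeatureSpec, t: int) -> FeatureFrame:
    """Extract the model input features for frame ``t`` of ``seq``."""
    if not 0 <= t < seq.n_frames:
        raise IndexError(f"frame {t} out of range for sequence of length {seq.n_frames}")
    spec.validate_against(seq)
    idx = {name: i for i, name in enumerate(seq.landmark_names)}
    P = seq.frames[t]
    visual = np.empty((spec.n_visual, 3))
    for n, (a, b) in enumerate(spec.visual_pairs):
        visual[n] = P[idx[a]] - P[idx[b]]
    proprio = np.empty(spec.n_proprio)
    avail = np.ones(spec.n_visual + spec.n_proprio, dtype=bool)
    for m, (a, b, c, d) in enumerate(spec.angle_defs):
        ang, ok = _segment_angle(P[idx[a]] - P[idx[b]], P[idx[c]] - P[idx[d]])
        proprio[m] = ang
        avail[spec.n_visual + m] = ok
    return FeatureFrame(visual, proprio, avail)


def extract_feature_streams(seq: MotionSequence, spec: BodyFeatureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized feature extraction over all frames.

    Returns ``(visual, proprio)`` with shapes ``(T, N, 3)`` and ``(T, M)``.
    Degenerate angles (zero-length segments) are returned as 0; per-frame
    availability handling is the scalar API's job.
    """
    spec.validate_against(seq)
    idx = {name: i for i, name in enumerate(seq.landmark_names)}
    P = seq.frames  # (T, K, 3)
    ai = [idx[a] for a, _ in spec.visual_pairs]
    bi = [idx[b] for _, b in spec.visual_pairs]
    visual = P[:, ai, :] - P[:, bi, :]
    ua = [idx[a] for a, _, _, _ in spec.angle_defs]
    ub = [idx[b] for _, b, _, _ in spec.angle_defs]
    vc = [idx[c] for _, _, c, _ in spec.angle_defs]
    vd = [idx[d] for _, _, _, d in spec.angle_defs]
    U = P[:, ua, :] - P[:, ub, :]
    V = P[:, vc, :] - P[:, vd, :]
    nu = np.linalg.norm(U, axis=2)
    nv = np.linalg.norm(V, axis=2)
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(denom > 0, np.einsum("tmk,tmk->tm", U, V) / np.where(denom > 0, denom, 1.0), 1.0)
    proprio = np.arccos(np.clip(cosang, -1.0, 1.0))
    return visual, proprio


def default_feature_spec() -> BodyFeatureSpec:
    """The default N=12 / M=8 assignment for the synthetic articulated body.

    Limb-segment relative positions plus shoulder/elbow/hip/knee joint
    angles; the total input dimensionality is 44.
    """
    visual_pairs = [
        ("head", "neck"),
        ("neck", "pelvis"),
        ("l_shoulder", "neck"), ("r_shoulder", "neck"),
        ("l_elbow", "l_shoulder"), ("r_elbow", "r_shoulder"),
        ("l_hand", "l_elbow"), ("r_hand", "r_elbow"),
        ("l_knee", "l_hip"), ("r_knee", "r_hip"),
        ("l_foot", "l_knee"), ("r_foot", "r_knee"),
    ]
    angle_defs = [
        ("l_elbow", "l_shoulder", "pelvis", "neck"),   # l shoulder swing vs torso
        ("r_elbow", "r_shoulder", "pelvis", "neck"),   # r shoulder swing vs torso
        ("l_shoulder", "l_elbow", "l_hand", "l_elbow"),  # l elbow flexion
        ("r_shoulder", "r_elbow", "r_hand", "r_elbow"),  # r elbow flexion
        ("l_knee", "l_hip", "pelvis", "neck"),         # l hip swing vs torso
        ("r_knee", "r_hip", "pelvis", "neck"),         # r hip swing vs torso
        ("l_hip", "l_knee", "l_foot", "l_knee"),       # l knee flexion
        ("r_hip", "r_knee", "r_foot", "r_knee"),       # r knee flexion
    ]
    return BodyFeatureSpec(visual_pairs=visual_pairs, angle_defs=angle_defs)
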