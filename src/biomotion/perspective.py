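"""Stage Ic: adaptive Euler rotation of the visual direction stream.

All visual motion directions are rotated by a shared rotation matrix

    R_mu = R_x(mu_x) . R_y(mu_y) . R_z(mu_z)

parameterized by three adaptive angle biases. One-dimensional (angle)
features are rotation-invariant and bypass this stage. The biases are
adapted by online gradient descent with momentum on the top-down prediction
error, which implements visuo-spatial perspective-taking: the model rotates
its percept until it matches a learned frame of reference.

The matrices below follow the model's sign layout exactly (column-vector
convention); angles are unbounded — convergence is measured with the
wrap-safe orientation-difference metric, not with the raw angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PerspectiveState", "euler_rotation_matrix", "euler_rotation_derivatives",
    "rotate_visual", "update_angles",
]


def _rx(a: np.ndarray):
    c, s = np.cos(a), np.sin(a)
    o, z = np.ones_like(a), np.zeros_like(a)
    return np.stack(
        [np.stack([o, z, z], -1), np.stack([z, c, -s], -1), np.stack([z, s, c], -1)], -2
    )


def _ry(a: np.ndarray):
    c, s = np.cos(a), np.sin(a)
    o, z = np.ones_like(a), np.zeros_like(a)
    return np.stack(
        [np.stack([c, z, s], -1), np.stack([z, o, z], -1), np.stack([-s, z, c], -1)], -2
    )


def _rz(a: np.ndarray):
    c, s = np.cos(a), np.sin(a)
    o, z = np.ones_like(a), np.zeros_like(a)
    return np.stack(
        [np.stack([c, -s, z], -1), np.stack([s, c, z], -1), np.stack([z, z, o], -1)], -2
    )


def _drx(a: np.ndarray):
    c, s = np.cos(a), np.sin(a)
    z = np.zeros_like(a)
    return np.stack(
        [np.stack([z, z, z], -1), np.stack([z, -s, -c], -1), np.stack([z, c, -s], -1)], -2
    )


def _dry(a: np.ndarray):
    c, s = np.cos(a), np.sin(a)
    z = np.zeros_like(a)
    return np.stack(
        [np.stack([-s, z, c], -1), np.stack([z, z, z], -1), np.stack([-c, z, -s], -1)], -2
    )


def _drz(a: np.ndarray):
    c, s = np.cos(a), np.sin(a)
    z = np.zeros_like(a)
    return np.stack(
        [np.stack([-s, -c, z], -1), np.stack([c, -s, z], -1), np.stack([z, z, z], -1)], -2
    )


def euler_rotation_matrix(mu: np.ndarray) -> np.ndarray:
    """R_mu = R_x(mu_x) @ R_y(mu_y) @ R_z(mu_z).

    ``mu`` has shape ``(..., 3)``; the result has shape ``(..., 3, 3)``.
    """
    mu = np.asarray(mu, dtype=float)
    return _rx(mu[..., 0]) @ _ry(mu[..., 1]) @ _rz(mu[..., 2])


def euler_rotation_derivatives(mu: np.ndarray) -> np.ndarray:
    """Partial derivatives dR_mu/dmu_a, stacked on a leading axis.

    Returns shape ``(..., 3, 3, 3)`` where index ``[..., a, :, :]`` is the
    derivative with respect to angle ``a`` in (x, y, z) order.
    """
    mu = np.asarray(mu, dtype=float)
    rx, ry, rz = _rx(mu[..., 0]), _ry(mu[..., 1]), _rz(mu[..., 2])
    dx = _drx(mu[..., 0]) @ ry @ rz
    dy = rx @ _dry(mu[..., 1]) @ rz
    dz = rx @ ry @ _drz(mu[..., 2])
    return np.stack([dx, dy, dz], axis=-3)


@dataclass
class PerspectiveState:
    """The three Euler angle biases with their momentum buffers."""

    mu: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    eta_mu: float = 0.0075
    m_mu: float = 0.85

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be finite")

    @property
    def rotation(self) -> np.ndarray:
        """The derived rotation matrix R_mu (always orthonormal, det 1)."""
        return euler_rotation_matrix(self.mu)

    def reset(self) -> None:
        self.mu = np.zeros_like(self.mu)
        self.velocity = np.zeros_like(self.velocity)


def rotate_visual(directions: np.ndarray, state: PerspectiveState | np.ndarray) -> np.ndarray:
    """Rotate visual motion directions ``(..., N, 3)`` by R_mu.

    ``state`` may be a :class:`PerspectiveState` or a rotation matrix.
    Magnitudes are preserved; angle features are never passed through here.
    """
    R = state.rotation if isinstance(state, PerspectiveState) else np.asarray(state)
    return directions @ np.swapaxes(R, -1, -2)


def update_angles(state: PerspectiveState, grad: np.ndarray) -> PerspectiveState:
    """One gradient-descent-with-momentum step on the angle biases.

    velocity <- m_mu * velocity - eta_mu * grad;  mu <- mu + velocity.
    A non-finite gradient signals upstream numerical instability and raises.
    """
    grad = np.asarray(grad, dtype=float)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite perspective gradient")
    state.velocity = state.m_mu * state.velocity - state.eta_mu * grad
    state.mu = state.mu + state.velocity
    return state
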