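"""Top-down prediction error, perspective gradient, and evaluation metrics.

The recognized winner pattern's instar vector is the model's top-down
prediction of the population activation; the residual

    delta_i = w_ik - o_i

is the self-supervised error signal. Backpropagated through the population
tuning matrices (transpose of W per visual feature) and the rotation stage,
it yields the gradient of E = 1/2 ||delta||^2 with respect to the three
Euler angle biases. Two simplifications keep the backward path stable and
cheap: the Stage Ib soft-normalizer gain and the static-neuron magnitude
are treated as locally constant. Both are exact here — the rotation
preserves direction magnitudes, so neither the normalizer gain nor the
static neuron actually varies with the angles.

Metrics: the orientation difference (OD) between the model's internal
rotation composed with the exogenous rotation and a trained view — the
minimal single-axis rotation angle between the two orientations — and the
winning-exclusiveness score of a pattern over labeled test conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import PatternLayer, WinnerRecord
from .perspective import euler_rotation_derivatives
from .population import PopulationActivation, PopulationConfig

__all__ = [
    "PredictionError", "prediction_error", "perspective_gradient",
    "backprop_to_perspective", "orientation_difference", "exclusiveness",
    "proprio_inference_error",
]


def availability_mask(cfg: PopulationConfig, availability: np.ndarray) -> np.ndarray:
    """Expand a per-feature availability flag to a per-neuron mask."""
    mask = np.zeros(cfg.total_dim, dtype=bool)
    for n in range(cfg.n_features):
        mask[cfg.slice_of(n)] = availability[n]
    return mask


@dataclass
class PredictionError:
    """Instar-minus-activation residual, zeroed on unavailable slices."""

    delta: np.ndarray
    availability: np.ndarray

    @property
    def energy(self) -> float:
        return 0.5 * float(np.sum(self.delta ** 2))


def prediction_error(activation: PopulationActivation, layer: PatternLayer,
                     winner: int) -> PredictionError:
    """delta_i = w_ik - o_i for the selected winner ``k``, gain-masked."""
    cfg = activation.config
    delta = layer.instar[winner] - activation.vector
    mask = availability_mask(cfg, activation.availability)
    delta = np.where(mask, delta, 0.0)
    return PredictionError(delta=delta, availability=activation.availability)


def perspective_gradient(delta: np.ndarray, d_pre: np.ndarray, mu: np.ndarray,
                         cfg: PopulationConfig) -> np.ndarray:
    """Gradient of E = 1/2 ||delta||^2 with respect to (mu_x, mu_y, mu_z).

    ``delta`` is the (masked) prediction error of shape ``(..., total_dim)``;
    ``d_pre`` holds the *pre-rotation* visual directions ``(..., N, 3)``;
    ``mu`` the Euler biases ``(..., 3)``. Only the direction-selective
    visual slices contribute: angle features are not rotated and the static
    neurons are rotation-invariant.
    """
    delta = np.asarray(delta, dtype=float)
    lead = delta.shape[:-1]
    N = cfg.n_visual
    # visual slices are the first N blocks of 27; drop the static neuron
    dvis = delta[..., : N * 27].reshape(*lead, N, 27)[..., :26]
    # dE/d(o_dir) = -delta_dir ; chain through o_dir = W (R d)
    A = dvis @ cfg.W_visual                      # (..., N, 3) = W^T delta_dir
    dR = euler_rotation_derivatives(mu)          # (..., 3, 3, 3)
    grad = -np.einsum("...ni,...aij,...nj->...a", A, dR, d_pre)
    return grad


def backprop_to_perspective(delta: PredictionError, d_pre: np.ndarray,
                            mu: np.ndarray, cfg: PopulationConfig) -> np.ndarray:
    """Validating wrapper around :func:`perspective_gradient`."""
    grad = perspective_gradient(delta.delta, d_pre, mu, cfg)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite perspective gradient")
    return grad


def _check_rotation(R: np.ndarray, name: str) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3) or not np.allclose(
        np.swapaxes(R, -1, -2) @ R, np.eye(3), atol=1e-8
    ) or not np.allclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError(f"{name} must be a rotation matrix")
    return R


def orientation_difference(P: np.ndarray, R_nu: np.ndarray, R_mu: np.ndarray) -> float:
    """Minimal rotation angle (radians) between R_mu R_nu and the view P.

    The pipeline composes the exogenous view rotation first and the internal
    perspective rotation second, so the derived orientation is R_mu R_nu;
    the OD is the axis-angle magnitude of P^T R_mu R_nu, in [0, pi]. It is 0
    exactly when the model has internally compensated the applied rotation.
    """
    P = _check_rotation(P, "P")
    R_nu = _check_rotation(R_nu, "R_nu")
    R_mu = _check_rotation(R_mu, "R_mu")
    M = np.swapaxes(P, -1, -2) @ R_mu @ R_nu
    tr = np.trace(M, axis1=-2, axis2=-1)
    ang = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
    return float(ang) if np.ndim(ang) == 0 else ang


def exclusiveness(record: WinnerRecord, n_patterns: int | None = None) -> dict[int, float]:
    """Winning-exclusiveness per trained pattern over labeled conditions.

    For each pattern that won at least once, the score is the maximum over
    conditions of (wins during that condition) / (total wins); 1 means the
    pattern responded to a single view-dependent movement only, and the
    lower bound is 1 / n_conditions for a pattern winning equally often in
    every condition. Patterns with zero wins are excluded.
    """
    if record.labels is None:
        raise ValueError("record must carry per-step condition labels")
    winners = np.asarray(record.winners)
    labels = np.asarray(record.labels)
    out: dict[int, float] = {}
    for p in np.unique(winners):
        sel = winners == p
        total = int(np.count_nonzero(sel))
        if total == 0:
            continue
        counts = np.bincount(labels[sel])
        out[int(p)] = float(counts.max() / total)
    return out


def proprio_inference_error(winner_instar: np.ndarray, truth_vector: np.ndarray,
                            cfg: PopulationConfig) -> float:
    """RMS error of the predicted proprioceptive populations.

    Compares the winner's instar against a ground-truth activation computed
    with all gains enabled (a shadow pass), over the proprioceptive slices
    only; the RMS is taken over per-feature slice error norms.
    """
    start = cfg.n_visual * 27
    d = (np.asarray(winner_instar) - np.asarray(truth_vector))[..., start:]
    per_feat = d.reshape(*d.shape[:-1], cfg.n_proprio, 3)
    norms2 = np.sum(per_feat ** 2, axis=-1)
    return np.sqrt(np.mean(norms2, axis=-1))
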