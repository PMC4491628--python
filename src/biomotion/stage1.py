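"""Stage Ia/Ib: input scaling, exponential smoothing, normalized velocity.

Every scalar input is first multiplied by a constant gain ``alpha`` and
exponentially smoothed with update factor ``lam``:

    s(t) = lam * s(t-1) + (1 - lam) * alpha * x(t).

The per-feature velocity is the one-step difference of the smoothed signal,
grouped 3D for visual features and scalar for angle features, and then
*softly* normalized: a velocity of magnitude above 1 is scaled to length 1,
smaller velocities pass through untouched,

    d = v * min(1 / ||v||, 1),   so   ||d|| = min(||v||, 1).

The scaling alpha therefore sets the raw-velocity threshold 1/alpha above
which a feature counts as moving with a fully valid direction; below it the
direction shrinks toward zero, trading a little scale/speed invariance for
robustness against noise in near-static features. Angle-feature velocities
are plain differences (angles live in [0, pi]; no circular unwrapping).

All operations accept a leading batch dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StageIConfig", "StageIState", "scale_and_smooth", "directional_velocity"]


@dataclass
class StageIConfig:
    """Scaling and smoothing parameters (defaults: alpha=5000, lam=0.95)."""

    alpha: float = 5000.0
    lam: float = 0.95

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.lam < 1.0:
            raise ValueError("lam must lie in [0, 1)")


@dataclass
class StageIState:
    """Smoothing buffers: the last smoothed vector and the one before it.

    On the first call the buffer is seeded with the first scaled input, so
    the initial velocity is zero rather than a spurious startup transient.
    """

    n_visual: int
    n_proprio: int
    smoothed: np.ndarray | None = field(default=None)
    prev_smoothed: np.ndarray | None = field(default=None)

    @property
    def n_inputs(self) -> int:
        return 3 * self.n_visual + self.n_proprio

    def reset(self) -> None:
        self.smoothed = None
        self.prev_smoothed = None


def scale_and_smooth(x: np.ndarray, state: StageIState, cfg: StageIConfig) -> np.ndarray:
    """Advance the smoothing buffers with one input frame and return s(t).

    ``x`` is the flat input vector of length ``3N + M`` (visual triplets
    first), optionally with leading batch dimensions.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != state.n_inputs:
        raise ValueError(
            f"input has {x.shape[-1]} scalars, state expects {state.n_inputs}"
        )
    scaled = cfg.alpha * x
    if state.smoothed is None:
        new = scaled.copy()
    else:
        new = cfg.lam * state.smoothed + (1.0 - cfg.lam) * scaled
    state.prev_smoothed = state.smoothed if state.smoothed is not None else new
    state.smoothed = new
    return new


def _soft_normalize_groups(v: np.ndarray, n_visual: int, n_proprio: int):
    """Per-feature soft normalization of a flat velocity vector."""
    lead = v.shape[:-1]
    vis = v[..., : 3 * n_visual].reshape(*lead, n_visual, 3)
    pro = v[..., 3 * n_visual:]
    vnorm = np.linalg.norm(vis, axis=-1, keepdims=True)
    vgain = np.minimum(1.0 / np.where(vnorm > 0, vnorm, 1.0), 1.0)
    dvis = vis * vgain
    pnorm = np.abs(pro)
    pgain = np.minimum(1.0 / np.where(pnorm > 0, pnorm, 1.0), 1.0)
    dpro = pro * pgain
    return dvis, dpro


def directional_velocity(smoothed: np.ndarray, state: StageIState):
    """Per-feature normalized motion direction from the smoothing buffers.

    Returns ``(visual, proprio)`` with shapes ``(..., N, 3)`` and
    ``(..., M)``; each feature's magnitude is ``min(||v||, 1)``. A static
    feature yields the zero direction.
    """
    if state.prev_smoothed is None:
        raise ValueError("directional_velocity requires at least one processed frame")
    v = np.asarray(smoothed, dtype=float) - state.prev_smoothed
    return _soft_normalize_groups(v, state.n_visual, state.n_proprio)
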