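"""Stage II: direction-selective population coding with a unit-norm budget.

Each feature's motion direction (dimensionality ``D`` of 3 for visual, 1 for
angle features) is projected onto a combinatorial set of tuning vectors: all
sign patterns in ``{-1, 0, +1}^D`` except the all-zero one, each normalized
to unit length — 26 direction-selective neurons per visual feature, 2 per
angle. The tuning set is isotropic,

    W^T W = beta^2 * (3^D - 1) / D * I,

so scaling the rows by ``beta = L * sqrt(D / (3^D - 1))`` makes the
population response to any unit direction have norm exactly ``L``. A
per-feature *static* neuron tops the slice up to length ``L`` when the
direction magnitude is below 1:

    o_s = sqrt(max(0, L^2 - l^2)),   l = ||W d||.

With ``L = 1 / sqrt(N + M)`` the concatenation of all feature populations
has norm 1 whenever every feature is available — the prerequisite for the
cosine-based pattern matching of Stage III. An exogenous gain ``g_n`` in
{0, 1} multiplies a feature's whole slice and marks it unavailable when 0.

Default configuration: N=12 visual, M=8 proprioceptive features ->
12*27 + 8*3 = 348 population neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "PopulationConfig", "PopulationActivation",
    "build_tuning_matrix", "beta_for", "encode_feature", "encode_all",
]


def beta_for(D: int, L: float) -> float:
    """Row scaling that gives the population response norm L for unit input."""
    if D not in (1, 2, 3):
        raise ValueError("D must be 1, 2, or 3")
    if L <= 0:
        raise ValueError("L must be positive")
    return L * np.sqrt(D / (3.0 ** D - 1.0))


def build_tuning_matrix(D: int, beta: float) -> np.ndarray:
    """All nonzero sign patterns in {-1,0,1}^D, unit-normalized, scaled by beta.

    Shape ``(3^D - 1, D)``; each row is a neuron's preferred direction.
    """
    if D not in (1, 2, 3):
        raise ValueError("D must be 1, 2, or 3")
    rows = np.array([p for p in product((1, 0, -1), repeat=D) if any(p)], dtype=float)
    rows /= np.linalg.norm(rows, axis=1, keepdims=True)
    return beta * rows


@dataclass
class PopulationConfig:
    """Geometry and gains of the concatenated population code."""

    n_visual: int = 12
    n_proprio: int = 8
    gains: np.ndarray = field(default=None)  # (N + M,) in {0, 1}

    def __post_init__(self) -> None:
        if self.n_visual < 1 or self.n_proprio < 0:
            raise ValueError("need n_visual >= 1 and n_proprio >= 0")
        if self.gains is None:
            self.gains = np.ones(self.n_features)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (self.n_features,):
            raise ValueError("gains must have one entry per feature")
        self.L = 1.0 / np.sqrt(self.n_features)
        self.W_visual = build_tuning_matrix(3, beta_for(3, self.L))   # (26, 3)
        self.W_proprio = build_tuning_matrix(1, beta_for(1, self.L))  # (2, 1)
        # slice bookkeeping: visual slices of 27 first, then proprio slices of 3
        vis_block, pro_block = 27, 3
        self.slice_bounds: list[tuple[int, int]] = []
        off = 0
        for _ in range(self.n_visual):
            self.slice_bounds.append((off, off + vis_block))
            off += vis_block
        for _ in range(self.n_proprio):
            self.slice_bounds.append((off, off + pro_block))
            off += pro_block
        self.total_dim = off

    @property
    def n_features(self) -> int:
        return self.n_visual + self.n_proprio

    def feature_dim(self, n: int) -> int:
        return 3 if n < self.n_visual else 1

    def slice_of(self, n: int) -> slice:
        a, b = self.slice_bounds[n]
        return slice(a, b)


@dataclass
class PopulationActivation:
    """Concatenated population vector with per-feature availability."""

    vector: np.ndarray            # (..., total_dim)
    availability: np.ndarray      # (N + M,) bool
    config: PopulationConfig

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector, axis=-1))


def _check_direction(direction: np.ndarray) -> None:
    mag = np.linalg.norm(direction, axis=-1)
    if np.any(mag > 1.0 + 1e-6):
        raise ValueError(
            f"direction magnitude {float(np.max(mag)):.6f} exceeds the Stage Ib "
            "contract (<= 1)"
        )


def encode_feature(direction: np.ndarray, cfg: PopulationConfig, n: int) -> np.ndarray:
    """Population slice for feature ``n``: W d followed by the static neuron.

    ``direction`` has shape ``(..., D)`` with magnitude at most 1; the
    returned slice has norm ``L`` exactly (before the gain ``g_n``).
    """
    direction = np.atleast_1d(np.asarray(direction, dtype=float))
    _check_direction(direction)
    W = cfg.W_visual if n < cfg.n_visual else cfg.W_proprio
    o_dir = direction @ W.T
    l2 = np.sum(o_dir ** 2, axis=-1, keepdims=True)
    o_s = np.sqrt(np.maximum(0.0, cfg.L ** 2 - l2))
    return cfg.gains[n] * np.concatenate([o_dir, o_s], axis=-1)


def encode_all(visual: np.ndarray, proprio: np.ndarray, cfg: PopulationConfig,
               gains: np.ndarray | None = None) -> PopulationActivation:
    """Encode all feature directions into the concatenated population vector.

    ``visual`` has shape ``(..., N, 3)``, ``proprio`` shape ``(..., M)``.
    When all features are available and driven by unit directions the
    result has norm 1; in general the norm is sqrt(available / (N + M)).
    """
    visual = np.asarray(visual, dtype=float)
    proprio = np.asarray(proprio, dtype=float)
    if visual.shape[-2:] != (cfg.n_visual, 3):
        raise ValueError(f"visual must have shape (..., {cfg.n_visual}, 3)")
    if proprio.shape[-1] != cfg.n_proprio:
        raise ValueError(f"proprio must have shape (..., {cfg.n_proprio})")
    g = cfg.gains if gains is None else np.asarray(gains, dtype=float)
    _check_direction(visual)
    _check_direction(proprio[..., None])

    gv = g[: cfg.n_visual]
    gp = g[cfg.n_visual:]
    L2 = cfg.L ** 2

    o_vis = visual @ cfg.W_visual.T                      # (..., N, 26)
    s_vis = np.sqrt(np.maximum(0.0, L2 - np.sum(o_vis ** 2, axis=-1, keepdims=True)))
    vis_slices = np.concatenate([o_vis, s_vis], axis=-1) * gv[..., :, None]

    o_pro = proprio[..., None] @ cfg.W_proprio.T         # (..., M, 2)
    s_pro = np.sqrt(np.maximum(0.0, L2 - np.sum(o_pro ** 2, axis=-1, keepdims=True)))
    pro_slices = np.concatenate([o_pro, s_pro], axis=-1) * gp[..., :, None]

    lead = visual.shape[:-2]
    vector = np.concatenate(
        [vis_slices.reshape(*lead, -1), pro_slices.reshape(*lead, -1)], axis=-1
    )
    return PopulationActivation(vector, availability=g > 0, config=cfg)
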