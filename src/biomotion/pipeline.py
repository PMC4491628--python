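"""Assembled processing pipeline: features -> Stage I -> II -> III.

:class:`MotionModel` wires the stages together for three modes of use:

* **training** — drive the pattern layer with full sensory input at a fixed
  (identity) internal perspective while instar and lateral learning are
  enabled; the exogenous training view is applied to the data itself;
* **testing** — learning disabled; winners are recorded against condition
  labels;
* **perspective adaptation** — learning disabled, the Euler angle biases
  descend the top-down prediction error; many independent test runs are
  processed as one batch.

Stage I smoothing is an IIR filter and is applied to whole sequences with
``scipy.signal.lfilter``; only the pattern-layer recurrence is sequential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .config import DEFAULT_PARAMS
from .features import BodyFeatureSpec, default_feature_spec, extract_feature_streams
from .inference import availability_mask, perspective_gradient, orientation_difference
from .io import MotionSequence
from .patterns import PatternLayer, WinnerRecord, lateral_inhibition_term
from .perspective import PerspectiveState, euler_rotation_matrix
from .population import PopulationConfig, encode_all
from .stage1 import StageIConfig, _soft_normalize_groups
from .synthetic import ViewTransform, apply_view

__all__ = ["MotionModel", "AdaptationResult"]


@dataclass
class AdaptationResult:
    """Outcome of a batch of perspective-adaptation runs."""

    mu: np.ndarray            # (B, 3) final Euler biases
    od_min: np.ndarray        # (B, T) min-over-views OD trajectory, radians
    od_per_view: np.ndarray   # (B, n_views) final OD per trained view
    winners: np.ndarray       # (B, T) winner indices
    proprio_rms: np.ndarray | None = None  # (B, T) when a shadow pass ran

    @property
    def final_od_min(self) -> np.ndarray:
        return self.od_min[:, -1]


class MotionModel:
    """The full three-stage model with its default parameterization."""

    def __init__(self, feature_spec: BodyFeatureSpec | None = None,
                 params: dict | None = None, seed: int = 0):
        self.spec = feature_spec or default_feature_spec()
        p = dict(DEFAULT_PARAMS)
        p.update(params or {})
        self.params = p
        self.stage1 = StageIConfig(alpha=p["alpha"], lam=p["lam"])
        self.pop = PopulationConfig(self.spec.n_visual, self.spec.n_proprio)
        self.rng = np.random.default_rng(seed)
        self.layer = PatternLayer(
            self.pop.total_dim, theta=p["theta"], b=p["b"], epsilon=p["epsilon"],
            eta=p["eta"], eta_l=p["eta_l"],
            seed=np.random.default_rng(self.rng.integers(2 ** 31)),
        )
        self.perspective = PerspectiveState(eta_mu=p["eta_mu"], m_mu=p["m_mu"])

    # ------------------------------------------------------------ stage I + II
    def preprocess(self, seq: MotionSequence, view: ViewTransform | None = None):
        """Feature extraction and Stage Ia/Ib over a whole sequence.

        Returns the per-frame normalized motion directions ``(dvis, dpro)``
        of shapes ``(T, N, 3)`` and ``(T, M)``; the smoothing buffer is
        seeded with the first frame, so the first directions are zero.
        """
        if view is not None:
            seq = apply_view(seq, view)
        vis, pro = extract_feature_streams(seq, self.spec)
        T = vis.shape[0]
        x = np.concatenate([vis.reshape(T, -1), pro], axis=1)
        scaled = self.stage1.alpha * x
        lam = self.stage1.lam
        # s(t) = lam s(t-1) + (1-lam) scaled(t), seeded with scaled(0)
        zi = (lam * scaled[0])[None, :]
        smoothed, _ = lfilter([1.0 - lam], [1.0, -lam], scaled, axis=0, zi=zi)
        v = np.vstack([np.zeros((1, x.shape[1])), np.diff(smoothed, axis=0)])
        return _soft_normalize_groups(v, self.spec.n_visual, self.spec.n_proprio)

    def encode_stream(self, dvis: np.ndarray, dpro: np.ndarray,
                      gains: np.ndarray | None = None):
        """Stage II over a direction stream; returns (T, total_dim)."""
        return encode_all(dvis, dpro, self.pop, gains=gains).vector

    # ---------------------------------------------------------------- training
    def train_sequence(self, seq: MotionSequence, view: ViewTransform | None = None,
                       reset_sequence: bool = True) -> WinnerRecord:
        """Drive the pattern layer with learning enabled (identity perspective)."""
        dvis, dpro = self.preprocess(seq, view)
        O = self.encode_stream(dvis, dpro)
        if reset_sequence:
            self.layer.reset_sequence_state()
        winners = np.empty(O.shape[0], dtype=int)
        for t in range(O.shape[0]):
            winners[t] = self.layer.step(O[t], learn=True)
        return WinnerRecord(winners=winners)

    # ----------------------------------------------------------------- testing
    def test_sequence(self, seq: MotionSequence, view: ViewTransform | None = None,
                      label: int = 0, reset_sequence: bool = True) -> WinnerRecord:
        """Recognition without learning or perspective adaptation."""
        dvis, dpro = self.preprocess(seq, view)
        O = self.encode_stream(dvis, dpro)
        if reset_sequence:
            self.layer.reset_sequence_state()
        winners = np.empty(O.shape[0], dtype=int)
        for t in range(O.shape[0]):
            winners[t] = self.layer.step(O[t], learn=False)
        return WinnerRecord(winners=winners, labels=np.full(O.shape[0], label))

    # ----------------------------------------------------- perspective adaption
    def adapt_perspective(self, dvis: np.ndarray, dpro: np.ndarray,
                          R_nu: np.ndarray, views: list[np.ndarray],
                          proprio_drive: bool = True,
                          adapt: bool = True,
                          shadow_proprio: bool = False,
                          record_every: int = 1) -> AdaptationResult:
        """Batched perspective adaptation over independent test runs.

        ``dvis``/``dpro`` are *pre-internal-rotation* direction streams with
        shapes ``(B, T, N, 3)`` and ``(B, T, M)`` — the exogenous rotation
        ``R_nu`` (``(B, 3, 3)``) must already be part of the stimulus (it
        was applied to the landmark data). ``views`` are the trained view
        rotations used for the OD metric. ``proprio_drive=False`` zeroes the
        proprioceptive gains (vision-only observation); ``adapt=False``
        freezes the angle biases (negative control). With
        ``shadow_proprio=True`` a ground-truth activation with all gains
        enabled is computed alongside and the proprioceptive RMS error of
        the winner's prediction is recorded.
        """
        B, T = dvis.shape[0], dvis.shape[1]
        p = self.params
        layer = self.layer
        cfg = self.pop

        gains = np.ones(cfg.n_features)
        if not proprio_drive:
            gains[cfg.n_visual:] = 0.0
        mask = availability_mask(cfg, gains > 0)

        # ground-truth activation stream (all gains, no internal rotation bias
        # on proprio; visual truth is irrelevant for the proprio RMS metric)
        truth = None
        if shadow_proprio:
            truth = self.encode_stream(dvis, dpro)  # (B, T, dim)

        mu = np.zeros((B, 3))
        vel = np.zeros((B, 3))
        prev = np.full(B, -1, dtype=int)

        trained = layer.trained
        denom = np.maximum(layer.instar_norms, layer.r)
        Wn = layer.instar / denom[:, None]          # (P, dim) normalized instars
        inh_mat = lateral_inhibition_term(layer.lateral, layer.gamma)
        inh_mat = np.where(trained[None, :], inh_mat, 0.0)
        np.fill_diagonal(inh_mat, 0.0)
        P = layer.n_patterns
        neg_inf_free = np.where(trained, 0.0, -np.inf)

        n_rec = (T + record_every - 1) // record_every
        od_min = np.empty((B, n_rec))
        winners_rec = np.empty((B, T), dtype=int)
        rms_rec = np.empty((B, T)) if shadow_proprio else None
        views_arr = np.stack(views)                 # (V, 3, 3)

        rng = self.rng
        start = cfg.n_visual * 27

        for t in range(T):
            R = euler_rotation_matrix(mu)                       # (B, 3, 3)
            dv = np.einsum("bij,bnj->bni", R, dvis[:, t])       # rotated dirs
            O = self.encode_stream(dv, dpro[:, t], gains=gains)  # (B, dim)
            nets = Wn @ O.T                                     # (P, B)
            has_prev = prev >= 0
            if has_prev.any():
                nets[:, has_prev] += inh_mat[prev[has_prev]].T
            noisy = nets + layer.gamma * rng.standard_cauchy((P, B))
            noisy += neg_inf_free[:, None]
            w = np.argmax(noisy, axis=0)                        # (B,)
            winners_rec[:, t] = w
            prev = w

            delta = layer.instar[w] - O                         # (B, dim)
            delta[:, ~mask] = 0.0
            if adapt:
                grad = perspective_gradient(delta, dvis[:, t], mu, cfg)
                vel = p["m_mu"] * vel - p["eta_mu"] * grad
                mu = mu + vel

            if shadow_proprio:
                d = (layer.instar[w] - truth[:, t])[:, start:]
                per_feat = d.reshape(B, cfg.n_proprio, 3)
                rms_rec[:, t] = np.sqrt(np.mean(np.sum(per_feat ** 2, axis=-1), axis=-1))

            if t % record_every == 0 or t == T - 1:
                idx = min(t // record_every, n_rec - 1)
                Rt = euler_rotation_matrix(mu)
                M = np.einsum("vji,bjk,bkl->bvil", views_arr, Rt, R_nu)
                tr = np.trace(M, axis1=-2, axis2=-1)
                od = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
                od_min[:, idx] = od.min(axis=1)

        Rf = euler_rotation_matrix(mu)
        M = np.einsum("vji,bjk,bkl->bvil", views_arr, Rf, R_nu)
        tr = np.trace(M, axis1=-2, axis2=-1)
        od_final = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))

        return AdaptationResult(mu=mu, od_min=od_min, od_per_view=od_final,
                                winners=winners_rec, proprio_rms=rms_rec)

    # ------------------------------------------------------------------- misc
    def orientation_differences(self, R_nu: np.ndarray, mu: np.ndarray,
                                views: list[np.ndarray]) -> np.ndarray:
        R_mu = euler_rotation_matrix(mu)
        return np.array([orientation_difference(P, R_nu, R_mu) for P in views])
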