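"""Stage III: growing neural-noise-based clustering and sequence learning.

A dynamically growing layer of *pattern* neurons segments the stream of
population activations into motion patterns. Each pattern holds an instar
weight vector; its stimulus-driven net input is the cosine similarity
between instar and activation (the presynaptic division by
``max(||instar||, r)`` normalizes the instar; activations are unit vectors
by the Stage II norm budget). Pattern activations are Cauchy random
variables centred on the net input with scale ``gamma``; the single *free*
pattern (instar norm <= r) is centred on the recruitment threshold
``theta`` instead. The most active neuron is the *winner*; only the winner
learns (winner-takes-all instar learning), and when the free pattern wins
it is recruited to represent the novel stimulus and a fresh free pattern is
appended.

Because activation differences of two Cauchy variables are again Cauchy,
the probability that the free pattern beats the best-matching trained
pattern has the closed form

    p = 1/2 + arctan((theta - net_g) / (2 gamma)) / pi,

and ``gamma`` can be set from a recruitment remainder ``epsilon`` and
breadth ``b`` via ``gamma = tan(epsilon pi) b / 2`` so that a stimulus at
similarity ``theta + b`` spawns a new pattern with probability ``epsilon``.

Sequences are learned laterally: the previous winner ``k`` inhibits every
other trained pattern ``j`` through a weight ``w_kj`` (initialized 0.5 = no
inhibition). Under noise-only drive the inhibition term is calibrated so
that ``p(o_j > o_k)`` is approximately ``w_kj``; the weights are adapted in
batch whenever a winner transition occurs, toward the empirical probability
observed over the dwell interval. After training, the layer can *free-run*:
driven by noise and lateral inhibition alone it replays learned winner
sequences.

When learning is disabled (testing, free run) the free pattern does not
compete for the winner: recruitment is a learning event, and a free
pattern's fixed activation centre ``theta`` would otherwise outvote every
imperfectly matching trained pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PatternLayer", "WinnerRecord", "gamma_from", "recruitment_probability",
    "lateral_inhibition_term", "free_run",
]


def gamma_from(epsilon: float, b: float) -> float:
    """Cauchy noise scale from recruitment remainder ``epsilon`` and breadth ``b``."""
    if not 0.0 < epsilon <= 0.5:
        raise ValueError("epsilon must lie in (0, 0.5]")
    if b <= 0:
        raise ValueError("b must be positive")
    return np.tan(epsilon * np.pi) * b / 2.0


def recruitment_probability(net_g: np.ndarray | float, layer: "PatternLayer | None" = None,
                            *, theta: float | None = None, gamma: float | None = None):
    """Closed-form probability that the free pattern beats a trained pattern
    whose stimulus net input is ``net_g``."""
    if layer is not None:
        theta, gamma = layer.theta, layer.gamma
    if theta is None or gamma is None:
        raise ValueError("provide a layer or explicit theta and gamma")
    return 0.5 + np.arctan((theta - np.asarray(net_g, dtype=float)) / (2.0 * gamma)) / np.pi


def lateral_inhibition_term(w: np.ndarray | float, gamma: float,
                            printed_form: bool = False) -> np.ndarray | float:
    """Lateral inhibition in (-1, 0] exerted by the previous winner.

    For ``w < 0.5`` the term is ``tanh(2 gamma tan((w - 1/2) pi))``; weights
    at or above the 0.5 initialization exert no inhibition (and no
    facilitation). ``printed_form=True`` selects the historical variant
    ``tanh(-2 gamma tan(w pi))``, kept for comparison only: it is maximally
    inhibitory at w = 0.5 and does not satisfy the no-input transition
    contract.
    """
    w = np.asarray(w, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("lateral weights must lie in [0, 1]")
    if printed_form:
        return np.tanh(-2.0 * gamma * np.tan(w * np.pi))
    out = np.where(
        w < 0.5,
        np.tanh(2.0 * gamma * np.tan(np.clip(w - 0.5, -0.5 + 1e-300, 0.0) * np.pi)),
        0.0,
    )
    return out if out.ndim else float(out)


@dataclass
class WinnerRecord:
    """Per-step winner indices with optional condition labels."""

    winners: np.ndarray
    labels: np.ndarray | None = None

    def histogram(self, n_patterns: int) -> np.ndarray:
        return np.bincount(self.winners, minlength=n_patterns)

    def transitions(self) -> np.ndarray:
        """Indices t where the winner changed relative to t - 1."""
        w = self.winners
        return np.flatnonzero(w[1:] != w[:-1]) + 1


class PatternLayer:
    """Growing pattern layer with noise-based recruitment and lateral weights.

    Parameters follow the model defaults: ``theta = cos 60 deg``,
    ``b = 0.034``, ``epsilon = 0.001``, instar rate ``eta = 0.01``, lateral
    rate ``eta_l = 0.6``. The free/trained threshold ``r`` defaults to
    ``eta / 2`` (any value in (0, eta) works; a single instar update of a
    free pattern on a unit activation reaches norm ``eta > r`` and converts
    it to a trained pattern).
    """

    def __init__(self, dim: int, *, theta: float | None = None, b: float = 0.034,
                 epsilon: float = 0.001, eta: float = 0.01, eta_l: float = 0.6,
                 r: float | None = None, gamma: float | None = None,
                 seed: int | np.random.Generator = 0):
        self.dim = int(dim)
        self.theta = float(np.cos(np.pi / 3.0)) if theta is None else float(theta)
        self.b = float(b)
        self.epsilon = float(epsilon)
        self.gamma = gamma_from(epsilon, b) if gamma is None else float(gamma)
        self.eta = float(eta)
        self.r = eta / 2.0 if r is None else float(r)
        if not 0.0 < self.r < self.eta:
            raise ValueError("need 0 < r < eta so one update recruits a free pattern")
        self.eta_l = float(eta_l)
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

        self.instar = np.zeros((1, self.dim))
        self.instar_norms = np.zeros(1)
        self.lateral = np.full((1, 1), 0.5)
        self.prev_winner: int | None = None
        self._net_buffer: list[np.ndarray] = []

    # ------------------------------------------------------------------ state
    @property
    def n_patterns(self) -> int:
        return self.instar.shape[0]

    @property
    def trained(self) -> np.ndarray:
        """Boolean mask of trained patterns (instar norm > r)."""
        return self.instar_norms > self.r

    @property
    def n_trained(self) -> int:
        return int(np.count_nonzero(self.trained))

    @property
    def free_index(self) -> int:
        """Index of the single free pattern (always the last one)."""
        return self.n_patterns - 1

    def reset_sequence_state(self) -> None:
        """Forget the previous winner and the transition buffer (trial start)."""
        self.prev_winner = None
        self._net_buffer = []

    # ------------------------------------------------------------- net inputs
    def net_inputs(self, activation: np.ndarray, include_lateral: bool = True) -> np.ndarray:
        """Net input per pattern: cosine to the instar plus lateral inhibition.

        The free pattern's slot carries its activation centre ``theta`` (it
        has no stimulus-driven net input).
        """
        o = np.asarray(activation, dtype=float)
        denom = np.maximum(self.instar_norms, self.r)
        nets = (self.instar @ o) / denom
        nets[~self.trained] = self.theta
        if include_lateral and self.prev_winner is not None:
            k = self.prev_winner
            inh = lateral_inhibition_term(self.lateral[k], self.gamma)
            inh = np.where(self.trained, inh, 0.0)
            inh[k] = 0.0
            nets = nets + inh
        return nets

    def net_input(self, j: int, activation: np.ndarray, include_lateral: bool = True) -> float:
        return float(self.net_inputs(activation, include_lateral)[j])

    # -------------------------------------------------------------- activation
    def activate(self, activation: np.ndarray):
        """Noisy pattern outputs and the winner index (training-mode rules:
        the free pattern competes, centred on theta)."""
        nets = self.net_inputs(activation)
        outputs = nets + self.gamma * self.rng.standard_cauchy(self.n_patterns)
        return outputs, int(np.argmax(outputs)), nets

    def winner_no_learning(self, nets: np.ndarray) -> int:
        """Winner restricted to trained patterns (testing / free-run mode)."""
        if self.n_trained == 0:
            raise ValueError("no trained patterns; run training first")
        outputs = nets + self.gamma * self.rng.standard_cauchy(self.n_patterns)
        outputs = np.where(self.trained, outputs, -np.inf)
        return int(np.argmax(outputs))

    # ---------------------------------------------------------------- learning
    def train_winner(self, winner: int, activation: np.ndarray) -> None:
        """Instar update of the winner; recruit if it was the free pattern."""
        was_free = not self.trained[winner]
        o = np.asarray(activation, dtype=float)
        self.instar[winner] += self.eta * (o - self.instar[winner])
        self.instar_norms[winner] = np.linalg.norm(self.instar[winner])
        if was_free and self.instar_norms[winner] > self.r:
            self._append_free_pattern()

    def _append_free_pattern(self) -> None:
        self.instar = np.vstack([self.instar, np.zeros(self.dim)])
        self.instar_norms = np.append(self.instar_norms, 0.0)
        P = self.n_patterns
        lat = np.full((P, P), 0.5)
        lat[: P - 1, : P - 1] = self.lateral
        self.lateral = lat

    def buffer_nets(self, nets: np.ndarray) -> None:
        self._net_buffer.append(np.asarray(nets, dtype=float))

    def update_lateral(self, k: int) -> None:
        """Batch lateral update of the outgoing weights of pattern ``k``
        after a winner transition, from the buffered net inputs."""
        if not self._net_buffer or k is None:
            self._net_buffer = []
            return
        P = self.n_patterns
        T = len(self._net_buffer)
        mat = np.full((T, P), self.theta)
        for t, row in enumerate(self._net_buffer):
            mat[t, : row.shape[0]] = row
        p = 0.5 + np.arctan((mat - mat[:, [k]]) / (2.0 * self.gamma)) / np.pi
        p_bar = p.mean(axis=0)
        targets = self.trained.copy()
        targets[k] = False
        self.lateral[k, targets] += self.eta_l * (p_bar[targets] - self.lateral[k, targets])
        np.clip(self.lateral[k], 0.0, 1.0, out=self.lateral[k])
        self._net_buffer = []

    # ------------------------------------------------------------------- step
    def step(self, activation: np.ndarray, learn: bool = True) -> int:
        """One full time step: winner selection, sequence bookkeeping, learning."""
        if learn:
            nets = self.net_inputs(activation)
            outputs = nets + self.gamma * self.rng.standard_cauchy(self.n_patterns)
            winner = int(np.argmax(outputs))
            # the batch window runs from the step after the previous transition
            # through the current transition step, so the averaged probability
            # approximates the per-step chance of leaving the dwelling winner
            self.buffer_nets(nets)
            if self.prev_winner is not None and winner != self.prev_winner:
                self.update_lateral(self.prev_winner)
            self.train_winner(winner, activation)
        else:
            nets = self.net_inputs(activation)
            winner = self.winner_no_learning(nets)
        self.prev_winner = winner
        return winner

    # ---------------------------------------------------------- serialization
    def save(self, path: str | Path) -> None:
        """Snapshot instar, lateral weights, parameters, and counters (.npz)."""
        np.savez(
            path,
            instar=self.instar,
            lateral=self.lateral,
            params=np.array([self.theta, self.b, self.epsilon, self.gamma,
                             self.eta, self.eta_l, self.r]),
            prev_winner=np.array(-1 if self.prev_winner is None else self.prev_winner),
        )

    @classmethod
    def load(cls, path: str | Path, seed: int | np.random.Generator = 0) -> "PatternLayer":
        data = np.load(path)
        theta, b, epsilon, gamma, eta, eta_l, r = data["params"]
        layer = cls(dim=data["instar"].shape[1], theta=theta, b=b, epsilon=epsilon,
                    eta=eta, eta_l=eta_l, r=r, gamma=gamma, seed=seed)
        layer.instar = data["instar"]
        layer.instar_norms = np.linalg.norm(layer.instar, axis=1)
        layer.lateral = data["lateral"]
        pw = int(data["prev_winner"])
        layer.prev_winner = None if pw < 0 else pw
        return layer


def free_run(layer: PatternLayer, steps: int, reset_sequence: bool = False) -> WinnerRecord:
    """Drive the layer by noise and lateral inhibition alone (all gains 0).

    No instar or lateral learning takes place, and the free pattern does not
    compete. Returns the winner sequence; with untrained lateral weights the
    histogram is uniform over trained patterns, after cyclic training the
    trained winner cycle is replayed.
    """
    if reset_sequence:
        layer.reset_sequence_state()
    zero = np.zeros(layer.dim)
    winners = np.empty(steps, dtype=int)
    for t in range(steps):
        winners[t] = layer.step(zero, learn=False)
    return WinnerRecord(winners=winners)
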