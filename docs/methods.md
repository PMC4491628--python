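# Methods

This note documents the model as implemented, the choices made where the
design was genuinely open, what the synthetic stimuli do and do not emulate,
and the numerical details a user should know before trusting or extending
the results.

## Model summary and assumptions

The model assumes that (i) bodily landmarks have already been identified and
assigned to fixed network inputs (no automatic feature assignment), (ii)
depth is available during learning (the 2D-projection experiments probe what
happens when it is not at test time), and (iii) recognition can rely on
relative *motion* alone — posture and form are not used. Feature selection
is static: a `BodyFeatureSpec` names 12 ordered landmark pairs (relative
positions, visual pathway) and 8 segment-pair angles (proprioceptive
pathway). Angles are computed by `arccos` of the normalized inner product
and live in `[0, π]`; their velocities are plain differences (no circular
unwrapping — angles cannot wrap). A degenerate angle (zero-length segment)
is flagged unavailable rather than raising.

Coordinates are right-handed with y vertical; the four canonical training
views are rotations about the vertical axis by 0°, 90°, 180°, 270°
(egocentric, right, facing, left). The coordinate convention is declared in
the generator, not baked into the stage mathematics.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 5000 | input scaling; 1/α is the raw-velocity saturation threshold (length units per frame) |
| λ | 0.95 | exponential smoothing factor per 120 Hz frame |
| η | 0.01 | instar (pattern) learning rate |
| θ | cos 60° | recruitment threshold on cosine similarity |
| b, ε | 0.034, 0.001 | recruitment breadth and remainder; γ = tan(επ)·b/2 ≈ 5.34·10⁻⁵ |
| η_l | 0.6 | lateral (transition) learning rate per transition event |
| η_μ, m_μ | 0.0075, 0.85 | perspective gradient-descent rate and momentum |
| r | η/2 | free/trained instar-norm threshold (any 0 < r < η works: one update of a free pattern on a unit activation reaches norm η) |
| L | 1/√(N+M) | per-feature population norm budget (1/√20 by default) |

## Numerical and design choices

* **Stage Ib soft normalization** uses gain `min(1/‖v‖, 1)` per feature, so
  `‖d‖ = min(‖v‖, 1)`: only features moving faster than 1/α in raw units
  are normalized to unit length; slower features shrink toward zero, which
  protects the direction code from noise at near-zero velocity at a small
  cost in scale/speed invariance.
* **Smoothing seed.** The smoothing buffer is seeded with the first scaled
  input, so the first velocity is zero and no startup transient is encoded.
* **Population scaling.** The combinatorial tuning set (all nonzero sign
  patterns of `{−1,0,1}^D`, unit-normalized) is isotropic:
  `WᵀW = β²(3^D−1)/D · I`. Hence `β = L·√(D/(3^D−1))` is the unique row
  scaling for which any unit direction elicits a response of norm exactly
  `L`, and the static neuron `o_s = √(max(0, L² − l²))` (clipped against
  rounding when `l ≈ L`) tops every available slice up to `L`. With
  `L = 1/√(N+M)` the concatenation is a unit vector whenever all features
  are available — the property the cosine-based pattern matching relies on.
  No rectification is applied to negative projections; cosine matching
  tolerates signed codes.
* **Lateral inhibition transfer.** The inhibition exerted by the previous
  winner through a lateral weight `w` is `tanh(2γ·tan((w−½)π))` for
  `w < 0.5` and exactly 0 otherwise (no facilitation; the term stays in
  `(−1, 0]`). This satisfies both calibration anchors: no inhibition at the
  0.5 initialization, and a noise-only transition probability
  `p(o_j > o_k) ≈ w` (exact up to the tanh clamp, which only bites for
  `w ≲ γ`). A historical variant `tanh(−2γ·tan(wπ))` is available behind
  `printed_form=True` for comparison; it is maximally inhibitory at
  `w = 0.5` and fails both anchors.
* **Transition batch window.** The lateral batch update at a winner
  transition averages over the net inputs buffered from the step after the
  previous transition *through the transition step itself*. The averaged
  probability then approximates the per-step chance of leaving the dwelling
  winner (≈ 1/dwell for the true successor, ≈ 0 for others), which is what
  makes free-run replay reproduce not only the order but also roughly the
  tempo of a learned sequence. Buffered nets include the lateral term that
  was active at the time; the free pattern is excluded from updates.
* **Free pattern outside learning.** Recruitment is a learning event, so
  when learning is disabled (testing, free run) the free pattern does not
  compete for the winner; otherwise its fixed activation centre θ would
  outvote every imperfectly matching trained pattern. During training it
  competes exactly as specified. Free-run mode disables all learning.
* **Winner ties** go to the lowest index (a measure-zero event under Cauchy
  noise). Each layer owns a single seeded generator.
* **Backprop simplifications.** The gradient of `½‖δ‖²` with respect to the
  Euler biases treats the Stage Ib normalizer gain and the static-neuron
  magnitude as locally constant. Both are exact here: the rotation sits
  downstream of the normalization and preserves magnitudes, so neither
  quantity varies with μ (the static neuron's analytic μ-gradient is
  identically zero). Finite-difference tests hold at 10⁻⁴ relative error.
  A corollary: when the free pattern would win (zero instar), the gradient
  is exactly zero — the perspective only moves on the word of a trained
  pattern.
* **Orientation difference.** `OD_i = arccos((tr(P_iᵀ R_μ R_ν) − 1)/2)`,
  clipped into the arccos domain. The composition order follows the
  pipeline: the exogenous rotation `R_ν` acts on the data first, the
  internal `R_μ` second, so the derived orientation is `R_μR_ν`. The Euler
  biases themselves are unbounded; OD is the wrap-safe convergence measure.
  μ is reset to zero at each test trial start (configurable by simply not
  resetting the state).

## Synthetic stimuli

The generator is a two-level kinematic chain (torso → arms, legs; 15
landmarks) driven by sinusoidal joint angles — the smallest structure that
exercises every feature type of the default N=12/M=8 assignment. Three
kinds differ in cycle frequency (6, 8, 5 cycles per 360 frames at 120 Hz),
amplitude pattern, and arm asymmetry; the dribble-like kind adds a
double-frequency arm action. The left/right arm asymmetry is what makes the
heading of a 2D-projected walker recoverable, and mirroring a projected
walker therefore flips the recognized heading. "Subjects" are emulated by
±15% per-segment morphology scaling plus white Gaussian posture-control
noise on every joint angle (default SD 0.02 rad — small, trial-to-trial
postural variability; it is the free knob controlling residual orientation
variance after convergence). Identical seeds give identical stimuli.

What the generator does **not** emulate: ground contact and biomechanical
dynamics, soft-tissue marker artefacts, non-periodic movement segments, and
the idiosyncratic coordination patterns of real actors. Passing tests
therefore show that the architecture learns, segments, sequences, and
re-orients periodic articulated motion with realistic variability — not
that it reaches any particular accuracy on real motion-capture recordings.

## Experiment scales

Experiments run at desk scale: the single-motion study presents one trial
(360 frames) twenty times; the multi-view studies train 3 kinds × 4 views ×
20 repetitions; the random-view study tests 50 independent Haar-uniform
rotations (5000 adaptation steps each, batched across runs) against the
35° success criterion. The full suite runs in well under a minute on one
core; `RunConfig` and the experiment arguments restore larger scales.
Motion files are read and written as TRC or a documented whitespace tabular
dialect; C3D is binary and intentionally out of scope.

## Known limitations

* Perspective adaptation handles orientation only; scale/zoom and speed are
  not adapted online (α is fixed).
* Angle features stand in for proprioception during observation (they are
  computable from vision and rotation-invariant); true efferent signals are
  not modelled. With vision-only drive the residual proprioceptive RMS
  error converges but stays somewhat above the full-drive level, because
  winner selection then ignores the proprioceptive slices entirely.
* The winner-cycle comparison between driven and free-run operation uses a
  majority-smoothed, dominant-successor cycle: two patterns encoding
  overlapping trajectory segments can flutter at hand-over, and a pattern
  may be skipped on a given traversal, so equivalence is asserted on the
  cyclic order of shared patterns.
* Pattern growth never prunes or merges; long heterogeneous training
  schedules grow a few hundred patterns.
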