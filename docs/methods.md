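# Methods

## Model

A growth-transform (GT) neuron carries a membrane potential `v` bounded
by `|v| ≤ v_c` (threshold at 0) and minimizes the power functional
`H(v) = ½ Q_self v² − b v + Ψ v`.  The barrier spike function
`Ψ(v) = I_Ψ` for `v > 0` and 0 otherwise enforces the complementary
slackness of the threshold constraint at every instant; its temporal
mean is the KKT multiplier and plays the role of a firing rate.  `I_Ψ`
(the hyperpolarization parameter) sets the post-spike reset strength and
hence the maximum firing rate; `v_c` only needs to be large enough to
contain the operating range.

Dynamics are realized as the discrete growth-transform map

    v ← v_c · (−g·v_c + λ·v) / (−g·v + λ·v_c),     g = ∂H/∂v,

one application per time step.  The map is bounded by construction
(`|v| ≤ v_c` exactly, at every step) and descends `H` whenever
`λ > |g|`.  `λ` is chosen adaptively per step as
`max(λ_floor, λ_margin·maxᵢ|gᵢ|)` shared across the neurons of a
simulation, which keeps the descent condition satisfied as synaptic
weights grow during learning while remaining fully deterministic.

An ON-OFF pair receives `+b` and `−b`; within a pair there are no
synapses (enforced structurally).  Pairs couple through the off-diagonal
entries of `Q` acting on the differential potentials `vⱼ⁺ − vⱼ⁻`.  At
steady state the network satisfies `Q v̄ = b`, each pair is orthogonal
(`v̄⁺ v̄⁻ = 0`), and total firing equals `‖v̄‖₁` (with `Q_ii = 1`).

## Integration accuracy and the fractional-step mode

The plain map (one full application per step) reproduces the isolated
pair's steady state *exactly* (e.g. `b = 0.5` gives a period-2 cycle
with duty 1/2: `Ψ̄⁺ = 0.5`, `v̄⁺ = 0`).  In coupled networks, however,
the map's finite step size leaves an O(step) bias in the temporal means.
The fractional-step mode `v ← (1−α)v + α·map(v)` shrinks this bias
linearly in `α`:

* `α = 1` (default): fastest; adequate wherever only the fixed point or
  spike counts matter.
* `α = 0.1` with windows of a few hundred steps: the configuration used
  inside training loops; steady-state means are accurate to a few
  percent, which the mean-based learning rule tolerates.
* `NeuronConfig.fine()` (`α = 0.01`, 10 000 settling steps): used when
  the *values* of the means are asserted; the ON-OFF identities then
  hold to ~2·10⁻³ (orthogonality products below tol² = 2.5·10⁻³ with
  tol = 0.05).

Averages are taken over the trailing `T_avg` steps after discarding a
settling transient (`T_settle`); excluding the transient is this
package's convention, so reported expectations describe the stationary
regime.  With `T_avg = 1000` the normalized spike count of a neuron is
quantized on an exact 1/1000 grid.  Default constants: `v_c = 1`,
`I_Ψ = 1`, `Q_self = 1`, `λ_floor = 2`, `λ_margin = 1.1` — chosen so
that stimuli scaled to [0, 1] sit inside the non-saturating dynamic
range `|b_eff| < Q_self·v_c + I_Ψ = 2`.  The
simulation kernel has a pure-numpy reference implementation and an
optional numba version that is verified bit-identical to it.

## Learning rule

Total mean spiking `L(Q) = Σᵢ(Ψ̄ᵢ⁺ + Ψ̄ᵢ⁻) = ‖v̄‖₁` under `Qv̄ = b` is
descended by `Q ← Q + η(Ψ̄⁺ − Ψ̄⁻)(v̄⁺ − v̄⁻)ᵀ` off the diagonal.  The
sign convention (add the spike-weighted correlation) was fixed by two
independent checks: an analytic expansion around `Q = I`, and a
finite-difference oracle of the closed-form loss `‖Q⁻¹b‖₁` on 2-pair
networks (cosine of update vs −∇L positive at every sampled
differentiable state; states within 0.05 of an L1 kink are excluded
because the gradient does not exist there).  `ΔQ_ii = 0` holds exactly
and structurally: the rule never touches the diagonal.

Two update schedules are provided.  `mean_field` (default) forms the
update from products of window means — deterministic and cheap.
`per_step` accumulates instantaneous `Ψ(t)·v(t)` products over the
window, the literally spike-based schedule; it additionally captures the
within-window covariance and is the stable choice on densely coupled
hidden layers (the mean-field product diverges there at usable learning
rates).  Divergence (loss persistently above 150% of its early value)
aborts training with diagnostics.

Template projection replaces the stimulus by `b₀ − Q t` for a fixed
random template `t`; the same rule with the presynaptic factor
`v̄ⱼ + tⱼ` then drives `Qt` toward the data: exactly onto a single
training point, and near the componentwise median of a cluster (the
L1-optimal representative).  Online presentation order is the dataset
order by default, with an optional seeded shuffle; the supervised
fixtures shuffle, since class-blocked orderings bias online updates
toward the last-seen class.

## Architectures

* **Domain description / anomaly detection** — dense trainable network,
  random fixed template, template-projection training over the cloud.
  The decision threshold is the `1 − reject_frac` quantile of the
  training points' firing rates (maximum at `reject_frac = 0`,
  boundary inclusive), so the accepted region shrinks monotonically as
  the rejection fraction grows.
* **Linear classifiers** — pairs `[label, features…, bias]` with the
  stimulus `[y, x, 1]`, `y ∈ {−1,+1}`.  The feed-forward variant trains
  only the synapses into the label pair (L1 regression of `y` on `x`);
  inference scores the label pair alone.  The fully-connected variant
  trains and scores the whole network.  The *reported* sparsity
  `ρ_train` is always network-wide for both variants — that is the
  comparison under which full lateral training ends markedly sparser at
  equal accuracy.
* **Network 1** — `S` frozen sub-networks (`Q_s ≈ I` plus small random
  off-diagonals, uniform templates): the summed mean potentials of
  sub-network `s` equal `−‖Q_s t_s − x‖₁` up to O(off-diagonal), so the
  hidden code is a bank of L1 distances to random centroids (scaled by
  1/D before the trained top layer, keeping them in the neurons' range).
* **Networks 2–3** — one coupled hidden differential network spanning
  all sub-networks (off-diagonal weights uniform ±0.5, connection
  probability 0.5, mask frozen at build).  Hidden features are the
  ON-half mean potentials of the input pairs, a rectified random mixture
  `v̄⁺ ≈ min(β, 0)`.  Network 3 additionally clamps the label vector
  into every sub-network and into the top layer (scalar ±1 for binary
  tasks, `{−1,+1}^C` with +1 at the class otherwise).  Inter-layer
  connections are fixed; network 3 uses a fixed inter-layer gain of 4,
  compensating the amplitude shrinkage of its aggressively sparsified
  hidden code.  Training is layer-local with a
  `(epochs_joint, epochs_top)` schedule.  The XOR recipes reflect each
  design: network 2 adapts its label-free hidden layer gently
  (η₁ = 0.002) because its readout depends on preserving the feature
  code, while network 3 adapts fully with the per-step schedule — its
  label-informed layers keep inference robust while firing drops.
* **Recurrent time-series mode** — the stimulus frame advances every
  `T/L` steps through the presentation window while the clamped label
  stays fixed; updates use the trailing-window means.  Constant
  sequences reduce bit-identically to the static fit.

Inference always clamps each candidate label, simulates every layer
stage-wise (hidden layer to steady state, its means passed upward as
static inputs), and returns the argmin of `ρ` over candidates with ties
broken toward the smallest class index (the margin is reported).

Model selection: when enabled, the epoch with the best accuracy (on the
validation split if one exists, else on the training set) is kept;
accuracy ties — and only exact ties by default — are broken toward the
*sparsest* model, then the earliest epoch.  Preferring the sparser model
among equally accurate epochs is the framework's own objective; with an
earliest-epoch rule alone the multi-layer networks systematically return
early, barely sparsified weights.

## Synthetic study conditions

All generators are pure functions of parameters and a seed.  The 2-D
fixtures use noise whose per-sample displacement norm is clipped at 3σ,
which makes the advertised margin properties (blobs separable with
margin `separation − 3·noise`; XOR quadrants never crossing the
boundary) hold for every seed rather than with high probability.
The drift generator random-walks six 16-dimensional class profiles
across ten batches and scales every sample by a concentration factor in
[0.5, 1.5] — emulating the batch structure, drift, and intensity spread
of a metal-oxide gas-sensor array, but not real sensor physics,
correlated noise, or class imbalance; passing the protocol here shows
the machinery works under drift, not field performance.  The time-series
generator emits smooth class-mean trajectories (offset plus
low-frequency sinusoid) with white noise: separable by design, unlike
real activity-recognition data.  Feature scaling to [0, 1] is always
fitted on the training split only; the few-shot protocol takes 10
samples per class (all of them if a class is smaller), 10% validation,
rest test.

Problem sizes in the shipped studies (tens of 2-D points, hidden widths
S = 16–50 for XOR, S = 4 with 150-sample batches for the drift
protocol, 300–600-step presentation windows) were chosen so each study
finishes in seconds to a couple of minutes on a single core while the
qualitative results — perfect separation of the linear fixture, XOR by
majority vote over five seeds, the sparsity ordering network 3 <
network 2 < network 1, per-phase accuracy recovery and sparsity decline
under drift — are stable across master seeds.

## Known limitations

* Steady-state means carry an O(α) discretization bias; quantitative
  identities need the fine integration preset.
* The local rule's equilibrium decorrelates (`E[vᵢvⱼ] = 0`) rather than
  reaching the global L1 optimum; sparsity gains beyond that point are
  not guaranteed.
* Minimum-spiking margins on hard non-linear problems are small; single
  runs of the multi-layer networks have volatile boundaries, which is
  why decisions are reported as majority votes over seeds.
* Binary label clamps (`|y| = 1`) sit at the firing-saturation edge by
  design; their firing is symmetric across candidates until lateral
  weights learn label-feature structure.
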