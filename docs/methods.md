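# Methods

## Scope and model structure

`trustwalk` implements two competing dynamical accounts of how a human
agent's judgement of an AI system's reliability evolves over repeated
interactions, on a discrete scale of n = 11 levels (a deliberate
coarse-graining of the 0–100 rating slider: fine enough to resolve
meaningful movement, small enough that the dynamics stay interpretable).

Both accounts are generator-driven linear dynamics over the level basis;
they differ in what the state *is*:

* **Markov birth–death walk** — the agent occupies a definite level;
  uncertainty is the modeller's. The state is a probability vector φ(t)
  evolved by the Kolmogorov forward equation dφ/dt = Kφ, φ(t) = e^{tK}φ(0).
* **Quantum walk** — the judgement is indeterminate between measurements;
  the state is an amplitude vector ψ(t) evolved by the Schrödinger
  equation dψ/dt = −iHψ, ψ(t) = e^{−itH}ψ(0), read out by the Born rule
  Q(R = i) = |ψ_i|².

Out of scope by design: open-system (Lindblad) dynamics, measurement
collapse-and-restart between ratings, likelihood-based model fitting, EEG
acquisition and the upstream cleaning chain (filtering, line-noise removal,
ICA, artifact subspace reconstruction, re-referencing), and real-time
EEG-adaptive parameter updating.

## The generators and their parameters

**Intensity matrix K** (n×n, tridiagonal). Column j carries the flow out of
level j: K[j+1, j] = β⁺ (up), K[j−1, j] = β⁻ (down), K[j, j] = −α with
α = β⁺ + β⁻. Defaults β⁺ = 0.6, β⁻ = 0.4, hence α = 1; all rates are per
unit model time and dimensionless otherwise. Two structural choices are
worth stating because the prose convention ("intensity from row i to column
j") conflicts with the evolution equation φ(t) = e^{tK}φ(0), which needs
*columns* to sum to zero:

* K is built column-oriented so the stated evolution equation conserves
  probability; with row orientation it would not.
* At the boundary levels the out-of-range flow is dropped and the diagonal
  adjusted (−β⁺ at level 0, −β⁻ at level n−1): reflecting boundaries.
  A uniform diagonal −α at the boundaries would leak probability.

The stationary law is the detailed-balance geometric distribution
π_i ∝ (β⁺/β⁻)^i, exposed as `stationary_distribution`.

**Hamiltonian H** (n×n, real symmetric). Diagonal μ_x = 0.05·x — a linear
potential accumulating drift toward high reliability while the AI keeps
agreeing; off-diagonals σ² = 0.7 — diffusion of amplitude to neighbouring
levels (σ² is treated as the literal off-diagonal value, matching the
printed matrices, not as a square root); corners H[0, n−1] = H[n−1, 0] =
z = 0.2 — a direct coupling between the extreme levels that models abrupt
collapse of high reliability expectations. The corner coupling is applied
only for n ≥ 3 (at n = 2 the corner cell is the ordinary off-diagonal).
Amplitudes are stored complex throughout: e^{−itH} of a real matrix is
complex-valued; only |ψ|² is exposed at the interface.

Both propagators are computed exactly — `scipy.linalg.expm` for K, a
spectral decomposition (`scipy.linalg.eigh`) for the symmetric H — and are
verified in the tests against an independent fixed-step fourth-order ODE
integration and against closed-form two-state limits (exponential
relaxation for the chain, sin²(σt) Rabi transfer for the wave).

## Rating scale and initial states

Ratings are binned in 9-point half-open bins [0,9) → 0, [9,18) → 1, …,
[81,90) → 9, with [90,100] → 10; equivalently min(⌊r/9⌋, 10). Boundary
values (9.0, 18.0, …) belong to the upper bin; the binning is only defined
for n = 11.

Two initial states are supported:

* **uniform** — probabilities 1/n or amplitudes 1/√n;
* **weighted** — a 7-point symmetric stencil centred on the mapped
  post-practice rating: probabilities
  (0.025, 0.0625, 0.17, 0.5, 0.17, 0.0625, 0.025), amplitudes
  (0.17, 0.24, 0.41, 0.71, 0.41, 0.24, 0.17), zero elsewhere.

The stencils as printed do not normalise exactly (probability sum 1.015,
squared amplitude norm 1.0133). Both dynamics presume normalised states, so
`weighted_initial` renormalises by default and returns the raw stencil —
as a plain array, since it violates the typed-state invariants — only
behind `normalize=False` for fixture comparisons. At the scale boundaries
the stencil is truncated to the valid levels and then renormalised, the
simplest rule consistent with "zero beyond the three nearest neighbours".

## Time mapping and model comparison

Model time is mapped to the session as t = trial_index × `time_scale`,
with each block's rating read out at the block's last trial. The default
is **0.1 model time units per trial**. Rationale: with σ² = 0.7 the
spectral range of H is ≈ 2.8, giving the quantum wave a dominant period of
roughly 4.5 time units. At one unit per trial that period would be 4.5
*trials*, so ratings taken every 28 trials would alias several whole
oscillations and the characteristic slow wave across a 560-trial session
could never appear; at 0.1 units per trial the period is ≈ 45 trials — a
regular wave over the session that the per-block ratings resolve. The scale
remains a free configuration parameter.

`compare_models` builds both trajectories from the same start (weighted
stencil at the mapped block-0 rating by default), evaluates them at the
block-end times with **no re-initialisation between ratings**, and scores
each by RMSE between the expected state E[R] = Σ i·P(R = i) and the
observed binned states over blocks ≥ 1 (block 0 defines the start; the
pre-practice rating is carried in the data but not scored). The expectation
is used as the point prediction because it yields smooth trajectories; the
modal state is available (`modal_state`) as an alternative readout. RMSE is
in units of levels on the 11-level scale.

The self-recovery study (in the acceptance tests) draws a start state
uniformly from levels 1–9 per replicate, generates one rating per block by
a seeded multinomial draw from the generating model's readout distribution
at that block's time — the generative use of two explicitly
measurement-probabilistic models — and checks that the generating model
wins the RMSE comparison in ≥ 95 of 100 replicates. A deterministic argmax
readout was rejected as the sampling rule: it leaves nothing for the
replicate seed to vary except the start state, and it is confounded
whenever quantum-generated data happens to sit near the Markov stationary
mean (≈ 8.1 at the default rates).

## Synthetic session generator

The generator emulates the study design the models target: 20 blocks × 28
trials (560 trials), exactly 21 match / 7 mismatch per block in seeded
random order; a manifest of 294 real + 294 AI-synthesised face identifiers,
each used at most once, with a 50/50 class balance among the 560 presented;
reaction times lognormal with mean 0.7 s and SD 0.25 s (typical for a
two-choice image judgement), truncated at the 2 s response deadline —
slower draws become timeouts with no AI feedback. Participant
classification *accuracy* is not modelled: the Wizard-of-Oz manipulation
controls agreement independently of correctness, so responses are fair
coin flips and the stimulus class is carried only for manifest realism.

Per-block reliability ratings follow an explicitly parametric damped
cosine around an asymptote,

    rating(b) = A + (r₀ − A + a·cos(2πb/T))·e^{−λb} + ε,  clipped to [0, 100],

with b = 0 the pre-practice rating, b = 1 post-practice, b = k+1 after
block k (defaults: r₀ = 48.9, A = 75, a = 15, T = 6 blocks, λ = 0.15 per
block, ε ~ N(0, 3²)). This form is the package's own generator device for
the oscillate-then-dampen pattern such studies describe qualitatively; it
is not an empirical claim, and the defaults were chosen once as a plausible
mid-scale start converging to a "mostly reliable" impression under a 75%
agreement schedule. A least-squares refit of (A, λ) on seeded trajectories
recovers both to well under 10% median relative error (tested).

## EEG epochs and the ERP stage

Epochs are synthesised time-locked to the AI-feedback event on a 19-channel
10–20 montage at 250 Hz over −1300…+950 ms. The window endpoints snap to
the sample grid t_k = tmin + k/f_s (563 samples, last at +948 ms), since
2250 ms is not an integer number of 4 ms samples. Each responded trial is
the sum of its condition's Gaussian-bump components placed on a scalp
region's channels plus white noise (default SD 5 µV, a plausible residual
for cleaned single-trial EEG). The default template gives both conditions
an early occipital visual response (120 ms) and a central positivity at
376 ms of 4 µV (match) vs 8 µV (mismatch), the mismatch condition adding a
−2 µV dip at 268 ms — the oddball morphology, rare events driving the
larger P3-like deflection. Timeout trials have no feedback event and are
skipped.

The baseline is 600 ms of fixation preceding the image stimulus, whose
position relative to the feedback event varies with reaction time (image
onset at −(RT + 0.3 s)); the generator therefore stores a per-trial
baseline window, clipped to the epoch support. When RT + 0.9 s exceeds the
1.3 s pre-event span the usable window shrinks, and trials whose window
vanishes are dropped by `baseline_correct` with a warning — at the default
reaction-time distribution roughly 10–15% of trials. Real-data ingestion
would need event markers and is out of scope.

The ERP stage itself is deliberately simple and operates on already-clean
epochs: rejection of trials with > 100 µV voltage swings (peak-to-peak by
default, since a "voltage change" is a range; an absolute-amplitude mode is
provided) and of trials with responses slower than 2 s or missing;
per-trial baseline subtraction; condition averaging; the match − mismatch
difference wave; region averages over an editable frontal / central /
left-temporal / right-temporal / parietal / occipital map; and
sample-aligned peak detection (no sub-sample interpolation — reported
latencies are multiples of the 4 ms sample period). Condition averaging is
cross-checked against MNE's epoch averaging in the tests.

Because the per-trial baseline windows are anchored to each trial's own
simulated fixation, the stage is implemented directly in numpy rather than
on MNE's common-baseline epoch container.

## Numerical choices and degenerate inputs

* Probability vectors must be non-negative within 1e−12 and sum to 1
  within 1e−9; unit norm likewise for amplitude vectors. Propagator
  round-off (entries at ~−1e−16) is folded to |·| within the 1e−12 band.
* Negative evolution times are rejected at the public API; time reversal
  is exercised internally for the unitarity tests.
* Empty rejection output is returned as an empty epoch set; averaging
  refuses a condition with zero trials explicitly.
* Flat waveforms in peak detection return the window start flagged
  `flat=True` rather than an arbitrary extremum; ties break to the
  earliest sample.
* All generators are deterministic given (config, seed); the end-to-end
  runner derives per-stage seeds from the master seed with
  `numpy.random.SeedSequence` and logs them.

## What passing tests do and do not show

The synthetic generators reproduce the *design* of the emulated study
(trial counts, condition ratios, manifest structure, rating cadence, ERP
morphology and its condition contrast), so green tests demonstrate that the
estimation and comparison machinery behaves correctly on data with that
structure. They do not validate the damped-cosine rating law or the
Gaussian-bump ERP shapes as models of human behaviour, and synthetic white
noise lacks the temporal and spatial correlation of real EEG — so recovery
margins here are optimistic relative to real recordings. Published
headline RMSE values from rating data that was never released cannot be
reproduced and are not targeted; the package instead verifies every printed
worked value (the 48.9% → level 5 mapping, α = 1, the stencil entries, the
session design counts) and the models' mathematical invariants.

## Problem sizes

Default test and acceptance runs use the full 560-trial session for the
ERP chain, 1000-draw conservation suites, single t = 10 integrations at
step 1e−4 for the ODE oracles, and 100 replicates per model for
self-recovery; the whole suite completes in well under a minute on one
CPU.
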