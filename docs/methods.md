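# Methods

## The neuron model

`samsnn` simulates populations of self-adaptive multicompartment (SAM)
neurons: a leaky integrate-and-fire soma coupled to two lumped dendritic
compartments — one receiving excitatory input, one inhibitory — with a
spike-frequency-adaptive firing threshold.  In continuous form the three
potentials follow first-order kinetics with a common membrane time constant
τ_v; the soma additionally couples to each dendrite through a conductance-like
gain g·(V_den − V_rev).  The package integrates the exact discrete-time form
with step Δt (decay factors μ = exp(−Δt/τ_v), λ = exp(−Δt/τ_a)):

```
τ(t+Δt)  = λ τ(t) + (1−λ) z(t)                  adaptation trace, τ ∈ [0, 1]
Γ(t+Δt)  = τ0 + η τ(t+Δt)                       dynamic threshold
V(t+Δt)  = μV + (1−μ)[R_m I_soma + g_e(V_e−V_exc) + g_i(V_i−V_inh)] − Γ z(t)
V_e(t+Δt) = μV_e + (1−μ) R_me I_e               (V_i analogous)
z(t+Δt)  = 1  iff  V(t+Δt) > Γ(t+Δt) and the neuron is not refractory
```

A spike subtracts the current threshold from the membrane potential (soft
reset) and opens a refractory window of `t_ref` ms during which the potential
keeps integrating but cannot trigger.  All state is initialized at zero; the
update is deterministic.

### Units

The model mixes nominal units (Ω, nA, mV) that only ever appear as products
with unit resistances, so all quantities are treated as normalized model
units; a "current of 0.65 nA" is the dimensionless drive amplitude 0.65.
Times are in ms.

### Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| R_m, R_me, R_mi | 1 | membrane resistances (soma, dendrites) |
| τ_v | 20 ms | membrane time constant (all compartments, readout leak) |
| τ_a | 700 ms | adaptation time constant |
| η | 1.8 | adaptation-to-threshold gain |
| τ0 | 0.01 | baseline threshold |
| g_exc, g_inh | 1 | dendro-somatic coupling gains |
| V_exc, V_inh | 0 | dendritic reversal potentials |
| Δt | 1 ms | integration step |
| d_* | 5 ms | synaptic delays, per pathway |
| t_ref | 7 ms | refractory duration |

The coupling is implemented as (1−μ)·g·(V_den − V_rev), which reduces to the
bare (1−μ)·V_den form at the default g = 1, V_rev = 0 while making the
dendritic gains independently tunable.

**Refractory duration.**  The reference description mentions a refractory
period but assigns it no value, and the f–I plateau is set almost entirely by
it: the minimum inter-spike interval is `t_ref/Δt + 1` steps.  The default,
7 ms, caps the rate at 125 Hz, the integer-period cap closest to the
reported ~135 Hz saturation that still leaves the saturation knee inside the
0–1 sweep range.  No integer cap reproduces both the reported plateau height
and the reported knee position simultaneously: the intrinsic (refractory-free)
discrete dynamics fire at ≈116 Hz at drive 0.65 and keep rising to ≈146 Hz at
drive 1.0, so a plateau *beginning* at 0.65 would have to sit near 116 Hz.
The f–I landmark numbers produced by this package therefore deviate from the
reference values by roughly 8–14%.

**A steady-state identity.**  Averaging the adaptation recursion over a limit
cycle gives ⟨τ⟩ = ⟨z⟩ exactly, hence the time-averaged saturated threshold is

    Γ_sat = τ0 + η · f · Δt         (f the steady rate)

This identity pins Γ_sat ≈ 0.254 at a 135.5 Hz plateau and ≈ 0.235 at our
125 Hz plateau; a saturated threshold of 0.1585 would require f = 82.5 Hz.
The reference figure pair (plateau rate, saturated threshold) is mutually
inconsistent under the printed equations; this package reports the values the
dynamics actually produce.

## Single-neuron protocols

Because the soma receives no feedforward input in the network architecture,
f–I sweeps inject constant currents into the dendrites: `excitatory_only`
(+A into the excitatory dendrite), `inhibitory_only` (−A into the inhibitory
dendrite; always silent), and `simultaneous` (+A excitatory with −r·A
inhibitory).  With the symmetric default couplings an equal-and-opposite pair
cancels exactly in the soma, which would make the paired protocol silent at
every amplitude; the ratio r defaults to 0.15, the value implied by the
reported shift of the saturation knee (0.65 → 0.77).  Each amplitude is
simulated for 10 s of model time with the first 3 s discarded (τ_a = 700 ms
needs several time constants to equilibrate); the saturated threshold is the
mean of Γ over the final second.  The knee is the smallest amplitude whose
rate is within 0.5 Hz (below the rate-estimation quantum at 7 s of retained
spiking) of the plateau, where a plateau requires the trailing 10% of the
grid to sit within that tolerance of the maximum; sweeps without a plateau
report "no saturation" rather than failing.

Parameter grids vary two of {η, τ0, τ_v, R_m} with the rest at defaults and a
fixed suprathreshold drive into the excitatory dendrite.  The R_m axis sets
the common membrane resistance of all three compartments (the default
parameter set assigns them one value); varying the somatic resistance alone
would be a no-op under dendritic drive.  The monotonicity structure —
Γ_sat non-decreasing in η, τ0, R_m and non-increasing in τ_v, steady rate
non-decreasing in R_m — holds throughout.  The absolute Γ_sat levels at
extreme τ0 values do not match the reference figure readings at any single
drive: by the identity above they would require steady rates of ~28 Hz
(τ0 = 0.15) and ~17 Hz (τ0 = 0.02) at the *same* drive, and the τ0 = 0.02
rate always far exceeds the τ0 = 0.15 rate whenever the latter fires at all.

## Network architecture

Three layers: spiking inputs, a hidden SAM population, and readouts.  Six
weight matrices connect input and hidden spikes to the three compartments;
the input-to-soma pathway is disabled by default (overridable).  Weights are
initialized as (w0/√n_pre)·|N(0,1)| with w0 = Δt/R_m, each presynaptic neuron
carries a fixed random sign (inhibitory with probability `frac_inhibitory`,
default 0.2), the somatic recurrent matrix is rescaled to spectral radius
< 1 when necessary (it is the loop that can destabilize) and has no
self-connections, and each pathway is thinned by an independent Bernoulli
mask at the configured connectivity.  Synaptic delays are per-pathway
integers (default 5 ms).  Readouts are leaky integrators sharing τ_v; for the
store-recall task a logistic function is applied to them.

**Deep rewiring.**  Sign constraints are maintained by deep rewiring: after
each optimizer step an L1 drift of lr·0.01 pulls active magnitudes toward
zero (temperature 0: no exploratory noise term, configurable), any weight
whose signed magnitude would cross zero becomes dormant (exactly zero), and
an equal number of dormant synapses per matrix is re-activated at random with
the presynaptic sign, conserving the active-synapse count exactly.

**SynOps.**  The simulator counts one synaptic operation per spike and
outgoing active synapse (readout fan-out included), the standard proxy for
neuromorphic energy cost.

## Surrogate-gradient learning

There is no autodifferentiation dependency: backpropagation through time is
an explicit adjoint recursion through the update equations above, written in
numpy.  The spike nonlinearity uses the pseudo-derivative
k·max(0, 1−|v|) with k = 0.3 and v = (V−Γ)/Γ the threshold-normalized
potential (clipped to |v| ≤ 10 before the hinge; the hinge is zero beyond
|v| = 1 so clipping only guards intermediates against the small-Γ
denominator).  Gradient flows through the membrane potential (factor 1/Γ)
*and* through the threshold (factor −V/Γ², then onward through the
adaptation recursion), so the slow threshold dynamics participate in credit
assignment — this is what makes working-memory solutions expressible.
Refractory gating is treated as a stop-gradient.

Correctness is established by an independent oracle: replacing the hard
threshold with the antiderivative of the pseudo-derivative yields a C¹
"smoothed" network whose exact gradient the same backward code computes;
central finite differences on that network agree with the adjoint recursion
to better than 1e−4 relative error (tested on a 3-neuron toy net across all
six pathways).

The supervised loss is the cross entropy between labels and the softmax of
the readout averaged over a trailing window, plus the rate-regularization
term μ_f·Σ_j(rate_j − f0)² with target f0 = 10 Hz, which is exactly zero when
every neuron hits the target.  The optimizer is ADAM (default lr 1e−3,
standard moments), one step per batch, followed by the rewiring step.

### Operating regime for training

Two empirical findings shaped the training defaults, both documented because
they are easy to trip over:

1. **Saturation kills learning.**  With dense, predominantly excitatory
   inputs at the w0 initialization, every hidden neuron sits at the
   refractory ceiling (~125 Hz), |v| ≥ 1 almost everywhere, and the surrogate
   gradient into the hidden weights is numerically zero.  Training
   experiments therefore use a balanced inhibitory fraction (0.5) and, for
   the store-recall task, a reduced initial weight scale, placing the
   population in a fluctuation-driven 10–50 Hz regime where most units stay
   inside the hinge's support.
2. **Silent units cannot recover.**  A unit with V ≈ 0 and Γ = τ0 sits at
   v = −1, exactly on the hinge boundary, so a dead unit receives no
   gradient.  With adaptation enabled, aggressive learning rates silence
   units progressively (40/50 dead at lr 5e−3 on the pattern task); the
   classifier default is lr 1e−3.

## Reinforcement meta-learning

The navigation agent lives in the unit square.  Position is encoded per axis
by 10 neurons with Gaussian tuning curves r_max·exp(−100(ξ_i−ξ)²), r_max =
500 Hz, preferred values evenly spaced on [0, 1], spikes drawn per step as
Bernoulli(rate·Δt); the neuron count per axis is a design choice (the tuning
formula fixes only the width).  Rewards are volley-coded by two groups of
8 neurons (positive/negative).  Five readouts parameterize the policy: means
tanh(λ1), tanh(λ2), standard deviations σ(λ3), σ(λ4), and the value estimate
λ5.  The sampled velocity is capped to Euclidean norm `max_speed` (0.02
arena-widths per step); log-probabilities refer to the uncapped sample.
Reaching within `goal_radius` (0.05) of the goal yields reward 1 (there are
no negative rewards in this task, though the encoder supports them) and
teleports the agent to a uniform random position; the goal is fixed within
an episode; Gaussian positional noise of std 0.03 perturbs every step.

Each iteration collects K = 10 episodes of T = 2000 steps (defaults), then
minimizes the clipped PPO surrogate (ε = 0.2) with batch-normalized
advantages on the discounted returns (γ = 0.99, computed by backward
recursion and verified against the O(T²) definition), a value-regression
term with coefficient 0.5, and the same rate regularization — one ADAM step
per iteration, so the probability ratio is 1 at update time and the clip is
inactive; multiple PPO epochs per batch (which re-unroll under current
parameters with the stored inputs and actions) are supported but not default.
The clip parameter, advantage normalization and value coefficient are
standard PPO choices not restated in the reference description.

The packaged experiments run a scaled-down arena (tens of iterations, 5
episodes × 300 steps, 30 hidden neurons, goal radius 0.25) where trained
performance separates cleanly from the untrained baseline (typically ~50 vs
~3 goals per iteration); full-scale goal counts and convergence horizons are
out of scope.

## Synthetic tasks

All generators are pure functions of their seed and produce class-balanced,
validated event rasters.

* **Noisy spike patterns** — five Poisson template rasters (default 80
  channels at 50 Hz over 2000 steps), drawn once and fixed; instances jitter
  every spike by Gaussian noise (δ in ms, times clipped to the horizon,
  colliding spikes collapse) and delete spikes independently.  Note that the
  templates are *stationary*: after large jitter the class signal is almost
  entirely the per-channel count profile, a pure rate code.  This matters
  for what the noisy-pattern experiments can show (below).
* **Oriented bars** — eight 27×27 images (bars at 22.5° spacing through the
  center), 73 pixels (10%) perturbed with Gaussian noise, Bernoulli-rate
  encoded; the 0° and 90° images are exact transposes before noise.
* **Store-recall** — 40 channels: bits of two 10-bit streams on channels
  0–19, store and recall command volleys on 20–29 and 30–39.  Active
  channels emit regular spike trains (one spike per 3 steps) for the whole
  frame rather than firing every step — with every-step firing the hidden
  population saturates and cannot learn.  The target during a recall frame
  is the 20-bit content of the most recent store frame; trials are re-drawn
  until they contain a store, a recall, and no recall before the first
  store.
* **Sequential images** — pixels presented in raster order, one channel per
  threshold level (80 levels evenly spaced in (0, 1)); a channel fires when
  the intensity crosses its level between consecutive pixels, in either
  direction, and a final cue channel marks the end of the presentation.  A
  seeded seven-segment "digit-like" generator (labelled synthetic; strokes,
  random shifts, pixel noise) stands in for handwritten digits so nothing is
  downloaded.

What the generators do *not* emulate: real digit-image statistics, temporal
structure inside pattern templates (they are stationary Poisson), correlated
noise across channels, and trial-to-trial nonstationarity.  Passing tests
demonstrate the mechanisms — adaptation-based memory, surrogate-gradient
credit assignment, sign-constrained rewiring — on these idealized streams,
not performance on natural data.

## Desk-scale experiment results and limits

The packaged experiments run at deliberately reduced problem sizes chosen as
the package's own test geometry (50-neuron networks, 400–1000-step horizons,
tens of epochs); the headline observations:

* Noise-free 5-class patterns: a 50-neuron network fits to 100% training
  accuracy within ~60 epochs.
* Navigation: PPO training multiplies goals-per-iteration by an order of
  magnitude over the untrained policy within ~30 iterations at the reduced
  scale.
* Store-recall: per-bit recall accuracy rises from chance (0.50) to ~0.70–
  0.77 with 20 hidden neurons.  Two structural effects cap desk-scale
  performance: a linear probe reading the adaptation traces directly from an
  *untrained* reservoir decodes only ~67% (reaching higher accuracy requires
  the input weights to reorganize into command-gated writing, which is slow),
  and with frames much shorter than τ_a the trace decay between frames
  (λ^20 ≈ 0.97) makes "most recent store" discrimination intrinsically hard.
* Jitter robustness: with 500-ms jitter the η = 0 ablation consistently
  matches or beats the adaptive network, because the surviving class signal
  is a stationary rate code and spike-frequency adaptation high-pass-filters
  precisely that signal.  (Separately, at full initialization drive an η = 0
  network saturates at the refractory ceiling and cannot learn at all —
  adaptation does rescue trainability — but that contrast is about drive
  level, not jitter.)  The corresponding acceptance check is left failing
  rather than redefined.

## Numerical choices

* Strict spike inequality V > Γ, evaluated after the same step's potential
  update; the reset and spike test use the threshold refreshed with the
  previous step's spike.
* τ ∈ [0, 1] by construction (convex combination), so Γ ≥ τ0 always.
* Dormant synapses are exactly zero; re-activated ones start at magnitude
  1e−12 with the presynaptic sign so they cannot re-cross within the same
  step.
* Knee detection is deterministic given the grid and tolerance; ties resolve
  to the smallest amplitude.
* The store-recall loss and accuracy are evaluated over the trailing half of
  each recall frame: with 5-ms delays and a 20-ms readout leak the first
  steps of a frame still reflect the previous frame.
* One global seed fans out to named sub-seeds (topology, data, policy, env)
  via SeedSequence with a CRC-32 spawn key, so components can be re-seeded
  independently and every experiment is reproducible bit-for-bit on the
  deterministic paths.
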