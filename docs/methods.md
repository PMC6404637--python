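# Methods

`pfcwm` simulates a prefrontal-cortex working-memory (WM) circuit in which
dopamine D1 activation sets a single control parameter — the relative gain of
excitatory→excitatory versus excitatory→inhibitory synapses — and measures the
consequences of that control at three scales: WM behavior (system), neuronal
avalanches (network), and excitation/inhibition current balance (cell).  This
note records the model, the conventions, and every place where the design was
genuinely open and a choice had to be made.

## Network model

The circuit is a recurrent leaky integrate-and-fire (LIF) network of `N_E`
excitatory and `N_I` inhibitory neurons.  Excitatory neurons are partitioned
into `p = 5` item-selective populations Es1..Es5 (each a fraction `f = 0.1` of
`N_E`) and one non-selective remainder Ens.  Connectivity is Erdős–Rényi:
every ordered pair is connected independently with probability `c`.  Synapses
are delta pulses: a presynaptic spike, after a uniform 0–1 ms delay (quantized
up to the integration grid, minimum one step), jumps the postsynaptic
potential by the synaptic efficacy J (mV); inhibitory inputs jump it
downward.  Efficacies by class: within a selective population E→E synapses
take the potentiated value `J_p = 0.45` mV (a stand-in for prior Hebbian
learning of the items), between selective populations the baseline
`J_b = 0.10` mV, and connections to/within Ens take `J_p` with probability
`γ = 0.1`, else `J_b`.  E→I, I→E, I→I are fixed (0.135, 0.25, 0.20 mV).
Membrane dynamics, thresholds, reset, refractoriness and the Gaussian
external drive (`μ_ext`, `σ_ext` per class) follow the standard LIF equations
with forward-Euler integration at `dt = 0.1` ms.

Only E→E synapses are dynamic, with Tsodyks–Markram facilitation/depression
carried per presynaptic neuron: utilization `u` (release probability proxy,
baseline `U = 0.2`) jumps by `U(1−u)` at each spike and relaxes back with
`τ_u = 1500` ms; resources `x` (baseline `X = 1`) are consumed by `u⁺·x` per
spike and recover with `τ_x = 200` ms.  The transmitted efficacy is
`J·u⁺·x` with the post-jump `u` and pre-jump `x`.  Slow facilitation plus
fast depression is what lets a stimulated population carry a memory: after a
strong transient, its outgoing synapses remain facilitated for ~1.5 s.

Working memory in this regime is *not* tonic elevated firing.  A loaded item
is maintained as periodic population reactivations: brief (~20–40 ms)
high-rate events recurring every 150–300 ms, riding on the facilitated
synapses, with near-silence in between.  All success criteria in the
protocols are built around this mode (see below).

## Dopamine modulation

D1 receptor activation `D ∈ [0, 2]` scales all E→E efficacies by `A_EE(D)`
and E→I efficacies by `A_EI(D)`; I→E and I→I are never scaled.  Both gains
are logistic in `D` with shared steepness `K_c = 0.150`, but the E→E sigmoid
is shifted earlier and the E→I sigmoid later by `D_V = 0.105`, reflecting the
earlier saturation of D1 effects on glutamatergic input to pyramidal cells
than to interneurons.  The difference `ΔA = A_EE − A_EI` is therefore ≥ 0,
symmetric about the intermediate activation `D_0 = 1.0`, and maximal exactly
there: intermediate dopamine tilts the circuit maximally toward recurrent
excitation.  Gains are stored as dimensionless multipliers (1.04, not 104 %).

The gain range `[A_min, A_max]` is a calibration parameter (the two published
trajectory variants differ exactly in this range).  The range family has one
anchor and one depth, chosen as follows and then frozen:

* **Anchor `A_min = 1`.**  With these sigmoids the gains at `D_0` equal
  `A_min ± δ` (the normalizer cancels the sigmoid term), and the realized
  range over the whole D domain is roughly `A_min ± (D_L/2)/(1 + D_L/2)`
  with `D_L = A_max − A_min` (so `A_max` is a nominal parameter, not an
  attained gain).  Anchoring at 1 makes the two gains bracket the published
  baseline efficacies at `D_0`, and — as the trajectory construction demands
  — makes both gains weak (< 1) at very low D1 activation and strong (> 1)
  at very high activation.
* **Depth `D_L` by border proximity at `D_0`.**  Larger depth widens the
  `A_EE`–`A_EI` split at `D_0` and moves the resting state toward the
  transition.  The depth is raised until the `D_0` resting state reaches the
  onset of collective spontaneous activity of the most active selective
  population while staying below self-sustained ignition ("imaginary
  memory").  In finite networks the transition rounds into a band: collective
  fluctuations with scale-free avalanches appear first (rate ~1–5 Hz), and
  single-population dominance (≥ 10 Hz) considerably later; calibrating past
  the onset into the burst-dominated part of the band destroys the avalanche
  statistics (branching parameter far from 1, steep exponents), so the
  target is the onset itself.  Frozen values: `D_L = 1.5` for the desk-scale
  default (`A_min=1, A_max=2.5`), `D_L = 0.85` for the full-size network
  (`DAParams.full_scale()`).
* `calibrate_scaling_range` automates the depth-style search along the
  `A_min` axis for other configurations (bisecting against a resting-rate
  threshold with a safety margin); the frozen defaults above are its
  products combined with the endpoint constraint.

## Network scales

Two reference configurations are built in:

* **Full scale** (`NetworkSpec.paper_scale()`): 8000 E / 2000 I, `c = 0.2`
  — the published configuration; ~14 s per 2 s simulation on one CPU.
* **Desk scale** (`NetworkSpec()` default): 2000 E / 500 I with `c = 0.8`,
  preserving the mean in-degree (1600 E + 400 I inputs per neuron) and hence
  the mean recurrent drive; ~3 s per 2 s simulation.  The denser connectivity
  raises shared-input correlations, so the desk network synchronizes more:
  its near-border states are more population-spike-like, which biases
  avalanche statistics (branching parameter plateaus near ~0.8 rather than
  1) and flattens the dopamine contrast of stimulus-evoked activity (the E/I
  current correlation keeps rising with D instead of peaking at D_0).
  Criticality measurements and the current-correlation dose-response
  therefore default to the full-scale network; the many-trial behavioral
  sweeps (T_sens bisections, ISI-CV pooling) use the desk scale.

## Protocols and conventions

* **Noise discretization.**  Per step `V` gains
  `(dt/τ)(μ−V) + σ√(2·dt/τ)·ξ`, making the stationary free-membrane mean and
  SD equal to `μ_ext` and `σ_ext` independent of `dt` (verified by test).
* **Refractoriness.**  After a spike `V` is clamped to `V_r` for
  `τ_arp = 2` ms; synaptic arrivals during the clamp are discarded
  (configurable to accumulate).
* **Initial conditions and burn-in.**  `V ~ U[V_r, θ)`, `u = U`, `x = X`;
  the first 200 ms of every analysis window are discarded.
* **Persistence criterion** (`PersistenceCriterion`): an item counts as held
  iff the target population's rate stays ≥ 2 Hz in every sliding 400 ms
  window from 200 ms after stimulus offset to trial end (1500 ms after
  offset).  The window must span at least one reactivation cycle; the trial
  must outlast the facilitation time so that a decaying stimulus echo is not
  scored as memory.  A held item keeps every window above ~4 Hz; the resting
  state stays below ~0.5 Hz.  An update additionally requires the previously
  active population below 2 Hz over the final 400 ms.  All thresholds are
  explicit parameters.
* **T_sens / T_flexi.**  Minimal stimulus duration for loading/updating,
  found by bisection at 1 ms resolution between a failing lower and a
  succeeding upper bound; success at a probed duration is the majority over
  3 fixed seeds.  `T_sens = ∞` (sentinel) when even the upper bound fails.
  Sensitivity is `1/T_sens`; flexibility is the reciprocal of `T_flexi`
  normalized by the grid minimum.
* **Avalanches.**  Spikes of the most active selective population are binned
  at width Δt; maximal runs of non-empty bins are avalanches; size = spike
  count.  Δt follows the published derivation — twice the mean population
  inter-event interval — evaluated on the `D_0` resting state and then held
  fixed across DA levels (at full scale and the published resting rate this
  reproduces the 0.3 ms value; at other rates the literal 0.3 ms no longer
  equals 2×IEI).  The exponent is fitted by log-binned geometric-mean
  smoothing (10 bins/decade), KS-optimal range selection (≥ 1 decade), and a
  least-squares slope in log-log coordinates.  The branching parameter is
  the mean over avalanches of (second-bin count)/(first-bin count), with
  single-bin avalanches contributing 0 (configurable).
* **E/I balance.**  Per-neuron current traces are recorded as summed
  potential increments per 5 ms bin in four channels (recurrent-E,
  recurrent-I, external, leak).  The correlation magnitude |ρ| uses the
  standard Pearson coefficient; the "total" variant correlates
  (recurrent-E + external) against (recurrent-I + leak), the
  "recurrent-only" variant the two recurrent channels.  No lag correction is
  applied (lags are sub-bin).  The ISI CV is σ/μ of within-neuron intervals
  pooled across the population (per-neuron averaging available).

## What the synthetic generators emulate

`pfcwm.fixtures` produces ground-truth inputs for the analysis layer:
Galton–Watson avalanche rasters with known offspring mean, discrete
power-law samples with known exponent (inverse-CDF, independent of the
fitting code), Gaussian pairs with known correlation, and renewal spike
trains with known ISI law.  They validate the estimators, not the network:
they contain no refractoriness, no rate nonstationarity and no
finite-population ceiling, so estimator accuracy on them is an upper bound
on accuracy on simulation output.

## Numerical choices and degenerate inputs

Delays round up (never to zero) so causality is strict; equal-size avalanche
samples are rejected as unfittable; constant current traces yield a flagged
NaN correlation; empty rasters give empty avalanche sets but an error for
the branching parameter; power-law fits on fewer than 50 avalanches carry a
`low_count` flag; simulations abort with a diagnostic if |V| exceeds a guard
bound (1000 mV) or the spike raster exceeds its preallocated capacity
(500 Hz mean rate).

## Known limitations

* The branching-parameter estimator has a rate floor: with bin width 2×IEI
  of the reference state, any state whose population rate matches the
  reference has ~2 spikes per occupied bin, and even temporally unstructured
  (Poisson-like) activity then yields σ ≈ 0.9–1.1.  Consequently σ separates
  D1 levels only insofar as their resting rates differ from the reference
  state's; at the onset-calibrated operating point the low-D resting rate is
  close to the D_0 floor rate, and the σ drop at low D1 activation is within
  the estimator's baseline noise rather than clearly below 1.  The exponent
  α and the location of the σ optimum are the discriminating observables in
  this configuration.

* The desk-scale network's elevated synchrony compresses the dynamic range
  of the branching parameter (plateau ~0.8); quantitative criticality values
  should be read from the full-scale configuration.
* Loading/updating success near threshold is stochastic; T_sens/T_flexi at
  1 ms resolution carry trial-to-trial noise of tens of ms, which is why
  dose-response conclusions are drawn from argmax locations on a 0.2-spaced
  DA grid, not from single durations.
* Exponent estimates from single 2 s runs rest on a few hundred avalanches;
  the fitted range selection (KS) then has appreciable variance, controlled
  by averaging over 15 trials.
* The model omits conductance-based synapses, receptor kinetics, spatial
  structure, and D2 pathways; dopamine enters only through the two static
  gain factors.
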