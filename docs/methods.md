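# Methods

This note documents the modeling and numerical choices behind `iwavesim`,
the assumptions baked into its defaults, and what the synthetic-data-driven
tests do and do not establish.

## Neuron and synapse model

Neurons are conductance-based leaky integrate-and-fire point models:

    C dV/dt = −g_L (V − E_L) − Σ_r g_r s_r(V) (V − E_r) + I_ext,

with four single-exponential receptor conductances.  NMDA carries the
standard sigmoidal magnesium-block factor
`s(V) = 1 / (1 + 0.28·exp(−0.062 V))`; the other receptors have `s = 1`.
An excitatory synapse of weight *w* (nS) increments AMPA by *w* and NMDA by
`0.5 w`; an inhibitory one increments GABA_A by *w* and GABA_B by `0.2 w`.
This is a functional re-implementation of the source model's dynamics, not
a line-for-line port: the original biophysical constants are not reprinted
in the paper this package follows, so membrane parameters (C = 150/100 pF,
τ_m = 15/10 ms, E_L = −70 mV, V_th = −50 mV, V_reset = −65 mV, t_ref =
2/1 ms for excitatory/inhibitory cells), receptor kinetics (τ = 2, 100, 6,
150 ms; E_rev = 0, 0, −70, −90 mV), connection probabilities, base weights
and layer depth fractions are all *documented, editable assumptions* in
`config.py`.  Every quantitative conclusion drawn from the defaults should
be read with that caveat.

Integration is fixed-step exponential Euler at dt = 0.01 ms, with
conductances frozen within a step and spike times aligned to step
boundaries.  The step was validated by the package's own convergence
analysis (below).  Synaptic events are delivered through a circular buffer
after exactly the stored per-synapse delay, rounded to whole steps (minimum
one step).

### Noise

The per-neuron noise process is a Poisson train of instantaneous charge
kicks, ΔV = A·w_eff/C with amplitude A (1–50 nA) and an effective width
w_eff = 1 ms.  A literal brief current pulse of one time-step would inject
charge proportional to dt, making noise efficacy depend on the integration
step and breaking the convergence analysis; delivering the equivalent
charge in a single step is dt-invariant and preserves the intended
"short, suprathreshold kick" semantics.  The noise rate is
`rate_scalar × base_rate` (base 5 Hz by default) per neuron, independent of
the afferent drive and unaffected by TMS.

### TMS representation

Activation is an input–output map: for each population or afferent group
with proportion *p*, `round(p·N)` members are drawn without replacement,
freshly per trial (a Bernoulli-per-member variant was considered and
rejected for its extra variance at small N).  Directly activated neurons
are forced to spike at the pulse and propagate orthodromically with their
stored delays; activated afferent terminals trigger all of their synapses
with the appropriate delays.  Refractory neurons ignore the pulse.

## Geometry and wiring

The 79-site triangular lattice is built generously and trimmed to the
target count nearest the column axis, ties broken by polar angle — a
deterministic rule that reproduces the canonical count while preserving
triangular packing.  Depths are uniform within each layer's band; the
default band fractions (L2/3: 10–45%, L5: 45–80%, L6: 80–100% of 2700 µm)
are assumptions standing in for unpublished ex-vivo measurements.

The default connectivity diagram gives every excitatory population a
projection to all six populations; basket cells project within their own
layer, to the excitatory populations of the other layers, and between the
L2/3 and L5 BC pools.  With the six afferent projections this yields the
38 weight-scalar projections of the optimization vector, and contains every
projection the sensitivity analysis singles out (e.g. L5 PTN→L2/3 IT,
L2/3 BC→L5 PTN, the L5 PTN recurrent).  The 24 conduction-velocity scalars
are enumerated as 6 cortical pre-populations × 3 target layers plus one per
afferent group; for afferents the scalar divides the sampled conduction
latency.  Afferent latencies are `max(0, N(µ, σ))` with optimizable µ, σ,
re-derived deterministically from frozen standard-normal draws whenever the
parameter vector changes.  The full vector is 98 parameters, grouped by
category and alphabetical within category — a stable, diffable order for
checkpoints.

## Corticospinal signal and objectives

Per trial, L5 PTN spikes in a post-pulse window are binned at 10 kHz,
band-pass filtered with a zero-phase second-order Butterworth (200–1500 Hz)
and then averaged (filter-then-average; the alternative order is
indistinguishable for a linear filter up to edge effects, and
filter-then-average matches per-trial processing of real recordings).  A
5 ms pre-pulse margin is filtered with the trace and trimmed so the D-wave,
which sits at the window edge, is not distorted by filter transients.
Amplitudes are arbitrary units throughout; every waveform objective is a
relative error, so the scale cancels.  Wave windows are configuration:
the helper `windows_from_latencies` centers them on a target's peak
latencies with boundaries at inter-peak midpoints.

The 51 objectives follow the printed table: 16 wave-feature errors (D rows
dropped for a D− target), firing-rate and mean-ISI pairs for five
populations, peak/mean ratio (target 1) and coefficient of variation
(target 0) of the 1 ms-Gaussian-smoothed population spike density for all
six populations, per-population ISI spread and noise-weight minimization
(noise weight = amplitude × rate scalar / 50), and the post-I3 amplitude.
Silent populations take the steady-state window length as their mean ISI —
a maximal penalty that keeps the error finite.

## Particle swarm optimizer

Positions are Sobol-initialized (next power of two, truncated).  The five
hyperparameters follow the published sigmoid schedules; with the published
constants the formula as printed runs *backwards* for the cognitive and
social weights relative to the described exploration→convergence
progression, while the inertial, gain and noise curves are already
correct.  Both conventions are implemented (`direction="as_printed"` /
`"described"`); the default flips only the cognitive and social exponents
so all five curves match the described behavior.

The update used is

    v ← clip( w·v + g·(c·r₁∘(p_best − x) + s·r₂∘(n_best − x)), ±0.1·range )
    x ← reflect( x + v + N(0, σ_noise) ),

with fresh per-coordinate uniform draws r₁, r₂.  Three resolutions of
genuine ambiguity, validated on the known-optimum sphere benchmark while
the optimizer was developed: the gain scales the attraction terms rather
than the whole velocity (scaling the momentum by gain × inertia, both > 1
early, grows velocities without bound); velocities are clamped to 10% of
the parameter range per coordinate (a standard PSO stabilizer absent from
the printed update); and the "star topology with 5% neighborhoods" is
realized as ring segments sized at 5% of the swarm plus the current best
particle as a hub visible to all (a literal star topology is fully
connected, which contradicts the stated size unless read as
hub-and-spoke).  Failed or non-finite evaluations are retried once, then
the particle keeps its previous best for that iteration.

The unified-model search interpolates two fitted vectors on a weight grid,
keeps designated coordinates (the activation proportions) response-
specific, and selects the weight minimizing
`mean(e₊, e₋) + |e₊ − e₋|` — a blend that reproduces both response types
without favoring either.  Pareto bookkeeping over the four objective
groups and normalized inter-solution distances are post-hoc utilities over
saved history, not part of the update loop.

## TVAT sensitivity analysis

The default subset is 42 parameters: all 12 activation proportions plus 30
synaptic weight scalars (6 afferent, 18 excitatory intracortical, 6
within-layer BC projections) — afferent weights are included because the
grouped sensitivities dichotomize feedforward versus feedback synaptic
strength.  Grids span 0 to each parameter's optimization maximum with 21
levels (861 pairs × 441 points; the enumerator reports pair and simulation
counts rather than forcing any externally quoted total).

Each (pair, wave) surface is fitted with the full bivariate cubic basis
(9 non-constant terms) under elastic-net regularization, penalty chosen by
10-fold cross-validation (deterministic, unshuffled folds); parameters are
range-normalized to [0, 1].  Amplitudes are standardized **per wave across
the whole campaign**, not per surface: per-surface z-scoring erases the
coefficient magnitudes the effect sizes are meant to accumulate (a surface
driven by one parameter alone would always normalize to |coef| ≈ 1,
making rankings unrecoverable in principle).  Fits with R² < 0.5 and
constant surfaces are excluded.  Effect size of parameter *p* on a wave =
Σ |coefficients of terms involving p| over included fits containing *p*;
interaction terms count toward both parameters.  The preferential rule is
max ≥ 1.5 × second-max, with a positive max over a zero runner-up counting
as preferential.  The surrogate generator exposes the matching closed-form
ground truth: for a linear surrogate the campaign standard deviation of a
wave is `sqrt((2/n)·var(levels)·Σᵢ c²ᵢ)`, so the standardized-scale effect
sizes — the estimand the analysis reports — are known exactly.

## Graph metrics

The 12-node population graph carries per-edge empirical connection
probability (autapses excluded from the denominator), mean realized delay
(including the 0.2 ms transmission delay) and sign.  All metrics are
referenced to L5 PTN via exhaustive simple-path enumeration; for the
target itself the path-dependent fields are null (any walk that leaves and
returns repeats the node).  Weighted path statistics use the per-path
total log probability as weights exactly as printed — the weights are
negative and averages normalize by the weight sum, fixing the convention
with a worked two-path example in the test suite; an absolute-value-weight
variant sits behind a flag.  Centralities follow the printed formulas with
hop-count distance by default and a delay-weighted switch; closeness is
computed over the reachable set and unreachable nodes contribute zero to
the harmonic sum.  Betweenness is the raw (unnormalized) sum of
shortest-path fractions.

## Classifiers

Features are standardized per column; the 12-row table is augmented with
noisy copies (sd 0.3 ≈ 9% of the augmented variance; default 20 copies —
the count is not externally specified).  Validation is stratified 10-fold
with 5 repeats, and folds are *grouped* so all copies of one original row
stay on one side of the split — without this the classifier memorizes the
prototypes and even label-shuffled data scores near 100%.  Binary tasks
use ridge-penalized logistic regression, multiclass tasks an RBF support
vector classifier, both with grid-searched hyperparameters.  The
randomized recursive feature elimination draws 5 random features per
repeat (100 repeats), iteratively drops the feature whose removal least
degrades group-aware cross-validated accuracy down to 2 survivors (binary)
or 1 (multiclass), and ranks features by survivals divided by inclusions.
RFE's internal folds are independent of the final validation folds.

## Synthetic data

Target waveforms are sums of biphasic difference-of-Gaussians wavelets
(trough trailing the peak by half the wave width), sampled at 10 kHz,
truncated 2 ms post-pulse and band-passed exactly like real recordings;
the DoG shape is zero-mean, so filtering moves peak latencies by at most
about one sample and the round-trip through feature extraction is tight.
Default latencies (2.8/4.4/6.0/7.6 ms) mimic the ~600 Hz I-wave
periodicity but are free configuration, not measurements.  Polynomial
surrogates and planted-structure feature tables (threshold rules with a
separability margin, nearest-centroid multiclass structure, permutation
nulls) provide closed-form ground truth for the TVAT and classifier
stages.  All generators are bit-reproducible given their seed.

What the synthetic tests show: that each stage recovers structure it is
built to recover, under noise models chosen to be recoverable.  What they
do not show: that the default biophysics reproduces any particular human
recording — the experimental constraints are not publicly deposited, and
the defaults here are assumptions.

## Problem sizes used in the tests

The test suite exercises reduced versions of the full-scale computations:
parameter recovery fits 6 activation proportions on a 19-microcolumn
column (3 trials, 190 ms protocol, ~240 simulator evaluations); the
sensitivity-analysis oracle uses 6 parameters at 11 levels; the time-step
sweep uses 5 s × 5 trials over dt ∈ {0.005, 0.01, 0.05} ms; classifier
fixtures use 24 nodes × 10 copies.  The full-scale enumerations (861
pairs, 98-dimensional swarm) are verified combinatorially without running
the corresponding simulations.

The recovery check evaluates candidates under the same protocol seed as
its target, making the objective deterministic with a zero-error optimum
at the true parameters; across-seed trial resampling adds ~25% feature
noise on a column this small and would confound optimizer error with
sampling noise.

## Known limitations

No dendrites, axonal morphology, ephaptic coupling, short-term plasticity,
thalamic loop or inter-column connectivity; antidromic activation is
represented only through its delay equivalence to orthodromic propagation.
Conclusions from the default configuration inherit the Esser-derived
constants' uncertainty.  The TMS input–output representation is valid only
for the pulse configuration it emulates and cannot extrapolate to other
coil orientations or waveforms.
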