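# Methods

This note documents the models implemented in `posnersim`, the choices
made where the procedure left freedom, and what the simulations do and
do not establish.

## Task

Both models perform a discrete-time Posner task. A central cue (left /
neutral / right) precedes a lateral target; when lateral, the cue is
valid with probability 0.8. Responses are classified *correct*,
*anticipated* (before target onset), *incorrect* (wrong side; choice
task only) or *slow* (past the deadline). RT is the response instant
minus the target-onset instant, in model time units.

## Bayesian observer (sensory model)

### Model

On a trial the target appears at a time drawn uniformly from
{1..t_max}, t_max = 100, on the left with prior probability ρ (0.8, 0.5
or 0.2 according to the cue), and stays on. Each time unit the observer
receives one stimulus per side, `S ~ N(m, σ²)` with σ = 2 and m = s on
the target side after onset, m = 0 otherwise. The three per-step
likelihood factors (hypotheses: target already left, already right, not
yet) are products of two Gaussian kernels with the normalizing constant
dropped, so each lies in (0, 1].

The posterior that the target has *already* appeared on a side is a sum
over all possible onset times of the sequence likelihood times the
per-time appearance prior (ρ/t_max or (1−ρ)/t_max). The implementation
maintains three scaled accumulators — `acc_l`, `acc_r` (the
likelihood-weighted onset sums) and `acc_nbar` (the running no-target
likelihood product) — with the recurrence

    acc_side ← f_side · (acc_side + p_side(t) · acc_nbar)
    acc_nbar ← acc_nbar · f_nbar

where `p_side(t)` is the appearance prior at step t (zero after t_max;
hypotheses created earlier keep accumulating likelihood afterwards).
The no-target mass is `acc_nbar · (1 − t/t_max)` (zero after t_max).

### Numerical choices

* The three accumulators are rescaled by their sum every step;
  posteriors are invariant under a common scale and raw likelihood
  products would underflow within tens of steps. The recurrence is
  validated against a literal evaluation of the defining sums
  (`naive_posterior`) to 1e−9 relative error on 1000+ random histories.
* The SRT decision rule is evaluated as `1 − posterior_none ≥ γ` rather
  than `posterior_l + posterior_r ≥ γ`: identical in exact arithmetic,
  but exactly 1 at t_max in floating point, which preserves the
  guarantee that an SRT trial always ends by t_max even at γ = 1.
* CRT ties (both side posteriors crossing γ on the same step) are
  resolved by a fair coin. A CRT trial without a response before the
  absolute time index 1000 is slow; slow trials carry no RT (null, not
  zero).
* The stimulus stream stops at the first response; at the reported
  signal-to-noise ratios slow responses never occur in practice.

### Trial mix

Reported pooled accuracies mix half neutral-cue trials and half
lateral-cue trials (split evenly between left and right cues), with the
target side drawn from ρ in every trial, so lateral-cue trials are valid
in 80% of cases. The mix matters little: per-cue-type statistics are
conditioned on the cue, and the SRT pooled accuracy is nearly
independent of the mix.

### Calibration

Responding at posterior ≥ γ leaves at most 1−γ probability mass on "no
target yet", so the anticipated-response rate cannot exceed 1−γ except
through sampling error; tests bound it by (1−γ) + 3·√(γ(1−γ)/N).

## Spiking networks (motor model)

### Neuron and network

Leaky integrate-and-fire neurons with V_rest = V_reset = −65 mV,
V_threshold = −40 mV, τ = 10 time units:

    V(t+1) = V_rest + (V(t) − V_rest)·e^(−1/τ) + I(t)

The decay factor is the fixed per-step constant e^(−1/τ) of a
time-invariant leaky integrator. When V(t+1) reaches threshold the
neuron spikes and the stored potential is reset. `I` sums the bias, a
5 mV external current on stimulated input neurons, the weights of
synapses whose presynaptic neuron spiked on the *previous* step
(synchronous update, one-step synaptic delay), and optional Gaussian
membrane noise drawn independently per neuron and time unit.

Networks are fully connected over all ordered pairs of distinct neurons
(no self-loops): 6 neurons / 30 synapses for SRT, 7 / 42 for CRT.
Genomes are the N biases followed by the N(N−1) weights in row-major
order of the weight matrix with the diagonal skipped.

### Trial protocol

Potentials are reset to rest and inputs to the bias. 50 silent units,
then the cue input current for a uniform integer duration in
[100, 200], then the target current in addition to the still-on cue.
The first output spike at *any* time ends the trial (anticipated if
before target onset); without one the trial ends 1000 units after
target onset (slow). Membrane noise, when enabled, applies in all
phases including the silent period. If both CRT outputs fire on the
same step the response side is a fair coin. Correct responses earn
1000·e^(−0.01·rt) fitness; all error classes earn zero.

A task presents each (cue type, target side) combination a fixed number
of times per side: cue ratio 8:5:2 (valid:neutral:invalid) gives 30
trials, 8:8:2 gives 36.

### Genetic algorithm

Five islands of 20 genomes, genes i.i.d. uniform on [−3, 3) at
generation 0. Per generation and island: the fittest genome is copied
unchanged (ties: lowest index), and 19 children are produced by two
binary tournaments (entrants distinct within a tournament, drawn with
replacement across tournaments; exact fitness ties decided by a coin),
uniform crossover, and per-gene mutation (probability 0.05 of adding a
uniform draw from [−0.3, 0.3), the result clipped into [−3, 3)).
Clipping rather than resampling was chosen as the least distorting way
to keep genes in the interval. Every 10 generations a *copy* of each
island's fittest genome moves to a uniformly chosen other island,
replacing a uniformly chosen member that is not that island's fittest,
so sizes stay at 20; the migrant carries its fitness value. Fitness is
re-evaluated every generation on freshly drawn trials (cue durations,
noise), the carried elite included.

The population evaluator runs all 100 genomes × all trials as one
vectorized simulation. All genomes within a generation see the same
cue durations (a fair comparison); noise is independent per genome,
trial, neuron and time unit. The vectorized path is tested for exact
agreement with the single-trial reference path in the noiseless case.

### Population RT statistics

For each individual and cue type, the median RT over its correct trials
is computed; an individual with no correct response for a cue type is
null for it and excluded. Population mean, SD and a normal-approximation
95% CI (±1.96·SD/√n) are taken over non-null medians, with n reported
explicitly. (The statistics are computed over all 100 individuals of
the five islands pooled.)

## Problem sizes

Observer sweeps default to 10^5 trials per configuration, which puts
the Monte-Carlo standard error of any reported percentage below 0.2
points. Evolution runs use the full 300-generation schedule by default;
the bundled analysis scripts truncate Condition A at 110 generations
(the noiseless runs reach errorless floor-RT performance within ~30–40
generations) and Condition C at 200 generations (the error rate
plateaus well before then), which leaves the reported quantities
unchanged at much lower cost.

## What the simulations show — and what they do not

The synthetic tasks are exactly the environments the models are defined
for, so the experiments characterize the models, not human data: the
observer is an optimal detector with known priors (no learning, no
catch trials, two locations only), and the networks see noiseless or
white-Gaussian-noise currents with a fixed 5 mV stimulus scale. Evolved
outcomes are stochastic: error rates and the cue-type RT *ordering* are
stable across seeds, but end-of-run RT point values vary at the
tens-of-percent level and are treated as indicative. Single-trial
trajectories are irreproducible by design (unknown noise realizations).

## Known limitations

* Continuous-time dynamics, synaptic delays beyond one step,
  conductance-based synapses and within-trial plasticity are out of
  scope of the neuron model.
* The observer models external (stimulus) noise only; the networks
  model internal (membrane) noise only.
* Statistical comparisons between cue types (significance tests) are
  not reproduced; the package reports means, SDs and CIs.
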