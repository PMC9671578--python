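# Methods

This note documents the models, numerical choices and limitations behind
`lickshape`, in the order the pipeline runs.

## Data model

A trial is a half-open 4 s window [−2000, 2000) ms around taste delivery at
t = 0, which is itself a lick (the one that triggers delivery).  Spike and
lick times are strictly increasing real numbers in milliseconds; sub-ms
spike pairs are preserved in the trial record but collapse (with a warning)
in the 4000-dimensional {0,1} rasterization, which has exactly one entry
per millisecond.  Event tables are plain CSV (neuron_id, trial_id, tastant,
event_type, time_ms), written at full float precision so round trips are
lossless; rounding on write is deliberately avoided because it can push an
event sitting just inside the window onto its boundary.

## Smoothing and binning

Smoothing convolves the binary train with a unit-area Gaussian, σ equal to
the "smoothing window" in ms, truncated at ±3σ and renormalized.  With a
unit-area kernel the integral of the smoothed train equals the spike count,
which keeps rate information explicit.  Convolution zero-pads outside the
window, so spikes near the edges lose mass symmetrically — the simplest
boundary contract.  Binning counts spikes in half-open bins; when the bin
width does not divide 4000 the final bin is partial, so the total count is
always conserved.  Pre-/post-taste halves are split after smoothing the
full window, not before.

The headline representation smooths at 250 ms, where decoding scores are
stable with respect to the window.  Phase-sensitive analyses (interlick and
randomized-interval alignment) instead use a 25 ms window: the lick cycle is
~130 ms, and a kernel wider than the cycle erases exactly the
within-interval timing those analyses measure.  A practitioner should pick
the window relative to the timescale being interrogated, and the two
defaults encode that.

## Synthetic generator

The generator is the package's stand-in for recordings from a freely
licking animal and defines the conditions under which every calibration is
run.

- **Licking**: interlick intervals are base_ili + Gaussian jitter
  (defaults 130 ms and 10 ms, ≈7.7 Hz), resampled when ≤ 20 ms; licks cover
  the whole window, which guarantees the six dry licks before delivery and
  at least five complete post-delivery intervals.  The invariant
  base_ili > 3·jitter keeps resampling rare and intervals positive.
- **Spiking**: pre-taste spikes are homogeneous Poisson at a baseline rate
  (default 5 spikes/s).  Post-taste spikes are an inhomogeneous Poisson
  process sampled exactly by thinning, with intensity
  λ(t) = rate · exp(κ cos 2π(φ(t) − μ)) / I₀(κ), where φ(t) is the phase
  within the current interlick interval.  The von-Mises bump has unit mean
  over phase, so κ reshapes spike timing *without changing the expected
  count* — rate and phase codes are dissociated by construction, which real
  data cannot guarantee.  Tests verify both the count preservation and the
  circular-mean recovery of μ.
- **Determinism**: every neuron draws from its own `numpy` Generator seeded
  from its config; population helpers derive independent per-neuron seeds
  from one master seed, so changing one neuron's seed perturbs only that
  neuron.

What the generator does **not** model: taste-evoked changes in lick pattern,
adaptation, bursting, refractoriness, or correlations between neurons.
Passing calibrations therefore demonstrate that the *analysis* behaves
correctly under controlled rate/phase structure — not that real gustatory
responses look like this.  The generator's interlick intervals are also more
metronomic than real licking; see the randomized-interval section for where
that matters.

## SVM decoding

One trial = one feature vector.  Smoothed features are sampled every 10 ms
(the 250 ms-smoothed signal is heavily oversampled at 1 ms; decimation
changes no scores but cuts solver work several-fold).  The classifier is a
linear SVM, C = 1, one-vs-rest, with per-column standardization fit on the
training split only; ties in the decision values resolve to the
lexicographically first class.  The solver tolerance is 1e-2 rather than
libsvm's 1e-3: only test-set predictions are consumed, and they are
insensitive to the final KKT digits.  A score is the mean test accuracy
over 20 stratified random 67/33 splits (stratification prevents empty
classes at 15 trials per tastant).  Neurons with fewer than 3 trials in a
class are skipped with a logged reason.  Two calibrations anchor the
protocol: structureless populations score 0.2 ± 0.02 (five-way) and 0.5
(pairwise), and disjoint constant features score exactly 1.0.

## Rate–Phase codes

The five post-delivery interlick intervals [t₀=0, t₁), …, [t₄, t₅) define
the RP code: R = (spikes in the five intervals)/5 — the denominator is
always the five declared intervals — and P is the unweighted mean over all
spikes of (t − tᵢ₋₁)/(tᵢ − tᵢ₋₁).  An alternative reading averages
per-interval mean phases first; it is available behind
`per_interval_mean=True`, and the two coincide when intervals hold equal
spike counts.  The spike-level average is the default because it is the
operational formula for a pooled phase.  Phase is linear in [0, 1), not
circular: a spike at the start of an interval and one at its end are
maximally different by fiat of the interval construction.  Trials lacking
five post-delivery licks, or firing in none of the five intervals, are
excluded (as values, not errors) with reasons `too_few_licks` / `no_spikes`.

Separation scores are computed by exact search, not gradient descent.  The
score of a line family is the maximal fraction of points correctly split,
over both tastant-to-side assignments; a point on the line counts as
"right of" it.  For a fixed direction, thresholds need only be scanned at
projection midpoints plus ±∞.  Over directions, the score is piecewise
constant and can change only where two projections tie, i.e. at angles
perpendicular to an inter-point difference; enumerating those critical
angles, the midpoints of the gaps between them, and the two axis
directions attains the global maximum.  Tests verify agreement with a
1000-angle brute-force grid to 1e-12 and the invariants
combination ≥ max(rate, phase) ≥ 0.5.  Scores are computed on all trials
(no train/test split): they describe geometric separability, not
generalization.

## Elastic shape analysis

The SRSF q = sgn(f′)·√|f′| (centred finite differences for f′) turns the
extended Fisher–Rao metric into the L² distance
√∫(q_f − q_g)² dt (trapezoid rule) and makes it invariant under common
time warps.  The analytic pair f(t)=t, g(t)=t² on [0,1], with distance
√(2 − 4√2/3), anchors the implementation to 1e-3 at 1000 samples.

**Alignment** minimizes ‖q_f − (q_g∘γ)√γ′‖ over monotone, boundary-fixed γ
by dynamic programming on an n×n lattice: candidate steps are the coprime
pairs (Δi, Δj) with components ≤ 7 (slopes between 1/7 and 7); edge costs
integrate the warped-SRSF residual along the step with trapezoid weights
and linear interpolation of q_g.  The identity path is in the lattice, so
alignment never increases the distance.  Since any monotone lattice path
factors into coprime primitive steps with identical cost, setting the slope
bound to n−1 makes the DP an *exact* search over all lattice warps; tests
exploit this to match an exhaustive path enumeration exactly on small
grids.  The DP kernel is compiled with numba.  Default grids: 200 samples
for the whole post-taste window, 50 per interlick segment (30 in the
scaled-down population tests); distances computed on the normalized domain
are rescaled by √span.

**Karcher mean**: initialized at the cross-sectional SRSF mean, then
iterates align-all/re-average, recentring by the inverse of the mean warp
to fix the gauge freedom (otherwise the mean drifts along the orbit).  The
objective (sum of squared aligned distances) is tracked; an iteration that
fails to improve it terminates the loop and the best iterate is returned,
so the recorded trace is nonincreasing by construction and a
non-converged call is flagged rather than failed.  Default 8 iterations
with relative tolerance 1e-4; the population analyses cap this lower
(2–4) because the objective is within a fraction of a percent of its
plateau after two iterations at these data sizes.

**Modes.**  *Whole-window*: one alignment of the post-taste 2 s.
*Interlick*: each of the five intervals is rescaled to [0,1] and aligned
separately across trials; aligned segments and segment warps are
concatenated (warps into a single continuous increasing function fixing
the five joins), so segment warps are directly interpretable as lick-phase
maps, in register with the RP-code phase definition.  *Randomized
intervals*: the control — four breakpoints drawn uniformly in absolute time
within the five-lick window (bounded by the shortest trial's span, minimum
segment 20 ms by resampling), shared across trials, each trial's last
segment running to its own span end; the partition deliberately ignores
lick timing.  Scores are averaged over 20 random partitions by default.
Breakpoints are intentionally *not* rescaled per trial: scaling by each
trial's span would track the licks and leak lick information into the
control.

**Warp features for decoding**: γ resampled to 100 points with the
identity subtracted, so the classifier sees timing deviations rather than
the shared ramp.

**Code-recovery behavior** under the generator: rate-only populations give
aligned-train scores well above warp scores; phase-only populations the
converse.  Phase-locked populations score higher (both aligned/original and
warp/original ratios) under interlick than under randomized partitions,
and the difference is null-calibrated when κ = 0.  The margin of that
comparison scales with trial-to-trial lick variability — with the
generator's fairly metronomic licking (10 ms jitter per interval) a random
partition still cuts most trials at similar phases, so the interlick
advantage, while clearly significant at 50 neurons, is smaller than it
would be under more variable natural licking.

## Statistics

The normality test (D'Agostino–Pearson K², χ² with 2 df, n ≥ 20 enforced),
one-sample one-sided t and paired t delegate to scipy behind thin wrappers
that enforce the contracts (sample sizes, nonzero variance, p ∈ [0,1]) and
return labelled results; their type-I error is verified at α = 0.05 over
500 null replicates.  QQ data uses plotting positions (i − ½)/n against
standard-normal quantiles.  Representation comparisons report the mean of
per-neuron ratios (variant/original), not the ratio of means, matching the
paired neuron-by-neuron design; interlick-vs-random comparisons use a
paired t on the same neuron set in both arms.

## Problem sizes

Calibrations and population checks run at desk scale, chosen once: 200
neurons for the chance-level calibration; 50 neurons per cell for the
code-recovery matrix and the interlick-vs-random comparison (the latter on
one phase-distinct tastant pair, 6 random repeats, segment grid 30, 10 SVM
repeats); 500 replicates for test calibration.  Library defaults remain at
the full protocol (20 SVM repeats, 20 random partitions, segment grid 50).

## Known limitations

- The DP searches piecewise-linear lattice warps with bounded slope;
  extreme timing differences (a bump at the very edge of a segment) cannot
  be fully absorbed, so a little timing information can remain in aligned
  trains.
- Fisher–Rao invariance holds up to discretization error that shrinks with
  grid refinement; steeply kinked warps need dense grids (the 4000-sample
  check bounds the error at 2.5e-3).
- Separation scores are exact but quadratic-plus in the number of points
  (all inter-point directions); intended for tens of trials, not thousands.
- P is a linear mean; strongly bimodal phase distributions within a trial
  are summarized poorly (a limitation of the RP reduction itself, which
  the elastic analysis exists to lift).
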