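# lickshape

Tools for asking a precise question about single neurons in the gustatory
cortex of a licking rodent: when the animal samples a tastant by rhythmic
licking, how much of the neuron's taste information is carried by its firing
*rate*, how much by spike *timing*, and how much does that timing gain from
being read *relative to the lick cycle* rather than in absolute time?

The package is a complete, tested reimplementation of that analysis for
trial-aligned spike/lick event data, driven by a synthetic generator so
every stage can be exercised and calibrated without access to recordings.
It is aimed at systems neuroscientists analyzing event-aligned spike trains
under rhythmic sampling behaviors (licking, whisking, sniffing).

## What it computes

Each trial is a 4 s window centered on taste delivery at t = 0 (the
delivery-triggering lick), with spike times, lick times and one of five
tastant labels (sucrose, NaCl, citric acid, quinine, water).

- **Preprocessing** (`lickshape.spike_io`): {0,1} rasterization at 1 ms,
  binning, and smoothing by convolution with a unit-area Gaussian kernel
  (σ = smoothing window).
- **SVM decoding** (`lickshape.decoding`): per-neuron classification scores
  from a linear SVM (C = 1, one-vs-rest, features standardized on the
  training split), averaged over 20 stratified 67/33 train/test splits;
  five-way and all ten pairwise scores; "coding neurons" are those scoring
  more than one standard deviation above the population mean.
- **Rate–Phase codes** (`lickshape.rate_phase`): each trial collapses to
  (R, P) over the first five post-delivery interlick intervals — R the mean
  spike count per interval, P the mean relative spike position in [0, 1)
  within its interval.  Separation scores report the best fraction of two
  tastants' RP points split by a vertical line (rate only), a horizontal
  line (phase only), or any line (combination), found by exact search over
  the finitely many geometrically distinct lines.
- **Elastic shape analysis** (`lickshape.elastic`): smoothed trains are
  compared in the extended Fisher–Rao metric via the square-root slope
  function q = sgn(f′)√|f′|, aligned to their Karcher mean by
  dynamic-programming time warping.  Aligned trains retain rate
  information; the warp functions γ retain the timing information removed
  by alignment, and each feeds its own SVM.  Alignment runs over the whole
  post-taste window, over each of the first five interlick intervals
  (warps then read as lick-phase maps), or over five random partitions of
  the same five-lick span — the control that tests whether the lick cycle
  itself matters.
- **Statistics** (`lickshape.stats`): D'Agostino–Pearson K² normality test,
  one-sided and paired t tests, QQ data, and per-neuron score-ratio
  summaries (aligned/original, warp/original).
- **Synthetic data** (`lickshape.synthetic`): Gaussian-jittered periodic
  licking (~7.7 Hz, six dry licks before delivery) and inhomogeneous-Poisson
  spiking whose intensity is modulated over lick phase by a unit-mean
  von-Mises bump, so firing rate and phase locking are independently
  controllable per tastant.

## Worked example

```python
from lickshape.synthetic import GeneratorConfig, TasteCodeSpec, generate_neuron
from lickshape.decoding import features_from_dataset, classification_score
from lickshape.rate_phase import dataset_rp_codes, separation_scores
from lickshape.elastic import esa_classification_scores

# a rate-coding neuron: per-tastant rates 2, 4, 8, 16, 32 spikes/s
neuron = generate_neuron(GeneratorConfig(seed=7, code_spec=TasteCodeSpec.rate_code()))

feats = features_from_dataset(neuron, "smoothed", window=250.0)
score = classification_score(feats, seed=0)
print(f"5-way SVM score (smoothed, 250 ms): {score.score:.3f}")

codes, excluded = dataset_rp_codes(neuron)
res = separation_scores(codes["sucrose"], codes["water"])
print(f"sucrose vs water separation: rate={res.rate_score:.3f} "
      f"phase={res.phase_score:.3f} combination={res.combination_score:.3f} "
      f"({len(excluded)} trials excluded)")

esa = esa_classification_scores(neuron, "interlick", window=25.0,
                                karcher_iters=3, seed=0)
print("interlick ESA scores:", {k: round(v.score, 3) for k, v in esa.items()})
```

prints

```
5-way SVM score (smoothed, 250 ms): 0.514
sucrose vs water separation: rate=1.000 phase=0.692 combination=1.000 (5 trials excluded)
interlick ESA scores: {'original': 0.383, 'aligned': 0.394, 'warp': 0.294}
```

Read: this neuron decodes five tastants at 0.51 (chance is 0.2).  Its most
extreme rate pair (2 vs 32 spikes/s) separates perfectly on R alone, so the
combination line gains nothing over the vertical line, while P alone reaches
only 0.69.  Under interlick elastic alignment the aligned trains (rate
information, 0.39) decode about as well as the original trains, but the
warp functions (timing information, 0.29) decode far worse — the signature
of a rate-coding neuron.

A full run (dataset → scores → RP → ESA → report) goes through one config:

```sh
lickshape run --config cfg.json     # see lickshape.pipeline.PipelineConfig
```

or stage by stage with `lickshape synth / decode / rpcode / rpsep / esa /
report`.

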