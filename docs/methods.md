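# Methods

## The model

The package treats local chromatin folding as a supervised learning problem
in both directions.  The genome is tiled into fixed bins (default 10 kbp).
Sequence information is an M×N matrix of fractional factor occupancies
x_{i,j} ∈ [0,1]; structure is an N×N contact-enrichment matrix P(c_ij)
obtained from raw Hi-C counts by ICE balancing followed by division by the
mean contact at each genomic separation (so every diagonal has mean 1 and
the entropic polymer decay is removed).

**Forward model.**  For a window of w bins plus two w-bin flanks, a width-1
convolutional filter maps the M factor values at each position to a single
chromatin state

    σ_i = logistic(Σ_j W⁰_j x_{i,j} + β₀) ∈ (0, 1),

and a dense stack maps the 3w-long state sequence to the w(w+1)/2 elements
of the flattened upper triangle (diagonal included) of the local map.  Layer
sizes interpolate exponentially between input and output:
size(k) = floor(n_in (n_out/n_in)^{k/n_layers}); for w = 80 this gives
460, 881, 1690, 3240 over four layers.  Every dense layer is
ReLU-activated, including the output layer — contact enrichments are
non-negative, and the recursion y^n = ReLU(W^n y^{n-1} + β) is applied
uniformly.  A flag (`output_activation`) switches the last layer to linear
if desired.

**Backward model.**  An independent dense stack maps the w(w+1)/2 local
contacts to the inner w chromatin states (the flanks are not predicted:
the local map carries little information about them and including them
destabilises convergence).  Hidden layers are ReLU, the output layer is
sigmoid so predicted states stay in (0,1).  For w = 80 the schedule gives
943, 274, 80.  Its training labels are the forward model's own σ sequence,
restricted to the inner w positions.

**Training.**  Cost = mean squared error on the distance-normalized
enrichments (plus an L2 penalty on the filter weights, forward model only).
Each epoch shuffles the training set and visits 30 contiguous shards;
updates are stochastic gradient descent with momentum.  Inverted dropout
(rate 0.1) acts on the dense hidden layers only — never on the filter
output or the output layer.  After each epoch the validation cost is
evaluated without dropout; the parameters with the best validation cost are
returned, and fitting stops when that cost has not improved (relative
min_delta 1e-4) for `patience` epochs.  All randomness (initialization,
shuffling, dropout) flows from a single integer seed, making runs
bit-reproducible on a given platform (exact floating-point reproducibility
across BLAS builds/thread counts is not guaranteed).

Hyperparameter defaults and why:

| knob | default | rationale |
|---|---|---|
| learning_rate | 0.5 | the cost is a *mean* over ~10³ outputs, so per-weight gradients are small; 0.5 with momentum 0.9 converges in a few hundred epochs where 0.01 is an order of magnitude away from convergence |
| momentum | 0.9 | standard heavy-ball value; higher values oscillated |
| lr_decay / lr_patience | 0.5 / 8 | halve the rate after 8 stalled epochs (plateau schedule); rescues late-stage convergence without destabilising the early phase |
| patience | 25 | several decay steps fit inside one stopping window |
| l2_filter | 1e-4 | weak shrinkage; keeps filter weights identified without biasing ranks |
| dropout | 0.1 | on dense hidden layers |
| n_batches | 30 | shards per epoch; batch size ≈ n_train/30 |
| max_epochs | 500 | upper bound; early stopping normally triggers first |

**Filter orientation.**  The model is exactly invariant under
(W⁰, β₀) → (−W⁰, −β₀) together with W¹ → −W¹, b¹ → b¹ + W¹·1 (this maps
σ → 1−σ).  After training, the filter is oriented so σ correlates
positively with a designated "active" reference track; the reparameterisation
changes no model output.

## Preprocessing conventions

- Coordinates are 0-based half-open (BED convention); bins tile each
  chromosome, the last bin possibly partial (its true width is the coverage
  denominator).
- Enriched intervals of one factor are unioned before computing per-bin
  coverage fractions, so values never exceed 1.
- Transcription score per bin = Σ_genes counts × (fraction of the bin
  occupied by the gene); active ⇔ score > 1, with ties labelled inactive.
- Contact pairs are intra-chromosomal only; with deduplication on, each
  unique pair id counts once.
- ICE: multiplicative bias updates b_i ← b_i·(rowsum_i/mean) until the
  relative row-sum spread is below `tol` (default 1e-5); zero-marginal bins
  are masked, plus optionally bins below a marginal quantile (`mask_frac`,
  default 0 — no extra masking).
- Expected-by-distance pools all supplied chromosomes by default
  (`per-chrom` available); entries at distance 0 are retained.
- Windows lacking full flanks are dropped (no padding); inner starts are
  w + k·stride.  Mirror augmentation appends the left-right inverted twin
  of every sample; a twin pair shares its train/validation assignment to
  avoid leakage.  The validation split subsamples 20 % of pool keys with a
  seeded generator.
- Bagging averages all window outputs covering a genome element
  (inverted-orientation outputs are un-mirrored first); predictions are
  stored as a diagonal band of width w.
- Gaussian smoothing uses a kernel normalized to sum 1, truncated at 4σ,
  with reflect padding.
- Roundtrip prediction splices the backward model's inner-w sequence into
  the forward model's own σ flanks before re-entering the forward dense
  stack (the alternative — aggregating backward states genome-wide and
  recutting 3w windows — is available via `backward_states`).

## Sensitivity analysis

Gradients are exact reverse-mode derivatives through the trained stacks
(the same backpropagation code used for training), taken with respect to
the chromatin states σ, not the raw tracks; the gradient with respect to
raw tracks factorizes through σ(1−σ)·W⁰ and a helper computes it.  The
ReLU subgradient at exactly 0 is taken as 0.  Distance-stratified averages
probe, in every test window, the pair (i,j) at separation d centred on the
inner-window midpoint (odd-d half-bin offsets round left), and report the
per-d mean and mean-square profile over windows.  Backward-model gradients
are class-conditioned on the central state (inactive < 0.3, active > 0.7 by
default).

## Synthetic data generator

The generator emulates the structure of binned embryo Hi-C plus
factor-occupancy tracks, with the ground truth retained:

- Hidden states: alternating active/inactive domains with geometric lengths
  (mean 10 bins ≈ 100 kbp, the sub-megabase domain scale); active values
  ~ N(1.0, 0.05), inactive ~ N(0.2, 0.05), clipped to [0,1] — matching the
  bimodal state distribution a trained filter produces on real chromatin.
- Tracks: mixing weights v carry both signs (magnitudes 0.8–2, rescaled up
  if too weak to span the state range with occupancies in [0,1]); each
  factor responds linearly to the unit-scaled logit of the state (positive
  weights enriched in active domains, negative in inactive), so that with
  zero noise the logistic filter with (v, intercept) returns the states
  exactly (up to the logit clip of 0.005).  Centred beta(2,2) noise of
  scale 0.25 is added and entries are re-clipped.
- Contacts: E(i,j) = exp(α(s_i+s_j−1) − γ·mean(s_{i..j}) + η_ij) with
  α = 0.8 (active contacting sites promote contact), γ = 1.2 (inactive
  interiors promote contact — the TAD-like rule), symmetric lognormal noise
  η (sd 0.2).  The normalized map divides E by its per-distance mean; the
  raw map draws Poisson counts with intensity E·C·(d+1)^{−1} (C = 100).

What the generator does *not* emulate: experimental visibility biases
(ICE's target), unmappable regions, inter-chromosomal contacts,
chromosome-scale compartment checkerboards, and any polymer physics beyond
the local state rule.  Passing the end-to-end suite therefore shows that
the pipeline and models recover a known sequence→structure rule from noisy
bounded data at realistic scale — not that they reproduce real-genome
correlation values.

## Study scale for the end-to-end suite

The trained-pipeline tests run at N = 4000 bins, M = 12 factors, w = 40,
stride 2, seed 1, max 400 epochs — the architecture schedule scales
automatically, and this fits a complete forward + backward training cycle
in a few minutes on one CPU.  Windows: 2498 train / 624 validation / 722
held-out test (mirror-augmented).

## Known limitations

- ICE assumes equal visibility; applied to data whose true marginals vary
  (as the generator's do), it flattens genuine signal.  The pipeline test
  therefore checks convergence to the pipeline's own noiseless limit.
- The filter weight ranking is recovered approximately (rank correlation
  ≈ 0.8 at the default noise), not exactly: the dense stack can absorb
  monotone reparameterisations of σ, leaving the filter scale weakly
  identified.
- Early stopping on a finite validation set, dropout noise and SGD make
  the learned parameters seed-dependent; all reported end-to-end numbers
  are at fixed seeds.
- The backward model predicts only the inner w states and smooths: its
  predictions correlate better with a Gaussian-smoothed σ than with raw σ,
  consistent with the forward model exploiting mainly neighbourhood-scale
  state structure.
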