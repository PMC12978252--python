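# Methods

This note documents the models, estimators and design choices behind the
package. It is written for someone who wants to understand what each stage
computes, which parameters matter, and what the synthetic benchmarks do and
do not demonstrate.

## Decay-rate estimation from SLAM-seq counts

Metabolic labelling with 4-thiouridine (4sU) marks newly transcribed RNA;
during library preparation the incorporated 4sU reads out as T→C
conversions. After a fixed pulse the conversion ratio at a transcript's T
positions tracks the transcription rate, and at steady state the decay rate
equals transcription divided by abundance. The estimator is therefore

    log k(g, c) = log( (ΣnTC + 1) / (ΣnT + 1) ) − log TPM(g, c)

with natural logarithms throughout. `n_T` is the total T-base coverage at
counted T positions (per-site read coverage summed over sites, as an
mpileup-based counter produces) and `n_TC` the total converted bases.
Filters, in order:

- transcripts with across-sample mean TPM strictly above 1 enter the
  analysis;
- optionally, site-level records with a conversion fraction at or above
  0.8 are dropped before aggregation — chemical conversion rates are a few
  percent, so near-complete conversion implies a germline variant rather
  than labelling (the 0.8 default is a parameter; anything between the
  highest plausible chemical rate and a heterozygous 0.5 minus noise is
  defensible);
- biological replicates are pooled by summing counts *before* the ratio is
  taken; a pooled T coverage below 10 makes the entry missing;
- per cell line, estimates strictly beyond median ± 3×IQR are masked
  (boundary values are kept — a deterministic tie rule).

Missing values stay missing (never imputed); the decay matrix carries an
explicit mask. Replicate-level estimates are recomputed with the same
formulas (unpooled) solely to give the per-gene one-way ANOVA across cell
lines its within-group variance; ANOVA p-values are Benjamini–Hochberg
corrected across genes.

The expression used in the denominator is the replicate-pooled per-cell-line
TPM; a per-replicate denominator would mix measurement noise into every
replicate's estimate and the assay's expression values are far more stable
than its conversion counts.

## The RBP-expression VAE

The cell state is summarised by the expression of the RNA-binding-protein
(RBP) gene set. A variational autoencoder with a single 500-unit hidden
layer compresses the D-dimensional RBP log-TPM vector to a 50-dimensional
Gaussian latent (defaults; both configurable). Loss:

    L = mean_j (x_j − x̂_j)² + β · [ −½ Σ_d (1 + logvar_d − mu_d² − e^{logvar_d}) ]

The reconstruction term is a *mean* over features while the KL term is a
*sum* over latent dimensions, so a dimension-free β would let the KL crush
the per-feature reconstruction signal; the default final β is therefore
1/D, the weight at which the two terms are commensurate, and β ramps
linearly from 0 over the first half of training so reconstruction is
learned before the prior is enforced. Profiles are z-scored per feature
inside the model (training a network on raw log-TPM offsets of ~4 wastes
thousands of optimiser steps learning the mean).

Because a cell-line panel provides only a handful of profiles, training
augments each profile with Gaussian jitter (σ = 0.05 × per-feature SD, 200
draws per profile by default). The model with the lowest validation total
loss (validation at the final β, so epochs are comparable) is returned.
Reconstruction quality is the Pearson correlation between original and
mu-path reconstructed values over all matrix entries.

## The hybrid stability model

The predictor maps (one-hot sequence, RBP profile) → log decay:

1. sequence head: two convolutional blocks (conv → leaky ReLU → batch
   norm → max pool → dropout), then three parallel dilated convolutions
   (dilations 1, 2, 4) whose outputs are summed residually with the block
   input (a 1×1 projection aligns channels when they differ), then a leaky
   ReLU and a flatten;
2. cell-state head: the pretrained VAE encoder's mean (mu) path, copied
   into the model;
3. integration: the concatenated features pass through a fully connected
   network to a scalar.

Sequences are one-hot encoded over channels A, C, G, T (U→T, ambiguous
IUPAC letters become all-zero columns), right-padded with zero columns to
`max_length`; transcripts outside the eligible length window are excluded,
never truncated. The training defaults are: Adam at
learning rate 0.001, batch 32, MSE loss, gradient clipping (global-norm,
default 5), training in two stages — 10 epochs with the encoder frozen,
then 5 epochs with everything free — and the snapshot with the best
validation Pearson is returned. Unstated sizes default to block 1 = 128
filters / kernel 12 / pool 4 / dropout 0.2, block 2 = 64/6/4/0.2, dilated
stage 64 filters of width 5, all overridable and recorded in run metadata.
Targets are z-scored on the training split only and predictions are mapped
back for reporting. "Residual parallel" is implemented as
`x (+ projection) + Σ_d conv_d(x)`; summing rather than concatenating keeps
the stage shape-preserving, which is what a residual combination means.

Splits are 80/5/15 (train/validation/test) over gene × cell-line instances
by default; a gene-disjoint mode (entire genes held out) and a
leave-one-cell-line-out mode implement the ablation protocols. Genes need
at least 4 unmasked cell-line decay values to enter training.

## Saliency interpretation

For each instance the exact backpropagated gradient of the prediction is
taken with respect to both inputs. Per-position importance is
|gradient × input| (the gradient at the observed base), zero in the
padding. Cell-state-specific sequence regulation is located by cross-cell
variability: per position, the SD of importance across cell lines is
detrended against the mean–variance relationship — a lowess fit of log SD
on log mean, pooled across *all* genes because the mean–variance law is a
property of the model, not of one transcript — and each position scores
SD / trend-expected SD, smoothed with a 10-nt moving average. (A raw CV =
SD/mean explodes where importance ≈ 0 and would hand the top decile to
noise positions; the corpus with fewer than 200 pooled positions falls
back to the raw CV.) Positions above the global 90th percentile seed
regions; runs separated by ≤ 20 nt merge; regions are reported in 0-based
half-open transcript coordinates (BED).

RBPs are ranked by gradient magnitude: the median over genes of the mean
|gradient| across cell lines. For a regulator acting multiplicatively
through a motif count the per-gene magnitude tracks the count, so each
gene's top-decile RBPs form the "differentially salient" RBP–gene pairs
fed to the enrichment step. The cross-cell CV of each RBP's gradient is
reported alongside; note that for an exactly linear interaction the causal
regulator's gradient is *constant* across cells, so CV alone cannot rank
causal regulators.

## Motif discovery and network statistics

De novo discovery is an exact k-mer scan (k = 6–8 by default): every k-mer
present in the pooled sequences is scored by the mutual information (bits)
between per-sequence presence and the foreground/background label. A
candidate is kept when its permutation z-score (label shuffles) exceeds 4
*and* its exact two-sided hypergeometric p-value survives Bonferroni
correction over the number of k-mers tested (family-wise α = 0.05) — with
tens of thousands of candidates a z cut alone would pass noise k-mers.
Survivors are de-duplicated greedily (hit-vector Jaccard > 0.5 with a
better-scoring kept motif) and k-mers differing in ≤ 1 position collapse
into an IUPAC consensus. The default background is length- and GC-matched
segments sampled from non-region portions of the same transcripts, which
controls composition bias.

Network statistics: per (motif, RBP), a one-sided hypergeometric p for
the over-representation of motif-bearing genes in the RBP's salient gene
set, with BH q-values over all matrix cells; per nominated pair, the
distribution of per-gene Spearman correlations between RBP expression and
regulon decay across cell lines, summarised by its median and a Wilcoxon
rank-sum test against non-regulon genes. Ranked-list enrichment cuts genes
into equal-population bins (default 9, stable tie-break on gene id) and
reports MI(hit, bin), a permutation z, and per-bin signed log10
hypergeometric p-values (positive = enriched, negative = depleted) — the
heat-strip representation.

## The synthetic-data generator

The generator is the test surface: it produces data whose regulatory
structure is known exactly.

- Sequences: i.i.d. uniform A/C/G/T background (uniform composition avoids
  confounding motif discovery), lengths uniform in a configurable range;
  each planted motif is inserted per gene with probability 0.4 at a
  uniform non-overlapping position (rejection sampling, 100 attempts).
- RBP expression: low-rank factor structure L·F (the non-negative shift is
  carried inside the factorisation so the noiseless matrix has rank
  exactly `latent_rank`) plus idiosyncratic per-RBP noise (SD 0.4 against
  a factor scale of 0.7). The idiosyncratic term is essential realism:
  exactly low-rank expression over six cell lines makes dozens of RBPs
  statistically interchangeable with any given regulator.
- Decay: log k(g,c) = b_g + Σ_j w_j · count(motif_j, g) · z(rbp_j, c) + ε,
  with per-gene baselines b_g ~ N(0, 0.7²), column-standardised RBP
  expression z, and ε ~ N(0, 0.3²). The default planted interactions are
  two stabilisers (negative weights −1.0 and −0.7): more of the RBP, slower
  decay of motif-bearing transcripts. Effect sizes are free simulation
  parameters — there is no measured value to match for them; the defaults make
  context effects comparable to, but not larger than, gene-intrinsic
  baseline differences.
- Expression: log-normal TPM (μ = ln 20, σ = 1) with small per-cell jitter.
- SLAM-seq counts: nT ~ Poisson(depth × relative expression × #T positions)
  — `depth` is mean read coverage and T-base coverage accumulates over all
  T positions — and nTC ~ Binomial(nT, p) with
  p = clip(0.05 × exp(log k)·TPM / geometric-mean, 10⁻⁴, 0.99).
  The conversion probability is proportional to the steady-state
  transcription rate (decay × abundance), normalised so 0.05 is the
  conversion fraction of the typical transcript (a realistic value for a
  4-hour pulse); the estimator's `−log TPM` inverts the abundance factor
  exactly, so estimated and true log decay agree up to an additive
  constant. Replicates are independent draws.

Everything is deterministic under the master seed (independent named
streams via `SeedSequence`).

What the generator does **not** emulate: isoform structure, UTR
annotation, non-uniform base composition, RNA secondary structure,
read-level errors, batch effects, or regulatory effects that are
non-multiplicative in RBP abundance. Passing the planted-recovery
benchmarks therefore demonstrates that the pipeline's machinery recovers
the structure it models, not that real decay data satisfies that model.

## The end-to-end benchmark and its problem sizes

`greyhound.experiments.planted_recovery` runs the full chain — generator →
decay estimation → VAE → model training → saliency → regions → motifs →
RBP–motif network — on one seed and measures recovery at every stage. The
benchmark uses 2000 transcripts of 120–300 nt across 6 cell lines with 40
RBPs, a narrower network (24 filters, 16 latent dimensions, 128-unit
integration layer) in float32, and two-stage epochs of 40 + 15. These sizes
are the package's desk-scale working point: short transcripts and a narrow
network keep a full run under ~10 minutes on one CPU core, and the epoch
counts give the optimiser a step budget comparable to the default
full-scale protocol (10 + 5 epochs at ~40 000 instances ≈ 20 000 updates) on the
smaller instance set — at 10 + 5 epochs on 12 000 instances the network
stops at gene-baseline memorisation and never forms motif detectors.

Two models are trained on the same data. The *prediction* protocol uses
the default instance-level split and its held-out r is the headline
prediction number. The *interpretation* protocol uses the gene-disjoint
split: with instances split at random, a desk-scale network can satisfy
the loss by memorising gene identity through the flatten layer (every
random sequence is its own fingerprint), which leaves saliency spread over
whole transcripts rather than motif positions; holding out entire genes
makes validation-based model selection favour networks whose sequence
features transfer — i.e. actual motif detectors — which is the property
saliency analysis needs. This is the same gene-disjoint ablation the
package exposes as a split mode for robustness checks.

## Known limitations

- **Single-RBP attribution is limited by the cell-line panel.** With six
  cell lines, any RBP whose standardised expression correlates ≳0.9 with
  the causal regulator is statistically indistinguishable from it at
  realistic noise levels, and the gradient at the expression input spreads
  over that correlated cluster according to the encoder's weights. In the
  planted benchmark the *motif* side of the network is recovered reliably
  (the top discovered motif is the planted one) and the planted regulator's
  regulon shows the planted anticorrelation, but the minimum-p edge of the
  motif–RBP matrix typically names a proxy from the cluster rather than
  the planted RBP itself. More cell lines, or stronger idiosyncratic
  expression variation, shrink the cluster; experimental follow-up is what
  resolves it in practice.
- The NumPy training loop is single-threaded; a full-scale problem
  (≈7000 transcripts of 512–4096 nt, 128-filter blocks, 1378 RBPs) is
  supported by the code but takes hours rather than minutes at that size.
- The exact-k-mer motif scan has no degenerate-position optimisation
  beyond the post-hoc IUPAC collapse; motifs with more than one variable
  position are found as families of exact k-mers.
- The permutation z for binary labels is computed from hypergeometric
  resampling of the overlap count, which is the exact label-shuffle null
  for presence/absence data; for multi-category labels full shuffles are
  used.

## Numerical conventions

- Natural log for decay rates everywhere; log₂ for mutual information.
- CV/variability ε = 1e-8; batch-norm ε = 1e-5; Adam (β₁, β₂, ε) =
  (0.9, 0.999, 1e-8).
- Interval outputs are 0-based half-open in transcript space.
- Outlier and expression filters use strict inequalities at their stated
  boundaries.
- float64 is the default compute dtype (gradient checks against central
  finite differences hold to ≤1e-3 relative); float32 is available for the
  large benchmark runs.
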