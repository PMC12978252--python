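# greyhound

Context-specific mRNA decay modelling: who destabilises what, and in which
cellular context?

Transcript stability is set jointly by *cis* sequence elements (motifs,
typically in the 3′UTR) and *trans* factors (RNA-binding proteins, RBPs)
whose expression varies between cell states. This package implements an
integrated pipeline for dissecting that interaction:

1. **SLAM-seq decay estimation** — per-gene, per-cell-line log decay rates
   from T→C conversion counts and steady-state expression, using the
   steady-state rule log k = log(conversion ratio) − log(TPM) with
   coverage, expression, variant and outlier filters, replicate pooling,
   and a per-gene ANOVA of decay differences across cell lines.
2. **Cell-state encoding** — a variational autoencoder (VAE) compresses
   the RBP expression vector into a low-dimensional latent code.
3. **Hybrid stability model** — a convolutional network over the one-hot
   transcript sequence (two conv blocks, then residual parallel dilated
   convolutions with dilations 1/2/4) is combined with the VAE encoder's
   mean vector in a fully connected integration network to predict log
   decay; training transfers the pretrained encoder frozen for 10 epochs,
   then fine-tunes everything for 5 (Adam, lr 0.001, batch 32, MSE,
   gradient clipping, best-validation-Pearson snapshot).
4. **Interpretation** — exact input gradients (saliency) per gene ×
   cell line; sequence regions whose importance varies across cell lines
   (mean–variance-detrended variability, top decile, runs merged within
   20 nt) and high-gradient RBPs.
5. **Motif/network inference** — mutual-information k-mer discovery over
   the variable regions against a GC/length-matched background, a
   hypergeometric RBP×motif enrichment map, regulon Spearman/Wilcoxon
   validation, and ranked-gene-list enrichment heat strips.
6. **Synthetic benchmark** — a generator that plants known motif–RBP
   interactions (log k = baseline + Σ w·count·z_RBP + noise) and
   binomially samples SLAM-seq counts consistent with them, so every
   stage has a ground-truth test surface.

The intended user is a computational biologist with decay profiling
(SLAM-seq style) and expression data across a panel of cell lines or
conditions, who wants candidate cis–trans regulatory pairs with honest
statistics. The neural-network layer is a small self-contained NumPy
implementation (`greyhound.nn`) with exact reverse-mode gradients — the
same code path yields training gradients and saliency maps, and it is
verified against finite differences in the test suite.

## Worked example

Generate a planted synthetic dataset and run the full pipeline from the
shell:

```
greyhound simulate --out demo --seed 5 --scale smoke
greyhound run-all --data demo --out demo_run --demo-scale smoke --seed 5
```

`demo_run/` then contains the decay matrix, ANOVA table, trained VAE,
predictions, RBP variability ranking, variable regions (BED + FASTA),
discovered motifs, the RBP×motif edge table, and a manifest with input
hashes and the seed. Or drive the library directly — this is the
end-to-end benchmark (2000 transcripts, 6 cell lines, 2 planted
stabilising interactions), as run:

```python
from greyhound.experiments import planted_recovery
out = planted_recovery(seed=101)
```

which printed, on this machine:

```
decay_recovery_r:            0.988     # estimated vs true log decay
vae_reconstruction_r:        0.976
heldout_r_instance_split:    0.792     # prediction protocol, held-out r
heldout_r_gene_holdout:      0.489     # never-seen genes
saliency_top_decile_planted: 0.384     # vs 0.093 for background positions
motifs:                      ['ATAATA', 'TAATAN', 'NATAAT', 'TAATAAT']
regulon_median_rho:          -0.886    # planted stabiliser's regulon
regulon_wilcoxon_p:          2.7e-292
```

Reading this: the decay estimator reconstructs the generating decay rates
almost exactly; the model predicts held-out gene×cell decay well; saliency
variability concentrates four-fold on the planted motif positions; de novo
discovery returns the planted AUA-type element (`ATAATA`) as its top
motif; and the planted stabiliser's regulon decay is strongly
anticorrelated with the regulator's expression, as planted (negative
weight: more RBP → slower decay). Identifying the *individual* causal RBP
from six cell lines is limited by expression collinearity — see
`docs/methods.md` for that analysis.

The per-stage model objects follow the familiar model/results pattern:

```python
from greyhound import SlamDecayModel
res = SlamDecayModel.from_files("counts.tsv", "expr.tsv").fit()
print(res.summary())         # filters applied, entries estimated, log base
decay = res.decay            # gene x cell-line matrix with missingness mask
anova = res.anova()          # per-gene F, p, BH q across cell lines
```

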