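"""Planted-signal recovery experiment.

Runs the whole pipeline on one synthetic dataset with known planted
cis-trans interactions and measures how much of the planted structure each
stage recovers.  Two models are trained on the same data: one under the
default instance-level split (the prediction protocol, whose held-out r is
reported) and one under the gene-disjoint split (the interpretation
protocol — only motif detectors that generalise to unseen transcripts
survive model selection there, which is what saliency analysis needs).

The returned dictionary carries, per stage: decay-estimator recovery r,
VAE reconstruction r, held-out prediction r for both protocols, the
planted-position saliency enrichment, the discovered motifs and whether
the top one overlaps a planted motif, the RBP variability ranking of the
planted regulators, the minimum-p cell of the motif-RBP matrix, and the
regulon sign statistics.
"""

from __future__ import annotations

import time

import numpy as np
from scipy import stats

from greyhound.simulate import SimConfig, simulate_dataset
from greyhound.slam import SlamDecayModel
from greyhound.vae import RBPVAE, VAEConfig
from greyhound.model import ModelConfig, build_instances, GreyHound
from greyhound.saliency import (
    compute_saliency_maps,
    variability_profiles,
    call_variable_regions,
    variable_rbps,
    region_sequences,
)
from greyhound.motifs import (
    discover_motifs,
    matched_background,
    motif_rbp_enrichment,
    motif_hits,
    regulon_correlation,
)

__all__ = ["planted_recovery", "overlaps_planted", "DEFAULT_E2E"]

#: study conditions of the scaled end-to-end experiment: 2000 transcripts
#: across 6 cell lines with two planted stabilising interactions; transcript
#: length and network width are reduced to desk scale (see docs/methods.md)
DEFAULT_E2E = dict(
    n_genes=2000,
    length_range=(120, 300),
    n_rbps=40,
    latent_rank=4,
    depth=200.0,
    vae=dict(hidden_size=64, latent_size=16, epochs=40, augment_draws=60),
    model=dict(
        conv_blocks=((24, 12, 5, 0.2), (24, 5, 5, 0.2)),
        dilated_filters=24,
        dilated_kernel=5,
        integration=(128,),
        latent_size=16,
        stage1_epochs=40,
        stage2_epochs=15,
        dtype="float32",
    ),
)


def overlaps_planted(pattern: str, planted: str, min_overlap: int = 4) -> bool:
    """True when a discovered pattern shares a >= min_overlap exact word
    with the planted motif (IUPAC letters in the pattern count as matches
    when they include the planted base)."""
    from greyhound.motifs import _IUPAC_EXPAND

    pattern = pattern.upper()
    for w in range(min_overlap, min(len(pattern), len(planted)) + 1):
        for i in range(len(pattern) - w + 1):
            word = pattern[i : i + w]
            for j in range(len(planted) - w + 1):
                target = planted[j : j + w]
                if all(t in _IUPAC_EXPAND[c] for c, t in zip(word, target)):
                    return True
    return False


def planted_recovery(seed: int, scale: dict | None = None, verbose: bool = False) -> dict:
    """Full pipeline on one seeded synthetic dataset; returns recovery metrics."""
    p = dict(DEFAULT_E2E)
    if scale:
        p.update(scale)
    t0 = time.time()
    cfg = SimConfig(
        n_genes=p["n_genes"],
        length_range=p["length_range"],
        n_rbps=p["n_rbps"],
        latent_rank=p["latent_rank"],
        seed=seed,
    )
    truth, counts = simulate_dataset(cfg, depth=p["depth"])
    planted = [(m, f"RBP{idx:04d}", w) for m, idx, w in cfg.planted_interactions]

    # decay estimation and its recovery against the generating truth
    dec = SlamDecayModel(counts, truth.expression).fit()
    est = dec.decay.values
    tr = truth.true_log_decay.loc[est.index, est.columns]
    ok = est.notna().to_numpy()
    decay_r = float(np.corrcoef(est.to_numpy()[ok], tr.to_numpy()[ok])[0, 1])

    # VAE pretraining
    vae = RBPVAE.from_dataframe(truth.rbp_matrix, VAEConfig(seed=seed, **p["vae"])).fit()
    vae_r = float(vae.reconstruction_quality(truth.rbp_matrix))

    max_len = p["length_range"][1]

    def _train(mode):
        inst = build_instances(
            truth.sequences, dec.decay, truth.rbp_matrix,
            seed=seed, mode=mode, max_length=max_len, min_length=1,
        )
        mcfg = ModelConfig(max_length=max_len, min_length=1, seed=seed, **p["model"])
        res = GreyHound(inst, vae, mcfg).fit()
        return inst, res

    # prediction protocol: instance-level split
    _, res_pred = _train("random")
    r_instance = float(res_pred.evaluate("test")["pearson"])

    # interpretation protocol: gene-disjoint split
    inst, res_interp = _train("gene_holdout")
    r_holdout = float(res_interp.evaluate("test")["pearson"])

    # saliency -> variable regions -> motifs -> edges
    maps = compute_saliency_maps(res_interp.model)
    rbp_table, salient_pairs = variable_rbps(maps, inst.rbp_ids)
    ranking = list(rbp_table["rbp"])
    planted_ranks = {r: ranking.index(r) + 1 for _m, r, _w in planted}
    by_gene: dict[str, list] = {}
    for m in maps:
        by_gene.setdefault(m.gene, []).append(m)
    profiles = variability_profiles(by_gene)
    lengths = {g: ms[0].length for g, ms in by_gene.items()}

    planted_scores, other_scores = [], []
    for g, ms in by_gene.items():
        L = lengths[g]
        prof = profiles[g][:L]
        mask = np.zeros(L, bool)
        for motif, start in truth.motif_positions.get(g, []):
            mask[start : start + len(motif)] = True
        planted_scores.append(prof[mask])
        other_scores.append(prof[~mask])
    planted_scores = np.concatenate(planted_scores)
    other_scores = np.concatenate(other_scores)
    thr = np.quantile(np.concatenate([planted_scores, other_scores]), 0.9)
    frac_planted_top = float((planted_scores > thr).mean())
    frac_other_top = float((other_scores > thr).mean())
    # hypergeometric enrichment of planted positions in the top decile
    N = planted_scores.size + other_scores.size
    K = int((planted_scores > thr).sum() + (other_scores > thr).sum())
    n_pl = planted_scores.size
    k_pl = int((planted_scores > thr).sum())
    loc_p = float(stats.hypergeom.sf(k_pl - 1, N, K, n_pl))

    regions = call_variable_regions(profiles, lengths)
    regions = [r for r in regions if r.end - r.start >= 6]
    region_sequences(regions, truth.sequences)
    fg = [r.subsequence for r in regions]
    excl: dict[str, list] = {}
    for r in regions:
        excl.setdefault(r.gene, []).append((r.start, r.end))
    bg = matched_background(fg, truth.sequences, exclude=excl, seed=seed)
    motifs = discover_motifs(fg, bg, seed=seed)
    top_motif = motifs[0].pattern if motifs else ""
    top_overlaps = bool(motifs) and any(
        overlaps_planted(top_motif, m) for m, _r, _w in planted
    )

    best_edge = (None, None)
    edge_is_planted = False
    if motifs:
        _pmat, edges = motif_rbp_enrichment(motifs, salient_pairs, truth.sequences)
        be = min(edges, key=lambda e: e.p)
        best_edge = (be.rbp, be.motif)
        edge_is_planted = any(
            be.rbp == rbp and overlaps_planted(be.motif, m) for m, rbp, _w in planted
        )

    # regulon sign recovery for the first planted (stabilising) pair
    motif0, rbp0, _w0 = planted[0]
    hit = motif_hits(motif0, truth.sequences)
    reg = dec.decay.values.loc[dec.decay.values.index.intersection(hit)]
    bgd = dec.decay.values.loc[~dec.decay.values.index.isin(hit)]
    median_rho, wilcoxon_p, _ = regulon_correlation(
        truth.rbp_matrix.loc[rbp0], reg, bgd
    )

    out = dict(
        seed=seed,
        decay_recovery_r=decay_r,
        vae_reconstruction_r=vae_r,
        heldout_r_instance_split=r_instance,
        heldout_r_gene_holdout=r_holdout,
        planted_rbp_ranks=planted_ranks,
        best_planted_rbp_rank=min(planted_ranks.values()),
        saliency_top_decile_planted=frac_planted_top,
        saliency_top_decile_other=frac_other_top,
        saliency_localization_p=loc_p,
        n_regions=len(regions),
        motifs=[m.pattern for m in motifs],
        top_motif=top_motif,
        top_motif_overlaps_planted=top_overlaps,
        best_edge=best_edge,
        edge_is_planted=edge_is_planted,
        regulon_median_rho=float(median_rho),
        regulon_wilcoxon_p=float(wilcoxon_p),
        runtime_s=time.time() - t0,
    )
    if verbose:
        for k, v in out.items():
            print(f"  {k}: {v}")
    return out
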