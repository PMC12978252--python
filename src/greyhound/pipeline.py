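"""Pipeline plumbing: configuration, stage orchestration, manifests.

``run_pipeline`` executes decay estimation -> VAE pretraining -> model
training -> saliency interpretation -> motif/network inference on a set
of input files (optionally produced by the synthetic generator), writing
each stage's outputs plus a JSON manifest (input hashes, seed, versions,
stage list) into a run directory.  Re-running with the same config and
seed reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from greyhound import __version__
from greyhound import io as ghio
from greyhound.simulate import SimConfig, simulate_dataset, write_truth
from greyhound.slam import SlamDecayModel, DecayMatrix
from greyhound.vae import RBPVAE, VAEConfig, VAEResults
from greyhound.model import ModelConfig, build_instances, GreyHound
from greyhound.saliency import (
    compute_saliency_maps,
    variability_profiles,
    call_variable_regions,
    variable_rbps,
    region_sequences,
    regions_to_bed,
)
from greyhound.motifs import (
    discover_motifs,
    matched_background,
    motif_rbp_enrichment,
)

__all__ = ["RunConfig", "run_pipeline", "make_demo", "DEMO_SCALES"]

STAGES = ("decay", "vae", "train", "interpret", "motifs", "report")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialised verbatim into the run dir."""

    fasta: str
    expression: str
    counts: str
    rbp_matrix: str
    outdir: str
    seed: int = 0
    # decay estimation
    tpm_min: float = 1.0
    min_coverage: int = 10
    pseudo: float = 1.0
    iqr_k: float = 3.0
    # modelling
    vae: VAEConfig = field(default_factory=VAEConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    split_fractions: tuple[float, float, float] = (0.80, 0.05, 0.15)
    split_mode: str = "random"
    min_cells: int = 4
    # interpretation
    cv_quantile: float = 0.90
    merge_gap: int = 20
    min_region_len: int = 6
    motif_k_range: tuple[int, int] = (6, 8)
    motif_z_threshold: float = 4.0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "vae" in data and isinstance(data["vae"], dict):
            data["vae"] = VAEConfig(**data["vae"])
        if "model" in data and isinstance(data["model"], dict):
            m = data["model"]
            for key in ("conv_blocks", "dilations", "integration"):
                if key in m and m[key] is not None:
                    m[key] = tuple(tuple(b) if isinstance(b, list) else b for b in m[key])
            data["model"] = ModelConfig(**m)
        for key in ("split_fractions", "motif_k_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the pipeline; returns the run directory.

    Raises ValueError (with file context) on schema violations; a partial
    run still leaves a valid manifest listing the stages that completed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "run_config.yaml")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "platform": platform.platform(),
        "numpy": np.__version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("fasta", cfg.fasta),
                ("expression", cfg.expression),
                ("counts", cfg.counts),
                ("rbp_matrix", cfg.rbp_matrix),
            )
        },
        "stages": [],
        "parameters": {
            "tpm_min": cfg.tpm_min,
            "min_coverage": cfg.min_coverage,
            "pseudo": cfg.pseudo,
            "iqr_k": cfg.iqr_k,
            "split_mode": cfg.split_mode,
            "min_cells": cfg.min_cells,
            "cv_quantile": cfg.cv_quantile,
            "merge_gap": cfg.merge_gap,
            "motif_z_threshold": cfg.motif_z_threshold,
        },
    }

    def _save_manifest():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    report = ghio.validate_inputs(cfg.fasta, cfg.expression, cfg.counts)
    (outdir / "validation.txt").write_text(str(report) + "\n")
    if not report.ok:
        _save_manifest()
        raise ValueError(f"input validation failed:\n{report}")

    sequences = ghio.read_fasta(cfg.fasta)
    expression = ghio.read_expression(cfg.expression)
    counts = ghio.read_counts(cfg.counts)
    rbp_matrix = ghio.read_expression(cfg.rbp_matrix)

    # -- decay ------------------------------------------------------------
    decay_res = None
    if "decay" in stages:
        decay_res = SlamDecayModel(
            counts,
            expression,
            tpm_min=cfg.tpm_min,
            min_coverage=cfg.min_coverage,
            pseudo=cfg.pseudo,
            iqr_k=cfg.iqr_k,
        ).fit()
        decay_res.decay.to_tsv(outdir / "decay_matrix.tsv")
        anova = decay_res.anova()
        anova.to_csv(outdir / "decay_anova.tsv", sep="\t")
        (outdir / "decay_summary.txt").write_text(decay_res.summary() + "\n")
        manifest["stages"].append("decay")
        _save_manifest()

    # -- VAE --------------------------------------------------------------
    vae_res = None
    if "vae" in stages:
        vae_cfg = dataclasses.replace(cfg.vae, seed=cfg.seed)
        vae_res = RBPVAE.from_dataframe(rbp_matrix, vae_cfg).fit()
        vae_res.save(outdir / "rbp_vae.npz")
        vae_res.history.to_csv(outdir / "vae_history.tsv", sep="\t", index=False)
        manifest["stages"].append("vae")
        _save_manifest()

    # -- GreyHound training -----------------------------------------------
    model_res = None
    inst = None
    if "train" in stages:
        if decay_res is None or vae_res is None:
            raise ValueError("train stage requires decay and vae stages")
        inst = build_instances(
            sequences,
            decay_res.decay,
            rbp_matrix,
            split_fractions=cfg.split_fractions,
            seed=cfg.seed,
            mode=cfg.split_mode,
            max_length=cfg.model.max_length,
            min_length=cfg.model.min_length,
            min_cells=cfg.min_cells,
        )
        model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed)
        model_res = GreyHound(inst, vae_res, model_cfg).fit()
        model_res.predictions("all").to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        model_res.history.to_csv(outdir / "train_history.tsv", sep="\t", index=False)
        (outdir / "model_summary.txt").write_text(model_res.summary() + "\n")
        manifest["stages"].append("train")
        _save_manifest()

    # -- interpretation ---------------------------------------------------
    regions = None
    salient_pairs = None
    if "interpret" in stages:
        if model_res is None:
            raise ValueError("interpret stage requires the train stage")
        maps = compute_saliency_maps(model_res.model)
        rbp_table, salient_pairs = variable_rbps(maps, inst.rbp_ids)
        rbp_table.to_csv(outdir / "rbp_variability.tsv", sep="\t", index=False)
        by_gene: dict[str, list] = {}
        for m in maps:
            by_gene.setdefault(m.gene, []).append(m)
        profiles = variability_profiles(by_gene)
        lengths = {g: ms[0].length for g, ms in by_gene.items()}
        regions = call_variable_regions(profiles, lengths, cfg.cv_quantile, cfg.merge_gap)
        regions = [r for r in regions if r.end - r.start >= cfg.min_region_len]
        region_sequences(regions, sequences)
        regions_to_bed(regions, outdir / "variable_regions.bed")
        with open(outdir / "variable_regions.fa", "w") as fh:
            for i, r in enumerate(regions):
                fh.write(f">{r.gene}:{r.start}-{r.end}\n{r.subsequence}\n")
        manifest["stages"].append("interpret")
        _save_manifest()

    # -- motifs -----------------------------------------------------------
    if "motifs" in stages:
        if regions is None or salient_pairs is None:
            raise ValueError("motifs stage requires the interpret stage")
        fg = [r.subsequence for r in regions]
        excl: dict[str, list] = {}
        for r in regions:
            excl.setdefault(r.gene, []).append((r.start, r.end))
        bg = matched_background(fg, sequences, exclude=excl, seed=cfg.seed)
        motifs = discover_motifs(
            fg,
            bg,
            k_range=cfg.motif_k_range,
            z_threshold=cfg.motif_z_threshold,
            seed=cfg.seed,
        )
        pd.DataFrame(
            [(m.pattern, m.k, m.mi, m.z, m.n_hits) for m in motifs],
            columns=["pattern", "k", "MI", "z", "n_hits"],
        ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
        if motifs:
            pmat, edges = motif_rbp_enrichment(motifs, salient_pairs, sequences)
            with np.errstate(divide="ignore"):
                (-np.log10(pmat)).to_csv(outdir / "rbp_motif_neglog10p.tsv", sep="\t")
            pd.DataFrame(
                [(e.rbp, e.motif, e.p, e.q, e.overlap) for e in edges],
                columns=["rbp", "motif", "p", "q", "overlap"],
            ).to_csv(outdir / "rbp_motif_edges.tsv", sep="\t", index=False)
        manifest["stages"].append("motifs")
        _save_manifest()

    if "report" in stages:
        manifest["stages"].append("report")
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _save_manifest()
    return outdir


DEMO_SCALES = {
    "smoke": dict(n_genes=200, length_range=(100, 240), n_rbps=30),
    "test": dict(n_genes=1000, length_range=(120, 300), n_rbps=40),
    "full": dict(n_genes=5000, length_range=(512, 4096), n_rbps=200),
}


def demo_run_config(data_dir, outdir, scale: str = "smoke", seed: int = 0) -> RunConfig:
    """RunConfig for a demo dataset, with model sizes suited to its scale.

    Demo transcripts are short (see ``DEMO_SCALES``), so the conv stack and
    VAE are shrunk accordingly and the two training stages are lengthened
    to give the optimiser a step budget comparable to the full-scale
    protocol on the smaller instance set.
    """
    data = Path(data_dir)
    scales = {
        "smoke": dict(
            max_length=240,
            vae=VAEConfig(hidden_size=32, latent_size=8, epochs=30, augment_draws=40),
            model=dict(
                conv_blocks=((16, 8, 4, 0.2), (16, 5, 4, 0.2)),
                dilated_filters=16, dilated_kernel=5, integration=(32,),
                latent_size=8, stage1_epochs=12, stage2_epochs=6, dtype="float32",
            ),
        ),
        "test": dict(
            max_length=300,
            vae=VAEConfig(hidden_size=64, latent_size=16, epochs=40, augment_draws=60),
            model=dict(
                conv_blocks=((24, 12, 5, 0.2), (24, 5, 5, 0.2)),
                dilated_filters=24, dilated_kernel=5, integration=(128,),
                latent_size=16, stage1_epochs=40, stage2_epochs=15, dtype="float32",
            ),
        ),
    }
    if scale not in scales:
        raise ValueError(f"demo scale must be one of {sorted(scales)}")
    spec = scales[scale]
    model_cfg = ModelConfig(max_length=spec["max_length"], min_length=1, **spec["model"])
    return RunConfig(
        fasta=str(data / "transcripts.fa"),
        expression=str(data / "expression.tsv"),
        counts=str(data / "conversion_counts.tsv"),
        rbp_matrix=str(data / "rbp_expression.tsv"),
        outdir=str(outdir),
        seed=seed,
        vae=spec["vae"],
        model=model_cfg,
        min_cells=1,
    )


def make_demo(outdir, seed: int = 0, scale: str = "smoke", depth: float = 200.0) -> Path:
    """Write a self-contained synthetic demo dataset plus digests."""
    if scale not in DEMO_SCALES:
        raise ValueError(f"scale must be one of {sorted(DEMO_SCALES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed, latent_rank=4, **DEMO_SCALES[scale])
    truth, counts = simulate_dataset(cfg, depth=depth)
    write_truth(truth, outdir)
    counts.to_csv(outdir / "conversion_counts.tsv", sep="\t", index=False)
    digests = {
        name: _sha256(outdir / name)
        for name in (
            "transcripts.fa",
            "rbp_expression.tsv",
            "expression.tsv",
            "true_log_decay.tsv",
            "conversion_counts.tsv",
            "truth.json",
        )
    }
    with open(outdir / "digests.json", "w") as fh:
        json.dump({"seed": seed, "scale": scale, "sha256": digests}, fh, indent=1)
    return outdir
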