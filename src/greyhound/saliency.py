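"""Gradient-based interpretation of a trained decay model.

For each (gene, cell line) instance the gradient of the predicted decay
with respect to both heads is computed exactly by backpropagation:
``seq_grad`` (4 x L, at the one-hot input) and ``rbp_grad`` (over the RBP
expression vector).  Per-position importance is |gradient x input| — the
magnitude of the gradient at the observed base — masked to zero in the
padding.

Cell-state-specific regulation is then located by *variability across cell
lines*: positions (or RBPs) whose importance changes between cellular
contexts.  Position profiles use a coefficient of variation (CV) across
cell lines, detrended against the mean-variance relationship (lowess of
log SD on log mean) and smoothed with a moving average; positions in the
top decile of the global CV distribution seed variable regions, which are
merged when separated by at most 20 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SaliencyMap",
    "VariableRegion",
    "compute_saliency",
    "compute_saliency_maps",
    "position_variability",
    "variability_profiles",
    "call_variable_regions",
    "variable_rbps",
    "regions_to_bed",
    "region_sequences",
]


@dataclass
class SaliencyMap:
    """Exact input gradients for one gene x cell instance."""

    gene: str
    cell: str
    seq_grad: np.ndarray  # (4, L)
    rbp_grad: np.ndarray  # (D,)
    position_importance: np.ndarray  # (L,), |grad x input|, zero in padding
    length: int


@dataclass
class VariableRegion:
    """A merged run of high-variability positions on one transcript.

    Coordinates are 0-based half-open in transcript space.
    """

    gene: str
    start: int
    end: int
    peak_cv: float
    subsequence: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")


def compute_saliency(model, gene_index: int, cell_index: int) -> SaliencyMap:
    """Saliency for one instance of the model's InstanceSet (eval mode)."""
    inst = model.instances
    X = inst.X[gene_index : gene_index + 1]
    P = inst.profiles[cell_index : cell_index + 1]
    for p in model.params():
        if not np.all(np.isfinite(p.value)):
            raise ValueError(f"model parameter {p.name} contains non-finite values")
    model.forward(X, P, train=False)
    gX, gP = model.backward(np.ones(1, dtype=X.dtype))
    L = inst.lengths[gene_index]
    imp = np.abs((gX[0] * X[0]).sum(axis=0))
    imp[L:] = 0.0
    return SaliencyMap(
        gene=inst.genes[gene_index],
        cell=inst.cells[cell_index],
        seq_grad=gX[0],
        rbp_grad=gP[0],
        position_importance=imp,
        length=int(L),
    )


def compute_saliency_maps(model, genes: list[str] | None = None, chunk: int = 128) -> list[SaliencyMap]:
    """Saliency for every (gene, cell) pair, optionally restricted to genes.

    Computed in batches: in eval mode every instance's output depends only
    on its own input, so one backward pass yields each instance's exact
    gradient.
    """
    inst = model.instances
    gene_rows = (
        list(range(len(inst.genes))) if genes is None else [inst.genes.index(g) for g in genes]
    )
    pairs = [(gi, ci) for gi in gene_rows for ci in range(len(inst.cells))]
    maps: list[SaliencyMap] = []
    for start in range(0, len(pairs), chunk):
        batch = pairs[start : start + chunk]
        X = inst.X[[gi for gi, _ in batch]]
        P = inst.profiles[[ci for _, ci in batch]]
        model.forward(X, P, train=False)
        gX, gP = model.backward(np.ones(len(batch), dtype=X.dtype))
        for row, (gi, ci) in enumerate(batch):
            L = int(inst.lengths[gi])
            imp = np.abs((gX[row] * X[row]).sum(axis=0))
            imp[L:] = 0.0
            maps.append(
                SaliencyMap(
                    gene=inst.genes[gi],
                    cell=inst.cells[ci],
                    seq_grad=gX[row],
                    rbp_grad=gP[row],
                    position_importance=imp,
                    length=L,
                )
            )
    return maps


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def variability_profiles(
    maps_by_gene: dict[str, list[SaliencyMap]],
    smooth_window: int = 10,
    eps: float = 1e-8,
    detrend_min_positions: int = 200,
    lowess_frac: float = 0.3,
    max_fit_points: int = 3000,
) -> dict[str, np.ndarray]:
    """Corpus-wide mean-variance-detrended variability profiles.

    The mean-variance relationship of saliency magnitudes is a property of
    the model, not of one transcript, so the lowess fit of log SD on log
    mean pools positions across *all* genes; each position's score is its
    cross-cell SD divided by the trend-expected SD at its mean.  This
    keeps scores comparable across genes (a raw CV = SD/mean explodes at
    near-zero-importance positions and would hand the global top decile to
    noise).  Falls back to per-gene raw CV when the pooled corpus is
    smaller than ``detrend_min_positions``.
    """
    stats_by_gene: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    pooled_mean, pooled_sd = [], []
    for gene, ms in maps_by_gene.items():
        if len(ms) < 2:
            raise ValueError(f"gene {gene} has maps for < 2 cell lines")
        L = ms[0].length
        imp = np.stack([m.position_importance[:L] for m in ms])
        sd = imp.std(axis=0, ddof=0)
        mean = imp.mean(axis=0)
        stats_by_gene[gene] = (mean, sd, L)
        ok = sd > 0
        pooled_mean.append(mean[ok])
        pooled_sd.append(sd[ok])
    pooled_mean = np.concatenate(pooled_mean) if pooled_mean else np.array([])
    profiles: dict[str, np.ndarray] = {}
    if pooled_mean.size >= detrend_min_positions:
        pooled_sd = np.concatenate(pooled_sd)
        lm, ls = np.log(pooled_mean + eps), np.log(pooled_sd + eps)
        if lm.size > max_fit_points:
            rng = np.random.default_rng(0)
            sel = rng.choice(lm.size, max_fit_points, replace=False)
        else:
            sel = np.arange(lm.size)
        fit = sm.nonparametric.lowess(ls[sel], lm[sel], frac=lowess_frac)
        fx, fy = fit[:, 0], fit[:, 1]
        for gene, (mean, sd, L) in stats_by_gene.items():
            expected = np.exp(np.interp(np.log(mean + eps), fx, fy))
            score = np.where(sd > 0, sd / (expected + eps), 0.0)
            full = np.zeros(maps_by_gene[gene][0].position_importance.shape[0])
            full[:L] = _moving_average(score, smooth_window)
            full[L:] = 0.0
            profiles[gene] = np.maximum(full, 0.0)
    else:
        for gene, ms in maps_by_gene.items():
            profiles[gene] = position_variability(
                ms, smooth_window=smooth_window, eps=eps, detrend_min_positions=np.inf
            )
    return profiles


def position_variability(
    maps: list[SaliencyMap],
    smooth_window: int = 10,
    eps: float = 1e-8,
    detrend_min_positions: int = 200,
) -> np.ndarray:
    """Smoothed, mean-variance-detrended CV profile for one gene.

    ``maps`` are the saliency maps of a single gene across >= 2 cell lines.
    Raw CV is SD/(mean + eps) per position; with enough positions the SD is
    first detrended by a lowess fit of log SD on log mean (the detrended
    score is SD divided by the trend-expected SD), which removes the
    trivial scaling of variance with importance magnitude.  The profile is
    finally smoothed with a ``smooth_window`` moving average.  Padding
    positions stay exactly zero.
    """
    if len(maps) < 2:
        raise ValueError("need saliency maps from >= 2 cell lines")
    gene = maps[0].gene
    L = maps[0].length
    for m in maps:
        if m.gene != gene or m.length != L:
            raise ValueError("all maps must describe the same gene")
    imp = np.stack([m.position_importance[:L] for m in maps])
    sd = imp.std(axis=0, ddof=0)
    mean = imp.mean(axis=0)
    if L >= detrend_min_positions and np.any(sd > 0):
        pos = sd > 0
        log_mean = np.log(mean[pos] + eps)
        log_sd = np.log(sd[pos] + eps)
        fit = sm.nonparametric.lowess(log_sd, log_mean, frac=0.5, return_sorted=False)
        cv = np.zeros(L)
        cv[pos] = sd[pos] / (np.exp(fit) + eps)
    else:
        cv = sd / (mean + eps)
    full = np.zeros(maps[0].position_importance.shape[0])
    full[:L] = _moving_average(cv, smooth_window)
    full[:L] = np.maximum(full[:L], 0.0)
    full[L:] = 0.0
    return full


def call_variable_regions(
    cv_profiles: dict[str, np.ndarray],
    lengths: dict[str, int],
    quantile: float = 0.90,
    merge_gap: int = 20,
) -> list[VariableRegion]:
    """Threshold CV profiles globally and merge nearby runs into regions.

    The threshold is the ``quantile`` of all in-sequence CV values pooled
    across genes; positions above it (and strictly positive) seed regions;
    runs separated by <= ``merge_gap`` nt merge.  Idempotent in the sense
    that the merged regions' position sets reproduce themselves.
    """
    pooled = np.concatenate([cv_profiles[g][: lengths[g]] for g in cv_profiles]) if cv_profiles else np.array([])
    if pooled.size == 0 or not np.any(pooled > 0):
        return []
    threshold = float(np.quantile(pooled, quantile))
    regions: list[VariableRegion] = []
    for gene, profile in cv_profiles.items():
        L = lengths[gene]
        above = np.flatnonzero((profile[:L] > threshold) & (profile[:L] > 0))
        if above.size == 0:
            continue
        start = prev = int(above[0])
        for pos in above[1:]:
            pos = int(pos)
            if pos - prev - 1 <= merge_gap:
                prev = pos
            else:
                regions.append(_make_region(gene, start, prev + 1, profile))
                start = prev = pos
            prev = pos
        regions.append(_make_region(gene, start, prev + 1, profile))
    return regions


def _make_region(gene: str, start: int, end: int, profile: np.ndarray) -> VariableRegion:
    return VariableRegion(gene=gene, start=start, end=end, peak_cv=float(profile[start:end].max()))


def variable_rbps(
    maps: list[SaliencyMap],
    rbp_ids: list[str],
    quantile: float = 0.90,
    pair_quantile: float = 0.90,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Rank RBPs by the saliency of their expression input.

    Per gene, each RBP's importance is the mean of |rbp_grad| over cell
    lines; the ranking score is the median of that importance across
    genes (high gradient values mark regulators the model relies on).
    For a regulator acting multiplicatively through a motif count, the
    per-gene gradient magnitude tracks the motif count, so the per-gene
    top-``pair_quantile`` RBPs form the "differentially salient"
    RBP-gene pairs used downstream for motif enrichment.  The cross-cell
    CV of each RBP's gradient is reported alongside as ``cv``.

    Returns (ranked table with a ``flagged`` column for scores above the
    ``quantile`` of all scores, mapping rbp -> salient gene set).
    """
    genes = sorted({m.gene for m in maps})
    cells = sorted({m.cell for m in maps})
    if len(genes) < 2 or len(cells) < 2:
        raise ValueError("need maps across >= 2 genes and >= 2 cell lines")
    imp_by_gene: dict[str, np.ndarray] = {}
    cv_by_gene: dict[str, np.ndarray] = {}
    for gene in genes:
        grads = np.stack(
            [np.abs(m.rbp_grad) for m in maps if m.gene == gene]
        )  # (n_cells, D)
        if grads.shape[0] < 2:
            continue
        imp_by_gene[gene] = grads.mean(axis=0)
        cv_by_gene[gene] = grads.std(axis=0, ddof=0) / (grads.mean(axis=0) + 1e-8)
    imp_matrix = np.stack([imp_by_gene[g] for g in imp_by_gene])  # (genes, D)
    cv_matrix = np.stack([cv_by_gene[g] for g in cv_by_gene])
    score = np.median(imp_matrix, axis=0)
    cv_score = np.median(cv_matrix, axis=0)
    cutoff = float(np.quantile(score, quantile))
    table = (
        pd.DataFrame(
            {"rbp": rbp_ids, "score": score, "cv": cv_score, "flagged": score > cutoff}
        )
        .sort_values("score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    salient_pairs: dict[str, set[str]] = {r: set() for r in rbp_ids}
    gene_list = list(imp_by_gene)
    for gi, gene in enumerate(gene_list):
        thr = np.quantile(imp_matrix[gi], pair_quantile)
        for d in np.flatnonzero(imp_matrix[gi] > thr):
            salient_pairs[rbp_ids[d]].add(gene)
    return table, salient_pairs


def regions_to_bed(regions: list[VariableRegion], path) -> None:
    """Write regions as BED (transcript-space, 0-based half-open).

    Score is 1000 x peak CV normalised to the best region.
    """
    top = max((r.peak_cv for r in regions), default=1.0) or 1.0
    with open(path, "w") as fh:
        for r in regions:
            score = int(round(1000 * r.peak_cv / top))
            fh.write(f"{r.gene}\t{r.start}\t{r.end}\tvariable_region\t{score}\t.\n")


def region_sequences(regions: list[VariableRegion], sequences: dict[str, str]) -> list[VariableRegion]:
    """Attach subsequences from the transcript FASTA dict; returns regions."""
    for r in regions:
        r.subsequence = sequences[r.gene][r.start : r.end]
    return regions
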