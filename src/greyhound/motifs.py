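"""Mutual-information motif discovery and RBP-motif network statistics.

De novo discovery scans all exact k-mers (default k = 6..8) occurring in a
foreground sequence set and scores each by the mutual information (in
bits) between per-sequence motif presence and the foreground/background
label; significance comes from a permutation z-score of the MI under label
shuffles, and redundant k-mers (hit-vector Jaccard > 0.5 with a
better-scoring kept motif) are removed greedily.  Kept k-mers differing in
at most one position are collapsed into an IUPAC consensus.

Downstream statistics mirror the regulatory-network construction: one-sided
hypergeometric enrichment of motif-bearing genes within each RBP's
differentially-salient gene set; Spearman correlation between an RBP's
expression and the decay of its motif-defined regulon across cell lines
(Wilcoxon rank-sum against non-regulon genes); and enrichment/depletion of
motif-bearing genes along a ranked gene list cut into equal-population
bins (MI + permutation z + signed per-bin log10 hypergeometric p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MotifModel",
    "MotifEnrichmentResult",
    "RBPMotifEdge",
    "mutual_information",
    "permutation_z",
    "discover_motifs",
    "motif_hits",
    "motif_rbp_enrichment",
    "regulon_correlation",
    "ranked_list_enrichment",
]

_IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_TO_IUPAC = {frozenset(v): k for k, v in _IUPAC_EXPAND.items() if k != "U"}


@dataclass
class MotifModel:
    """A k-mer motif (IUPAC letters allowed) with its discovery statistics."""

    pattern: str
    k: int = 0
    source: str = "discovered"
    mi: float = float("nan")
    z: float = float("nan")
    n_hits: int = 0

    def __post_init__(self) -> None:
        self.pattern = self.pattern.upper()
        if self.k == 0:
            self.k = len(self.pattern)
        if self.k < 4:
            raise ValueError("motif length must be >= 4")
        bad = set(self.pattern) - set(_IUPAC_EXPAND)
        if bad:
            raise ValueError(f"non-IUPAC letters in motif: {sorted(bad)}")

    def matches(self, sequence: str) -> bool:
        return _iupac_search(sequence.upper().replace("U", "T"), self.pattern)


def _iupac_search(sequence: str, pattern: str) -> bool:
    k = len(pattern)
    allowed = [set(_IUPAC_EXPAND[c]) for c in pattern]
    for i in range(len(sequence) - k + 1):
        if all(sequence[i + j] in allowed[j] for j in range(k)):
            return True
    return False


@dataclass
class MotifEnrichmentResult:
    """Ranked-list enrichment profile of one motif (heat-strip row)."""

    motif: str
    mi: float
    z_score: float
    n_hits: int
    per_bin_log10_p: np.ndarray  # signed: positive = enriched, negative = depleted
    bin_counts: np.ndarray
    bin_hits: np.ndarray


def plot_heat_strip(results: "list[MotifEnrichmentResult]", ax=None):
    """Enrichment/depletion heat strip over ranked-list bins, one motif per
    row: red = enriched, blue = depleted, intensity = |log10 p|."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * max(1, len(results)) + 1))
    mat = np.stack([r.per_bin_log10_p for r in results])
    lim = max(1.0, np.abs(mat).max())
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_yticks(range(len(results)))
    ax.set_yticklabels([f"{r.motif}  (MI={r.mi:.3f}, z={r.z_score:.1f})" for r in results])
    ax.set_xlabel("ranked-list bin (low score -> high)")
    plt.colorbar(im, ax=ax, label="signed log10 p")
    return ax


@dataclass
class RBPMotifEdge:
    rbp: str
    motif: str
    p: float
    q: float = float("nan")
    overlap: int = 0
    median_rho: float = float("nan")
    wilcoxon_p: float = float("nan")


def mutual_information(labels, hits) -> float:
    """Plug-in mutual information (bits) of the hits x labels table.

    ``labels`` may be any categorical vector (>= 2 observed categories);
    ``hits`` is typically boolean motif presence.
    """
    labels = np.asarray(labels)
    hits = np.asarray(hits)
    if labels.shape != hits.shape:
        raise ValueError("labels and hits must align")
    lab_cats, li = np.unique(labels, return_inverse=True)
    if len(lab_cats) < 2:
        raise ValueError("need >= 2 label categories")
    hit_cats, hi = np.unique(hits, return_inverse=True)
    table = np.bincount(
        hi * len(lab_cats) + li, minlength=len(hit_cats) * len(lab_cats)
    ).reshape(len(hit_cats), len(lab_cats)).astype(float)
    return _mi_from_table(table)


def _mi_from_table(table: np.ndarray) -> float:
    n = table.sum()
    p = table / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px @ py))
    return float(np.nansum(terms))


def permutation_z(labels, hits, n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation z-score of MI(labels, hits) under label shuffles.

    Returns +inf when the permutation MI distribution is degenerate
    (zero SD) — a sentinel for 'beyond permutation resolution'.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels)
    hits = np.asarray(hits)
    obs = mutual_information(labels, hits)
    lab_cats, li = np.unique(labels, return_inverse=True)
    hit_cats, hi = np.unique(hits, return_inverse=True)
    nl, nh = len(lab_cats), len(hit_cats)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    shuffled = li.copy()
    for i in range(n_perm):
        rng.shuffle(shuffled)
        table = np.bincount(hi * nl + shuffled, minlength=nh * nl).reshape(nh, nl).astype(float)
        perms[i] = _mi_from_table(table)
    sd = perms.std(ddof=0)
    if sd == 0:
        return float("inf") if obs > perms.mean() else 0.0
    return float((obs - perms.mean()) / sd)


def _binary_mi(n: int, n_fg: int, h: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Vectorised MI (bits) for binary hit/label tables.

    n: total sequences, n_fg: foreground count, h: hits overall,
    k: hits within foreground.  All arrays broadcast.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    cells = [
        (k, n_fg),
        (h - k, n - n_fg),
        (n_fg - k, n_fg),
        ((n - n_fg) - (h - k), n - n_fg),
    ]
    px = np.stack([h / n, h / n, 1 - h / n, 1 - h / n])
    py = np.array([n_fg / n, 1 - n_fg / n, n_fg / n, 1 - n_fg / n])
    mi = np.zeros_like(h)
    for (count, _tot), pxi, pyi in zip(cells, px, py):
        p = count / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * np.log2(p / (pxi * pyi))
        mi += np.where(p > 0, term, 0.0)
    return mi


def _kmer_hit_matrix(sequences: list[str], k_values: list[int]) -> tuple[list[str], np.ndarray]:
    """All k-mers present in >= 1 sequence and their presence matrix."""
    sets = []
    vocab: dict[str, int] = {}
    for seq in sequences:
        s = seq.upper().replace("U", "T")
        present = set()
        for k in k_values:
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" in kmer:
                    continue
                present.add(kmer)
        sets.append(present)
        for kmer in present:
            vocab.setdefault(kmer, len(vocab))
    hits = np.zeros((len(sequences), len(vocab)), dtype=bool)
    for i, present in enumerate(sets):
        for kmer in present:
            hits[i, vocab[kmer]] = True
    return list(vocab), hits


def discover_motifs(
    foreground: list[str],
    background: list[str],
    k_range: tuple[int, int] = (6, 8),
    max_motifs: int = 10,
    z_threshold: float = 4.0,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    jaccard_max: float = 0.5,
    collapse_iupac: bool = True,
) -> list[MotifModel]:
    """Exact-k-mer MI scan of foreground vs background sequences.

    Every k-mer (k in ``k_range``, inclusive) present in the pooled set is
    scored by MI between presence and the fg/bg label; candidates are
    ranked by MI and kept when both (a) their permutation z-score (label
    shuffles) exceeds ``z_threshold`` and (b) their exact two-sided
    hypergeometric p-value survives Bonferroni correction over the number
    of k-mers tested (family-wise level ``alpha``) — the many-candidates
    scaling without which a z cut alone passes noise k-mers.  Survivors
    are de-duplicated by greedy Jaccard filtering on their hit vectors and
    collapsed into IUPAC consensus patterns.
    """
    if len(foreground) < 20:
        raise ValueError("need >= 20 foreground sequences")
    if not background:
        raise ValueError("background sequence set must be non-empty")
    sequences = list(foreground) + list(background)
    labels = np.zeros(len(sequences), dtype=bool)
    labels[: len(foreground)] = True
    k_values = list(range(k_range[0], k_range[1] + 1))
    vocab, hits = _kmer_hit_matrix(sequences, k_values)
    n, n_fg = len(sequences), len(foreground)
    h = hits.sum(axis=0)
    k_in = hits[labels].sum(axis=0)
    mi = _binary_mi(n, n_fg, h, k_in)

    # permutation null: hypergeometric draws of the foreground overlap
    rng = np.random.default_rng(seed)
    order = np.argsort(mi)[::-1]
    candidates = order[: max(5 * max_motifs, 50)]
    kept: list[tuple[str, float, float, np.ndarray, int]] = []
    n_tested = len(vocab)
    for idx in candidates:
        k_perm = rng.hypergeometric(h[idx], n - h[idx], n_fg, size=n_perm)
        mi_perm = _binary_mi(n, n_fg, np.full(n_perm, h[idx]), k_perm)
        sd = mi_perm.std(ddof=0)
        z = float("inf") if sd == 0 else (mi[idx] - mi_perm.mean()) / sd
        if z <= z_threshold:
            continue
        p_over = stats.hypergeom.sf(k_in[idx] - 1, n, h[idx], n_fg)
        p_under = stats.hypergeom.cdf(k_in[idx], n, h[idx], n_fg)
        p_two = min(1.0, 2.0 * min(p_over, p_under))
        if p_two * n_tested > alpha:
            continue
        vec = hits[:, idx]
        redundant = False
        for _p, _mi, _z, kept_vec, _h in kept:
            inter = np.sum(vec & kept_vec)
            union = np.sum(vec | kept_vec)
            if union and inter / union > jaccard_max:
                redundant = True
                break
        if not redundant:
            kept.append((vocab[idx], float(mi[idx]), float(z), vec, int(h[idx])))
        if len(kept) >= max_motifs:
            break

    motifs = [
        MotifModel(pattern=p, source="discovered", mi=m, z=z, n_hits=nh)
        for p, m, z, _v, nh in kept
    ]
    if collapse_iupac:
        motifs = _collapse_motifs(motifs)
    return motifs


def _collapse_motifs(motifs: list[MotifModel]) -> list[MotifModel]:
    """Merge same-length patterns differing in <= 1 position into consensus."""
    out: list[MotifModel] = []
    used = [False] * len(motifs)
    for i, m in enumerate(motifs):
        if used[i]:
            continue
        group = [m]
        used[i] = True
        for j in range(i + 1, len(motifs)):
            other = motifs[j]
            if used[j] or len(other.pattern) != len(m.pattern):
                continue
            mism = sum(a != b for a, b in zip(m.pattern, other.pattern))
            if mism <= 1:
                group.append(other)
                used[j] = True
        if len(group) == 1:
            out.append(m)
            continue
        consensus = "".join(
            _TO_IUPAC[frozenset(c for g in group for c in _IUPAC_EXPAND[g.pattern[pos]])]
            for pos in range(len(m.pattern))
        )
        out.append(
            MotifModel(
                pattern=consensus,
                source="discovered",
                mi=m.mi,
                z=m.z,
                n_hits=max(g.n_hits for g in group),
            )
        )
    return out


def matched_background(
    foreground: list[str],
    sequences: dict[str, str],
    exclude: dict[str, list[tuple[int, int]]] | None = None,
    per_sequence: int = 3,
    gc_tolerance: float = 0.1,
    seed: int = 0,
) -> list[str]:
    """Length- and GC-matched background segments for motif discovery.

    For each foreground segment, ``per_sequence`` windows of the same
    length are sampled from random transcripts, avoiding ``exclude``
    intervals (e.g. the variable regions themselves); a window is accepted
    if its GC fraction is within ``gc_tolerance`` of the foreground
    segment's (up to 20 attempts, then the last draw is taken).
    """
    rng = np.random.default_rng(seed)
    ids = list(sequences)
    exclude = exclude or {}
    out: list[str] = []

    def _gc(s: str) -> float:
        return (s.count("G") + s.count("C")) / max(len(s), 1)

    for seg in foreground:
        L = len(seg)
        target = _gc(seg)
        for _ in range(per_sequence):
            chosen = None
            for _attempt in range(20):
                gid = ids[rng.integers(0, len(ids))]
                seq = sequences[gid]
                if len(seq) <= L:
                    continue
                start = int(rng.integers(0, len(seq) - L))
                if any(start < e and start + L > s for s, e in exclude.get(gid, [])):
                    continue
                chosen = seq[start : start + L]
                if abs(_gc(chosen) - target) <= gc_tolerance:
                    break
            if chosen is not None:
                out.append(chosen)
    if not out:
        raise ValueError("could not sample any background segment")
    return out


def motif_hits(motif: MotifModel | str, sequences: dict[str, str]) -> set[str]:
    """Genes whose sequence contains the motif (IUPAC-aware exact match)."""
    if isinstance(motif, str):
        motif = MotifModel(pattern=motif, source="supplied")
    return {g for g, s in sequences.items() if motif.matches(s)}


def motif_rbp_enrichment(
    motifs: list[MotifModel],
    salient_pairs: dict[str, set[str]],
    sequences: dict[str, str],
    all_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, list[RBPMotifEdge]]:
    """Pairwise hypergeometric enrichment of motif hits in salient gene sets.

    For each (motif, RBP): a one-sided hypergeometric p-value for the
    over-representation of motif-bearing genes within the genes for which
    the RBP is differentially salient.  Benjamini-Hochberg q-values are
    computed over all cells of the matrix.  Returns (p-value matrix
    [RBP x motif], edge list).
    """
    from statsmodels.stats.multitest import multipletests

    if not salient_pairs or all(len(v) == 0 for v in salient_pairs.values()):
        raise ValueError("salient gene sets are empty")
    genes = list(all_genes) if all_genes is not None else list(sequences)
    gene_set = set(genes)
    N = len(genes)
    edges: list[RBPMotifEdge] = []
    pmat = pd.DataFrame(
        1.0, index=sorted(salient_pairs), columns=[m.pattern for m in motifs]
    )
    for motif in motifs:
        hit_genes = motif_hits(motif, {g: sequences[g] for g in genes}) & gene_set
        K = len(hit_genes)
        for rbp in pmat.index:
            salient = salient_pairs[rbp] & gene_set
            n_s = len(salient)
            overlap = len(hit_genes & salient)
            if K == 0 or n_s == 0:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(overlap - 1, N, K, n_s))
            pmat.loc[rbp, motif.pattern] = p
            edges.append(RBPMotifEdge(rbp=rbp, motif=motif.pattern, p=p, overlap=overlap))
    qs = multipletests([e.p for e in edges], method="fdr_bh")[1]
    for e, q in zip(edges, qs):
        e.q = float(q)
    return pmat, edges


def regulon_correlation(
    rbp_expression: pd.Series,
    regulon_decay: pd.DataFrame,
    background_decay: pd.DataFrame,
) -> tuple[float, float, pd.Series]:
    """Spearman rho between RBP expression and regulon decay across cells.

    Per gene: Spearman correlation between the RBP's per-cell expression
    and that gene's per-cell decay.  Returns (median regulon rho, Wilcoxon
    rank-sum p of regulon rhos vs background rhos, the regulon rho series).
    """
    cells = [c for c in regulon_decay.columns if c in rbp_expression.index]
    if len(cells) < 3:
        raise ValueError("need >= 3 cell lines")
    if len(regulon_decay) < 5:
        raise ValueError("need >= 5 regulon genes")
    x = rbp_expression[cells].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("constant RBP expression vector")

    def _rhos(decay: pd.DataFrame) -> pd.Series:
        out = {}
        for gene, row in decay[cells].iterrows():
            y = row.to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < 3 or np.std(y[ok]) == 0:
                continue
            rho, _ = stats.spearmanr(x[ok], y[ok])
            if np.isfinite(rho):
                out[gene] = rho
        return pd.Series(out, dtype=float)

    reg = _rhos(regulon_decay)
    bg = _rhos(background_decay)
    if len(reg) == 0 or len(bg) == 0:
        raise ValueError("no usable genes for correlation")
    _, p = stats.ranksums(reg, bg)
    return float(reg.median()), float(p), reg


def ranked_list_enrichment(
    gene_scores: pd.Series,
    motif: MotifModel | str,
    sequences: dict[str, str],
    n_bins: int = 9,
    n_perm: int = 1000,
    seed: int = 0,
) -> MotifEnrichmentResult:
    """Enrichment/depletion of motif-bearing genes along a ranked list.

    Genes are sorted by score (stable tie-break on gene id) and cut into
    ``n_bins`` equal-population bins; the result carries MI(hit, bin), a
    permutation z-score, and per-bin signed log10 hypergeometric p-values
    (positive = enriched, negative = depleted), the heat-strip of
    FIRE/iPAGE-style figures.
    """
    if isinstance(motif, str):
        motif = MotifModel(pattern=motif, source="supplied")
    genes = [g for g in gene_scores.index if g in sequences]
    if len(genes) < 5 * n_bins:
        raise ValueError(f"need >= {5 * n_bins} genes for {n_bins} bins")
    ordered = np.array(sorted(genes, key=lambda g: (gene_scores[g], g)))
    bins = np.array_split(np.arange(len(ordered)), n_bins)
    bin_of = np.empty(len(ordered), dtype=int)
    for b, idx in enumerate(bins):
        bin_of[idx] = b
    hit_set = motif_hits(motif, {g: sequences[g] for g in genes})
    hits = np.array([g in hit_set for g in ordered])

    if n_bins == 1:
        mi, z = 0.0, 0.0
    else:
        mi = mutual_information(bin_of, hits)
        z = permutation_z(bin_of, hits, n_perm=n_perm, seed=seed)

    N = len(ordered)
    K = int(hits.sum())
    per_bin = np.zeros(n_bins)
    bin_counts = np.array([len(b) for b in bins])
    bin_hits = np.array([int(hits[idx].sum()) for idx in bins])
    for b in range(n_bins):
        n_b, k_b = int(bin_counts[b]), int(bin_hits[b])
        p_over = stats.hypergeom.sf(k_b - 1, N, K, n_b)
        p_under = stats.hypergeom.cdf(k_b, N, K, n_b)
        if p_over <= p_under:
            per_bin[b] = -np.log10(max(p_over, 1e-300))
        else:
            per_bin[b] = np.log10(max(p_under, 1e-300))
    return MotifEnrichmentResult(
        motif=motif.pattern,
        mi=mi,
        z_score=z,
        n_hits=K,
        per_bin_log10_p=per_bin,
        bin_counts=bin_counts,
        bin_hits=bin_hits,
    )
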