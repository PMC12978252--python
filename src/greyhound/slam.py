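"""SLAM-seq decay-rate estimation.

Turns per-gene T->C conversion counts plus steady-state expression into a
gene x cell-line matrix of log decay rates.  At steady state the decay rate
equals the transcription rate divided by abundance; the T->C conversion
ratio after a 4sU pulse tracks transcription, so

    log k(g, c) = log(conversion ratio) - log(TPM)        (natural log)

with a pseudo-count of 1 on the ratio, a minimum T coverage of 10 reads,
an average-expression filter (> 1 TPM), an optional site-level germline
variant filter, and a per-cell-line 3 x IQR outlier mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DecayMatrix",
    "SlamDecayModel",
    "DecayResults",
    "filter_expressed",
    "mask_variant_sites",
    "conversion_ratio",
    "estimate_decay",
    "filter_outliers",
    "decay_anova",
    "transcription_expression_correlation",
]


@dataclass
class DecayMatrix:
    """Gene x cell-line log decay estimates with an explicit missingness mask.

    ``mask`` is True where the estimate is missing (insufficient coverage,
    failed filters, or outlier-masked); masked entries are NaN in ``values``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.values.shape == self.mask.shape
        v = self.values.to_numpy(dtype=float)
        m = self.mask.to_numpy(dtype=bool)
        if np.any(~np.isfinite(v[~m])):
            raise ValueError("unmasked decay entries must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        out = self.values.where(~self.mask)
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "DecayMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, mask=values.isna())


def filter_expressed(expression: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Genes whose across-sample mean TPM is strictly above ``threshold``."""
    if expression.size == 0:
        raise ValueError("empty expression matrix")
    if (expression.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    means = expression.mean(axis=1)
    return expression.index[means > threshold]


def mask_variant_sites(
    site_records: pd.DataFrame, variant_fraction_threshold: float = 0.8
) -> pd.DataFrame:
    """Drop sites whose conversion fraction looks like a germline variant.

    Chemical 4sU conversion rates are far below heterozygous (~0.5) or
    homozygous (~1.0) variant fractions, so sites converting at or above the
    threshold are removed before aggregation.  Expects columns
    ``t_cov`` and ``tc``; no-op on an empty frame.
    """
    if site_records.empty:
        return site_records
    frac = site_records["tc"] / site_records["t_cov"].replace(0, np.nan)
    keep = ~(frac >= variant_fraction_threshold)
    return site_records[keep.fillna(True)]


def conversion_ratio(
    n_t,
    n_tc,
    min_coverage: int = 10,
    pseudo: float = 1.0,
) -> float:
    """Replicate-pooled conversion ratio for one gene x cell line.

    Replicate counts are summed *before* the ratio is taken; if the summed
    T coverage is below ``min_coverage`` the value is missing (NaN).
    """
    n_t = np.atleast_1d(np.asarray(n_t))
    n_tc = np.atleast_1d(np.asarray(n_tc))
    if (n_t < 0).any() or (n_tc < 0).any():
        raise ValueError("counts must be non-negative")
    if (n_tc > n_t).any():
        raise ValueError("n_TC cannot exceed n_T")
    tot_t = float(n_t.sum())
    tot_tc = float(n_tc.sum())
    if tot_t < min_coverage:
        return float("nan")
    return (tot_tc + pseudo) / (tot_t + pseudo)


def estimate_decay(ratio: float, expression: float, eps: float = 0.0) -> float:
    """log decay = ln(ratio) - ln(expression + eps); NaN on bad input."""
    if not np.isfinite(ratio) or not np.isfinite(expression):
        return float("nan")
    if ratio <= 0 or expression + eps <= 0:
        warnings.warn("nonpositive ratio or expression; decay set to missing")
        return float("nan")
    return float(np.log(ratio) - np.log(expression + eps))


def filter_outliers(values: np.ndarray | pd.Series, k: float = 3.0) -> np.ndarray:
    """Boolean mask (True = masked) for entries strictly beyond median +/- k*IQR.

    NaNs are ignored for the statistics and stay unmasked-missing.  Values
    exactly on the boundary are kept (strict inequality).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() == 0:
        raise ValueError("all values missing")
    if finite.sum() < 4:
        raise ValueError("need at least 4 values to estimate IQR thresholds")
    med = np.median(x[finite])
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = med - k * iqr, med + k * iqr
    mask = np.zeros_like(x, dtype=bool)
    mask[finite] = (x[finite] < lo) | (x[finite] > hi)
    return mask


def decay_anova(replicate_decay: pd.DataFrame) -> pd.DataFrame:
    """Per-gene one-way ANOVA of log decay across cell lines.

    ``replicate_decay`` is long-format with columns
    ``gene, sample, replicate, log_decay``; rows with missing values are
    dropped.  Returns a frame with columns ``F, p, q`` (Benjamini-Hochberg
    q across genes).  Requires >= 2 cell lines with >= 2 replicates each.
    """
    df = replicate_decay.dropna(subset=["log_decay"])
    out = []
    for gene, sub in df.groupby("gene", sort=True):
        groups = [g["log_decay"].to_numpy() for _, g in sub.groupby("sample")]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*groups)
        if not np.isfinite(p):
            f, p = 0.0, 1.0
        out.append((gene, float(f), float(p)))
    if not out:
        raise ValueError("no gene has >= 2 cell lines with >= 2 replicates")
    res = pd.DataFrame(out, columns=["gene", "F", "p"]).set_index("gene")
    res["q"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    return res


def transcription_expression_correlation(
    ratios: pd.DataFrame, expression: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-gene Spearman rho between conversion ratio and expression.

    Both inputs are gene x sample; genes need >= 3 samples with finite
    ratios.  Returns (rho per gene, one-sided Wilcoxon signed-rank p that
    the rho distribution's median exceeds zero).
    """
    common = ratios.index.intersection(expression.index)
    rhos = {}
    for gene in common:
        r = ratios.loc[gene].to_numpy(dtype=float)
        e = expression.loc[gene, ratios.columns].to_numpy(dtype=float)
        ok = np.isfinite(r) & np.isfinite(e)
        if ok.sum() < 3:
            continue
        rho, _ = stats.spearmanr(r[ok], e[ok])
        if np.isfinite(rho):
            rhos[gene] = rho
    rho_series = pd.Series(rhos, name="rho")
    if len(rho_series) == 0:
        return rho_series, float("nan")
    nonzero = rho_series[rho_series != 0]
    if len(nonzero) == 0:
        return rho_series, 1.0
    _, p = stats.wilcoxon(nonzero, alternative="greater")
    return rho_series, float(p)


class SlamDecayModel:
    """Decay-rate estimator over a conversion-count table and expression matrix.

    Parameters
    ----------
    counts : long-format DataFrame with columns gene, sample, replicate, n_T, n_TC
    expression : gene x sample TPM matrix (samples = cell lines)
    tpm_min : average-expression filter threshold (strictly greater-than)
    min_coverage : minimum summed T coverage per gene x cell line
    pseudo : pseudo-count added to both numerator and denominator of the ratio
    iqr_k : outlier threshold in IQR multiples around the per-cell-line median
    site_records : optional site-level frame (gene, sample, position, t_cov, tc)
    variant_fraction_threshold : site-level germline-variant filter
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        expression: pd.DataFrame,
        tpm_min: float = 1.0,
        min_coverage: int = 10,
        pseudo: float = 1.0,
        iqr_k: float = 3.0,
        site_records: pd.DataFrame | None = None,
        variant_fraction_threshold: float = 0.8,
    ) -> None:
        required = {"gene", "sample", "replicate", "n_T", "n_TC"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        self.counts = counts
        self.expression = expression
        self.tpm_min = tpm_min
        self.min_coverage = min_coverage
        self.pseudo = pseudo
        self.iqr_k = iqr_k
        self.site_records = site_records
        self.variant_fraction_threshold = variant_fraction_threshold

    @classmethod
    def from_files(cls, counts_path, expression_path, **kwargs) -> "SlamDecayModel":
        counts = pd.read_csv(counts_path, sep="\t")
        expression = pd.read_csv(expression_path, sep="\t", index_col=0)
        return cls(counts, expression, **kwargs)

    def _aggregate_sites(self) -> pd.DataFrame:
        """Re-derive gene-level counts from variant-filtered site records."""
        sites = mask_variant_sites(self.site_records, self.variant_fraction_threshold)
        agg = (
            sites.groupby(["gene", "sample", "replicate"], sort=True)[["t_cov", "tc"]]
            .sum()
            .reset_index()
            .rename(columns={"t_cov": "n_T", "tc": "n_TC"})
        )
        return agg

    def fit(self) -> "DecayResults":
        counts = self.counts
        if self.site_records is not None and not self.site_records.empty:
            counts = self._aggregate_sites()
        expressed = filter_expressed(self.expression, self.tpm_min)
        counts = counts[counts["gene"].isin(expressed)]
        cells = sorted(counts["sample"].unique())
        genes = sorted(counts["gene"].unique())

        # pooled (replicate-combined) ratios and decay
        pooled = counts.groupby(["gene", "sample"], sort=True)[["n_T", "n_TC"]].sum()
        ratio = pd.DataFrame(np.nan, index=genes, columns=cells)
        for (gene, cell), row in pooled.iterrows():
            ratio.loc[gene, cell] = conversion_ratio(
                row["n_T"], row["n_TC"], self.min_coverage, self.pseudo
            )
        expr = self.expression.reindex(index=genes, columns=cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            decay = np.log(ratio.to_numpy()) - np.log(expr.to_numpy())
        decay = pd.DataFrame(decay, index=genes, columns=cells)

        # replicate-level estimates (same formulas, unpooled) for ANOVA
        rep_rows = []
        for (gene, cell, rep), row in (
            counts.groupby(["gene", "sample", "replicate"], sort=True)[["n_T", "n_TC"]]
            .sum()
            .iterrows()
        ):
            r = conversion_ratio(row["n_T"], row["n_TC"], self.min_coverage, self.pseudo)
            d = estimate_decay(r, float(expr.loc[gene, cell]))
            rep_rows.append((gene, cell, rep, d))
        replicate_decay = pd.DataFrame(
            rep_rows, columns=["gene", "sample", "replicate", "log_decay"]
        )

        # per-cell-line 3 x IQR outlier mask on the pooled estimates
        mask = decay.isna()
        outlier_masked = 0
        for cell in cells:
            col = decay[cell].to_numpy()
            if np.isfinite(col).sum() >= 4:
                m = filter_outliers(col, self.iqr_k)
                outlier_masked += int(m.sum())
                mask[cell] |= m
        values = decay.where(~mask)
        dm = DecayMatrix(
            values=values,
            mask=mask,
            metadata={
                "pseudo_count": self.pseudo,
                "min_coverage": self.min_coverage,
                "tpm_min": self.tpm_min,
                "iqr_k": self.iqr_k,
                "log_base": "e",
                "n_outliers_masked": outlier_masked,
            },
        )
        return DecayResults(
            model=self,
            decay=dm,
            ratios=ratio,
            replicate_decay=replicate_decay,
            expression=expr,
        )


@dataclass
class DecayResults:
    """Fitted decay estimates plus the diagnostics that hang off them."""

    model: SlamDecayModel
    decay: DecayMatrix
    ratios: pd.DataFrame
    replicate_decay: pd.DataFrame
    expression: pd.DataFrame

    def anova(self) -> pd.DataFrame:
        return decay_anova(self.replicate_decay)

    def transcription_expression(self) -> tuple[pd.Series, float]:
        return transcription_expression_correlation(self.ratios, self.expression)

    def summary(self) -> str:
        dm = self.decay
        n_est = int((~dm.mask.to_numpy()).sum())
        lines = [
            "SLAM-seq decay estimates",
            "=" * 40,
            f"genes:               {dm.values.shape[0]}",
            f"cell lines:          {dm.values.shape[1]}",
            f"estimated entries:   {n_est} / {dm.values.size}",
            f"outliers masked:     {dm.metadata['n_outliers_masked']}",
            f"min coverage:        {dm.metadata['min_coverage']}",
            f"pseudo-count:        {dm.metadata['pseudo_count']}",
            f"TPM filter (mean >): {dm.metadata['tpm_min']}",
            f"IQR multiple:        {dm.metadata['iqr_k']}",
            "log base:            natural",
        ]
        return "\n".join(lines)
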