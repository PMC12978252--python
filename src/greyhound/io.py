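"""File formats and input validation.

All tabular formats are TSV (UTF-8, header row mandatory, empty cell =
missing).  Sequences travel as FASTA; interval outputs are BED-like with
0-based half-open transcript coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "read_fasta",
    "read_expression",
    "read_counts",
    "ValidationReport",
    "validate_inputs",
]


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered id->sequence dict; duplicate ids raise."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no sequences parsed from {path}")
    return sequences


def read_expression(path) -> pd.DataFrame:
    """Gene x sample TPM matrix with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty expression matrix {path}")
    return df


def read_counts(path) -> pd.DataFrame:
    """Conversion-count table: gene, sample, replicate, n_T, n_TC."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "replicate", "n_T", "n_TC"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table {path} missing columns {sorted(missing)}")
    return df


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def __str__(self) -> str:
        lines = []
        for msg in self.fatal:
            lines.append(f"FATAL: {msg}")
        for msg in self.warnings:
            lines.append(f"WARNING: {msg}")
        if not lines:
            lines.append("all inputs valid")
        return "\n".join(lines)


def validate_inputs(
    fasta_path=None,
    expression_path=None,
    counts_path=None,
    decay_path=None,
) -> ValidationReport:
    """Cross-check the pipeline's input files.

    Checks FASTA id uniqueness, matrix header consistency, count
    integrality and bounds (n_TC <= n_T), TPM non-negativity; classifies
    problems as fatal vs warnings (e.g. genes present in the FASTA but
    absent from the decay matrix are warned and listed for exclusion).
    """
    report = ValidationReport()
    sequences = None
    if fasta_path is not None:
        try:
            sequences = read_fasta(fasta_path)
        except ValueError as exc:
            report.fatal.append(str(exc))
    expression = None
    if expression_path is not None:
        try:
            expression = read_expression(expression_path)
            if (expression.to_numpy(dtype=float) < 0).any():
                report.fatal.append("negative TPM values in expression matrix")
            if expression.index.duplicated().any():
                report.fatal.append("duplicate gene ids in expression matrix")
        except Exception as exc:  # ragged rows etc. surface here
            report.fatal.append(f"expression matrix: {exc}")
    if counts_path is not None:
        try:
            counts = read_counts(counts_path)
            for col in ("n_T", "n_TC"):
                vals = counts[col]
                if not np.issubdtype(vals.dtype, np.integer):
                    if not np.allclose(vals, vals.round()):
                        report.fatal.append(f"non-integer values in {col}")
                if (vals < 0).any():
                    report.fatal.append(f"negative values in {col}")
            if (counts["n_TC"] > counts["n_T"]).any():
                report.fatal.append("n_TC exceeds n_T in counts table")
        except Exception as exc:
            report.fatal.append(f"counts table: {exc}")
    decay = None
    if decay_path is not None:
        try:
            decay = pd.read_csv(decay_path, sep="\t", index_col=0)
        except Exception as exc:
            report.fatal.append(f"decay matrix: {exc}")
    if sequences is not None and decay is not None:
        missing = sorted(set(sequences) - set(decay.index))
        if missing:
            report.warnings.append(
                f"{len(missing)} FASTA sequences absent from decay matrix (excluded)"
            )
            report.excluded_genes.extend(missing)
    if sequences is not None and expression is not None:
        shared = set(sequences) & set(expression.index)
        if not shared:
            report.fatal.append("no genes shared between FASTA and expression matrix")
    return report
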