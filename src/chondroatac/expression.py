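"""TPM normalisation, expressed-gene filtering and replicate-correlation QC.

TPM (transcripts per kilobase per million) first divides each gene's
count by its length in kilobases, then scales each sample so the values
sum to one million — making expression comparable across genes and
libraries.  Genes whose mean TPM across replicates strictly exceeds a
threshold (default 2) are called expressed; pairwise Pearson
correlation on log2(TPM+1) quantifies replicate agreement.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "compute_tpm",
    "expressed_genes",
    "replicate_correlation",
    "read_counts_tsv",
    "write_counts_tsv",
]


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM-normalise a gene (rows) x sample (columns) count matrix.

    ``lengths`` gives gene lengths in bp, indexed like ``counts``.  Each
    column of the result sums to 1e6; an all-zero sample stays all-zero
    and is flagged with a warning.  Zero or negative lengths and negative
    counts are rejected.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")

    rate = counts.div(lengths / 1000.0, axis=0)
    col_sums = rate.sum(axis=0)
    zero_cols = col_sums == 0
    if zero_cols.any():
        warnings.warn(
            f"all-zero sample(s): {list(counts.columns[zero_cols])}; TPM left at zero"
        )
        col_sums = col_sums.replace(0, 1.0)
    return rate.div(col_sums, axis=1) * 1e6


def expressed_genes(tpm: pd.DataFrame, threshold: float = 2.0) -> list[str]:
    """Genes whose mean TPM across samples is strictly greater than ``threshold``."""
    if tpm.shape[1] < 1:
        raise ValueError("need at least one sample")
    mean = tpm.mean(axis=1)
    return list(tpm.index[mean > threshold])


def replicate_correlation(tpm: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples.

    By default computed on log2(TPM+1), the conventional scale for
    expression QC; set ``log_transform=False`` for the raw scale.
    Zero-variance samples yield NaN entries with a warning; the diagonal
    is 1.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need at least two samples")
    data = np.log2(tpm + 1.0) if log_transform else tpm
    variances = data.var(axis=0)
    if (variances == 0).any():
        warnings.warn(
            f"zero-variance sample(s): {list(tpm.columns[variances == 0])}; "
            "their correlations are undefined (NaN)"
        )
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV with a ``length`` column and sample columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError(f"{path}: expected a 'length' column")
    lengths = df["length"]
    counts = df.drop(columns=["length"])
    return counts, lengths


def write_counts_tsv(counts: pd.DataFrame, lengths: pd.Series, path: str | Path) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index))
    out.to_csv(path, sep="\t", index_label="gene_id")
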