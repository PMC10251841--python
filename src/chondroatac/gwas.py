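"""Permutation test for GWAS-SNP enrichment in open-chromatin peaks.

The question: do trait-associated (candidate) SNPs fall inside ATAC-seq
peaks more often than random SNPs from the same panel?  The null is
built by repeatedly drawing size-matched random SNP sets from the full
panel and recording their in-peak proportion; fold enrichment is the
observed proportion over the null mean, and the one-tailed empirical p
uses the add-one correction so it can never be exactly zero.

For the standard presence/absence statistic, the in-peak count of a
uniform without-replacement draw of k SNPs from a panel with m in-peak
members is exactly hypergeometric(m, N-m, k), so null counts are drawn
from that distribution directly rather than materialising each index
sample; the effect-weighted variant performs explicit index draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "SNPRecord",
    "EnrichmentResult",
    "snp_in_peak_mask",
    "snp_in_peaks",
    "select_candidates",
    "permutation_enrichment",
    "read_snp_table",
    "write_snp_table",
]


@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    pos: int
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("SNP position must be >= 0")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed in-peak proportion vs a size-matched permutation null."""

    observed_prop: float
    null_props: np.ndarray = field(repr=False)
    null_mean: float
    null_sd: float
    fold: float
    p_value: float
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "observed_prop": self.observed_prop,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _as_frame(snps) -> pd.DataFrame:
    if isinstance(snps, pd.DataFrame):
        return snps
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "p": [s.p_value for s in snps],
        }
    )


def snp_in_peak_mask(snps, peaks: Sequence[GenomicInterval]) -> np.ndarray:
    """Boolean array: SNP i lies inside a peak (start <= pos < end).

    Peaks are merged first, so the result is independent of peak overlap
    structure.
    """
    df = _as_frame(snps).reset_index(drop=True)
    merged = merge_intervals(peaks)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms: dict[str, list[tuple[int, int]]] = {}
    for iv in merged:
        chroms.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, spans in chroms.items():
        by_chrom[chrom] = (
            np.array([s for s, _ in spans], dtype=np.int64),
            np.array([e for _, e in spans], dtype=np.int64),
        )
    mask = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends = entry
        pos = sub["pos"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(ends, pos, side="right")
        ok = (idx < len(starts)) & (starts[np.minimum(idx, len(starts) - 1)] <= pos)
        mask[sub.index.to_numpy()] = ok
    return mask


def snp_in_peaks(snps, peaks: Sequence[GenomicInterval]) -> tuple[int, float]:
    """Count and proportion of SNPs falling inside (merged) peaks."""
    df = _as_frame(snps)
    if len(df) == 0:
        raise ValueError("empty SNP list")
    mask = snp_in_peak_mask(df, peaks)
    count = int(mask.sum())
    return count, count / len(df)


def select_candidates(
    snps, p_threshold: float | None = None, top_k: int | None = None
) -> pd.DataFrame:
    """Select candidate SNPs by p-value threshold or smallest-p top-k.

    Ties are broken deterministically by (chrom, pos).  Exactly one of
    ``p_threshold`` / ``top_k`` must be given.
    """
    if (p_threshold is None) == (top_k is None):
        raise ValueError("specify exactly one of p_threshold or top_k")
    df = _as_frame(snps)
    if "p" not in df.columns or df["p"].isna().all():
        raise ValueError("SNP table has no p-values")
    ordered = df.sort_values(["p", "chrom", "pos"], kind="mergesort")
    if p_threshold is not None:
        out = ordered[ordered["p"] <= p_threshold]
    else:
        out = ordered.head(top_k)
    if len(out) == 0:
        raise ValueError("no SNP passes the candidate selection")
    return out.reset_index(drop=True)


def permutation_enrichment(
    candidates,
    all_snps,
    peaks: Sequence[GenomicInterval],
    n_perm: int = 10000,
    seed: int | None = None,
    with_replacement: bool = False,
    effect_weighted: bool = False,
) -> EnrichmentResult:
    """Size-matched permutation test of candidate-SNP enrichment in peaks.

    Each of ``n_perm`` draws samples ``len(candidates)`` SNPs from the
    panel (without replacement by default) and records the in-peak
    proportion.  fold = observed / mean(null);
    p = (1 + #{null >= observed}) / (1 + n_perm).

    With ``effect_weighted`` the statistic is the mean |effect| (the
    ``p`` column interpreted as an effect magnitude) of in-peak SNPs,
    computed by explicit index sampling.
    """
    cand = _as_frame(candidates)
    panel = _as_frame(all_snps)
    k, N = len(cand), len(panel)
    if k == 0:
        raise ValueError("empty candidate set")
    if k > N:
        raise ValueError(f"candidate set ({k}) larger than SNP panel ({N})")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)

    panel_mask = snp_in_peak_mask(panel, peaks)
    cand_mask = snp_in_peak_mask(cand, peaks)
    m = int(panel_mask.sum())

    if effect_weighted:
        eff = panel["p"].to_numpy(dtype=float)
        cand_eff = cand["p"].to_numpy(dtype=float)
        obs = float(np.abs(cand_eff[cand_mask]).sum() / max(cand_mask.sum(), 1))
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(N, size=k, replace=with_replacement)
            sel = panel_mask[idx]
            null[i] = np.abs(eff[idx][sel]).sum() / max(sel.sum(), 1)
        n_ge = int((null >= obs).sum())
        null_props = null
        observed = obs
    else:
        obs_count = int(cand_mask.sum())
        if with_replacement:
            null_counts = rng.binomial(k, m / N, size=n_perm)
        else:
            null_counts = rng.hypergeometric(m, N - m, k, size=n_perm)
        null_props = null_counts / k
        observed = obs_count / k
        n_ge = int((null_counts >= obs_count).sum())

    null_mean = float(null_props.mean())
    null_sd = float(null_props.std(ddof=1)) if n_perm > 1 else 0.0
    if null_mean > 0:
        fold = observed / null_mean
    elif observed > 0:
        fold = float("inf")
        warnings.warn("null mean is zero with nonzero observed proportion")
    else:
        fold = float("nan")
        warnings.warn("observed and null proportions are both zero; fold undefined")
    p = (1 + n_ge) / (1 + n_perm)
    return EnrichmentResult(
        observed_prop=float(observed),
        null_props=null_props,
        null_mean=null_mean,
        null_sd=null_sd,
        fold=fold,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a SNP TSV with columns chrom, pos[, p]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if "p" not in df.columns:
        df["p"] = np.nan
    return df


def write_snp_table(snps: pd.DataFrame, path: str | Path) -> None:
    snps.to_csv(path, sep="\t", index=False)
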