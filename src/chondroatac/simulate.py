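"""Synthetic data generators emulating an ATAC-seq + RNA-seq study design.

Every generator returns its observables *together with the ground truth*
(true peaks, bound flags, expressed flags), so downstream stages can be
tested for recovery without any real sequencing data.  The emulated
structure:

* three biological replicates of peak calls over a desk-scale genome
  (default 3 chromosomes x 1 Mb, 100 genes), with controlled
  inter-replicate dropout and boundary jitter;
* fragment lengths from the nucleosome ladder — a four-component
  mixture of sub-100 bp (nucleosome-free), ~200 (mono-), ~400 (di-) and
  ~600 bp (tri-nucleosome) fragments — with cut sites concentrated
  inside peaks;
* SNP panels with a controlled in-peak enrichment fold for candidates;
* motif sites with or without footprint protection (suppressed Tn5
  cuts over the motif span);
* negative-binomial count matrices for three replicates, with a
  configured fraction of genes below the expression threshold.

All randomness flows through ``numpy`` generators seeded from
``config.seed`` plus a per-generator stream constant, so each generator
is deterministic under a fixed config regardless of call order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import GeneModel
from .footprint import PWM, MotifSite
from .intervals import GenomicInterval

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "PlacementError",
    "make_genome",
    "simulate_replicate_peaks",
    "simulate_fragments",
    "simulate_snps",
    "simulate_footprint_sites",
    "simulate_counts",
    "simulate_term_map",
    "simulate_motif_sequences",
    "demo_pwms",
    "write_fragments_bed",
    "write_config",
    "read_config",
]

# per-generator rng stream constants (seeded as [seed, stream])
_STREAM_GENOME = 1
_STREAM_PEAKS = 2
_STREAM_FRAGMENTS = 3
_STREAM_SNPS = 4
_STREAM_FOOTPRINT = 5
_STREAM_COUNTS = 6
_STREAM_TERMS = 7
_STREAM_SEQS = 8


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement cannot be satisfied."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generators.

    Defaults mirror the structure of a three-replicate chondrocyte
    ATAC/RNA experiment at desk scale: peaks average 572 bp, roughly
    46% of them promoter-proximal, a nucleosome-ladder fragment mixture
    dominated by sub-nucleosomal fragments, and candidate SNPs enriched
    ~2.3-fold in open chromatin.
    """

    n_replicates: int = 3
    n_true_peaks: int = 200
    peak_length_mean: int = 572
    replicate_dropout: float = 0.1
    peak_jitter: float = 0.10
    promoter_peak_fraction: float = 0.4561
    fragment_mixture: tuple[float, float, float, float] = (0.45, 0.35, 0.15, 0.05)
    n_fragments: int = 50_000
    peak_cut_enrichment: float = 10.0
    tss_cut_fraction: float = 0.1
    tss_cut_sd: float = 200.0
    snp_count: int = 10_000
    n_candidate_snps: int = 500
    snp_enrichment_fold: float = 2.32
    bound_motif_fraction: float = 0.8
    n_footprint_sites: int = 500
    footprint_depletion: float = 0.5
    footprint_site_rate: float = 1.0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    n_genes: int = 100
    gene_length_mean: int = 8_000
    silent_gene_fraction: float = 0.3
    count_dispersion: float = 0.5
    library_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("replicate_dropout", "promoter_peak_fraction",
                     "bound_motif_fraction", "silent_gene_fraction", "peak_jitter",
                     "tss_cut_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be in [0, 1]")
        weights = tuple(float(w) for w in self.fragment_mixture)
        if len(weights) != 4 or any(w < 0 for w in weights):
            raise ValueError("fragment_mixture needs 4 non-negative weights")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("fragment_mixture weights must sum to 1")
        self.fragment_mixture = weights
        for name in ("n_replicates", "n_true_peaks", "n_fragments", "snp_count",
                     "n_candidate_snps", "n_footprint_sites", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.snp_enrichment_fold < 0:
            raise ValueError("snp_enrichment_fold must be >= 0")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be > 0")


@dataclass(frozen=True)
class SyntheticGenome:
    """A desk-scale stand-in for a reference genome plus gene annotation."""

    chrom_lengths: dict[str, int]
    genes: tuple[GeneModel, ...]
    seed: int

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene identifiers must be unique")
        for g in self.genes:
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"{g.gene_id} extends past its chromosome")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    lengths: Sequence[int],
    occupied: dict[str, list[tuple[int, int]]],
    margin: int = 0,
    max_attempts: int = 1000,
    avoid: Mapping[str, list[tuple[int, int]]] | None = None,
) -> list[tuple[str, int, int]]:
    """Uniformly place spans without overlap (plus ``margin`` spacing)."""
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed = []
    for length in lengths:
        for _ in range(max_attempts):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            L = chrom_lengths[chrom]
            if L <= length:
                continue
            start = int(rng.integers(0, L - length))
            end = start + length
            spans = occupied.setdefault(chrom, [])
            if any(start - margin < e and s < end + margin for s, e in spans):
                continue
            if avoid and any(start < e and s < end for s, e in avoid.get(chrom, [])):
                continue
            spans.append((start, end))
            placed.append((chrom, start, end))
            break
        else:
            raise PlacementError(
                f"could not place a span of {length} bp after {max_attempts} attempts"
            )
    return placed


def _allocate_spans(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    lengths: Sequence[int],
    margin: int = 0,
) -> list[tuple[str, int, int]]:
    """Place spans without overlap by random gap allocation.

    Spans are assigned to chromosomes proportionally to free space, then
    laid out in random order with the remaining slack split uniformly at
    random among the inter-span gaps.  Succeeds whenever the spans (plus
    margins) fit, regardless of packing density.
    """
    chroms = sorted(chrom_lengths)
    order = rng.permutation(len(lengths))
    remaining = {c: chrom_lengths[c] for c in chroms}
    assignment: dict[str, list[int]] = {c: [] for c in chroms}
    for i in order:
        need = lengths[i] + margin
        free = np.array([max(0, remaining[c]) for c in chroms], dtype=float)
        feasible = free >= need
        if not feasible.any():
            raise PlacementError(
                f"cannot place a span of {lengths[i]} bp: genome exhausted"
            )
        w = np.where(feasible, free, 0.0)
        c = chroms[int(rng.choice(len(chroms), p=w / w.sum()))]
        assignment[c].append(int(i))
        remaining[c] -= need
    spans: list[tuple[str, int, int] | None] = [None] * len(lengths)
    for c in chroms:
        idxs = assignment[c]
        if not idxs:
            continue
        used = sum(lengths[i] + margin for i in idxs)
        slack = chrom_lengths[c] - used
        gaps = rng.multinomial(slack, np.full(len(idxs) + 1, 1.0 / (len(idxs) + 1)))
        cursor = 0
        for gap, i in zip(gaps, idxs):
            cursor += int(gap)
            spans[i] = (c, cursor, cursor + lengths[i])
            cursor += lengths[i] + margin
    return [s for s in spans if s is not None]


def make_genome(config: SimulationConfig) -> SyntheticGenome:
    """Generate a genome with non-overlapping genes on both strands.

    Gene lengths are lognormal around ``gene_length_mean``; each gene
    receives 1-5 exons and, with probability 0.9, a CDS spanning from
    inside its first exon to inside its last.  Raises
    :class:`PlacementError` if the requested genes cannot be placed.
    """
    rng = _rng(config, _STREAM_GENOME)
    n = config.n_genes
    if n == 0:
        return SyntheticGenome(dict(config.chrom_lengths), (), config.seed)

    mu = math.log(config.gene_length_mean)
    lengths = np.clip(
        rng.lognormal(mu, 0.5, size=n).astype(int), 1000, 50_000
    )
    spans = _allocate_spans(rng, config.chrom_lengths, lengths.tolist(), margin=200)
    genes = []
    pad = len(str(n))
    for i, (chrom, start, end) in enumerate(spans):
        glen = end - start
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6))
        if n_exons == 1:
            exons = ((start, end),)
        else:
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [glen]]) + start
            exons = tuple(
                (int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(n_exons)
            )
        cds_start = cds_end = None
        if rng.random() < 0.9:
            first_s, first_e = exons[0]
            last_s, last_e = exons[-1]
            cds_start = first_s + int(rng.integers(0, max(1, (first_e - first_s) // 2)))
            cds_end = last_e - int(rng.integers(0, max(1, (last_e - last_s) // 2)))
            if cds_end <= cds_start:
                cds_start = cds_end = None
        genes.append(
            GeneModel(
                gene_id=f"gene_{i + 1:0{pad}d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return SyntheticGenome(dict(config.chrom_lengths), tuple(genes), config.seed)


# ---------------------------------------------------------------------------
# replicate peaks
# ---------------------------------------------------------------------------

def simulate_replicate_peaks(
    genome: SyntheticGenome, config: SimulationConfig
) -> tuple[list[list[GenomicInterval]], list[GenomicInterval]]:
    """Simulate per-replicate peak sets around a shared set of true peaks.

    A configured fraction of true peaks is centred inside +/-3 kb
    promoter windows of random genes; the remainder is placed clear of
    all promoter windows, so the promoter fraction is controlled
    exactly.  Each replicate contains each true peak with probability
    ``1 - replicate_dropout``, with independent uniform boundary jitter
    of +/-``peak_jitter`` x length on each end.  Returns
    ``(replicate_sets, true_peaks)``.
    """
    rng = _rng(config, _STREAM_PEAKS)
    n = config.n_true_peaks
    if n == 0:
        return [[] for _ in range(config.n_replicates)], []

    lengths = np.maximum(
        100, rng.normal(config.peak_length_mean, 0.2 * config.peak_length_mean, n).astype(int)
    )
    promoters: dict[str, list[tuple[int, int]]] = {}
    for g in genome.genes:
        promoters.setdefault(g.chrom, []).append(
            (max(0, g.tss - 3000), min(genome.chrom_lengths[g.chrom], g.tss + 3000))
        )
    n_prom = int(round(config.promoter_peak_fraction * n))
    if n_prom > 0 and len(genome.genes) == 0:
        raise PlacementError("promoter peaks requested but the genome has no genes")

    occupied: dict[str, list[tuple[int, int]]] = {}
    true_peaks: list[GenomicInterval] = []
    # promoter-proximal peaks: centre uniform within the +/-3 kb window
    for i in range(n_prom):
        length = int(lengths[i])
        for _ in range(1000):
            g = genome.genes[rng.integers(0, len(genome.genes))]
            L = genome.chrom_lengths[g.chrom]
            lo = max(length // 2, g.tss - 3000 + length // 2)
            hi = min(L - length + length // 2, g.tss + 3000 - length // 2)
            if hi <= lo:
                continue
            center = int(rng.integers(lo, hi))
            start, end = center - length // 2, center - length // 2 + length
            if start < 0 or end > L:
                continue
            spans = occupied.setdefault(g.chrom, [])
            if any(start - 1000 < e and s < end + 1000 for s, e in spans):
                continue
            spans.append((start, end))
            true_peaks.append(GenomicInterval(g.chrom, start, end, name=f"peak_{i + 1}"))
            break
        else:
            raise PlacementError("could not place promoter-proximal peak")
    # background peaks: uniform, avoiding every promoter window
    rest = _place_nonoverlapping(
        rng,
        genome.chrom_lengths,
        [int(l) for l in lengths[n_prom:]],
        occupied,
        margin=1000,
        avoid=promoters,
    )
    for j, (chrom, start, end) in enumerate(rest):
        true_peaks.append(
            GenomicInterval(chrom, start, end, name=f"peak_{n_prom + j + 1}")
        )

    replicate_sets: list[list[GenomicInterval]] = []
    for _rep in range(config.n_replicates):
        present = rng.random(n) < (1.0 - config.replicate_dropout)
        peaks = []
        for keep, pk in zip(present, true_peaks):
            if not keep:
                continue
            jmax = max(1, int(config.peak_jitter * pk.length))
            d1 = int(rng.integers(-jmax, jmax + 1))
            d2 = int(rng.integers(-jmax, jmax + 1))
            L = genome.chrom_lengths[pk.chrom]
            start = max(0, pk.start + d1)
            end = min(L, pk.end + d2)
            if end > start:
                peaks.append(GenomicInterval(pk.chrom, start, end, name=pk.name))
        peaks.sort(key=lambda iv: (iv.chrom, iv.start))
        replicate_sets.append(peaks)
    return replicate_sets, true_peaks


# ---------------------------------------------------------------------------
# fragments and cut sites
# ---------------------------------------------------------------------------

_MIXTURE_COMPONENTS = ((30, 99), (200, 20), (400, 25), (600, 30))  # (a,b) or (mu,sd)


def _draw_lengths(rng: np.random.Generator, component: np.ndarray) -> np.ndarray:
    n = len(component)
    lengths = np.empty(n, dtype=np.int64)
    nfr = component == 0
    lengths[nfr] = rng.integers(30, 100, size=int(nfr.sum()))
    for ci in (1, 2, 3):
        mask = component == ci
        mu, sd = _MIXTURE_COMPONENTS[ci]
        lengths[mask] = np.maximum(
            20, rng.normal(mu, sd, size=int(mask.sum())).astype(np.int64)
        )
    return lengths


def simulate_fragments(
    genome: SyntheticGenome,
    peaks: Sequence[GenomicInterval],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fragments with ladder lengths and peak-concentrated cuts.

    Fragment lengths follow the four-component nucleosome-ladder
    mixture.  A fraction ``tss_cut_fraction`` of fragments starts near a
    random TSS (normal spread ``tss_cut_sd``); of the remainder, each
    fragment's left cut is placed inside peak bp with probability
    ``f*rho / (f*rho + 1 - rho)`` (``f`` the configured enrichment,
    ``rho`` the peak genome fraction), which makes the in-peak :
    background per-bp cut-density ratio equal ``f`` exactly among
    non-TSS fragments.  Returns ``(fragments, cut_sites)`` DataFrames;
    cut sites carry the +4/-5 Tn5 correction of the two fragment ends.
    """
    from .signal_peaks import fragments_to_cut_sites

    if rng is None:
        rng = _rng(config, _STREAM_FRAGMENTS)
    n = config.n_fragments
    chroms = sorted(genome.chrom_lengths)
    clens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)

    peak_list = [(p.chrom, p.start, p.end) for p in peaks]
    peak_bp = sum(e - s for _, s, e in peak_list)
    rho = peak_bp / genome.total_length
    f = config.peak_cut_enrichment
    p_in = (f * rho) / (f * rho + (1.0 - rho)) if peak_bp > 0 else 0.0

    component = rng.choice(4, size=n, p=list(config.fragment_mixture))
    lengths = _draw_lengths(rng, component)
    at_tss = (
        rng.random(n) < config.tss_cut_fraction
        if len(genome.genes) > 0
        else np.zeros(n, dtype=bool)
    )
    in_peak = (rng.random(n) < p_in) & ~at_tss

    frag_chrom = np.empty(n, dtype=object)
    frag_start = np.empty(n, dtype=np.int64)

    n_tss = int(at_tss.sum())
    if n_tss > 0:
        gidx = rng.integers(0, len(genome.genes), size=n_tss)
        offsets = rng.normal(0.0, config.tss_cut_sd, size=n_tss).astype(np.int64)
        idx = np.flatnonzero(at_tss)
        for j in range(n_tss):
            g = genome.genes[gidx[j]]
            L = genome.chrom_lengths[g.chrom]
            frag_chrom[idx[j]] = g.chrom
            frag_start[idx[j]] = min(max(0, g.tss + offsets[j]), L - 1)

    n_in = int(in_peak.sum())
    if n_in > 0:
        sizes = np.array([e - s for _, s, e in peak_list], dtype=float)
        pick = rng.choice(len(peak_list), size=n_in, p=sizes / sizes.sum())
        offs = (rng.random(n_in) * sizes[pick]).astype(np.int64)
        idx = np.flatnonzero(in_peak)
        for j, (pi, off) in enumerate(zip(pick, offs)):
            chrom, s, _ = peak_list[pi]
            frag_chrom[idx[j]] = chrom
            frag_start[idx[j]] = s + off

    background = ~in_peak & ~at_tss
    if background.any():
        # uniform over non-peak bp via rejection against merged peaks
        idx = np.flatnonzero(background)
        weights = clens / clens.sum()
        need = idx.copy()
        from .gwas import snp_in_peak_mask

        while len(need) > 0:
            ci = rng.choice(len(chroms), size=len(need), p=weights)
            pos = (rng.random(len(need)) * clens[ci]).astype(np.int64)
            cand = pd.DataFrame({"chrom": [chroms[i] for i in ci], "pos": pos})
            bad = (
                snp_in_peak_mask(cand, list(peaks)) if peak_bp > 0
                else np.zeros(len(need), dtype=bool)
            )
            ok = ~bad
            frag_chrom[need[ok]] = cand["chrom"].to_numpy()[ok]
            frag_start[need[ok]] = pos[ok]
            need = need[bad]

    clen_map = genome.chrom_lengths
    frag_end = frag_start + lengths
    for i in range(n):
        L = clen_map[frag_chrom[i]]
        if frag_end[i] > L:
            frag_end[i] = L
        if frag_end[i] <= frag_start[i]:
            frag_start[i] = frag_end[i] - 1
    fragments = pd.DataFrame(
        {"chrom": frag_chrom, "start": frag_start, "end": frag_end}
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    cuts = fragments_to_cut_sites(fragments)
    return fragments, cuts


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def simulate_snps(
    genome: SyntheticGenome,
    peaks: Sequence[GenomicInterval],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a background SNP panel and an enriched candidate set.

    Background SNPs are uniform over the genome with Uniform(0,1)
    p-values.  Candidates fall inside peaks with probability
    ``min(1, fold * rho)`` (``rho`` = peak genome fraction), uniform
    within peak bp, otherwise uniform over non-peak bp; their p-values
    are Uniform(0, 0.01).  Returns ``(background, candidates)``.
    """
    rng = _rng(config, _STREAM_SNPS)
    from .gwas import snp_in_peak_mask

    chroms = sorted(genome.chrom_lengths)
    clens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    weights = clens / clens.sum()

    def uniform_positions(count: int) -> pd.DataFrame:
        ci = rng.choice(len(chroms), size=count, p=weights)
        pos = (rng.random(count) * clens[ci]).astype(np.int64)
        return pd.DataFrame({"chrom": [chroms[i] for i in ci], "pos": pos})

    background = uniform_positions(config.snp_count)
    background["p"] = rng.random(config.snp_count)

    peak_list = [(p.chrom, p.start, p.end) for p in peaks]
    sizes = np.array([e - s for _, s, e in peak_list], dtype=float)
    rho = sizes.sum() / genome.total_length if len(peak_list) else 0.0
    p_in = config.snp_enrichment_fold * rho
    if p_in > 1.0:
        warnings.warn(
            f"snp_enrichment_fold={config.snp_enrichment_fold} requires in-peak "
            f"proportion {p_in:.3f} > 1; capped at 1"
        )
        p_in = 1.0

    k = config.n_candidate_snps
    in_peak = rng.random(k) < p_in
    chrom_col = np.empty(k, dtype=object)
    pos_col = np.empty(k, dtype=np.int64)
    n_in = int(in_peak.sum())
    if n_in > 0:
        pick = rng.choice(len(peak_list), size=n_in, p=sizes / sizes.sum())
        offs = (rng.random(n_in) * sizes[pick]).astype(np.int64)
        idx = np.flatnonzero(in_peak)
        for j in range(n_in):
            chrom, s, _ = peak_list[pick[j]]
            chrom_col[idx[j]] = chrom
            pos_col[idx[j]] = s + offs[j]
    need = np.flatnonzero(~in_peak)
    while len(need) > 0:
        draw = uniform_positions(len(need))
        bad = (
            snp_in_peak_mask(draw, list(peaks)) if len(peak_list) and p_in < 1.0
            else np.zeros(len(need), dtype=bool)
        )
        ok = ~bad
        chrom_col[need[ok]] = draw["chrom"].to_numpy()[ok]
        pos_col[need[ok]] = draw["pos"].to_numpy()[ok]
        need = need[bad]
    candidates = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_col, "p": rng.random(k) * 0.01}
    )
    return background, candidates


# ---------------------------------------------------------------------------
# footprint sites
# ---------------------------------------------------------------------------

def simulate_footprint_sites(
    genome: SyntheticGenome,
    peaks: Sequence[GenomicInterval],
    pwm: PWM,
    config: SimulationConfig,
    window: int = 100,
) -> tuple[list[MotifSite], np.ndarray, pd.DataFrame]:
    """Simulate motif sites inside peaks with Tn5 footprint protection.

    Each site receives Poisson(``footprint_site_rate``) cuts per base
    over +/-``window`` of its centre; at *bound* sites (fraction
    ``bound_motif_fraction``) the rate over the motif span is multiplied
    by ``footprint_depletion``.  Returns ``(sites, bound_flags,
    cut_sites)``.
    """
    rng = _rng(config, _STREAM_FOOTPRINT)
    usable = [p for p in peaks if p.length >= pwm.length]
    if not usable:
        raise ValueError("no peak long enough to hold the motif")
    n = config.n_footprint_sites
    sizes = np.array([p.length - pwm.length + 1 for p in usable], dtype=float)
    weights = sizes / sizes.sum()
    # site windows must not overlap, or one site's flank cuts would leak
    # into a neighbour's centre and dilute the footprint
    min_sep = 2 * window + pwm.length
    taken: dict[str, list[int]] = {}
    sites: list[MotifSite] = []
    attempts = 0
    while len(sites) < n:
        attempts += 1
        if attempts > 200 * n:
            raise PlacementError(
                f"could not place {n} motif sites with {min_sep} bp separation"
            )
        pi = int(rng.choice(len(usable), p=weights))
        start = int(usable[pi].start + rng.random() * sizes[pi])
        chrom = usable[pi].chrom
        centers = taken.setdefault(chrom, [])
        center = start + pwm.length // 2
        if any(abs(center - c) < min_sep for c in centers):
            continue
        centers.append(center)
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(MotifSite(chrom, start, start + pwm.length, strand))
    bound = rng.random(n) < config.bound_motif_fraction

    width = 2 * window + 1
    half = pwm.length // 2
    center_lo, center_hi = window - half, window - half + pwm.length
    base_rate = np.full(width, config.footprint_site_rate)
    depleted = base_rate.copy()
    depleted[center_lo:center_hi] *= config.footprint_depletion

    chroms, positions = [], []
    for site, is_bound in zip(sites, bound):
        rate = depleted if is_bound else base_rate
        counts = rng.poisson(rate)
        offsets = np.repeat(np.arange(width), counts)
        positions.append(site.center - window + offsets)
        chroms.extend([site.chrom] * int(counts.sum()))
    cuts = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.concatenate(positions) if positions else np.array([], dtype=np.int64),
            "strand": "+",
        }
    )
    cuts = cuts[cuts["pos"] >= 0].reset_index(drop=True)
    return sites, bound, cuts


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    genome: SyntheticGenome, config: SimulationConfig, n_samples: int = 3
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate negative-binomial RNA-seq counts for replicate samples.

    A fraction ``silent_gene_fraction`` of genes receives a target TPM
    in (0.05, 1) — safely below the expressed threshold of 2 — and the
    rest a lognormal TPM of at least 8.  Per-gene means shared across
    replicates are scaled to the configured library size; counts are
    negative-binomial with shape ``count_dispersion`` (smaller = noisier),
    tuned so replicate log-scale Pearson correlation sits near 0.8.
    Returns ``(counts, gene_lengths, expressed_truth)``.
    """
    rng = _rng(config, _STREAM_COUNTS)
    genes = genome.genes
    if len(genes) == 0:
        raise ValueError("genome has no genes")
    ids = [g.gene_id for g in genes]
    lengths = pd.Series([g.exonic_length for g in genes], index=ids, name="length")

    silent = rng.random(len(genes)) < config.silent_gene_fraction
    tpm_target = np.where(
        silent,
        rng.uniform(0.05, 1.0, len(genes)),
        np.exp2(rng.normal(3.0, 2.0, len(genes))),
    )
    # target TPMs must themselves sum to 1e6, so realised TPM tracks the
    # target: silent genes keep their sub-threshold values and the
    # expressed genes absorb the remaining budget
    if (~silent).any():
        budget = 1e6 - tpm_target[silent].sum()
        tpm_target[~silent] *= budget / tpm_target[~silent].sum()
    length_kb = lengths.to_numpy() / 1000.0
    mu = tpm_target * length_kb
    mu *= config.library_size / mu.sum()

    disp = config.count_dispersion
    counts = {}
    for s in range(n_samples):
        p = disp / (disp + mu)
        counts[f"rep{s + 1}"] = rng.negative_binomial(disp, p)
    df = pd.DataFrame(counts, index=ids)
    expressed = pd.Series(~silent, index=ids, name="expressed")
    return df, lengths, expressed


# ---------------------------------------------------------------------------
# term maps, sequences, demo PWMs
# ---------------------------------------------------------------------------

def simulate_term_map(
    genome: SyntheticGenome,
    config: SimulationConfig,
    n_terms: int = 30,
    size_range: tuple[int, int] = (5, 40),
) -> dict[str, set[str]]:
    """Random gene-to-term map over the genome's genes."""
    rng = _rng(config, _STREAM_TERMS)
    ids = [g.gene_id for g in genome.genes]
    out: dict[str, set[str]] = {}
    pad = len(str(n_terms))
    for t in range(n_terms):
        size = int(rng.integers(size_range[0], min(size_range[1], len(ids)) + 1))
        members = rng.choice(len(ids), size=size, replace=False)
        out[f"TERM:{t + 1:0{pad}d}"] = {ids[i] for i in members}
    return out


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def consensus_sequence(pwm: PWM) -> str:
    return "".join("ACGT"[i] for i in pwm.matrix.argmax(axis=1))


def simulate_motif_sequences(
    peaks: Sequence[GenomicInterval],
    pwm: PWM,
    config: SimulationConfig,
    planted_fraction: float = 0.8,
    n_background: int | None = None,
    background_length: int = 500,
) -> tuple[list[str], list[str], np.ndarray]:
    """Random sequences for peaks, with the motif consensus planted in a
    controlled fraction of targets; backgrounds are unplanted random DNA.

    Returns ``(target_seqs, background_seqs, planted_flags)``.
    """
    rng = _rng(config, _STREAM_SEQS)
    motif = consensus_sequence(pwm)
    targets, planted = [], np.zeros(len(peaks), dtype=bool)
    for i, pk in enumerate(peaks):
        seq = random_dna(rng, max(pk.length, pwm.length + 2))
        if rng.random() < planted_fraction:
            pos = int(rng.integers(0, len(seq) - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
            planted[i] = True
        targets.append(seq)
    if n_background is None:
        n_background = 3 * len(peaks)
    backgrounds = [random_dna(rng, background_length) for _ in range(n_background)]
    return targets, backgrounds, planted


def demo_pwms() -> list[PWM]:
    """Small built-in PWM library for demos: a CCAAT-box (NF-Y-like) and a
    TGACTCA (AP-1/FOS-like) motif, both with strong information content."""

    def sharp(seq: str, p: float = 0.91) -> np.ndarray:
        m = np.full((len(seq), 4), (1.0 - p) / 3.0)
        for i, b in enumerate(seq):
            m[i, "ACGT".index(b)] = p
        return m

    return [
        PWM("NFY_CCAAT", sharp("AGCCAATCA")),
        PWM("FOS_AP1", sharp("TGACTCA")),
    ]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["fragment_mixture"] = list(data["fragment_mixture"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["fragment_mixture"] = tuple(data["fragment_mixture"])
    return SimulationConfig(**data)
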