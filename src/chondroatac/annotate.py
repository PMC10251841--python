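"""Peak-to-feature annotation with a fixed priority and over-representation tests.

Feature tracks (promoter, UTRs, exon, intron, downstream) are derived
from gene models; each peak is assigned the single highest-priority
category it overlaps by at least 1 bp, in the order

    promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal intergenic

mirroring the convention of promoter-first annotators.  The promoter is
the strand-aware +/-3 kb window around the TSS by default.  Peaks are
also assigned their nearest gene by TSS-to-midpoint distance, and gene
sets can be tested for term over-representation with a hypergeometric
upper-tail test plus Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, merge_intervals, overlap_bp

__all__ = [
    "GeneModel",
    "PeakAnnotation",
    "ORAResult",
    "CATEGORIES",
    "feature_tracks",
    "annotate_peak",
    "annotate_peaks",
    "annotation_summary",
    "ora_test",
    "read_gene_table",
    "write_gene_table",
    "read_term_map",
    "write_annotations",
]

#: priority order; distal_intergenic is the fallback for no overlap
CATEGORIES = (
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS, exon structure and optional CDS."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("gene span must satisfy 0 <= start < end")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping and "
                    "within the gene span"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not (self.start <= self.cds_start < self.cds_end <= self.end):
                raise ValueError(f"{self.gene_id}: CDS outside gene span")

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost coordinate on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class PeakAnnotation:
    peak: GenomicInterval
    category: str
    nearest_gene: str | None
    distance_to_tss: int | None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class ORAResult:
    """Hypergeometric over-representation result for one term."""

    term_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    adjusted_p: float
    significant: bool


# ---------------------------------------------------------------------------
# feature tracks
# ---------------------------------------------------------------------------

def _subtract(span: tuple[int, int], blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Subtract sorted non-overlapping blocks from a span."""
    out = []
    cursor = span[0]
    for s, e in blocks:
        s, e = max(s, span[0]), min(e, span[1])
        if e <= s:
            continue
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


def _intersect(span: tuple[int, int], blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in blocks:
        s, e = max(s, span[0]), min(e, span[1])
        if e > s:
            out.append((s, e))
    return out


def feature_tracks(
    genes: Sequence[GeneModel],
    promoter_flank: int = 3000,
    downstream_flank: int = 3000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Derive per-category interval tracks from gene models.

    * promoter: strand-aware TSS +/- ``promoter_flank``
    * 5'/3' UTR: exonic sequence outside the CDS, split by strand
    * exon: coding exon bodies (full exons for non-coding genes)
    * intron: gene span minus exons
    * downstream: ``downstream_flank`` bp past the gene 3' end

    Intervals are clipped to ``[0, chrom_length)``.
    """
    tracks: dict[str, list[GenomicInterval]] = {c: [] for c in CATEGORIES[:-1]}

    def clip_add(cat: str, chrom: str, start: int, end: int) -> None:
        start = max(0, start)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[chrom])
        if end > start:
            tracks[cat].append(GenomicInterval(chrom, start, end))

    for g in genes:
        clip_add("promoter", g.chrom, g.tss - promoter_flank, g.tss + promoter_flank)
        if g.strand == "+":
            clip_add("downstream", g.chrom, g.end, g.end + downstream_flank)
        else:
            clip_add("downstream", g.chrom, g.start - downstream_flank, g.start)

        if g.coding:
            left_utr = _intersect((g.start, g.cds_start), g.exons)
            right_utr = _intersect((g.cds_end, g.end), g.exons)
            five, three = (left_utr, right_utr) if g.strand == "+" else (right_utr, left_utr)
            for s, e in five:
                clip_add("five_prime_utr", g.chrom, s, e)
            for s, e in three:
                clip_add("three_prime_utr", g.chrom, s, e)
            for s, e in _intersect((g.cds_start, g.cds_end), g.exons):
                clip_add("exon", g.chrom, s, e)
        else:
            for s, e in g.exons:
                clip_add("exon", g.chrom, s, e)

        for s, e in _subtract((g.start, g.end), g.exons):
            clip_add("intron", g.chrom, s, e)

    return tracks


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

class _TrackIndex:
    """Merged, sorted per-chromosome arrays supporting overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        merged = merge_intervals(intervals)
        chroms: dict[str, list[tuple[int, int]]] = {}
        for iv in merged:
            chroms.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in chroms.items():
            starts = np.array([s for s, _ in spans], dtype=np.int64)
            ends = np.array([e for _, e in spans], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends)

    def overlaps(self, peak: GenomicInterval) -> bool:
        entry = self._by_chrom.get(peak.chrom)
        if entry is None:
            return False
        starts, ends = entry
        # merged intervals are disjoint & sorted: candidate is the one whose
        # end is the first to exceed peak.start
        i = int(np.searchsorted(ends, peak.start, side="right"))
        return i < len(starts) and starts[i] < peak.end


def build_track_index(
    tracks: Mapping[str, Sequence[GenomicInterval]]
) -> dict[str, _TrackIndex]:
    return {cat: _TrackIndex(ivs) for cat, ivs in tracks.items()}


def _nearest_gene(
    peak: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str | None, int | None]:
    mid = peak.midpoint
    best: tuple[int, str] | None = None
    best_signed = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        dist = abs(mid - g.tss)
        key = (dist, g.gene_id)
        if best is None or key < best:
            best = key
            best_signed = (mid - g.tss) if g.strand == "+" else (g.tss - mid)
    if best is None:
        return None, None
    return best[1], best_signed


def annotate_peak(
    peak: GenomicInterval,
    tracks: Mapping[str, Sequence[GenomicInterval]] | Mapping[str, _TrackIndex],
    genes: Sequence[GeneModel],
) -> PeakAnnotation:
    """Assign one feature category (priority order) and the nearest gene.

    The category is the highest-priority track the peak overlaps by >=1
    bp; a peak overlapping nothing is ``distal_intergenic``.  The nearest
    gene minimises |peak midpoint - TSS| (ties broken by lexicographic
    gene id); the signed distance is negative upstream of the TSS in gene
    orientation.
    """
    index = (
        tracks
        if all(isinstance(v, _TrackIndex) for v in tracks.values())
        else build_track_index(tracks)
    )
    category = "distal_intergenic"
    for cat in CATEGORIES[:-1]:
        idx = index.get(cat)
        if idx is not None and idx.overlaps(peak):
            category = cat
            break
    gene_id, signed = _nearest_gene(peak, genes)
    return PeakAnnotation(peak, category, gene_id, signed)


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    tracks: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
) -> list[PeakAnnotation]:
    index = build_track_index(tracks)
    return [annotate_peak(p, index, genes) for p in peaks]


def annotation_summary(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Percentage of peaks per category; always reports all seven categories."""
    if len(annotations) == 0:
        raise ValueError("no annotations to summarise")
    counts = {c: 0 for c in CATEGORIES}
    for ann in annotations:
        counts[ann.category] += 1
    n = len(annotations)
    return {c: 100.0 * counts[c] / n for c in CATEGORIES}


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_test(
    gene_set: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.01,
) -> list[ORAResult]:
    """Hypergeometric over-representation of ``gene_set`` in each term.

    For a universe of N genes, a term with K members and a query set of n
    genes containing k term members, p = P(X >= k) for X hypergeometric.
    BH adjustment is applied across all tested terms; ``significant``
    flags adjusted p <= ``alpha``.  Results are sorted by (adjusted p,
    raw p, term id).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    query = set(gene_set)
    if not query <= universe_set:
        raise ValueError("gene_set must be a subset of the universe")
    N, n = len(universe_set), len(query)

    terms = sorted(term_map)
    rows = []
    for term in terms:
        members = set(term_map[term]) & universe_set
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(p, 1.0)))
    if not rows:
        return []
    pvals = np.array([r[3] for r in rows])
    adj = multipletests(pvals, method="fdr_bh")[1]
    results = [
        ORAResult(term, k, n, K, N, p, float(q), bool(q <= alpha))
        for (term, k, K, p), q in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term_id))
    return results


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a TSV with semicolon-joined exon blocks."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\texons\tcds_start\tcds_end\n")
        for g in genes:
            exons = ";".join(f"{s}-{e}" for s, e in g.exons)
            cs = g.cds_start if g.cds_start is not None else "NA"
            ce = g.cds_end if g.cds_end is not None else "NA"
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t{exons}\t{cs}\t{ce}\n"
            )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    genes = []
    for row in df.itertuples(index=False):
        exons = tuple(
            tuple(int(x) for x in block.split("-")) for block in str(row.exons).split(";")
        )
        cds_start = None if str(row.cds_start) == "NA" else int(row.cds_start)
        cds_end = None if str(row.cds_end) == "NA" else int(row.cds_end)
        genes.append(
            GeneModel(
                row.gene_id, row.chrom, row.strand, int(row.start), int(row.end),
                exons, cds_start, cds_end,
            )
        )
    return genes


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column (term_id, gene_id) TSV into term -> gene-set."""
    df = pd.read_csv(path, sep="\t", names=["term_id", "gene_id"], header=0)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.term_id, set()).add(row.gene_id)
    return out


def write_annotations(annotations: Sequence[PeakAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcategory\tnearest_gene\tdistance_to_tss\n")
        for a in annotations:
            gene = a.nearest_gene if a.nearest_gene is not None else "NA"
            dist = a.distance_to_tss if a.distance_to_tss is not None else "NA"
            fh.write(
                f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t{a.category}\t{gene}\t{dist}\n"
            )
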