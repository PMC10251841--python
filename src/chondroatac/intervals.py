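"""Genomic interval algebra and replicate-consensus peak construction.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` bases and abutting intervals do
not overlap.

The consensus rule implemented by :func:`consensus_peaks` keeps a peak
when it reproduces — with strictly more than a given fraction of
*reciprocal* overlap — in a required number of biological replicates,
then unions mutually overlapping retained peaks into one consensus
region.  This is the deterministic reproducibility filter commonly
applied to per-replicate ATAC-seq peak calls before downstream
annotation.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "ConsensusPeak",
    "read_bed",
    "write_bed",
    "overlap_bp",
    "reciprocal_overlap_pass",
    "merge_intervals",
    "consensus_peaks",
    "genome_fraction",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ConsensusPeak:
    """A reproducible peak: the union span of mutually linked replicate peaks.

    ``support`` holds the indices of the replicates contributing at least
    one retained peak to this consensus region.
    """

    interval: GenomicInterval
    support: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.support) < 1:
            raise ValueError("consensus peak requires non-empty support")


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into a list of :class:`GenomicInterval`, preserving order.

    Lines starting with ``track``, ``browser`` or ``#`` and blank lines are
    skipped.  Malformed records raise :class:`ValueError` naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3, or BED6 ('.' strand) when name/score present."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is None and iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# overlap primitives
# ---------------------------------------------------------------------------

def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap_pass(
    a: GenomicInterval, b: GenomicInterval, threshold: float = 0.5
) -> bool:
    """True iff the shared span strictly exceeds ``threshold`` of *both* lengths.

    Strict inequality: two intervals overlapping by exactly half of each
    fail at ``threshold=0.5``.  An interval that is *entirely* covered
    satisfies its side of the test at any threshold (otherwise identical
    intervals could never pass at threshold 1).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ov = overlap_bp(a, b)
    if ov == 0:
        return False
    pass_a = ov > threshold * a.length or ov == a.length
    pass_b = ov > threshold * b.length or ov == b.length
    return pass_a and pass_b


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping (not merely abutting) intervals per chromosome."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
            continue
        merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class _ChromIndex:
    """Sorted per-chromosome interval lists with a windowed overlap query."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start)):
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts = {c: [iv.start for iv in lst] for c, lst in self._by_chrom.items()}
        self._max_len = {
            c: max(iv.length for iv in lst) for c, lst in self._by_chrom.items()
        }

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        lst = self._by_chrom.get(query.chrom)
        if not lst:
            return []
        starts = self._starts[query.chrom]
        # any overlapper starts after query.start - max_len and before query.end
        lo = bisect_left(starts, query.start - self._max_len[query.chrom])
        hi = bisect_right(starts, query.end - 1)
        return [iv for iv in lst[lo:hi] if overlap_bp(iv, query) > 0]


def consensus_peaks(
    replicate_sets: Sequence[Sequence[GenomicInterval]],
    min_replicates: int = 2,
    threshold: float = 0.5,
) -> list[ConsensusPeak]:
    """Build consensus peaks from per-replicate peak sets.

    A peak is *retained* when at least ``min_replicates - 1`` other
    replicates each contain a peak passing the strict reciprocal-overlap
    test against it.  Retained peaks that overlap by >=1 bp are then
    linked transitively (across and within replicates) and each linked
    component is emitted as one :class:`ConsensusPeak` spanning the outer
    bounds of its members.  Output is sorted by (chrom, start) and its
    intervals are pairwise disjoint.

    Each replicate set is pre-merged internally so that "a peak" is well
    defined even if the caller supplies overlapping fragments.
    """
    if min_replicates > len(replicate_sets):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds the {len(replicate_sets)} "
            "replicate sets provided"
        )
    merged_sets = [merge_intervals(s) for s in replicate_sets]
    indexes = [_ChromIndex(s) if s else None for s in merged_sets]

    retained: list[tuple[int, GenomicInterval]] = []
    for i, peaks in enumerate(merged_sets):
        for p in peaks:
            n_partner_reps = 0
            for j, idx in enumerate(indexes):
                if j == i or idx is None:
                    continue
                if any(
                    reciprocal_overlap_pass(p, q, threshold)
                    for q in idx.overlapping(p)
                ):
                    n_partner_reps += 1
            if n_partner_reps >= min_replicates - 1:
                retained.append((i, p))

    # transitive union of overlapping retained peaks via a sorted sweep
    retained.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end))
    out: list[ConsensusPeak] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_support: set[int] = set()

    def _flush() -> None:
        if cur_chrom is not None:
            out.append(
                ConsensusPeak(
                    GenomicInterval(
                        cur_chrom,
                        cur_start,
                        cur_end,
                        name=",".join(f"rep{r}" for r in sorted(cur_support)),
                        score=float(len(cur_support)),
                    ),
                    frozenset(cur_support),
                )
            )

    for rep, p in retained:
        if p.chrom == cur_chrom and p.start < cur_end:
            cur_end = max(cur_end, p.end)
            cur_support.add(rep)
        else:
            _flush()
            cur_chrom, cur_start, cur_end = p.chrom, p.start, p.end
            cur_support = {rep}
    _flush()
    return out


def genome_fraction(
    intervals: Iterable[GenomicInterval], chrom_lengths: Mapping[str, int]
) -> float:
    """Fraction of the genome covered by the union of ``intervals``.

    Overlapping inputs are counted once.  Intervals extending past their
    chromosome end (or on unknown chromosomes) raise :class:`ValueError`.
    """
    total = sum(chrom_lengths.values())
    if total <= 0:
        raise ValueError("chromosome lengths must sum to > 0")
    covered = 0
    for iv in merge_intervals(intervals):
        if iv.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > chrom_lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {chrom_lengths[iv.chrom]}"
            )
        covered += iv.length
    return covered / total
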