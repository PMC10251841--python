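"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive all-pairs / per-base algorithms
so they share no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from chondroatac.intervals import GenomicInterval

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# consensus-peak oracle: all-pairs reciprocal test + fixpoint transitive union
# ---------------------------------------------------------------------------

def _naive_merge(intervals):
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out = []
    for iv in ivs:
        if out and out[-1][0] == iv.chrom and iv.start < out[-1][2]:
            out[-1][2] = max(out[-1][2], iv.end)
        else:
            out.append([iv.chrom, iv.start, iv.end])
    return [GenomicInterval(c, s, e) for c, s, e in out]


def consensus_oracle(replicate_sets, min_replicates=2, threshold=0.5):
    """Returns sorted tuples (chrom, start, end, frozenset(support))."""
    merged = [_naive_merge(s) for s in replicate_sets]
    retained = []
    for i, peaks in enumerate(merged):
        for p in peaks:
            partner_reps = set()
            for j, other in enumerate(merged):
                if j == i:
                    continue
                for q in other:
                    if p.chrom != q.chrom:
                        continue
                    ov = max(0, min(p.end, q.end) - max(p.start, q.start))
                    la, lb = p.end - p.start, q.end - q.start
                    if (ov > threshold * la or ov == la) and (
                        ov > threshold * lb or ov == lb
                    ):
                        partner_reps.add(j)
            if len(partner_reps) >= min_replicates - 1:
                retained.append((i, p))
    clusters = [[p.chrom, p.start, p.end, {i}] for i, p in retained]
    changed = True
    while changed:
        changed = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                if ca[0] == cb[0] and ca[1] < cb[2] and cb[1] < ca[2]:
                    clusters[a] = [
                        ca[0], min(ca[1], cb[1]), max(ca[2], cb[2]), ca[3] | cb[3],
                    ]
                    del clusters[b]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e, frozenset(sup)) for c, s, e, sup in clusters)


def random_replicate_sets(rng, n_reps=3, max_intervals=100, span=10_000, chroms=("chr1", "chr2")):
    sets = []
    for _ in range(n_reps):
        n = int(rng.integers(1, max_intervals + 1))
        ivs = []
        for _ in range(n):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, span - 10))
            length = int(rng.integers(10, 500))
            ivs.append(GenomicInterval(chrom, start, min(start + length, span)))
        sets.append(ivs)
    return sets


# ---------------------------------------------------------------------------
# per-base annotation oracle
# ---------------------------------------------------------------------------

def annotation_oracle_category(peak, tracks):
    """Highest-priority category over every base the peak covers."""
    from chondroatac.annotate import CATEGORIES

    best = len(CATEGORIES) - 1  # distal_intergenic
    for base in range(peak.start, peak.end):
        for rank, cat in enumerate(CATEGORIES[:-1]):
            if rank >= best:
                break
            for iv in tracks[cat]:
                if iv.chrom == peak.chrom and iv.start <= base < iv.end:
                    best = rank
                    break
    return CATEGORIES[best]


# ---------------------------------------------------------------------------
# BH brute force
# ---------------------------------------------------------------------------

def bh_oracle(pvals):
    """Definitional Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
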