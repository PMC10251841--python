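"""Feature tracks, priority annotation and over-representation testing."""

import numpy as np
import pytest
from scipy import stats

from chondroatac.annotate import (
    CATEGORIES,
    GeneModel,
    annotate_peak,
    annotate_peaks,
    annotation_summary,
    feature_tracks,
    ora_test,
    read_gene_table,
    write_gene_table,
)
from chondroatac.intervals import GenomicInterval
from conftest import annotation_oracle_category, bh_oracle


def make_gene(gene_id="g1", chrom="chr1", strand="+", start=10_000, end=20_000,
              exons=None, cds=(11_000, 19_000)):
    exons = exons if exons is not None else ((start, start + 2000), (end - 2000, end))
    cds_start, cds_end = cds if cds else (None, None)
    return GeneModel(gene_id, chrom, strand, start, end, exons, cds_start, cds_end)


class TestFeatureTracks:
    def test_plus_strand_promoter_window(self):
        tracks = feature_tracks([make_gene(start=10_000, end=20_000)])
        [prom] = tracks["promoter"]
        assert (prom.start, prom.end) == (7000, 13_000)

    def test_minus_strand_promoter_window(self):
        g = make_gene(strand="-", start=40_000, end=50_000,
                      exons=((40_000, 42_000), (48_000, 50_000)), cds=(41_000, 49_000))
        tracks = feature_tracks([g])
        [prom] = tracks["promoter"]
        assert (prom.start, prom.end) == (47_000, 53_000)

    def test_single_exon_gene_has_no_intron(self):
        g = make_gene(exons=((10_000, 20_000),), cds=(11_000, 19_000))
        assert feature_tracks([g])["intron"] == []

    def test_utrs_split_by_strand(self):
        plus = feature_tracks([make_gene(strand="+")])
        minus = feature_tracks([make_gene(strand="-")])
        # + strand: exonic sequence before the CDS is the 5'UTR
        assert plus["five_prime_utr"] == [GenomicInterval("chr1", 10_000, 11_000)]
        assert plus["three_prime_utr"] == [GenomicInterval("chr1", 19_000, 20_000)]
        # - strand: the same genomic pieces swap roles
        assert minus["five_prime_utr"] == [GenomicInterval("chr1", 19_000, 20_000)]
        assert minus["three_prime_utr"] == [GenomicInterval("chr1", 10_000, 11_000)]

    def test_noncoding_gene_keeps_exons_but_no_utrs(self):
        g = make_gene(cds=None)
        tracks = feature_tracks([g])
        assert tracks["five_prime_utr"] == [] and tracks["three_prime_utr"] == []
        assert len(tracks["exon"]) == 2

    def test_downstream_is_strandwise(self):
        plus = feature_tracks([make_gene(strand="+")])["downstream"]
        assert plus == [GenomicInterval("chr1", 20_000, 23_000)]
        g = make_gene(strand="-", start=40_000, end=50_000,
                      exons=((40_000, 50_000),), cds=(41_000, 49_000))
        minus = feature_tracks([g])["downstream"]
        assert minus == [GenomicInterval("chr1", 37_000, 40_000)]


class TestAnnotatePeak:
    def test_promoter_beats_exon(self):
        g = make_gene()
        tracks = feature_tracks([g])
        # overlaps both the promoter window and the first exon
        ann = annotate_peak(GenomicInterval("chr1", 10_500, 11_500), tracks, [g])
        assert ann.category == "promoter"

    def test_no_overlap_is_distal_intergenic(self):
        g = make_gene()
        ann = annotate_peak(GenomicInterval("chr1", 500_000, 500_200),
                            feature_tracks([g]), [g])
        assert ann.category == "distal_intergenic"

    def test_signed_distance_negative_upstream(self):
        g = make_gene(strand="+", start=10_000)  # TSS at 10,000
        tracks = feature_tracks([g])
        up = annotate_peak(GenomicInterval("chr1", 5000, 5100), tracks, [g])
        down = annotate_peak(GenomicInterval("chr1", 15_000, 15_100), tracks, [g])
        assert up.distance_to_tss < 0 < down.distance_to_tss
        gm = make_gene(strand="-", start=40_000, end=50_000,
                       exons=((40_000, 50_000),), cds=(41_000, 49_000))
        tracks_m = feature_tracks([gm])
        # for a - strand gene, upstream means to the right of the TSS (50,000)
        up_m = annotate_peak(GenomicInterval("chr1", 55_000, 55_100), tracks_m, [gm])
        assert up_m.distance_to_tss < 0

    def test_nearest_gene_tie_broken_lexicographically(self):
        ga = make_gene("gA", start=10_000, end=12_000, exons=((10_000, 12_000),),
                       cds=(10_500, 11_500))
        gb = make_gene("gB", strand="-", start=18_000, end=20_000,
                       exons=((18_000, 20_000),), cds=(18_500, 19_500))
        # midpoint 15,000 is equidistant from TSS 10,000 and TSS 20,000
        ann = annotate_peak(GenomicInterval("chr1", 14_950, 15_050),
                            feature_tracks([ga, gb]), [ga, gb])
        assert ann.nearest_gene == "gA"

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        genes = []
        for i in range(8):
            start = int(rng.integers(0, 80_000))
            length = int(rng.integers(2000, 15_000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(np.arange(1, length), 2 * n_ex - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [length]]) + start
            exons = tuple((int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(n_ex))
            cds = (exons[0][0] + 10, exons[-1][1] - 10) if rng.random() < 0.8 else None
            genes.append(GeneModel(f"g{i}", "chr1", strand, start, start + length,
                                   exons, *(cds or (None, None))))
        tracks = feature_tracks(genes)
        for _ in range(200):
            start = int(rng.integers(0, 99_000))
            peak = GenomicInterval("chr1", start, start + int(rng.integers(50, 800)))
            ann = annotate_peak(peak, tracks, genes)
            assert ann.category == annotation_oracle_category(peak, tracks)


class TestAnnotationSummary:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            annotation_summary([])

    def test_percentages_cover_all_categories_and_sum_to_100(self, rng):
        g = make_gene()
        tracks = feature_tracks([g])
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 60_000, 97)
        ]
        summary = annotation_summary(annotate_peaks(peaks, tracks, [g]))
        assert set(summary) == set(CATEGORIES)
        assert sum(summary.values()) == pytest.approx(100.0, abs=0.01)

    def test_uniform_spread_across_categories(self):
        anns = annotate_peaks(
            [GenomicInterval("chr1", 1, 2)], {c: [] for c in CATEGORIES[:-1]}, []
        )
        summary = annotation_summary(anns)
        assert summary["distal_intergenic"] == 100.0


class TestOraTest:
    def test_whole_universe_term_is_unenriched(self):
        universe = [f"g{i}" for i in range(50)]
        res = ora_test(universe[:10], {"T": set(universe)}, universe)
        assert res[0].p_value == pytest.approx(1.0)

    def test_zero_hits_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        res = ora_test(["g0"], {"T": {"g40", "g41"}}, universe)
        assert res[0].k == 0 and res[0].p_value == pytest.approx(1.0)

    def test_matches_pmf_sum_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        term = {f"g{i}" for i in range(10)}
        gene_set = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(50, 55)]
        [res] = ora_test(gene_set, {"T": term}, universe)
        assert res.k == 5
        oracle = sum(stats.hypergeom.pmf(x, 100, 10, 10) for x in range(5, 11))
        assert res.p_value == pytest.approx(oracle, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_test([], {"T": set()}, [])

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_test(["x"], {"T": {"a"}}, ["a", "b"])

    def test_bh_adjustment_matches_definitional_brute_force(self, rng):
        universe = [f"g{i}" for i in range(80)]
        term_map = {}
        for t in range(25):
            size = int(rng.integers(3, 30))
            term_map[f"T{t}"] = set(rng.choice(universe, size, replace=False))
        gene_set = list(rng.choice(universe, 20, replace=False))
        results = ora_test(gene_set, term_map, universe)
        raw = {r.term_id: r.p_value for r in results}
        terms = sorted(raw)
        expected = bh_oracle([raw[t] for t in terms])
        got = {r.term_id: r.adjusted_p for r in results}
        for t, e in zip(terms, expected):
            assert got[t] == pytest.approx(e, rel=1e-12)
        # adjusted p >= raw p, monotone in raw-p rank
        ordered = sorted(results, key=lambda r: r.p_value)
        for a, b in zip(ordered, ordered[1:]):
            assert a.adjusted_p <= b.adjusted_p + 1e-15
        for r in results:
            assert r.adjusted_p >= r.p_value - 1e-15

    def test_null_calibration_against_permutation(self, rng):
        # the hypergeometric p for one term should match the frequency of
        # equally-or-more extreme overlaps under random gene-set draws
        universe = [f"g{i}" for i in range(40)]
        term = set(universe[:12])
        gene_set = list(rng.choice(universe, 10, replace=False))
        [res] = ora_test(gene_set, {"T": term}, universe)
        draws = 10_000
        uni = np.array(universe)
        hits = 0
        for _ in range(draws):
            sample = rng.choice(uni, 10, replace=False)
            if len(set(sample) & term) >= res.k:
                hits += 1
        mc = hits / draws
        se = np.sqrt(res.p_value * (1 - res.p_value) / draws)
        assert abs(mc - res.p_value) < 4 * se + 1e-9


def test_gene_table_round_trip(tmp_path):
    genes = [
        make_gene("a"),
        make_gene("b", strand="-", start=40_000, end=50_000,
                  exons=((40_000, 43_000), (45_000, 50_000)), cds=(41_000, 49_000)),
        make_gene("c", cds=None),
    ]
    path = tmp_path / "genes.tsv"
    write_gene_table(genes, path)
    assert read_gene_table(path) == genes
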