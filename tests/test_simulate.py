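"""Synthetic-data generators: determinism, degenerate cases and constructions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from chondroatac.expression import compute_tpm, expressed_genes, replicate_correlation
from chondroatac.footprint import aggregate_footprint
from chondroatac.gwas import snp_in_peak_mask, snp_in_peaks
from chondroatac.intervals import GenomicInterval, genome_fraction
from chondroatac.signal_peaks import cut_site_index
from chondroatac.simulate import (
    PlacementError,
    SimulationConfig,
    demo_pwms,
    make_genome,
    read_config,
    simulate_counts,
    simulate_footprint_sites,
    simulate_fragments,
    simulate_replicate_peaks,
    simulate_snps,
    write_config,
)


SMALL = dict(chrom_lengths={"chr1": 300_000}, n_genes=20, n_true_peaks=60)


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(replicate_dropout=1.5)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(fragment_mixture=(0.5, 0.5, 0.5, 0.0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_true_peaks=-1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_genes=7)
        path = tmp_path / "cfg.yaml"
        write_config(cfg, path)
        assert read_config(path) == cfg


class TestMakeGenome:
    def test_zero_genes_gives_empty_gene_list(self):
        genome = make_genome(SimulationConfig(n_genes=0))
        assert genome.genes == ()

    def test_two_genes_fit_small_chromosome(self):
        cfg = SimulationConfig(
            chrom_lengths={"chrA": 10_000}, n_genes=2, gene_length_mean=1000
        )
        genome = make_genome(cfg)
        (a, b) = sorted(genome.genes, key=lambda g: g.start)
        assert a.end <= b.start and b.end <= 10_000

    def test_impossible_placement_raises(self):
        cfg = SimulationConfig(
            chrom_lengths={"chrA": 5_000}, n_genes=50, gene_length_mean=4000
        )
        with pytest.raises(PlacementError):
            make_genome(cfg)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        assert make_genome(cfg) == make_genome(cfg)

    def test_tss_strand_orientation(self):
        genome = make_genome(SimulationConfig(seed=3, **SMALL))
        for g in genome.genes:
            assert g.tss == (g.start if g.strand == "+" else g.end)
            assert len(g.exons) >= 1


class TestReplicatePeaks:
    def test_no_dropout_keeps_every_peak_everywhere(self):
        cfg = SimulationConfig(seed=1, replicate_dropout=0.0, **SMALL)
        genome = make_genome(cfg)
        reps, true_peaks = simulate_replicate_peaks(genome, cfg)
        for peaks in reps:
            assert len(peaks) == len(true_peaks)

    def test_full_dropout_empties_every_replicate(self):
        cfg = SimulationConfig(seed=1, replicate_dropout=1.0, **SMALL)
        genome = make_genome(cfg)
        reps, _ = simulate_replicate_peaks(genome, cfg)
        assert all(len(p) == 0 for p in reps)

    def test_presence_rate_matches_binomial_expectation(self):
        # P(peak in >=2 of 3 replicates), X ~ Bin(3, 0.8): 3*0.64*0.2 + 0.512
        cfg = SimulationConfig(
            seed=9, replicate_dropout=0.2, n_true_peaks=200,
            chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000}, n_genes=50,
        )
        genome = make_genome(cfg)
        reps, true_peaks = simulate_replicate_peaks(genome, cfg)
        names = [set(p.name for p in peaks) for peaks in reps]
        n_two_plus = sum(
            1 for t in true_peaks if sum(t.name in s for s in names) >= 2
        )
        expect = 0.896
        se = np.sqrt(expect * (1 - expect) / 200)
        assert abs(n_two_plus / 200 - expect) < 3 * se

    def test_deterministic_and_within_bounds(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        genome = make_genome(cfg)
        a = simulate_replicate_peaks(genome, cfg)
        b = simulate_replicate_peaks(genome, cfg)
        assert a == b
        for peaks in a[0]:
            for p in peaks:
                assert 0 <= p.start < p.end <= genome.chrom_lengths[p.chrom]

    def test_promoter_fraction_controls_planting(self):
        cfg = SimulationConfig(seed=4, promoter_peak_fraction=0.5, **SMALL)
        genome = make_genome(cfg)
        _, true_peaks = simulate_replicate_peaks(genome, cfg)
        windows = [
            GenomicInterval(g.chrom, max(0, g.tss - 3000), g.tss + 3000)
            for g in genome.genes
        ]
        snps = pd.DataFrame(
            {"chrom": [p.chrom for p in true_peaks],
             "pos": [p.midpoint for p in true_peaks]}
        )
        in_prom = snp_in_peak_mask(snps, windows).sum()
        assert in_prom == round(0.5 * len(true_peaks))


class TestFragments:
    def test_pure_nfr_mixture_all_short(self):
        cfg = SimulationConfig(seed=1, fragment_mixture=(1.0, 0, 0, 0),
                               n_fragments=2000, **SMALL)
        genome = make_genome(cfg)
        _, tp = simulate_replicate_peaks(genome, cfg)
        frags, _ = simulate_fragments(genome, tp, cfg)
        lengths = frags["end"] - frags["start"]
        assert (lengths < 100).all()

    def test_ladder_modes_present_under_equal_weights(self):
        cfg = SimulationConfig(seed=1, fragment_mixture=(0.25, 0.25, 0.25, 0.25),
                               n_fragments=10_000, **SMALL)
        genome = make_genome(cfg)
        _, tp = simulate_replicate_peaks(genome, cfg)
        frags, _ = simulate_fragments(genome, tp, cfg)
        lengths = (frags["end"] - frags["start"]).to_numpy()
        for lo, hi in ((150, 250), (350, 450), (550, 650)):
            frac = ((lengths >= lo) & (lengths < hi)).mean()
            assert 0.2 < frac < 0.3

    def test_peak_enrichment_factor_recovered(self):
        cfg = SimulationConfig(seed=6, n_fragments=100_000, tss_cut_fraction=0.0,
                               peak_cut_enrichment=10.0, **SMALL)
        genome = make_genome(cfg)
        _, tp = simulate_replicate_peaks(genome, cfg)
        frags, _ = simulate_fragments(genome, tp, cfg)
        starts = pd.DataFrame({"chrom": frags["chrom"], "pos": frags["start"]})
        mask = snp_in_peak_mask(starts, tp)
        peak_bp = sum(p.length for p in tp)
        ratio = (mask.sum() / peak_bp) / (
            (~mask).sum() / (genome.total_length - peak_bp)
        )
        assert 8 < ratio < 12

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=8, n_fragments=3000, **SMALL)
        genome = make_genome(cfg)
        _, tp = simulate_replicate_peaks(genome, cfg)
        a, ca = simulate_fragments(genome, tp, cfg)
        b, cb = simulate_fragments(genome, tp, cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ca, cb)


class TestSnps:
    def test_fold_one_matches_peak_coverage(self):
        cfg = SimulationConfig(seed=3, snp_enrichment_fold=1.0,
                               n_candidate_snps=5000, **SMALL)
        genome = make_genome(cfg)
        _, tp = simulate_replicate_peaks(genome, cfg)
        _, cand = simulate_snps(genome, tp, cfg)
        _, prop = snp_in_peaks(cand, tp)
        rho = genome_fraction(tp, genome.chrom_lengths)
        se = np.sqrt(rho * (1 - rho) / 5000)
        assert abs(prop - rho) < 3 * se

    def test_excessive_fold_capped_with_warning(self):
        cfg = SimulationConfig(seed=3, snp_enrichment_fold=1000.0, **SMALL)
        genome = make_genome(cfg)
        _, tp = simulate_replicate_peaks(genome, cfg)
        with pytest.warns(UserWarning, match="capped"):
            _, cand = simulate_snps(genome, tp, cfg)
        _, prop = snp_in_peaks(cand, tp)
        assert prop == 1.0

    def test_fold_three_proportion(self):
        cfg = SimulationConfig(seed=5, snp_enrichment_fold=3.0,
                               n_candidate_snps=20_000, **SMALL)
        genome = make_genome(cfg)
        _, tp = simulate_replicate_peaks(genome, cfg)
        _, cand = simulate_snps(genome, tp, cfg)
        rho = genome_fraction(tp, genome.chrom_lengths)
        _, prop = snp_in_peaks(cand, tp)
        se = np.sqrt(3 * rho * (1 - 3 * rho) / 20_000)
        assert abs(prop - 3 * rho) < 3 * se


class TestFootprintSites:
    def _peaks(self):
        return [GenomicInterval("chr1", 10_000 + i * 6000, 10_000 + i * 6000 + 4000)
                for i in range(40)]

    def test_unbound_sites_give_flat_profile(self):
        cfg = SimulationConfig(seed=2, bound_motif_fraction=0.0, n_footprint_sites=300)
        genome = make_genome(dataclasses.replace(cfg, n_genes=0))
        sites, bound, cuts = simulate_footprint_sites(
            genome, self._peaks(), demo_pwms()[0], cfg
        )
        assert not bound.any()
        profile = aggregate_footprint(cut_site_index(cuts), sites)
        assert 0.9 < profile.depth_score < 1.1

    def test_zero_depletion_silences_bound_centers(self):
        cfg = SimulationConfig(seed=2, bound_motif_fraction=1.0,
                               footprint_depletion=0.0, n_footprint_sites=100)
        genome = make_genome(dataclasses.replace(cfg, n_genes=0))
        pwm = demo_pwms()[0]
        sites, _, cuts = simulate_footprint_sites(genome, self._peaks(), pwm, cfg)
        index = cut_site_index(cuts)
        half = pwm.length // 2
        for site in sites:
            lo, hi = site.center - half, site.center - half + pwm.length
            pos = index["chr1"]
            assert np.searchsorted(pos, hi) == np.searchsorted(pos, lo)

    def test_half_depletion_halves_center_rate(self):
        cfg = SimulationConfig(seed=7, bound_motif_fraction=1.0,
                               footprint_depletion=0.5, n_footprint_sites=500)
        genome = make_genome(dataclasses.replace(cfg, n_genes=0))
        sites, _, cuts = simulate_footprint_sites(
            genome, self._peaks(), demo_pwms()[0], cfg
        )
        profile = aggregate_footprint(cut_site_index(cuts), sites)
        assert 1.8 < profile.depth_score < 2.2


class TestCounts:
    def test_tiny_dispersion_gives_near_perfect_correlation(self):
        cfg = SimulationConfig(seed=1, count_dispersion=500.0, **SMALL)
        genome = make_genome(cfg)
        counts, lengths, _ = simulate_counts(genome, cfg)
        tpm = compute_tpm(counts, lengths)
        corr = replicate_correlation(tpm)
        off = corr.to_numpy()[np.triu_indices(3, 1)]
        assert (off > 0.97).all()

    def test_silent_fraction_recovered_after_tpm_filter(self):
        cfg = SimulationConfig(
            seed=13, n_genes=1000, silent_gene_fraction=0.3,
            chrom_lengths={f"chr{i}": 3_000_000 for i in range(1, 6)},
        )
        genome = make_genome(cfg)
        counts, lengths, truth = simulate_counts(genome, cfg)
        tpm = compute_tpm(counts, lengths)
        n_expressed = len(expressed_genes(tpm))
        se = np.sqrt(1000 * 0.3 * 0.7)
        assert abs(n_expressed - 700) < 3 * se
        assert abs(int(truth.sum()) - 700) < 3 * se

    def test_correlation_calibrated_near_study_level(self):
        rs = []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed)
            genome = make_genome(cfg)
            counts, lengths, _ = simulate_counts(genome, cfg)
            tpm = compute_tpm(counts, lengths)
            corr = replicate_correlation(tpm)
            rs.append(corr.to_numpy()[np.triu_indices(3, 1)].mean())
        assert 0.7 < np.mean(rs) < 0.9

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=21, **SMALL)
        genome = make_genome(cfg)
        a = simulate_counts(genome, cfg)
        b = simulate_counts(genome, cfg)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_requires_genes(self):
        cfg = SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            simulate_counts(make_genome(cfg), cfg)
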