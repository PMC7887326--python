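"""Determinism, invariants and statistical calibration of the generator."""
from dataclasses import replace

import numpy as np
import pytest

from m5ckit import synthetic_data as sd
from m5ckit.synthetic_data import CONDITION_A, CONDITION_B, SimulationConfig


class TestGenome:
    def test_deterministic_under_fixed_seed(self, sim_config, genome):
        again = sd.generate_genome(sim_config)
        assert {c: g.sequence for c, g in again.items()} == {
            c: g.sequence for c, g in genome.items()
        }

    def test_gc_content_concentrates(self):
        cfg = SimulationConfig(seed=11, n_chroms=1, chrom_len=50_000, gc_content=0.5)
        seq = sd.generate_genome(cfg)["chr1"].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        # binomial 3-sigma bound at n=50k is ~0.007
        assert 0.48 <= gc <= 0.52

    def test_no_chromosomes(self):
        assert sd.generate_genome(SimulationConfig(seed=1, n_chroms=0)) == {}

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrom_len"):
            sd.generate_genome(SimulationConfig(seed=1, chrom_len=500))


class TestTranscriptome:
    def test_count_and_invariants(self, transcriptome, sim_config):
        assert len(transcriptome) == sim_config.n_genes
        for m in transcriptome:
            assert m.utr5_len + m.cds_len + m.utr3_len == m.spliced_length
            assert m.cds_len >= 6 and m.cds_len % 3 == 0

    def test_both_strands_represented(self, transcriptome):
        assert {m.strand for m in transcriptome} == {"+", "-"}

    def test_genes_never_overlap(self, transcriptome):
        by_chrom = {}
        for m in transcriptome:
            by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_deterministic(self, genome, sim_config, transcriptome):
        again = sd.generate_transcriptome(genome, sim_config)
        assert again == transcriptome

    def test_genome_too_small_suggests_fewer_genes(self):
        cfg = SimulationConfig(seed=1, n_chroms=1, chrom_len=2000, n_genes=50)
        genome = sd.generate_genome(cfg)
        with pytest.raises(ValueError, match="n_genes"):
            sd.generate_transcriptome(genome, cfg)


class TestPlantMethylation:
    def test_no_differential_means_equal_levels(self, transcriptome, genome):
        cfg = SimulationConfig(seed=3, fraction_differential=0.0)
        t = sd.plant_methylation(transcriptome, genome, cfg)
        assert (t.sites.true_level_condA == t.sites.true_level_condB).all()

    def test_all_differential_respects_min_effect(self, transcriptome, genome):
        cfg = SimulationConfig(seed=3, fraction_differential=1.0, differential_effect=0.3)
        t = sd.plant_methylation(transcriptome, genome, cfg)
        delta = (t.sites.true_level_condB - t.sites.true_level_condA).abs()
        assert (delta >= 0.3 - 1e-12).all()
        assert (t.sites.direction == "hyper").any()
        assert (t.sites.direction == "hypo").any()

    def test_sites_sit_on_sense_strand_cytosines(self, truth, genome):
        for r in truth.sites.itertuples():
            base = genome[r.chrom].sequence[r.pos]
            assert base == ("C" if r.strand == "+" else "G")

    def test_insufficient_cytosines_rejected(self, transcriptome, genome):
        cfg = SimulationConfig(seed=3, n_methylated_sites=10**6)
        with pytest.raises(ValueError, match="cytosines"):
            sd.plant_methylation(transcriptome, genome, cfg)


class TestPileups:
    def test_fully_methylated_site_is_all_c(self, transcriptome, genome):
        cfg = SimulationConfig(seed=5, site_levels=(1.0,), fraction_differential=0.0,
                               n_methylated_sites=50)
        t = sd.plant_methylation(transcriptome, genome, cfg)
        p = sd.simulate_pileups(t, transcriptome, genome, cfg)
        keys = set(map(tuple, t.sites[["chrom", "pos", "strand"]].to_numpy()))
        planted = p[[tuple(k) in keys for k in
                     p[["chrom", "pos", "strand"]].to_numpy()]]
        assert (planted.t_count == 0).all()

    def test_unmethylated_without_error_is_all_t(self, transcriptome, genome):
        cfg = SimulationConfig(seed=5, site_levels=(0.0,), fraction_differential=0.0,
                               non_conversion_rate=0.0, n_methylated_sites=50)
        t = sd.plant_methylation(transcriptome, genome, cfg)
        p = sd.simulate_pileups(t, transcriptome, genome, cfg)
        assert (p.c_count == 0).all()

    def test_half_methylated_mean_matches_expectation(self, transcriptome, genome):
        # E[c/n] = 0.5 + 0.5 * ncr = 0.5025 at pi = 0.5
        cfg = SimulationConfig(seed=5, site_levels=(0.5,), fraction_differential=0.0,
                               n_methylated_sites=500, coverage_mean=100.0)
        t = sd.plant_methylation(transcriptome, genome, cfg)
        p = sd.simulate_pileups(t, transcriptome, genome, cfg)
        keys = set(map(tuple, t.sites[["chrom", "pos", "strand"]].to_numpy()))
        planted = p[[tuple(k) in keys for k in
                     p[["chrom", "pos", "strand"]].to_numpy()]]
        total_n = planted.c_count.sum() + planted.t_count.sum()
        assert total_n > 100_000
        assert 0.49 <= planted.c_count.sum() / total_n <= 0.52

    def test_nonsensical_error_rate_rejected(self, truth, transcriptome, genome):
        cfg = SimulationConfig(seed=5)
        cfg.non_conversion_rate = 0.6  # bypass construction-time validation
        with pytest.raises(ValueError, match="non_conversion_rate"):
            sd.simulate_pileups(truth, transcriptome, genome, cfg)

    def test_every_truth_site_covered_in_every_replicate(self, truth, pileups,
                                                         sim_config):
        keys = set(map(tuple, truth.sites[["chrom", "pos", "strand"]].to_numpy()))
        planted = pileups[[tuple(k) in keys for k in
                           pileups[["chrom", "pos", "strand"]].to_numpy()]]
        per_site = planted.groupby(["chrom", "pos", "strand"]).size()
        assert (per_site == 2 * sim_config.n_replicates).all()

    def test_deterministic(self, truth, transcriptome, genome, sim_config, pileups):
        again = sd.simulate_pileups(truth, transcriptome, genome, sim_config)
        assert again.equals(pileups)


class TestExpression:
    def test_deterministic(self, transcriptome, sim_config):
        a, _ = sd.simulate_expression(transcriptome, sim_config)
        b, _ = sd.simulate_expression(transcriptome, sim_config)
        assert a.equals(b)

    def test_null_genes_have_small_fold_changes(self, genome):
        cfg = SimulationConfig(seed=9, n_genes=200, n_chroms=4, chrom_len=100_000,
                               fraction_de=0.0, n_replicates=4)
        tx = sd.generate_transcriptome(sd.generate_genome(cfg), cfg)
        counts, gtruth = sd.simulate_expression(tx, cfg)
        ctrl = counts[[c for c in counts if c.startswith(CONDITION_A)]].mean(axis=1)
        treat = counts[[c for c in counts if c.startswith(CONDITION_B)]].mean(axis=1)
        lfc = np.log2((treat + 0.5) / (ctrl + 0.5))
        assert (gtruth.true_log2fc == 0).all()
        assert np.median(np.abs(lfc)) < 0.2

    def test_de_genes_exceed_fold_change_floor(self, transcriptome, sim_config):
        _, gtruth = sd.simulate_expression(transcriptome, sim_config)
        de = gtruth[gtruth.is_de]
        assert (de.true_log2fc.abs() >= np.log2(1.5)).all()

    def test_zero_replicates_rejected(self, transcriptome):
        with pytest.raises(ValueError, match="n_replicates"):
            SimulationConfig(seed=1, n_replicates=0)

    def test_nonpositive_dispersion_rejected(self, transcriptome, sim_config):
        cfg = replace(sim_config, expression_dispersion=0.0)
        with pytest.raises(ValueError, match="dispersion"):
            sd.simulate_expression(transcriptome, cfg)


class TestRbpTracks:
    def test_full_enrichment_overlaps_truth(self, transcriptome, truth, genome):
        cfg = SimulationConfig(seed=13, rbp_enrichment=1.0)
        tracks = sd.generate_rbp_tracks(transcriptome, truth, cfg, genome)
        positions = {
            (r.chrom, r.pos) for r in truth.sites.itertuples()
        }
        for ivs in tracks.values():
            for iv in ivs:
                assert any(
                    c == iv.chrom and iv.start <= p < iv.end for c, p in positions
                )

    def test_deterministic(self, transcriptome, truth, sim_config, genome):
        a = sd.generate_rbp_tracks(transcriptome, truth, sim_config, genome)
        b = sd.generate_rbp_tracks(transcriptome, truth, sim_config, genome)
        assert a == b

    def test_bad_width_rejected(self, transcriptome, truth, sim_config, genome):
        cfg = replace(sim_config, rbp_site_width=0)
        with pytest.raises(ValueError, match="width"):
            sd.generate_rbp_tracks(transcriptome, truth, cfg, genome)
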