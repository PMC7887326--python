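"""Region annotation, metagene projection, context classes and count conservation."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m5ckit import distribution_profiling as dp
from m5ckit.datatypes import GenomeSequence, TranscriptModel, reverse_complement


@pytest.fixture
def plus_tx():
    # spliced length 100: 5'UTR 20, CDS 60, 3'UTR 20, two exons with an intron
    return TranscriptModel(
        "t1", "g1", "chr1", "+", ((0, 50), (100, 150)), cds_start=20, cds_end=130
    )


@pytest.fixture
def minus_tx():
    # same geometry on the minus strand: 5'UTR is the high-coordinate side
    return TranscriptModel(
        "t2", "g2", "chr1", "-", ((0, 50), (100, 150)), cds_start=20, cds_end=130
    )


class TestAnnotateRegion:
    def test_first_cds_base_is_start_codon(self, plus_tx):
        assert dp.annotate_region(20, "+", plus_tx) == "start_codon"
        assert dp.annotate_region(22, "+", plus_tx) == "start_codon"

    def test_last_cds_base_is_stop_codon(self, plus_tx):
        # spliced offset 79 = genomic 129 (through the intron)
        assert dp.annotate_region(129, "+", plus_tx) == "stop_codon"
        assert dp.annotate_region(127, "+", plus_tx) == "stop_codon"

    def test_utrs_and_cds_interior(self, plus_tx):
        assert dp.annotate_region(0, "+", plus_tx) == "five_prime_utr"
        assert dp.annotate_region(40, "+", plus_tx) == "cds"
        assert dp.annotate_region(140, "+", plus_tx) == "three_prime_utr"

    def test_intronic_and_wrong_strand_are_intergenic(self, plus_tx):
        assert dp.annotate_region(70, "+", plus_tx) == "intergenic"
        assert dp.annotate_region(40, "-", plus_tx) == "intergenic"

    def test_minus_strand_reverses_region_order(self, minus_tx):
        # genomic 129 is spliced offset 20 = first CDS base on the minus strand
        assert dp.annotate_region(129, "-", minus_tx) == "start_codon"
        assert dp.annotate_region(20, "-", minus_tx) == "stop_codon"
        assert dp.annotate_region(140, "-", minus_tx) == "five_prime_utr"
        assert dp.annotate_region(0, "-", minus_tx) == "three_prime_utr"

    def test_noncoding_label(self):
        nc = TranscriptModel("t3", "g3", "chr1", "+", ((0, 100),))
        assert dp.annotate_region(10, "+", nc) == "noncoding"

    def test_region_counts_conserve_total(self, called, transcriptome):
        for sites in called.values():
            rc = dp.region_counts(sites, transcriptome)
            assert rc["count"].sum() == len(sites)


class TestMetagene:
    def test_region_midpoints(self, plus_tx):
        # midpoints: 5'UTR offset 10 (pos 10), CDS offset 50 (genomic 100),
        # 3'UTR offset 90 (genomic 140)
        assert dp.metagene_coordinate(10, plus_tx) == pytest.approx(0.5)
        assert dp.metagene_coordinate(100, plus_tx) == pytest.approx(1.5)
        assert dp.metagene_coordinate(140, plus_tx) == pytest.approx(2.5)

    def test_first_utr3_base_maps_to_region_start(self, plus_tx):
        assert dp.metagene_coordinate(130, plus_tx) == pytest.approx(2.0)

    def test_median_rescaled_respects_widths(self, plus_tx):
        medians = (100.0, 400.0, 100.0)  # widths 0.5 / 2.0 / 0.5 after scaling to 3
        x = dp.metagene_coordinate(
            100, plus_tx, "median_rescaled", region_medians=medians
        )
        assert x == pytest.approx(0.5 + 0.5 * 2.0)

    def test_projection_inverts(self, plus_tx):
        for off in range(plus_tx.spliced_length):
            pos = plus_tx.spliced_to_genomic(off)
            assert plus_tx.genomic_to_spliced(pos) == off
            x = dp.metagene_coordinate(pos, plus_tx)
            assert 0.0 <= x < 3.0

    def test_unknown_scaling_rejected(self, plus_tx):
        with pytest.raises(ValueError, match="scaling"):
            dp.metagene_coordinate(10, plus_tx, "banana")


class TestWindows:
    def _genome(self, seq):
        return {"chr1": GenomeSequence("chr1", seq)}

    def test_whole_chromosome_window(self):
        seq = "AAAAAAAAAACAAAAAAAAAA"  # C at position 10 of a 21-nt chrom
        assert dp.extract_window(self._genome(seq), "chr1", 10, "+") == seq

    def test_minus_strand_is_reverse_complement(self):
        seq = "ACGTACGTACGACGTACGTAC"  # G at 10 -> C on the minus strand
        w = dp.extract_window(self._genome(seq), "chr1", 10, "-")
        assert w == reverse_complement(seq)
        assert w[10] == "C"

    def test_edge_padding_with_n(self):
        seq = "AAACGGGGGGGGGGGGG"
        w = dp.extract_window(self._genome(seq), "chr1", 3, "+")
        assert w.startswith("N" * 7)
        assert w[10] == "C"

    def test_non_c_centre_flags_coordinate_bug(self):
        with pytest.raises(ValueError, match="not C"):
            dp.extract_window(self._genome("A" * 21), "chr1", 10, "+")


class TestContext:
    @pytest.mark.parametrize(
        "nxt,nxt2,expected",
        [("G", "A", "CG"), ("A", "G", "CHG"), ("A", "A", "CHH"),
         ("C", "G", "CHG"), ("T", "T", "CHH"), ("G", "G", "CG")],
    )
    def test_examples(self, nxt, nxt2, expected):
        w = "A" * 10 + "C" + nxt + nxt2 + "A" * 8
        assert dp.classify_context(w) == expected

    def test_n_disqualifies(self):
        assert dp.classify_context("A" * 10 + "CNA" + "A" * 8) is None
        assert dp.classify_context("A" * 10 + "CAN" + "A" * 8) is None

    def test_agrees_with_pattern_oracle_on_all_neighbor_pairs(self):
        for nxt in "ACGT":
            for nxt2 in "ACGT":
                w = "T" * 10 + "C" + nxt + nxt2 + "T" * 8
                if nxt == "G":
                    expected = "CG"
                elif nxt2 == "G":
                    expected = "CHG"
                else:
                    expected = "CHH"
                assert dp.classify_context(w) == expected


class TestPfm:
    def test_identical_windows_are_binary(self):
        w = "A" * 10 + "C" + "G" * 10
        pfm = dp.position_frequency_matrix([w, w, w])
        assert set(np.unique(pfm.to_numpy())) == {0.0, 1.0}
        assert pfm.loc["C", 10] == 1.0

    def test_t_reported_as_u(self):
        pfm = dp.position_frequency_matrix(["TCA"])
        assert pfm.loc["U", 0] == 1.0

    def test_split_column(self):
        a = "A" * 10 + "C" + "A" + "G" * 9
        b = "A" * 10 + "C" + "G" + "G" * 9
        pfm = dp.position_frequency_matrix([a, b])
        assert pfm.loc["A", 11] == 0.5
        assert pfm.loc["G", 11] == 0.5

    def test_columns_sum_to_one(self, called, genome):
        sites = called["control"]
        windows = [
            dp.extract_window(genome, r.chrom, r.pos, r.strand)
            for r in sites.itertuples()
        ]
        pfm = dp.position_frequency_matrix(windows)
        assert np.allclose(pfm.sum(axis=0), 1.0, atol=1e-12)
        assert pfm.loc["C", 10] == 1.0

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            dp.position_frequency_matrix(["ACG", "ACGT"])


class TestSitesPerGene:
    def _sites(self, genes):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": range(len(genes)), "strand": "+",
             "gene": genes, "level": 0.5, "coverage": 30, "pvalue": 1e-6}
        )

    def test_open_bin_and_proportions(self):
        genes = ["g1", "g2"] + ["g3"] * 9
        hist = dp.sites_per_gene_distribution(self._sites(genes))
        h = dict(zip(hist["bin"], hist["proportion"]))
        assert h["1"] == pytest.approx(2 / 3)
        assert h[">8"] == pytest.approx(1 / 3)

    def test_empty(self):
        hist = dp.sites_per_gene_distribution(self._sites([]))
        assert hist["count"].sum() == 0

    def test_all_single_site(self):
        hist = dp.sites_per_gene_distribution(self._sites(["g1", "g2", "g3"]))
        assert dict(zip(hist["bin"], hist["proportion"]))["1"] == 1.0

    def test_proportions_sum_to_one(self):
        genes = ["g1"] * 4 + ["g2"] * 2 + ["g3"]
        hist = dp.sites_per_gene_distribution(self._sites(genes))
        assert hist["proportion"].sum() == pytest.approx(1.0)


class TestTwoProportion:
    def test_identical_proportions(self):
        assert dp.two_proportion_test(50, 100, 50, 100) == pytest.approx(1.0)

    def test_fisher_fallback_on_sparse_cells(self):
        from m5ckit.differential_methylation import fisher_exact_two_sided

        assert dp.two_proportion_test(9, 10, 1, 10) == pytest.approx(
            fisher_exact_two_sided(9, 1, 1, 9), rel=1e-12
        )

    def test_matches_long_hand_z_statistic(self):
        k1, n1, k2, n2 = 300, 1000, 200, 1000
        p1, p2 = k1 / n1, k2 / n2
        pp = (k1 + k2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        expected = float(stats.chi2.sf(z**2, df=1))
        assert dp.two_proportion_test(k1, n1, k2, n2) == pytest.approx(
            expected, rel=1e-10
        )

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError):
            dp.two_proportion_test(0, 0, 1, 10)


class TestChromosomeDensity:
    def _sites(self, chroms, positions):
        return pd.DataFrame(
            {"chrom": chroms, "pos": positions, "strand": "+", "gene": "",
             "level": 0.5, "coverage": 30, "pvalue": 1e-6}
        )

    def test_single_bin_concentration(self):
        sites = self._sites(["chr1"] * 10, range(10))
        bins, totals = dp.chromosome_density(sites, {"chr1": 1000}, 100)
        assert bins["chr1"][0] == 10
        assert bins["chr1"][1:].sum() == 0
        assert totals["chr1"] == 10

    def test_conservation_over_chromosomes(self, called, genome):
        lengths = {c: len(g) for c, g in genome.items()}
        for sites in called.values():
            bins, totals = dp.chromosome_density(sites, lengths, 5000)
            assert sum(b.sum() for b in bins.values()) == len(sites)
            for chrom, b in bins.items():
                assert b.sum() == totals[chrom]
                assert len(b) == -(-lengths[chrom] // 5000)

    def test_empty_chromosome_has_zero_vector(self):
        bins, _ = dp.chromosome_density(self._sites([], []), {"chrX": 250}, 100)
        assert bins["chrX"].tolist() == [0, 0, 0]

    def test_site_beyond_length_rejected(self):
        sites = self._sites(["chr1"], [2000])
        with pytest.raises(ValueError, match="beyond"):
            dp.chromosome_density(sites, {"chr1": 1000}, 100)
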