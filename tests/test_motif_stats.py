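"""Gly-Gly pair statistics, rich k-mer counting, Fisher tests, NtcA scanning."""

import math
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ncostmin import genome_model as gm
from ncostmin import motif_stats as ms
from ncostmin import synthetic_data as sim
from ncostmin.errors import ConfigurationError
from ncostmin.genome_model import GeneFeature, GenomeRecord, GenomicInterval
from ncostmin.motif_stats import GLY_CODONS, GLY_PAIRS

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestGlyGlyPairs:
    def test_adjacent_pair_counted(self):
        obs = ms.gly_gly_pairs([["ATG", "GGA", "GGT", "TAA"]])
        assert obs[("GGA", "GGT")] == 1 and sum(obs.values()) == 1

    def test_separated_glycines_not_counted(self):
        obs = ms.gly_gly_pairs([["ATG", "GGA", "AAA", "GGT", "TAA"]])
        assert sum(obs.values()) == 0

    def test_pairs_never_span_genes(self):
        obs = ms.gly_gly_pairs([["ATG", "GGA"], ["GGT", "TAA"]])
        assert sum(obs.values()) == 0

    @given(st.lists(st.lists(st.sampled_from(list(GLY_CODONS) + ["AAA", "TTT"]),
                             max_size=30), max_size=5))
    def test_matches_sliding_oracle(self, codon_lists):
        oracle = Counter()
        for codons in codon_lists:
            for i in range(len(codons) - 1):
                if codons[i] in GLY_CODONS and codons[i + 1] in GLY_CODONS:
                    oracle[(codons[i], codons[i + 1])] += 1
        obs = ms.gly_gly_pairs(codon_lists)
        assert {p: c for p, c in obs.items() if c} == dict(oracle)

    def test_invariant_to_gene_order_and_strand(self):
        genome, genes, _ = sim.simulate_genome(
            n_genes=10, codon_weights=sim.default_codon_weights(0.5), seed=8)
        stats1 = ms.codon_pair_stats(genome, genes)
        flipped_genome = GenomeRecord("g", gm.reverse_complement(genome.sequence))
        L = genome.length
        flipped_genes = [
            GeneFeature(g.gene_id, L - g.end, L - g.start,
                        "-" if g.strand == "+" else "+")
            for g in reversed(genes)
        ]
        stats2 = ms.codon_pair_stats(flipped_genome, flipped_genes)
        assert stats1.observed == stats2.observed
        assert stats1.expected == pytest.approx(stats2.expected)


class TestExpectedPairs:
    def test_uniform_arithmetic(self):
        counts = Counter({"GGA": 50, "GGT": 50})  # P = 0.05 each
        expected = ms.expected_pair_counts(counts, 1000, 400)
        assert expected[("GGA", "GGT")] == pytest.approx(0.05 * 0.05 * 400)

    def test_absent_codon_zero_expectation(self):
        counts = Counter({"GGA": 50})
        expected = ms.expected_pair_counts(counts, 1000, 400)
        assert expected[("GGC", "GGA")] == 0.0

    def test_zero_codons_rejected(self):
        with pytest.raises(ValueError):
            ms.expected_pair_counts(Counter(), 0, 0)


class TestAffinityBinning:
    def test_default_table_orders_pairs(self):
        table = ms.default_affinity_table()
        assert set(table.scores) == {a + b for a, b in GLY_PAIRS}
        low = {h for h in table.scores if table.bin_of(h) == 0}
        high = {h for h in table.scores if table.bin_of(h) == table.n_bins - 1}
        assert all(h.startswith(("GGT", "GGC")) for h in low)
        assert all(h.startswith("GGA") or h == "GGGGGG" for h in high)

    def test_single_bin_equals_global_ratio(self):
        stats = ms.CodonPairStats(
            observed={p: 2 for p in GLY_PAIRS},
            expected={p: 1.0 for p in GLY_PAIRS})
        table = ms.AffinityTable(scores={a + b: 1.0 for a, b in GLY_PAIRS},
                                 bin_edges=())
        bins = ms.bin_by_affinity(stats, table)
        assert len(bins) == 1 and bins[0]["o_e"] == pytest.approx(2.0)

    def test_zero_expectation_bin_excluded(self, caplog):
        stats = ms.CodonPairStats(
            observed={p: 0 for p in GLY_PAIRS},
            expected={(a, b): (1.0 if a == "GGA" else 0.0)
                      for a, b in GLY_PAIRS})
        bins = ms.bin_by_affinity(stats, ms.default_affinity_table())
        assert bins and all(b["expected"] > 0 for b in bins)
        assert any("zero expectation" in r.message for r in caplog.records)

    def test_unmapped_pair_rejected(self):
        stats = ms.CodonPairStats(observed={p: 0 for p in GLY_PAIRS},
                                  expected={p: 1.0 for p in GLY_PAIRS})
        table = ms.AffinityTable(scores={"GGAGGA": 1.0}, bin_edges=())
        with pytest.raises(ConfigurationError):
            ms.bin_by_affinity(stats, table)

    def test_planted_depletion_lands_in_top_bin(self):
        """Destroying half the top-affinity adjacencies halves that bin's O/E."""
        table = ms.default_affinity_table()
        top = {h for h in table.scores if table.bin_of(h) == table.n_bins - 1}
        genome, genes, _ = sim.simulate_genome(
            n_genes=400, mean_gene_len=400,
            codon_weights=sim.default_codon_weights(0.5),
            glygly_keep={h: 0.5 for h in top}, seed=5)
        bins = ms.bin_by_affinity(ms.codon_pair_stats(genome, genes), table)
        by_bin = {b["bin"]: b["o_e"] for b in bins}
        top_idx = table.n_bins - 1
        # swaps recreate a small fraction of destroyed pairs, so the planted
        # keep probability of 0.5 appears as a ratio somewhat above 0.5
        assert 0.35 <= by_bin[top_idx] <= 0.8
        assert all(by_bin[i] > by_bin[top_idx] + 0.2
                   for i in by_bin if i != top_idx)


class TestRichMotifs:
    def test_all_pyrimidine_window(self):
        genome = GenomeRecord("g", "CCCCCCCCCC")
        assert ms.rich_motif_count([GenomicInterval(0, 10)], genome, 10) == 1

    def test_boundary_eighty_percent_passes(self):
        genome = GenomeRecord("g", "CCCCCCCCAA")
        assert ms.rich_motif_count([GenomicInterval(0, 10)], genome, 10) == 1

    def test_below_threshold_fails(self):
        genome = GenomeRecord("g", "CCCCCCCAAA")
        assert ms.rich_motif_count([GenomicInterval(0, 10)], genome, 10) == 0

    def test_short_region_contributes_nothing(self):
        genome = GenomeRecord("g", "CCCCC")
        assert ms.rich_motif_count([GenomicInterval(0, 5)], genome, 10) == 0

    @given(dna, st.sampled_from([4, 6]))
    def test_matches_window_oracle(self, seq, k):
        if len(seq) == 0:
            return
        genome = GenomeRecord("g", seq)
        need = math.ceil(0.8 * k - 1e-9)
        oracle = sum(
            1 for i in range(len(seq) - k + 1)
            if sum(b in "CT" for b in seq[i:i + k]) >= need)
        assert ms.rich_motif_count([GenomicInterval(0, len(seq))], genome, k) == oracle

    def test_collapse_counts_runs(self):
        genome = GenomeRecord("g", "CCCCCCCCCCCC")  # 12 C: three 10-mers overlap
        regions = [GenomicInterval(0, 12)]
        assert ms.rich_motif_count(regions, genome, 10) == 3
        assert ms.rich_motif_count(regions, genome, 10, collapse=True) == 1

    def test_complement_exchanges_classes(self):
        genome, genes, _ = sim.simulate_genome(n_genes=5, seed=4)
        comp = GenomeRecord("g", gm.complement(genome.sequence))
        regions = [GenomicInterval(0, genome.length)]
        for k in (10, 12):
            assert ms.rich_motif_count(regions, genome, k, 0.8, "pyrimidine") == \
                ms.rich_motif_count(regions, comp, k, 0.8, "purine")


class TestExpectedMotifs:
    def test_certain_class_gives_all_windows(self):
        genome = GenomeRecord("g", "C" * 30)
        exp = ms.expected_motif_count([GenomicInterval(0, 30)], genome, 10)
        assert exp == pytest.approx(21.0)

    def test_half_composition_tail(self):
        # P(X >= 8), X ~ Binomial(10, 0.5): direct summation oracle
        oracle = sum(math.comb(10, i) for i in range(8, 11)) / 2**10
        assert oracle == 0.0546875
        genome = GenomeRecord("g", "CT" * 20 + "AG" * 20)
        regions = [GenomicInterval(0, 80)]
        exp = ms.expected_motif_count(regions, genome, 10)
        assert exp == pytest.approx(71 * oracle)

    def test_empty_regions_rejected(self):
        genome = GenomeRecord("g", "ACGT")
        with pytest.raises(ValueError):
            ms.expected_motif_count([], genome, 10)


class TestFisher:
    def test_no_association(self):
        assert ms.fisher_normalized(10, 10, 10, 10) == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        a = ms.fisher_normalized(912, 676, 100, 100)
        b = ms.fisher_normalized(100, 100, 912, 676)
        assert a == pytest.approx(b)

    def test_degenerate_margin_flagged(self, caplog):
        assert ms.fisher_normalized(0, 0, 5, 7) == 1.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_matches_hypergeometric_enumeration(self):
        """Exact enumeration over all tables with the observed margins."""
        table = [[91, 68], [10, 10]]
        row0, row1 = sum(table[0]), sum(table[1])
        col0 = table[0][0] + table[1][0]
        n = row0 + row1

        def prob(a):  # P(first cell = a) under the hypergeometric null
            return (math.comb(row0, a) * math.comb(row1, col0 - a)
                    / math.comb(n, col0))

        p_obs = prob(table[0][0])
        lo = max(0, col0 - row1)
        hi = min(col0, row0)
        oracle = sum(prob(a) for a in range(lo, hi + 1)
                     if prob(a) <= p_obs * (1 + 1e-9))
        assert ms.fisher_normalized(91, 68.2, 10, 10.4) == pytest.approx(
            oracle, rel=1e-9)


class TestNtcaScan:
    def test_simple_hit(self):
        up = "T" * 36 + "GTACGATCGAGTAC" + "T" * 30
        genome = GenomeRecord("g", up + "ATGAAATAA")
        gene = GeneFeature("x", len(up), len(up) + 9, "+")
        hits, n_genes = ms.ntca_scan([gene], genome)
        assert n_genes == 1 and hits[0].distance_to_start == 44
        assert hits[0].matched_sequence == "GTACGATCGAGTAC"

    def test_exactly_100bp_upstream_excluded(self):
        motif = "GTACGATCGAGTAC"
        up = motif + "T" * 86  # motif starts exactly 100 bp upstream
        genome = GenomeRecord("g", up + "ATGAAATAA")
        gene = GeneFeature("x", len(up), len(up) + 9, "+")
        hits, n_genes = ms.ntca_scan([gene], genome)
        assert hits == [] and n_genes == 0

    def test_malformed_pattern_rejected(self):
        genome = GenomeRecord("g", "ACGT" * 30)
        with pytest.raises(ConfigurationError):
            ms.ntca_scan([], genome, motif_pattern="GTAZZZTAC")

    def test_planted_sites_recovered_exactly(self):
        genome, genes, truth = sim.simulate_genome(n_genes=30, ntca_sites=8,
                                                   seed=13)
        hits, n_genes = ms.ntca_scan(genes, genome)
        planted_genes = {s["gene_id"] for s in truth.ntca_sites}
        assert {h.gene_id for h in hits} == planted_genes
        assert n_genes == len(planted_genes) == 8
        planted = {(s["gene_id"], s["distance"]) for s in truth.ntca_sites}
        assert {(h.gene_id, h.distance_to_start) for h in hits} >= planted

    def test_minus_strand_distance(self):
        motif = "GTACGATCGAGTAC"
        gene_seq = "ATGAAATAA"
        downstream = "T" * 20 + gm.reverse_complement(motif) + "T" * 40
        genome = GenomeRecord("g", gm.reverse_complement(gene_seq) + downstream)
        gene = GeneFeature("x", 0, 9, "-")
        hits, n_genes = ms.ntca_scan([gene], genome)
        assert n_genes == 1
        # motif's reading-orientation 5' base sits at genomic 42; the gene's
        # 5' end is at genomic 8, so the strand-aware distance is 34
        assert hits[0].distance_to_start == 34
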