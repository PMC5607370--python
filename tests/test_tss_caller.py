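"""Skellam test, merging, positional classification, and curation filtering."""

import numpy as np
import pytest
from scipy import stats

from ncostmin import synthetic_data as sim
from ncostmin import tss_caller as tc
from ncostmin.coverage import FivePrimeCoverage
from ncostmin.errors import ConfigurationError, NcostminError
from ncostmin.genome_model import GeneFeature


def make_cov(fwd=None, rev=None, length=100, label="x"):
    fwd = np.zeros(length, dtype=int) if fwd is None else np.asarray(fwd)
    rev = np.zeros(len(fwd), dtype=int) if rev is None else np.asarray(rev)
    return FivePrimeCoverage(fwd=fwd, rev=rev, library_label=label)


def skellam_sf_oracle(d, rate_e, rate_c):
    """Brute-force convolution of two Poisson mass functions.

    P(D >= d) = sum_i P(X_e = i) * P(X_c <= i - d), truncated far into the
    negligible tail of both laws.
    """
    n = int(10 * max(rate_e, rate_c) + 200)
    pe = stats.poisson.pmf(np.arange(n), rate_e)
    cdf_c = stats.poisson.cdf(np.arange(n), rate_c)
    total = 0.0
    for i in range(n):
        j = i - d
        if j >= 0:
            total += pe[i] * cdf_c[min(j, n - 1)]
    return float(total)


class TestBackground:
    def test_uniform(self):
        cov = make_cov(fwd=np.full(50, 2))
        assert tc.estimate_background(cov)["+"] == pytest.approx(2.0)

    def test_all_zero_floored(self, caplog):
        cov = make_cov(length=50)
        assert tc.estimate_background(cov)["+"] == 0.01
        assert any("all-zero" in r.message for r in caplog.records)

    def test_spike_trimmed(self):
        fwd = np.ones(100, dtype=int)
        fwd[42] = 10**6
        cov = make_cov(fwd=fwd)
        assert tc.estimate_background(cov)["+"] == pytest.approx(1.0)


class TestSkellamPvalue:
    def test_symmetric_null_nonpositive_difference(self):
        assert tc.skellam_pvalue(0, 0, 1.0, 1.0) >= 0.5

    def test_large_excess_is_significant(self):
        p = tc.skellam_pvalue(50, 0, 1.0, 1.0)
        assert p < 1e-10
        assert p == pytest.approx(skellam_sf_oracle(50, 1.0, 1.0), abs=1e-9)

    def test_monotone_in_enriched_count(self):
        ps = [tc.skellam_pvalue(e, 3, 2.0, 2.0) for e in range(0, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_rates(self):
        with pytest.raises(ConfigurationError):
            tc.skellam_pvalue(1, 0, 0.0, 1.0)
        with pytest.raises(ConfigurationError):
            tc.skellam_pvalue(1, 0, float("nan"), 1.0)

    @pytest.mark.parametrize("rate_e,rate_c", [(0.5, 0.5), (2, 5), (20, 1)])
    def test_matches_convolution_oracle(self, rate_e, rate_c):
        for e in (0, 1, 5, 40, 120):
            for c in (0, 2, 30):
                assert tc.skellam_pvalue(e, c, rate_e, rate_c) == pytest.approx(
                    skellam_sf_oracle(e - c, rate_e, rate_c), abs=1e-9)


class TestMergeCalls:
    def _call(self, pos, count, strand="+"):
        return tc.TssCall(pos, strand, count, 0.0, 1e-20)

    def test_within_range_merges_to_max(self):
        merged = tc.merge_calls([self._call(100, 10), self._call(103, 50)], 5)
        assert len(merged) == 1 and merged[0].position == 103

    def test_beyond_range_kept_separate(self):
        merged = tc.merge_calls([self._call(100, 10), self._call(106, 50)], 5)
        assert [c.position for c in merged] == [100, 106]

    def test_tie_breaks_to_smaller_position(self):
        merged = tc.merge_calls([self._call(100, 50), self._call(103, 50)], 5)
        assert merged[0].position == 100

    def test_idempotent(self, rng):
        calls = [self._call(int(p), int(c), s)
                 for p, c, s in zip(rng.integers(0, 500, 60),
                                    rng.integers(1, 100, 60),
                                    rng.choice(list("+-"), 60))]
        once = tc.merge_calls(calls, 5)
        assert tc.merge_calls(once, 5) == once

    def test_strands_independent(self):
        merged = tc.merge_calls([self._call(100, 10, "+"), self._call(102, 20, "-")], 5)
        assert len(merged) == 2


class TestCallTss:
    def test_below_noise_threshold_empty(self):
        enriched = make_cov(fwd=np.full(200, 3))
        control = make_cov(length=200)
        assert tc.call_tss(enriched, control) == []

    def test_curation_removes_small_differences(self):
        """enriched=150 vs control=100 is significant but diff 50 < 100."""
        fwd_e = np.ones(2000, dtype=int)
        fwd_e[500] = 150
        fwd_c = np.ones(2000, dtype=int)
        fwd_c[500] = 100
        params = tc.TssCallerParams(depth_norm="none")
        calls = tc.call_tss(make_cov(fwd=fwd_e), make_cov(fwd=fwd_c), params)
        assert calls == []
        relaxed = tc.TssCallerParams(depth_norm="none", curation_min_diff=10)
        assert len(tc.call_tss(make_cov(fwd=fwd_e), make_cov(fwd=fwd_c), relaxed)) == 1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(NcostminError):
            tc.call_tss(make_cov(length=10), make_cov(length=20))

    def test_retained_calls_satisfy_all_filters(self):
        genome, genes, truth, cov = sim.fixture_tss_recovery(seed=3, n_genes=10)
        params = tc.TssCallerParams()
        calls = tc.call_tss(cov["deplete_12h_enriched"], cov["deplete_12h_control"],
                            params)
        assert calls
        for c in calls:
            assert c.enriched_count >= params.noise_threshold
            assert c.p_value < params.p_threshold
            assert c.diff >= params.curation_min_diff

    def test_null_false_positive_rate_controlled(self, rng):
        """Under pure Poisson noise the per-position call rate at a relaxed
        threshold stays within 2x of the nominal level."""
        L = 50_000
        lam = 2.0
        enriched = make_cov(fwd=rng.poisson(lam, L), rev=rng.poisson(lam, L))
        control = make_cov(fwd=rng.poisson(lam, L), rev=rng.poisson(lam, L))
        alpha = 1e-3
        params = tc.TssCallerParams(p_threshold=alpha, noise_threshold=1,
                                    curation_min_diff=0)
        calls = []
        for strand in "+-":
            e = enriched.counts(strand).astype(float)
            c = control.counts(strand).astype(float)
            bg_e = tc.estimate_background(enriched)[strand]
            bg_c = tc.estimate_background(control)[strand]
            for pos in range(L):
                if e[pos] >= params.noise_threshold:
                    p = tc.skellam_pvalue(e[pos], c[pos], bg_e, bg_c)
                    if p < alpha:
                        calls.append(pos)
        assert len(calls) / (2 * L) <= 2 * alpha


class TestClassify:
    GENES = [GeneFeature("gA", 500, 900, "+")]

    @pytest.mark.parametrize("pos,strand,expected", [
        (480, "+", {"primary"}),
        (600, "+", {"internal"}),
        (600, "-", {"antisense"}),
        (920, "+", {"downstream"}),
        (50, "+", {"orphan"}),
        (250, "+", {"primary"}),   # exactly 250 upstream: inclusive
        (249, "+", {"orphan"}),    # 251 upstream: outside window
        (929, "+", {"downstream"}),  # 29 nt downstream: < 30
        (930, "+", {"orphan"}),      # 30 nt downstream: strict
    ])
    def test_examples(self, pos, strand, expected):
        call = tc.TssCall(pos, strand, 200, 0.0, 1e-20)
        tc.classify_tss(call, self.GENES)
        assert call.categories == expected

    def test_combination_categories(self):
        genes = [GeneFeature("gA", 500, 900, "+"), GeneFeature("gB", 550, 800, "-")]
        call = tc.TssCall(600, "+", 200, 0.0, 1e-20)
        tc.classify_tss(call, genes)
        assert call.categories == {"internal", "antisense"}
        assert call.gene_ids["internal"] == ("gA",)
        assert call.gene_ids["antisense"] == ("gB",)

    def test_minus_strand_geometry(self):
        genes = [GeneFeature("gA", 500, 900, "-")]
        for pos, strand, expected in [(950, "-", {"primary"}),
                                      (600, "-", {"internal"}),
                                      (600, "+", {"antisense"}),
                                      (480, "-", {"downstream"})]:
            call = tc.TssCall(pos, strand, 200, 0.0, 1e-20)
            tc.classify_tss(call, genes)
            assert call.categories == expected, (pos, strand)

    def test_orphan_iff_no_other_category(self):
        call = tc.TssCall(5, "+", 200, 0.0, 1e-20)
        tc.classify_tss(call, self.GENES)
        assert call.categories == {"orphan"} and call.gene_ids["orphan"] == ()


class TestCensus:
    def _classified(self, cats):
        call = tc.TssCall(0, "+", 10, 0.0, 1e-20)
        call.categories = set(cats)
        return call

    def test_single_and_combination(self):
        calls = [self._classified({"internal"}),
                 self._classified({"internal", "antisense"}),
                 self._classified({"internal", "primary"})]
        census = tc.category_census(calls)
        assert census == {"Internal": 1, "Internal antisense": 1,
                          "Internal primary": 1}
        assert sum(census.values()) == len(calls)  # partition, no double count

    def test_fixture_census_matches_truth(self):
        genome, genes, truth, cov = sim.fixture_tss_recovery(seed=6, n_genes=20)
        calls = tc.classify_all(
            tc.call_tss(cov["deplete_12h_enriched"], cov["deplete_12h_control"]),
            genes)
        census = tc.category_census(calls)
        assert census == {"Internal": 20, "Primary": 20}


class TestLeaderless:
    def test_boundary_distances(self):
        genes = [GeneFeature("gA", 500, 900, "+")]
        at_start = tc.classify_tss(tc.TssCall(500, "+", 200, 0.0, 1e-20), genes)
        eleven_up = tc.classify_tss(tc.TssCall(489, "+", 200, 0.0, 1e-20), genes)
        assert "primary" in at_start.categories and "primary" in eleven_up.categories
        assert tc.leaderless_fraction([at_start], genes) == 1.0
        assert tc.leaderless_fraction([eleven_up], genes) == 0.0

    def test_no_primary_calls_reports_missing(self):
        genes = [GeneFeature("gA", 500, 900, "+")]
        call = tc.classify_tss(tc.TssCall(600, "+", 200, 0.0, 1e-20), genes)
        assert tc.leaderless_fraction([call], genes) is None

    def test_planted_fraction_recovered(self):
        genome, genes, truth, cov = sim.fixture_leaderless(seed=0)
        calls = tc.classify_all(
            tc.call_tss(cov["deplete_12h_enriched"], cov["deplete_12h_control"]),
            genes)
        assert tc.leaderless_fraction(calls, genes) == pytest.approx(0.10)
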