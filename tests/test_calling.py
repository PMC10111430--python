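"""Wilson intervals, the conversion null, adjustment and the calling rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stst

from hairpincall.calling import (
    ConversionEstimate,
    adjust_pvalues,
    binomial_nonconversion_pvalue,
    call_methylation,
    estimate_conversion_rate,
    genome_average_methylation,
    methylation_level_histogram,
    methylation_ratio,
    wilson_interval,
)
from hairpincall.sites_io import CytosineRecord

from oracles import bh_stepup, binom_tail_by_summation, wilson_by_quadratic


class TestMethylationRatio:
    @pytest.mark.parametrize(
        "meth, unmeth, expected",
        [(4, 9, 0.308), (19, 43, 0.306), (14, 18, 0.438), (12, 13, 0.480), (0, 50, 0.0)],
    )
    def test_values(self, meth, unmeth, expected):
        assert round(methylation_ratio(meth, unmeth), 3) == expected

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            methylation_ratio(0, 0)


class TestWilsonInterval:
    @pytest.mark.parametrize(
        "meth, total, lower",
        [(4, 13, 0.127), (19, 62, 0.206), (14, 32, 0.282), (12, 25, 0.300), (3, 21, 0.050)],
    )
    def test_printed_lower_bounds(self, meth, total, lower):
        assert round(wilson_interval(meth, total)[0], 3) == lower

    def test_zero_successes(self):
        assert wilson_interval(0, 25)[0] == 0.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            wilson_interval(5, 4)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            lo, up = wilson_interval(k, n)
            olo, oup = wilson_by_quadratic(k, n)
            assert lo == pytest.approx(olo, abs=1e-9)
            assert up == pytest.approx(oup, abs=1e-9)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(4, 13), (19, 62), (0, 10), (10, 10), (250, 900)]:
            lo, up = wilson_interval(k, n)
            slo, sup = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert (lo, up) == pytest.approx((slo, sup), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(stst.integers(min_value=1, max_value=300), stst.data())
    def test_lower_bound_monotone_in_successes(self, n, data):
        k = data.draw(stst.integers(min_value=0, max_value=n - 1))
        assert wilson_interval(k, n)[0] <= wilson_interval(k + 1, n)[0] + 1e-12

    def test_bounds_bracket_ratio(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            lo, up = wilson_interval(k, n)
            assert lo <= k / n <= up


class TestConversionRate:
    def test_pooled_rate(self):
        records = [
            CytosineRecord("L", 1, "+", "CG", 30, 5000),
            CytosineRecord("L", 2, "+", "CHH", 17, 4953),
        ]
        est = estimate_conversion_rate(records)
        assert est.ct_count == 10000 and est.t_count == 9953
        assert est.rate == pytest.approx(99.53)
        assert est.failure_prob == pytest.approx(1 - 0.9953)

    def test_all_converted(self):
        est = estimate_conversion_rate([CytosineRecord("L", 1, "+", "CG", 0, 100)])
        assert est.rate == 100.0 and est.failure_prob == 0.0

    def test_none_converted(self):
        est = estimate_conversion_rate([CytosineRecord("L", 1, "+", "CG", 50, 0)])
        assert est.rate == 0.0

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            estimate_conversion_rate([CytosineRecord("L", 1, "+", "CG", 0, 0)])


class TestBinomialPvalue:
    def test_zero_meth_is_one(self):
        assert binomial_nonconversion_pvalue(0, 30, 0.005) == 1.0

    def test_all_meth_closed_form(self):
        assert binomial_nonconversion_pvalue(7, 7, 0.1) == pytest.approx(0.1**7)

    def test_example_4_of_13(self):
        expected = binom_tail_by_summation(4, 13, 0.005)
        assert binomial_nonconversion_pvalue(4, 13, 0.005) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0, 0.2))
            assert binomial_nonconversion_pvalue(k, n, p) == pytest.approx(
                binom_tail_by_summation(k, n, p), abs=1e-12
            )

    def test_monotone_in_meth_reads(self):
        prev = 2.0
        for k in range(0, 31):
            cur = binomial_nonconversion_pvalue(k, 30, 0.01)
            assert cur <= prev + 1e-15
            prev = cur


class TestAdjustPvalues:
    def test_single_p_unchanged_under_bh(self):
        assert adjust_pvalues([0.033])[0] == pytest.approx(0.033)

    def test_bh_stepup_example(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="BH")
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bonferroni(self):
        assert adjust_pvalues([0.02], method="bonferroni")[0] == pytest.approx(0.02)
        assert adjust_pvalues([0.02, 0.5, 0.9], method="bonferroni") == pytest.approx(
            [0.06, 1.0, 1.0]
        )

    def test_bh_matches_definition_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            assert adjust_pvalues(p, method="BH") == pytest.approx(bh_stepup(p))

    def test_empty(self):
        assert len(adjust_pvalues([])) == 0


class TestCallMethylation:
    conv = ConversionEstimate(t_count=9950, ct_count=10000)  # eps = 0.005

    def test_low_coverage_never_significant(self):
        records = [CytosineRecord("c", 1, "+", "CHH", 3, 0)]
        (call,) = call_methylation(records, self.conv)
        assert not call.significant

    def test_strong_site_significant(self):
        records = [CytosineRecord("c", 1, "+", "CHH", 4, 9)]
        (call,) = call_methylation(records, self.conv)
        assert call.significant
        assert call.ci_lower == pytest.approx(0.127, abs=5e-4)

    def test_low_ci_lower_blocks_call(self):
        # 1/100: binomial p may be small-ish but the Wilson floor fails
        records = [CytosineRecord("c", 1, "+", "CHH", 1, 99)]
        (call,) = call_methylation(records, self.conv)
        assert call.ci_lower < 0.05 and not call.significant

    def test_every_record_receives_a_call(self):
        records = [
            CytosineRecord("c", i, "+", "CHH", 0, 0) for i in range(1, 6)
        ]
        calls = call_methylation(records, self.conv)
        assert len(calls) == 5
        assert all(c.ratio == 0.0 and not c.significant for c in calls)

    def test_significance_invariant(self, small_sim):
        conv = estimate_conversion_rate(small_sim.spikein_counts[0])
        calls = call_methylation(small_sim.replicates[0], conv)
        for c in calls:
            assert c.ci_lower - 1e-12 <= c.ratio <= c.ci_upper + 1e-12
            if c.significant:
                assert c.record.coverage >= 4
                assert c.ci_lower >= 0.05
                assert c.q_adj < 0.05
            if c.ratio == 0.0:
                assert c.p_raw == 1.0


class TestGenomeAverage:
    def test_all_unmethylated(self):
        records = [CytosineRecord("c", 1, "+", "CHH", 0, 40)]
        assert genome_average_methylation(records) == 0.0

    def test_pooled_arithmetic(self):
        records = [
            CytosineRecord("c", 1, "+", "CHH", 1, 99),
            CytosineRecord("c", 2, "+", "CHH", 0, 100),
        ]
        assert genome_average_methylation(records) == pytest.approx(0.5)

    def test_simulator_matches_expected_failure_rate(self, small_sim):
        # no true methylation; background nonconversion 0.005 -> ~0.5%
        # pooled; stem-protected sites add a small positive excess
        background = [
            r for r in small_sim.replicates[0]
            if small_sim.truth.status(r.chrom, r.pos) == "outside"
        ]
        avg = genome_average_methylation(background)
        n_reads = sum(r.coverage for r in background)
        se = 100 * np.sqrt(0.005 * 0.995 / n_reads)
        assert abs(avg - 0.5) < 4 * se

    def test_per_chromosome_variant(self, small_sim):
        per = genome_average_methylation(small_sim.replicates[0], by_chromosome=True)
        assert set(per) == set(small_sim.genome.names)


class TestHistogram:
    def _call(self, chrom, pos, meth, unmeth, context="CHH"):
        rec = CytosineRecord(chrom, pos, "+", context, meth, unmeth)
        conv = ConversionEstimate(995000, 1000000)
        return call_methylation([rec], conv)[0]

    def test_coverage_cap_excludes(self):
        from dataclasses import replace

        call = self._call("c", 1, 600, 900)  # coverage 1500
        hist = methylation_level_histogram([replace(call, significant=True)])
        assert all(v.sum() == 0 for v in hist.values())

    def test_low_ratio_sites_in_first_bin(self):
        from dataclasses import replace

        calls = [
            replace(self._call("c", i, 1, 19), significant=True) for i in range(1, 6)
        ]
        hist = methylation_level_histogram(calls)
        assert hist["CHH"][0] == 5 and hist["CHH"][1:].sum() == 0

    def test_stem_sites_modal_bin_near_protection_level(self, small_sim):
        conv = estimate_conversion_rate(small_sim.spikein_counts[0])
        calls = call_methylation(small_sim.replicates[0], conv)
        hist = methylation_level_histogram(calls)
        pooled = sum(hist.values())
        # protection 0.30 -> called stem sites concentrate in the 21-40% bins
        assert pooled.sum() > 0
        assert pooled[2] + pooled[3] > 0.5 * pooled.sum()
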