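"""The binomial enrichment test, its CIs, and the matched/binned variants."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutspectra.compare import (
    MINLIKE,
    binomial_ci,
    binomial_pvalue,
    enrichment_test,
    match_reference_windows,
    matched_comparison,
    pooled_class_enrichment,
    scored_bin_enrichment,
)
from mutspectra.intervals import CompartmentSet, bin_by_score
from mutspectra.spectrum import SpectrumTable


def minlike_oracle(k: int, n: int, p: Fraction) -> float:
    """Exact rational enumeration of the minimum-likelihood two-sided p."""
    a, b = p.numerator, p.denominator
    nums = [comb(n, j) * a**j * (b - a) ** (n - j) for j in range(n + 1)]
    return float(Fraction(sum(v for v in nums if v <= nums[k]), b**n))


def make_table(S, O, name="t"):
    return SpectrumTable(name, np.asarray(S), np.asarray(O))


class TestBinomialPvalue:
    def test_small_case_matches_enumeration(self):
        got = binomial_pvalue(5, 20, 0.1)
        assert got == pytest.approx(minlike_oracle(5, 20, Fraction(1, 10)), rel=1e-12)

    @pytest.mark.parametrize("n", [1, 7, 20, 33])
    @pytest.mark.parametrize("p", [Fraction(1, 20), Fraction(1, 2), Fraction(7, 10)])
    def test_grid_against_rational_oracle(self, n, p):
        for k in range(n + 1):
            got = binomial_pvalue(k, n, float(p))
            assert got == pytest.approx(minlike_oracle(k, n, p), rel=1e-11)

    def test_doubled_tail_convention(self):
        k, n, p = 3, 30, 0.25
        lo = stats.binom.cdf(k, n, p)
        hi = stats.binom.sf(k - 1, n, p)
        assert binomial_pvalue(k, n, p, tail="doubled") == pytest.approx(
            min(1, 2 * min(lo, hi))
        )
        with pytest.raises(ValueError):
            binomial_pvalue(1, 2, 0.5, tail="bogus")


class TestBinomialCI:
    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = binomial_ci(0, 50)
        assert lo == 0.0 and hi < 1.0

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = binomial_ci(50, 50)
        assert hi == 1.0 and lo > 0.0

    def test_matches_beta_quantile_oracle(self):
        k, n, level = 5, 20, 0.95
        lo, hi = binomial_ci(k, n, level)
        a = (1 - level) / 2
        assert lo == pytest.approx(stats.beta.ppf(a, k, n - k + 1), rel=1e-9)
        assert hi == pytest.approx(stats.beta.ppf(1 - a, k + 1, n - k), rel=1e-9)


class TestEnrichmentTest:
    def test_identical_tables_are_null(self, rng):
        S = rng.integers(50, 500, size=96)
        t = make_table(S, np.full(96, 100_000))
        res = enrichment_test(t, t)
        assert res["enrichment"].dropna().round(12).eq(1.0).all()
        assert not res["significant"].any()

    def test_ratio_equals_counts_over_expected(self, rng):
        t = make_table(rng.integers(0, 300, 96), rng.integers(10_000, 50_000, 96))
        r = make_table(rng.integers(50, 300, 96), rng.integers(10_000, 50_000, 96))
        res = enrichment_test(t, r)
        ok = res["testable"]
        np.testing.assert_allclose(
            res.loc[ok, "enrichment"],
            res.loc[ok, "S"] / res.loc[ok, "expected"],
            rtol=1e-12,
        )

    def test_bonferroni_uses_testable_count(self):
        S_ref = np.full(96, 100)
        S_ref[:10] = 0  # ten untestable types
        ref = make_table(S_ref, np.full(96, 10_000), "ref")
        S_t = np.full(96, 100)
        S_t[20] = 200  # p ~ 2e-16; boundary cases decided by m
        test = make_table(S_t, np.full(96, 10_000), "test")
        res = enrichment_test(test, ref)
        assert int(res["testable"].sum()) == 86
        assert not res.loc[res.index[:10], "testable"].any()
        assert res.loc[res.index[20], "significant"]

    def test_swapping_test_and_reference_inverts_ratios(self, small_genome, default_truth):
        from mutspectra.simulate import halves, simulate_variants
        from mutspectra.spectrum import tabulate

        a, b = halves(small_genome.extent)
        obs, _ = simulate_variants(small_genome, [(a, None), (b, None)], default_truth)
        ta, tb = tabulate(obs, a, small_genome), tabulate(obs, b, small_genome)
        fwd = pooled_class_enrichment(tb, ta)["enrichment"]
        rev = pooled_class_enrichment(ta, tb)["enrichment"]
        np.testing.assert_allclose(fwd, 1 / rev, rtol=0.1)

    def test_type_set_mismatch_rejected(self):
        t = make_table(np.zeros(96), np.full(96, 100))
        with pytest.raises(ValueError):
            enrichment_test(t.collapse_to_classes(), t)

    def test_degenerate_reference_rejected(self):
        t = make_table(np.full(96, 10), np.full(96, 100))
        empty = make_table(np.zeros(96), np.full(96, 100))
        with pytest.raises(ValueError):
            enrichment_test(t, empty)

    def test_familywise_error_controlled_with_large_reference(self, rng):
        """With a reference far larger than the test compartment (the regime
        the fixed-reference null is designed for), the fraction of null
        replicates with any Bonferroni-significant type stays near alpha."""
        nrep = 150
        lam = np.full(96, 400.0)
        O_t = np.full(96, 40_000)
        ratio = 40
        any_sig = 0
        for _ in range(nrep):
            St = rng.poisson(lam)
            Sr = rng.poisson(lam * ratio)
            test = make_table(St, O_t)
            ref = make_table(Sr, O_t * ratio, "ref")
            res = enrichment_test(test, ref)
            any_sig += bool(res["significant"].any())
        fwer = any_sig / nrep
        mc_se = np.sqrt(0.05 * 0.95 / nrep)
        assert fwer <= 0.05 + 3 * mc_se


@pytest.fixture(scope="module")
def scenario():
    from mutspectra.simulate import hotspot_tiers, simulate_genome

    genome = simulate_genome(800_000, seed=21)
    tiers = hotspot_tiers(
        genome.extent, tier_scores=(1.0, 2.0, 3.0, 4.0),
        n_per_tier=40, width=2_000, seed=22,
    )
    outside = tiers.drop_scores("outside").complement(
        genome.extent, name="outside"
    )
    return genome, tiers, outside


class TestScoredBins:
    def test_null_bins_have_unit_ratios(self, scenario):
        from mutspectra.simulate import SimulationTruth, simulate_variants

        genome, tiers, outside = scenario
        truth = SimulationTruth(seed=23)
        bins = bin_by_score(tiers, n_bins=4)
        obs, _ = simulate_variants(
            genome, [(outside, None)] + [(b, None) for b in bins], truth
        )
        res = scored_bin_enrichment(obs, genome, tiers, bins, reference=outside)
        cg = res.xs("C>G", level="type")
        assert ((cg["enrichment"] - 1).abs() < 0.25).all()
        assert not res["significant"].fillna(False).any()

    def test_empty_bin_flagged_not_fatal(self, scenario):
        from mutspectra.simulate import SimulationTruth, simulate_variants

        genome, tiers, outside = scenario
        truth = SimulationTruth(seed=24)
        bins = bin_by_score(tiers, n_bins=4)
        empty = CompartmentSet("empty_bin", ())
        obs, _ = simulate_variants(genome, [(outside, None)], truth)
        res = scored_bin_enrichment(
            obs, genome, tiers, bins[:1] + [empty], reference=outside
        )
        assert res.loc["empty_bin"]["empty"].all()
        assert not res.loc[bins[0].name]["empty"].any()


class TestMatching:
    def test_identical_covariates_match_is_noop(self, rng):
        rows = [("c1", 1000 * i, 1000 * i + 500, float(x))
                for i, x in enumerate(np.linspace(-1, 1, 50))]
        wt = CompartmentSet("t", rows)
        wr = CompartmentSet("r", rows)
        matched, diag = match_reference_windows(wt, wr, n_bins=5, seed=1)
        assert diag.matched_ref_mean == pytest.approx(diag.test_mean, abs=0.05)
        assert diag.n_matched_windows == 50

    def test_unmatchable_bin_raises_with_bin_name(self):
        wt = CompartmentSet("t", [("c1", 0, 10, -5.0), ("c1", 20, 30, 5.0)])
        wr = CompartmentSet("r", [("c2", 0, 10, 10.0)])  # outside test support
        with pytest.raises(ValueError, match="bin"):
            match_reference_windows(wt, wr, n_bins=2, seed=0)

    def test_matched_mean_tracks_shifted_test_distribution(self, rng):
        ref_rows = [("c1", 1000 * i, 1000 * i + 500, float(x))
                    for i, x in enumerate(np.linspace(-1, 1, 200))]
        test_rows = [("c2", 1000 * i, 1000 * i + 500, float(x))
                     for i, x in enumerate(np.linspace(-0.8, 0.0, 40))]
        matched, diag = match_reference_windows(
            CompartmentSet("t", test_rows), CompartmentSet("r", ref_rows),
            n_bins=8, seed=3,
        )
        assert abs(diag.matched_ref_mean - diag.test_mean) < 0.05
        assert abs(diag.unmatched_ref_mean - diag.test_mean) > 0.3
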