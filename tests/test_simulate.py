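"""The synthetic-data generator: determinism, planted structure, closed forms."""

import numpy as np
import pytest
from scipy import stats

from mutspectra.catalog import PolarizationMode
from mutspectra.intervals import CompartmentSet
from mutspectra.io import write_vcf
from mutspectra.opportunities import count_contexts
from mutspectra.simulate import (
    DEFAULT_N_CHROMOSOMES,
    OpportunitySites,
    SimulationTruth,
    default_rate_vector,
    expand_class_multipliers,
    halves,
    simulate_compartments,
    simulate_genome,
    simulate_variants,
)
from mutspectra.spectrum import classify, sfs, tabulate


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        a = simulate_genome(4_000, seed=9)
        b = simulate_genome(4_000, seed=9)
        assert a.sequence("chr1") == b.sequence("chr1")
        c = simulate_genome(4_000, seed=10)
        assert a.sequence("chr1") != c.sequence("chr1")

    def test_pure_gc(self):
        g = simulate_genome(500, gc_fraction=1.0, seed=1)
        assert set(g.sequence("chr1")) <= {"G", "C"}

    def test_gc_within_binomial_ci(self):
        n = 200_000
        gc_req = 0.41
        g = simulate_genome(n, gc_fraction=gc_req, seed=2)
        gc = sum(b in "GC" for b in g.sequence("chr1"))
        lo, hi = stats.binomtest(gc, n).proportion_ci(0.999, method="exact")
        assert lo <= gc_req <= hi

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_genome(0)
        with pytest.raises(ValueError):
            simulate_genome(10, gc_fraction=1.5)


class TestTruth:
    def test_cohort_defaults_model_the_study_cohort(self):
        truth = SimulationTruth()
        assert truth.n_chromosomes == 13_860
        assert truth.n_individuals == 6_930
        assert truth.n_chromosomes == DEFAULT_N_CHROMOSOMES

    def test_singleton_fraction_closed_form(self):
        # alpha = 1.8 puts about 53% of variants at count 1
        truth = SimulationTruth()
        assert truth.expected_singleton_fraction() == pytest.approx(0.53, abs=0.01)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationTruth(n_chromosomes=13_861)
        with pytest.raises(ValueError):
            SimulationTruth(base_rates=np.full(96, -1.0))
        with pytest.raises(ValueError):
            SimulationTruth(multiallelic_fraction=1.5)

    def test_multiplier_expansion(self):
        v = expand_class_multipliers({"C>A": 2.0})
        assert (v[:16] == 2.0).all() and (v[16:] == 1.0).all()
        assert (expand_class_multipliers(None) == 1.0).all()
        assert (expand_class_multipliers(1.3) == 1.3).all()
        with pytest.raises(ValueError):
            expand_class_multipliers({"bogus": 1.0})

    def test_rate_vector_is_cpg_elevated(self):
        v = default_rate_vector()
        from mutspectra.catalog import CATALOG

        cpg_ct = [t.index for t in CATALOG if t.context[1:] == "CG" and t.alt == "T"]
        other_ct = [
            t.index for t in CATALOG
            if t.mutation_class == "C>T" and t.context[1:] != "CG"
        ]
        assert v[cpg_ct].mean() > 5 * v[other_ct].mean()


class TestSimulateVariants:
    def test_zero_rates_give_valid_empty_callset(self, small_genome, tmp_path):
        truth = SimulationTruth(base_rates=np.zeros(96), seed=1)
        a, b = halves(small_genome.extent)
        obs, manifest = simulate_variants(small_genome, [(a, None), (b, None)], truth)
        assert len(obs) == 0
        write_vcf(obs, tmp_path / "empty.vcf", extent=small_genome.extent)
        from mutspectra.io import read_vcf

        assert len(read_vcf(tmp_path / "empty.vcf")) == 0

    def test_deterministic_outputs(self, small_genome, tmp_path):
        truth = SimulationTruth(seed=77)
        a, b = halves(small_genome.extent)
        frames = []
        for rep in range(2):
            obs, _ = simulate_variants(small_genome, [(a, None), (b, None)], truth)
            path = tmp_path / f"v{rep}.vcf"
            write_vcf(obs, path, extent=small_genome.extent)
            frames.append(path.read_bytes())
        assert frames[0] == frames[1]

    def test_every_variant_sits_on_a_valid_opportunity(self, small_genome):
        """Reclassifying the simulated callset recovers the recorded types."""
        truth = SimulationTruth(seed=13)
        a, b = halves(small_genome.extent)
        obs, _ = simulate_variants(small_genome, [(a, None), (b, None)], truth)
        cls = classify(obs, small_genome, PolarizationMode())
        # below 50% frequency the major-allele rule recovers the planted
        # polarity, so recorded and reclassified types must agree exactly
        low = cls[2 * cls["dac"] < cls["an"]]
        assert (low["type_index"] == low["true_type"]).all()
        assert (cls["type_index"] >= 0).all()

    def test_multiallelic_fraction_near_target(self, small_genome):
        truth = SimulationTruth(seed=14)
        a, b = halves(small_genome.extent)
        obs, _ = simulate_variants(small_genome, [(a, None), (b, None)], truth)
        frac = obs.duplicated(["contig", "pos"], keep=False).mean()
        assert frac == pytest.approx(0.06, abs=0.02)
        sites = obs.groupby(["contig", "pos"])
        assert (sites["ref"].nunique() == 1).all()
        assert (sites["alt"].nunique() == sites.size()).all()

    def test_singleton_fraction_matches_closed_form(self, small_genome):
        truth = SimulationTruth(seed=15)
        a, b = halves(small_genome.extent)
        obs, _ = simulate_variants(small_genome, [(a, None), (b, None)], truth)
        hist = sfs(obs)
        n = hist.sum()
        got = hist.get(1, 0) / n
        expect = truth.expected_singleton_fraction()
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(got - expect) < 4 * se

    def test_round_trip_chi_square_across_seeds(self, small_genome):
        """Pipeline spectra of simulated data fit the planted rates."""
        a, b = halves(small_genome.extent)
        sites_a = OpportunitySites(small_genome, a)
        opp = sites_a.opportunity_table()
        rejected = 0
        for seed in range(20):
            truth = SimulationTruth(seed=100 + seed, multiallelic_fraction=0.0)
            obs, manifest = simulate_variants(small_genome, [(sites_a, None)], truth)
            table = tabulate(obs, a, small_genome, opp=opp)
            expect = np.array(manifest["expected_counts"]["A"])
            # under major-allele polarization a high-frequency derived allele
            # flips type; restrict to low-frequency rows for the comparison
            keep = expect > 5
            chi2 = ((table.S[keep] - expect[keep]) ** 2 / expect[keep]).sum()
            p = stats.chi2.sf(chi2, df=int(keep.sum()))
            rejected += p < 0.01
        assert rejected <= 2

    def test_rate_too_high_raises(self):
        g = simulate_genome(500, seed=3)
        comp = CompartmentSet("all", [("chr1", 0, 500)])
        truth = SimulationTruth(base_rates=np.full(96, 2.0), seed=4)
        with pytest.raises(ValueError, match="rate"):
            simulate_variants(g, [(comp, None)], truth)

    def test_planted_multiplier_shifts_expected_counts(self, small_genome):
        a, b = halves(small_genome.extent)
        truth = SimulationTruth(seed=16, multipliers={"B": {"C>G": 1.5}})
        _, manifest = simulate_variants(
            small_genome, [(a, None), (b, {"C>G": 1.5})], truth
        )
        ea = np.array(manifest["expected_counts"]["A"])
        eb = np.array(manifest["expected_counts"]["B"])
        opp_a = count_contexts(small_genome, a).type_counts
        opp_b = count_contexts(small_genome, b).type_counts
        ra, rb = ea / opp_a, eb / opp_b
        np.testing.assert_allclose(rb[16:32], 1.5 * ra[16:32], rtol=1e-12)
        np.testing.assert_allclose(rb[:16], ra[:16], rtol=1e-12)


class TestSimulateCompartments:
    def test_halves_cover_extent_disjointly(self, small_genome):
        a, b = simulate_compartments(small_genome.extent, {"kind": "halves"})
        assert a.intersect(b).empty
        union = a.union(b)
        assert union.total_length == sum(small_genome.extent.values())

    def test_hotspot_round_trip_through_binning(self, small_genome):
        from mutspectra.intervals import bin_by_score

        tiers = simulate_compartments(
            small_genome.extent,
            {"kind": "hotspots", "tier_scores": (1.0, 2.0), "n_per_tier": 5,
             "width": 500},
            seed=5,
        )
        bins = bin_by_score(tiers, n_bins=2)
        assert {float(s) for s in bins[0].scores()} == {1.0}
        assert {float(s) for s in bins[1].scores()} == {2.0}

    def test_covariate_track_matches_generating_function(self, small_genome):
        from mutspectra.intervals import tile_windows, window_means

        track = simulate_compartments(
            small_genome.extent,
            {"kind": "covariate", "step": 2_000, "amplitude": 0.7},
            seed=6,
        )
        assert track.scored
        assert track.scores().max() <= 0.7 + 1e-9
        win = tile_windows(small_genome.extent, 2_000)
        means = window_means(track, win)
        np.testing.assert_allclose(means, track.scores(), rtol=1e-9)

    def test_terminal_region(self, small_genome):
        par = simulate_compartments(
            small_genome.extent,
            {"kind": "terminal", "contig": "chr1", "length": 5_000},
        )
        assert par.intervals() == [("chr1", 0, 5_000)]

    def test_unknown_kind_rejected(self, small_genome):
        with pytest.raises(ValueError):
            simulate_compartments(small_genome.extent, {"kind": "bogus"})
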