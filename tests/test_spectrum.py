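"""Spectrum tabulation, SFS, class collapse and type exclusion."""

import numpy as np
import pandas as pd
import pytest

from mutspectra.catalog import (
    CATALOG,
    PolarizationMode,
    canonicalize,
)
from mutspectra.intervals import CompartmentSet
from mutspectra.io import Genome, read_vcf, write_vcf
from mutspectra.opportunities import count_contexts
from mutspectra.spectrum import (
    FrequencyFilter,
    SpectrumTable,
    polarize,
    sfs,
    tabulate,
)

#                 123456789012345678901
SEQ = "TTACGTATCGATACATTTGCA"
GENOME = Genome({"chr1": SEQ})
AN = 1000

# Hand-written callset: (pos, ref, alt, ac); classified by hand below.
# Site 9 is triallelic (C->T and C->G) and contributes two observations.
RECORDS = [
    (4, "C", "T", 1),     # ACG context -> ACG>ATG
    (9, "C", "T", 2),     # TCG context -> TCG>TTG
    (9, "C", "G", 1),     # TCG context -> TCG>TGG
    (14, "C", "A", 990),  # ACA context, alt is major -> AAA>ACA rev = TTT>TGT
    (18, "T", "C", 3),    # TTG ctx (pos 18 central T, flanks T,G) -> TTG>TCG
    (20, "C", "A", 500),  # exact 50/50: skipped as ambiguous
]


def hand_expected():
    expect = {}

    def add(ctx, alt):
        t = canonicalize(ctx, alt)
        expect[t.index] = expect.get(t.index, 0) + 1

    add("ACG", "T")
    add("TCG", "T")
    add("TCG", "G")
    # pos 14: alt A is major (990/1000); ancestral A, derived C, flanks A_A
    add("AAA", "C")
    add("TTG", "C")
    return expect


def make_obs(records=RECORDS, an=AN):
    rows = [
        ("chr1", pos, "ACGT".index(ref), "ACGT".index(alt), ac, an)
        for pos, ref, alt, ac in records
    ]
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "ac", "an"]
    ).astype({"ref": np.uint8, "alt": np.uint8})


WHOLE = CompartmentSet("all", [("chr1", 0, len(SEQ))])


class TestTabulate:
    def test_hand_classification_oracle(self):
        table = tabulate(make_obs(), WHOLE, GENOME)
        expect = hand_expected()
        for i in range(96):
            assert table.S[i] == expect.get(i, 0), CATALOG[i].label
        assert table.S_tot == 5
        # the ambiguous 50/50 site is in the skip log, not the counts
        assert (table.skip_log["reason"] == "ambiguous-polarization").sum() == 1

    def test_triallelic_site_contributes_two_counts(self):
        table = tabulate(make_obs(), WHOLE, GENOME)
        t1, t2 = canonicalize("TCG", "T"), canonicalize("TCG", "G")
        assert table.S[t1.index] == 1 and table.S[t2.index] == 1

    def test_empty_callset(self):
        table = tabulate(make_obs([]), WHOLE, GENOME)
        assert table.S_tot == 0
        assert table.D == 0
        assert np.isnan(table.r).all()

    def test_order_independence(self, rng):
        obs = make_obs()
        shuffled = obs.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = tabulate(obs, WHOLE, GENOME)
        b = tabulate(shuffled, WHOLE, GENOME)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_compartment_restriction_by_focal_position(self):
        # only sites at 0-based positions 0..9 (1-based 1..10)
        left = CompartmentSet("left", [("chr1", 0, 10)])
        table = tabulate(make_obs(), left, GENOME)
        assert table.S_tot == 3  # positions 4, 9, 9

    def test_opportunity_table_mismatch_rejected(self):
        other = count_contexts(GENOME, CompartmentSet("other", [("chr1", 0, 5)]))
        with pytest.raises(ValueError):
            tabulate(make_obs(), WHOLE, GENOME, opp=other)

    def test_frequency_filter_counting_oracle(self, rng):
        an = 10_000
        records = [
            (int(p), "C", "T", int(ac))
            for p, ac in zip(
                rng.choice(np.arange(3, 19), size=12, replace=False),
                rng.integers(1, an // 2, size=12),
            )
        ]
        obs = make_obs(
            [(p, SEQ[p - 1], "T" if SEQ[p - 1] != "T" else "A", ac) for p, _, _, ac in records],
            an=an,
        )
        filt = FrequencyFilter(max_daf=0.01)
        table = tabulate(obs, WHOLE, GENOME, filt=filt)
        cls_all = tabulate(obs, WHOLE, GENOME)
        # oracle: count records below 1% frequency among classifiable ones
        retained = (obs["ac"] / obs["an"] < 0.01).sum()
        dropped = (obs["ac"] / obs["an"] >= 0.01).sum()
        assert cls_all.S_tot - table.S_tot <= dropped
        assert table.S_tot <= retained


class TestSpectrumTable:
    def test_normalization_identity(self, small_genome, default_truth):
        from mutspectra.simulate import halves, simulate_variants

        a, b = halves(small_genome.extent)
        obs, _ = simulate_variants(small_genome, [(a, None), (b, None)], default_truth)
        for comp in (a, b):
            table = tabulate(obs, comp, small_genome)
            assert table.normalization_residual() < 1e-12

    def test_relative_diversity_invariant_to_opportunity_scaling(self):
        S = np.arange(96, dtype=np.int64)
        O = np.full(96, 1000, dtype=np.int64)
        t1 = SpectrumTable("x", S, O)
        t3 = SpectrumTable("x", S, 3 * O)
        np.testing.assert_allclose(t1.r, t3.r, rtol=1e-14)

    def test_counts_cannot_exceed_opportunities(self):
        with pytest.raises(ValueError):
            SpectrumTable("x", np.full(96, 5), np.full(96, 4))

    def test_undefined_diversity_flagged_when_no_opportunities(self):
        O = np.full(96, 100, dtype=np.int64)
        O[3] = 0
        S = np.zeros(96, dtype=np.int64)
        S[0] = 10
        t = SpectrumTable("x", S, O)
        assert np.isnan(t.d[3])
        assert np.isfinite(t.d[0])


class TestCollapse:
    def test_totals_conserved(self):
        S = np.arange(96, dtype=np.int64)
        O = np.full(96, 10_000, dtype=np.int64)
        t = SpectrumTable("x", S, O)
        c = t.collapse_to_classes()
        assert c.S_tot == t.S_tot
        assert c.O_tot == t.O_tot
        assert len(c.frame) == 6

    def test_single_class_carries_everything(self):
        S = np.zeros(96, dtype=np.int64)
        S[:16] = 7  # all C>A
        t = SpectrumTable("x", S, np.full(96, 1000, dtype=np.int64))
        c = t.collapse_to_classes()
        assert c.frame.loc["C>A", "S"] == 112
        assert (c.frame.drop("C>A")["S"] == 0).all()

    def test_class_diversity_matches_direct_recomputation(self, rng):
        S = rng.integers(0, 500, size=96)
        O = rng.integers(500, 10_000, size=96)
        t = SpectrumTable("x", S, O)
        c = t.collapse_to_classes()
        for k, cls in enumerate(c.frame.index):
            sel = slice(16 * k, 16 * (k + 1))
            assert c.frame.loc[cls, "d"] == pytest.approx(
                S[sel].sum() / O[sel].sum(), rel=1e-14
            )


class TestExcludeTypes:
    def test_drop_nothing_is_identity(self):
        t = SpectrumTable("x", np.arange(96), np.full(96, 1000))
        pd.testing.assert_frame_equal(t.exclude_types([]).frame, t.frame)

    def test_cpg_exclusion_recomputes_normalization(self, rng):
        S = rng.integers(0, 500, size=96)
        t = SpectrumTable("x", S, np.full(96, 10_000))
        t2 = t.exclude_types("cpg")
        assert len(t2.frame) == 84
        assert t2.normalization_residual() < 1e-12
        from mutspectra.catalog import CPG_TYPE_MASK

        assert t2.S_tot == S[~CPG_TYPE_MASK].sum()

    def test_cpg_exclusion_equals_masking_contexts(self, small_genome, default_truth):
        """Dropping CpG types equals rebuilding with NCG contexts masked."""
        from mutspectra.simulate import halves, simulate_variants

        a, _ = halves(small_genome.extent)
        obs, _ = simulate_variants(small_genome, [(a, None)], default_truth)
        dropped = tabulate(obs, a, small_genome).exclude_types("cpg")

        # mask every NCG/CGN site in a copy of the genome, rebuild from scratch
        seq = small_genome.sequence("chr1")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        masked = arr.copy()
        masked[cg] = ord("N")
        masked[cg + 1] = ord("N")
        masked_genome = Genome({"chr1": masked.tobytes().decode()})
        rebuilt = tabulate(obs, a, masked_genome)

        cpg_labels = {t.label for t in CATALOG if t.context[1:] == "CG"}
        common = [l for l in dropped.labels]
        for label in common:
            assert label not in cpg_labels
        # non-CpG-context counts agree wherever masking does not clip flanks
        got = dropped.frame["S"]
        ref = rebuilt.frame["S"].reindex(
            [l for l in rebuilt.frame.index if l in common]
        )
        # masking N's also removes non-CpG sites adjacent to CG dinucleotides,
        # so rebuilt counts are a lower bound and CpG rows are exactly zero
        for t in CATALOG:
            if t.context[1:] == "CG":
                assert rebuilt.frame.loc[t.label, "S"] == 0


class TestSFS:
    def test_small_example(self):
        obs = make_obs([(4, "C", "T", 1), (9, "C", "T", 1), (14, "C", "A", 2)])
        hist = sfs(obs)
        assert hist.to_dict() == {1: 2, 2: 1}

    def test_empty_stream(self):
        assert sfs(make_obs([])).empty

    def test_missing_allele_counts_rejected(self):
        with pytest.raises(ValueError):
            sfs(pd.DataFrame({"contig": [], "pos": []}))

    def test_generator_round_trip_chi_square(self, small_genome):
        """Realized SFS is consistent with the truncated power law."""
        from scipy import stats

        from mutspectra.simulate import SimulationTruth, halves, simulate_variants

        truth = SimulationTruth(seed=5, n_chromosomes=200, sfs_alpha=1.8)
        a, b = halves(small_genome.extent)
        obs, _ = simulate_variants(small_genome, [(a, None), (b, None)], truth)
        hist = sfs(obs)
        pmf = truth.sfs_pmf()
        # pool the tail so expected counts stay reasonable
        edges = [1, 2, 3, 4, 6, 11, 200]
        got = np.array(
            [hist.reindex(range(lo, hi), fill_value=0).sum() for lo, hi in zip(edges[:-1], edges[1:])]
        )
        exp = len(obs) * np.array(
            [pmf[lo - 1 : hi - 1].sum() for lo, hi in zip(edges[:-1], edges[1:])]
        )
        chi2 = ((got - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, df=len(got) - 1)
        assert p > 0.01


class TestPolarizeMultiallelic:
    def test_major_alt_repolarizes_all_site_alleles(self):
        # ref C with alts T (major, 800/1000) and G (rare): ancestral is T,
        # derived alleles are C (count 150) and G (count 50)
        obs = make_obs([(4, "C", "T", 800), (4, "C", "G", 50)])
        out = polarize(obs, PolarizationMode())
        out = out.sort_values("alt").reset_index(drop=True)
        # row with alt G: ancestral T, derived G
        g_row = out[out["alt"] == 2].iloc[0]
        assert g_row["anc"] == 3 and g_row["der"] == 2 and g_row["dac"] == 50
        t_row = out[out["alt"] == 3].iloc[0]
        assert t_row["anc"] == 3 and t_row["der"] == 1 and t_row["dac"] == 150

    def test_tied_major_alleles_skipped(self):
        obs = make_obs([(4, "C", "T", 400), (4, "C", "G", 400)])
        out = polarize(obs, PolarizationMode())
        assert (out["skip"] == "ambiguous-polarization").all()
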