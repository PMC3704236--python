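import math

import numpy as np
import pytest

from codonscape.conservation_tests import (
    CodonAlignment,
    StratumTable,
    build_akashi_tables,
    cmh_test,
    mh_common_odds_ratio,
    randomized_codon_set_reference,
    woolf_test,
)
from codonscape.preferred_codons import PreferredCodonSet
from codonscape.synthetic_data import (
    SimConfig,
    generate_genome,
    generate_ortholog_alignments,
)

from _oracles import (
    cmh_statsmodels,
    mh_or_statsmodels,
    random_stratified_tables,
    woolf_reference,
)


def _tables(rows):
    return [StratumTable(f"g{i}", *r) for i, r in enumerate(rows)]


PREF = PreferredCodonSet(choice={"I": "ATC", "F": "TTC", "K": "AAG"})


class TestBuildTables:
    def test_synonymous_preferred_increments_a(self):
        aln = CodonAlignment("g", ["ATC"], ["ATT"])
        # single-codon stratum is unusable; check raw tallies via two codons
        aln = CodonAlignment("g", ["ATC", "ATT", "ATC", "ATT"], ["ATT", "AGA", "ATA", "ATC"])
        (t,) = build_akashi_tables([aln], PREF)
        assert (t.a, t.b, t.c, t.d) == (2, 0, 1, 1)

    def test_hand_tally_of_ten_codons(self):
        focal = ["ATC", "ATC", "ATT", "ATT", "TTC", "TTT", "AAG", "AAA", "ATC", "ATT"]
        other = ["ATT", "AGA", "ATC", "CGA", "TTT", "TTC", "AAA", "AGA", "ATC", "ATT"]
        # preferred: ATC, TTC, AAG; conserved where amino acids match
        # codon:     p&c  p&n  u&c  u&n  p&c  u&c  p&c  u&n  p&c  u&c
        (t,) = build_akashi_tables([CodonAlignment("g", focal, other)], PREF)
        assert (t.a, t.b, t.c, t.d) == (4, 1, 3, 2)

    def test_gaps_stops_and_unassigned_families_skipped(self):
        focal = ["ATC", "ATG", "GTT", "ATT", "ATC", "ATT"]
        other = ["---", "ATG", "GTC", "TAA", "ATC", "CGG"]
        # ATC/--- skipped (gap), ATG nondegenerate, GTT family unassigned,
        # ATT/TAA skipped (stop) -> only last two codons scored
        (t,) = build_akashi_tables([CodonAlignment("g", focal, other)], PREF)
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_unusable_tables_dropped(self):
        aln = CodonAlignment("g", ["ATC", "ATC"], ["ATT", "ATA"])  # all preferred
        assert build_akashi_tables([aln], PREF) == []

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            CodonAlignment("g", ["ATC"], [])


class TestMHOddsRatio:
    def test_single_table(self):
        assert mh_common_odds_ratio(_tables([(10, 5, 5, 10)])) == pytest.approx(4.0)

    def test_identical_strata_preserve_or(self):
        assert mh_common_odds_ratio(_tables([(10, 5, 5, 10)] * 2)) == pytest.approx(4.0)

    def test_scaled_strata_share_or(self):
        assert mh_common_odds_ratio(
            _tables([(2, 1, 1, 2), (20, 10, 10, 20)])
        ) == pytest.approx(4.0)

    def test_zero_denominator_reports_inf(self):
        assert mh_common_odds_ratio(_tables([(5, 0, 0, 5)])) == math.inf


class TestCMH:
    def test_two_identical_tables_with_continuity(self):
        chi2, p = cmh_test(_tables([(10, 5, 5, 10)] * 2), continuity=True)
        assert chi2 == pytest.approx(5.22, abs=0.005)

    def test_single_stratum_reduces_to_corrected_chi2(self):
        t = _tables([(12, 4, 5, 9)])
        chi2, _ = cmh_test(t, continuity=True)
        ref_chi2, _ = cmh_statsmodels(np.array([[12, 4, 5, 9]]), correction=True)
        assert chi2 == pytest.approx(ref_chi2)

    def test_independence_tables_give_zero(self):
        # a = E exactly: (6,6,6,6) has E = 12*12/24 = 6
        chi2, p = cmh_test(_tables([(6, 6, 6, 6)] * 3), continuity=False)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_one_sided_halves_p_in_the_right_direction(self):
        t = _tables([(10, 5, 5, 10)] * 2)  # OR > 1
        _, p_two = cmh_test(t, "two_sided")
        _, p_gt = cmh_test(t, "greater")
        assert p_gt == pytest.approx(p_two / 2)
        t_neg = _tables([(5, 10, 10, 5)] * 2)  # OR < 1
        _, p_gt_neg = cmh_test(t_neg, "greater")
        assert p_gt_neg > 0.9


class TestWoolf:
    def test_identical_tables_are_homogeneous(self):
        stat, df, p = woolf_test(_tables([(10, 5, 5, 10)] * 4))
        assert stat == pytest.approx(0.0)
        assert df == 3

    def test_opposed_ors_are_heterogeneous(self):
        stat, df, p = woolf_test(_tables([(40, 10, 10, 40), (10, 40, 40, 10)]))
        assert p < 1e-6

    def test_df_is_k_minus_one(self):
        for k in (2, 5, 9):
            assert woolf_test(_tables([(8, 3, 4, 7)] * k))[1] == k - 1

    def test_needs_two_tables(self):
        with pytest.raises(ValueError):
            woolf_test(_tables([(10, 5, 5, 10)]))


class TestOracleEquivalence:
    def test_mh_or_and_cmh_match_statsmodels(self, rng):
        for _ in range(50):
            abcd = random_stratified_tables(rng, n_tables=int(rng.integers(2, 12)))
            tables = _tables(abcd.tolist())
            assert mh_common_odds_ratio(tables) == pytest.approx(
                mh_or_statsmodels(abcd), rel=1e-9
            )
            chi2, p = cmh_test(tables, continuity=True)
            ref_chi2, ref_p = cmh_statsmodels(abcd, correction=True)
            assert chi2 == pytest.approx(ref_chi2, rel=1e-9, abs=1e-12)
            assert p == pytest.approx(ref_p, rel=1e-9, abs=1e-12)

    def test_woolf_matches_reference_formulation(self, rng):
        for _ in range(50):
            abcd = random_stratified_tables(rng, n_tables=int(rng.integers(2, 12)))
            stat, df, p = woolf_test(_tables(abcd.tolist()))
            ref_stat, ref_df, ref_p = woolf_reference(abcd)
            assert stat == pytest.approx(ref_stat, rel=1e-9, abs=1e-9)
            assert (df, p) == (ref_df, pytest.approx(ref_p, rel=1e-6, abs=1e-12))


class TestRandomizedReference:
    def test_single_set_is_zero_or_one(self, sim_small):
        alns = generate_ortholog_alignments(sim_small)[:40]
        frac = randomized_codon_set_reference(
            alns, sim_small.cluster_preferred(0), n_sets=1, seed=3
        )
        assert frac in (0.0, 1.0)

    def test_planted_preferred_set_beats_random_sets(self, sim_small):
        alns = generate_ortholog_alignments(sim_small)
        sub = [
            a for a in alns if sim_small.truth["labels"][a.gene_id] == 0
        ]
        frac = randomized_codon_set_reference(
            sub, sim_small.cluster_preferred(0), n_sets=300, seed=3
        )
        assert frac < 0.05

    def test_unassigned_families_stay_unassigned_in_random_sets(self):
        # only Ile assigned: random sets must not score other families
        alns = [
            CodonAlignment(
                "g%d" % i,
                ["ATC", "ATT", "TTT", "TTC"] * 5,
                ["ATT", "CGA", "TTC", "TTT"] * 5,
            )
            for i in range(4)
        ]
        only_ile = PreferredCodonSet(choice={"I": "ATC"})
        frac = randomized_codon_set_reference(alns, only_ile, n_sets=20, seed=1)
        assert 0.0 <= frac <= 1.0


class TestPlantedOrRecovery:
    def test_null_or_near_one(self):
        cfg = SimConfig(
            seed=77, n_genes=150, S=1, separation=0.4, mean_len=150,
            flank_width=50, mean_introns=0, conservation_or=1.0,
        )
        sim = generate_genome(cfg)
        tables = build_akashi_tables(
            generate_ortholog_alignments(sim), sim.cluster_preferred(0)
        )
        assert mh_common_odds_ratio(tables) == pytest.approx(1.0, abs=0.1)

    def test_cmh_p_uniform_under_null(self):
        # null calibration over seeds: p-values should not pile up low
        ps = []
        for seed in range(20):
            cfg = SimConfig(
                seed=1000 + seed, n_genes=40, S=1, separation=0.4, mean_len=100,
                flank_width=50, mean_introns=0, conservation_or=1.0,
            )
            sim = generate_genome(cfg)
            tables = build_akashi_tables(
                generate_ortholog_alignments(sim), sim.cluster_preferred(0)
            )
            ps.append(cmh_test(tables)[1])
        assert sum(p < 0.05 for p in ps) <= 3
        assert np.mean(ps) == pytest.approx(0.5, abs=0.25)
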