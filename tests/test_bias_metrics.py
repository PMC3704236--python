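import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codonscape.bias_metrics import (
    CodonCounts,
    background_composition,
    bias_profile,
    centered_usage,
    expected_family_frequencies,
    family_homozygosity,
    gc_metrics,
    nc_prime,
    nc_wright,
    senc_x,
    _family_f_prime,
)
from codonscape.genetic_code import DEGENERACY, DEGENERATE_AAS, FAMILIES
from codonscape.seq_models import GeneRecord

from _oracles import nc_brute_force
from conftest import random_codon_counts

UNIFORM_BG = {b: 0.25 for b in "ACGT"}


class TestFamilyHomozygosity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 1), 0.5),  # (4*0.625-1)/3
            ((5, 0), 1.0),  # monomorphic
            ((2, 0, 0, 0), 1.0),
            ((1, 1), 0.0),
        ],
    )
    def test_known_values(self, counts, expected):
        assert family_homozygosity(counts) == pytest.approx(expected)

    def test_small_families_unusable(self):
        assert family_homozygosity((1, 0)) is None
        assert family_homozygosity((0, 0)) is None

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6))
    def test_bounded_by_one(self, counts):
        f = family_homozygosity(counts)
        if f is not None:
            assert f <= 1.0 + 1e-12


class TestNcWright:
    def test_single_codon_per_family_gives_20(self):
        counts = {FAMILIES[aa][0]: 3 for aa in DEGENERATE_AAS}
        assert nc_wright(CodonCounts("g", counts)) == 20.0

    def test_uniform_usage_clamps_to_61(self):
        counts = {}
        for aa in DEGENERATE_AAS:
            d = DEGENERACY[aa]
            for c in FAMILIES[aa]:
                counts[c] = 60 // d
        assert nc_wright(CodonCounts("g", counts)) == 61.0

    def test_half_homozygosity_every_class_gives_38(self):
        # (3,1,0,...) per family gives F-hat = 0.5 for any degeneracy
        counts = {
            "TTT": 3, "TTC": 1,  # Phe (2-fold)
            "ATT": 3, "ATC": 1,  # Ile (3-fold)
            "GTT": 3, "GTC": 1,  # Val (4-fold)
            "CTT": 3, "CTC": 1,  # Leu (6-fold)
        }
        assert nc_wright(CodonCounts("g", counts)) == pytest.approx(38.0)

    def test_missing_ile_imputed_from_two_and_fourfold(self):
        counts = {
            "TTT": 3, "TTC": 1,  # F2 = 0.5
            "GTT": 5, "GTC": 0,  # F4 = 1.0
            "CTT": 5, "CTC": 0,  # F6 = 1.0
        }
        # F3 imputed as (0.5 + 1.0)/2 = 0.75
        expected = 2 + 9 / 0.5 + 1 / 0.75 + 5 / 1.0 + 3 / 1.0
        assert nc_wright(CodonCounts("g", counts)) == pytest.approx(expected)

    def test_no_usable_family_is_nan(self):
        assert math.isnan(nc_wright(CodonCounts("g", {"TTT": 1})))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            cc = random_codon_counts(rng)
            assert nc_wright(cc) == pytest.approx(nc_brute_force(cc.counts), abs=1e-9)


class TestNcPrime:
    def test_equals_nc_under_uniform_background(self, rng):
        for _ in range(20):
            cc = random_codon_counts(rng)
            assert nc_prime(cc, UNIFORM_BG) == pytest.approx(
                nc_wright(cc), abs=1e-9
            )

    def test_no_excess_bias_floor_when_chi2_zero(self):
        # frequencies exactly at the bg-derived expectation -> F' = (n-m)/(m(n-1))
        bg = {"A": 0.1, "C": 0.4, "G": 0.3, "T": 0.2}
        e = expected_family_frequencies(bg)["F"]  # Phe: TTT, TTC
        n = 50.0
        counts = np.array([e[0] * n, e[1] * n])
        m = 2
        assert _family_f_prime(counts, e) == pytest.approx((n - m) / (m * (n - 1)))

    def test_monomorphic_family_more_biased_under_skewed_background(self):
        # all usage on TTT while the background favors C at position 3;
        # the Phe family is ordered (TTC, TTT)
        bg = {"A": 0.1, "C": 0.7, "G": 0.1, "T": 0.1}
        e = expected_family_frequencies(bg)["F"]
        counts = np.array([0.0, 10.0])  # TTT only
        f_plain = family_homozygosity(counts)
        f_corr = _family_f_prime(counts, e)
        assert f_corr > f_plain

    def test_skewed_background_explains_away_compositional_bias(self):
        # a gene matching an AT-rich background is less biased by Nc' than Nc
        bg = {"A": 0.35, "C": 0.15, "G": 0.15, "T": 0.35}
        expected = expected_family_frequencies(bg)
        counts = {}
        for aa in DEGENERATE_AAS:
            for c, e in zip(FAMILIES[aa], expected[aa]):
                counts[c] = int(round(120 * e))
        cc = CodonCounts("g", counts)
        assert nc_prime(cc, bg) > nc_wright(cc)


class TestGcMetrics:
    @pytest.mark.parametrize(
        "cds,gc3,gc_cds",
        [
            ("ATGGCC", 1.0, 4 / 6),
            ("ATGGCGAAT", 2 / 3, 4 / 9),
            ("AAAGATTAT", 0.0, 1 / 9),
        ],
    )
    def test_hand_counts(self, cds, gc3, gc_cds):
        g = GeneRecord("g", cds)
        got = gc_metrics(g)
        assert got[0] == pytest.approx(gc3)
        assert got[1] == pytest.approx(gc_cds)

    def test_intronless_gene_has_nan_gc_i(self):
        got = gc_metrics(GeneRecord("g", "ATGGCC"))
        assert math.isnan(got[2])

    def test_gc_plus_at_is_one(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            g = GeneRecord("g", seq, introns=[seq[::-1]], flank_up=seq, flank_down=seq)
            gc3, gc_cds, gc_i, gc_f = gc_metrics(g)
            at_cds = (seq.count("A") + seq.count("T")) / len(seq)
            assert gc_cds + at_cds == pytest.approx(1.0)

    def test_terminal_stop_excluded_from_gc3(self):
        # TGA's A would lower GC3 if counted
        assert gc_metrics(GeneRecord("g", "ATGGCCTGA"))[0] == pytest.approx(1.0)


class TestSencX:
    @pytest.mark.parametrize(
        "counts,d,expected",
        [
            ((12, 0, 0, 0), 4, 1.0),
            ((5, 5, 5, 5), 4, 0.0),
            ((3, 1), 2, 0.4),  # ENC-X = 1/0.625 = 1.6
        ],
    )
    def test_known_values(self, counts, d, expected):
        assert senc_x(counts, d) == pytest.approx(expected)

    def test_nondegenerate_rejected(self):
        with pytest.raises(ValueError):
            senc_x((5,), 1)

    @given(
        st.lists(st.integers(0, 20), min_size=4, max_size=4).filter(
            lambda c: sum(c) >= 1
        ),
        st.integers(2, 10),
    )
    def test_scaling_invariance(self, counts, k):
        scaled = [k * c for c in counts]
        assert senc_x(scaled, 4) == pytest.approx(senc_x(counts, 4))


class TestCenteredUsage:
    @pytest.mark.parametrize(
        "p,d,expected",
        [(0.25, 4, 0.0), (1.0, 4, 1.0), (0.4, 4, 0.2), (0.5, 2, 0.0), (0.0, 4, -1 / 3)],
    )
    def test_known_values(self, p, d, expected):
        assert centered_usage(p, d) == pytest.approx(expected)

    @given(st.floats(0, 1), st.integers(2, 6))
    def test_range_and_center(self, p, d):
        v = centered_usage(p, d)
        assert -1 / (d - 1) - 1e-12 <= v <= 1 + 1e-12
        if v == 0:
            assert p == pytest.approx(1 / d)


def test_background_composition_pools_and_floors():
    bg = background_composition(["AAAA", "TTTT"])
    assert bg["A"] == pytest.approx(0.5, abs=1e-6)
    assert bg["G"] > 0 and bg["C"] > 0  # floored, never zero
    assert sum(bg.values()) == pytest.approx(1.0)


def test_bias_profile_bounds_on_synthetic_genes(sim_small):
    bg = background_composition(
        [g.flank_up for g in sim_small.genes] + [g.flank_down for g in sim_small.genes]
    )
    for g in sim_small.genes[:30]:
        p = bias_profile(g, bg)
        assert 20.0 <= p.nc <= 61.0
        assert 20.0 <= p.nc_prime <= 61.0
        assert 0.0 <= p.gc3 <= 1.0
        for v in p.senc.values():
            assert math.isnan(v) or 0.0 <= v <= 1.0
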