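import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import panmotif as pm
from panmotif.motif_discovery import AA_ALPHABET, TripeptideStat

from conftest import random_peptides

peptide_pools = st.lists(
    st.text(alphabet=AA_ALPHABET, min_size=7, max_size=7), min_size=1, max_size=40
)


def brute_force_counts(peptides):
    """Independent nested-loop tally of all forward and reverse windows."""
    fwd, rev = Counter(), Counter()
    for pep in peptides:
        f, r = pm.segment_tripeptides(pep)
        fwd.update(f)
        rev.update(r)
    return fwd, rev


class TestSegmentation:
    def test_window_convention(self):
        fwd, rev = pm.segment_tripeptides("ABCDEFG")
        assert fwd == ["ABC", "BCD", "CDE", "DEF", "EFG"]
        assert rev == ["GFE", "FED", "EDC", "DCB", "CBA"]

    def test_homopolymer(self):
        fwd, rev = pm.segment_tripeptides("AAAAAAA")
        assert fwd + rev == ["AAA"] * 10

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            pm.segment_tripeptides("ABCDEF")

    def test_638_pool_segments_into_6380(self, validated_pool):
        pool = validated_pool[:638] if len(validated_pool) >= 638 else validated_pool
        total = sum(len(f) + len(r) for f, r in map(pm.segment_tripeptides, (p.sequence for p in pool)))
        assert total == 10 * len(pool)


class TestCountAbundance:
    def test_forward_and_reverse_tallied_separately(self):
        stats = {s.motif: s for s in pm.count_abundance(["SLHTAAA", "CLHTDDD"])}
        assert stats["LHT"].n_forward == 2
        # the reversal THL appears only in the reverse windows
        assert stats["THL"].n_reverse == 2
        assert stats["THL"].n_forward == 0

    def test_palindrome_counts_both_orientations(self):
        stats = {s.motif: s for s in pm.count_abundance(["APFPAAA"])}
        assert stats["PFP"].n_forward == 1
        assert stats["PFP"].n_reverse == 1

    @given(peptide_pools)
    @settings(derandomize=True, max_examples=50)
    def test_conservation_sum_is_10x_pool(self, peptides):
        stats = pm.count_abundance(peptides)
        assert sum(s.abundance for s in stats) == 10 * len(peptides)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            pool = random_peptides(rng, int(rng.integers(1, 60)))
            fwd, rev = brute_force_counts(pool)
            stats = pm.count_abundance(pool)
            assert {s.motif: s.n_forward for s in stats if s.n_forward} == dict(fwd)
            assert {s.motif: s.n_reverse for s in stats if s.n_reverse} == dict(rev)

    def test_empty_pool(self):
        assert pm.count_abundance([]) == []

    def test_multiplicity_weighting_flag(self):
        pool = [pm.Heptapeptide("AAAAAAA", 3, ["a", "b", "c"])]
        plain = pm.count_abundance(pool)
        weighted = pm.count_abundance(
            pool, pm.DiscoveryConfig(weight_by_multiplicity=True)
        )
        assert plain[0].abundance == 10
        assert weighted[0].abundance == 30


class TestPermutationTest:
    def test_shuffle_invariant_pool_gives_p_one(self):
        pool = ["AAAAAAA", "AAAAAAA"]
        cfg = pm.DiscoveryConfig(n_permutations=50, rng_seed=1)
        stats = pm.permutation_test(pm.count_abundance(pool), pool, cfg)
        (stat,) = stats
        assert stat.motif == "AAA"
        assert stat.p_raw == 1.0

    def test_seeded_runs_are_bitwise_identical(self, validated_pool):
        pool = validated_pool[:80]
        cfg = pm.DiscoveryConfig(n_permutations=100, rng_seed=42)
        obs = pm.count_abundance(pool)
        p1 = [s.p_raw for s in pm.permutation_test(obs, pool, cfg)]
        p2 = [s.p_raw for s in pm.permutation_test(obs, pool, cfg)]
        assert p1 == p2

    def test_single_peptide_matches_exhaustive_enumeration(self):
        """p_raw for one 7-mer of distinct residues vs all 5040 orders.

        A motif is present in a shuffled peptide iff it or its reversal
        occurs as a substring; the exact null probability is the fraction
        of the 7! residue orders where that happens.
        """
        peptide = "ACDEFGH"
        cfg = pm.DiscoveryConfig(n_permutations=10_000, rng_seed=7)
        stats = pm.permutation_test(
            pm.count_abundance([peptide]), [peptide], cfg
        )
        exact = {}
        orders = ["".join(p) for p in itertools.permutations(peptide)]
        for stat in stats:
            motif, rev = stat.motif, stat.motif[::-1]
            hits = sum(motif in o or rev in o for o in orders)
            exact[stat.motif] = hits / len(orders)
        for stat in stats:
            p_true = exact[stat.motif]
            mc_sd = math.sqrt(p_true * (1 - p_true) / cfg.n_permutations)
            assert abs(stat.p_raw - p_true) <= 3 * mc_sd + 2 / cfg.n_permutations

    def test_within_peptide_variant_runs(self):
        pool = ["ACDEFGH", "HGFEDCA"]
        cfg = pm.DiscoveryConfig(
            n_permutations=50, rng_seed=3, shuffle_unit="within-peptide"
        )
        stats = pm.permutation_test(pm.count_abundance(pool), pool, cfg)
        assert all(0 < s.p_raw <= 1 for s in stats)

    def test_invalid_n_permutations_rejected(self):
        with pytest.raises(ValueError):
            pm.DiscoveryConfig(n_permutations=0)


class TestBonferroniAndSelection:
    @pytest.mark.parametrize(
        "p_raw, m, expected",
        [(0.01, 3, 0.03), (0.01, 3734, 1.0), (1e-5, 3734, 0.03734)],
    )
    def test_adjustment_arithmetic(self, p_raw, m, expected):
        stats = [
            TripeptideStat(motif="AAA", n_forward=1, n_reverse=0, p_raw=p_raw)
        ] * m
        cfg = pm.DiscoveryConfig()
        out = pm.bonferroni_adjust(stats, cfg)
        assert out[0].p_adj == pytest.approx(expected)

    def test_p_adj_monotone_in_m(self):
        stat = TripeptideStat("AAA", 1, 0, p_raw=1e-4)
        small = pm.bonferroni_adjust([stat], pm.DiscoveryConfig())[0]
        big = pm.bonferroni_adjust(
            [stat], pm.DiscoveryConfig(bonferroni_m="all-8000")
        )[0]
        assert stat.p_raw <= small.p_adj <= big.p_adj

    def test_selection_rule_and_reasons(self):
        cfg = pm.DiscoveryConfig(abundance_threshold=20, alpha=0.05)
        stats = [
            TripeptideStat("XXX", 25, 0, p_raw=0.1, p_adj=0.2),
            TripeptideStat("YYY", 5, 0, p_raw=0.001, p_adj=0.01),
            TripeptideStat("ZZZ", 5, 0, p_raw=0.5, p_adj=1.0),
            TripeptideStat("WWW", 20, 0, p_raw=0.5, p_adj=1.0),  # not > 20
        ]
        selected = {s.motif: s for s in pm.select_motifs(stats, cfg)}
        assert set(selected) == {"XXX", "YYY"}
        assert selected["XXX"].selection_reason == frozenset({"abundant"})
        assert selected["YYY"].selection_reason == frozenset({"significant"})

    def test_six_abundant_seven_significant_four_overlap_gives_nine(self):
        """Union of the abundance and significance channels: 6 + 7 - 4 = 9."""
        cfg = pm.DiscoveryConfig()
        motifs = [f"{a}{b}A" for a, b in itertools.product(AA_ALPHABET[:4], repeat=2)]
        stats = []
        for i in range(13):
            abundant = i < 6  # motifs 0-5 exceed the count threshold
            significant = 2 <= i < 9  # motifs 2-8 are significant: overlap 2-5
            stats.append(
                TripeptideStat(
                    motifs[i],
                    30 if abundant else 10,
                    0,
                    p_raw=0.001 if significant else 0.5,
                    p_adj=0.01 if significant else 1.0,
                )
            )
        selected = pm.select_motifs(stats, cfg)
        assert len(selected) == 9


class TestExtendMotifs:
    def test_agreeing_flanks_build_consensus(self):
        (motif,) = pm.extend_motifs(["PFP"], ["ASPFPTG", "CSPFPTD"])
        assert motif.consensus == "SPFPT"
        assert motif.anchor == "PFP"
        assert not motif.unextended
        assert motif.column_support == [1.0, 1.0, 1.0, 1.0, 1.0]

    def test_no_agreement_outside_anchor_is_unextended(self):
        (motif,) = pm.extend_motifs(["PFP"], ["APFPAAA", "CPFPCCC"])
        assert motif.unextended
        assert motif.consensus == "PFP"

    def test_single_supporter_skipped(self):
        assert pm.extend_motifs(["PFP"], ["APFPAAA", "CCCCCCC"]) == []

    def test_reversed_supporters_are_flipped_into_orientation(self):
        # CTPFPSC carries the reversal of SPF; it aligns after flipping
        (motif,) = pm.extend_motifs(["SPF"], ["ASPFPTG", "CTPFPSC"])
        assert motif.consensus == "SPFPT"
        assert set(motif.supporters) == {"ASPFPTG", "CTPFPSC"}

    def test_consensus_trimmed_to_max_len(self):
        supporters = ["MSPFPTG", "MSPFPTG", "MSPFPTG"]
        (motif,) = pm.extend_motifs(["PFP"], supporters, max_len=6)
        assert len(motif.consensus) == 6
        assert "PFP" in motif.consensus

    def test_spiked_pool_recovers_embedded_pentapeptide(self):
        """A 5-mer spiked at varied offsets is reassembled from its anchors."""
        rng = np.random.default_rng(13)
        pool = random_peptides(rng, 60)
        for i in range(18):
            offset = int(rng.integers(0, 3))
            flank = random_peptides(rng, 1)[0]
            pep = (flank[:offset] + "SPFPT" + flank[offset + 5 :])[:7]
            pool[i] = pep
        extended = pm.extend_motifs(["SPF", "PFP", "FPT"], pool)
        assert any(m.consensus == "SPFPT" for m in extended)
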