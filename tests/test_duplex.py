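"""Duplex search, RRS/RDS location, site filters and the overlap test."""

from __future__ import annotations

from functools import lru_cache

import pytest

from srnatim import (
    BindingSite,
    RelativeInterval,
    RibosomeSite,
    Transcript,
    duplex_fold,
    find_rrs,
    find_srna_sites,
    overlaps,
    start_codon_bonus,
)
from srnatim import nearest_neighbor as nn
from srnatim.duplex import apply_site_filters, suboptimal_duplexes


class TestStartCodonBonus:
    @pytest.mark.parametrize(
        "codon,expected", [("AUG", -1.19), ("GUG", -0.075), ("UUG", 0.0), ("CUG", 0.0)]
    )
    def test_values(self, codon, expected):
        assert start_codon_bonus(codon) == expected

    def test_dna_codon_is_normalized(self):
        assert start_codon_bonus("ATG") == -1.19

    def test_bad_codon(self):
        with pytest.raises(ValueError):
            start_codon_bonus("AXG")


def oracle_best_duplex(a: str, b: str) -> float:
    """Exhaustive minimum duplex energy by forward chain enumeration.

    Anchored on the FIRST pair and extended pair by pair (the
    implementation's DP is anchored on the last pair), enumerating every
    gap combination up to the loop cap.  Only for tiny inputs.
    """

    @lru_cache(maxsize=None)
    def best_from(i: int, j: int) -> float:
        best = 0.0  # chain may terminate at (i, j)
        for i2 in range(i + 1, min(len(a), i + 2 + nn.MAX_LOOP_SIDE)):
            ga = i2 - i - 1
            for j2 in range(j - 1, max(-1, j - 2 - nn.MAX_LOOP_SIDE), -1):
                if not nn.can_pair(a[i2], b[j2]):
                    continue
                gb = j - j2 - 1
                if ga == 0 and gb == 0:
                    cost = nn.stack_energy((a[i], b[j]), (a[i2], b[j2]))
                else:
                    cost = nn.LOOP_OPEN + nn.LOOP_PER_NT * (ga + gb)
                best = min(best, cost + best_from(i2, j2))
        return best

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            if nn.can_pair(a[i], b[j]):
                best = min(best, nn.DUPLEX_INIT + best_from(i, j))
    return best


ANTI_RRS = "UCACCUCCUU"
RRS_MOTIF = nn.reverse_complement(ANTI_RRS)  # AAGGAGGUGA


class TestDuplexFold:
    def test_matches_exhaustive_enumeration_on_planted_motif(self):
        a = "AACA" + RRS_MOTIF + "ACAAACA"
        hit = duplex_fold(a, ANTI_RRS)
        assert hit is not None
        assert hit.energy == pytest.approx(oracle_best_duplex(a, ANTI_RRS), abs=1e-9)
        assert (hit.a_start, hit.a_end) == (4, 13)

    @pytest.mark.parametrize(
        "a,b",
        [
            ("AAACAAGGUGAACAA", ANTI_RRS),
            ("ACGUACGUACGUACGUACGU", "UGCAUGCA"),
            ("AAUUCCGGAAUUCCGG", "CCGGAAUU"),
        ],
    )
    def test_matches_exhaustive_enumeration_random_cases(self, a, b):
        hit = duplex_fold(a, b)
        expected = oracle_best_duplex(a, b)
        if hit is None:
            assert expected >= 0.0
        else:
            assert hit.energy == pytest.approx(expected, abs=1e-9)

    def test_no_complementarity_gives_no_hit(self):
        assert duplex_fold("A" * 30, "AAAAAAA") is None

    def test_tie_break_most_upstream(self):
        a = "AA" + RRS_MOTIF + "AAAA" + RRS_MOTIF + "AA"
        hit = duplex_fold(a, ANTI_RRS)
        assert hit.a_start == 2  # identical motifs: 5'-most wins

    def test_reported_pairs_are_complementary(self):
        a = "AACA" + RRS_MOTIF + "ACAAACA"
        hit = duplex_fold(a, ANTI_RRS)
        for i, j in hit.pairs:
            assert nn.can_pair(a[i], ANTI_RRS[j])


class TestSuboptimal:
    def test_two_separate_motifs_give_two_sites(self):
        a = "AA" + RRS_MOTIF + "AACAACAACAACAA" + RRS_MOTIF + "AA"
        hits = suboptimal_duplexes(a, ANTI_RRS, energy_cutoff=-5.0)
        starts = sorted(h.a_start for h in hits)
        assert starts == [2, 26]

    def test_overlapping_tracebacks_are_deduplicated(self):
        a = "AACA" + RRS_MOTIF + "ACAAACA"
        hits = suboptimal_duplexes(a, ANTI_RRS, energy_cutoff=-1.0)
        # one physical site: every retained hit is the same region or a
        # clearly distinct weaker one, never a >50%-overlapping clone
        for h in hits:
            others = [k for k in hits if k is not h]
            for k in others:
                ov = min(h.a_end, k.a_end) - max(h.a_start, k.a_start) + 1
                shorter = min(h.a_end - h.a_start, k.a_end - k.a_start) + 1
                same_b = min(h.b_end, k.b_end) >= max(h.b_start, k.b_start)
                assert not (ov > 0.5 * shorter and same_b)


def _transcript_with_motif(utr: int = 40) -> Transcript:
    # RRS motif ending 3 nt before the start codon, pairing-poor elsewhere
    seq = "AC" * ((utr - 13) // 2 + 1)
    seq = seq[: utr - 13] + RRS_MOTIF + "ACA" + "AUG" + "CA" * 10
    return Transcript("m1", seq, utr)


class TestFindRRS:
    def test_planted_motif_located_with_codon_bonus(self, backend):
        t = _transcript_with_motif()
        site = find_rrs(t, backend)
        assert site is not None
        assert site.rrs == RelativeInterval(-13, -4)
        assert site.rds.rel_start == -13
        assert site.rds.length == 30
        raw = duplex_fold(RRS_MOTIF, ANTI_RRS).energy
        assert site.delta_G_R == pytest.approx(raw + (-1.19), abs=1e-9)

    def test_poly_a_transcript_has_no_rrs(self, backend):
        t = Transcript("polyA", "A" * 60 + "AUG" + "A" * 10, 60)
        assert find_rrs(t, backend) is None

    def test_rds_is_exactly_30_nt(self):
        with pytest.raises(ValueError):
            RibosomeSite(
                RelativeInterval(-12, -3), RelativeInterval(-12, +17), -5.0
            )


def _site(start: int, end: int, dG: float) -> BindingSite:
    return BindingSite(
        mrna=RelativeInterval(start, end),
        srna_start=1,
        srna_end=10,
        delta_G_S=dG,
        delta_G_duplex=dG,
        open_energy_mrna=0.0,
        open_energy_srna=0.0,
    )


class TestSiteFilters:
    """Boundary semantics: cutoffs are inclusive, just-misses are excluded."""

    def test_energy_boundary(self):
        kept = apply_site_filters([_site(-60, -45, -7.0), _site(-80, -65, -6.9)])
        assert [s.delta_G_S for s in kept] == [-7.0]

    def test_length_boundary(self):
        ten = _site(-60, -51, -12.0)  # exactly 10 nt
        nine = _site(-80, -72, -12.0)  # 9 nt
        assert apply_site_filters([ten, nine]) == [ten]

    def test_window_boundaries_inclusive(self):
        at_5p = _site(-150, -141, -12.0)
        beyond_5p = _site(-151, -142, -12.0)
        at_3p = _site(+11, +20, -12.0)
        beyond_3p = _site(+12, +21, -12.0)
        kept = apply_site_filters([at_5p, beyond_5p, at_3p, beyond_3p])
        assert kept == [at_5p, at_3p]

    def test_filters_are_monotone_in_their_thresholds(self):
        sites = [_site(-100 + 7 * k, -91 + 7 * k + k, -6.0 - k) for k in range(6)]
        base = set(
            (s.mrna.rel_start, s.mrna.rel_end)
            for s in apply_site_filters(sites, energy_cutoff=-9.0, min_len=12)
        )
        relaxed_e = set(
            (s.mrna.rel_start, s.mrna.rel_end)
            for s in apply_site_filters(sites, energy_cutoff=-7.0, min_len=12)
        )
        relaxed_l = set(
            (s.mrna.rel_start, s.mrna.rel_end)
            for s in apply_site_filters(sites, energy_cutoff=-9.0, min_len=10)
        )
        assert base <= relaxed_e and base <= relaxed_l


class TestFindSrnaSites:
    def test_planted_perfect_complement_is_recovered(self, backend):
        # 14-nt perfect complement centered near -60 in a pairing-poor UTR
        utr = "AC" * 80
        plant = "GGAUGUGGAUGUGG"
        pos = 160 - 67  # relative -67..-54
        seq = utr[:pos] + plant + utr[pos + 14 : 160] + "AUG" + "CA" * 10
        t = Transcript("p1", seq, 160)
        srna = nn.reverse_complement(plant)
        sites = find_srna_sites(srna, t, backend)
        assert len(sites) >= 1
        best = sites[0]
        assert best.mrna == RelativeInterval(-67, -54)
        assert best.srna_start == 1 and best.srna_end == 14
        assert best.delta_G_S <= -7.0

    def test_no_sites_is_a_valid_empty_result(self, backend):
        t = Transcript("p2", "AC" * 80 + "AUG" + "CA" * 10, 160)
        assert find_srna_sites("A" * 20, t, backend) == []


class TestOverlaps:
    @pytest.mark.parametrize(
        "site_iv,expected",
        [
            ((-12, +18), True),
            ((-133, -94), False),
            ((+15, +30), True),  # single shared position
            ((-40, -16), False),
        ],
    )
    def test_interval_intersection(self, site_iv, expected):
        rds = RibosomeSite(
            RelativeInterval(-15, -6), RelativeInterval(-15, +15), -8.0
        )
        site = _site(site_iv[0], site_iv[1], -10.0)
        assert overlaps(rds, site) is expected
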