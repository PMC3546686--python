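"""Partition-function accessibility vs exhaustive enumeration; RDS exposure."""

from __future__ import annotations

import math
import random

import pytest

from srnatim import (
    RelativeInterval,
    RibosomeSite,
    Transcript,
    find_rrs,
    opening_energy_to_probability,
    probability_to_opening_energy,
    rds_exposure,
    unpaired_probability,
    unpaired_probability_brute,
)
from srnatim.duplex import BindingSite
from srnatim.nearest_neighbor import reverse_complement, rt_kcal


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("AUGC", weights=[3, 3, 1, 1], k=n))


class TestPartitionFunction:
    def test_unstructured_sequence_is_fully_accessible(self):
        assert unpaired_probability("AAAAAAAAAA", (2, 7)) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_unconstrained(self, seed):
        rng = random.Random(seed)
        seq = _random_seq(rng, rng.randint(12, 22))
        lo = rng.randrange(len(seq) - 4)
        hi = min(len(seq) - 1, lo + rng.randint(1, 5))
        p = unpaired_probability(seq, (lo, hi))
        q = unpaired_probability_brute(seq, (lo, hi))
        assert p == pytest.approx(q, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6, 12))
    def test_matches_enumeration_constrained(self, seed):
        rng = random.Random(seed)
        seq = _random_seq(rng, rng.randint(12, 22))
        forb = set(rng.sample(range(len(seq)), 3))
        lo = rng.randrange(len(seq) - 4)
        hi = min(len(seq) - 1, lo + 3)
        p = unpaired_probability(seq, (lo, hi), forb)
        q = unpaired_probability_brute(seq, (lo, hi), forb)
        assert p == pytest.approx(q, abs=1e-9)

    def test_hairpin_stem_interval_matches_enumeration(self):
        # designed 20-nt hairpin: GC stem with an AAAA loop
        seq = "GGCGGC" + "AAAA" + reverse_complement("GGCGGC") + "AUCA"
        p = unpaired_probability(seq, (0, 5))
        q = unpaired_probability_brute(seq, (0, 5))
        assert p == pytest.approx(q, abs=1e-9)
        assert p < 0.5  # stem is mostly formed

    def test_forbidding_the_partner_strand_frees_the_interval(self):
        seq = "GGCGGC" + "AAAA" + reverse_complement("GGCGGC") + "AUCA"
        free = unpaired_probability(seq, (0, 5))
        released = unpaired_probability(seq, (0, 5), forbidden_bases=range(10, 16))
        assert released > free

    def test_constraint_inside_interval_never_decreases_probability(self):
        rng = random.Random(99)
        for _ in range(5):
            seq = _random_seq(rng, 18)
            lo, hi = 5, 10
            base = unpaired_probability(seq, (lo, hi))
            constrained = unpaired_probability(seq, (lo, hi), forbidden_bases={7})
            assert constrained >= base - 1e-12

    def test_scale_invariance_of_rescaled_recursion(self):
        from srnatim.accessibility import _log_partition

        seq = "GGCGGCAAAAGCCGCCAUCA"
        zs = [
            _log_partition(seq, frozenset(), None, 310.15, s) for s in (1.0, 4.0, 32.0)
        ]
        assert max(zs) - min(zs) < 1e-9

    def test_max_span_limits_pairing(self):
        # homopolymer arms cannot pair within themselves; the only pairs
        # cross the 30-nt spacer and exceed the span limit
        seq = "G" * 6 + "A" * 30 + "C" * 6
        wide = unpaired_probability(seq, (0, 5))
        narrow = unpaired_probability(seq, (0, 5), max_span=20)
        assert narrow == 1.0
        assert wide < 1.0

    def test_no_underflow_for_large_opening_energies(self):
        # 60 kcal/mol opening energy ~ P = 4e-43: must stay positive
        p = opening_energy_to_probability(60.0)
        assert 0.0 < p < 1e-40
        assert probability_to_opening_energy(p) == pytest.approx(60.0, rel=1e-12)

    def test_empty_interval_is_an_error(self):
        with pytest.raises(ValueError):
            unpaired_probability("ACGUACGU", (5, 3))


class TestOpeningEnergyConversions:
    def test_zero_energy_full_exposure(self):
        assert opening_energy_to_probability(0.0) == 1.0

    def test_rt_ln2_gives_half(self):
        assert opening_energy_to_probability(rt_kcal() * math.log(2)) == pytest.approx(0.5)

    def test_round_trip_through_reported_scale(self):
        # the scale of measured RDS exposures: P ~ 1.2e-5
        dE = probability_to_opening_energy(1.2e-5)
        assert dE == pytest.approx(-rt_kcal() * math.log(1.2e-5), rel=1e-12)
        assert opening_energy_to_probability(dE) == pytest.approx(1.2e-5, rel=1e-12)

    def test_negative_opening_energy_rejected(self):
        with pytest.raises(ValueError):
            opening_energy_to_probability(-0.1)


def _rds_for(t: Transcript) -> RibosomeSite:
    return RibosomeSite(
        RelativeInterval(-12, -3), RelativeInterval(-12, +18), -10.0
    )


class TestRdsExposure:
    def test_pairing_poor_window_is_nearly_fully_exposed(self, backend):
        # in an all-A background only the start codon's U can pair (with
        # single A partners), so the RDS stays almost fully exposed
        t = Transcript("u", "A" * 100 + "AUG" + "A" * 30, 100)
        res = rds_exposure(t, _rds_for(t), None, backend)
        assert res.probability > 0.8
        assert res.opening_energy < 0.2
        assert not res.constrained

    def test_releasing_hairpin_raises_exposure(self, backend):
        # hairpin: upstream arm pairs the RDS core; an sRNA site covering
        # the upstream arm frees the RDS (the activation mechanism)
        arm = "GCGGCUGCGG"
        # arm at abs 40..49 (rel -40..-31); its complement at abs 68..77
        # (rel -12..-3), i.e. over the RDS start; AUG at abs 80
        seq = ("AC" * 20 + arm + "AC" * 9 + reverse_complement(arm)
               + "AC" + "AUG" + "CA" * 15)
        t = Transcript("h", seq, 80)
        rds = _rds_for(t)
        free = rds_exposure(t, rds, None, backend)
        site = BindingSite(
            mrna=RelativeInterval(-40, -31),  # the upstream arm
            srna_start=1, srna_end=10, delta_G_S=-15.0, delta_G_duplex=-15.0,
            open_energy_mrna=0.0, open_energy_srna=0.0,
        )
        constrained = rds_exposure(t, rds, site, backend)
        assert constrained.constrained
        assert constrained.probability > free.probability

    def test_site_inside_rds_never_lowers_exposure(self, backend):
        rng = random.Random(5)
        seq = _random_seq(rng, 77) + "AUG" + _random_seq(rng, 20)
        t = Transcript("r", seq, 77)
        rds = _rds_for(t)
        free = rds_exposure(t, rds, None, backend)
        site = BindingSite(
            mrna=RelativeInterval(-8, +3), srna_start=1, srna_end=12,
            delta_G_S=-10.0, delta_G_duplex=-10.0,
            open_energy_mrna=0.0, open_energy_srna=0.0,
        )
        constrained = rds_exposure(t, rds, site, backend)
        assert constrained.probability >= free.probability - 1e-12

    def test_k_open_consistent_with_probability(self, backend):
        t = Transcript("u", "AC" * 50 + "AUG" + "CA" * 15, 100)
        res = rds_exposure(t, _rds_for(t), None, backend)
        if res.probability < 1.0:
            assert res.K_open == pytest.approx(
                res.probability / (1 - res.probability)
            )
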