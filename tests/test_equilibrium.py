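"""Equilibrium solvers: limits, identities, oracle cross-validation, alpha."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import bisect

from srnatim import (
    EquilibriumParams,
    alpha_for,
    constant_to_probability,
    energy_to_constant,
    fold_change,
    oracle_solve,
    probability_to_constant,
    solve,
    solve_no_srna,
    solve_nonoverlap,
    solve_overlap,
)
from srnatim.nearest_neighbor import rt_kcal

RT = rt_kcal()


def random_params(rng, topology):
    return EquilibriumParams(
        K_R=math.exp(rng.uniform(0, 40) / RT),
        K_S=math.exp(rng.uniform(0, 40) / RT),
        P_EF=10 ** rng.uniform(-6, 0),
        m_T=rng.uniform(1, 1e5),
        s_T=rng.uniform(0.1, 1e5),
        r_T=rng.uniform(1, 1e5),
        n=rng.uniform(1, 100),
        P_ES=10 ** rng.uniform(-6, 0) if topology == "nonoverlap" else None,
        topology=topology,
    )


class TestConversions:
    @pytest.mark.parametrize(
        "dG,expected", [(0.0, 1.0), (-RT * math.log(10), 10.0)]
    )
    def test_energy_to_constant(self, dG, expected):
        assert energy_to_constant(dG) == pytest.approx(expected, rel=1e-12)

    def test_strong_binding_constant_from_measured_energy(self):
        # a strong measured sRNA-mRNA hybridization energy
        assert energy_to_constant(-22.9) == pytest.approx(
            math.exp(22.9 / RT), rel=1e-12
        )

    @pytest.mark.parametrize("K,expected", [(1.0, 0.5), (0.0, 0.0), (3.0, 0.75)])
    def test_constant_to_probability(self, K, expected):
        assert constant_to_probability(K) == expected

    def test_k_p_round_trip(self):
        for K in (1e-8, 0.5, 1.0, 42.0, 1e3):
            assert probability_to_constant(
                constant_to_probability(K)
            ) == pytest.approx(K, rel=1e-12)


class TestBaseline:
    def test_weak_binding_limit_is_zero(self):
        assert solve_no_srna(1e-30, 1e-6, 100, 11400, 20) == pytest.approx(0.0, abs=1e-12)

    def test_saturation_limit(self):
        m_R = solve_no_srna(1e30, 1.0, 100, 11400, 20)
        assert m_R == pytest.approx(min(100, 11400 / 20), rel=1e-9)

    def test_matches_bisection_oracle(self):
        K_R, P_EF, m_T, r_T, n = 1e3, 1e-2, 100.0, 11400.0, 20.0

        def f(m_R):
            return K_R * P_EF * (m_T - m_R) * (r_T - n * m_R) - m_R

        ref = bisect(f, 0.0, min(m_T, r_T / n), xtol=1e-13)
        assert solve_no_srna(K_R, P_EF, m_T, r_T, n) == pytest.approx(ref, rel=1e-10)


class TestSolverVsOracle:
    """The eliminated-polynomial solvers against the un-eliminated system."""

    @pytest.mark.parametrize("topology", ["overlap", "nonoverlap"])
    def test_random_instances_agree_in_every_species(self, topology):
        rng = np.random.default_rng(7)
        totals = {
            "m_F": "m_T", "m_S": "m_T", "m_R": "m_T", "m_SR": "m_T",
            "m_TA": "m_T", "s_F": "s_T", "r_F": "r_T",
        }
        for i in range(60):
            p = random_params(rng, topology)
            a = solve(p)
            b = oracle_solve(p, np.random.default_rng(i))
            for name, tot in totals.items():
                va, vb = getattr(a, name), getattr(b, name)
                if max(abs(va), abs(vb)) < 1e-15 * getattr(p, tot):
                    continue  # both zero at working precision
                assert va == pytest.approx(vb, rel=1e-8), (name, p)

    def test_oracle_reproduces_closed_form_without_srna(self):
        p = EquilibriumParams(
            K_R=1e4, K_S=1e6, P_EF=1e-3, m_T=200, s_T=0.0, r_T=11400, n=20
        )
        m_R = solve_no_srna(p.K_R, p.P_EF, p.m_T, p.r_T, p.n)
        assert oracle_solve(p).m_R == pytest.approx(m_R, rel=1e-10)


class TestMassConservation:
    @pytest.mark.parametrize("topology", ["overlap", "nonoverlap"])
    def test_residuals_below_tolerance(self, topology):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = random_params(rng, topology)
            res = solve(p)
            assert abs(res.residuals["mrna_balance"]) <= 1e-9 * max(p.m_T, 1)
            assert abs(res.residuals["srna_balance"]) <= 1e-9 * max(p.s_T, 1)
            assert abs(res.residuals["ribosome_balance"]) <= 1e-9 * max(p.r_T, 1)
            for name in ("m_F", "m_S", "m_R", "m_SR"):
                assert -1e-9 * p.m_T <= getattr(res, name) <= p.m_T * (1 + 1e-9)


class TestLimits:
    def test_no_srna_alpha_is_exactly_one_overlap(self):
        p = EquilibriumParams(K_R=1e3, K_S=1e6, P_EF=1e-2,
                              m_T=100, s_T=0.0, r_T=11400, n=20)
        assert alpha_for(p)[0] == 1.0

    def test_no_srna_alpha_is_exactly_one_nonoverlap(self):
        p = EquilibriumParams(K_R=1e3, K_S=1e6, P_EF=1e-2, m_T=100, s_T=0.0,
                              r_T=11400, n=20, P_ES=1e-2, topology="nonoverlap")
        assert alpha_for(p)[0] == 1.0

    def test_unchanged_accessibility_means_no_effect(self):
        # sRNA binding that leaves RDS exposure unchanged leaves activity
        # unchanged, because the doubly bound complex still initiates
        for P in (1e-5, 1e-3, 0.2):
            p = EquilibriumParams(K_R=1e5, K_S=1e8, P_EF=P, m_T=150, s_T=100,
                                  r_T=11400, n=20, P_ES=P, topology="nonoverlap")
            assert abs(abs(alpha_for(p)[0]) - 1.0) < 1e-9

    def test_total_sequestration_limit(self):
        p = EquilibriumParams(K_R=1e3, K_S=1e25, P_EF=1e-2, m_T=100, s_T=200,
                              r_T=11400, n=20)
        assert solve_overlap(p).m_R < 1e-6

    def test_overlap_alpha_non_increasing_in_s_t(self):
        alphas = []
        for s_T in np.linspace(0, 300, 50):
            p = EquilibriumParams(K_R=1e6, K_S=1e12, P_EF=1e-3, m_T=150,
                                  s_T=float(s_T), r_T=11400, n=20)
            alphas.append(alpha_for(p)[0])
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(alphas, alphas[1:]))

    def test_overlap_alpha_non_increasing_in_k_s(self):
        alphas = []
        for dG in np.linspace(0, -30, 30):
            p = EquilibriumParams(K_R=1e6, K_S=energy_to_constant(float(dG)),
                                  P_EF=1e-3, m_T=150, s_T=100, r_T=11400, n=20)
            alphas.append(alpha_for(p)[0])
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(alphas, alphas[1:]))

    def test_nonoverlap_sign_matches_accessibility_change(self):
        for P_EF in np.logspace(-5, -0.5, 10):
            for P_ES in np.logspace(-5, -0.5, 10):
                p = EquilibriumParams(K_R=1e6, K_S=1e10, P_EF=float(P_EF),
                                      m_T=150, s_T=100, r_T=11400, n=20,
                                      P_ES=float(P_ES), topology="nonoverlap")
                alpha = alpha_for(p)[0]
                if abs(P_ES - P_EF) < 1e-12:
                    assert abs(abs(alpha) - 1.0) < 1e-9
                elif P_ES > P_EF:
                    assert alpha >= 1.0 - 1e-9
                else:
                    assert alpha <= -1.0 + 1e-9 or abs(alpha - 1.0) < 1e-9


class TestFoldChange:
    @pytest.mark.parametrize(
        "with_,without,expected", [(10, 5, 2.0), (5, 10, -2.0), (7, 7, 1.0)]
    )
    def test_signed_ratio(self, with_, without, expected):
        assert fold_change(with_, without) == pytest.approx(expected)

    def test_magnitude_at_least_one(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b = rng.uniform(1e-6, 1e4, 2)
            assert abs(fold_change(a, b)) >= 1.0

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ValueError, match="baseline inactive"):
            fold_change(5.0, 0.0)

    def test_vanished_activity_maps_to_minus_infinity(self):
        assert fold_change(0.0, 5.0) == -math.inf
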