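"""Parameter types, mutation kernel, and payoff computations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pggchoice import (
    GameEnsemble,
    GroupComposition,
    MutationRates,
    StrategyGame,
    expected_payoff,
    expected_payoffs,
    group_payoffs,
    mutation_kernel,
)
from pggchoice.io import params_from_yaml, params_to_yaml

from conftest import random_simplex


class TestGameEnsemble:
    def test_positivity_guard_rejects_unprofitable_worst_case(self):
        # a lone cooperator among g-1 defectors would earn pi0 - c + c*r/g <= 0
        with pytest.raises(ValueError, match="positivity"):
            GameEnsemble(n=1, r=(2.0,), g=10, c=1.0, pi0=0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=0, r=(), g=10),
            dict(n=2, r=(4.4,), g=10),
            dict(n=1, r=(3.0,), g=1),
            dict(n=1, r=(-1.0,), g=5),
            dict(n=1, r=(3.0,), g=5, c=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GameEnsemble(**kwargs)

    def test_yaml_round_trip_is_exact(self, fig1_ensemble, fig1_rates):
        text = params_to_yaml(fig1_ensemble, fig1_rates)
        ens, rates = params_from_yaml(text)
        assert ens == fig1_ensemble
        assert rates == fig1_rates


class TestMutationRates:
    def test_bounds(self):
        with pytest.raises(ValueError):
            MutationRates(nu_s=1.0, nu_g=0.0)
        with pytest.raises(ValueError):
            MutationRates(nu_s=0.0, nu_g=-0.1)

    def test_symmetric_constructor(self):
        assert MutationRates.symmetric(1e-3) == MutationRates(1e-3, 1e-3)


class TestMutationKernel:
    def test_no_mutation_gives_identity(self):
        for n in (1, 2, 3, 5):
            k = mutation_kernel(MutationRates(0.0, 0.0), n)
            np.testing.assert_array_equal(k, np.eye(2 * n))

    def test_two_resource_closed_forms(self):
        nu = 1e-3
        k = mutation_kernel(MutationRates.symmetric(nu), 2)
        # flattened order C1 C2 D1 D2: diagonal, game-only, strategy-only, double
        assert k[0, 0] == pytest.approx(0.998001, abs=0)
        assert k[0, 1] == pytest.approx(nu - nu**2)
        assert k[0, 2] == pytest.approx(nu - nu**2)
        assert k[0, 3] == pytest.approx(nu**2)

    def test_three_resource_uniform_split(self):
        k = mutation_kernel(MutationRates(nu_s=0.2, nu_g=0.3), 3)
        np.testing.assert_allclose(k.sum(axis=1), 1.0, atol=1e-12)
        # same strategy, one specific other game: (1 - 0.2) * 0.3 / 2
        assert k[0, 1] == pytest.approx(0.12)

    @settings(derandomize=True, max_examples=50)
    @given(
        nu_s=st.floats(0, 0.999),
        nu_g=st.floats(0, 0.999),
        n=st.integers(1, 6),
    )
    def test_rows_sum_to_one(self, nu_s, nu_g, n):
        k = mutation_kernel(MutationRates(nu_s, nu_g), n)
        assert (k >= 0).all()
        np.testing.assert_allclose(k.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_under_game_relabeling(self):
        n = 4
        k = mutation_kernel(MutationRates(0.1, 0.25), n)
        perm = np.array([2, 0, 3, 1])
        full = np.concatenate([perm, perm + n])  # relabel games in both strategy blocks
        np.testing.assert_allclose(k[np.ix_(full, full)], k, atol=0)

    def test_single_resource_ignores_game_mutation(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pggchoice.model"):
            k = mutation_kernel(MutationRates(nu_s=0.1, nu_g=0.5), 1)
        assert "ignored" in caplog.text
        np.testing.assert_allclose(k, [[0.9, 0.1], [0.1, 0.9]])


class TestGroupPayoffs:
    def test_full_cooperation_yields_r(self):
        ens = GameEnsemble(n=1, r=(4.4,), g=10)
        comp = GroupComposition(np.array([[10], [0]]))
        pay = group_payoffs(comp, ens)
        assert pay[0, 0] == pytest.approx(4.4)  # 1*4.4*10/10 - 1 + 1
        assert np.isnan(pay[1, 0])  # no defectors present

    def test_defectors_alone_earn_base_payoff(self):
        ens = GameEnsemble(n=2, r=(4.4, 2.8), g=3)
        comp = GroupComposition(np.array([[0, 0], [3, 0]]))
        pay = group_payoffs(comp, ens)
        assert pay[1, 0] == pytest.approx(1.0)

    def test_mixed_subgroup(self):
        ens = GameEnsemble(n=1, r=(2.8,), g=2)
        comp = GroupComposition(np.array([[1], [1]]))
        pay = group_payoffs(comp, ens)
        assert pay[0, 0] == pytest.approx(1.4)  # 2.8/2 - 1 + 1
        assert pay[1, 0] == pytest.approx(2.4)  # 2.8/2 + 1

    def test_wrong_total_rejected(self):
        ens = GameEnsemble(n=1, r=(3.0,), g=5)
        with pytest.raises(ValueError, match="group size"):
            group_payoffs(GroupComposition(np.array([[2], [2]])), ens)


def enumerate_expected_payoff(rho, ens, strategy, j):
    """Independent oracle: exhaustive enumeration over mate compositions
    using plain python combinatorics (no shared code with the closed form)."""
    g, r = ens.g, ens.r[j]
    pC, pD = rho[0, j], rho[1, j]
    pOther = 1.0 - pC - pD
    total = 0.0
    for nC in range(g):
        for nD in range(g - nC):
            rest = g - 1 - nC - nD
            coef = (
                math.factorial(g - 1)
                // (math.factorial(nC) * math.factorial(nD) * math.factorial(rest))
            )
            prob = coef * pC**nC * pD**nD * pOther**rest
            if strategy == "C":
                pay = ens.c * r * (1 + nC) / (1 + nC + nD) - ens.c + ens.pi0
            else:
                pay = ens.c * r * nC / (1 + nC + nD) + ens.pi0
            total += prob * pay
    return total


class TestExpectedPayoff:
    def test_everyone_cooperating_in_one_resource(self):
        ens = GameEnsemble(n=2, r=(4.4, 2.8), g=10)
        rho = np.zeros((2, 2))
        rho[0, 0] = 1.0
        assert expected_payoff(rho, StrategyGame("C", 1), ens) == pytest.approx(4.4)

    def test_all_defectors_degenerate_state(self):
        ens = GameEnsemble(n=2, r=(4.4, 2.8), g=10)
        rho = np.zeros((2, 2))
        rho[1, 0] = 1.0
        assert expected_payoff(rho, StrategyGame("D", 1), ens) == pytest.approx(1.0)
        # a measure-zero cooperator joining 9 defectors: 4.4/10 - 1 + 1
        assert expected_payoff(rho, StrategyGame("C", 1), ens) == pytest.approx(0.44)

    def test_off_simplex_state_rejected(self):
        ens = GameEnsemble(n=2, r=(4.4, 2.8), g=10)
        with pytest.raises(ValueError, match="simplex"):
            expected_payoff(np.full((2, 2), 0.3), StrategyGame("C", 1), ens)

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(1, 4))
            g = int(rng.integers(2, 21))
            ens = GameEnsemble(n=n, r=tuple(rng.uniform(0.5, 12, n)), g=g)
            rho = random_simplex(rng, n)
            pi = expected_payoffs(rho, ens)
            for j in range(n):
                assert pi[0, j] == pytest.approx(
                    enumerate_expected_payoff(rho, ens, "C", j), rel=1e-12
                )
                assert pi[1, j] == pytest.approx(
                    enumerate_expected_payoff(rho, ens, "D", j), rel=1e-12
                )

    def test_defector_advantage_identity(self):
        # pi_D - pi_C = c * (1 - r * E[1/subgroup size]) for the same state
        rng = np.random.default_rng(11)
        for _ in range(5):
            g = int(rng.integers(2, 15))
            ens = GameEnsemble(n=2, r=tuple(rng.uniform(1.0, 9.0, 2)), g=g)
            rho = random_simplex(rng, 2)
            pi = expected_payoffs(rho, ens)
            for j in range(2):
                pC, pD = rho[0, j], rho[1, j]
                inv_size = enumerate_inverse_size(pC, pD, g)
                expect = ens.c * (1.0 - ens.r[j] * inv_size)
                assert pi[1, j] - pi[0, j] == pytest.approx(expect, abs=1e-12)

    def test_cooperation_dominates_when_r_exceeds_group_size(self):
        g = 10
        ens = GameEnsemble(n=2, r=(g + 2, 3.0), g=g)
        rng = np.random.default_rng(3)
        for _ in range(10):
            rho = random_simplex(rng, 2)
            pi = expected_payoffs(rho, ens)
            assert pi[0, 0] > pi[1, 0]

    def test_payoffs_positive_under_guard(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = int(rng.integers(2, 12))
            ens = GameEnsemble(n=2, r=tuple(rng.uniform(0.2, 11, 2)), g=g)
            rho = random_simplex(rng, 2)
            assert (expected_payoffs(rho, ens) > 0).all()


def enumerate_inverse_size(pC, pD, g):
    """E[1 / (1 + nC + nD)] over the focal's mate composition."""
    total = 0.0
    for nC in range(g):
        for nD in range(g - nC):
            rest = g - 1 - nC - nD
            coef = (
                math.factorial(g - 1)
                // (math.factorial(nC) * math.factorial(nD) * math.factorial(rest))
            )
            total += coef * pC**nC * pD**nD * (1 - pC - pD) ** rest / (1 + nC + nD)
    return total
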