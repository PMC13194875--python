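"""Reaction network structure, Arrhenius law, right-hand side, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import roastkin as rk
from roastkin.kinetics import FIRST_ORDER_INDICES, SECOND_ORDER_INDICES, GAS_CONSTANT_KJ
from roastkin.species import CATALOGUE

NET = rk.coffee_network()


def _random_pars(rng, zero_ea=False):
    first = np.array(sorted(FIRST_ORDER_INDICES)) - 1
    k = np.empty(15)
    k[first] = rng.uniform(1e-5, 0.1, first.size)
    second = np.array(sorted(SECOND_ORDER_INDICES)) - 1
    k[second] = rng.uniform(1e-7, 1e-3, second.size)
    ea = np.zeros(15) if zero_ea else rng.uniform(40, 150, 15)
    return rk.KineticParameters(k, ea)


def _hand_rhs(c, k):
    """Independent transcription of the per-species balance laws."""
    CF, TA, AA, CA, TR, CGA, FA, LP, SUC, FRU, GLC, FAM, OTH = c
    (k1, k2, k3, k4, k5, k6, k7, k8, k9, k10, k11, k12, k13, k14, k15) = k
    return np.array([
        -k1 * CF,
        -k2 * TA,
        2 * k7 * FRU * FAM + 2 * k10 * GLC * FAM,
        -k11 * CA,
        -k12 * TR,
        -k13 * CGA,
        k13 * CGA - k14 * FA,
        -k15 * LP * FAM,
        -(k3 + k4) * SUC,
        k3 * SUC - k5 * FRU * FAM - k6 * FRU - k7 * FRU * FAM,
        k4 * SUC - k8 * GLC * FAM - k9 * GLC - k10 * GLC * FAM,
        -(k5 + k7) * FRU * FAM - (k8 + k10) * GLC * FAM - k15 * LP * FAM,
        k1 * CF + k2 * TA + 2 * k5 * FRU * FAM + k6 * FRU + 2 * k8 * GLC * FAM
        + k9 * GLC + k11 * CA + k12 * TR + k14 * FA + 2 * k15 * LP * FAM,
    ])


class TestNetworkStructure:
    def test_stoichiometric_columns_mass_balanced(self):
        S = NET.stoichiometric_matrix()
        assert S.shape == (13, 15)
        np.testing.assert_allclose(S.sum(axis=0), 0.0, atol=1e-14)

    def test_order_partition(self):
        first, second = NET.order_indices()
        assert first == FIRST_ORDER_INDICES
        assert second == SECOND_ORDER_INDICES
        # every second-order channel has free amino acids as co-precursor
        for r in NET.reactions:
            if r.order == "second":
                assert r.precursors[1] == "FAM"

    def test_duplication_factor_on_second_order_products(self):
        for r in NET.reactions:
            if r.order == "second":
                assert r.coefficients[r.product] == 2.0

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "network.json"
        NET.to_json(path)
        again = rk.ReactionNetwork.from_json(path)
        np.testing.assert_array_equal(
            again.stoichiometric_matrix(), NET.stoichiometric_matrix()
        )

    def test_unbalanced_reaction_rejected(self):
        from roastkin.kinetics import Reaction

        with pytest.raises(ValueError, match="sum"):
            Reaction(1, "first", ("CF",), "OTH", {"CF": -1.0, "OTH": 0.5})


class TestRhs:
    def test_matches_hand_written_balance_laws(self):
        rng = np.random.default_rng(0)
        pars = _random_pars(rng, zero_ea=True)  # zero E_a: rates == k_ref at any T
        for _ in range(20):
            c = rng.uniform(0, 10, 13)
            np.testing.assert_allclose(
                rk.rhs(c, 450.0, pars, NET), _hand_rhs(c, pars.k_ref), rtol=1e-12
            )

    def test_sucrose_inversion_example(self):
        k = np.zeros(15)
        k[2] = k[3] = 1e-3  # only SUC -> FRU and SUC -> GLC active
        pars = rk.KineticParameters(k, np.zeros(15))
        c = np.zeros(13)
        c[CATALOGUE.index("SUC")] = 7.5
        dc = rk.rhs(c, 400.0, pars, NET)
        assert dc[CATALOGUE.index("SUC")] == pytest.approx(-0.015)
        assert dc[CATALOGUE.index("FRU")] == pytest.approx(0.0075)
        assert dc[CATALOGUE.index("GLC")] == pytest.approx(0.0075)
        others = [j for j, code in enumerate(CATALOGUE.species)
                  if code not in ("SUC", "FRU", "GLC")]
        np.testing.assert_allclose(dc[others], 0.0, atol=1e-18)

    def test_zero_rates_give_zero_derivative(self):
        pars = rk.KineticParameters(np.zeros(15), np.zeros(15))
        np.testing.assert_array_equal(rk.rhs(np.ones(13), 500.0, pars, NET), np.zeros(13))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), T=st.floats(300, 550))
    def test_component_sum_vanishes(self, seed, T):
        rng = np.random.default_rng(seed)
        pars = _random_pars(rng)
        c = rng.uniform(0, 20, 13)
        assert abs(rk.rhs(c, T, pars, NET).sum()) < 1e-12

    def test_homogeneous_in_first_order_subnetwork(self):
        rng = np.random.default_rng(3)
        pars = _random_pars(rng)
        pars.k_ref[np.array(sorted(SECOND_ORDER_INDICES)) - 1] = 0.0
        c = rng.uniform(0, 10, 13)
        np.testing.assert_allclose(
            rk.rhs(3.0 * c, 480.0, pars, NET), 3.0 * rk.rhs(c, 480.0, pars, NET), rtol=1e-12
        )

    def test_negative_inputs_clamped(self):
        pars = _random_pars(np.random.default_rng(5))
        c = np.full(13, -1e-9)
        np.testing.assert_array_equal(rk.rhs(c, 450.0, pars, NET), np.zeros(13))


class TestArrhenius:
    def test_reference_temperature_identity(self):
        pars = _random_pars(np.random.default_rng(1))
        for i in (1, 8, 15):
            assert rk.arrhenius_rate(pars, i, pars.T_ref) == pytest.approx(
                pars.k_ref[i - 1], rel=1e-15
            )

    def test_zero_activation_energy_is_temperature_free(self):
        pars = rk.KineticParameters(np.full(15, 2e-3), np.zeros(15))
        for T in (300.0, 400.0, 520.0):
            assert rk.arrhenius_rate(pars, 4, T) == pytest.approx(2e-3, rel=1e-15)

    def test_reference_form_value(self):
        # frozen high-precision evaluation of the reference-form law at
        # k_ref = 2.5734e-2, E_a = 100.1612 kJ/mol, T = 400 K, T_ref = 473.15 K
        k = np.full(15, 2.5734e-2)
        ea = np.full(15, 100.1612)
        pars = rk.KineticParameters(k, ea, T_ref=473.15)
        assert rk.arrhenius_rate(pars, 14, 400.0) == pytest.approx(
            2.44502379050640e-4, rel=1e-12
        )

    def test_monotone_increasing_in_temperature(self):
        pars = _random_pars(np.random.default_rng(2))
        T = np.linspace(300, 550, 40)
        for i in range(1, 16):
            k = np.array([rk.arrhenius_rate(pars, i, t) for t in T])
            assert np.all(np.diff(k) > 0)

    def test_non_positive_temperature_rejected(self):
        pars = _random_pars(np.random.default_rng(4))
        with pytest.raises(ValueError):
            rk.arrhenius_rate(pars, 1, 0.0)


class TestAlphaReparameterisation:
    def test_zero_ea_alpha_equals_kref(self):
        pars = rk.KineticParameters(np.full(15, 3e-4), np.zeros(15))
        assert rk.alpha_from_reference(pars, 7) == pytest.approx(3e-4, rel=1e-15)

    def test_frozen_value(self):
        # k_ref = 1e-3, E_a = 100 kJ/mol, T_ref = 473.15 K
        pars = rk.KineticParameters(np.full(15, 1e-3), np.full(15, 100.0), T_ref=473.15)
        assert rk.alpha_from_reference(pars, 1) == pytest.approx(1.09688731518296e8, rel=1e-12)

    def test_roundtrip_with_standard_law(self):
        # alpha exp(-Ea/(RT)) must reproduce the reference form at any T
        pars = _random_pars(np.random.default_rng(6))
        rng = np.random.default_rng(7)
        for T in rng.uniform(300, 550, 10):
            for i in (2, 5, 14):
                alpha = rk.alpha_from_reference(pars, i)
                standard = alpha * np.exp(-pars.E_a[i - 1] / (GAS_CONSTANT_KJ * T))
                assert standard == pytest.approx(rk.arrhenius_rate(pars, i, T), rel=1e-12)


class TestClosedForms:
    def test_first_order_basics(self):
        assert rk.first_order_solution(5.0, 0.3, 0.0) == 0.0
        assert rk.first_order_solution(1.0, np.log(2.0), 1.0) == pytest.approx(0.5, rel=1e-14)
        assert rk.first_order_solution(5.0, 0.3, 1e4) == pytest.approx(5.0, rel=1e-12)
        t = np.linspace(0, 50, 200)
        B = np.array([rk.first_order_solution(2.0, 0.05, ti) for ti in t])
        assert np.all(np.diff(B) > 0) and np.all(B <= 2.0)

    def test_second_order_against_numerical_integration(self):
        # brute-force oracle: integrate the three-species bimolecular system
        A0, B0, k = 1.0, 2.0, 0.1
        sol = solve_ivp(
            lambda t, y: [-k * y[0] * y[1], -k * y[0] * y[1], k * y[0] * y[1]],
            (0.0, 5.0), [A0, B0, 0.0], rtol=1e-12, atol=1e-14, dense_output=True,
        )
        for t in (0.5, 2.0, 5.0):
            assert rk.second_order_solution(A0, B0, k, t) == pytest.approx(
                float(sol.sol(t)[2]), rel=1e-8
            )

    def test_second_order_limits(self):
        assert rk.second_order_solution(1.0, 2.0, 0.1, 0.0) == 0.0
        # limiting reactant exhausted
        assert rk.second_order_solution(1.0, 2.0, 0.1, 1e4) == pytest.approx(1.0, rel=1e-10)
        with pytest.raises(ValueError, match="distinct"):
            rk.second_order_solution(1.0, 1.0, 0.1, 2.0)

    def test_reversible_reduces_to_first_order(self):
        for t in (0.0, 1.3, 8.0):
            assert rk.reversible_solution(2.0, 0.4, 0.0, t) == pytest.approx(
                rk.first_order_solution(2.0, 0.4, t), rel=1e-14
            )

    def test_reversible_equilibrium(self):
        assert rk.reversible_solution(1.0, 0.5, 0.5, 1e4) == pytest.approx(0.5, rel=1e-12)
        assert rk.reversible_solution(3.0, 0.2, 0.6, 1e4) == pytest.approx(0.75, rel=1e-12)
        with pytest.raises(ValueError):
            rk.reversible_solution(1.0, 0.0, 0.0, 1.0)


class TestParameterValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rk.KineticParameters(np.full(15, -1e-3), np.zeros(15))

    def test_theta_roundtrip(self):
        pars = _random_pars(np.random.default_rng(8))
        again = rk.KineticParameters.from_theta(pars.theta, T_ref=pars.T_ref)
        np.testing.assert_array_equal(again.k_ref, pars.k_ref)
        np.testing.assert_array_equal(again.E_a, pars.E_a)
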