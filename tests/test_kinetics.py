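"""Rapid-equilibrium enzyme kinetics: free enzyme, rates, turnover."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from lobulepk.kinetics import (InteractionTable, competition_factor,
                               complex_concentrations, enzyme_rhs,
                               free_enzyme, metabolism_rates)


def single_pair_table(inv_km1=0.0, kcat=0.0, inv_ki=0.0, inv_kI=0.0,
                      kinact=0.0, fimax=1.0, inv_ec50=0.0,
                      vmax2=0.0, km2=1.0):
    return InteractionTable(
        kcat=[[kcat]], inv_Km1=[[inv_km1]], inv_Ki=[[inv_ki]],
        inv_KI=[[inv_kI]], kinact=[[kinact]], FImax=[[fimax]],
        inv_EC50=[[inv_ec50]], Vmax2=[vmax2], Km2=[km2])


class TestFreeEnzyme:
    def test_no_drug_leaves_pool_free(self):
        tbl = single_pair_table(inv_km1=1.0, inv_ki=0.5)
        assert free_enzyme(np.array([1.3]), np.array([0.0]), tbl) == pytest.approx(1.3)

    def test_single_pair_half_occupancy(self):
        # Km1 = 1 uM, other routes off, fuC = 1 uM -> denominator 2
        tbl = single_pair_table(inv_km1=1.0)
        assert free_enzyme(np.array([1.0]), np.array([1.0]), tbl) == pytest.approx(0.5)

    def test_three_drugs_brute_force_sum(self):
        inv_km1 = np.array([[0.5], [0.0], [2.0]])
        inv_ki = np.array([[0.0], [0.25], [1.0]])
        inv_kI = np.array([[0.1], [0.0], [0.0]])
        tbl = InteractionTable(
            kcat=np.zeros((3, 1)), inv_Km1=inv_km1, inv_Ki=inv_ki,
            inv_KI=inv_kI, kinact=np.zeros((3, 1)),
            FImax=np.ones((3, 1)), inv_EC50=np.zeros((3, 1)),
            Vmax2=np.zeros(3), Km2=np.ones(3))
        fuC = np.array([0.7, 1.9, 0.05])
        denom = 1.0 + sum((inv_km1 + inv_ki + inv_kI)[i, 0] * fuC[i]
                          for i in range(3))
        assert competition_factor(fuC, tbl)[0] == pytest.approx(denom, rel=1e-12)
        assert free_enzyme(np.array([1.0]), fuC, tbl)[0] == pytest.approx(1 / denom)


class TestMetabolismRates:
    def test_zero_concentration_zero_rate(self):
        tbl = single_pair_table(inv_km1=1.0, kcat=5.0, vmax2=3.0, km2=2.0)
        rate = metabolism_rates(np.array([0.0]), np.array([1.0]), tbl,
                                E0=np.array([4.0]))
        assert rate[0] == 0.0

    def test_linear_regime_first_order_constant(self):
        kcat, km1, e0, vmax2, km2 = 10.0, 2.0, 5.0, 3.0, 100.0
        tbl = single_pair_table(inv_km1=1 / km1, kcat=kcat, vmax2=vmax2, km2=km2)
        expected = kcat / km1 * e0 + vmax2 / km2
        for fuc in (1e-6, 1e-5):
            rate = metabolism_rates(np.array([fuc]), np.array([1.0]), tbl,
                                    E0=np.array([e0]))[0]
            assert rate / fuc == pytest.approx(expected, rel=1e-4)

    def test_saturation_approaches_vmax2(self):
        tbl = single_pair_table(vmax2=7.0, km2=0.5)
        rate = metabolism_rates(np.array([1e6]), np.array([1.0]), tbl,
                                E0=np.array([1.0]))[0]
        assert rate == pytest.approx(7.0, rel=1e-5)

    def test_monotone_in_concentration(self):
        tbl = single_pair_table(inv_km1=0.4, kcat=3.0, vmax2=2.0, km2=1.5)
        cs = np.logspace(-3, 3, 25)
        rates = [metabolism_rates(np.array([c]), np.array([1.0]), tbl,
                                  E0=np.array([2.0]))[0] for c in cs]
        assert np.all(np.diff(rates) > 0)

    def test_mutual_competitive_inhibition_emerges(self):
        """Two substrates of one enzyme automatically slow each other."""
        tbl = InteractionTable(
            kcat=[[5.0], [5.0]], inv_Km1=[[1.0], [1.0]],
            inv_Ki=np.zeros((2, 1)), inv_KI=np.zeros((2, 1)),
            kinact=np.zeros((2, 1)), FImax=np.ones((2, 1)),
            inv_EC50=np.zeros((2, 1)), Vmax2=np.zeros(2), Km2=np.ones(2))
        alone = metabolism_rates(np.array([0.5, 0.0]), np.array([1.0]), tbl,
                                 E0=np.array([1.0]))[0]
        together = metabolism_rates(np.array([0.5, 2.0]), np.array([1.0]), tbl,
                                    E0=np.array([1.0]))[0]
        assert together < alone


class TestEnzymeTurnover:
    def test_basal_fixed_point(self):
        tbl = single_pair_table()
        d = enzyme_rhs(np.array([1.0]), np.array([0.7]), tbl, kdeg=np.array([0.02]))
        assert d[0] == pytest.approx(0.0, abs=1e-15)
        # and relaxation toward 1 from elsewhere
        assert enzyme_rhs(np.array([0.5]), np.array([0.0]), tbl,
                          kdeg=np.array([0.02]))[0] > 0

    @pytest.mark.parametrize("fimax,ec50,fuc", [(3.0, 1.0, 1.0), (34.0, 0.54, 0.2)])
    def test_induction_steady_state_closed_form(self, fimax, ec50, fuc):
        """Constant inducer exposure: Etot -> 1 + (FImax-1) fuC/(EC50+fuC)."""
        kdeg = 0.0192
        tbl = single_pair_table(fimax=fimax, inv_ec50=1 / ec50)
        sol = solve_ivp(
            lambda t, y: enzyme_rhs(y, np.array([fuc]), tbl, np.array([kdeg])),
            (0.0, 20 / kdeg), [1.0], rtol=1e-10, atol=1e-12)
        expected = 1 + (fimax - 1) * fuc / (ec50 + fuc)
        assert sol.y[0, -1] == pytest.approx(expected, abs=1e-6)

    def test_half_potency_exposure_gives_half_maximal_induction(self):
        kdeg, fimax = 0.05, 9.0
        tbl = single_pair_table(fimax=fimax, inv_ec50=2.0)  # EC50 = 0.5
        sol = solve_ivp(
            lambda t, y: enzyme_rhs(y, np.array([0.5]), tbl, np.array([kdeg])),
            (0.0, 25 / kdeg), [1.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(1 + (fimax - 1) / 2, abs=1e-6)

    def test_mbi_steady_state_closed_form(self):
        """Constant inactivator: Etot -> kdeg / (kdeg + kinact fuC / (KI D))."""
        kdeg, kinact, kI, km1, fuc = 0.0192, 1.68, 1.15, 30.0, 0.3
        tbl = single_pair_table(inv_km1=1 / km1, inv_kI=1 / kI, kinact=kinact)
        d = 1 + fuc * (1 / km1 + 1 / kI)
        expected = kdeg / (kdeg + kinact * fuc / (kI * d))
        sol = solve_ivp(
            lambda t, y: enzyme_rhs(y, np.array([fuc]), tbl, np.array([kdeg])),
            (0.0, 20 / kdeg), [1.0], rtol=1e-10, atol=1e-13)
        assert sol.y[0, -1] == pytest.approx(expected, abs=1e-6)

    def test_pool_stays_positive(self):
        tbl = single_pair_table(inv_kI=1.0, kinact=50.0)
        sol = solve_ivp(
            lambda t, y: enzyme_rhs(y, np.array([10.0]), tbl, np.array([0.02])),
            (0.0, 500.0), [1.0], rtol=1e-8, atol=1e-12)
        assert np.all(sol.y > 0)


class TestComplexes:
    def test_zero_state_zero_complexes(self):
        tbl = single_pair_table(inv_km1=1.0, inv_ki=1.0, inv_kI=1.0)
        mets, inhs, mbis = complex_concentrations(
            np.array([0.0]), np.array([1.0]), tbl, E0=np.array([3.0]))
        assert mets[0, 0] == inhs[0, 0] == mbis[0, 0] == 0.0

    def test_equal_affinities_split_pool_in_four(self):
        # Km1 = Ki = KI = 3 uM and fuC = 3 uM: free and each complex equal
        tbl = single_pair_table(inv_km1=1 / 3, inv_ki=1 / 3, inv_kI=1 / 3)
        e0 = np.array([8.0])
        etot = np.array([1.0])
        efree = free_enzyme(etot, np.array([3.0]), tbl)
        assert efree[0] == pytest.approx(0.25)
        mets, inhs, mbis = complex_concentrations(
            np.array([3.0]), etot, tbl, E0=e0)
        assert mets[0, 0] == pytest.approx(e0[0] * efree[0])
        assert inhs[0, 0] == pytest.approx(e0[0] * efree[0])
        assert mbis[0, 0] == pytest.approx(e0[0] * efree[0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 50.0), min_size=2, max_size=2),
           st.floats(0.1, 3.0),
           st.lists(st.floats(0.01, 10.0), min_size=6, max_size=6))
    def test_total_enzyme_identity(self, fuc, etot, inv_consts):
        """Etot = Efree + sum of complexes / E0 for arbitrary states."""
        inv = np.array(inv_consts).reshape(2, 3)
        tbl = InteractionTable(
            kcat=np.zeros((2, 1)), inv_Km1=inv[:, :1], inv_Ki=inv[:, 1:2],
            inv_KI=inv[:, 2:3], kinact=np.zeros((2, 1)),
            FImax=np.ones((2, 1)), inv_EC50=np.zeros((2, 1)),
            Vmax2=np.zeros(2), Km2=np.ones(2))
        fuc = np.array(fuc)
        e0 = np.array([5.0])
        efree = free_enzyme(np.array([etot]), fuc, tbl)
        mets, inhs, mbis = complex_concentrations(fuc, np.array([etot]), tbl, e0)
        total = efree[0] + (mets + inhs + mbis).sum(axis=0)[0] / e0[0]
        assert total == pytest.approx(etot, rel=1e-10)
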