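"""Ideal-solution and hard-sphere equilibrium theories."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condcap import equilibrium as E


@pytest.fixture(scope="module")
def sigma_sub(dodeca, dodeca_table_rep):
    return E.effective_subunit_diameter(dodeca, dodeca_table_rep)


class TestPartitionIdeal:
    def test_kc_values(self):
        assert E.kc_ideal(0.0) == 1.0
        assert E.kc_ideal(7.0) == pytest.approx(1096.633, rel=1e-5)

    @given(e1=st.floats(0, 10), e2=st.floats(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_monotone(self, e1, e2):
        if e1 < e2:
            assert E.kc_ideal(e1) < E.kc_ideal(e2)


class TestCarnahanStarling:
    def test_exact_value(self):
        assert E.cs_mu_excess(0.0) == 0.0
        assert E.cs_mu_excess(0.3) == pytest.approx(1.671 / 0.343, rel=1e-3)

    def test_virial_limit(self):
        assert abs(E.cs_mu_excess(0.01) / 0.01 - 8.0) < 0.5

    def test_domain(self):
        with pytest.raises(ValueError):
            E.cs_mu_excess(1.0)
        with pytest.warns(UserWarning):
            E.cs_mu_excess(0.6)


class TestBMCSL:
    @pytest.mark.parametrize("eta", [1e-6, 0.01, 0.1, 0.3, 0.45])
    def test_reduces_to_cs_for_equal_diameters(self, eta):
        d = E.bmcsl_mu_excess((eta / 2, eta / 2), (1.0, 1.0), 0) - E.cs_mu_excess(eta)
        assert abs(d) < 1e-10

    def test_one_species_absent(self):
        assert E.bmcsl_mu_excess((0.2, 0.0), (1.0, 5.1), 0) == pytest.approx(
            E.cs_mu_excess(0.2), abs=1e-12
        )
        # infinite-dilution value of the large species is finite and large
        mu_cap = E.bmcsl_mu_excess((0.2, 0.0), (1.0, 5.1), 1)
        assert math.isfinite(mu_cap) and mu_cap > E.cs_mu_excess(0.2)

    def test_zero_density_limit(self):
        assert E.bmcsl_mu_excess((0.0, 0.0), (1.0, 2.0), 0) == 0.0

    @given(
        eta1=st.floats(1e-8, 0.2),
        eta2=st.floats(1e-8, 0.2),
        s2=st.floats(1.5, 6.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_positive_and_finite(self, eta1, eta2, s2):
        for sp in (0, 1):
            mu = E.bmcsl_mu_excess((eta1, eta2), (1.0, s2), sp)
            assert math.isfinite(mu) and mu > 0


class TestPartitionSolvers:
    def test_ideal_closed_form(self):
        p = E.TheoryParams(12, 1.7, 5.1, 0.0, 5.0, 5e-3, 4e-4, "ideal")
        sol = E.solve_partition_no_assembly(p)
        assert sol.K_c == pytest.approx(math.exp(5.0), rel=1e-12)
        assert sol.mass_residual() < 1e-10

    def test_hard_sphere_matches_ideal_at_zero_size(self):
        p = E.TheoryParams(12, 1e-7, 2e-7, 0.0, 3.0, 5e-3, 4e-4, "hard_sphere")
        sol = E.solve_partition_no_assembly(p)
        assert abs(sol.K_c - math.exp(3.0)) < 1e-8

    def test_no_field_is_symmetric(self, sigma_sub):
        p = E.TheoryParams(12, sigma_sub, 5.1, 0.0, 0.0, 5e-3, 4e-4, "hard_sphere")
        sol = E.solve_partition_no_assembly(p)
        assert sol.K_c == pytest.approx(1.0, abs=1e-9)

    def test_excluded_volume_reduces_partitioning(self, sigma_sub):
        """K_c^HS <= K_c^IS across an (eps_c, rho_T) grid, approaching
        equality at infinite dilution."""
        for eps_c in (1.0, 3.0, 5.0, 7.0):
            prev = None
            for rho in (1e-6, 1e-4, 4e-4):
                p = E.TheoryParams(12, sigma_sub, 5.1, 0.0, eps_c, 5e-3, rho, "hard_sphere")
                sol = E.solve_partition_no_assembly(p)
                assert sol.K_c <= E.kc_ideal(eps_c) * (1 + 1e-9)
            p0 = E.TheoryParams(12, sigma_sub, 5.1, 0.0, eps_c, 5e-3, 1e-8, "hard_sphere")
            assert E.solve_partition_no_assembly(p0).K_c == pytest.approx(
                E.kc_ideal(eps_c), rel=1e-3
            )


class TestTwoStateEquilibrium:
    def test_no_assembly_limit(self, sigma_sub):
        huge = 1e9
        p = E.TheoryParams(12, sigma_sub, 5.1, huge, 3.0, 5e-3, 4e-4, "hard_sphere")
        sol = E.solve_two_state_equilibrium(p)
        ref = E.solve_partition_no_assembly(
            E.TheoryParams(12, sigma_sub, 5.1, 0.0, 3.0, 5e-3, 4e-4, "hard_sphere")
        )
        assert sol.rhocap_c == 0.0
        assert sol.K_c == pytest.approx(ref.K_c, rel=1e-7)

    def test_ideal_yield_monotone_in_rho(self):
        ys = []
        for rho in np.geomspace(5e-5, 1e-3, 10):
            p = E.dodecahedron_theory_params(6.0, 7.0, 5.03e-3, rho, mode="ideal")
            ys.append(E.solve_two_state_equilibrium(p).f_c)
        assert np.all(np.diff(ys) >= -1e-10)

    def test_hard_sphere_yield_nonmonotone(self, sigma_sub):
        rhos = np.geomspace(5e-5, 1e-3, 15)
        ys = []
        for rho in rhos:
            p = E.dodecahedron_theory_params(
                6.0, 7.0, 5.03e-3, rho, mode="hard_sphere", sigma_sub=sigma_sub
            )
            ys.append(E.solve_two_state_equilibrium(p).f_c)
        ys = np.array(ys)
        imax = int(np.argmax(ys))
        assert 0 < imax < len(ys) - 1, "interior maximum expected"
        assert ys[-1] < ys[imax]

    def test_solution_invariants(self, sigma_sub):
        p = E.dodecahedron_theory_params(
            6.0, 7.0, 5.03e-3, 4e-4, mode="hard_sphere", sigma_sub=sigma_sub
        )
        sol = E.solve_two_state_equilibrium(p)
        assert sol.mass_residual() < 1e-10
        assert sol.f_c == pytest.approx(sol.f_c_c + sol.f_c_bg, abs=1e-12)
        assert 0 <= sol.f_c <= 1
        assert sol.eta_c < 0.74
        assert min(sol.rho1_c, sol.rho1_bg, sol.rhocap_c, sol.rhocap_bg) >= 0

    def test_condensate_capsid_density_saturates(self, sigma_sub):
        """d rho_cap^c / d rho_T becomes small past the yield optimum."""
        caps = []
        for rho in (4e-4, 6e-4, 8e-4, 1e-3):
            p = E.dodecahedron_theory_params(
                6.0, 7.0, 5.03e-3, rho, mode="hard_sphere", sigma_sub=sigma_sub
            )
            caps.append(E.solve_two_state_equilibrium(p).rhocap_c)
        # relative growth of condensate capsid density slows to a crawl
        early = (caps[1] - caps[0]) / caps[0]
        late = (caps[3] - caps[2]) / caps[2]
        assert late < early / 3

    def test_smaller_capsids_pack_better(self, sigma_sub):
        """At high rho_T, reducing sigma_cap raises the equilibrium yield."""
        ys = []
        for scap in (5.5, 5.1, 4.5):
            p = E.TheoryParams(
                12, sigma_sub, scap, E.capsid_free_energy(6.0), 7.0, 5.03e-3, 8e-4,
                "hard_sphere",
            )
            ys.append(E.solve_two_state_equilibrium(p).f_c)
        assert ys[0] < ys[1] < ys[2]


class TestClosePacking:
    def test_unit_diameter(self):
        assert E.close_packing_concentration(1.0) == pytest.approx(math.sqrt(2.0))

    def test_printed_capsid_diameter(self):
        # sqrt(2)/5.1^3; the printed estimate 1.28e-2 corresponds to a
        # slightly smaller effective diameter, hence the override path
        assert E.close_packing_concentration(5.1) == pytest.approx(1.066e-2, rel=1e-3)

    def test_scaling(self):
        assert E.close_packing_concentration(2.0) == pytest.approx(
            E.close_packing_concentration(1.0) / 8.0
        )

    def test_threshold_volume_ratio(self):
        v = E.threshold_volume_ratio(4.00e-4, 12, 1.28e-2)
        assert v == pytest.approx(2.61e-3, rel=2e-3)
        with pytest.raises(ValueError):
            E.threshold_volume_ratio(1.0, 12, 1e-3)

    @given(rho=st.floats(1e-6, 1e-3))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotone_in_rho(self, rho):
        v1 = E.threshold_volume_ratio(rho, 12, 1.28e-2)
        v2 = E.threshold_volume_ratio(rho * 1.1, 12, 1.28e-2)
        assert v2 > v1

    def test_close_packed_yield(self):
        vstar = 2.61e-3
        assert E.close_packed_yield(vstar, vstar) == 1.0
        assert E.close_packed_yield(2 * vstar, vstar) == 1.0
        got = E.close_packed_yield(vstar / 2, vstar)
        assert got == pytest.approx((1 / vstar + 1) / (2 / vstar + 1), rel=1e-12)
        assert got == pytest.approx(0.5006, abs=2e-3)

    @given(v=st.floats(1e-4, 2.6e-3))
    @settings(max_examples=30, deadline=None)
    def test_yield_monotone_below_threshold(self, v):
        vstar = 2.61e-3
        assert E.close_packed_yield(v, vstar) <= E.close_packed_yield(min(v * 1.2, vstar), vstar)


class TestModelDerivedParameters:
    def test_effective_diameter_reasonable(self, sigma_sub, dodeca):
        # between the attractor ring diameter and the circumscribing sphere
        assert 1.0 < sigma_sub < 2.0 * dodeca.circumradius

    def test_capsid_free_energy_favours_stronger_bonds(self):
        assert E.capsid_free_energy(7.0) < E.capsid_free_energy(6.0) < 0

    def test_calibration_reference(self):
        # by construction dG(eps_ss_ref) = (N_cap - 1) ln(rho_CSC)
        dg = E.capsid_free_energy(E.EPS_SS_REFERENCE)
        assert dg == pytest.approx(11 * math.log(E.RHO_CSC_REFERENCE), rel=1e-12)
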