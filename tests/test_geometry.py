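"""Subunit templates, pair rules, and reference capsid geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condcap import geometry as G


class TestDodecahedronSubunit:
    def test_role_counts(self, dodeca):
        roles = dodeca.roles
        assert roles.count("A") == 5
        assert roles.count("T") == 1
        assert roles.count("B") == 1

    def test_attractors_on_pentagon(self, dodeca):
        a = np.array([p.position for p in dodeca.pseudoatoms if p.label == "A"])
        # circumradius 1 about the symmetry axis
        np.testing.assert_allclose(np.hypot(a[:, 0], a[:, 1]), 1.0, atol=1e-12)
        # adjacent vertex distance is the pentagon chord 2 sin(pi/5)
        chord = np.linalg.norm(a[0] - a[1])
        assert chord == pytest.approx(2.0 * math.sin(math.pi / 5.0), abs=1e-12)

    def test_centroid_at_origin_mass_one(self, dodeca):
        np.testing.assert_allclose(dodeca.positions.mean(axis=0), 0.0, atol=1e-12)
        assert dodeca.mass == 1.0

    def test_inertia_spd_principal(self, dodeca):
        I = dodeca.inertia
        np.testing.assert_allclose(I, I.T, atol=1e-14)
        assert np.all(np.linalg.eigvalsh(I) > 0)
        # body axes are principal axes
        assert np.abs(I - np.diag(np.diag(I))).max() < 1e-12

    def test_scaling_covariance(self):
        t1 = G.build_dodecahedron_subunit(1.0)
        t2 = G.build_dodecahedron_subunit(2.0)
        np.testing.assert_allclose(t2.positions, 2.0 * t1.positions, atol=1e-12)
        np.testing.assert_allclose(t2.inertia, 4.0 * t1.inertia, atol=1e-12)

    def test_invalid_l0(self):
        with pytest.raises(G.InvalidParameterError):
            G.build_dodecahedron_subunit(-1.0)
        with pytest.raises(G.InvalidParameterError):
            G.build_dodecahedron_subunit(0.0)


class TestIcosahedronSubunit:
    def test_counts(self, ico):
        roles = ico.roles
        assert roles.count("EXC") == 45
        assert sum(1 for r in roles if r != "EXC") == 6

    def test_diameter_about_three_sigma(self, ico):
        assert 2.9 <= ico.shape_diameter <= 3.1

    def test_centroid_at_origin(self, ico):
        np.testing.assert_allclose(ico.positions.mean(axis=0), 0.0, atol=1e-12)

    def test_scaling(self):
        t1 = G.build_icosahedron_subunit(1.0)
        t2 = G.build_icosahedron_subunit(3.0)
        np.testing.assert_allclose(t2.positions, 3.0 * t1.positions, atol=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(G.InvalidParameterError):
            G.build_icosahedron_subunit(0.0)


class TestInteractionTable:
    def test_attraction_depth_is_eps_ss(self):
        table = G.build_interaction_table("dodecahedron", 6.0)
        rule = table.get("A", "A")
        assert rule.kind == "MORSE"
        assert rule.eps == 6.0
        # unshifted Morse minimum equals -eps_ss at r_eq
        assert G.pair_energy(table, "A", "A", max(rule.r_eq, 1e-12), shifted=False) == pytest.approx(-6.0)

    def test_repulsive_rules_independent_of_eps_ss(self):
        t0 = G.build_interaction_table("dodecahedron", 0.0)
        t9 = G.build_interaction_table("dodecahedron", 9.0)
        for pair in (("T", "T"), ("B", "T")):
            assert t0.get(*pair) == t9.get(*pair)
            assert not t0.get(*pair).is_attractive

    def test_zero_eps_attraction_nonpositive(self):
        table = G.build_interaction_table("dodecahedron", 0.0)
        r = np.linspace(1e-3, 2.0, 200)
        u = np.array([G.pair_energy(table, "A", "A", x) for x in r])
        assert np.all(u <= 0)
        assert np.all(u[r >= table.get("A", "A").r_cut] == 0)

    def test_icosahedron_complementarity(self):
        table = G.build_interaction_table("icosahedron", 6.0)
        r = np.linspace(0.3, 2.0, 100)
        # complementary pairs attract somewhere
        assert min(G.pair_energy(table, "A1", "B2", x) for x in r) < -1.0
        # non-complementary attractor pairs carry no rule at all
        for pair in (("A1", "A2"), ("B1", "B3"), ("A3", "A3")):
            assert table.get(*pair) is None
            assert all(G.pair_energy(table, *pair, x) == 0.0 for x in r)

    def test_unknown_model(self):
        with pytest.raises(G.InvalidParameterError):
            G.build_interaction_table("cube", 1.0)

    def test_negative_eps(self):
        with pytest.raises(G.InvalidParameterError):
            G.build_interaction_table("dodecahedron", -1.0)


class TestPairEnergy:
    def test_wca_zero_at_and_beyond_minimum(self, dodeca_table):
        rule = dodeca_table.get("T", "T")
        rmin = 2 ** (1 / 6) * rule.sigma
        assert G.pair_energy(dodeca_table, "T", "T", rmin) == pytest.approx(0.0, abs=1e-12)
        for r in (rmin * 1.01, rmin * 2, rmin * 10):
            assert G.pair_energy(dodeca_table, "T", "T", r) == 0.0

    def test_zero_beyond_cutoff_everywhere(self, dodeca_table, ico_table):
        for table, pair in ((dodeca_table, ("A", "A")), (ico_table, ("A1", "B1"))):
            rule = table.get(*pair)
            assert G.pair_energy(table, *pair, 10.0 * rule.r_cut) == 0.0

    def test_domain_error(self, dodeca_table):
        with pytest.raises(ValueError):
            G.pair_energy(dodeca_table, "A", "A", -0.1)

    @given(r=st.floats(min_value=1e-3, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_pair_exchange_symmetry(self, r):
        table = G.build_interaction_table("dodecahedron", 6.0)
        for a, b in (("T", "B"), ("A", "A"), ("T", "T")):
            assert G.pair_energy(table, a, b, r) == G.pair_energy(table, b, a, r)

    def test_continuity_at_cutoff(self, dodeca_table, ico_table):
        # cut-and-shifted energies vanish continuously at the cutoff: the
        # residual just inside is bounded by |u'(r_cut)| * delta
        delta = 1e-6
        for table in (dodeca_table, ico_table):
            for rule in table.rules.values():
                inside = abs(rule.energy(rule.r_cut - delta))
                slope = abs(rule.force_mag(rule.r_cut - delta))
                assert inside <= (slope + 1.0) * delta
                assert rule.energy(rule.r_cut) == 0.0


class TestReferenceCapsid:
    def test_dodecahedron_counts(self, dodeca_capsid):
        assert dodeca_capsid.n_cap == 12
        assert dodeca_capsid.n_bonds_complete == 30

    def test_icosahedron_counts(self, ico_capsid):
        assert ico_capsid.n_cap == 20
        assert ico_capsid.n_bonds_complete == 30

    def test_closure_energy(self, dodeca, dodeca_table, dodeca_capsid):
        """Total attraction of the closed shell equals bonds x per-bond
        minimum (every attractor pair sits exactly at its minimum)."""
        e = G.capsid_attraction_energy(dodeca_capsid, dodeca, dodeca_table)
        expected = 30 * G.min_bond_energy(dodeca_table)
        assert e == pytest.approx(expected, rel=0.05)

    def test_closure_energy_icosahedron(self, ico, ico_table, ico_capsid):
        e = G.capsid_attraction_energy(ico_capsid, ico, ico_table)
        expected = 30 * G.min_bond_energy(ico_table)
        assert e == pytest.approx(expected, rel=0.05)

    def test_no_repulsive_frustration(self, dodeca, dodeca_table, dodeca_capsid):
        """The assembled shell sits at zero repulsive energy."""
        pos, role_idx, body_idx = G.world_atoms(
            dodeca, dodeca_capsid.centers, dodeca_capsid.orientations
        )
        roles = dodeca.roles
        rep = 0.0
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if body_idx[i] == body_idx[j]:
                    continue
                rule = dodeca_table.get(roles[role_idx[i]], roles[role_idx[j]])
                if rule is None or rule.is_attractive:
                    continue
                rep += rule.energy(float(np.linalg.norm(pos[i] - pos[j])))
        assert rep == pytest.approx(0.0, abs=1e-10)

    def test_capsid_diameter(self, dodeca, dodeca_capsid):
        d = G.estimate_capsid_diameter(dodeca_capsid, dodeca)
        assert d == pytest.approx(5.1, rel=0.06)

    def test_template_mismatch(self, ico):
        with pytest.raises(G.InvalidParameterError):
            G.assemble_reference_capsid("dodecahedron", ico)


class TestSerialization:
    def test_json_roundtrip(self, dodeca, ico):
        for t in (dodeca, ico):
            t2 = G.SubunitTemplate.from_json(t.to_json())
            np.testing.assert_allclose(t2.positions, t.positions, atol=1e-15)
            assert t2.roles == t.roles
            np.testing.assert_allclose(t2.inertia, t.inertia, atol=1e-15)
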