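"""Bond detection, cluster classification, yields, and kinetics series."""

import math

import numpy as np
import pytest

from condcap import analysis as A
from condcap.fixtures import Fixture, generate_fixture, monomer_gas, planted_capsid, planted_dangler
from condcap.state import SystemState, Trajectory


def state_from(centers, quats, L):
    n = len(centers)
    return SystemState(
        centers=np.asarray(centers, float),
        orientations=np.asarray(quats, float),
        velocities=np.zeros((n, 3)),
        angular_momenta=np.zeros((n, 3)),
        box_L=L,
    )


class TestDetectBonds:
    def test_reference_capsid_graph(self, dodeca, dodeca_capsid):
        st = state_from(dodeca_capsid.centers, dodeca_capsid.orientations, 60.0)
        g = A.detect_bonds(st, dodeca)
        assert g.number_of_edges() == 30
        assert all(d == 5 for _, d in g.degree())

    def test_icosahedron_reference_graph(self, ico, ico_capsid):
        st = state_from(ico_capsid.centers, ico_capsid.orientations, 60.0)
        g = A.detect_bonds(st, ico)
        assert g.number_of_edges() == 30
        assert all(d == 3 for _, d in g.degree())

    def test_monomer_gas_empty(self, dodeca):
        st = monomer_gas(dodeca, N=50, L=80.0, seed=3)
        assert A.detect_bonds(st, dodeca).number_of_edges() == 0

    def test_threshold_contract(self, dodeca, dodeca_capsid):
        """Displacing a bonded pair by just over/under the 0.3 criterion."""
        i, j = 0, None
        d = np.linalg.norm(dodeca_capsid.centers - dodeca_capsid.centers[0], axis=1)
        d[0] = np.inf
        j = int(np.argmin(d))
        for shift, expect in ((0.31, 0), (0.29, 1)):
            centers = dodeca_capsid.centers[[i, j]].copy()
            quats = dodeca_capsid.orientations[[i, j]].copy()
            # translate subunit j radially so every site pair moves by `shift`
            direction = centers[1] / np.linalg.norm(centers[1])
            centers[1] = centers[1] + shift * direction
            st = state_from(centers, quats, 60.0)
            g = A.detect_bonds(st, dodeca)
            assert g.number_of_edges() == expect, shift

    def test_periodic_wrap(self, dodeca, dodeca_capsid):
        """A capsid straddling the box boundary is still fully bonded."""
        L = 40.0
        centers = dodeca_capsid.centers + np.array([L / 2.0 - 0.5, 0, 0])
        centers -= L * np.round(centers / L)
        st = state_from(centers, dodeca_capsid.orientations, L)
        assert A.detect_bonds(st, dodeca).number_of_edges() == 30


class TestFindClusters:
    def test_planted_capsid_with_monomers(self, dodeca):
        st = planted_capsid(dodeca, L=80.0, n_free=8, seed=5)
        g = A.detect_bonds(st, dodeca)
        rep = A.find_clusters(g, state=st, template=dodeca)
        assert sorted(rep.cluster_sizes, reverse=True) == [12] + [1] * 8
        assert rep.n_complete == 1
        assert rep.n_malformed == 0

    def test_dangler_classification(self, dodeca):
        st = planted_dangler(dodeca, L=80.0, seed=1)
        g = A.detect_bonds(st, dodeca)
        rep = A.find_clusters(g, state=st, template=dodeca)
        assert g.number_of_edges() == 26
        assert rep.n_complete == 0
        assert rep.n_danglers == 1
        assert rep.n_malformed == 1

    def test_empty_graph(self, dodeca):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(17))
        rep = A.find_clusters(g, template=dodeca)
        assert rep.cluster_sizes == [1] * 17
        assert rep.n_complete == 0

    def test_partition_of_subunits(self, dodeca):
        st = planted_capsid(dodeca, L=80.0, n_free=5, seed=2)
        g = A.detect_bonds(st, dodeca)
        rep = A.find_clusters(g, state=st, template=dodeca)
        assert rep.n == st.n


class TestYields:
    def test_all_assembled(self, dodeca):
        st = planted_capsid(dodeca, L=80.0, n_free=0, seed=0)
        g = A.detect_bonds(st, dodeca)
        rep = A.find_clusters(g, state=st, template=dodeca, R_c=10.0)
        f_c, f_c_c, f_c_bg = A.compute_yields(rep, 12, 80.0**3, 4.0 / 3 * math.pi * 1e3)
        assert f_c == 1.0
        assert f_c_c == 1.0  # capsid centroid at the origin, inside R_c
        assert f_c_bg == 0.0

    def test_half_assembled_split(self, dodeca):
        st = planted_capsid(dodeca, L=80.0, n_free=12, seed=0)
        g = A.detect_bonds(st, dodeca)
        rep = A.find_clusters(g, state=st, template=dodeca, R_c=10.0)
        f_c, f_c_c, f_c_bg = A.compute_yields(rep, 24, 80.0**3, 4.0 / 3 * math.pi * 1e3)
        assert f_c == pytest.approx(0.5)
        assert f_c_bg == 0.0
        assert f_c == f_c_c + f_c_bg

    def test_no_capsids(self, dodeca):
        st = monomer_gas(dodeca, N=30, L=80.0, seed=1)
        g = A.detect_bonds(st, dodeca)
        rep = A.find_clusters(g, state=st, template=dodeca, R_c=10.0)
        assert A.compute_yields(rep, 30, 80.0**3, 1.0) == (0.0, 0.0, 0.0)


class TestPartitionCoefficient:
    def test_constructed_ratio(self, dodeca):
        # 100 isolated monomers inside V_c = 2e4, 10 outside in V_bg = 2e6
        rng = np.random.default_rng(0)
        V_c = 2.0e4
        R_c = (3 * V_c / (4 * math.pi)) ** (1 / 3)
        L = (2.0e6 + V_c) ** (1 / 3)
        d_min = 3.0 * dodeca.circumradius
        inside = []
        while len(inside) < 100:
            p = rng.normal(size=3)
            p = p / np.linalg.norm(p) * rng.uniform(0, R_c * 0.95) ** 1.0
            if all(np.linalg.norm(p - q) > d_min for q in inside):
                inside.append(p)
        outside = []
        while len(outside) < 10:
            p = rng.uniform(-L / 2, L / 2, 3)
            if np.linalg.norm(p) > R_c + d_min and all(
                np.linalg.norm(p - q) > d_min for q in outside
            ):
                outside.append(p)
        centers = np.vstack([inside, outside])
        quats = np.tile([1.0, 0, 0, 0], (110, 1))
        st = state_from(centers, quats, L)
        g = A.detect_bonds(st, dodeca)
        rep = A.find_clusters(g, state=st, template=dodeca, R_c=R_c)
        kc, ok = A.measure_partition_coefficient(rep, V_c, L**3 - V_c)
        assert ok
        assert kc == pytest.approx((100 / V_c) / (10 / (L**3 - V_c)), rel=1e-12)

    def test_empty_background_flagged(self, dodeca):
        st = state_from(np.zeros((3, 3)) + [[0, 0, 0], [3, 0, 0], [0, 3, 0]],
                        np.tile([1.0, 0, 0, 0], (3, 1)), 60.0)
        g = A.detect_bonds(st, dodeca)
        rep = A.find_clusters(g, state=st, template=dodeca, R_c=10.0)
        kc, ok = A.measure_partition_coefficient(rep, 1.0, 1.0)
        assert not ok and math.isinf(kc)


class TestKineticsSeries:
    def test_median_step_series(self):
        t = np.arange(0, 201, 10.0)
        f = np.where(t >= 100, 0.8, 0.0)
        assert A.median_assembly_time(t, f) == pytest.approx(100.0, abs=10.0)

    def test_median_linear_ramp(self):
        t = np.linspace(0, 1000, 101)
        f = 0.6 * t / 1000
        assert A.median_assembly_time(t, f) == pytest.approx(500.0, rel=1e-9)

    def test_median_matches_brute_scan(self, rng):
        for _ in range(20):
            t = np.linspace(0, 100, 41)
            f = np.cumsum(rng.uniform(0, 1, 41))
            f /= f[-1]
            got = A.median_assembly_time(t, f)
            target = f[-1] / 2
            k = next(i for i in range(41) if f[i] >= target)
            assert t[max(k - 1, 0)] - 1e-9 <= got <= t[k] + 1e-9

    def test_median_undefined_for_zero_yield(self):
        with pytest.raises(A.AnalysisError):
            A.median_assembly_time(np.arange(5.0), np.zeros(5))

    def test_max_rate_linear_ramp(self):
        t = np.linspace(0, 100, 201)
        f = 0.004 * t
        assert A.max_assembly_rate(t, f) == pytest.approx(0.004, rel=0.02)

    def test_max_rate_constant_series(self):
        t = np.linspace(0, 100, 51)
        assert A.max_assembly_rate(t, np.full(51, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_max_rate_logistic(self):
        t = np.linspace(0, 200, 401)
        k, t0 = 0.08, 100.0
        f = 0.9 / (1 + np.exp(-k * (t - t0)))
        # analytic maximum slope of a logistic is amplitude * k / 4
        assert A.max_assembly_rate(t, f, width=2.0) == pytest.approx(0.9 * k / 4, rel=0.05)

    def test_too_short_series(self):
        with pytest.raises(A.InsufficientDataError):
            A.max_assembly_rate(np.arange(3.0), np.arange(3.0))


class TestTrajectoryAnalytics:
    def test_partition_of_unity_and_yield_identity(self, dodeca):
        frames = [
            planted_capsid(dodeca, L=80.0, n_free=12, seed=s) for s in range(3)
        ]
        for i, f in enumerate(frames):
            f.time = 10.0 * i
        traj = Trajectory(frames=frames)
        ts = A.analyze_trajectory(traj, dodeca, R_c=10.0)
        np.testing.assert_allclose(ts.f_c, ts.f_c_c + ts.f_c_bg, atol=1e-12)
        assert np.all((ts.f_c >= 0) & (ts.f_c <= 1))

    def test_analyzer_is_pure(self, dodeca):
        st = planted_dangler(dodeca, L=80.0, seed=7)
        traj = Trajectory(frames=[st])
        a = A.analyze_trajectory(traj, dodeca, R_c=10.0)
        b = A.analyze_trajectory(traj, dodeca, R_c=10.0)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_aggregate_replicates(self):
        mean, two_sem = A.aggregate_replicates([1.0, 2.0, 3.0, 4.0])
        assert mean == 2.5
        assert two_sem == pytest.approx(2 * np.std([1, 2, 3, 4], ddof=1) / 2)

    def test_off_target_fraction_dangler(self, dodeca):
        st = planted_dangler(dodeca, L=80.0, seed=1)
        # add 12 monomers on a far-away grid (spacing 5 >> bond range)
        grid = np.array(
            [[20.0 + 5.0 * i, 20.0 + 5.0 * j, 25.0] for i in range(4) for j in range(3)]
        )
        centers = np.vstack([st.centers, grid])
        quats = np.vstack([st.orientations, np.tile([1.0, 0, 0, 0], (12, 1))])
        merged = state_from(centers, quats, 80.0)
        g = A.detect_bonds(merged, dodeca)
        rep = A.find_clusters(g, state=merged, template=dodeca)
        assert rep.n_danglers == 1
        assert A.off_target_fraction(rep, 24) == pytest.approx(0.5)
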