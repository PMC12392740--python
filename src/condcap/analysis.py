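"""Trajectory analytics: bond graphs, clusters, yields, and kinetics.

Bond criteria follow the models' conventions:

* dodecahedron -- two subunits are bonded when the midpoints of a pentagon
  edge of each lie within ``0.3`` of one another (minimum image);
* icosahedron -- two subunits are bonded when *both* attractor pairs of a
  shared edge lie within ``1.3``.

Each subunit edge participates in at most one bond (the nearest candidate
wins), which prevents degree overflow from double counting in malformed
regimes.  Clusters are connected components of the bond graph; a cluster
is a *complete capsid* when it has exactly ``N_cap`` subunits each forming
the maximum number of bonds (5 or 3), a *dangler* when it has ``N_cap``
subunits but fewer bonds, and *malformed* when it is a dangler, is larger
than ``N_cap``, or contains an over-bonded subunit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from condcap.geometry import SubunitTemplate, quat_to_matrix
from condcap.state import SystemState, Trajectory

__all__ = [
    "BOND_CUTOFF_DODECAHEDRON",
    "BOND_CUTOFF_ICOSAHEDRON",
    "ClusterReport",
    "AssemblyTimeSeries",
    "detect_bonds",
    "find_clusters",
    "compute_yields",
    "measure_partition_coefficient",
    "median_assembly_time",
    "max_assembly_rate",
    "off_target_fraction",
    "analyze_trajectory",
    "aggregate_replicates",
]

BOND_CUTOFF_DODECAHEDRON = 0.3
BOND_CUTOFF_ICOSAHEDRON = 1.3


class AnalysisError(RuntimeError):
    pass


class InsufficientDataError(AnalysisError):
    pass


@dataclass
class ClusterReport:
    """Cluster decomposition of one frame."""

    graph: nx.Graph
    cluster_sizes: list[int]
    n_complete: int
    n_malformed: int
    n_danglers: int
    # per cluster: (size, bond_count, centroid (3,), in_condensate)
    per_cluster: list[tuple[int, int, np.ndarray, bool]]
    n_cap: int
    n_complete_condensate: int
    n_complete_background: int
    n_monomers_condensate: int
    n_monomers_background: int
    n_subunits_malformed: int

    @property
    def n(self) -> int:
        return sum(self.cluster_sizes)


def _world_bond_points(
    state: SystemState, template: SubunitTemplate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bond-detection points in the world frame.

    Returns (points, body index, edge slot) flattened over subunits.
    """
    pts_body = template.bond_points
    k = len(pts_body)
    n = state.n
    out = np.empty((n * k, 3))
    for i in range(n):
        R = quat_to_matrix(state.orientations[i])
        out[i * k : (i + 1) * k] = state.centers[i] + pts_body @ R.T
    body = np.repeat(np.arange(n), k)
    edge = np.tile(template.bond_point_edge, n)
    return out, body, edge


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def detect_bonds(state: SystemState, template: SubunitTemplate) -> nx.Graph:
    """Bond graph of one frame under the model's bond criterion."""
    L = state.box_L
    pts, body, edge = _world_bond_points(state, template)
    wrapped = np.mod(pts + L / 2.0, L)  # KDTree wants [0, L)
    cutoff = (
        BOND_CUTOFF_DODECAHEDRON
        if template.model == "dodecahedron"
        else BOND_CUTOFF_ICOSAHEDRON
    ) * template.length_scale

    tree = cKDTree(wrapped, boxsize=L)
    cand = tree.query_pairs(cutoff, output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(range(state.n))
    if len(cand) == 0:
        return g

    i, j = cand[:, 0], cand[:, 1]
    cross = body[i] != body[j]
    i, j = i[cross], j[cross]
    if len(i) == 0:
        return g
    d = np.linalg.norm(_min_image(pts[i] - pts[j], L), axis=1)

    if template.model == "dodecahedron":
        candidates = sorted(zip(d, i, j))
    else:
        # icosahedron: a bond needs BOTH attractor pairs of an edge pair
        # within the cutoff.  Edge slots come in (A, B) ordered pairs:
        # bond_points are [A1, B1, A2, B2, A3, B3] so point index p has
        # edge p // 2 and parity p % 2.
        pair_d: dict[tuple[int, int, int, int], list[float]] = {}
        k = len(template.bond_points)
        for dd, pi, pj in zip(d, i, j):
            bi, bj = int(body[pi]), int(body[pj])
            si, sj = int(pi % k), int(pj % k)
            ei, ej = si // 2, sj // 2
            if bi > bj or (bi == bj):
                bi, bj, ei, ej, si, sj = bj, bi, ej, ei, sj, si
            key = (bi, ei, bj, ej)
            pair_d.setdefault(key, []).append(float(dd))
        candidates = []
        for (bi, ei, bj, ej), ds in pair_d.items():
            if len(ds) >= 2:  # both attractor pairs within cutoff
                candidates.append((float(np.mean(sorted(ds)[:2])), (bi, ei), (bj, ej)))
        candidates.sort()

    used: set[tuple[int, int]] = set()
    if template.model == "dodecahedron":
        for dd, pi, pj in candidates:
            bi, bj = int(body[pi]), int(body[pj])
            slot_i = (bi, int(edge[pi]))
            slot_j = (bj, int(edge[pj]))
            if slot_i in used or slot_j in used:
                continue
            used.add(slot_i)
            used.add(slot_j)
            g.add_edge(bi, bj, sites=(slot_i[1], slot_j[1]), distance=float(dd))
    else:
        for dd, (bi, ei), (bj, ej) in candidates:
            slot_i, slot_j = (bi, ei), (bj, ej)
            if slot_i in used or slot_j in used:
                continue
            used.add(slot_i)
            used.add(slot_j)
            g.add_edge(bi, bj, sites=(ei, ej), distance=float(dd))
    return g


def _cluster_centroid(members: list[int], centers: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image-consistent centroid, wrapped into [-L/2, L/2)."""
    ref = centers[members[0]]
    disp = _min_image(centers[members] - ref, L)
    c = ref + disp.mean(axis=0)
    return _min_image(c, L)


def find_clusters(
    graph: nx.Graph,
    state: SystemState | None = None,
    template: SubunitTemplate | None = None,
    R_c: float | None = None,
) -> ClusterReport:
    """Connected-component decomposition with completeness classification.

    If ``state`` and ``R_c`` are given, each cluster is assigned to the
    condensate or background by its centroid position.
    """
    if template is None:
        raise AnalysisError("template required for completeness classification")
    n_cap = 12 if template.model == "dodecahedron" else 20
    max_deg = template.n_bond_sites

    sizes, per_cluster = [], []
    n_complete = n_malformed = n_danglers = 0
    n_comp_c = n_comp_bg = n_mono_c = n_mono_bg = 0
    n_sub_malformed = 0
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        size = len(members)
        sub = graph.subgraph(members)
        bonds = sub.number_of_edges()
        sizes.append(size)
        degrees = [d for _, d in sub.degree()]
        over = any(d > max_deg for d in degrees)
        complete = size == n_cap and all(d == max_deg for d in degrees)
        dangler = size == n_cap and not complete
        malformed = dangler or size > n_cap or over

        in_cond = False
        centroid = np.full(3, np.nan)
        if state is not None:
            centroid = _cluster_centroid(members, state.centers, state.box_L)
            if R_c is not None:
                in_cond = bool(np.linalg.norm(centroid) < R_c)
        per_cluster.append((size, bonds, centroid, in_cond))

        if complete:
            n_complete += 1
            if in_cond:
                n_comp_c += 1
            else:
                n_comp_bg += 1
        if dangler:
            n_danglers += 1
        if malformed:
            n_malformed += 1
            n_sub_malformed += size
        if size == 1:
            if in_cond:
                n_mono_c += 1
            else:
                n_mono_bg += 1
    return ClusterReport(
        graph=graph,
        cluster_sizes=sizes,
        n_complete=n_complete,
        n_malformed=n_malformed,
        n_danglers=n_danglers,
        per_cluster=per_cluster,
        n_cap=n_cap,
        n_complete_condensate=n_comp_c,
        n_complete_background=n_comp_bg,
        n_monomers_condensate=n_mono_c,
        n_monomers_background=n_mono_bg,
        n_subunits_malformed=n_sub_malformed,
    )


def compute_yields(
    report: ClusterReport, N: int, V: float, V_c: float
) -> tuple[float, float, float]:
    """Yields ``(f_c, f_c_c, f_c_bg)``: fractions of subunits in complete
    capsids overall and split by condensate/background membership.

    ``f_c = N_cap rho_cap / rho_T`` with the split by capsid centroid; the
    identity ``f_c = f_c_c + f_c_bg`` is exact by construction.
    """
    if report.n != N:
        raise AnalysisError("cluster report does not cover N subunits")
    n_cap = report.n_cap
    f_c_c = n_cap * report.n_complete_condensate / N
    f_c_bg = n_cap * report.n_complete_background / N
    return f_c_c + f_c_bg, f_c_c, f_c_bg


def measure_partition_coefficient(
    report: ClusterReport, V_c: float, V_bg: float
) -> tuple[float, bool]:
    """Measured monomer partition coefficient
    ``K_c = rho_1^c / rho_1^bg`` from a cluster report.

    Returns ``(K_c, ok)``; when the background holds no monomers the value
    is ``inf`` and ``ok`` is False (flagged, not raised).
    """
    rho_c = report.n_monomers_condensate / V_c
    rho_bg = report.n_monomers_background / V_bg
    if rho_bg == 0:
        return math.inf, False
    return rho_c / rho_bg, True


def median_assembly_time(times: np.ndarray, f_c: np.ndarray) -> float:
    """Earliest time at which the yield reaches half its final value,
    linearly interpolated between snapshots."""
    times = np.asarray(times, dtype=float)
    f_c = np.asarray(f_c, dtype=float)
    if len(times) != len(f_c) or len(times) < 2:
        raise InsufficientDataError("need at least two snapshots")
    target = f_c[-1] / 2.0
    if f_c[-1] <= 0:
        raise AnalysisError("final yield is zero; median time undefined")
    above = np.nonzero(f_c >= target)[0]
    k = int(above[0])
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    y0, y1 = f_c[k - 1], f_c[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))


def max_assembly_rate(times: np.ndarray, f_c: np.ndarray, width: float | None = None) -> float:
    """Maximum assembly rate from convolving the yield curve with the
    first derivative of a Gaussian (reflect-padded).

    ``width`` is the Gaussian standard deviation in time units; the
    default is 10 snapshot intervals.
    """
    times = np.asarray(times, dtype=float)
    f_c = np.asarray(f_c, dtype=float)
    if len(times) < 5:
        raise InsufficientDataError("need at least five snapshots")
    dt = float(np.mean(np.diff(times)))
    if width is None:
        width = 10.0 * dt
    sigma = max(width / dt, 1e-6)
    deriv = gaussian_filter1d(f_c, sigma=sigma, order=1, mode="reflect") / dt
    return float(np.max(deriv))


def off_target_fraction(report: ClusterReport, N: int) -> float:
    """Fraction of subunits residing in malformed clusters."""
    return report.n_subunits_malformed / N


@dataclass
class AssemblyTimeSeries:
    """Per-frame observables of one trajectory."""

    times: np.ndarray
    f_c: np.ndarray
    f_c_c: np.ndarray
    f_c_bg: np.ndarray
    K_c_meas: np.ndarray
    mean_cluster_size: np.ndarray
    off_target: np.ndarray
    n_complete: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "f_c": self.f_c,
                "f_c_c": self.f_c_c,
                "f_c_bg": self.f_c_bg,
                "K_c_meas": self.K_c_meas,
                "mean_cluster_size": self.mean_cluster_size,
                "off_target_fraction": self.off_target,
                "n_complete": self.n_complete,
            }
        )


def analyze_trajectory(
    traj: Trajectory, template: SubunitTemplate, R_c: float | None
) -> AssemblyTimeSeries:
    """Run bond/cluster analysis on every frame of a trajectory."""
    n_frames = len(traj)
    if n_frames == 0:
        raise InsufficientDataError("empty trajectory")
    cols = {k: np.zeros(n_frames) for k in
            ("f_c", "f_c_c", "f_c_bg", "K_c", "mcs", "off", "ncomp")}
    L = traj[0].box_L
    V = L**3
    V_c = 4.0 / 3.0 * math.pi * R_c**3 if R_c else 0.0
    V_bg = V - V_c
    for m, frame in enumerate(traj.frames):
        g = detect_bonds(frame, template)
        rep = find_clusters(g, state=frame, template=template, R_c=R_c)
        f_c, f_c_c, f_c_bg = compute_yields(rep, frame.n, V, V_c)
        cols["f_c"][m] = f_c
        cols["f_c_c"][m] = f_c_c
        cols["f_c_bg"][m] = f_c_bg
        if V_c > 0:
            kc, ok = measure_partition_coefficient(rep, V_c, V_bg)
            cols["K_c"][m] = kc if ok else np.nan
        else:
            cols["K_c"][m] = np.nan
        cols["mcs"][m] = float(np.mean(rep.cluster_sizes))
        cols["off"][m] = off_target_fraction(rep, frame.n)
        cols["ncomp"][m] = rep.n_complete
    return AssemblyTimeSeries(
        times=traj.times,
        f_c=cols["f_c"],
        f_c_c=cols["f_c_c"],
        f_c_bg=cols["f_c_bg"],
        K_c_meas=cols["K_c"],
        mean_cluster_size=cols["mcs"],
        off_target=cols["off"],
        n_complete=cols["ncomp"],
        metadata=dict(traj.metadata),
    )


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and twice the standard error of the mean over replicates
    (approximately a 95% confidence interval)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("no replicate values")
    if v.size == 1:
        return float(v[0]), math.inf
    return float(v.mean()), float(2.0 * v.std(ddof=1) / math.sqrt(v.size))
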