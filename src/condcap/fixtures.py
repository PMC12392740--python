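"""Synthetic configurations with planted ground truth.

These generators build :class:`SystemState` objects whose cluster content
is known by construction -- monomer gases, complete capsids, danglers
(a full-size capsid with one misoriented subunit, e.g. 12 subunits but
only 26 of 30 bonds), and condensates packed with capsids on an FCC
lattice at a prescribed packing fraction.  They exercise the trajectory
analytics without running any dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from condcap.geometry import (
    ReferenceCapsid,
    SubunitTemplate,
    assemble_reference_capsid,
    matrix_to_quat,
    quat_to_matrix,
)
from condcap.state import SystemState

__all__ = ["Fixture", "generate_fixture", "monomer_gas", "planted_capsid",
           "planted_dangler", "packed_condensate"]

ETA_RANDOM_LIMIT = 0.64
ETA_LATTICE_LIMIT = math.pi / (3.0 * math.sqrt(2.0))


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class Fixture:
    """A fixture request: kind plus its parameters."""

    kind: str  # monomer_gas | planted_capsid | dangler | packed_condensate
    params: dict = field(default_factory=dict)


def generate_fixture(spec: Fixture, template: SubunitTemplate, seed: int) -> SystemState:
    """Dispatch on the fixture kind; deterministic given the seed."""
    fns = {
        "monomer_gas": monomer_gas,
        "planted_capsid": planted_capsid,
        "dangler": planted_dangler,
        "packed_condensate": packed_condensate,
    }
    if spec.kind not in fns:
        raise FixtureError(f"unknown fixture kind {spec.kind!r}")
    return fns[spec.kind](template=template, seed=seed, **spec.params)


def _zero_state(centers, quats, L) -> SystemState:
    n = len(centers)
    return SystemState(
        centers=np.asarray(centers, dtype=float),
        orientations=np.asarray(quats, dtype=float),
        velocities=np.zeros((n, 3)),
        angular_momenta=np.zeros((n, 3)),
        box_L=L,
    )


def _random_quats(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1)[:, None]


def monomer_gas(template: SubunitTemplate, N: int, L: float, seed: int = 0) -> SystemState:
    """N isolated subunits: all pairwise center distances exceed three
    circumradii, so the bond graph is empty by construction."""
    rng = np.random.default_rng(seed)
    d_min = 3.0 * template.circumradius
    if N * (math.pi / 6.0) * d_min**3 > 0.3 * L**3:
        raise FixtureError("box too small for an isolated-monomer gas")
    centers = []
    while len(centers) < N:
        trial = rng.uniform(-L / 2.0, L / 2.0, size=3)
        ok = True
        for c in centers:
            d = trial - c
            d -= L * np.round(d / L)
            if np.dot(d, d) < d_min**2:
                ok = False
                break
        if ok:
            centers.append(trial)
    return _zero_state(centers, _random_quats(rng, N), L)


def _capsid_poses(template, offset, rotation=None):
    cap = assemble_reference_capsid(template.model, template)
    centers = cap.centers.copy()
    quats = cap.orientations.copy()
    if rotation is not None:
        centers = centers @ rotation.T
        rq = matrix_to_quat(rotation)
        quats = np.array([_quat_mul(rq, q) for q in quats])
    return centers + offset, quats


def _quat_mul(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _random_rotation(rng):
    q = rng.normal(size=4)
    return quat_to_matrix(q / np.linalg.norm(q))


def planted_capsid(
    template: SubunitTemplate, L: float, n_free: int = 0, seed: int = 0
) -> SystemState:
    """One complete capsid at the origin plus ``n_free`` distant monomers."""
    rng = np.random.default_rng(seed)
    centers, quats = _capsid_poses(template, np.zeros(3))
    cap_r = float(np.max(np.linalg.norm(centers, axis=1))) + template.circumradius
    free_min = cap_r + 3.0 * template.circumradius
    free_centers = []
    while len(free_centers) < n_free:
        trial = rng.uniform(-L / 2.0, L / 2.0, size=3)
        if np.linalg.norm(trial) < free_min:
            continue
        ok = all(
            np.dot(trial - c, trial - c) > (3.0 * template.circumradius) ** 2
            for c in free_centers
        )
        if ok:
            free_centers.append(trial)
    all_centers = np.vstack([centers] + ([free_centers] if n_free else []))
    all_quats = np.vstack([quats, _random_quats(rng, n_free)]) if n_free else quats
    return _zero_state(all_centers, all_quats, L)


def planted_dangler(
    template: SubunitTemplate, L: float, hinge_angle_deg: float = 40.0, seed: int = 0
) -> SystemState:
    """A full-size capsid whose last subunit is rotated about one of its
    bonded edges: that edge's bond survives, the rest break.

    For the dodecahedron this yields the classic 12-subunit, 26-bond
    dangler (the 11 intact subunits keep 25 bonds among themselves).
    """
    centers, quats = _capsid_poses(template, np.zeros(3))
    k = len(centers) - 1
    # hinge axis: the bonded edge of subunit k closest to subunit 0..k-1
    # use the subunit's first bond point pair in world frame
    R = quat_to_matrix(quats[k])
    pts = centers[k] + template.bond_points @ R.T
    if template.model == "dodecahedron":
        # pentagon edge 0 runs between vertices 0 and 1; its direction:
        body = template.positions
        a_idx = [i for i, r in enumerate(template.roles) if r == "A"]
        p0 = centers[k] + body[a_idx[0]] @ R.T
        p1 = centers[k] + body[a_idx[1]] @ R.T
    else:
        p0, p1 = pts[0], pts[1]
    axis = p1 - p0
    axis /= np.linalg.norm(axis)
    th = math.radians(hinge_angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    Rot = np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)
    centers[k] = p0 + Rot @ (centers[k] - p0)
    quats[k] = _quat_mul(matrix_to_quat(Rot), quats[k])
    return _zero_state(centers, quats, L)


def packed_condensate(
    template: SubunitTemplate,
    eta: float,
    R_c: float,
    sigma_cap: float,
    L: float | None = None,
    seed: int = 0,
) -> SystemState:
    """Complete capsids on an FCC lattice clipped to the condensate sphere
    at capsid packing fraction ``eta`` (achieved within the one-capsid
    quantization by placing the ``n`` lattice sites closest to the center,
    with ``n = round(eta V_c / v_cap)``)."""
    if not 0 < eta <= ETA_LATTICE_LIMIT:
        raise FixtureError("packing fraction must lie in (0, pi/(3 sqrt 2)]")
    rng = np.random.default_rng(seed)
    v_cap = math.pi / 6.0 * sigma_cap**3
    V_c = 4.0 / 3.0 * math.pi * R_c**3
    n_target = int(round(eta * V_c / v_cap))
    if n_target < 1:
        raise FixtureError("condensate too small to hold one capsid")
    # conventional FCC cell with 4 sites, cell edge from the local density
    a_c = (4.0 * v_cap / eta) ** (1.0 / 3.0)
    if a_c / math.sqrt(2.0) < sigma_cap * 0.999:
        raise FixtureError("requested packing exceeds FCC contact for sigma_cap")
    m = int(math.ceil(R_c / a_c)) + 1
    basis = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    grid = np.array(
        [
            (i + b[0], j + b[1], k + b[2])
            for i in range(-m, m + 1)
            for j in range(-m, m + 1)
            for k in range(-m, m + 1)
            for b in basis
        ]
    ) * a_c
    order = np.argsort(np.linalg.norm(grid, axis=1))
    sites = grid[order[:n_target]]
    if L is None:
        L = 2.0 * (R_c + 4.0 * sigma_cap)
    all_centers, all_quats = [], []
    for s in sites:
        c, q = _capsid_poses(template, s, rotation=_random_rotation(rng))
        all_centers.append(c)
        all_quats.append(q)
    return _zero_state(np.vstack(all_centers), np.vstack(all_quats), L)
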