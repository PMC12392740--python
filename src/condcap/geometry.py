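"""Rigid subunit models, pair interactions, and reference capsid geometries.

Two coarse-grained capsid subunits are provided:

* **Dodecahedron model** -- a pentagonal subunit with circumradius ``l0``.
  Five attractor (``A``) pseudoatoms sit at the pentagon vertices and carry
  a short-ranged Morse attraction of well depth ``eps_ss``.  A top (``T``)
  pseudoatom above the pentagon plane repels other ``T`` atoms (WCA),
  which enforces the dodecahedral dihedral angle (116.57 deg) at bonded
  contact, and a bottom (``B``) pseudoatom repels ``T`` atoms to block
  upside-down binding.  Twelve subunits close into a dodecahedral shell.

* **Icosahedron model** -- a triangular subunit of diameter ~= ``3 sigma``
  built from 45 excluder pseudoatoms (WCA excluded volume) tiling the face,
  plus 6 attractor pseudoatoms, two per edge, that bind complementary
  attractors on a partner edge through a Lennard-Jones well of depth
  ``eps_ss``.  Twenty subunits close into a T=1 icosahedral shell.

All quantities are in reduced units: energies in units of kT, lengths in
units of ``l0`` (dodecahedron) or ``sigma`` (icosahedron), subunit mass 1.

In the bound state the Morse attractors of neighbouring pentagons coincide
(``r_eq = 0``): two pentagons sharing an edge share both edge vertices, so
an assembled shell places matching attractors exactly on top of each other.
The repulsive diameters are derived from the closed-shell geometry so that
the assembled capsid is unfrustrated (zero repulsion, every attractor pair
at its minimum).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PseudoAtom",
    "SubunitTemplate",
    "PairPotential",
    "InteractionTable",
    "ReferenceCapsid",
    "build_dodecahedron_subunit",
    "build_icosahedron_subunit",
    "build_interaction_table",
    "pair_energy",
    "pair_force_mag",
    "assemble_reference_capsid",
    "estimate_capsid_diameter",
    "quat_to_matrix",
    "matrix_to_quat",
    "rotate",
]

GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0

#: cos of the angle between outward normals of adjacent dodecahedron faces
#: (pi minus the dihedral angle 116.565 deg)
_COS_DODE_NORMALS = 1.0 / math.sqrt(5.0)

#: icosahedron dihedral angle, 138.19 deg
ICO_DIHEDRAL = math.acos(-math.sqrt(5.0) / 3.0)

#: distance of a pentagon face center from the dodecahedron center,
#: for face circumradius 1 (equals phi^2 / 2)
DODE_FACE_CENTER_RADIUS = GOLDEN**2 / 2.0

# defaults for the dodecahedron subunit (heights in units of l0)
DEFAULT_H_T = 0.5
DEFAULT_H_B = 0.25
#: slack factor keeping the T-T WCA cutoff just inside the closed-shell
#: T-T separation, so the assembled capsid feels no residual repulsion
_TT_SLACK = 0.995
#: amplitude of the T-T repulsion (kT).  The top spheres approach each
#: other as a bonded hinge opens past the capsid dihedral (1.90 l0 at the
#: capsid angle down to 1.62 l0 at flat), so this repulsion acts as the
#: dihedral spring.  At amplitude 1 the spring is so soft (~0.05 kT for a
#: 30 deg opening) that curvature-mismatched 13-14-subunit shells grow
#: freely; at 8 the same opening costs ~1 kT and shells close cleanly at
#: 12 subunits.  Calibrated together with the Morse cutoff.
DEFAULT_EPS_TT = 8.0
DEFAULT_SIGMA_BT = 1.0
DEFAULT_MORSE_ALPHA = 5.0
#: r_cut = r_eq + factor / alpha.  Calibrated (with alpha above) so that a
#: complete inter-subunit bond -- two vertex attractor contacts of the
#: cut-and-shifted Morse well -- is worth ~1.45 eps_ss: productive assembly
#: at eps_ss ~= 6-7 and aggregate-dominated misassembly only above that.
DEFAULT_MORSE_RCUT_FACTOR = 1.9

# defaults for the icosahedron subunit (lengths in units of sigma)
ICO_EDGE = 3.0 * math.sqrt(3.0) / 2.0   # binding-triangle edge, circumdiameter 3 sigma
ICO_EXCLUDER_INSET = 0.31               # excluder plate inset from the binding edge
ICO_ATTRACTOR_OFFSET = 0.30             # in-plane offset of attractors from the edge
ICO_SIGMA_EE = 0.5                      # excluder-excluder WCA contact diameter


class InvalidParameterError(ValueError):
    """Raised for non-physical model parameters."""


# --------------------------------------------------------------------------
# quaternion helpers (scalar-first convention, w x y z)

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion ``(w, x, y, z)``."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Unit quaternion ``(w, x, y, z)`` of a proper rotation matrix."""
    t = np.trace(R)
    if t > 0:
        w = 0.5 * math.sqrt(1.0 + t)
        s = 0.25 / w
        q = np.array(
            [w, (R[2, 1] - R[1, 2]) * s, (R[0, 2] - R[2, 0]) * s, (R[1, 0] - R[0, 1]) * s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1.0 + R[i, i] - R[j, j] - R[k, k], 0.0))
        qv = np.empty(3)
        qv[i] = 0.5 * s
        qv[j] = (R[j, i] + R[i, j]) / (2 * s)
        qv[k] = (R[k, i] + R[i, k]) / (2 * s)
        w = (R[k, j] - R[j, k]) / (2 * s)
        q = np.array([w, qv[0], qv[1], qv[2]])
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` (..., 3) by unit quaternion ``q``."""
    return v @ quat_to_matrix(q).T


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class PseudoAtom:
    """One interaction site of a rigid subunit.

    ``label`` is the role tag (``T``/``B``/``A`` for the dodecahedron model,
    ``EXC`` or ``A1..A3``/``B1..B3`` for the icosahedron model), ``position``
    the body-frame coordinate and ``diameter`` the length scale of the rule
    the site participates in.
    """

    label: str
    position: tuple[float, float, float]
    diameter: float


@dataclass(frozen=True)
class SubunitTemplate:
    """Rigid-body description of one capsid subunit.

    The body frame has the subunit centroid (equal point masses) at the
    origin and the face normal along +z (pointing out of the assembled
    shell).  ``inertia`` is the body-frame inertia tensor of the point-mass
    distribution with total mass 1; the body axes are principal axes.
    """

    model: str
    pseudoatoms: tuple[PseudoAtom, ...]
    mass: float
    inertia: np.ndarray                   # (3, 3)
    circumradius: float                   # envelope radius incl. atom radii
    n_bond_sites: int                     # 5 (dodecahedron), 3 (icosahedron)
    shape_diameter: float                 # circumscribed pentagon/triangle diameter
    length_scale: float                   # l0 or sigma
    # bond-detection geometry (body frame):
    #   dodecahedron: midpoints of the 5 pentagon edges
    #   icosahedron: 6 attractor positions, two per edge
    bond_points: np.ndarray = field(repr=False, default=None)
    bond_point_edge: np.ndarray = field(repr=False, default=None)  # edge id per point

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.pseudoatoms])

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.pseudoatoms)

    @property
    def principal_inertia(self) -> np.ndarray:
        return np.diag(self.inertia).copy()

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "mass": self.mass,
                "length_scale": self.length_scale,
                "n_bond_sites": self.n_bond_sites,
                "shape_diameter": self.shape_diameter,
                "circumradius": self.circumradius,
                "pseudoatoms": [
                    {"label": a.label, "position": list(a.position), "diameter": a.diameter}
                    for a in self.pseudoatoms
                ],
            }
        )

    @staticmethod
    def from_json(text: str) -> "SubunitTemplate":
        d = json.loads(text)
        atoms = tuple(
            PseudoAtom(a["label"], tuple(a["position"]), a["diameter"])
            for a in d["pseudoatoms"]
        )
        return _finalize_template(
            d["model"], atoms, d["length_scale"], d["n_bond_sites"], d["shape_diameter"]
        )


@dataclass(frozen=True)
class PairPotential:
    """Descriptor of one pair rule: WCA, MORSE, or LJ (cut and shifted)."""

    kind: str          # "WCA" | "MORSE" | "LJ"
    eps: float
    sigma: float = 0.0   # WCA/LJ length scale
    alpha: float = 0.0   # Morse inverse range
    r_eq: float = 0.0    # Morse minimum position
    r_cut: float = 0.0

    def energy(self, r: float, shifted: bool = True) -> float:
        if r <= 0:
            raise ValueError("pair separation must be positive")
        if r >= self.r_cut:
            return 0.0
        u = self._raw(r)
        if shifted:
            u -= self._raw(self.r_cut)
        return u

    def _raw(self, r: float) -> float:
        if self.kind == "WCA":
            sr6 = (self.sigma / r) ** 6
            return 4.0 * self.eps * (sr6 * sr6 - sr6) + self.eps
        if self.kind == "LJ":
            sr6 = (self.sigma / r) ** 6
            return 4.0 * self.eps * (sr6 * sr6 - sr6)
        if self.kind == "MORSE":
            x = math.exp(-self.alpha * (r - self.r_eq))
            return self.eps * (x * x - 2.0 * x)
        raise ValueError(f"unknown pair kind {self.kind!r}")

    def force_mag(self, r: float) -> float:
        """-du/dr (positive = repulsive) of the cut-and-shifted potential."""
        if r <= 0:
            raise ValueError("pair separation must be positive")
        if r >= self.r_cut:
            return 0.0
        if self.kind in ("WCA", "LJ"):
            sr6 = (self.sigma / r) ** 6
            return 24.0 * self.eps * (2.0 * sr6 * sr6 - sr6) / r
        x = math.exp(-self.alpha * (r - self.r_eq))
        return 2.0 * self.alpha * self.eps * (x * x - x)

    @property
    def is_attractive(self) -> bool:
        return self.kind in ("MORSE", "LJ") and self.eps > 0


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric mapping from unordered role pairs to pair potentials."""

    model: str
    rules: dict[tuple[str, str], PairPotential]
    eps_ss: float

    def get(self, role_i: str, role_j: str) -> PairPotential | None:
        return self.rules.get(_key(role_i, role_j))

    @property
    def max_cutoff(self) -> float:
        return max(p.r_cut for p in self.rules.values())

    def roles(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a, b in self.rules:
            for r in (a, b):
                if r not in seen:
                    seen.append(r)
        return tuple(seen)


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ReferenceCapsid:
    """Poses of a complete capsid: centers and orientations of each subunit."""

    model: str
    centers: np.ndarray        # (N_cap, 3)
    orientations: np.ndarray   # (N_cap, 4) unit quaternions
    n_cap: int
    n_bonds_complete: int

    @property
    def subunit_poses(self):
        return list(zip(self.centers, self.orientations))


# --------------------------------------------------------------------------
# subunit builders

def _inertia_tensor(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    I = np.zeros((3, 3))
    for m, r in zip(masses, positions):
        I += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    return I


def _finalize_template(model, atoms, length_scale, n_bond_sites, shape_diameter):
    pos = np.array([a.position for a in atoms])
    masses = np.full(len(atoms), 1.0 / len(atoms))
    inertia = _inertia_tensor(pos, masses)
    circ = float(max(np.linalg.norm(p) + a.diameter / 2 for p, a in zip(pos, atoms)))
    bond_points, bond_edge = _bond_points(model, atoms)
    return SubunitTemplate(
        model=model,
        pseudoatoms=atoms,
        mass=1.0,
        inertia=inertia,
        circumradius=circ,
        n_bond_sites=n_bond_sites,
        shape_diameter=shape_diameter,
        length_scale=length_scale,
        bond_points=bond_points,
        bond_point_edge=bond_edge,
    )


def _bond_points(model: str, atoms) -> tuple[np.ndarray, np.ndarray]:
    if model == "dodecahedron":
        a_pos = np.array([a.position for a in atoms if a.label == "A"])
        n = len(a_pos)
        mids = np.array([(a_pos[k] + a_pos[(k + 1) % n]) / 2.0 for k in range(n)])
        return mids, np.arange(n)
    att = [(a.label, np.array(a.position)) for a in atoms if a.label != "EXC"]
    # order: edge k contributes (Ak, Bk)
    pts, edges = [], []
    for k in (1, 2, 3):
        for tag in (f"A{k}", f"B{k}"):
            (p,) = [p for lbl, p in att if lbl == tag]
            pts.append(p)
            edges.append(k - 1)
    return np.array(pts), np.array(edges)


def tt_sigma(l0: float, h_t: float = DEFAULT_H_T) -> float:
    """T-T WCA diameter placing the repulsive cutoff at the closed-shell
    T-T separation, so the dihedral angle is enforced without frustrating
    the assembled capsid."""
    r_top = DODE_FACE_CENTER_RADIUS * l0 + h_t * l0
    half = math.sqrt((1.0 - _COS_DODE_NORMALS) / 2.0)  # sin(theta_normals / 2)
    separation = 2.0 * r_top * half
    return _TT_SLACK * separation / 2 ** (1.0 / 6.0)


def build_dodecahedron_subunit(
    l0: float, h_t: float = DEFAULT_H_T, h_b: float = DEFAULT_H_B
) -> SubunitTemplate:
    """Pentagonal subunit with circumradius ``l0``.

    Five ``A`` attractors at the pentagon vertices, one ``T`` sphere a
    height ``h_t * l0`` above the pentagon plane on the symmetry axis and
    one ``B`` sphere ``h_b * l0`` below it.  The body origin is the centroid
    of the seven equal point masses, +z along the outward face normal.
    """
    if l0 <= 0:
        raise InvalidParameterError("l0 must be positive")
    z_plane = (h_b - h_t) * l0 / 7.0  # centroid at origin
    d_tt = tt_sigma(l0, h_t)
    atoms = []
    for k in range(5):
        th = 2.0 * math.pi * k / 5.0
        atoms.append(
            PseudoAtom(
                "A",
                (l0 * math.cos(th), l0 * math.sin(th), z_plane),
                DEFAULT_MORSE_RCUT_FACTOR / DEFAULT_MORSE_ALPHA * l0,
            )
        )
    atoms.append(PseudoAtom("T", (0.0, 0.0, z_plane + h_t * l0), d_tt))
    atoms.append(PseudoAtom("B", (0.0, 0.0, z_plane - h_b * l0), DEFAULT_SIGMA_BT * l0))
    return _finalize_template("dodecahedron", tuple(atoms), l0, 5, 2.0 * l0)


def ico_lj_sigma(sigma: float) -> float:
    """LJ length placing the attractor-pair minimum at the separation the
    matched attractors have when two faces meet at the icosahedral dihedral."""
    sep = 2.0 * ICO_ATTRACTOR_OFFSET * sigma * math.sin(ICO_DIHEDRAL / 2.0)
    return sep / 2 ** (1.0 / 6.0)


def build_icosahedron_subunit(sigma: float) -> SubunitTemplate:
    """Triangular subunit of diameter ~= ``3 sigma``.

    45 ``EXC`` excluders tile an inset triangular plate (9 rows of a
    triangular grid); 6 attractors sit two per edge, offset slightly into
    the face.  Edge ``k`` carries attractors tagged ``Ak`` (one third of the
    way along the edge, counterclockwise seen from outside) and ``Bk`` (two
    thirds).  Only A-type/B-type pairs attract, so two edges bind in the
    back-to-back orientation that realizes the icosahedral dihedral.
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    e = ICO_EDGE * sigma
    r_t = e / math.sqrt(3.0)  # binding-triangle circumradius = 1.5 sigma
    # corner 0 along body +x so reference-capsid poses map corners onto
    # polyhedron vertices
    corners = np.array(
        [
            [r_t * math.cos(a), r_t * math.sin(a), 0.0]
            for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
        ]
    )
    atoms: list[PseudoAtom] = []
    # excluder plate: triangular grid on the inset triangle
    inset_corners = corners * (1.0 - 2.0 * math.sqrt(3.0) * ICO_EXCLUDER_INSET * sigma / e)
    A, B, C = inset_corners
    for i in range(9):
        for j in range(9 - i):
            p = A + (i / 8.0) * (B - A) + (j / 8.0) * (C - A)
            atoms.append(PseudoAtom("EXC", tuple(p), ICO_SIGMA_EE * sigma))
    # attractors, two per edge
    d_lj = ico_lj_sigma(sigma)
    for k in range(3):
        P, Q = corners[k], corners[(k + 1) % 3]
        t_hat = (Q - P) / np.linalg.norm(Q - P)
        n_in = np.cross([0.0, 0.0, 1.0], t_hat)  # inward for ccw ordering
        for tag, frac in ((f"A{k + 1}", 1.0 / 3.0), (f"B{k + 1}", 2.0 / 3.0)):
            p = P + frac * e * t_hat + ICO_ATTRACTOR_OFFSET * sigma * n_in
            atoms.append(PseudoAtom(tag, tuple(p), d_lj))
    return _finalize_template("icosahedron", tuple(atoms), sigma, 3, 3.0 * sigma)


# --------------------------------------------------------------------------
# interaction tables

def build_interaction_table(model: str, eps_ss: float, length_scale: float = 1.0) -> InteractionTable:
    """Pair rules for the chosen model with attraction well depth ``eps_ss``.

    Repulsive rules (WCA) are independent of ``eps_ss``; only attractor
    pairs carry the well depth.  All potentials are cut and shifted to zero
    at their cutoff.
    """
    if eps_ss < 0:
        raise InvalidParameterError("eps_ss must be non-negative")
    s = length_scale
    if s <= 0:
        raise InvalidParameterError("length_scale must be positive")
    rules: dict[tuple[str, str], PairPotential] = {}
    if model == "dodecahedron":
        d_tt = tt_sigma(s)
        rules[_key("T", "T")] = PairPotential(
            "WCA", DEFAULT_EPS_TT, sigma=d_tt, r_cut=2 ** (1.0 / 6.0) * d_tt
        )
        d_bt = DEFAULT_SIGMA_BT * s
        rules[_key("B", "T")] = PairPotential(
            "WCA", 1.0, sigma=d_bt, r_cut=2 ** (1.0 / 6.0) * d_bt
        )
        alpha = DEFAULT_MORSE_ALPHA / s
        rules[_key("A", "A")] = PairPotential(
            "MORSE",
            eps_ss,
            alpha=alpha,
            r_eq=0.0,
            r_cut=DEFAULT_MORSE_RCUT_FACTOR / alpha,
        )
    elif model == "icosahedron":
        d_ee = ICO_SIGMA_EE * s
        rules[_key("EXC", "EXC")] = PairPotential(
            "WCA", 1.0, sigma=d_ee, r_cut=2 ** (1.0 / 6.0) * d_ee
        )
        d_lj = ico_lj_sigma(s)
        for i in (1, 2, 3):
            for j in (1, 2, 3):
                rules[_key(f"A{i}", f"B{j}")] = PairPotential(
                    "LJ", eps_ss, sigma=d_lj, r_cut=2.0 * d_lj
                )
    else:
        raise InvalidParameterError(f"unknown model {model!r}")
    return InteractionTable(model=model, rules=rules, eps_ss=eps_ss)


def pair_energy(
    table: InteractionTable, role_i: str, role_j: str, r: float, shifted: bool = True
) -> float:
    """Pair potential between two roles at separation ``r`` (0 beyond cutoff)."""
    if r <= 0:
        raise ValueError("pair separation must be positive")
    rule = table.get(role_i, role_j)
    if rule is None:
        return 0.0
    return rule.energy(r, shifted=shifted)


def pair_force_mag(table: InteractionTable, role_i: str, role_j: str, r: float) -> float:
    rule = table.get(role_i, role_j)
    if rule is None:
        return 0.0
    return rule.force_mag(r)


# --------------------------------------------------------------------------
# reference capsids

def _regular_faces(verts: np.ndarray, face_size: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Face centers and ccw-ordered face vertices of the convex regular
    polyhedron spanned by ``verts``, normalized so the face circumradius
    (vertex distance from its face center) equals 1."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(verts)
    # group hull triangles into coplanar faces by their outward plane
    groups: dict[tuple[int, ...], set[int]] = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        key = tuple(np.round(eq, 6))
        groups.setdefault(key, set()).update(simplex)
    # identical planes can round differently; merge by offset/normal match
    merged: list[tuple[np.ndarray, set[int]]] = []
    for key, idx in groups.items():
        n = np.array(key[:3])
        for n2, idx2 in merged:
            if np.linalg.norm(n - n2[:3]) < 1e-4 and abs(key[3] - n2[3]) < 1e-4:
                idx2.update(idx)
                break
        else:
            merged.append((np.array(key), set(idx)))
    centers, faces = [], []
    for _, idx in merged:
        fv = verts[sorted(idx)]
        assert len(fv) == face_size
        c = fv.mean(axis=0)
        n = c / np.linalg.norm(c)
        e1 = fv[0] - c
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        ang = np.arctan2((fv - c) @ e2, (fv - c) @ e1)
        faces.append(fv[np.argsort(ang)])
        centers.append(c)
    centers = np.array(centers)
    rc = np.linalg.norm(faces[0][0] - centers[0])
    return centers / rc, [f / rc for f in faces]


def _dodecahedron_faces() -> tuple[np.ndarray, list[np.ndarray]]:
    """Unit-scale regular dodecahedron: 12 face centers and ordered face
    vertex rings, with face circumradius normalized to 1."""
    phi = GOLDEN
    verts = [(sx, sy, sz) for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
    for a in (1 / phi, -1 / phi):
        for b in (phi, -phi):
            verts += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    return _regular_faces(np.array(verts, dtype=float), 5)


def _icosahedron_faces() -> tuple[np.ndarray, list[np.ndarray]]:
    """Unit-scale regular icosahedron: 20 face centers and ordered corner
    triples, with face circumradius normalized to 1."""
    phi = GOLDEN
    verts = []
    for a in (1, -1):
        for b in (phi, -phi):
            verts += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    return _regular_faces(np.array(verts, dtype=float), 3)


def assemble_reference_capsid(model: str, template: SubunitTemplate) -> ReferenceCapsid:
    """Poses placing subunits on the faces of the regular polyhedron.

    Matching attractor sites of neighbouring subunits coincide
    (dodecahedron) or sit at their pair-potential minimum (icosahedron), so
    the assembled shell satisfies the trajectory-analysis bond criterion on
    every shared edge.
    """
    if model != template.model:
        raise InvalidParameterError("template does not match requested model")
    if model == "dodecahedron":
        centers_u, faces = _dodecahedron_faces()
        scale = template.length_scale
        n_cap, n_bonds = 12, 30
        # body-frame pentagon plane offset (A atoms sit at z = z_plane)
        z_plane = [a.position[2] for a in template.pseudoatoms if a.label == "A"][0]
        shape_r = template.length_scale
    elif model == "icosahedron":
        centers_u, faces = _icosahedron_faces()
        # unit-scale faces have circumradius 1; binding triangle has
        # circumradius 1.5 sigma
        scale = 1.5 * template.length_scale
        n_cap, n_bonds = 20, 30
        z_plane = 0.0
        shape_r = 1.5 * template.length_scale
    else:
        raise InvalidParameterError(f"unknown model {model!r}")

    centers = []
    quats = []
    for c_u, fv_u in zip(centers_u, faces):
        c = c_u * scale
        fv = fv_u * scale
        n = c / np.linalg.norm(c)
        e1 = fv[0] - c
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        R = np.column_stack([e1, e2, n])
        # body vertex 0 lies along body +x at radius shape_r in the plane
        # z = z_plane; world position of the body origin:
        X = c - z_plane * n
        centers.append(X)
        quats.append(matrix_to_quat(R))
    return ReferenceCapsid(
        model=model,
        centers=np.array(centers),
        orientations=np.array(quats),
        n_cap=n_cap,
        n_bonds_complete=n_bonds,
    )


def world_atoms(
    template: SubunitTemplate, centers: np.ndarray, orientations: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World-frame pseudoatom positions for a set of subunit poses.

    Returns ``(positions, role_index, body_index)`` where ``role_index``
    maps into ``template.roles``.
    """
    body = template.positions
    n_at = len(body)
    roles = np.arange(n_at)
    out_pos = np.empty((len(centers) * n_at, 3))
    out_role = np.empty(len(centers) * n_at, dtype=int)
    out_body = np.empty(len(centers) * n_at, dtype=int)
    for i, (c, q) in enumerate(zip(centers, orientations)):
        R = quat_to_matrix(q)
        out_pos[i * n_at : (i + 1) * n_at] = c + body @ R.T
        out_role[i * n_at : (i + 1) * n_at] = roles
        out_body[i * n_at : (i + 1) * n_at] = i
    return out_pos, out_role, out_body


def capsid_attraction_energy(
    capsid: ReferenceCapsid, template: SubunitTemplate, table: InteractionTable
) -> float:
    """Total attractive pair energy of a reference capsid (shifted rules)."""
    pos, role_idx, body_idx = world_atoms(template, capsid.centers, capsid.orientations)
    roles = template.roles
    total = 0.0
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            if body_idx[i] == body_idx[j]:
                continue
            rule = table.get(roles[role_idx[i]], roles[role_idx[j]])
            if rule is None or not rule.is_attractive:
                continue
            r = float(np.linalg.norm(pos[i] - pos[j]))
            if r < 1e-12:
                total += rule.energy(1e-12)
            else:
                total += rule.energy(r)
    return total


def min_bond_energy(table: InteractionTable) -> float:
    """Energy of one complete inter-subunit bond at its minimum.

    For the dodecahedron model a bond is a shared pentagon edge: two
    coincident attractor pairs, each at the (shifted) Morse minimum.  For
    the icosahedron model a bond is a matched edge: two attractor pairs at
    the LJ minimum separation.
    """
    if table.model == "dodecahedron":
        rule = table.get("A", "A")
        return 2.0 * rule.energy(1e-15)
    rule = table.get("A1", "B1")
    return 2.0 * rule.energy(2 ** (1.0 / 6.0) * rule.sigma)


def estimate_capsid_diameter(capsid: ReferenceCapsid, template: SubunitTemplate) -> float:
    """Diameter of the sphere circumscribing the capsid's pseudoatoms
    (including their repulsive radii)."""
    pos, role_idx, _ = world_atoms(template, capsid.centers, capsid.orientations)
    diam = np.array([a.diameter for a in template.pseudoatoms])
    return float(2.0 * np.max(np.linalg.norm(pos, axis=1) + diam[role_idx] / 2.0))
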