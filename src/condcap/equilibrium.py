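"""Equilibrium theories of condensate-coupled capsid assembly.

Two levels of theory predict how subunits and assembled capsids partition
between a condensate (volume ``V_c``, field depth ``eps_c``) and the
background (volume ``V_bg``), and how much assembles:

* **Ideal solution (IS)** -- point particles; the monomer partition
  coefficient is ``K_c = exp(eps_c)`` (reduced units, beta = 1) and
  assembly follows the law of mass action.

* **Hard sphere (HS)** -- monomers and capsids are effective hard spheres
  of diameters ``sigma_sub`` and ``sigma_cap``; excess chemical potentials
  come from the Carnahan-Starling equation of state and its binary-mixture
  extension (BMCSL).  Excluded volume suppresses partitioning once the
  condensate packing fraction grows, which produces the non-monotonic
  yield-versus-concentration behaviour that ideal-solution theory misses.

The two-state approximation is used throughout: subunits exist either as
free monomers or as part of complete capsids of ``N_cap`` subunits.
Equilibrium imposes (i) in-phase mass action ``mu_cap = N_cap * mu_1`` and
(ii) cross-phase equality of each species' chemical potential, plus total
mass conservation.  Since a capsid couples to the condensate field with
``N_cap * eps_c``, the field term cancels from the in-phase mass action;
LLPS boosts assembly through the elevated monomer density inside.

Densities are number densities in reduced units; thermal-wavelength
factors are absorbed into the capsid formation free energy ``dG_cap``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from condcap.geometry import (
    InteractionTable,
    SubunitTemplate,
    assemble_reference_capsid,
    build_interaction_table,
    estimate_capsid_diameter,
    min_bond_energy,
    quat_to_matrix,
)

__all__ = [
    "TheoryParams",
    "PhaseSolution",
    "kc_ideal",
    "cs_mu_excess",
    "bmcsl_mu_excess",
    "solve_partition_no_assembly",
    "solve_two_state_equilibrium",
    "close_packing_concentration",
    "threshold_volume_ratio",
    "close_packed_yield",
    "capsid_free_energy",
    "default_bond_entropy",
    "effective_subunit_diameter",
    "dodecahedron_theory_params",
]

ETA_CLOSE_PACK = math.pi / (3.0 * math.sqrt(2.0))  # 0.7405
_REL_TOL = 1e-10

#: printed effective capsid hard-sphere diameter for the dodecahedron model
SIGMA_CAP_DODECAHEDRON = 5.1

#: bulk critical subunit concentration used to calibrate the per-bond
#: entropic penalty at the reference binding strength eps_ss = 6 (the
#: concentration around which bulk assembly turns on)
RHO_CSC_REFERENCE = 1.0e-3
EPS_SS_REFERENCE = 6.0


class SaturationError(RuntimeError):
    """The condensate cannot accommodate the requested material below the
    packing limit."""


@dataclass(frozen=True)
class TheoryParams:
    """Inputs of the two-state phase-partitioning theories.

    ``dG_cap`` is the standard free energy of forming one capsid from
    ``N_cap`` monomers (negative favours assembly); ``V_r = V_c / V_bg``.
    ``mode`` selects ideal-solution ("ideal") or hard-sphere
    ("hard_sphere") chemical potentials.
    """

    N_cap: int
    sigma_sub: float
    sigma_cap: float
    dG_cap: float
    eps_c: float
    V_r: float
    rho_T: float
    mode: str = "hard_sphere"

    def __post_init__(self):
        if self.mode not in ("ideal", "hard_sphere"):
            raise ValueError("mode must be 'ideal' or 'hard_sphere'")
        if not (self.sigma_cap > self.sigma_sub > 0):
            raise ValueError("require sigma_cap > sigma_sub > 0")
        if self.rho_T <= 0 or self.V_r <= 0:
            raise ValueError("rho_T and V_r must be positive")


@dataclass(frozen=True)
class PhaseSolution:
    """Equilibrium densities, partitioning, and yields of the two phases."""

    rho1_c: float
    rho1_bg: float
    rhocap_c: float
    rhocap_bg: float
    K_c: float
    eta_c: float
    eta_bg: float
    f_c: float
    f_c_c: float
    f_c_bg: float
    params: TheoryParams

    def mass_residual(self) -> float:
        """Relative error of total mass conservation (should be ~1e-10)."""
        p = self.params
        total = (self.rho1_c + p.N_cap * self.rhocap_c) * p.V_r + (
            self.rho1_bg + p.N_cap * self.rhocap_bg
        )
        return abs(total - p.rho_T * (1.0 + p.V_r)) / (p.rho_T * (1.0 + p.V_r))


# --------------------------------------------------------------------------
# chemical potentials

def kc_ideal(eps_c: float) -> float:
    """Ideal-solution partition coefficient ``exp(eps_c)`` (beta = 1)."""
    return math.exp(eps_c)


def cs_mu_excess(eta: float) -> float:
    """Carnahan-Starling excess chemical potential of a one-component hard
    sphere fluid at packing fraction ``eta``.

    Warns above ``eta = 0.5`` where the equation of state deviates
    significantly from real hard-sphere behaviour.
    """
    if eta < 0 or eta >= 1:
        raise ValueError("packing fraction must lie in [0, 1)")
    if eta > 0.5:
        warnings.warn(
            "Carnahan-Starling used at eta > 0.5; results are unreliable",
            stacklevel=2,
        )
    return (8.0 * eta - 9.0 * eta**2 + 3.0 * eta**3) / (1.0 - eta) ** 3


def bmcsl_mu_excess(etas, sigmas, species: int) -> float:
    """Excess chemical potential of one species in a binary hard-sphere
    mixture (BMCSL equation of state).

    Parameters
    ----------
    etas, sigmas:
        Per-species packing fractions and diameters (length 2; a species
        at zero density is allowed).
    species:
        Index (0 or 1) of the species whose chemical potential is wanted.

    The expression is the analytic derivative of the BMCSL excess free
    energy density with respect to the species density; it reduces exactly
    to the Carnahan-Starling form when the diameters are equal.
    """
    etas = np.asarray(etas, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(etas < 0) or np.any(sigmas <= 0):
        raise ValueError("packing fractions must be >= 0 and diameters > 0")
    rho = 6.0 * etas / (math.pi * sigmas**3)
    x = [math.pi / 6.0 * float(np.dot(rho, sigmas**n)) for n in range(4)]
    x0, x1, x2, x3 = x
    if x3 >= 1.0:
        raise ValueError("total packing fraction must be < 1")
    if x3 > 0.5:
        warnings.warn(
            "BMCSL used at total packing fraction > 0.5; results are unreliable",
            stacklevel=2,
        )
    si = float(sigmas[species])
    if x3 < 1e-9:
        # virial limit, avoids 0/0 in the closed form
        return float(math.pi / 6.0 * np.dot(rho, (si + sigmas) ** 3))
    om = 1.0 - x3
    log_om = math.log1p(-x3)
    # F_n = (pi/6) dA_ex/dxi_n, so that mu_i = sum_n F_n sigma_i^n
    F = (
        -log_om,
        3.0 * x2 / om,
        3.0 * (x1 * x3**2 * om + x2**2 * x3 + x2**2 * om**2 * log_om)
        / (x3**2 * om**2),
        (
            3.0 * x1 * x2 * x3**3 * om
            + 2.0 * x2**3 * x3**2
            - x2**3 * x3 * om
            - 2.0 * x2**3 * om**3 * log_om
            - x3 * om**2 * (x2**3 - x0 * x3**2)
        )
        / (x3**3 * om**3),
    )
    return float(sum(f * si**n for n, f in enumerate(F)))


def _mu_ex_1(rho1: float, rhocap: float, p: TheoryParams) -> float:
    if p.mode == "ideal":
        return 0.0
    eta1 = math.pi / 6.0 * rho1 * p.sigma_sub**3
    etac = math.pi / 6.0 * rhocap * p.sigma_cap**3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bmcsl_mu_excess((eta1, etac), (p.sigma_sub, p.sigma_cap), 0)


def _mu_ex_cap(rho1: float, rhocap: float, p: TheoryParams) -> float:
    if p.mode == "ideal":
        return 0.0
    eta1 = math.pi / 6.0 * rho1 * p.sigma_sub**3
    etac = math.pi / 6.0 * rhocap * p.sigma_cap**3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bmcsl_mu_excess((eta1, etac), (p.sigma_sub, p.sigma_cap), 1)


def _eta_total(rho1: float, rhocap: float, p: TheoryParams) -> float:
    return math.pi / 6.0 * (rho1 * p.sigma_sub**3 + rhocap * p.sigma_cap**3)


# --------------------------------------------------------------------------
# solvers

def solve_partition_no_assembly(params: TheoryParams) -> PhaseSolution:
    """Monomer partitioning without assembly (``eps_ss = 0``).

    Solves ``mu_1^c = mu_1^bg`` with
    ``mu_1 = ln rho_1 + mu_ex(eta) - eps_c [in condensate]`` together with
    mass conservation, by bracketed root finding on the background monomer
    density.  In ideal mode the closed form ``K_c = exp(eps_c)`` is used.
    """
    p = params
    total = p.rho_T * (1.0 + p.V_r)  # per unit background volume
    if p.mode == "ideal":
        kc = kc_ideal(p.eps_c)
        rho1_bg = total / (1.0 + kc * p.V_r)
        rho1_c = kc * rho1_bg
        return _package(rho1_c, rho1_bg, 0.0, 0.0, p)

    def g(rho1_bg: float) -> float:
        rho1_c = (total - rho1_bg) / p.V_r
        eta_c = _eta_total(rho1_c, 0.0, p)
        if eta_c >= ETA_CLOSE_PACK:
            return math.inf
        mu_c = math.log(rho1_c) + _mu_ex_1(rho1_c, 0.0, p) - p.eps_c
        mu_bg = math.log(rho1_bg) + _mu_ex_1(rho1_bg, 0.0, p)
        return mu_c - mu_bg

    lo, hi = total * 1e-16, total * (1.0 - 1e-13)
    if not math.isfinite(g(lo)):
        # even with almost everything in the background the condensate
        # density would exceed the packing limit
        raise SaturationError(
            "condensate packing fraction exceeds the close-packing bound "
            f"(rho_T={p.rho_T:g}, V_r={p.V_r:g}, eps_c={p.eps_c:g})"
        )
    rho1_bg = brentq(g, lo, hi, rtol=_REL_TOL, maxiter=300)
    rho1_c = (total - rho1_bg) / p.V_r
    return _package(rho1_c, rho1_bg, 0.0, 0.0, p)


def _phase_composition(mu1: float, eps: float, p: TheoryParams) -> tuple[float, float]:
    """Equilibrium (rho_1, rho_cap) of one phase with field depth ``eps``
    given the monomer chemical potential ``mu1`` (and, through mass action,
    ``mu_cap = N_cap mu1``).

    The mixture free energy is convex, so the composition is unique.
    Solved by a damped fixed-point / Newton iteration in log densities.
    """
    target = mu1 + eps
    lrc_ideal = min(p.N_cap * target - p.dG_cap, 700.0)
    if p.mode == "ideal":
        return math.exp(min(target, 700.0)), math.exp(lrc_ideal)

    eta_wall = 0.9999  # hard numerical wall, far beyond validity

    def lr1_given_cap(rhocap: float) -> float:
        # solve ln rho1 + mu_ex_1(rho1, rhocap) = target; monotone in rho1
        def f(lr1: float) -> float:
            return lr1 + _mu_ex_1(math.exp(lr1), rhocap, p) - target

        hi = target  # mu_ex >= 0 so f(hi) >= 0
        eta_cap = math.pi / 6.0 * rhocap * p.sigma_cap**3
        # keep rho1 below the numerical packing wall
        rho1_wall = 6.0 * (eta_wall - eta_cap) / (math.pi * p.sigma_sub**3)
        hi = min(hi, math.log(rho1_wall) - 1e-9)
        if f(hi) < 0:
            return hi  # pinned at the wall (only reachable mid-bracketing)
        lo = hi - 5.0
        while f(lo) > 0:
            lo -= 10.0
            if lo < -760:
                return -760.0
        return brentq(f, lo, hi, rtol=1e-15, maxiter=300)

    def G(lrc: float) -> float:
        rhocap = math.exp(lrc)
        if math.pi / 6.0 * rhocap * p.sigma_cap**3 >= eta_wall:
            return math.inf
        rho1 = math.exp(lr1_given_cap(rhocap))
        return lrc + _mu_ex_cap(rho1, rhocap, p) + p.dG_cap - p.N_cap * target

    # G is strictly increasing (Schur complement of the convex mixture free
    # energy), so a single bracketed root gives the unique composition.
    hi = math.log(6.0 * eta_wall / (math.pi * p.sigma_cap**3)) - 1e-9
    lo = min(lrc_ideal, hi) - 5.0
    while G(lo) > 0:
        lo -= 10.0
        if lo < -760:
            # no capsids at any relevant density
            return math.exp(lr1_given_cap(0.0)), 0.0
    if G(hi) < 0:
        raise SaturationError("phase composition pinned at the packing wall")
    lrc = brentq(G, lo, hi, rtol=1e-15, maxiter=300)
    rhocap = math.exp(lrc)
    return math.exp(lr1_given_cap(rhocap)), rhocap


def solve_two_state_equilibrium(params: TheoryParams) -> PhaseSolution:
    """Full two-state equilibrium: monomers and capsids in both phases.

    Cross-phase equality makes the monomer chemical potential ``mu1`` (and
    via mass action the capsid one) common to both phases, so the problem
    reduces to a single bracketed root find on ``mu1`` imposing total mass
    conservation; total mass is strictly increasing in ``mu1``.
    """
    p = params
    total = p.rho_T * (1.0 + p.V_r)

    def mass(mu1: float) -> float:
        rho1_c, rhocap_c = _phase_composition(mu1, p.eps_c, p)
        rho1_bg, rhocap_bg = _phase_composition(mu1, 0.0, p)
        return (
            (rho1_c + p.N_cap * rhocap_c) * p.V_r
            + rho1_bg
            + p.N_cap * rhocap_bg
            - total
        )

    def eta_c_of(mu1: float) -> float:
        rho1_c, rhocap_c = _phase_composition(mu1, p.eps_c, p)
        return _eta_total(rho1_c, rhocap_c, p)

    # bracket mu1: start from the dilute ideal guess and expand
    mu_lo = math.log(total) - p.eps_c - 5.0
    while mass(mu_lo) > 0:
        mu_lo -= 10.0
        if mu_lo < -750:
            raise RuntimeError("failed to bracket the chemical potential")
    mu_hi = mu_lo
    step = 2.0
    for _ in range(2000):
        trial = mu_hi + step
        if p.mode == "hard_sphere" and eta_c_of(trial) >= ETA_CLOSE_PACK:
            step *= 0.5
            if step < 1e-12:
                raise SaturationError(
                    "condensate reaches the close-packing bound before "
                    "accommodating the total subunit mass "
                    f"(rho_T={p.rho_T:g}, V_r={p.V_r:g}, eps_c={p.eps_c:g})"
                )
            continue
        mu_hi = trial
        if mass(mu_hi) > 0:
            break
    else:
        raise RuntimeError("failed to bracket the chemical potential")

    mu1 = brentq(mass, mu_lo, mu_hi, rtol=1e-14, maxiter=300)
    rho1_c, rhocap_c = _phase_composition(mu1, p.eps_c, p)
    rho1_bg, rhocap_bg = _phase_composition(mu1, 0.0, p)
    return _package(rho1_c, rho1_bg, rhocap_c, rhocap_bg, p)


def _package(rho1_c, rho1_bg, rhocap_c, rhocap_bg, p: TheoryParams) -> PhaseSolution:
    denom = p.rho_T * (1.0 + p.V_r)
    f_c_c = p.N_cap * rhocap_c * p.V_r / denom
    f_c_bg = p.N_cap * rhocap_bg / denom
    return PhaseSolution(
        rho1_c=rho1_c,
        rho1_bg=rho1_bg,
        rhocap_c=rhocap_c,
        rhocap_bg=rhocap_bg,
        K_c=rho1_c / rho1_bg if rho1_bg > 0 else math.inf,
        eta_c=_eta_total(rho1_c, rhocap_c, p),
        eta_bg=_eta_total(rho1_bg, rhocap_bg, p),
        f_c=f_c_c + f_c_bg,
        f_c_c=f_c_c,
        f_c_bg=f_c_bg,
        params=p,
    )


# --------------------------------------------------------------------------
# close-packing scaling laws

def close_packing_concentration(sigma_cap: float) -> float:
    """FCC close-packing number density ``sqrt(2) / sigma_cap^3`` of
    spheres with diameter ``sigma_cap``."""
    if sigma_cap <= 0:
        raise ValueError("sigma_cap must be positive")
    return math.sqrt(2.0) / sigma_cap**3


def threshold_volume_ratio(rho_T: float, N_cap: int, rho_CP: float) -> float:
    """Condensate volume ratio below which a close-packed condensate cannot
    hold all subunits: ``V_r* = 1 / (N_cap rho_CP / rho_T - 1)``."""
    if N_cap * rho_CP <= rho_T:
        raise ValueError(
            "N_cap * rho_CP must exceed rho_T: the condensate can never "
            "hold all subunits"
        )
    return 1.0 / (N_cap * rho_CP / rho_T - 1.0)


def close_packed_yield(V_r: float, V_r_star: float) -> float:
    """Maximum yield from the sphere-packing bound:
    ``f_CP = (1/V_r* + 1) / (1/V_r + 1)`` for ``V_r <= V_r*``, else 1."""
    if V_r <= 0 or V_r_star <= 0:
        raise ValueError("volume ratios must be positive")
    if V_r >= V_r_star:
        return 1.0
    return (1.0 / V_r_star + 1.0) / (1.0 / V_r + 1.0)


# --------------------------------------------------------------------------
# model-derived parameters

def default_bond_entropy(model: str = "dodecahedron") -> float:
    """Per-bond entropic penalty (kT) calibrated so the bulk critical
    subunit concentration at the reference binding strength equals
    ``RHO_CSC_REFERENCE`` (two-state convention
    ``rho_CSC = exp(dG_cap / (N_cap - 1))``)."""
    n_cap = 12 if model == "dodecahedron" else 20
    n_bonds = 30
    table = build_interaction_table(model, EPS_SS_REFERENCE)
    eps_bond = -min_bond_energy(table)
    dg_target = (n_cap - 1) * math.log(RHO_CSC_REFERENCE)
    return eps_bond + dg_target / n_bonds


def capsid_free_energy(
    eps_ss: float,
    model: str = "dodecahedron",
    ds_bond: float | None = None,
    n_bonds: int = 30,
) -> float:
    """Capsid formation free energy ``dG_cap = -n_bonds (eps_bond - ds_bond)``.

    The per-bond well depth ``eps_bond`` is measured from the pair-potential
    minimum of one complete inter-subunit bond; ``ds_bond`` is the per-bond
    entropic penalty (defaults to the calibrated value of
    :func:`default_bond_entropy`).
    """
    if ds_bond is None:
        ds_bond = default_bond_entropy(model)
    table = build_interaction_table(model, eps_ss)
    eps_bond = -min_bond_energy(table)
    return -n_bonds * (eps_bond - ds_bond)


def effective_subunit_diameter(
    template: SubunitTemplate,
    table: InteractionTable,
    n_orientations: int = 300,
    seed: int = 12345,
    dr: float = 0.02,
) -> float:
    """Orientation-averaged effective hard-sphere diameter of a subunit.

    Barker-Henderson-style construction: with ``f(r) = 1 - <exp(-u)>`` the
    Mayer average over random mutual orientations of the *repulsive* pair
    interactions, ``d_eff = (3 int f r^2 dr)^(1/3)``, which reproduces the
    model's repulsive second virial coefficient by construction.  The
    subunit's attractor sites carry no excluded volume, so this is much
    smaller than the circumscribing-sphere diameter.
    """
    rng = np.random.default_rng(seed)
    roles = template.roles
    rep_idx = [
        i
        for i, ri in enumerate(roles)
        if any(
            (rule := table.get(ri, rj)) is not None and not rule.is_attractive
            for rj in set(roles)
        )
    ]
    body = template.positions[rep_idx]
    rep_roles = [roles[i] for i in rep_idx]
    rules = {}
    for a in set(rep_roles):
        for b in set(rep_roles):
            rule = table.get(a, b)
            if rule is not None and not rule.is_attractive:
                rules[(a, b)] = rule
    r_max = 2.0 * max(np.linalg.norm(body, axis=1).max() + 0.0, 0.0) + table.max_cutoff
    r_grid = np.arange(dr / 2.0, r_max, dr)

    # random orientation pairs
    def rand_quats(n):
        q = rng.normal(size=(n, 4))
        return q / np.linalg.norm(q, axis=1)[:, None]

    qa, qb = rand_quats(n_orientations), rand_quats(n_orientations)
    pa = np.einsum("kij,aj->kai", np.array([quat_to_matrix(q) for q in qa]), body)
    pb = np.einsum("kij,aj->kai", np.array([quat_to_matrix(q) for q in qb]), body)

    mayer = np.empty(len(r_grid))
    for m, r in enumerate(r_grid):
        shift = np.array([0.0, 0.0, r])
        u = np.zeros(n_orientations)
        for i, ri in enumerate(rep_roles):
            for j, rj in enumerate(rep_roles):
                rule = rules.get((ri, rj))
                if rule is None:
                    continue
                d = np.linalg.norm(pb[:, j] + shift - pa[:, i], axis=1)
                mask = d < rule.r_cut
                if np.any(mask):
                    sr6 = (rule.sigma / d[mask]) ** 6
                    u[mask] += 4.0 * rule.eps * (sr6 * sr6 - sr6) + rule.eps
        mayer[m] = 1.0 - np.mean(np.exp(-np.clip(u, 0.0, 700.0)))
    d3 = 3.0 * np.sum(mayer * r_grid**2) * dr
    return float(d3 ** (1.0 / 3.0))


def dodecahedron_theory_params(
    eps_ss: float,
    eps_c: float,
    V_r: float,
    rho_T: float,
    mode: str = "hard_sphere",
    sigma_sub: float | None = None,
    sigma_cap: float = SIGMA_CAP_DODECAHEDRON,
    ds_bond: float | None = None,
) -> TheoryParams:
    """Theory parameters derived from the dodecahedron model geometry."""
    from condcap.geometry import build_dodecahedron_subunit

    if sigma_sub is None:
        template = build_dodecahedron_subunit(1.0)
        table = build_interaction_table("dodecahedron", 0.0)
        sigma_sub = effective_subunit_diameter(template, table)
    return TheoryParams(
        N_cap=12,
        sigma_sub=sigma_sub,
        sigma_cap=sigma_cap,
        dG_cap=capsid_free_energy(eps_ss, "dodecahedron", ds_bond=ds_bond),
        eps_c=eps_c,
        V_r=V_r,
        rho_T=rho_T,
        mode=mode,
    )
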