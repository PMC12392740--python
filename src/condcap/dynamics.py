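"""Rigid-body Langevin dynamics of capsid subunits in a periodic box.

The engine integrates translational and rotational Langevin equations for
rigid subunits built from pseudoatoms (see :mod:`condcap.geometry`),
coupled to the implicit condensate field at each body's center of mass.
The splitting is BAOAB: symplectic velocity-Verlet drift/kick with an
exact free-rotor quaternion update ("no-squish") and an exact
Ornstein-Uhlenbeck thermostat step; with ``gamma = 0`` the scheme reduces
to NVE and conserves energy to O(dt^2).

Reduced units: kT = 1, subunit mass = 1, lengths in l0 / sigma; the time
unit is ``t0 = l0 sqrt(m / kT)``.  The default friction ``gamma = 1``
gives a free-subunit diffusion constant ``D = kT / gamma = 1``; rotational
friction defaults to ``gamma * circumradius^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from condcap import _kernels as K
from condcap.condensate import CondensateSpec
from condcap.geometry import InteractionTable, SubunitTemplate, quat_to_matrix
from condcap.state import SystemState, Trajectory

__all__ = [
    "RunConfig",
    "initialize_random",
    "compute_forces",
    "compute_forces_bruteforce",
    "run",
    "measure_translational_diffusion",
    "PackingError",
    "UnstableTimestepError",
    "OverlapError",
]


class PackingError(RuntimeError):
    """Random placement failed: the box is too crowded."""


class UnstableTimestepError(RuntimeError):
    """Potential energy diverged during integration."""


class OverlapError(RuntimeError):
    """Two repulsive pseudoatoms collapsed below the numerical floor."""

    def __init__(self, atom_i: int, atom_j: int):
        super().__init__(f"pseudoatom overlap below numerical floor: atoms {atom_i}, {atom_j}")
        self.pair = (atom_i, atom_j)


ENERGY_DIVERGENCE = 1.0e6
PLACEMENT_RETRIES = 10_000


@dataclass(frozen=True)
class RunConfig:
    """Integration parameters (reduced units)."""

    dt: float = 5.0e-3
    gamma: float = 1.0
    temperature: float = 1.0
    t_F: float = 0.0
    snapshot_every: float = 500.0
    seed: int = 0
    neighbor_skin: float = 0.7
    gamma_rot: float | None = None  # default gamma * circumradius^2

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0 or self.t_F < 0:
            raise ValueError("gamma and t_F must be non-negative")


# --------------------------------------------------------------------------
# table packing

def _pack_table(template: SubunitTemplate, table: InteractionTable):
    roles = template.roles
    types = sorted(set(roles))
    tmap = {r: k for k, r in enumerate(types)}
    atom_type = np.array([tmap[r] for r in roles], dtype=np.int64)
    P = len(types)
    kind = np.zeros((P, P), dtype=np.int64)
    eps = np.zeros((P, P))
    par1 = np.zeros((P, P))
    req = np.zeros((P, P))
    rcut2 = np.zeros((P, P))
    shift = np.zeros((P, P))
    kind_code = {"WCA": 1, "MORSE": 2, "LJ": 3}
    for a in types:
        for b in types:
            rule = table.get(a, b)
            if rule is None or rule.eps == 0.0:
                continue
            i, j = tmap[a], tmap[b]
            kind[i, j] = kind_code[rule.kind]
            eps[i, j] = rule.eps
            par1[i, j] = rule.alpha if rule.kind == "MORSE" else rule.sigma
            req[i, j] = rule.r_eq
            rcut2[i, j] = rule.r_cut**2
            shift[i, j] = rule._raw(rule.r_cut)
    return atom_type, kind, eps, par1, req, rcut2, shift


def _field_params(spec: CondensateSpec | None):
    if spec is None or spec.eps_c == 0.0:
        return 0.0, 1.0, 1.0
    return spec.eps_c, spec.R_c, spec.alpha_C


# --------------------------------------------------------------------------
# initialization

def initialize_random(
    N: int,
    L: float,
    template: SubunitTemplate,
    seed: int,
    temperature: float = 1.0,
) -> SystemState:
    """Random non-overlapping centers, uniform orientations, and
    Maxwell-Boltzmann velocities/angular momenta at ``temperature``."""
    if N < 1:
        raise ValueError("N must be at least 1")
    rng = np.random.default_rng(seed)
    d_min = 2.0 * template.circumradius
    if N * (math.pi / 6.0) * d_min**3 > 0.55 * L**3:
        raise PackingError("requested density too high for random placement")
    centers = np.empty((N, 3))
    placed = 0
    while placed < N:
        for attempt in range(PLACEMENT_RETRIES):
            trial = rng.uniform(-L / 2.0, L / 2.0, size=3)
            if placed == 0:
                break
            d = centers[:placed] - trial
            d -= L * np.round(d / L)
            if np.min(np.einsum("ij,ij->i", d, d)) > d_min**2:
                break
        else:
            raise PackingError(f"failed to place subunit {placed} after {PLACEMENT_RETRIES} tries")
        centers[placed] = trial
        placed += 1

    q = rng.normal(size=(N, 4))
    q /= np.linalg.norm(q, axis=1)[:, None]
    vel = rng.normal(scale=math.sqrt(temperature), size=(N, 3))
    inertia = template.principal_inertia
    angmom = rng.normal(size=(N, 3)) * np.sqrt(inertia * temperature)
    return SystemState(
        centers=centers,
        orientations=q,
        velocities=vel,
        angular_momenta=angmom,
        box_L=L,
        time=0.0,
        rng_seed=seed,
    )


# --------------------------------------------------------------------------
# forces

def _alloc(n, n_at, max_pairs, L, r_list):
    M = n * n_at
    ncell = int(L / r_list)
    ncell3 = ncell**3 if ncell >= 3 else 1
    return dict(
        pair_i=np.empty(max_pairs, dtype=np.int64),
        pair_j=np.empty(max_pairs, dtype=np.int64),
        atom_world=np.empty((M, 3)),
        atom_off=np.empty((M, 3)),
        forces=np.empty((n, 3)),
        torques=np.empty((n, 3)),
        ref_pos=np.empty((n, 3)),
        ref_quat=np.empty((n, 4)),
        head=np.full(ncell3, -1, dtype=np.int64),
        nxt=np.empty(M, dtype=np.int64),
        cellof=np.empty(M, dtype=np.int64),
    )


def compute_forces(
    state: SystemState,
    table: InteractionTable,
    spec: CondensateSpec | None,
    template: SubunitTemplate,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Body forces, world-frame torques, and total potential energy
    (pair terms plus the condensate field), using the cell/Verlet list."""
    atom_type, kind, eps, par1, req, rcut2, shift = _pack_table(template, table)
    n, n_at = state.n, len(atom_type)
    r_list = table.max_cutoff + 1e-9
    rlist2 = np.where(kind > 0, (np.sqrt(rcut2) + 1e-9) ** 2, 0.0)
    eps_c, R_c, alpha_C = _field_params(spec)
    max_pairs = max(200_000, n * n_at * 40)
    while True:
        buf = _alloc(n, n_at, max_pairs, state.box_L, r_list)
        K.compute_world_atoms(
            state.centers, state.orientations, template.positions, buf["atom_world"], buf["atom_off"]
        )
        n_pairs = K.build_neighbor_list(
            buf["atom_world"], n_at, state.box_L, r_list, rlist2, kind, atom_type,
            buf["pair_i"], buf["pair_j"], buf["head"], buf["nxt"], buf["cellof"],
        )
        if n_pairs >= 0:
            break
        max_pairs *= 2
    energy, status, bi, bj = K.compute_forces(
        state.centers, state.orientations, buf["atom_world"], buf["atom_off"],
        n_at, atom_type, buf["pair_i"], buf["pair_j"], n_pairs,
        kind, eps, par1, req, rcut2, shift, state.box_L,
        eps_c, R_c, alpha_C, buf["forces"], buf["torques"],
    )
    if status == K.STATUS_OVERLAP:
        raise OverlapError(bi, bj)
    return buf["forces"], buf["torques"], float(energy)


def compute_forces_bruteforce(
    state: SystemState,
    table: InteractionTable,
    spec: CondensateSpec | None,
    template: SubunitTemplate,
) -> tuple[np.ndarray, np.ndarray, float]:
    """O(N^2) all-pairs reference implementation (numpy, no neighbor
    list); the oracle against which the production path is validated."""
    from condcap.condensate import condensate_force, condensate_potential

    n = state.n
    roles = template.roles
    body = template.positions
    L = state.box_L
    world = np.empty((n, len(roles), 3))
    for i in range(n):
        world[i] = state.centers[i] + body @ quat_to_matrix(state.orientations[i]).T
    forces = np.zeros((n, 3))
    torques = np.zeros((n, 3))
    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for a, ra in enumerate(roles):
                for b, rb in enumerate(roles):
                    rule = table.get(ra, rb)
                    if rule is None or rule.eps == 0.0:
                        continue
                    d = world[i, a] - world[j, b]
                    d -= L * np.round(d / L)
                    r = float(np.linalg.norm(d))
                    if r >= rule.r_cut:
                        continue
                    energy += rule.energy(max(r, 1e-300))
                    if r > 1e-12:
                        f = rule.force_mag(r) * d / r
                        forces[i] += f
                        forces[j] -= f
                        torques[i] += np.cross(world[i, a] - state.centers[i], f)
                        torques[j] += np.cross(world[j, b] - state.centers[j], -f)
    if spec is not None and spec.eps_c > 0:
        for i in range(n):
            r = float(np.linalg.norm(state.centers[i]))
            energy += condensate_potential(spec, r)
            f = condensate_force(spec, state.centers[i])
            forces[i] += f
    return forces, torques, energy


# --------------------------------------------------------------------------
# integration

def run(
    state: SystemState,
    config: RunConfig,
    table: InteractionTable,
    spec: CondensateSpec | None,
    template: SubunitTemplate,
) -> Trajectory:
    """Integrate Langevin dynamics, returning a trajectory with snapshots
    every ``config.snapshot_every`` time units (the initial state is frame
    zero).  Identical seeds and configuration give identical trajectories
    on one platform."""
    work = state.copy()
    work.validate(tol=1e-6)
    n, n_at = work.n, len(template.roles)
    atom_type, kind, eps, par1, req, rcut2, shift = _pack_table(template, table)
    eps_c, R_c, alpha_C = _field_params(spec)
    if spec is not None and spec.eps_c > 0:
        reach = spec.R_c + table.max_cutoff + template.circumradius
        if reach >= work.box_L / 2.0:
            raise ValueError("condensate plus interaction range exceeds half the box")
    inertia = template.principal_inertia
    gamma_rot = (
        config.gamma * template.circumradius**2
        if config.gamma_rot is None
        else config.gamma_rot
    )
    r_list = table.max_cutoff + config.neighbor_skin
    rlist2 = np.where(kind > 0, (np.sqrt(rcut2) + config.neighbor_skin) ** 2, 0.0)

    n_steps = int(round(config.t_F / config.dt))
    steps_per_snap = max(int(round(config.snapshot_every / config.dt)), 1)

    rng = np.random.default_rng(int(config.seed) % (2**31 - 1))
    thermo = config.gamma > 0 or gamma_rot > 0
    # cap the pre-drawn noise buffer at ~20 MB
    sub_steps = max(200, int(2.5e6 / max(n * 6, 1)))

    max_pairs = max(200_000, n * n_at * 40)
    buf = _alloc(n, n_at, max_pairs, work.box_L, r_list)

    traj = Trajectory(metadata=dict(
        dt=config.dt, gamma=config.gamma, gamma_rot=gamma_rot,
        temperature=config.temperature, t_F=config.t_F, seed=config.seed,
        model=template.model, eps_ss=table.eps_ss, eps_c=eps_c, R_c=R_c,
        box_L=work.box_L, N=n,
    ))
    traj.frames.append(work.copy())

    done = 0
    while done < n_steps:
        snap_todo = min(steps_per_snap, n_steps - done)
        snap_done = 0
        while snap_done < snap_todo:
            todo = min(sub_steps, snap_todo - snap_done)
            noise = (
                rng.standard_normal((todo, n, 6))
                if thermo
                else np.empty((1, 1, 6))
            )
            energy, status, bi, bj, _ = K.run_chunk(
                work.centers, work.orientations, work.velocities, work.angular_momenta,
                work.images, template.positions, atom_type, inertia,
                kind, eps, par1, req, rcut2, shift,
                work.box_L, eps_c, R_c, alpha_C,
                config.dt, config.gamma, gamma_rot, config.temperature,
                todo, noise, config.neighbor_skin, r_list, rlist2,
                buf["pair_i"], buf["pair_j"], buf["atom_world"], buf["atom_off"],
                buf["forces"], buf["torques"], buf["ref_pos"], buf["ref_quat"],
                buf["head"], buf["nxt"], buf["cellof"],
            )
            if status == K.STATUS_OVERFLOW:
                raise RuntimeError(
                    "neighbor-list capacity exceeded; the configuration is far "
                    "denser than the engine's sizing assumptions"
                )
            if status == K.STATUS_OVERLAP:
                raise OverlapError(bi, bj)
            if not math.isfinite(energy) or abs(energy) > ENERGY_DIVERGENCE:
                raise UnstableTimestepError(
                    f"potential energy {energy:.3g} at t={work.time:.3g}; reduce dt"
                )
            snap_done += todo
        done += snap_todo
        work.time = state.time + done * config.dt
        traj.frames.append(work.copy())
    return traj


def potential_energy(state, table, spec, template) -> float:
    return compute_forces(state, table, spec, template)[2]


def kinetic_temperature(state: SystemState, template: SubunitTemplate) -> tuple[float, float]:
    """Instantaneous translational and rotational kinetic temperatures."""
    ke_t, ke_r = K.kinetic_energy(
        state.velocities, state.angular_momenta, template.principal_inertia
    )
    n = state.n
    return 2.0 * ke_t / (3.0 * n), 2.0 * ke_r / (3.0 * n)


# --------------------------------------------------------------------------
# transport

def measure_translational_diffusion(traj: Trajectory, fit_window: tuple[float, float] | None = None) -> float:
    """Diffusion constant from the mean-square displacement slope / 6.

    Intended for non-interacting subunits (``eps_ss = 0``, ``eps_c = 0``).
    The fit excludes the ballistic window: by default it uses the second
    half of the trajectory (times well beyond ``m / gamma``).
    """
    if len(traj) < 5:
        raise ValueError("trajectory too short to fit a diffusion constant")
    t = traj.times - traj.times[0]
    dt_snap = float(np.mean(np.diff(t)))
    x = np.array([f.unwrapped for f in traj.frames])  # (F, N, 3)
    F = len(t)
    # time-origin-averaged MSD per lag
    lags = np.arange(1, F)
    msd = np.empty(F - 1)
    for m, lag in enumerate(lags):
        d = x[lag:] - x[:-lag]
        msd[m] = np.mean(np.sum(d * d, axis=2))
    tau = lags * dt_snap
    if fit_window is None:
        # exclude the ballistic/short-time window; restrict to lags short
        # enough to have many independent time origins
        fit_window = (tau[-1] / 30.0, tau[-1] / 8.0)
    mask = (tau >= fit_window[0]) & (tau <= fit_window[1])
    if mask.sum() < 3:
        raise ValueError("fit window contains fewer than three lags")
    slope = np.polyfit(tau[mask], msd[mask], 1)[0]
    return float(slope / 6.0)
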