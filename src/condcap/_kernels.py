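"""Numba kernels for the rigid-body Langevin engine.

Everything here operates on flat float64/int arrays; the object-facing
wrapper lives in :mod:`condcap.dynamics`.  Pair rules are encoded as
per-type-pair matrices: ``kind`` 0 = none, 1 = WCA, 2 = Morse, 3 = LJ,
with ``par1`` holding sigma (WCA/LJ) or alpha (Morse), ``req`` the Morse
minimum, ``rcut2`` the squared cutoff and ``shift`` the cut-and-shift
energy offset.

Integration uses a BAOAB splitting: half-kick, half-drift (translations
plus an exact free-rotor "no-squish" quaternion update), full
Ornstein-Uhlenbeck thermostat step, half-drift, force refresh, half-kick.
With zero friction the thermostat step is the identity and the scheme
reduces to symplectic velocity-Verlet rigid-body NVE.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERFLOW = 1
STATUS_OVERLAP = 2


@njit(cache=True, inline="always")
def _quat_rotate(q, v, out):
    """out = R(q) v for unit quaternion q (w x y z)."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    out[0] = (1 - 2 * (y * y + z * z)) * v[0] + 2 * (x * y - w * z) * v[1] + 2 * (x * z + w * y) * v[2]
    out[1] = 2 * (x * y + w * z) * v[0] + (1 - 2 * (x * x + z * z)) * v[1] + 2 * (y * z - w * x) * v[2]
    out[2] = 2 * (x * z - w * y) * v[0] + 2 * (y * z + w * x) * v[1] + (1 - 2 * (x * x + y * y)) * v[2]


@njit(cache=True, inline="always")
def _quat_rotate_T(q, v, out):
    """out = R(q)^T v (world -> body)."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    out[0] = (1 - 2 * (y * y + z * z)) * v[0] + 2 * (x * y + w * z) * v[1] + 2 * (x * z - w * y) * v[2]
    out[1] = 2 * (x * y - w * z) * v[0] + (1 - 2 * (x * x + z * z)) * v[1] + 2 * (y * z + w * x) * v[2]
    out[2] = 2 * (x * z + w * y) * v[0] + 2 * (y * z - w * x) * v[1] + (1 - 2 * (x * x + y * y)) * v[2]


@njit(cache=True)
def compute_world_atoms(pos, quat, body_pos, atom_world, atom_off):
    """World atom positions and offsets from their body centers."""
    n = pos.shape[0]
    n_at = body_pos.shape[0]
    tmp = np.empty(3)
    for i in range(n):
        for a in range(n_at):
            _quat_rotate(quat[i], body_pos[a], tmp)
            k = i * n_at + a
            atom_off[k, 0] = tmp[0]
            atom_off[k, 1] = tmp[1]
            atom_off[k, 2] = tmp[2]
            atom_world[k, 0] = pos[i, 0] + tmp[0]
            atom_world[k, 1] = pos[i, 1] + tmp[1]
            atom_world[k, 2] = pos[i, 2] + tmp[2]


@njit(cache=True, fastmath=True)
def build_neighbor_list(atom_world, n_at, L, r_list, rlist2, kind, atom_type, pair_i, pair_j,
                        head, nxt, cellof):
    """Verlet pair list over atoms (cell-list binning with per-type-pair
    list cutoffs ``rlist2``; same-body pairs and type pairs without a rule
    are excluded).  ``r_list`` is the largest list cutoff (cell size).
    ``head`` is a persistent all(-1) workspace of ncell^3 entries; it is
    restored to -1 before returning.  Returns the number of pairs or -1 on
    capacity overflow."""
    M = atom_world.shape[0]
    ncell = int(L / r_list)
    cap = pair_i.shape[0]
    count = 0
    if ncell < 3 or head.shape[0] < ncell * ncell * ncell:
        for i in range(M):
            bi = i // n_at
            for j in range(i + 1, M):
                if j // n_at == bi:
                    continue
                ti = atom_type[i % n_at]
                tj = atom_type[j % n_at]
                if kind[ti, tj] == 0:
                    continue
                dx = atom_world[i, 0] - atom_world[j, 0]
                dy = atom_world[i, 1] - atom_world[j, 1]
                dz = atom_world[i, 2] - atom_world[j, 2]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                if dy > 0.5 * L:
                    dy -= L
                elif dy < -0.5 * L:
                    dy += L
                if dz > 0.5 * L:
                    dz -= L
                elif dz < -0.5 * L:
                    dz += L
                if dx * dx + dy * dy + dz * dz < rlist2[ti, tj]:
                    if count >= cap:
                        return -1
                    pair_i[count] = i
                    pair_j[count] = j
                    count += 1
        return count

    cell_w = L / ncell
    for i in range(M):
        x = atom_world[i, 0] % L
        y = atom_world[i, 1] % L
        z = atom_world[i, 2] % L
        ix = min(int(x / cell_w), ncell - 1)
        iy = min(int(y / cell_w), ncell - 1)
        iz = min(int(z / cell_w), ncell - 1)
        c = (ix * ncell + iy) * ncell + iz
        cellof[i] = c
        nxt[i] = head[c]
        head[c] = i
    for i in range(M):
        bi = i // n_at
        ti = atom_type[i % n_at]
        ci = cellof[i]
        cz0 = ci % ncell
        cy0 = (ci // ncell) % ncell
        cx0 = ci // (ncell * ncell)
        for ox in range(-1, 2):
            jx = (cx0 + ox) % ncell
            for oy in range(-1, 2):
                jy = (cy0 + oy) % ncell
                for oz in range(-1, 2):
                    jz = (cz0 + oz) % ncell
                    c = (jx * ncell + jy) * ncell + jz
                    j = head[c]
                    while j >= 0:
                        if j > i:
                            tj = atom_type[j % n_at]
                            if j // n_at != bi and kind[ti, tj] != 0:
                                dx = atom_world[i, 0] - atom_world[j, 0]
                                dy = atom_world[i, 1] - atom_world[j, 1]
                                dz = atom_world[i, 2] - atom_world[j, 2]
                                if dx > 0.5 * L:
                                    dx -= L
                                elif dx < -0.5 * L:
                                    dx += L
                                if dy > 0.5 * L:
                                    dy -= L
                                elif dy < -0.5 * L:
                                    dy += L
                                if dz > 0.5 * L:
                                    dz -= L
                                elif dz < -0.5 * L:
                                    dz += L
                                if dx * dx + dy * dy + dz * dz < rlist2[ti, tj]:
                                    if count >= cap:
                                        for m in range(M):
                                            head[cellof[m]] = -1
                                        return -1
                                    pair_i[count] = i
                                    pair_j[count] = j
                                    count += 1
                        j = nxt[j]
    for i in range(M):
        head[cellof[i]] = -1
    return count


@njit(cache=True)
def compute_forces(
    pos,
    quat,
    atom_world,
    atom_off,
    n_at,
    atom_type,
    pair_i,
    pair_j,
    n_pairs,
    kind,
    eps,
    par1,
    req,
    rcut2,
    shift,
    L,
    eps_c,
    R_c,
    alpha_C,
    forces,
    torques_w,
):
    """Pair + condensate forces, world-frame torques, and total potential
    energy.  Returns (energy, status, bad_i, bad_j)."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
        torques_w[i, 0] = 0.0
        torques_w[i, 1] = 0.0
        torques_w[i, 2] = 0.0
    energy = 0.0
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        ti = atom_type[i % n_at]
        tj = atom_type[j % n_at]
        k = kind[ti, tj]
        dx = atom_world[i, 0] - atom_world[j, 0]
        dy = atom_world[i, 1] - atom_world[j, 1]
        dz = atom_world[i, 2] - atom_world[j, 2]
        if dx > 0.5 * L:
            dx -= L
        elif dx < -0.5 * L:
            dx += L
        if dy > 0.5 * L:
            dy -= L
        elif dy < -0.5 * L:
            dy += L
        if dz > 0.5 * L:
            dz -= L
        elif dz < -0.5 * L:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rcut2[ti, tj]:
            continue
        e = eps[ti, tj]
        if k == 2:
            # Morse (finite at r = 0 when req = 0)
            r = np.sqrt(r2)
            al = par1[ti, tj]
            x = np.exp(-al * (r - req[ti, tj]))
            energy += e * (x * x - 2.0 * x) - shift[ti, tj]
            if r > 1e-12:
                fr = 2.0 * al * e * (x * x - x) / r  # (-du/dr)/r
            else:
                fr = 0.0
        else:
            if r2 < 1e-16:
                return 0.0, STATUS_OVERLAP, i, j
            s2 = par1[ti, tj] * par1[ti, tj] / r2
            sr6 = s2 * s2 * s2
            if k == 1:  # WCA
                energy += 4.0 * e * (sr6 * sr6 - sr6) + e
            else:  # LJ
                energy += 4.0 * e * (sr6 * sr6 - sr6) - shift[ti, tj]
            fr = 24.0 * e * (2.0 * sr6 * sr6 - sr6) / r2
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        bi = i // n_at
        bj = j // n_at
        forces[bi, 0] += fx
        forces[bi, 1] += fy
        forces[bi, 2] += fz
        forces[bj, 0] -= fx
        forces[bj, 1] -= fy
        forces[bj, 2] -= fz
        torques_w[bi, 0] += atom_off[i, 1] * fz - atom_off[i, 2] * fy
        torques_w[bi, 1] += atom_off[i, 2] * fx - atom_off[i, 0] * fz
        torques_w[bi, 2] += atom_off[i, 0] * fy - atom_off[i, 1] * fx
        torques_w[bj, 0] -= atom_off[j, 1] * fz - atom_off[j, 2] * fy
        torques_w[bj, 1] -= atom_off[j, 2] * fx - atom_off[j, 0] * fz
        torques_w[bj, 2] -= atom_off[j, 0] * fy - atom_off[j, 1] * fx
    if eps_c > 0.0:
        for i in range(n):
            r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            if r < R_c:
                energy += -eps_c
            else:
                ex = np.exp(-alpha_C * (r - R_c))
                energy += -eps_c * (2.0 * ex - ex * ex)
                if r > 0.0:
                    dudr = 2.0 * alpha_C * eps_c * (ex - ex * ex)
                    forces[i, 0] -= dudr * pos[i, 0] / r
                    forces[i, 1] -= dudr * pos[i, 1] / r
                    forces[i, 2] -= dudr * pos[i, 2] / r
    return energy, STATUS_OK, -1, -1


@njit(cache=True, inline="always")
def _rotate_axis(quat_i, angmom_i, axis, theta):
    """Rotate quaternion about a body principal axis by theta and the
    body-frame angular momentum by -theta (exact free-rotor substep)."""
    half = 0.5 * theta
    if -0.02 < theta < 0.02:
        h2 = half * half
        c = 1.0 - 0.5 * h2 + h2 * h2 / 24.0
        s = half * (1.0 - h2 / 6.0 + h2 * h2 / 120.0)
    else:
        c = np.cos(half)
        s = np.sin(half)
    q0 = quat_i[0]
    q1 = quat_i[1]
    q2 = quat_i[2]
    q3 = quat_i[3]
    if axis == 0:
        quat_i[0] = c * q0 - s * q1
        quat_i[1] = c * q1 + s * q0
        quat_i[2] = c * q2 + s * q3
        quat_i[3] = c * q3 - s * q2
    elif axis == 1:
        quat_i[0] = c * q0 - s * q2
        quat_i[1] = c * q1 - s * q3
        quat_i[2] = c * q2 + s * q0
        quat_i[3] = c * q3 + s * q1
    else:
        quat_i[0] = c * q0 - s * q3
        quat_i[1] = c * q1 + s * q2
        quat_i[2] = c * q2 - s * q1
        quat_i[3] = c * q3 + s * q0
    ct = c * c - s * s
    st = 2.0 * s * c
    l0 = angmom_i[0]
    l1 = angmom_i[1]
    l2 = angmom_i[2]
    # body-frame vector rotates by -theta about the axis
    if axis == 0:
        angmom_i[1] = ct * l1 + st * l2
        angmom_i[2] = -st * l1 + ct * l2
    elif axis == 1:
        angmom_i[0] = ct * l0 - st * l2
        angmom_i[2] = st * l0 + ct * l2
    else:
        angmom_i[0] = ct * l0 + st * l1
        angmom_i[1] = -st * l0 + ct * l1


@njit(cache=True, fastmath=True)
def _free_rotor(quat, angmom, inertia, dt):
    """Exact-splitting free rigid-body rotation for all bodies (no-squish
    axis sequence 2,1,0,1,2 with half steps on the outer axes)."""
    n = quat.shape[0]
    for i in range(n):
        _rotate_axis(quat[i], angmom[i], 2, 0.5 * dt * angmom[i, 2] / inertia[2])
        _rotate_axis(quat[i], angmom[i], 1, 0.5 * dt * angmom[i, 1] / inertia[1])
        _rotate_axis(quat[i], angmom[i], 0, dt * angmom[i, 0] / inertia[0])
        _rotate_axis(quat[i], angmom[i], 1, 0.5 * dt * angmom[i, 1] / inertia[1])
        _rotate_axis(quat[i], angmom[i], 2, 0.5 * dt * angmom[i, 2] / inertia[2])
        norm = np.sqrt(
            quat[i, 0] ** 2 + quat[i, 1] ** 2 + quat[i, 2] ** 2 + quat[i, 3] ** 2
        )
        quat[i, 0] /= norm
        quat[i, 1] /= norm
        quat[i, 2] /= norm
        quat[i, 3] /= norm


@njit(cache=True, fastmath=True)
def run_chunk(
    pos,
    quat,
    vel,
    angmom,
    images,
    body_pos,
    atom_type,
    inertia,
    kind,
    eps,
    par1,
    req,
    rcut2,
    shift,
    L,
    eps_c,
    R_c,
    alpha_C,
    dt,
    gamma,
    gamma_rot,
    temperature,
    n_steps,
    noise,
    skin,
    r_list,
    rlist2,
    pair_i,
    pair_j,
    atom_world,
    atom_off,
    forces,
    torques_w,
    ref_pos,
    ref_quat,
    head,
    nxt,
    cellof,
):
    """Advance ``n_steps`` BAOAB steps.  Returns
    (energy, status, bad_i, bad_j, n_rebuilds)."""
    n = pos.shape[0]
    n_at = body_pos.shape[0]
    tmp = np.empty(3)

    c_t = np.exp(-gamma * dt) if gamma > 0 else 1.0
    s_t = np.sqrt((1.0 - c_t * c_t) * temperature)
    c_r = np.empty(3)
    s_r = np.empty(3)
    for k in range(3):
        c_r[k] = np.exp(-gamma_rot * dt / inertia[k]) if gamma_rot > 0 else 1.0
        s_r[k] = np.sqrt((1.0 - c_r[k] * c_r[k]) * inertia[k] * temperature)

    # initial neighbor list and forces
    compute_world_atoms(pos, quat, body_pos, atom_world, atom_off)
    n_pairs = build_neighbor_list(atom_world, n_at, L, r_list, rlist2, kind, atom_type, pair_i, pair_j, head, nxt, cellof)
    if n_pairs < 0:
        return 0.0, STATUS_OVERFLOW, -1, -1, 0
    for i in range(n):
        for d in range(3):
            ref_pos[i, d] = pos[i, d]
            ref_quat[i, d] = quat[i, d]
        ref_quat[i, 3] = quat[i, 3]
    energy, status, bi, bj = compute_forces(
        pos, quat, atom_world, atom_off, n_at, atom_type, pair_i, pair_j, n_pairs,
        kind, eps, par1, req, rcut2, shift, L, eps_c, R_c, alpha_C, forces, torques_w,
    )
    if status != STATUS_OK:
        return energy, status, bi, bj, 0
    n_rebuilds = 0
    half = 0.5 * dt

    # maximum atom arm for the rotation part of the rebuild criterion
    arm = 0.0
    for a in range(n_at):
        r = np.sqrt(body_pos[a, 0] ** 2 + body_pos[a, 1] ** 2 + body_pos[a, 2] ** 2)
        if r > arm:
            arm = r

    for step in range(n_steps):
        # B: half kick (torque converted to body frame)
        for i in range(n):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
            _quat_rotate_T(quat[i], torques_w[i], tmp)
            angmom[i, 0] += half * tmp[0]
            angmom[i, 1] += half * tmp[1]
            angmom[i, 2] += half * tmp[2]
        # A: half drift
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        _free_rotor(quat, angmom, inertia, half)
        # O: thermostat (noise pre-drawn by the caller)
        if gamma > 0 or gamma_rot > 0:
            for i in range(n):
                vel[i, 0] = c_t * vel[i, 0] + s_t * noise[step, i, 0]
                vel[i, 1] = c_t * vel[i, 1] + s_t * noise[step, i, 1]
                vel[i, 2] = c_t * vel[i, 2] + s_t * noise[step, i, 2]
                angmom[i, 0] = c_r[0] * angmom[i, 0] + s_r[0] * noise[step, i, 3]
                angmom[i, 1] = c_r[1] * angmom[i, 1] + s_r[1] * noise[step, i, 4]
                angmom[i, 2] = c_r[2] * angmom[i, 2] + s_r[2] * noise[step, i, 5]
        # A: half drift
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        _free_rotor(quat, angmom, inertia, half)
        # wrap and track images
        for i in range(n):
            for d in range(3):
                if pos[i, d] >= 0.5 * L:
                    pos[i, d] -= L
                    images[i, d] += 1
                    ref_pos[i, d] -= L
                elif pos[i, d] < -0.5 * L:
                    pos[i, d] += L
                    images[i, d] -= 1
                    ref_pos[i, d] += L
        # neighbor list health check
        max_move = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            dz = pos[i, 2] - ref_pos[i, 2]
            move = np.sqrt(dx * dx + dy * dy + dz * dz)
            dq = 0.0
            for d in range(4):
                diff = quat[i, d] - ref_quat[i, d]
                dq += diff * diff
            move += 2.0 * arm * np.sqrt(dq)
            if move > max_move:
                max_move = move
        compute_world_atoms(pos, quat, body_pos, atom_world, atom_off)
        if max_move > 0.5 * skin:
            n_pairs = build_neighbor_list(
                atom_world, n_at, L, r_list, rlist2, kind, atom_type, pair_i, pair_j,
                head, nxt, cellof
            )
            if n_pairs < 0:
                return 0.0, STATUS_OVERFLOW, -1, -1, n_rebuilds
            n_rebuilds += 1
            for i in range(n):
                for d in range(3):
                    ref_pos[i, d] = pos[i, d]
                    ref_quat[i, d] = quat[i, d]
                ref_quat[i, 3] = quat[i, 3]
        # force refresh + B: half kick
        energy, status, bi, bj = compute_forces(
            pos, quat, atom_world, atom_off, n_at, atom_type, pair_i, pair_j, n_pairs,
            kind, eps, par1, req, rcut2, shift, L, eps_c, R_c, alpha_C, forces, torques_w,
        )
        if status != STATUS_OK:
            return energy, status, bi, bj, n_rebuilds
        for i in range(n):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
            _quat_rotate_T(quat[i], torques_w[i], tmp)
            angmom[i, 0] += half * tmp[0]
            angmom[i, 1] += half * tmp[1]
            angmom[i, 2] += half * tmp[2]
    return energy, STATUS_OK, -1, -1, n_rebuilds


@njit(cache=True)
def kinetic_energy(vel, angmom, inertia):
    n = vel.shape[0]
    ke_t = 0.0
    ke_r = 0.0
    for i in range(n):
        ke_t += 0.5 * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
        for k in range(3):
            ke_r += 0.5 * angmom[i, k] ** 2 / inertia[k]
    return ke_t, ke_r
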