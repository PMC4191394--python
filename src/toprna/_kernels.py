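"""Numba-compiled inner loops: energies, forces, BAOAB Langevin steps.

Everything here operates on plain numpy arrays packed by
:mod:`toprna.cg_engine`.  Forces are the exact negative gradient of the
reported energy (checked by finite differences in the test suite).
Energy breakdown order: bond, angle, improper, dihedral, LJ, restraint.
All inner loops are written in scalar form: on one CPU the force pass
costs well under 100 microseconds for a tRNA-sized (249-bead) system.
"""

import numpy as np
from numba import njit

ACC_FACTOR = 4.184e-4  # (kcal/mol/A)/amu -> A/fs^2


@njit(cache=True, fastmath=True)
def _wrap_pi(x):
    while x > np.pi:
        x -= 2.0 * np.pi
    while x < -np.pi:
        x += 2.0 * np.pi
    return x


@njit(cache=True, fastmath=True)
def build_neighbor_list(x, rlist, excl, pi_buf, pj_buf):
    n = x.shape[0]
    rl2 = rlist * rlist
    cnt = 0
    for i in range(n):
        xi = x[i, 0]
        yi = x[i, 1]
        zi = x[i, 2]
        for j in range(i + 1, n):
            if excl[i, j] == 0:
                continue
            dx = xi - x[j, 0]
            dy = yi - x[j, 1]
            dz = zi - x[j, 2]
            if dx * dx + dy * dy + dz * dz < rl2:
                pi_buf[cnt] = i
                pj_buf[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def build_neighbor_list_params(
    x, rlist, excl, rmin_mat, eps_mat, shift_mat,
    pi_buf, pj_buf, rmin_buf, eps_buf, shift_buf,
):
    """Neighbor list plus per-pair LJ parameters gathered once per
    rebuild (matrix lookups inside the force loop dominate otherwise)."""
    n = x.shape[0]
    rl2 = rlist * rlist
    cnt = 0
    for i in range(n):
        xi = x[i, 0]
        yi = x[i, 1]
        zi = x[i, 2]
        for j in range(i + 1, n):
            dx = xi - x[j, 0]
            dy = yi - x[j, 1]
            dz = zi - x[j, 2]
            if dx * dx + dy * dy + dz * dz < rl2 and excl[i, j] != 0:
                pi_buf[cnt] = i
                pj_buf[cnt] = j
                rmin_buf[cnt] = rmin_mat[i, j]
                eps_buf[cnt] = eps_mat[i, j]
                shift_buf[cnt] = shift_mat[i, j]
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def forces_energy(
    x, f,
    bonds, bond_r0, bond_k,
    angles, angle_t0, angle_k,
    imps, imp_p0, imp_k,
    dihes, dihe_p0, dihe_k,
    cutoff,
    res_idx, res_rmin, res_rmax, res_kmin, res_kmax, res_fmax,
    pi_buf, pj_buf, rmin_buf, eps_buf, shift_buf, n_pairs,
):
    f[:] = 0.0
    e = np.zeros(6)

    # bonds: E = k (b - b0)^2
    for t in range(bonds.shape[0]):
        i = bonds[t, 0]
        j = bonds[t, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        b = np.sqrt(dx * dx + dy * dy + dz * dz)
        db = b - bond_r0[t]
        e[0] += bond_k[t] * db * db
        coef = -2.0 * bond_k[t] * db / b
        f[i, 0] += coef * dx
        f[i, 1] += coef * dy
        f[i, 2] += coef * dz
        f[j, 0] -= coef * dx
        f[j, 1] -= coef * dy
        f[j, 2] -= coef * dz

    # angles: E = k (cos theta - cos theta0)^2 -- smooth at theta = pi,
    # where a harmonic-in-theta force law would diverge as 1/sin
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cosT = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cosT > 1.0:
            cosT = 1.0
        elif cosT < -1.0:
            cosT = -1.0
        dcos = cosT - np.cos(angle_t0[t])
        e[1] += angle_k[t] * dcos * dcos
        dEdcos = 2.0 * angle_k[t] * dcos
        cu = -dEdcos / nu
        cv = -dEdcos / nv
        fix = cu * (vx / nv - cosT * ux / nu)
        fiy = cu * (vy / nv - cosT * uy / nu)
        fiz = cu * (vz / nv - cosT * uz / nu)
        fkx = cv * (ux / nu - cosT * vx / nv)
        fky = cv * (uy / nu - cosT * vy / nv)
        fkz = cv * (uz / nu - cosT * vz / nv)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz

    # chirality impropers: E = k (V - V0)^2 with V the signed volume of
    # the three bonds leaving the center bead (first index).  Smooth
    # polynomial -- no collinearity singularity.
    for t in range(imps.shape[0]):
        s0 = imps[t, 0]
        a = imps[t, 1]
        b = imps[t, 2]
        c = imps[t, 3]
        ux = x[a, 0] - x[s0, 0]
        uy = x[a, 1] - x[s0, 1]
        uz = x[a, 2] - x[s0, 2]
        vx = x[b, 0] - x[s0, 0]
        vy = x[b, 1] - x[s0, 1]
        vz = x[b, 2] - x[s0, 2]
        wx = x[c, 0] - x[s0, 0]
        wy = x[c, 1] - x[s0, 1]
        wz = x[c, 2] - x[s0, 2]
        # V = u . (v x w)
        vwx = vy * wz - vz * wy
        vwy = vz * wx - vx * wz
        vwz = vx * wy - vy * wx
        V = ux * vwx + uy * vwy + uz * vwz
        dV = V - imp_p0[t]
        e[2] += imp_k[t] * dV * dV
        g = 2.0 * imp_k[t] * dV
        # grad_a V = v x w ; grad_b V = w x u ; grad_c V = u x v
        wux = wy * uz - wz * uy
        wuy = wz * ux - wx * uz
        wuz = wx * uy - wy * ux
        uvx = uy * vz - uz * vy
        uvy = uz * vx - ux * vz
        uvz = ux * vy - uy * vx
        f[a, 0] -= g * vwx
        f[a, 1] -= g * vwy
        f[a, 2] -= g * vwz
        f[b, 0] -= g * wux
        f[b, 1] -= g * wuy
        f[b, 2] -= g * wuz
        f[c, 0] -= g * uvx
        f[c, 1] -= g * uvy
        f[c, 2] -= g * uvz
        f[s0, 0] += g * (vwx + wux + uvx)
        f[s0, 1] += g * (vwy + wuy + uvy)
        f[s0, 2] += g * (vwz + wuz + uvz)

    # backbone dihedrals: E = k (1 - cos(phi - phi0))
    if True:
        quads, p0s, ks = dihes, dihe_p0, dihe_k
        for t in range(quads.shape[0]):
            a0 = quads[t, 0]
            a1 = quads[t, 1]
            a2 = quads[t, 2]
            a3 = quads[t, 3]
            b1x = x[a1, 0] - x[a0, 0]
            b1y = x[a1, 1] - x[a0, 1]
            b1z = x[a1, 2] - x[a0, 2]
            b2x = x[a2, 0] - x[a1, 0]
            b2y = x[a2, 1] - x[a1, 1]
            b2z = x[a2, 2] - x[a1, 2]
            b3x = x[a3, 0] - x[a2, 0]
            b3y = x[a3, 1] - x[a2, 1]
            b3z = x[a3, 2] - x[a2, 2]
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            cx = n1y * n2z - n1z * n2y
            cy = n1z * n2x - n1x * n2z
            cz = n1x * n2y - n1y * n2x
            sphi = -(cx * b2x + cy * b2y + cz * b2z) / nb2
            cphi = n1x * n2x + n1y * n2y + n1z * n2z
            phi = np.arctan2(sphi, cphi)
            e[3] += ks[t] * (1.0 - np.cos(phi - p0s[t]))
            dEdphi = ks[t] * np.sin(phi - p0s[t])
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            if n1sq < 1e-12 or n2sq < 1e-12:
                continue
            sv = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
            tv = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
            c0 = -dEdphi * nb2 / n1sq
            c3 = dEdphi * nb2 / n2sq
            F0x = c0 * n1x
            F0y = c0 * n1y
            F0z = c0 * n1z
            F3x = c3 * n2x
            F3y = c3 * n2y
            F3z = c3 * n2z
            f[a0, 0] += F0x
            f[a0, 1] += F0y
            f[a0, 2] += F0z
            f[a3, 0] += F3x
            f[a3, 1] += F3y
            f[a3, 2] += F3z
            f[a1, 0] += -(1.0 + sv) * F0x + tv * F3x
            f[a1, 1] += -(1.0 + sv) * F0y + tv * F3y
            f[a1, 2] += -(1.0 + sv) * F0z + tv * F3z
            f[a2, 0] += sv * F0x - (1.0 + tv) * F3x
            f[a2, 1] += sv * F0y - (1.0 + tv) * F3y
            f[a2, 2] += sv * F0z - (1.0 + tv) * F3z

    # Lennard-Jones over the neighbor list (energy-shifted at cutoff)
    rc2 = cutoff * cutoff
    for t in range(n_pairs):
        i = pi_buf[t]
        j = pj_buf[t]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        eps = eps_buf[t]
        rmin = rmin_buf[t]
        s2 = rmin * rmin / r2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        e[4] += eps * (s12 - 2.0 * s6) - shift_buf[t]
        coef = 12.0 * eps * (s12 - s6) / r2
        f[i, 0] += coef * dx
        f[i, 1] += coef * dy
        f[i, 2] += coef * dz
        f[j, 0] -= coef * dx
        f[j, 1] -= coef * dy
        f[j, 2] -= coef * dz

    # flat-bottom restraints: E = 0.5 k d^2 inside the harmonic range,
    # linear with slope fmax beyond d_c = fmax / k
    for t in range(res_idx.shape[0]):
        i = res_idx[t, 0]
        j = res_idx[t, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        ev = 0.0
        fv = 0.0
        if d < res_rmin[t]:
            delta = res_rmin[t] - d
            kk = res_kmin[t]
            dc = res_fmax[t] / kk
            if delta <= dc:
                ev = 0.5 * kk * delta * delta
                fv = kk * delta  # pushes outward (increasing d)
            else:
                ev = res_fmax[t] * (delta - dc) + 0.5 * kk * dc * dc
                fv = res_fmax[t]
        elif d > res_rmax[t]:
            delta = d - res_rmax[t]
            kk = res_kmax[t]
            dc = res_fmax[t] / kk
            if delta <= dc:
                ev = 0.5 * kk * delta * delta
                fv = -kk * delta  # pulls inward (decreasing d)
            else:
                ev = res_fmax[t] * (delta - dc) + 0.5 * kk * dc * dc
                fv = -res_fmax[t]
        e[5] += ev
        if d > 1e-12:
            f[i, 0] += fv * dx / d
            f[i, 1] += fv * dy / d
            f[i, 2] += fv * dz / d
            f[j, 0] -= fv * dx / d
            f[j, 1] -= fv * dy / d
            f[j, 2] -= fv * dz / d
    return e


@njit(cache=True, fastmath=True)
def langevin_chunk(
    x, v, n_steps, dt, gamma, kT, mass, seed,
    bonds, bond_r0, bond_k,
    angles, angle_t0, angle_k,
    imps, imp_p0, imp_k,
    dihes, dihe_p0, dihe_k,
    cutoff,
    res_idx, res_rmin, res_rmax, res_kmin, res_kmax, res_fmax,
    rmin_mat, eps_mat, shift_mat,
    excl, rlist, nlist_every,
):
    """BAOAB Langevin dynamics for ``n_steps``; deterministic for a
    given seed.  gamma in 1/fs, dt in fs, kT in kcal/mol.  Returns the
    final energy breakdown.  gamma = 0 reduces to velocity Verlet."""
    np.random.seed(seed)
    n = x.shape[0]
    f = np.zeros_like(x)
    maxp = n * (n - 1) // 2
    pi_buf = np.empty(maxp, dtype=np.int64)
    pj_buf = np.empty(maxp, dtype=np.int64)
    rmin_buf = np.empty(maxp)
    eps_buf = np.empty(maxp)
    shift_buf = np.empty(maxp)
    n_pairs = build_neighbor_list_params(
        x, rlist, excl, rmin_mat, eps_mat, shift_mat,
        pi_buf, pj_buf, rmin_buf, eps_buf, shift_buf,
    )
    e = forces_energy(
        x, f, bonds, bond_r0, bond_k, angles, angle_t0, angle_k,
        imps, imp_p0, imp_k, dihes, dihe_p0, dihe_k,
        cutoff,
        res_idx, res_rmin, res_rmax, res_kmin, res_kmax, res_fmax,
        pi_buf, pj_buf, rmin_buf, eps_buf, shift_buf, n_pairs,
    )
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    inv_m = ACC_FACTOR / mass
    sig = np.sqrt(ACC_FACTOR * kT / mass)
    half = 0.5 * dt
    for step in range(n_steps):
        for i in range(n):
            hi = half * inv_m[i]
            v[i, 0] += hi * f[i, 0]
            v[i, 1] += hi * f[i, 1]
            v[i, 2] += hi * f[i, 2]
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        if gamma > 0.0:
            xi = np.random.standard_normal(3 * n)
            for i in range(n):
                si = c2 * sig[i]
                v[i, 0] = c1 * v[i, 0] + si * xi[3 * i]
                v[i, 1] = c1 * v[i, 1] + si * xi[3 * i + 1]
                v[i, 2] = c1 * v[i, 2] + si * xi[3 * i + 2]
        for i in range(n):
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        if (step + 1) % nlist_every == 0:
            n_pairs = build_neighbor_list_params(
                x, rlist, excl, rmin_mat, eps_mat, shift_mat,
                pi_buf, pj_buf, rmin_buf, eps_buf, shift_buf,
            )
        e = forces_energy(
            x, f, bonds, bond_r0, bond_k, angles, angle_t0, angle_k,
            imps, imp_p0, imp_k, dihes, dihe_p0, dihe_k,
            cutoff,
            res_idx, res_rmin, res_rmax, res_kmin, res_kmax, res_fmax,
            pi_buf, pj_buf, rmin_buf, eps_buf, shift_buf, n_pairs,
        )
        for i in range(n):
            hi = half * inv_m[i]
            v[i, 0] += hi * f[i, 0]
            v[i, 1] += hi * f[i, 1]
            v[i, 2] += hi * f[i, 2]
    return e


@njit(cache=True, fastmath=True)
def kinetic_energy(v, mass):
    """Kinetic energy in kcal/mol from velocities in A/fs."""
    ke = 0.0
    for i in range(v.shape[0]):
        ke += 0.5 * mass[i] * (
            v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
        )
    return ke / ACC_FACTOR
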