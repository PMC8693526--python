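"""Numba kernels for neighbor search and force evaluation.

All kernels use orthorhombic minimum-image convention.  Forces are
accumulated into caller-provided arrays in kcal/(mol A); energies return in
kcal/mol; virials are the diagonal of sum_pairs r_a * F_a (kcal/mol),
accumulated per dimension so the barostat can couple the lateral and normal
pressure components separately.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "build_pair_list", "pair_energy_forces", "bond_energy_forces",
    "angle_energy_forces", "dihedral_energy_forces", "brute_pair_list",
]


@njit(cache=True, fastmath=True)
def _is_excluded(i, j, excl):
    for k in range(excl.shape[1]):
        e = excl[i, k]
        if e == -1:
            break
        if e == j:
            return True
    return False


@njit(cache=True, fastmath=True)
def brute_pair_list(pos, box, rlist, excl):
    """O(N^2) neighbor pairs within rlist, exclusions removed."""
    n = pos.shape[0]
    r2max = rlist * rlist
    cap = 32
    count = 0
    # counting pass
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            if dx * dx + dy * dy + dz * dz < r2max:
                if not _is_excluded(i, j, excl):
                    count += 1
    ii = np.empty(count, dtype=np.int64)
    jj = np.empty(count, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            if dx * dx + dy * dy + dz * dz < r2max:
                if not _is_excluded(i, j, excl):
                    ii[k] = i
                    jj[k] = j
                    k += 1
    return ii, jj


@njit(cache=True, fastmath=True)
def _cell_pair_list(pos, box, rlist, excl):
    n = pos.shape[0]
    ncx = int(box[0] // rlist)
    ncy = int(box[1] // rlist)
    ncz = int(box[2] // rlist)
    ncell = ncx * ncy * ncz
    r2max = rlist * rlist

    # bin beads (positions assumed wrapped into [0, L))
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx)
        cy = int(pos[i, 1] / box[1] * ncy)
        cz = int(pos[i, 2] / box[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        counts[c] += 1
    start = np.zeros(ncell + 1, dtype=np.int64)
    for c in range(ncell):
        start[c + 1] = start[c] + counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = start[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    # two passes: count then fill
    total = 0
    for phase in range(2):
        if phase == 1:
            ii = np.empty(total, dtype=np.int64)
            jj = np.empty(total, dtype=np.int64)
        else:
            ii = np.empty(0, dtype=np.int64)
            jj = np.empty(0, dtype=np.int64)
        k = 0
        for cx in range(ncx):
            for cy in range(ncy):
                for cz in range(ncz):
                    c = (cx * ncy + cy) * ncz + cz
                    for a in range(start[c], start[c + 1]):
                        i = order[a]
                        for ox in range(-1, 2):
                            for oy in range(-1, 2):
                                for oz in range(-1, 2):
                                    nx = (cx + ox) % ncx
                                    ny = (cy + oy) % ncy
                                    nz = (cz + oz) % ncz
                                    c2 = (nx * ncy + ny) * ncz + nz
                                    for b in range(start[c2], start[c2 + 1]):
                                        j = order[b]
                                        if j <= i:
                                            continue
                                        dx = pos[i, 0] - pos[j, 0]
                                        dy = pos[i, 1] - pos[j, 1]
                                        dz = pos[i, 2] - pos[j, 2]
                                        dx -= box[0] * np.rint(dx / box[0])
                                        dy -= box[1] * np.rint(dy / box[1])
                                        dz -= box[2] * np.rint(dz / box[2])
                                        if dx * dx + dy * dy + dz * dz < r2max:
                                            if not _is_excluded(i, j, excl):
                                                if phase == 1:
                                                    ii[k] = i
                                                    jj[k] = j
                                                k += 1
        if phase == 0:
            total = k
    return ii, jj


def build_pair_list(pos, box, rlist, excl):
    """Neighbor pairs within ``rlist`` (cell binning; O(N^2) fallback for
    boxes under three cells in any dimension, where cell aliasing would
    double-count)."""
    if min(int(box[0] // rlist), int(box[1] // rlist), int(box[2] // rlist)) < 3:
        return brute_pair_list(pos, box, rlist, excl)
    return _cell_pair_list(pos, box, rlist, excl)


@njit(cache=True, fastmath=True)
def pair_energy_forces_switch(
    pos, box, ii, jj, types, c12_mat, c6_mat, charges, ke_over_eps,
    r_inner, cutoff, forces, virial,
):
    """GROMACS-style switched LJ + Coulomb over a pair list.

    Below ``r_inner`` the plain 12-6 force acts (energy raised by a
    constant); between ``r_inner`` and the cutoff a cubic force-switch
    takes force and its derivative smoothly to zero, term by term
    (repulsive r^-12, dispersive r^-6, Coulomb r^-1 switched from zero).
    This is the convention of Martini simulations run in LAMMPS/GROMACS.
    Returns (e_lj, e_coul, min_r2).
    """
    e_lj = 0.0
    e_c = 0.0
    rc = cutoff
    r1 = r_inner
    t = rc - r1
    # per-term switch coefficients divided by the term coefficient C:
    # force of C r^-n is n C r^-(n+1); A = (t f' - 3 f)/t^2, B = (2 f - t f')/t^3
    # evaluated at rc, linear in C
    a12 = (t * (-12.0 * 13.0 / rc**14) - 3.0 * (12.0 / rc**13)) / t**2
    b12 = (2.0 * (12.0 / rc**13) - t * (-12.0 * 13.0 / rc**14)) / t**3
    a6 = (t * (-6.0 * 7.0 / rc**8) - 3.0 * (6.0 / rc**7)) / t**2
    b6 = (2.0 * (6.0 / rc**7) - t * (-6.0 * 7.0 / rc**8)) / t**3
    # energy constants so E(rc) = 0 and E continuous at r1
    sh12 = -(1.0 / rc**12) + a12 / 3.0 * t**3 + b12 / 4.0 * t**4
    sh6 = -(1.0 / rc**6) + a6 / 3.0 * t**3 + b6 / 4.0 * t**4
    # Coulomb switched over the whole range (r1 = 0)
    ac = -5.0 / rc**4
    bc = 4.0 / rc**5
    shc = -(1.0 / rc) + ac / 3.0 * rc**3 + bc / 4.0 * rc**4
    rc2 = rc * rc
    min_r2 = 1.0e30
    for k in range(ii.shape[0]):
        i = ii[k]
        j = jj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
        if r2 >= rc2 or r2 < 1.0e-12:
            continue
        ti = types[i]
        tj = types[j]
        c12 = c12_mat[ti, tj]
        c6 = c6_mat[ti, tj]
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        ir6 = inv_r**6
        ir12 = ir6 * ir6
        e = c12 * (ir12 + sh12) - c6 * (ir6 + sh6)
        fmag = 12.0 * c12 * ir12 * inv_r - 6.0 * c6 * ir6 * inv_r
        if r > r1:
            dr = r - r1
            dr2 = dr * dr
            dr3 = dr2 * dr
            fmag += c12 * (a12 * dr2 + b12 * dr3)
            fmag -= c6 * (a6 * dr2 + b6 * dr3)
            e -= c12 * (a12 / 3.0 * dr3 + b12 / 4.0 * dr2 * dr2)
            e += c6 * (a6 / 3.0 * dr3 + b6 / 4.0 * dr2 * dr2)
        e_lj += e
        fscal = fmag * inv_r
        qq = charges[i] * charges[j]
        if qq != 0.0:
            cq = ke_over_eps * qq
            dr2 = r * r
            dr3 = dr2 * r
            e_c += cq * (inv_r + shc - ac / 3.0 * dr3 - bc / 4.0 * dr2 * dr2)
            fscal += cq * (inv_r * inv_r + ac * dr2 + bc * dr3) * inv_r
        fx = fscal * dx
        fy = fscal * dy
        fz = fscal * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz
    return e_lj, e_c, min_r2


@njit(cache=True, fastmath=True)
def pair_energy_forces(
    pos, box, ii, jj, types, sigma_mat, eps_mat, eshift_mat,
    charges, ke_over_eps, cutoff, forces, virial,
):
    """LJ (energy-shifted) + shifted-force Coulomb over a pair list.

    Returns (e_lj, e_coul, min_r2): the minimum squared distance seen lets
    the caller detect overlapping beads.
    """
    e_lj = 0.0
    e_c = 0.0
    rc2 = cutoff * cutoff
    inv_rc = 1.0 / cutoff
    inv_rc2 = inv_rc * inv_rc
    min_r2 = 1.0e30
    for k in range(ii.shape[0]):
        i = ii[k]
        j = jj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
        if r2 >= rc2 or r2 < 1.0e-12:
            continue
        ti = types[i]
        tj = types[j]
        sig = sigma_mat[ti, tj]
        eps = eps_mat[ti, tj]
        inv_r2 = 1.0 / r2
        s2 = sig * sig * inv_r2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        e_lj += 4.0 * eps * (s12 - s6) - eshift_mat[ti, tj]
        fscal = 24.0 * eps * (2.0 * s12 - s6) * inv_r2
        qq = charges[i] * charges[j]
        if qq != 0.0:
            r = np.sqrt(r2)
            c = ke_over_eps * qq
            e_c += c * (1.0 / r - inv_rc + (r - cutoff) * inv_rc2)
            fscal += c * (inv_r2 - inv_rc2) / r
        fx = fscal * dx
        fy = fscal * dy
        fz = fscal * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz
    return e_lj, e_c, min_r2


@njit(cache=True, fastmath=True)
def bond_energy_forces(pos, box, bonds, r0, kb, forces, virial):
    e = 0.0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[k]
        e += kb[k] * dr * dr
        # V = Kb (r - r0)^2  ->  |F| = 2 Kb |dr|
        fscal = -2.0 * kb[k] * dr / r
        fx = fscal * dx
        fy = fscal * dy
        fz = fscal * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz
    return e


@njit(cache=True, fastmath=True)
def angle_energy_forces(
    pos, box, angles, style, theta0, ka, forces, virial
):
    """Angle terms; style 0 = cosine-squared, style 1 = harmonic (radians)."""
    e = 0.0
    for m in range(angles.shape[0]):
        i = angles[m, 0]
        j = angles[m, 1]
        k = angles[m, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ux -= box[0] * np.rint(ux / box[0])
        uy -= box[1] * np.rint(uy / box[1])
        uz -= box[2] * np.rint(uz / box[2])
        vx -= box[0] * np.rint(vx / box[0])
        vy -= box[1] * np.rint(vy / box[1])
        vz -= box[2] * np.rint(vz / box[2])
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        # d(cos)/du and d(cos)/dv
        dcux = vx / (ru * rv) - c * ux / (ru * ru)
        dcuy = vy / (ru * rv) - c * uy / (ru * ru)
        dcuz = vz / (ru * rv) - c * uz / (ru * ru)
        dcvx = ux / (ru * rv) - c * vx / (rv * rv)
        dcvy = uy / (ru * rv) - c * vy / (rv * rv)
        dcvz = uz / (ru * rv) - c * vz / (rv * rv)
        if style[m] == 0:
            c0 = np.cos(theta0[m])
            diff = c - c0
            e += ka[m] * diff * diff
            coeff = -2.0 * ka[m] * diff  # -dV/dcos
        else:
            th = np.arccos(c)
            diff = th - theta0[m]
            e += ka[m] * diff * diff
            s = np.sqrt(1.0 - c * c)
            if s < 1.0e-8:
                s = 1.0e-8
            coeff = 2.0 * ka[m] * diff / s  # -dV/dcos = dV/dtheta / sin
        f1x = coeff * dcux
        f1y = coeff * dcuy
        f1z = coeff * dcuz
        f3x = coeff * dcvx
        f3y = coeff * dcvy
        f3z = coeff * dcvz
        forces[i, 0] += f1x
        forces[i, 1] += f1y
        forces[i, 2] += f1z
        forces[k, 0] += f3x
        forces[k, 1] += f3y
        forces[k, 2] += f3z
        forces[j, 0] -= f1x + f3x
        forces[j, 1] -= f1y + f3y
        forces[j, 2] -= f1z + f3z
        virial[0] += ux * f1x + vx * f3x
        virial[1] += uy * f1y + vy * f3y
        virial[2] += uz * f1z + vz * f3z
    return e


@njit(cache=True, fastmath=True)
def dihedral_energy_forces(
    pos, box, dihedrals, phi0, kd, nd, forces, virial
):
    """Single-term Fourier dihedral V = K [1 + cos(n phi - phi0)]."""
    e = 0.0
    for m in range(dihedrals.shape[0]):
        i1 = dihedrals[m, 0]
        i2 = dihedrals[m, 1]
        i3 = dihedrals[m, 2]
        i4 = dihedrals[m, 3]
        b1x = pos[i2, 0] - pos[i1, 0]
        b1y = pos[i2, 1] - pos[i1, 1]
        b1z = pos[i2, 2] - pos[i1, 2]
        b2x = pos[i3, 0] - pos[i2, 0]
        b2y = pos[i3, 1] - pos[i2, 1]
        b2z = pos[i3, 2] - pos[i2, 2]
        b3x = pos[i4, 0] - pos[i3, 0]
        b3y = pos[i4, 1] - pos[i3, 1]
        b3z = pos[i4, 2] - pos[i3, 2]
        b1x -= box[0] * np.rint(b1x / box[0])
        b1y -= box[1] * np.rint(b1y / box[1])
        b1z -= box[2] * np.rint(b1z / box[2])
        b2x -= box[0] * np.rint(b2x / box[0])
        b2y -= box[1] * np.rint(b2y / box[1])
        b2z -= box[2] * np.rint(b2z / box[2])
        b3x -= box[0] * np.rint(b3x / box[0])
        b3y -= box[1] * np.rint(b3y / box[1])
        b3z -= box[2] * np.rint(b3z / box[2])
        # n1 = b1 x b2 ; n2 = b2 x b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1.0e-12 or n2sq < 1.0e-12:
            continue  # collinear: torsion undefined, zero contribution
        # phi via atan2 (IUPAC sign convention)
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        sy = (mx * n2x + my * n2y + mz * n2z) / nb2
        cx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sy, cx)
        arg = nd[m] * phi - phi0[m]
        e += kd[m] * (1.0 + np.cos(arg))
        dvdphi = -kd[m] * nd[m] * np.sin(arg)
        # gradients of phi w.r.t. the four positions (this phi convention)
        g1x = nb2 / n1sq * n1x
        g1y = nb2 / n1sq * n1y
        g1z = nb2 / n1sq * n1z
        g4x = -nb2 / n2sq * n2x
        g4y = -nb2 / n2sq * n2y
        g4z = -nb2 / n2sq * n2z
        d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g2x = -(1.0 + d12) * g1x + d32 * g4x
        g2y = -(1.0 + d12) * g1y + d32 * g4y
        g2z = -(1.0 + d12) * g1z + d32 * g4z
        g3x = d12 * g1x - (1.0 + d32) * g4x
        g3y = d12 * g1y - (1.0 + d32) * g4y
        g3z = d12 * g1z - (1.0 + d32) * g4z
        f1x = -dvdphi * g1x
        f1y = -dvdphi * g1y
        f1z = -dvdphi * g1z
        f2x = -dvdphi * g2x
        f2y = -dvdphi * g2y
        f2z = -dvdphi * g2z
        f3x = -dvdphi * g3x
        f3y = -dvdphi * g3y
        f3z = -dvdphi * g3z
        f4x = -dvdphi * g4x
        f4y = -dvdphi * g4y
        f4z = -dvdphi * g4z
        forces[i1, 0] += f1x
        forces[i1, 1] += f1y
        forces[i1, 2] += f1z
        forces[i2, 0] += f2x
        forces[i2, 1] += f2y
        forces[i2, 2] += f2z
        forces[i3, 0] += f3x
        forces[i3, 1] += f3y
        forces[i3, 2] += f3z
        forces[i4, 0] += f4x
        forces[i4, 1] += f4y
        forces[i4, 2] += f4z
        # virial with atom 2 as local origin: r1 = -b1, r3 = b2, r4 = b2+b3
        virial[0] += -b1x * f1x + b2x * f3x + (b2x + b3x) * f4x
        virial[1] += -b1y * f1y + b2y * f3y + (b2y + b3y) * f4y
        virial[2] += -b1z * f1z + b2z * f3z + (b2z + b3z) * f4z
    return e
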