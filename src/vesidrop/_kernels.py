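"""Numba kernels: nonbonded/bonded forces, cell lists, stress binning.

All kernels work in reduced units (d = kBT = m = 1).  The nonbonded cutoff
equals the bead diameter d = 1.  The random force uses a counter-based,
per-pair, per-step hash RNG so that forces are independent of pair
iteration order and bit-reproducible for a given seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_MIX1 = np.uint64(0x9E3779B97F4A7C15)
_MIX2 = np.uint64(0xBF58476D1CE4E5B9)
_MIX3 = np.uint64(0x94D4A785DD58DDF3)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53
_SQRT12 = math.sqrt(12.0)


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = x + _MIX1
    z = (z ^ (z >> np.uint64(30))) * _MIX2
    z = (z ^ (z >> np.uint64(27))) * _MIX3
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def pair_uniform(seed, step, i, j):
    """Deterministic uniform in [0, 1) for unordered pair (i, j) at a step."""
    if i > j:
        i, j = j, i
    z = _splitmix64(np.uint64(seed))
    z = _splitmix64(z ^ np.uint64(step))
    z = _splitmix64(z ^ np.uint64(i))
    z = _splitmix64(z ^ np.uint64(j))
    return float(z >> np.uint64(11)) * _INV53


@njit(cache=True, inline="always", fastmath=True)
def _min_image(d, L):
    return d - L * math.floor(d / L + 0.5)


# ----------------------------------------------------------------------
# cell list
# ----------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _build_cells(pos, box, ncx, ncy, ncz):
    n = pos.shape[0]
    ntot = ncx * ncy * ncz
    idx = np.empty(n, np.int64)
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
        idx[i] = (cx * ncy + cy) * ncz + cz
    start = np.zeros(ntot + 1, np.int64)
    for i in range(n):
        start[idx[i] + 1] += 1
    for c in range(ntot):
        start[c + 1] += start[c]
    order = np.empty(n, np.int64)
    fill = start[:ntot].copy()
    for i in range(n):
        order[fill[idx[i]]] = i
        fill[idx[i]] += 1
    return start, order


# 13 half-space neighbor cell offsets (plus the same-cell i<j loop)
_HALF_OFFSETS = np.array(
    [(dx, dy, dz)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz > 0) or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0)],
    dtype=np.int64,
)


@njit(cache=True)
def build_pair_list(pos, box, cutoff):
    """All unordered pairs with minimum-image distance below ``cutoff``.

    Uses a cell list when the box accommodates >= 3 cells per axis,
    otherwise falls back to the O(N^2) loop.  Returns (i, j) int64 arrays.
    """
    n = pos.shape[0]
    ncx = int(box[0] // cutoff)
    ncy = int(box[1] // cutoff)
    ncz = int(box[2] // cutoff)
    c2 = cutoff * cutoff
    cap = 32 + int(7.0 * cutoff ** 3 * n)  # generous for rho ~ 3
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    m = 0
    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n):
            for j in range(i + 1, n):
                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                if dx * dx + dy * dy + dz * dz < c2:
                    if m >= cap:
                        raise ValueError("pair list capacity exceeded")
                    pi[m] = i
                    pj[m] = j
                    m += 1
        return pi[:m], pj[:m]
    start, order = _build_cells(pos, box, ncx, ncy, ncz)
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                a0, a1 = start[c], start[c + 1]
                # same cell
                for a in range(a0, a1):
                    i = order[a]
                    for b in range(a + 1, a1):
                        j = order[b]
                        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                        if dx * dx + dy * dy + dz * dz < c2:
                            if m >= cap:
                                raise ValueError("pair list capacity exceeded")
                            pi[m] = i
                            pj[m] = j
                            m += 1
                # half neighbor cells
                for k in range(_HALF_OFFSETS.shape[0]):
                    ox = (cx + _HALF_OFFSETS[k, 0]) % ncx
                    oy = (cy + _HALF_OFFSETS[k, 1]) % ncy
                    oz = (cz + _HALF_OFFSETS[k, 2]) % ncz
                    c2idx = (ox * ncy + oy) * ncz + oz
                    b0, b1 = start[c2idx], start[c2idx + 1]
                    for a in range(a0, a1):
                        i = order[a]
                        for b in range(b0, b1):
                            j = order[b]
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz < c2:
                                if m >= cap:
                                    raise ValueError("pair list capacity exceeded")
                                pi[m] = i
                                pj[m] = j
                                m += 1
    return pi[:m], pj[:m]


# ----------------------------------------------------------------------
# nonbonded forces
# ----------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _pair_interact(i, j, pos, vel, species, fmat, box, gamma, sigma_dt,
                   seed, step, forces):
    """Accumulate the DPD pair force; returns (conservative virial, overlap)."""
    dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
    dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
    dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= 1.0:
        return 0.0, False
    if r2 < 1e-24:
        return 0.0, True
    r = math.sqrt(r2)
    ex = dx / r
    ey = dy / r
    ez = dz / r
    w = 1.0 - r
    fc = fmat[species[i], species[j]] * w
    ft = fc
    if gamma > 0.0:
        dvx = vel[i, 0] - vel[j, 0]
        dvy = vel[i, 1] - vel[j, 1]
        dvz = vel[i, 2] - vel[j, 2]
        ev = ex * dvx + ey * dvy + ez * dvz
        ft += -gamma * w * w * ev
    if sigma_dt > 0.0:
        u = pair_uniform(seed, step, i, j)
        ft += sigma_dt * w * (_SQRT12 * (u - 0.5))
    forces[i, 0] += ft * ex
    forces[i, 1] += ft * ey
    forces[i, 2] += ft * ez
    forces[j, 0] -= ft * ex
    forces[j, 1] -= ft * ey
    forces[j, 2] -= ft * ez
    return fc * r, False


@njit(cache=True, fastmath=True)
def _forces_sorted(pos_s, vel_s, species_s, ids, fmat, box, gamma, sigma_dt,
                   seed, step, start, ncx, ncy, ncz, forces_s):
    """Pair forces on cell-sorted arrays; neighbor shifts replace min-image.

    ``ids`` carries the original bead index of each sorted slot (the RNG is
    keyed on original indices so results are sort-invariant).  Returns
    (conservative virial, overlap count).
    """
    virial = 0.0
    noverlap = 0
    Lx, Ly, Lz = box[0], box[1], box[2]
    noff = _HALF_OFFSETS.shape[0]
    use_noise = sigma_dt > 0.0
    use_gamma = gamma > 0.0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                a0, a1 = start[c], start[c + 1]
                for koff in range(noff + 1):
                    if koff == noff:  # same cell
                        b0, b1 = a0, a1
                        sx = 0.0
                        sy = 0.0
                        sz = 0.0
                        same = True
                    else:
                        ox = cx + _HALF_OFFSETS[koff, 0]
                        oy = cy + _HALF_OFFSETS[koff, 1]
                        oz = cz + _HALF_OFFSETS[koff, 2]
                        sx = 0.0
                        sy = 0.0
                        sz = 0.0
                        # wrapped neighbor cell: unwrap its bead coordinates
                        # (dx = xi - xj - s, with s = -L when the neighbor
                        # logically sits below 0, +L when above ncx-1)
                        if ox < 0:
                            ox += ncx
                            sx = -Lx
                        elif ox >= ncx:
                            ox -= ncx
                            sx = Lx
                        if oy < 0:
                            oy += ncy
                            sy = -Ly
                        elif oy >= ncy:
                            oy -= ncy
                            sy = Ly
                        if oz < 0:
                            oz += ncz
                            sz = -Lz
                        elif oz >= ncz:
                            oz -= ncz
                            sz = Lz
                        cn = (ox * ncy + oy) * ncz + oz
                        b0, b1 = start[cn], start[cn + 1]
                        same = False
                    for a in range(a0, a1):
                        xi = pos_s[a, 0]
                        yi = pos_s[a, 1]
                        zi = pos_s[a, 2]
                        vxi = vel_s[a, 0]
                        vyi = vel_s[a, 1]
                        vzi = vel_s[a, 2]
                        si = species_s[a]
                        idi = ids[a]
                        fxi = 0.0
                        fyi = 0.0
                        fzi = 0.0
                        jstart = a + 1 if same else b0
                        for b in range(jstart, b1):
                            dx = xi - pos_s[b, 0] - sx
                            dy = yi - pos_s[b, 1] - sy
                            dz = zi - pos_s[b, 2] - sz
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= 1.0:
                                continue
                            if r2 < 1e-24:
                                noverlap += 1
                                continue
                            r = math.sqrt(r2)
                            inv_r = 1.0 / r
                            w = 1.0 - r
                            fc = fmat[si, species_s[b]] * w
                            ft = fc
                            if use_gamma:
                                ev = (dx * (vxi - vel_s[b, 0])
                                      + dy * (vyi - vel_s[b, 1])
                                      + dz * (vzi - vel_s[b, 2])) * inv_r
                                ft -= gamma * w * w * ev
                            if use_noise:
                                u = pair_uniform(seed, step, idi, ids[b])
                                ft += sigma_dt * w * (_SQRT12 * (u - 0.5))
                            g = ft * inv_r
                            gx = g * dx
                            gy = g * dy
                            gz = g * dz
                            fxi += gx
                            fyi += gy
                            fzi += gz
                            forces_s[b, 0] -= gx
                            forces_s[b, 1] -= gy
                            forces_s[b, 2] -= gz
                            virial += fc * r
                        forces_s[a, 0] += fxi
                        forces_s[a, 1] += fyi
                        forces_s[a, 2] += fzi
    return virial, noverlap


@njit(cache=True, fastmath=True)
def nonbonded_forces(pos, vel, species, fmat, box, gamma, sigma_dt,
                     seed, step, forces):
    """Full nonbonded force evaluation.  Returns (virial, overlap_flag).

    ``virial`` is the conservative pair virial sum  Sigma f_c * r.
    """
    n = pos.shape[0]
    ncx = int(box[0] // 1.0)
    ncy = int(box[1] // 1.0)
    ncz = int(box[2] // 1.0)
    if ncx < 3 or ncy < 3 or ncz < 3:
        virial = 0.0
        overlap = False
        for i in range(n):
            for j in range(i + 1, n):
                v, o = _pair_interact(i, j, pos, vel, species, fmat, box,
                                      gamma, sigma_dt, seed, step, forces)
                virial += v
                overlap |= o
        return virial, overlap
    start, order = _build_cells(pos, box, ncx, ncy, ncz)
    pos_s = np.empty_like(pos)
    vel_s = np.empty_like(vel)
    species_s = np.empty_like(species)
    for k in range(n):
        i = order[k]
        pos_s[k, 0] = pos[i, 0]
        pos_s[k, 1] = pos[i, 1]
        pos_s[k, 2] = pos[i, 2]
        vel_s[k, 0] = vel[i, 0]
        vel_s[k, 1] = vel[i, 1]
        vel_s[k, 2] = vel[i, 2]
        species_s[k] = species[i]
    forces_s = np.zeros_like(forces)
    virial, noverlap = _forces_sorted(
        pos_s, vel_s, species_s, order, fmat, box, gamma, sigma_dt,
        seed, step, start, ncx, ncy, ncz, forces_s)
    for k in range(n):
        i = order[k]
        forces[i, 0] += forces_s[k, 0]
        forces[i, 1] += forces_s[k, 1]
        forces[i, 2] += forces_s[k, 2]
    return virial, noverlap > 0


@njit(cache=True, fastmath=True)
def nonbonded_forces_bruteforce(pos, vel, species, fmat, box, gamma, sigma_dt,
                                seed, step, forces):
    """O(N^2) reference evaluation (oracle for the cell-list path)."""
    n = pos.shape[0]
    virial = 0.0
    overlap = False
    for i in range(n):
        for j in range(i + 1, n):
            v, o = _pair_interact(i, j, pos, vel, species, fmat, box,
                                  gamma, sigma_dt, seed, step, forces)
            virial += v
            overlap |= o
    return virial, overlap


# ----------------------------------------------------------------------
# bonded forces
# ----------------------------------------------------------------------

@njit(cache=True)
def bonded_forces(pos, box, bonds, angles, k_bond, l0, k_angle, theta0,
                  forces):
    """Harmonic bonds + cosine bending.  Returns (energy, virial)."""
    energy = 0.0
    virial = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -k_bond * (r - l0)  # along +e pushes apart when compressed
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        energy += 0.5 * k_bond * (r - l0) ** 2
        virial += fmag * r
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]  # apex
        k = angles[t, 2]
        ax = _min_image(pos[i, 0] - pos[j, 0], box[0])
        ay = _min_image(pos[i, 1] - pos[j, 1], box[1])
        az = _min_image(pos[i, 2] - pos[j, 2], box[2])
        bx = _min_image(pos[k, 0] - pos[j, 0], box[0])
        by = _min_image(pos[k, 1] - pos[j, 1], box[1])
        bz = _min_image(pos[k, 2] - pos[j, 2], box[2])
        la = math.sqrt(ax * ax + ay * ay + az * az)
        lb = math.sqrt(bx * bx + by * by + bz * bz)
        if la < 1e-12 or lb < 1e-12:
            continue
        ct = (ax * bx + ay * by + az * bz) / (la * lb)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        theta = math.acos(ct)
        energy += k_angle * (1.0 - math.cos(theta - theta0))
        # dU/dcos(theta); sin(theta - pi) = -sin(theta) cancels exactly,
        # so the straight rest angle has the well-defined limit k_angle
        if abs(theta0 - math.pi) < 1e-12:
            dudc = k_angle
        else:
            st = math.sin(theta)
            if st < 1e-8:
                st = 1e-8
            dudc = -k_angle * math.sin(theta - theta0) / st
        # gradients of cos(theta)
        inv_ab = 1.0 / (la * lb)
        gax = bx * inv_ab - ct * ax / (la * la)
        gay = by * inv_ab - ct * ay / (la * la)
        gaz = bz * inv_ab - ct * az / (la * la)
        gbx = ax * inv_ab - ct * bx / (lb * lb)
        gby = ay * inv_ab - ct * by / (lb * lb)
        gbz = az * inv_ab - ct * bz / (lb * lb)
        fix = -dudc * gax
        fiy = -dudc * gay
        fiz = -dudc * gaz
        fkx = -dudc * gbx
        fky = -dudc * gby
        fkz = -dudc * gbz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        virial += fix * ax + fiy * ay + fiz * az
        virial += fkx * bx + fky * by + fkz * bz
    return energy, virial


# ----------------------------------------------------------------------
# stress binning (Irving-Kirkwood straight-line contour)
# ----------------------------------------------------------------------

@njit(cache=True, inline="always")
def _pair_fc(i, j, pos, species, fmat, box):
    """Conservative force vector on i and minimum-image dr = r_i - r_j."""
    dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
    dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
    dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
    r = math.sqrt(dx * dx + dy * dy + dz * dz)
    a = fmat[species[i], species[j]]
    if r >= 1.0 or r < 1e-12:
        return 0.0, 0.0, 0.0, dx, dy, dz
    f = a * (1.0 - r) / r
    return f * dx, f * dy, f * dz, dx, dy, dz


@njit(cache=True)
def radial_stress_bins(pos, vel, species, fmat, box,
                       bonds, angles, k_bond, l0, k_angle, theta0,
                       pair_i, pair_j, center, bin_w, nbins, nsub,
                       include_kinetic):
    """Accumulate P_N, P_T and chain-bead counts on radial shells.

    Contributions are not yet divided by shell volume; returns raw sums
    (PN_sum, PT_sum, rhoC_count) for one frame.
    """
    PN = np.zeros(nbins)
    PT = np.zeros(nbins)
    rc = np.zeros(nbins)
    inv_sub = 1.0 / nsub

    # nonbonded conservative pairs
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        fx, fy, fz, dx, dy, dz = _pair_fc(i, j, pos, species, fmat, box)
        if fx == 0.0 and fy == 0.0 and fz == 0.0:
            continue
        _bin_radial_segment(pos[i, 0], pos[i, 1], pos[i, 2], dx, dy, dz,
                            fx, fy, fz, box, center, bin_w, nbins, nsub,
                            inv_sub, PN, PT)
    # bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -k_bond * (r - l0) / r
        _bin_radial_segment(pos[i, 0], pos[i, 1], pos[i, 2], dx, dy, dz,
                            fmag * dx, fmag * dy, fmag * dz, box, center,
                            bin_w, nbins, nsub, inv_sub, PN, PT)
    # angles: central-force decomposition onto the two arms
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        ax = _min_image(pos[i, 0] - pos[j, 0], box[0])
        ay = _min_image(pos[i, 1] - pos[j, 1], box[1])
        az = _min_image(pos[i, 2] - pos[j, 2], box[2])
        bx = _min_image(pos[k, 0] - pos[j, 0], box[0])
        by = _min_image(pos[k, 1] - pos[j, 1], box[1])
        bz = _min_image(pos[k, 2] - pos[j, 2], box[2])
        la = math.sqrt(ax * ax + ay * ay + az * az)
        lb = math.sqrt(bx * bx + by * by + bz * bz)
        if la < 1e-12 or lb < 1e-12:
            continue
        ct = (ax * bx + ay * by + az * bz) / (la * lb)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        theta = math.acos(ct)
        if abs(theta0 - math.pi) < 1e-12:
            dudc = k_angle
        else:
            st = math.sin(theta)
            if st < 1e-8:
                st = 1e-8
            dudc = -k_angle * math.sin(theta - theta0) / st
        inv_ab = 1.0 / (la * lb)
        fix = -dudc * (bx * inv_ab - ct * ax / (la * la))
        fiy = -dudc * (by * inv_ab - ct * ay / (la * la))
        fiz = -dudc * (bz * inv_ab - ct * az / (la * la))
        fkx = -dudc * (ax * inv_ab - ct * bx / (lb * lb))
        fky = -dudc * (ay * inv_ab - ct * by / (lb * lb))
        fkz = -dudc * (az * inv_ab - ct * bz / (lb * lb))
        _bin_radial_segment(pos[i, 0], pos[i, 1], pos[i, 2], ax, ay, az,
                            fix, fiy, fiz, box, center, bin_w, nbins, nsub,
                            inv_sub, PN, PT)
        _bin_radial_segment(pos[k, 0], pos[k, 1], pos[k, 2], bx, by, bz,
                            fkx, fky, fkz, box, center, bin_w, nbins, nsub,
                            inv_sub, PN, PT)
    # kinetic + chain density
    n = pos.shape[0]
    for i in range(n):
        rx = _min_image(pos[i, 0] - center[0], box[0])
        ry = _min_image(pos[i, 1] - center[1], box[1])
        rz = _min_image(pos[i, 2] - center[2], box[2])
        r = math.sqrt(rx * rx + ry * ry + rz * rz)
        ib = int(r / bin_w)
        if ib >= nbins:
            continue
        if species[i] == 1:  # C bead
            rc[ib] += 1.0
        if include_kinetic and r > 1e-9:
            ux = rx / r
            uy = ry / r
            uz = rz / r
            vn = vel[i, 0] * ux + vel[i, 1] * uy + vel[i, 2] * uz
            v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            PN[ib] += vn * vn
            PT[ib] += 0.5 * (v2 - vn * vn)
    return PN, PT, rc


@njit(cache=True, inline="always")
def _bin_radial_segment(px, py, pz, dx, dy, dz, fx, fy, fz, box, center,
                        bin_w, nbins, nsub, inv_sub, PN, PT):
    tr = fx * dx + fy * dy + fz * dz
    for s in range(nsub):
        t = (s + 0.5) * inv_sub
        qx = px - dx * t
        qy = py - dy * t
        qz = pz - dz * t
        rx = _min_image(qx - center[0], box[0])
        ry = _min_image(qy - center[1], box[1])
        rz = _min_image(qz - center[2], box[2])
        r = math.sqrt(rx * rx + ry * ry + rz * rz)
        ib = int(r / bin_w)
        if ib >= nbins or r < 1e-9:
            continue
        ux = rx / r
        uy = ry / r
        uz = rz / r
        fn = fx * ux + fy * uy + fz * uz
        dn = dx * ux + dy * uy + dz * uz
        pn = fn * dn
        PN[ib] += pn * inv_sub
        PT[ib] += 0.5 * (tr - pn) * inv_sub


@njit(cache=True)
def planar_stress_bins(pos, vel, species, fmat, box,
                       bonds, k_bond, l0, pair_i, pair_j,
                       axis, nbins, include_kinetic):
    """Accumulate P_N (along ``axis``) and transverse mean per slab.

    The pair virial is distributed over slabs in exact proportion to the
    segment length inside each slab.  Raw sums; divide by slab volume
    outside.  (Angle terms are omitted here: planar slabs in this package
    are solvent-only W/S systems.)
    """
    L = box[axis]
    dz = L / nbins
    PN = np.zeros(nbins)
    PT = np.zeros(nbins)
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        fx, fy, fz, ddx, ddy, ddz = _pair_fc(i, j, pos, species, fmat, box)
        if fx == 0.0 and fy == 0.0 and fz == 0.0:
            continue
        _bin_planar_segment(pos, i, fx, fy, fz, ddx, ddy, ddz, axis, L, dz,
                            nbins, PN, PT)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        ddx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        ddy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        ddz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
        if r < 1e-12:
            continue
        fmag = -k_bond * (r - l0) / r
        _bin_planar_segment(pos, i, fmag * ddx, fmag * ddy, fmag * ddz,
                            ddx, ddy, ddz, axis, L, dz, nbins, PN, PT)
    if include_kinetic:
        n = pos.shape[0]
        for i in range(n):
            ib = int(pos[i, axis] / dz)
            if ib >= nbins:
                ib = nbins - 1
            vn = vel[i, axis]
            v2 = vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            PN[ib] += vn * vn
            PT[ib] += 0.5 * (v2 - vn * vn)
    return PN, PT


@njit(cache=True, inline="always")
def _bin_planar_segment(pos, i, fx, fy, fz, ddx, ddy, ddz, axis, L, dz,
                        nbins, PN, PT):
    d_ax = ddx if axis == 0 else (ddy if axis == 1 else ddz)
    f_ax = fx if axis == 0 else (fy if axis == 1 else fz)
    pn = f_ax * d_ax
    tr = fx * ddx + fy * ddy + fz * ddz
    pt = 0.5 * (tr - pn)
    zi = pos[i, axis]
    zj = zi - d_ax  # unwrapped partner coordinate
    zlo = zi if zi < zj else zj
    zhi = zj if zi < zj else zi
    seg = zhi - zlo
    if seg < 1e-9:
        ib = int((0.5 * (zlo + zhi)) % L / dz)
        if ib >= nbins:
            ib = nbins - 1
        PN[ib] += pn
        PT[ib] += pt
        return
    k0 = int(math.floor(zlo / dz))
    k1 = int(math.floor(zhi / dz))
    for k in range(k0, k1 + 1):
        lo = zlo if zlo > k * dz else k * dz
        hi = zhi if zhi < (k + 1) * dz else (k + 1) * dz
        if hi <= lo:
            continue
        frac = (hi - lo) / seg
        ib = k % nbins
        PN[ib] += pn * frac
        PT[ib] += pt * frac


@njit(cache=True)
def axisym_stress_bins(pos, vel, species, fmat, box,
                       bonds, k_bond, l0, pair_i, pair_j,
                       axis_x, axis_z, y0, cell, nr, ny, nsub,
                       include_kinetic):
    """Accumulate cylindrical stress components on an (r, y) grid.

    The symmetry axis is parallel to the y (index 1) direction and passes
    through (axis_x, axis_z); y is measured from y0.  Returns raw sums of
    P_yy and the mean transverse component (P_rr + P_phiphi)/2, plus bead
    counts, all on the (nr, ny) grid.
    """
    Pyy = np.zeros((nr, ny))
    Ptrans = np.zeros((nr, ny))
    cnt = np.zeros((nr, ny))
    inv_sub = 1.0 / nsub
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        fx, fy, fz, ddx, ddy, ddz = _pair_fc(i, j, pos, species, fmat, box)
        if fx == 0.0 and fy == 0.0 and fz == 0.0:
            continue
        _bin_axisym_segment(pos[i, 0], pos[i, 1], pos[i, 2], ddx, ddy, ddz,
                            fx, fy, fz, box, axis_x, axis_z, y0, cell,
                            nr, ny, nsub, inv_sub, Pyy, Ptrans)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        ddx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        ddy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        ddz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
        if r < 1e-12:
            continue
        fm = -k_bond * (r - l0) / r
        _bin_axisym_segment(pos[i, 0], pos[i, 1], pos[i, 2], ddx, ddy, ddz,
                            fm * ddx, fm * ddy, fm * ddz, box, axis_x,
                            axis_z, y0, cell, nr, ny, nsub, inv_sub,
                            Pyy, Ptrans)
    n = pos.shape[0]
    for i in range(n):
        rx = _min_image(pos[i, 0] - axis_x, box[0])
        rz = _min_image(pos[i, 2] - axis_z, box[2])
        rr = math.sqrt(rx * rx + rz * rz)
        yy = _min_image(pos[i, 1] - y0, box[1])
        ir = int(rr / cell)
        iy = int(math.floor(yy / cell)) + ny // 2
        if ir >= nr or iy < 0 or iy >= ny:
            continue
        cnt[ir, iy] += 1.0
        if include_kinetic and rr > 1e-9:
            ux = rx / rr
            uz = rz / rr
            vr = vel[i, 0] * ux + vel[i, 2] * uz
            vp = -vel[i, 0] * uz + vel[i, 2] * ux
            Pyy[ir, iy] += vel[i, 1] ** 2
            Ptrans[ir, iy] += 0.5 * (vr * vr + vp * vp)
    return Pyy, Ptrans, cnt


@njit(cache=True, inline="always")
def _bin_axisym_segment(px, py, pz, ddx, ddy, ddz, fx, fy, fz, box,
                        axis_x, axis_z, y0, cell, nr, ny, nsub, inv_sub,
                        Pyy, Ptrans):
    for s in range(nsub):
        t = (s + 0.5) * inv_sub
        qx = px - ddx * t
        qy = py - ddy * t
        qz = pz - ddz * t
        rx = _min_image(qx - axis_x, box[0])
        rz = _min_image(qz - axis_z, box[2])
        rr = math.sqrt(rx * rx + rz * rz)
        yy = _min_image(qy - y0, box[1])
        ir = int(rr / cell)
        iy = int(math.floor(yy / cell)) + ny // 2
        if ir >= nr or iy < 0 or iy >= ny or rr < 1e-9:
            continue
        ux = rx / rr
        uz = rz / rr
        fr = fx * ux + fz * uz
        dr_r = ddx * ux + ddz * uz
        fp = -fx * uz + fz * ux
        dr_p = -ddx * uz + ddz * ux
        Pyy[ir, iy] += fy * ddy * inv_sub
        Ptrans[ir, iy] += 0.5 * (fr * dr_r + fp * dr_p) * inv_sub
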