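"""Numba kernels for the time-stepping hot loop.

These mirror the numpy reference implementation in :mod:`mpsim.forcefield`
(a test asserts agreement) but run the full BAOAB Langevin step over many
integration steps per call. Excluded-volume pairs go through a Verlet
neighbour list with a displacement-triggered rebuild; dipolar interactions
are a direct all-pairs sum (no cutoff). Summation order over candidate
pairs is fixed by the (i-major) build order, and pairs outside the true
cutoff contribute exactly zero, so trajectories are bitwise independent of
when the list was last rebuilt.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SKIN = 0.3


@njit(cache=True, fastmath=False)
def _bsearch(keys, key):
    lo, hi = 0, len(keys)
    while lo < hi:
        mid = (lo + hi) // 2
        if keys[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < len(keys) and keys[lo] == key


@njit(cache=True, fastmath=False)
def build_neighbors(pos, diam, excl_keys, nb_i, nb_j, pos_ref):
    """Fill the Verlet list with pairs inside cutoff+skin; return count (-1 on overflow)."""
    n = pos.shape[0]
    cap = nb_i.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            rc = 0.5 * (diam[i] + diam[j]) + SKIN
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc * rc:
                if _bsearch(excl_keys, i * n + j):
                    continue
                if count >= cap:
                    return -1
                nb_i[count] = i
                nb_j[count] = j
                count += 1
    for i in range(n):
        for d in range(3):
            pos_ref[i, d] = pos[i, d]
    return count


@njit(cache=True, fastmath=False)
def compute_forces(
    pos,
    ori,
    diam,
    edges,
    r0e,
    tris,
    s0,
    teth,
    r0t,
    nb_i,
    nb_j,
    nb_count,
    ks,
    kal,
    kh,
    eps,
    lam_a3,
    hx,
    hy,
    hz,
    mag_on,
    n_mnp,
    forces,
    torques,
):
    """All forces on all elements and torques on the dipoles, in place."""
    p = pos.shape[0]
    nb = p - n_mnp  # blobs first, MNPs last
    forces[:] = 0.0
    torques[:] = 0.0

    # neo-Hookean edges
    for k in range(edges.shape[0]):
        i, j = edges[k, 0], edges[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        x = r / r0e[k]
        kappa = (np.sqrt(x) + x**-2.5) / (x + x**-3.0)
        fmag = ks * kappa * (x - 1.0) / r  # along d, on i
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # local-area constraint
    for k in range(tris.shape[0]):
        a, b, c = tris[k, 0], tris[k, 1], tris[k, 2]
        e1x = pos[b, 0] - pos[a, 0]
        e1y = pos[b, 1] - pos[a, 1]
        e1z = pos[b, 2] - pos[a, 2]
        e2x = pos[c, 0] - pos[a, 0]
        e2y = pos[c, 1] - pos[a, 1]
        e2z = pos[c, 2] - pos[a, 2]
        nx = e1y * e2z - e1z * e2y
        ny = e1z * e2x - e1x * e2z
        nz = e1x * e2y - e1y * e2x
        s = 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
        cx = (pos[a, 0] + pos[b, 0] + pos[c, 0]) / 3.0
        cy = (pos[a, 1] + pos[b, 1] + pos[c, 1]) / 3.0
        cz = (pos[a, 2] + pos[b, 2] + pos[c, 2]) / 3.0
        coef = -kal * (s - s0[k]) / s
        for v in range(3):
            iv = tris[k, v]
            wx = pos[iv, 0] - cx
            wy = pos[iv, 1] - cy
            wz = pos[iv, 2] - cz
            wn = np.sqrt(wx * wx + wy * wy + wz * wz)
            forces[iv, 0] += coef * wx / wn
            forces[iv, 1] += coef * wy / wn
            forces[iv, 2] += coef * wz / wn

    # inter-shell tethers
    for k in range(teth.shape[0]):
        i, j = teth[k, 0], teth[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        fmag = kh * (r - r0t[k]) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # WCA excluded volume over the neighbour list
    for k in range(nb_count):
        i, j = nb_i[k], nb_j[k]
        rc = 0.5 * (diam[i] + diam[j])
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc:
            continue
        sigma2 = rc * rc / 2.0 ** (1.0 / 3.0)
        s6 = (sigma2 / r2) ** 3
        fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2  # F/r, repulsive
        forces[i, 0] -= fr * dx
        forces[i, 1] -= fr * dy
        forces[i, 2] -= fr * dz
        forces[j, 0] += fr * dx
        forces[j, 1] += fr * dy
        forces[j, 2] += fr * dz

    # magnetics: dipole-dipole + Zeeman
    if mag_on and n_mnp > 0:
        hloc = np.empty((n_mnp, 3))
        for a in range(n_mnp):
            hloc[a, 0] = hx
            hloc[a, 1] = hy
            hloc[a, 2] = hz
        if lam_a3 != 0.0:
            for a in range(n_mnp):
                ia = nb + a
                for b2 in range(a + 1, n_mnp):
                    ib = nb + b2
                    dx = pos[ib, 0] - pos[ia, 0]
                    dy = pos[ib, 1] - pos[ia, 1]
                    dz = pos[ib, 2] - pos[ia, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    r = np.sqrt(r2)
                    inv_r = 1.0 / r
                    nx2 = dx * inv_r
                    ny2 = dy * inv_r
                    nz2 = dz * inv_r
                    eax = ori[a, 0]
                    eay = ori[a, 1]
                    eaz = ori[a, 2]
                    ebx = ori[b2, 0]
                    eby = ori[b2, 1]
                    ebz = ori[b2, 2]
                    ee = eax * ebx + eay * eby + eaz * ebz
                    ean = eax * nx2 + eay * ny2 + eaz * nz2
                    ebn = ebx * nx2 + eby * ny2 + ebz * nz2
                    inv_r3 = inv_r / r2
                    pref = 3.0 * lam_a3 * inv_r3 * inv_r
                    # force on b from a
                    fbx = pref * ((ee - 5.0 * ean * ebn) * nx2 + ean * ebx + ebn * eax)
                    fby = pref * ((ee - 5.0 * ean * ebn) * ny2 + ean * eby + ebn * eay)
                    fbz = pref * ((ee - 5.0 * ean * ebn) * nz2 + ean * ebz + ebn * eaz)
                    forces[ib, 0] += fbx
                    forces[ib, 1] += fby
                    forces[ib, 2] += fbz
                    forces[ia, 0] -= fbx
                    forces[ia, 1] -= fby
                    forces[ia, 2] -= fbz
                    # local fields: h_a += lam a^3 (3 (e_b.n) n - e_b)/r^3
                    la3r3 = lam_a3 * inv_r3
                    hloc[a, 0] += la3r3 * (3.0 * ebn * nx2 - ebx)
                    hloc[a, 1] += la3r3 * (3.0 * ebn * ny2 - eby)
                    hloc[a, 2] += la3r3 * (3.0 * ebn * nz2 - ebz)
                    hloc[b2, 0] += la3r3 * (3.0 * ean * nx2 - eax)
                    hloc[b2, 1] += la3r3 * (3.0 * ean * ny2 - eay)
                    hloc[b2, 2] += la3r3 * (3.0 * ean * nz2 - eaz)
        for a in range(n_mnp):
            ex = ori[a, 0]
            ey = ori[a, 1]
            ez = ori[a, 2]
            torques[a, 0] = ey * hloc[a, 2] - ez * hloc[a, 1]
            torques[a, 1] = ez * hloc[a, 0] - ex * hloc[a, 2]
            torques[a, 2] = ex * hloc[a, 1] - ey * hloc[a, 0]


@njit(cache=True, fastmath=False)
def _rotate_orientations(ori, angvel, h):
    """Rodrigues rotation of each unit dipole about its angular velocity, angle |w|*h."""
    for a in range(ori.shape[0]):
        wx = angvel[a, 0]
        wy = angvel[a, 1]
        wz = angvel[a, 2]
        wn = np.sqrt(wx * wx + wy * wy + wz * wz)
        if wn < 1e-300:
            continue
        phi = wn * h
        ux = wx / wn
        uy = wy / wn
        uz = wz / wn
        c = np.cos(phi)
        s = np.sin(phi)
        ex = ori[a, 0]
        ey = ori[a, 1]
        ez = ori[a, 2]
        dot = ux * ex + uy * ey + uz * ez
        cx = uy * ez - uz * ey
        cy = uz * ex - ux * ez
        cz = ux * ey - uy * ex
        nx2 = ex * c + cx * s + ux * dot * (1.0 - c)
        ny2 = ey * c + cy * s + uy * dot * (1.0 - c)
        nz2 = ez * c + cz * s + uz * dot * (1.0 - c)
        norm = np.sqrt(nx2 * nx2 + ny2 * ny2 + nz2 * nz2)
        ori[a, 0] = nx2 / norm
        ori[a, 1] = ny2 / norm
        ori[a, 2] = nz2 / norm


@njit(cache=True, fastmath=False)
def run_chunk(
    pos,
    vel,
    ori,
    angvel,
    forces,
    torques,
    noise_t,
    noise_r,
    dt,
    mass,
    inertia,
    c1t,
    c2t,
    c1r,
    c2r,
    diam,
    edges,
    r0e,
    tris,
    s0,
    teth,
    r0t,
    excl_keys,
    nb_i,
    nb_j,
    nb_state,
    pos_ref,
    ks,
    kal,
    kh,
    eps,
    lam_a3,
    hx,
    hy,
    hz,
    mag_on,
    n_mnp,
):
    """Advance ``noise_t.shape[0]`` BAOAB steps in place.

    Returns the number of steps completed (== n_steps on success). A
    neighbour-list overflow stops integration cleanly BEFORE consuming the
    step's noise (the caller grows the buffers and resumes with the unused
    noise), so the trajectory is unaffected. Returns -2 on non-finite
    forces."""
    n_steps = noise_t.shape[0]
    p = pos.shape[0]
    half = 0.5 * dt
    skin_half2 = (SKIN * 0.5) ** 2

    def _need_rebuild():
        for i in range(p):
            dx = pos[i, 0] - pos_ref[i, 0]
            dy = pos[i, 1] - pos_ref[i, 1]
            dz = pos[i, 2] - pos_ref[i, 2]
            if dx * dx + dy * dy + dz * dz > skin_half2:
                return True
        return False

    # entry: neighbour list + forces consistent with current positions.
    # Demand 1.5x headroom so a mid-chunk rebuild cannot overflow; an entry
    # overflow is safe to retry (nothing mutated yet).
    cnt = build_neighbors(pos, diam, excl_keys, nb_i, nb_j, pos_ref)
    if cnt < 0 or 3 * cnt > 2 * nb_i.shape[0]:
        return -1
    nb_state[0] = cnt
    compute_forces(
        pos, ori, diam, edges, r0e, tris, s0, teth, r0t, nb_i, nb_j, cnt,
        ks, kal, kh, eps, lam_a3, hx, hy, hz, mag_on, n_mnp, forces, torques,
    )

    for s in range(n_steps):
        # B
        for i in range(p):
            for d in range(3):
                vel[i, d] += half * forces[i, d] / mass
        for a in range(n_mnp):
            for d in range(3):
                angvel[a, d] += half * torques[a, d] / inertia
        # A
        for i in range(p):
            for d in range(3):
                pos[i, d] += half * vel[i, d]
        _rotate_orientations(ori, angvel, half)
        # O
        for i in range(p):
            for d in range(3):
                vel[i, d] = c1t[i] * vel[i, d] + c2t[i] * noise_t[s, i, d]
        for a in range(n_mnp):
            for d in range(3):
                angvel[a, d] = c1r * angvel[a, d] + c2r * noise_r[s, a, d]
        # A
        for i in range(p):
            for d in range(3):
                pos[i, d] += half * vel[i, d]
        _rotate_orientations(ori, angvel, half)
        # force refresh + B
        if _need_rebuild():
            cnt = build_neighbors(pos, diam, excl_keys, nb_i, nb_j, pos_ref)
            if cnt < 0:
                return -3  # cannot happen with entry headroom; hard stop
            nb_state[0] = cnt
        compute_forces(
            pos, ori, diam, edges, r0e, tris, s0, teth, r0t, nb_i, nb_j, nb_state[0],
            ks, kal, kh, eps, lam_a3, hx, hy, hz, mag_on, n_mnp, forces, torques,
        )
        ok = True
        for i in range(p):
            for d in range(3):
                if not np.isfinite(forces[i, d]):
                    ok = False
        if not ok:
            return -2
        for i in range(p):
            for d in range(3):
                vel[i, d] += half * forces[i, d] / mass
        for a in range(n_mnp):
            for d in range(3):
                angvel[a, d] += half * torques[a, d] / inertia
    return n_steps
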