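"""Numba kernels for the reduced-scale 3D bead-spring polymer.

Overdamped (Brownian) dynamics: each 0.014-s timestep is split into
``n_sub`` force substeps for bond-stiffness stability; noise with variance
``2 D dt_sub`` per coordinate is applied every substep.  Excluded volume
uses a Verlet pair list rebuilt once per full step from a cell list.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def seed_np(seed):
    np.random.seed(seed)


@njit(cache=True)
def bond_energy_nb(r, k, b0):
    return 0.5 * k * (r - b0) ** 2


@njit(cache=True)
def excluded_energy_nb(r, eps, sigma):
    if r >= sigma:
        return 0.0
    eps_m = 46656.0 / 823543.0
    x = r * np.sqrt(6.0 / 7.0) / sigma
    return (eps / eps_m) * x**12 * (x * x - 1.0) + eps


_STENCIL = np.array(
    [(0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
     (1, -1, -1), (1, -1, 0), (1, -1, 1),
     (1, 0, -1), (1, 0, 0), (1, 0, 1),
     (1, 1, -1), (1, 1, 0), (1, 1, 1)], dtype=np.int64)


@njit(cache=True)
def build_pairs(pos, cutoff, pairs):
    """Cell-list pair search (counting sort + forward half stencil).

    Returns the number of candidate pairs within ``cutoff``.
    """
    n = pos.shape[0]
    lo0 = pos[:, 0].min()
    lo1 = pos[:, 1].min()
    lo2 = pos[:, 2].min()
    inv = 1.0 / cutoff
    n0 = int((pos[:, 0].max() - lo0) * inv) + 1
    n1 = int((pos[:, 1].max() - lo1) * inv) + 1
    n2 = int((pos[:, 2].max() - lo2) * inv) + 1
    # dilute/spread-out chains: cap the grid at ~4 cells per monomer by
    # coarsening the cells (larger cells stay correct, just scan more pairs)
    while n0 * n1 * n2 > 4 * n + 64:
        inv *= 0.62
        n0 = int((pos[:, 0].max() - lo0) * inv) + 1
        n1 = int((pos[:, 1].max() - lo1) * inv) + 1
        n2 = int((pos[:, 2].max() - lo2) * inv) + 1
    ncell = n0 * n1 * n2
    count = np.zeros(ncell + 1, dtype=np.int32)
    cell = np.empty(n, dtype=np.int32)
    for i in range(n):
        c0 = int((pos[i, 0] - lo0) * inv)
        c1 = int((pos[i, 1] - lo1) * inv)
        c2 = int((pos[i, 2] - lo2) * inv)
        c = (c0 * n1 + c1) * n2 + c2
        cell[i] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int32)
    fill = count[:-1].copy()
    for i in range(n):
        c = cell[i]
        order[fill[c]] = i
        fill[c] += 1
    cut2 = cutoff * cutoff
    m = 0
    cap = pairs.shape[0]
    for c in range(ncell):
        a_lo = count[c]
        a_hi = count[c + 1]
        if a_lo == a_hi:
            continue
        c2i = c % n2
        c1i = (c // n2) % n1
        c0i = c // (n1 * n2)
        # within-cell pairs
        for ai in range(a_lo, a_hi):
            i = order[ai]
            for bi in range(ai + 1, a_hi):
                j = order[bi]
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if dx * dx + dy * dy + dz * dz < cut2 and m < cap:
                    pairs[m, 0] = i
                    pairs[m, 1] = j
                    m += 1
        # forward half-stencil
        for si in range(13):
            a0 = c0i + _STENCIL[si, 0]
            a1 = c1i + _STENCIL[si, 1]
            a2 = c2i + _STENCIL[si, 2]
            if a0 < 0 or a0 >= n0 or a1 < 0 or a1 >= n1 or a2 < 0 or a2 >= n2:
                continue
            cc = (a0 * n1 + a1) * n2 + a2
            b_lo = count[cc]
            b_hi = count[cc + 1]
            for ai in range(a_lo, a_hi):
                i = order[ai]
                for bi in range(b_lo, b_hi):
                    j = order[bi]
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    if dx * dx + dy * dy + dz * dz < cut2 and m < cap:
                        pairs[m, 0] = i
                        pairs[m, 1] = j
                        m += 1
    return m


@njit(cache=True)
def advance(pos, backbone_ok, lef_bonds, n_lef,
            n_steps, n_sub, dt, D, k_bond, b0, eps, sigma, conf_k, conf_r,
            mon_pairs, captured, capture_t, t0, capture_radius,
            pairs_buf, forces, xi):
    """Run ``n_steps`` full timesteps; returns (steps_done, diverged).

    ``mon_pairs`` are monomer index pairs monitored for first passage
    within ``capture_radius`` (checked once per full step); results are
    written to ``captured``/``capture_t``.  Exits early when every
    monitored pair is captured and ``mon_pairs`` is nonempty.
    """
    n = pos.shape[0]
    dt_sub = dt / n_sub
    mob = D * dt_sub
    noise = np.sqrt(2.0 * D * dt_sub)
    eps_m = 46656.0 / 823543.0
    x_pre = np.sqrt(6.0 / 7.0) / sigma
    skin_cut = sigma + 0.6
    npairs = 0
    ksub = 0
    for step in range(n_steps):
        if step % 2 == 0:
            npairs = build_pairs(pos, skin_cut, pairs_buf)
        for sub in range(n_sub):
            for i in range(n):
                forces[i, 0] = 0.0
                forces[i, 1] = 0.0
                forces[i, 2] = 0.0
            # backbone + LEF harmonic bonds
            for i in range(n - 1):
                if backbone_ok[i]:
                    _spring(pos, forces, i, i + 1, k_bond, b0)
            for bi in range(n_lef):
                a = lef_bonds[bi, 0]
                c = lef_bonds[bi, 1]
                if a != c:
                    _spring(pos, forces, a, c, k_bond, b0)
            # excluded volume
            for p in range(npairs):
                i = pairs_buf[p, 0]
                j = pairs_buf[p, 1]
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < sigma * sigma and r2 > 1e-12:
                    r = np.sqrt(r2)
                    x = r * x_pre
                    x2 = x * x
                    x11 = x2 * x2 * x2 * x2 * x2 * x  # x^11
                    dudr = (eps / eps_m) * (14.0 * x11 * x2 - 12.0 * x11) * x_pre
                    f = -dudr / r
                    forces[i, 0] += f * dx
                    forces[i, 1] += f * dy
                    forces[i, 2] += f * dz
                    forces[j, 0] -= f * dx
                    forces[j, 1] -= f * dy
                    forces[j, 2] -= f * dz
            # confinement + integration
            for i in range(n):
                if conf_k > 0.0:
                    rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
                    if rr > conf_r:
                        f = -conf_k * (rr - conf_r) / rr
                        forces[i, 0] += f * pos[i, 0]
                        forces[i, 1] += f * pos[i, 1]
                        forces[i, 2] += f * pos[i, 2]
                for c in range(3):
                    d = mob * forces[i, c]
                    if d > 0.5:
                        d = 0.5
                    elif d < -0.5:
                        d = -0.5
                    pos[i, c] += d + noise * xi[ksub, i, c]
            ksub += 1
        # capture monitoring, once per full step
        all_done = mon_pairs.shape[0] > 0
        for q in range(mon_pairs.shape[0]):
            if captured[q]:
                continue
            a = mon_pairs[q, 0]
            c = mon_pairs[q, 1]
            dx = pos[a, 0] - pos[c, 0]
            dy = pos[a, 1] - pos[c, 1]
            dz = pos[a, 2] - pos[c, 2]
            if dx * dx + dy * dy + dz * dz <= capture_radius * capture_radius:
                captured[q] = 1
                capture_t[q] = t0 + step + 1
            else:
                all_done = False
        if not np.isfinite(pos[0, 0]):
            return step + 1, 1
        if all_done:
            return step + 1, 0
    return n_steps, 0


@njit(cache=True, inline="always")
def _spring(pos, forces, i, j, k, b0):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    if r < 1e-9:
        return
    f = -k * (r - b0) / r
    forces[i, 0] += f * dx
    forces[i, 1] += f * dy
    forces[i, 2] += f * dz
    forces[j, 0] -= f * dx
    forces[j, 1] -= f * dy
    forces[j, 2] -= f * dz
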