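"""Numba kernels for the 1D loop-extrusion lattice engine.

State layout (shared with :mod:`loopsynapse.lattice`):

* per-LEF arrays ``left``, ``right`` (motor sites), ``stall_l``/``stall_r``
  (latched BE stalls), ``longlived``;
* one per-site flag byte ``flags`` (bits: BE site, stall-draw for leftward /
  rightward arrivals, break barrier to the left / right, broken DSB-end
  site) and one packed per-site occupancy word ``pack`` (motor count in the
  low 12 bits, owner LEF id of the last motor to enter in the high bits;
  the owner is valid whenever exactly one LEF's motors sit on the site);
* ``end_stack`` bookkeeping of which LEFs have motors on each broken end
  site, used by the gap walk (end sites allow co-occupancy);
* ``meta`` scalar slots: 0 free loadable sites, 1 loading events,
  2 loading events at DSB ends, 3 active DSBs, 4 stack overflows,
  5 load failures.

Within one Monte Carlo step the update order is: unbinding draws for every
LEF, immediate reloading of unbound LEFs, then motor moves in a fresh
random permutation of all mobile motors, then synapsis monitoring.

Randomness comes from an inline xorshift64* stream seeded per run;
unbinding uses geometric skipping with thinning (the unstabilized rate
``p_off`` bounds every LEF's rate), so its RNG cost scales with the number
of unbinding events rather than the number of LEFs.
"""

import numpy as np
from numba import njit

META_FREE = 0
META_LOADS = 1
META_LOADS_END = 2
META_ACTIVE = 3
META_OVERFLOW = 4
META_LOADFAIL = 5

# site flag bits
F_BE = 1          # boundary element occupies this site
F_BLK_L = 2       # convergent BE for motors stepping leftward onto the site
F_BLK_R = 4       # convergent BE for motors stepping rightward onto the site
F_BAR_L = 8       # broken end: cannot step leftward from this site
F_BAR_R = 16      # broken end: cannot step rightward from this site
F_END = 32        # broken DSB-end site (co-occupancy, targeted loading)

_CNT_BITS = 12
_CNT_MASK = (1 << _CNT_BITS) - 1

_MULT = np.uint64(0x2545F4914F6CDD1D)
_INV53 = 1.0 / 9007199254740992.0


def make_rng_state(seed: int) -> np.ndarray:
    """Seed the kernel RNG via one splitmix64 round (state must be nonzero)."""
    mask = (1 << 64) - 1
    z = (int(seed) + 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    if z == 0:
        z = 0x1234567887654321
    return np.array([z], dtype=np.uint64)


@njit(cache=True, inline="always")
def _rnd(rng):
    x = rng[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    rng[0] = x
    return float((x * _MULT) >> np.uint64(11)) * _INV53


@njit(cache=True, inline="always")
def _count(v):
    return v & _CNT_MASK


@njit(cache=True, inline="always")
def _owner(v):
    return v >> _CNT_BITS


@njit(cache=True, inline="always")
def _leave(s, l, pack, flags, end_idx, end_stack, end_stack_n, meta):
    v = pack[s]
    pack[s] = v - 1  # decrement count, keep owner bits
    f = flags[s]
    if f & F_END:
        ei = end_idx[s]
        n = end_stack_n[ei]
        for k in range(n):
            if end_stack[ei, k] == l:
                end_stack[ei, k] = end_stack[ei, n - 1]
                end_stack_n[ei] = n - 1
                break
    elif _count(v) == 1 and not (f & F_BE):
        meta[META_FREE] += 1


@njit(cache=True, inline="always")
def _enter(t, l, pack, flags, end_idx, end_stack, end_stack_n, meta):
    f = flags[t]
    v = pack[t]
    if f & F_END:
        ei = end_idx[t]
        n = end_stack_n[ei]
        if n < end_stack.shape[1]:
            end_stack[ei, n] = l
            end_stack_n[ei] = n + 1
        else:
            meta[META_OVERFLOW] += 1
    elif _count(v) == 0 and not (f & F_BE):
        meta[META_FREE] -= 1
    pack[t] = (l << _CNT_BITS) | (_count(v) + 1)


@njit(cache=True, inline="always")
def _load_one(l, F, G, left, right, pack, flags,
              end_sites, end_idx, end_stack, end_stack_n, meta, rng):
    """Load LEF ``l`` with both motors on one site.

    Broken DSB-end sites carry loading weight ``F`` each and stay loadable
    regardless of occupancy; every free site that is neither a BE nor an end
    carries weight 1.
    """
    n_end = end_sites.shape[0]
    w_end = F * n_end
    total = w_end + meta[META_FREE]
    if total <= 0:
        meta[META_LOADFAIL] += 1
        return
    u = _rnd(rng) * total
    if u < w_end:
        idx = int(u / F)
        if idx >= n_end:
            idx = n_end - 1
        s = end_sites[idx]
    else:
        while True:
            s = int(_rnd(rng) * G)
            if _count(pack[s]) == 0 and flags[s] & (F_BE | F_END) == 0:
                break
    left[l] = s
    right[l] = s
    _enter(s, l, pack, flags, end_idx, end_stack, end_stack_n, meta)
    _enter(s, l, pack, flags, end_idx, end_stack, end_stack_n, meta)
    meta[META_LOADS] += 1
    if flags[s] & F_END:
        meta[META_LOADS_END] += 1


@njit(cache=True)
def init_load(F, G, left, right, pack, flags,
              end_sites, end_idx, end_stack, end_stack_n, meta, rng):
    for l in range(left.shape[0]):
        _load_one(l, F, G, left, right, pack, flags,
                  end_sites, end_idx, end_stack, end_stack_n, meta, rng)


@njit(cache=True, inline="always")
def _gap_left(e, cl, left, right, pack, end_idx, end_stack, end_stack_n):
    """Unextruded sites strictly between constraining motor ``cl`` and end ``e``.

    Sites holding a motor or lying inside a (gap-bridging) loop count as
    extruded; nested loops are skipped via their right-motor anchors.  The
    walk stops once more than two unextruded sites are seen.
    """
    pos = e - 1
    ei = end_idx[e]
    if ei >= 0:
        mn = e
        n = end_stack_n[ei]
        for k in range(n):
            lef = end_stack[ei, k]
            if right[lef] == e and left[lef] < mn:
                mn = left[lef]
        if mn < e:
            pos = mn - 1
    unext = 0
    while pos > cl and unext <= 2:
        v = pack[pos]
        if _count(v) > 0:
            lef = _owner(v)
            if right[lef] == pos:
                pos = left[lef] - 1
            else:
                pos -= 1
        else:
            unext += 1
            pos -= 1
    return unext


@njit(cache=True, inline="always")
def _gap_right(e2, cr, left, right, pack, end_idx, end_stack, end_stack_n):
    pos = e2 + 1
    ei = end_idx[e2]
    if ei >= 0:
        mx = e2
        n = end_stack_n[ei]
        for k in range(n):
            lef = end_stack[ei, k]
            if left[lef] == e2 and right[lef] > mx:
                mx = right[lef]
        if mx > e2:
            pos = mx + 1
    unext = 0
    while pos < cr and unext <= 2:
        v = pack[pos]
        if _count(v) > 0:
            lef = _owner(v)
            if left[lef] == pos:
                pos = right[lef] + 1
            else:
                pos += 1
        else:
            unext += 1
            pos += 1
    return unext


@njit(cache=True)
def run_steps(n_steps, t0,
              left, right, stall_l, stall_r, longlived,
              pack, flags, end_sites, end_idx, end_stack, end_stack_n,
              perm, meta, rng,
              dsb_left, dsb_state, dsb_time, cons, cons_n, cons_map,
              p_off, b, w, r, llf, F, monitor):
    """Advance the lattice ``n_steps`` Monte Carlo steps (early exit once all
    monitored DSBs are resolved).  Returns the number of steps executed."""
    N = left.shape[0]
    G = pack.shape[0]
    n_dsb = dsb_left.shape[0]
    use_skip = 0.0 < p_off < 0.5
    log1mp = np.log(1.0 - p_off) if use_skip else 0.0
    for step in range(n_steps):
        t = t0 + step + 1
        # --- unbinding draws (thinned: p_off bounds every LEF's rate) -----
        if p_off > 0.0:
            l = -1
            while True:
                if use_skip:
                    u = _rnd(rng)
                    if u <= 0.0:
                        u = _INV53
                    l += 1 + int(np.log(u) / log1mp)
                else:
                    l += 1
                if l >= N:
                    break
                f = 1.0
                if longlived[l]:
                    f *= llf
                fl = flags[left[l]] | flags[right[l]]
                if fl & F_BE:
                    f *= w
                if fl & F_END:
                    f *= r
                if not use_skip:
                    if _rnd(rng) >= p_off / f:
                        continue
                elif f > 1.0 and _rnd(rng) >= 1.0 / f:
                    continue
                # unbind LEF l
                _leave(left[l], l, pack, flags, end_idx, end_stack, end_stack_n, meta)
                _leave(right[l], l, pack, flags, end_idx, end_stack, end_stack_n, meta)
                stall_l[l] = 0
                stall_r[l] = 0
                left[l] = -1
                k = cons_map[l]
                if k >= 0:
                    m = cons_n[k]
                    for j in range(m):
                        if cons[k, j] == l:
                            cons[k, j] = cons[k, m - 1]
                            cons_n[k] = m - 1
                            break
                    cons_map[l] = -1
                    if cons_n[k] == 0 and dsb_state[k] == 0:
                        dsb_state[k] = 2
                        dsb_time[k] = t
                        meta[META_ACTIVE] -= 1
        # --- immediate reloading -----------------------------------------
        for l in range(N):
            if left[l] == -1:
                _load_one(l, F, G, left, right, pack, flags,
                          end_sites, end_idx, end_stack, end_stack_n, meta, rng)
        # --- motor moves, random order over mobile motors ----------------
        m_mob = 0
        for l in range(N):
            if not stall_l[l]:
                perm[m_mob] = l << 1
                m_mob += 1
            if not stall_r[l]:
                perm[m_mob] = (l << 1) | 1
                m_mob += 1
        for i in range(m_mob - 1, 0, -1):
            j = int(_rnd(rng) * (i + 1))
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp
        for i in range(m_mob):
            mid = perm[i]
            l = mid >> 1
            if mid & 1:
                s = right[l]
                fs = flags[s]
                if fs & F_BAR_R or s + 1 >= G:
                    continue
                tgt = s + 1
                ft = flags[tgt]
                if not (ft & F_END) and _count(pack[tgt]) > 0:
                    continue
                _leave(s, l, pack, flags, end_idx, end_stack, end_stack_n, meta)
                _enter(tgt, l, pack, flags, end_idx, end_stack, end_stack_n, meta)
                right[l] = tgt
                if ft & F_BLK_R and _rnd(rng) < b:
                    stall_r[l] = 1
            else:
                s = left[l]
                fs = flags[s]
                if fs & F_BAR_L or s - 1 < 0:
                    continue
                tgt = s - 1
                ft = flags[tgt]
                if not (ft & F_END) and _count(pack[tgt]) > 0:
                    continue
                _leave(s, l, pack, flags, end_idx, end_stack, end_stack_n, meta)
                _enter(tgt, l, pack, flags, end_idx, end_stack, end_stack_n, meta)
                left[l] = tgt
                if ft & F_BLK_L and _rnd(rng) < b:
                    stall_l[l] = 1
        # --- synapsis monitoring -----------------------------------------
        if monitor and n_dsb > 0:
            for k in range(n_dsb):
                if dsb_state[k] != 0:
                    continue
                e = dsb_left[k]
                m = cons_n[k]
                cl = np.int64(-1)
                cr = np.int64(G)
                for j in range(m):
                    lef = cons[k, j]
                    if left[lef] > cl:
                        cl = left[lef]
                    if right[lef] < cr:
                        cr = right[lef]
                gl = _gap_left(e, cl, left, right, pack, end_idx,
                               end_stack, end_stack_n)
                if gl <= 2:
                    gr = _gap_right(e + 1, cr, left, right, pack, end_idx,
                                    end_stack, end_stack_n)
                    if gr <= 2:
                        dsb_state[k] = 1
                        dsb_time[k] = t
                        meta[META_ACTIVE] -= 1
            if meta[META_ACTIVE] == 0:
                return step + 1
    return n_steps


@njit(cache=True)
def introduce_breaks(dsb_left, left, right, pack, flags,
                     end_sites, end_idx, end_stack, end_stack_n, meta,
                     cons, cons_n, cons_map, dsb_state, dsb_time,
                     initially_constrained):
    """Break every DSB site simultaneously and record constraining LEF sets.

    A LEF constrains a DSB iff its motors flank both end sites; post-break no
    LEF can newly span a break, so the sets only shrink via unbinding.
    """
    n_dsb = dsb_left.shape[0]
    N = left.shape[0]
    for k in range(n_dsb):
        e = dsb_left[k]
        for off in range(2):
            s = e + off
            ei = 2 * k + off
            end_sites[ei] = s
            end_idx[s] = ei
            if _count(pack[s]) == 0 and not (flags[s] & F_BE):
                meta[META_FREE] -= 1
            flags[s] |= F_END
        flags[e] |= F_BAR_R
        flags[e + 1] |= F_BAR_L
    for l in range(N):
        cons_map[l] = -1
        if left[l] >= 0 and flags[left[l]] & F_END:
            ei = end_idx[left[l]]
            if end_stack_n[ei] < end_stack.shape[1]:
                end_stack[ei, end_stack_n[ei]] = l
                end_stack_n[ei] += 1
        if right[l] >= 0 and flags[right[l]] & F_END and right[l] != left[l]:
            ei = end_idx[right[l]]
            if end_stack_n[ei] < end_stack.shape[1]:
                end_stack[ei, end_stack_n[ei]] = l
                end_stack_n[ei] += 1
    meta[META_ACTIVE] = 0
    for k in range(n_dsb):
        e = dsb_left[k]
        cnt = 0
        for l in range(N):
            if cons_map[l] == -1 and left[l] <= e and right[l] >= e + 1:
                if cnt < cons.shape[1]:
                    cons[k, cnt] = l
                    cnt += 1
                    cons_map[l] = k
        cons_n[k] = cnt
        if cnt == 0:
            dsb_state[k] = 2
            dsb_time[k] = 0
            initially_constrained[k] = 0
        else:
            dsb_state[k] = 0
            initially_constrained[k] = 1
            meta[META_ACTIVE] += 1
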