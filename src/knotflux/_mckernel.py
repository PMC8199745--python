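"""Jitted Metropolis driver for the closed wormlike chain.

One call runs a batch of crankshaft trials in place.  Per trial, a single
pass over the static edges serves two purposes: excluded-volume screening
(with a cheap distance-to-rotation-axis reject) and topology-check
triggering.  A rigid rotation of a sub-chain sweeps a region whose points
keep their distance to the rotation axis, so a static segment that stays
farther from the axis segment than the arc's maximal radial extent can
never be crossed; only when some static edge violates that bound is the
(comparatively costly) modular Alexander-determinant comparison run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._geometry import (ssd2, psd2, rotate_arc, writhe_edges_vs_rest,
                        alexander_fp2, seg_triangle_param)


@njit(cache=True)
def _one_minus_cos(verts, k):
    n = verts.shape[0]
    km = (k - 1) % n
    kp = (k + 1) % n
    ax = verts[k, 0] - verts[km, 0]
    ay = verts[k, 1] - verts[km, 1]
    az = verts[k, 2] - verts[km, 2]
    bx = verts[kp, 0] - verts[k, 0]
    by = verts[kp, 1] - verts[k, 1]
    bz = verts[kp, 2] - verts[k, 2]
    denom = np.sqrt((ax * ax + ay * ay + az * az)
                    * (bx * bx + by * by + bz * bz))
    if denom <= 1e-300:
        return 0.0
    return 1.0 - (ax * bx + ay * by + az * bz) / denom


@njit(cache=True)
def gate_scan(verts, h0, overlap_d2):
    """Juxtaposition test for a hairpin whose five vertices start at h0.

    Returns (edge, sign): the unique non-hairpin, non-adjacent edge that
    pierces the interior of the gate triangle (hairpin vertices h0, h0+2,
    h0+4) without coming within sqrt(overlap_d2) of any hairpin edge;
    (-1, 0) when there is none or more than one.
    """
    n = verts.shape[0]
    i0 = h0 % n
    i2 = (h0 + 2) % n
    i4 = (h0 + 4) % n
    found = -1
    for e in range(n):
        de = (e - i0) % n
        if de <= 4 or de == n - 1:  # hairpin edges + adjacent edges
            continue
        t = seg_triangle_param(verts[e], verts[(e + 1) % n],
                               verts[i0], verts[i2], verts[i4])
        if t >= 0.0:
            if found >= 0:
                return -1, 0
            found = e
    if found < 0:
        return -1, 0
    if overlap_d2 > 0.0:
        e1 = (found + 1) % n
        for k in range(4):
            h = (i0 + k) % n
            h1 = (h + 1) % n
            if ssd2(verts[found, 0], verts[found, 1], verts[found, 2],
                    verts[e1, 0], verts[e1, 1], verts[e1, 2],
                    verts[h, 0], verts[h, 1], verts[h, 2],
                    verts[h1, 0], verts[h1, 1], verts[h1, 2]) < overlap_d2:
                return -1, 0
    # sign: direction of the T edge along the gate normal (right-hand rule
    # around the hairpin traversal i0 -> i2 -> i4)
    ux = verts[i2, 0] - verts[i0, 0]
    uy = verts[i2, 1] - verts[i0, 1]
    uz = verts[i2, 2] - verts[i0, 2]
    vx = verts[i4, 0] - verts[i0, 0]
    vy = verts[i4, 1] - verts[i0, 1]
    vz = verts[i4, 2] - verts[i0, 2]
    nx = uy * vz - uz * vy
    ny = uz * vx - ux * vz
    nz = ux * vy - uy * vx
    e1 = (found + 1) % n
    tx = verts[e1, 0] - verts[found, 0]
    ty = verts[e1, 1] - verts[found, 1]
    tz = verts[e1, 2] - verts[found, 2]
    s = nx * tx + ny * ty + nz * tz
    return found, (1 if s > 0.0 else -1)


@njit(cache=True)
def mc_run_scan(verts, n_trials, g, max_angle, max_arc, d2, use_ev, frozen,
                use_twist, dlk, twist_coef, wr0, check_knot, target_det,
                target_d2odd, prime, prime2, seed, scan_every, gate_h0,
                overlap_d2, ev_verts,
                ev_edge, ev_sign, counters):
    """mc_run plus periodic juxtaposition scanning.

    Every scan_every trials the current conformation is tested with
    gate_scan; events are counted in counters (counters[0] += scans,
    counters[1] += events) and, while the buffer lasts, the conformation,
    T-edge index, and crossing sign are stored in ev_verts/ev_edge/ev_sign
    starting at counters[2].
    """
    done = 0
    n_acc = 0
    n_checks = 0
    n_krej = 0
    wr = wr0
    sub_seed = seed
    while done < n_trials:
        batch = min(scan_every, n_trials - done)
        sub_seed = (sub_seed * 1103515245 + 12345) % 2147483647
        na, wr, nc, nk = mc_run(verts, batch, g, max_angle, max_arc, d2,
                                use_ev, frozen, use_twist, dlk, twist_coef,
                                wr, check_knot, target_det, target_d2odd,
                                prime, prime2, sub_seed)
        n_acc += na
        n_checks += nc
        n_krej += nk
        done += batch
        counters[0] += 1
        e, s = gate_scan(verts, gate_h0, overlap_d2)
        if e >= 0:
            counters[1] += 1
            slot = counters[2]
            if slot < ev_verts.shape[0]:
                for k in range(verts.shape[0]):
                    ev_verts[slot, k, 0] = verts[k, 0]
                    ev_verts[slot, k, 1] = verts[k, 1]
                    ev_verts[slot, k, 2] = verts[k, 2]
                ev_edge[slot] = e
                ev_sign[slot] = s
                counters[2] += 1
    return n_acc, wr, n_checks, n_krej


@njit(cache=True)
def mc_run(verts, n_trials, g, max_angle, max_arc, d2, use_ev, frozen,
           use_twist, dlk, twist_coef, wr0, check_knot, target_det,
           target_d2odd, prime, prime2, seed):
    """Run n_trials crankshaft trials on verts (modified in place).

    Returns (n_accept, wr, n_knot_checks, n_knot_rejects).  wr tracks the
    writhe incrementally and is only meaningful when use_twist is True.
    """
    np.random.seed(seed)
    n = verts.shape[0]
    trial = np.empty_like(verts)
    elist = np.empty(n, np.int64)
    n_acc = 0
    n_checks = 0
    n_krej = 0
    wr = wr0
    d = np.sqrt(d2)
    for _ in range(n_trials):
        # pick pivots i, j = i + arc with no frozen vertex strictly between
        ok = False
        i = 0
        arc = 2
        for _try in range(200):
            i = np.random.randint(0, n)
            arc = 2 + np.random.randint(0, max_arc - 1)
            ok = True
            k = (i + 1) % n
            j = (i + arc) % n
            while k != j:
                if frozen[k]:
                    ok = False
                    break
                k = (k + 1) % n
            if ok:
                break
        if not ok:
            continue
        j = (i + arc) % n
        angle = (2.0 * np.random.random() - 1.0) * max_angle
        rotate_arc(verts, i, j, angle, trial)
        for k in range(arc):
            elist[k] = (i + k) % n

        # maximal radial extent of the moved arc from the rotation axis
        axx = verts[i, 0]
        axy = verts[i, 1]
        axz = verts[i, 2]
        bxx = verts[j, 0]
        bxy = verts[j, 1]
        bxz = verts[j, 2]
        r2max = 0.0
        k = (i + 1) % n
        while k != j:
            r2 = psd2(verts[k, 0], verts[k, 1], verts[k, 2],
                      axx, axy, axz, bxx, bxy, bxz)
            if r2 > r2max:
                r2max = r2
            k = (k + 1) % n
        rmax = np.sqrt(r2max)
        prune2 = rmax * rmax  # static edge within this of the axis -> check
        reach = rmax + d      # plus d for excluded volume
        reach2 = reach * reach

        # one pass over static edges: EV + knot-check trigger
        ev_fail = False
        needs_check = False
        f = j
        while f != i:
            f1 = (f + 1) % n
            # static edge (f, f1): distance to the rotation axis segment
            da2 = ssd2(verts[f, 0], verts[f, 1], verts[f, 2],
                       verts[f1, 0], verts[f1, 1], verts[f1, 2],
                       axx, axy, axz, bxx, bxy, bxz)
            if da2 < prune2:
                needs_check = True
            if use_ev and da2 < reach2:
                # detailed pair check against all moved edges
                for kk in range(arc):
                    e = elist[kk]
                    e1 = (e + 1) % n
                    if f == e1 or f1 == e:
                        continue
                    if ssd2(trial[e, 0], trial[e, 1], trial[e, 2],
                            trial[e1, 0], trial[e1, 1], trial[e1, 2],
                            trial[f, 0], trial[f, 1], trial[f, 2],
                            trial[f1, 0], trial[f1, 1], trial[f1, 2]) < d2:
                        ev_fail = True
                        break
                if ev_fail:
                    break
            f = f1
        if ev_fail:
            continue

        dE = g * (_one_minus_cos(trial, i) + _one_minus_cos(trial, j)
                  - _one_minus_cos(verts, i) - _one_minus_cos(verts, j))
        dwr = 0.0
        if use_twist:
            el = elist[:arc]
            dwr = (writhe_edges_vs_rest(trial, el)
                   - writhe_edges_vs_rest(verts, el))
            tw_old = dlk - wr
            tw_new = dlk - (wr + dwr)
            dE += twist_coef * (tw_new * tw_new - tw_old * tw_old)
        if dE > 0.0 and np.random.random() > np.exp(-dE):
            continue
        if check_knot and needs_check:
            n_checks += 1
            sub_seed = np.random.randint(0, 2 ** 30)
            dres, d2res = alexander_fp2(trial, prime, prime2, sub_seed,
                                        target_d2odd > 0)
            if dres != target_det or \
                    (target_d2odd > 0 and d2res != target_d2odd):
                n_krej += 1
                continue
        for k in range(n):
            verts[k, 0] = trial[k, 0]
            verts[k, 1] = trial[k, 1]
            verts[k, 2] = trial[k, 2]
        wr += dwr
        n_acc += 1
    return n_acc, wr, n_checks, n_krej
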