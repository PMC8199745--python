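"""Numba kernels for polygon geometry: segment distances, excluded volume,
crankshaft rotations, the exact Gauss-integral writhe, triangle piercing
tests, and the Koniaris–Muthukumar chain reduction.

All kernels operate on (N, 3) float64 vertex arrays describing closed
polygons; edge e connects vertex e to vertex (e+1) % N.  Inner loops are
written scalar-wise (no temporary arrays) because they run millions of
times per Monte Carlo batch.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True)
def _cross(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True, fastmath=True)
def ssd2(p1x, p1y, p1z, q1x, q1y, q1z, p2x, p2y, p2z, q2x, q2y, q2z):
    """Squared minimum distance between segments [p1,q1] and [p2,q2]
    (scalar core, Ericson's clamped closest-point algorithm)."""
    d1x = q1x - p1x
    d1y = q1y - p1y
    d1z = q1z - p1z
    d2x = q2x - p2x
    d2y = q2y - p2y
    d2z = q2z - p2z
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    if a <= _EPS and e <= _EPS:
        return rx * rx + ry * ry + rz * rz
    if a <= _EPS:
        s = 0.0
        t = f / e
        t = min(max(t, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= _EPS:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            if denom > _EPS:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            tn = b * s + f
            if tn < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif tn > e:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
            else:
                t = tn / e
    cx = p1x + s * d1x - p2x - t * d2x
    cy = p1y + s * d1y - p2y - t * d2y
    cz = p1z + s * d1z - p2z - t * d2z
    return cx * cx + cy * cy + cz * cz


@njit(cache=True)
def seg_seg_dist2(p1, q1, p2, q2):
    """Squared minimum distance between segments (array interface)."""
    return ssd2(p1[0], p1[1], p1[2], q1[0], q1[1], q1[2],
                p2[0], p2[1], p2[2], q2[0], q2[1], q2[2])


@njit(cache=True, fastmath=True)
def psd2(px, py, pz, ax, ay, az, bx, by, bz):
    """Squared distance from point p to segment [a, b] (scalar core)."""
    dx = bx - ax
    dy = by - ay
    dz = bz - az
    dd = dx * dx + dy * dy + dz * dz
    if dd <= _EPS:
        ex = px - ax
        ey = py - ay
        ez = pz - az
        return ex * ex + ey * ey + ez * ez
    t = ((px - ax) * dx + (py - ay) * dy + (pz - az) * dz) / dd
    t = min(max(t, 0.0), 1.0)
    ex = px - ax - t * dx
    ey = py - ay - t * dy
    ez = pz - az - t * dz
    return ex * ex + ey * ey + ez * ez


@njit(cache=True)
def point_seg_dist2(p, a, b):
    return psd2(p[0], p[1], p[2], a[0], a[1], a[2], b[0], b[1], b[2])


@njit(cache=True)
def min_gap2_all(verts):
    """Minimum squared distance over all non-adjacent edge pairs."""
    n = verts.shape[0]
    best = 1e300
    for i in range(n):
        i1 = (i + 1) % n
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            j1 = (j + 1) % n
            g = ssd2(verts[i, 0], verts[i, 1], verts[i, 2],
                     verts[i1, 0], verts[i1, 1], verts[i1, 2],
                     verts[j, 0], verts[j, 1], verts[j, 2],
                     verts[j1, 0], verts[j1, 1], verts[j1, 2])
            if g < best:
                best = g
    return best


@njit(cache=True)
def ev_ok_edges(verts, elist, d2):
    """Excluded-volume check of the edges in `elist` against all edges not
    in the list (adjacent pairs exempt).  Pairs within elist are skipped:
    the caller guarantees those edges move rigidly together."""
    n = verts.shape[0]
    m = elist.shape[0]
    inlist = np.zeros(n, np.bool_)
    for k in range(m):
        inlist[elist[k]] = True
    for k in range(m):
        e = elist[k]
        e1 = (e + 1) % n
        for f in range(n):
            if inlist[f]:
                continue
            f1 = (f + 1) % n
            if f == e1 or f1 == e or f == e:
                continue
            if ssd2(verts[e, 0], verts[e, 1], verts[e, 2],
                    verts[e1, 0], verts[e1, 1], verts[e1, 2],
                    verts[f, 0], verts[f, 1], verts[f, 2],
                    verts[f1, 0], verts[f1, 1], verts[f1, 2]) < d2:
                return False
    return True


@njit(cache=True, fastmath=True)
def rotate_arc(verts, i, j, angle, out):
    """Copy verts into out with vertices strictly between pivots i and j
    (walking forward cyclically from i) rotated by `angle` about the axis
    from vertex i to vertex j (Rodrigues formula, scalar core)."""
    n = verts.shape[0]
    for k in range(n):
        out[k, 0] = verts[k, 0]
        out[k, 1] = verts[k, 1]
        out[k, 2] = verts[k, 2]
    ux = verts[j, 0] - verts[i, 0]
    uy = verts[j, 1] - verts[i, 1]
    uz = verts[j, 2] - verts[i, 2]
    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
    if norm <= _EPS:
        return
    ux /= norm
    uy /= norm
    uz /= norm
    c = np.cos(angle)
    s = np.sin(angle)
    k = (i + 1) % n
    while k != j:
        vx = verts[k, 0] - verts[i, 0]
        vy = verts[k, 1] - verts[i, 1]
        vz = verts[k, 2] - verts[i, 2]
        cx = uy * vz - uz * vy
        cy = uz * vx - ux * vz
        cz = ux * vy - uy * vx
        du = ux * vx + uy * vy + uz * vz
        f = du * (1.0 - c)
        out[k, 0] = verts[i, 0] + vx * c + cx * s + ux * f
        out[k, 1] = verts[i, 1] + vy * c + cy * s + uy * f
        out[k, 2] = verts[i, 2] + vz * c + cz * s + uz * f
        k = (k + 1) % n
    return


@njit(cache=True, fastmath=True)
def gauss_pair_idx(V, i, i1, W, j, j1):
    """Gauss-integral writhe contribution of directed edges (V[i]->V[i1])
    and (W[j]->W[j1]): signed solid angle / 4 pi (scalar core)."""
    r13x = W[j, 0] - V[i, 0]
    r13y = W[j, 1] - V[i, 1]
    r13z = W[j, 2] - V[i, 2]
    r14x = W[j1, 0] - V[i, 0]
    r14y = W[j1, 1] - V[i, 1]
    r14z = W[j1, 2] - V[i, 2]
    r23x = W[j, 0] - V[i1, 0]
    r23y = W[j, 1] - V[i1, 1]
    r23z = W[j, 2] - V[i1, 2]
    r24x = W[j1, 0] - V[i1, 0]
    r24y = W[j1, 1] - V[i1, 1]
    r24z = W[j1, 2] - V[i1, 2]
    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x
    l1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    l2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    l3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    l4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if l1 <= _EPS or l2 <= _EPS or l3 <= _EPS or l4 <= _EPS:
        return 0.0
    a1 = (n1x * n2x + n1y * n2y + n1z * n2z) / (l1 * l2)
    a2 = (n2x * n3x + n2y * n3y + n2z * n3z) / (l2 * l3)
    a3 = (n3x * n4x + n3y * n4y + n3z * n4z) / (l3 * l4)
    a4 = (n4x * n1x + n4y * n1y + n4z * n1z) / (l4 * l1)
    a1 = min(max(a1, -1.0), 1.0)
    a2 = min(max(a2, -1.0), 1.0)
    a3 = min(max(a3, -1.0), 1.0)
    a4 = min(max(a4, -1.0), 1.0)
    omega = (np.arcsin(a1) + np.arcsin(a2) + np.arcsin(a3) + np.arcsin(a4))
    # sign of (r34 x r12) . r13
    r34x = W[j1, 0] - W[j, 0]
    r34y = W[j1, 1] - W[j, 1]
    r34z = W[j1, 2] - W[j, 2]
    r12x = V[i1, 0] - V[i, 0]
    r12y = V[i1, 1] - V[i, 1]
    r12z = V[i1, 2] - V[i, 2]
    sx = r34y * r12z - r34z * r12y
    sy = r34z * r12x - r34x * r12z
    sz = r34x * r12y - r34y * r12x
    sgn = sx * r13x + sy * r13y + sz * r13z
    if sgn > 0.0:
        return omega / (4.0 * np.pi)
    elif sgn < 0.0:
        return -omega / (4.0 * np.pi)
    return 0.0


@njit(cache=True)
def gauss_pair(p1, p2, p3, p4):
    V = np.empty((2, 3))
    W = np.empty((2, 3))
    for d in range(3):
        V[0, d] = p1[d]
        V[1, d] = p2[d]
        W[0, d] = p3[d]
        W[1, d] = p4[d]
    return gauss_pair_idx(V, 0, 1, W, 0, 1)


@njit(cache=True)
def writhe_exact(verts):
    """Writhe of the closed polygon: Gauss double integral via the exact
    per-pair solid-angle expression, summed over non-adjacent pairs."""
    n = verts.shape[0]
    w = 0.0
    for i in range(n):
        i1 = (i + 1) % n
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            w += 2.0 * gauss_pair_idx(verts, i, i1, verts, j, (j + 1) % n)
    return w


@njit(cache=True)
def writhe_edges_vs_rest(verts, elist):
    """Sum of Gauss terms between edges in elist and all other edges (each
    unordered pair counted twice, as in the double integral).  Used for
    incremental writhe updates under rigid sub-chain rotations."""
    n = verts.shape[0]
    m = elist.shape[0]
    inlist = np.zeros(n, np.bool_)
    for k in range(m):
        inlist[elist[k]] = True
    w = 0.0
    for k in range(m):
        e = elist[k]
        e1 = (e + 1) % n
        for f in range(n):
            if inlist[f]:
                continue
            f1 = (f + 1) % n
            if f == e1 or f1 == e:
                continue
            w += 2.0 * gauss_pair_idx(verts, e, e1, verts, f, f1)
    return w


# ---------------------------------------------------------------------------
# triangle tests and KM reduction
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seg2d_cross(p1x, p1y, p2x, p2y, q1x, q1y, q2x, q2y):
    """Do 2-D segments [p1,p2] and [q1,q2] intersect (inclusive)?"""
    d1x = p2x - p1x
    d1y = p2y - p1y
    d2x = q2x - q1x
    d2y = q2y - q1y
    den = d1x * d2y - d1y * d2x
    rx = q1x - p1x
    ry = q1y - p1y
    if np.abs(den) <= 1e-15:
        if np.abs(rx * d1y - ry * d1x) > 1e-12:
            return False
        l2 = d1x * d1x + d1y * d1y
        if l2 <= 1e-30:
            return False
        t0 = (rx * d1x + ry * d1y) / l2
        t1 = t0 + (d2x * d1x + d2y * d1y) / l2
        lo = min(t0, t1)
        hi = max(t0, t1)
        return hi >= -1e-9 and lo <= 1.0 + 1e-9
    s = (rx * d2y - ry * d2x) / den
    t = (rx * d1y - ry * d1x) / den
    return -1e-9 <= s <= 1.0 + 1e-9 and -1e-9 <= t <= 1.0 + 1e-9


@njit(cache=True)
def _coplanar_seg_tri_hit(p, q, a, b, c, n):
    """2-D overlap of segment and triangle after projecting out the
    triangle normal n (conservative near-coplanar fallback)."""
    nn = np.sqrt(_dot(n, n))
    if nn <= _EPS:
        return True
    ez = n / nn
    ref = np.zeros(3)
    if np.abs(ez[0]) < 0.9:
        ref[0] = 1.0
    else:
        ref[1] = 1.0
    ex = _cross(ref, ez)
    ex = ex / np.sqrt(_dot(ex, ex))
    ey = _cross(ez, ex)
    px = _dot(p, ex)
    py = _dot(p, ey)
    qx = _dot(q, ex)
    qy = _dot(q, ey)
    tx = np.empty(3)
    ty = np.empty(3)
    tx[0] = _dot(a, ex)
    ty[0] = _dot(a, ey)
    tx[1] = _dot(b, ex)
    ty[1] = _dot(b, ey)
    tx[2] = _dot(c, ex)
    ty[2] = _dot(c, ey)
    for k in range(3):
        k1 = (k + 1) % 3
        if _seg2d_cross(px, py, qx, qy, tx[k], ty[k], tx[k1], ty[k1]):
            return True
    mx = 0.5 * (px + qx)
    my = 0.5 * (py + qy)
    neg = False
    pos = False
    for k in range(3):
        k1 = (k + 1) % 3
        cr = (tx[k1] - tx[k]) * (my - ty[k]) - (ty[k1] - ty[k]) * (mx - tx[k])
        if cr > 0:
            pos = True
        elif cr < 0:
            neg = True
    return not (neg and pos)


@njit(cache=True, fastmath=True)
def seg_tri_hit_idx(V, s, t, T, ia, ib, ic, conservative):
    """Does segment V[s]->V[t] intersect triangle (T[ia], T[ib], T[ic])?

    conservative=True counts grazes/coplanar contacts as hits (used by the
    KM reduction, where a false positive only delays a deletion);
    conservative=False demands a transversal interior piercing.
    """
    ax = T[ia, 0]
    ay = T[ia, 1]
    az = T[ia, 2]
    abx = T[ib, 0] - ax
    aby = T[ib, 1] - ay
    abz = T[ib, 2] - az
    acx = T[ic, 0] - ax
    acy = T[ic, 1] - ay
    acz = T[ic, 2] - az
    nx = aby * acz - abz * acy
    ny = abz * acx - abx * acz
    nz = abx * acy - aby * acx
    px = V[s, 0]
    py = V[s, 1]
    pz = V[s, 2]
    dx = V[t, 0] - px
    dy = V[t, 1] - py
    dz = V[t, 2] - pz
    denom = nx * dx + ny * dy + nz * dz
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    dd = np.sqrt(dx * dx + dy * dy + dz * dz)
    eps = 1e-9 if conservative else 1e-12
    if np.abs(denom) <= eps * nn * (dd + _EPS):
        if not conservative:
            return False
        if nn <= _EPS:
            return True
        dp = (nx * (px - ax) + ny * (py - ay) + nz * (pz - az)) / nn
        dq = (nx * (V[t, 0] - ax) + ny * (V[t, 1] - ay)
              + nz * (V[t, 2] - az)) / nn
        scale = max(np.sqrt(abx * abx + aby * aby + abz * abz),
                    np.sqrt(acx * acx + acy * acy + acz * acz))
        if min(np.abs(dp), np.abs(dq)) > 1e-7 * (scale + 1.0) and dp * dq > 0.0:
            return False
        pvec = np.empty(3)
        qvec = np.empty(3)
        av = np.empty(3)
        bv = np.empty(3)
        cv = np.empty(3)
        nv = np.empty(3)
        for d in range(3):
            pvec[d] = V[s, d]
            qvec[d] = V[t, d]
            av[d] = T[ia, d]
            bv[d] = T[ib, d]
            cv[d] = T[ic, d]
        nv[0] = nx
        nv[1] = ny
        nv[2] = nz
        return _coplanar_seg_tri_hit(pvec, qvec, av, bv, cv, nv)
    tt = (nx * (ax - px) + ny * (ay - py) + nz * (az - pz)) / denom
    tol = 1e-9 if conservative else -1e-12
    if tt < -tol or tt > 1.0 + tol:
        return False
    xx = px + tt * dx - ax
    xy = py + tt * dy - ay
    xz = pz + tt * dz - az
    d00 = abx * abx + aby * aby + abz * abz
    d01 = abx * acx + aby * acy + abz * acz
    d11 = acx * acx + acy * acy + acz * acz
    d20 = xx * abx + xy * aby + xz * abz
    d21 = xx * acx + xy * acy + xz * acz
    den = d00 * d11 - d01 * d01
    if np.abs(den) <= _EPS:
        return conservative
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    u = 1.0 - v - w
    if conservative:
        margin = 1e-9
        return (u >= -margin) and (v >= -margin) and (w >= -margin)
    margin = 1e-10
    return (u > margin) and (v > margin) and (w > margin)


@njit(cache=True)
def seg_triangle_hit(p, q, a, b, c, conservative):
    V = np.empty((2, 3))
    T = np.empty((3, 3))
    for d in range(3):
        V[0, d] = p[d]
        V[1, d] = q[d]
        T[0, d] = a[d]
        T[1, d] = b[d]
        T[2, d] = c[d]
    return seg_tri_hit_idx(V, 0, 1, T, 0, 1, 2, conservative)


@njit(cache=True)
def seg_triangle_param(p, q, a, b, c):
    """Parameter t along [p,q] of a strict interior piercing of triangle
    (a,b,c), or -1.0 if none."""
    ab = b - a
    ac = c - a
    n = _cross(ab, ac)
    d = q - p
    denom = _dot(n, d)
    if np.abs(denom) <= _EPS:
        return -1.0
    t = _dot(n, a - p) / denom
    if t <= 1e-10 or t >= 1.0 - 1e-10:
        return -1.0
    x = p + t * d
    v0 = x - a
    d00 = _dot(ab, ab)
    d01 = _dot(ab, ac)
    d11 = _dot(ac, ac)
    d20 = _dot(v0, ab)
    d21 = _dot(v0, ac)
    den = d00 * d11 - d01 * d01
    if np.abs(den) <= _EPS:
        return -1.0
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    u = 1.0 - v - w
    if u > 1e-9 and v > 1e-9 and w > 1e-9:
        return t
    return -1.0


@njit(cache=True)
def km_reduce_verts(verts):
    """Koniaris–Muthukumar reduction: repeatedly delete vertex v whenever
    the triangle (prev, v, next) is pierced by no other chain edge.  The
    output polygon is ambient-isotopic to the input."""
    n = verts.shape[0]
    nxt = np.empty(n, np.int64)
    prv = np.empty(n, np.int64)
    for k in range(n):
        nxt[k] = (k + 1) % n
        prv[k] = (k - 1) % n
    alive = np.ones(n, np.bool_)
    m = n
    changed = True
    while changed and m > 3:
        changed = False
        v = 0
        while not alive[v]:
            v += 1
        start = v
        while True:
            if m <= 3:
                break
            p = prv[v]
            q = nxt[v]
            blocked = False
            # centroid prescreen: an edge farther from the triangle centroid
            # than the triangle's reach plus half its own length cannot hit
            cx = (verts[p, 0] + verts[v, 0] + verts[q, 0]) / 3.0
            cy = (verts[p, 1] + verts[v, 1] + verts[q, 1]) / 3.0
            cz = (verts[p, 2] + verts[v, 2] + verts[q, 2]) / 3.0
            reach = 0.0
            for w in (p, v, q):
                dx = verts[w, 0] - cx
                dy = verts[w, 1] - cy
                dz = verts[w, 2] - cz
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > reach:
                    reach = r2
            reach = np.sqrt(reach)
            s = q
            while True:
                t = nxt[s]
                if t == p:
                    break
                if s != q and s != p and s != v and t != p and t != q and t != v:
                    dx = verts[s, 0] - cx
                    dy = verts[s, 1] - cy
                    dz = verts[s, 2] - cz
                    ex = verts[t, 0] - cx
                    ey = verts[t, 1] - cy
                    ez = verts[t, 2] - cz
                    d2a = dx * dx + dy * dy + dz * dz
                    d2b = ex * ex + ey * ey + ez * ez
                    gx = verts[t, 0] - verts[s, 0]
                    gy = verts[t, 1] - verts[s, 1]
                    gz = verts[t, 2] - verts[s, 2]
                    lim = reach + np.sqrt(gx * gx + gy * gy + gz * gz)
                    if min(d2a, d2b) > lim * lim:
                        s = t
                        continue
                    if seg_tri_hit_idx(verts, s, t, verts, p, v, q, True):
                        blocked = True
                        break
                s = t
            if not blocked:
                alive[v] = False
                nxt[p] = q
                prv[q] = p
                m -= 1
                changed = True
                if v == start:
                    start = p
                v = q
            else:
                v = nxt[v]
            if v == start:
                break
    out = np.empty((m, 3))
    v = 0
    while not alive[v]:
        v += 1
    for k in range(m):
        out[k, 0] = verts[v, 0]
        out[k, 1] = verts[v, 1]
        out[k, 2] = verts[v, 2]
        v = nxt[v]
    return out


# ---------------------------------------------------------------------------
# projections, crossings, modular Alexander determinant
# ---------------------------------------------------------------------------

@njit(cache=True)
def project_crossings(verts, ex, ey, ez, max_crossings):
    """All crossings of the polygon projected on the (ex, ey) plane viewed
    along +ez.

    Returns (status, rec, nc): status 0 on success, 1 for a degenerate
    projection, 2 if max_crossings is exceeded.  rec rows are
    (edge_a, edge_b, param_a, param_b, depth_a, depth_b, sign).
    """
    n = verts.shape[0]
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    for k in range(n):
        x[k] = verts[k, 0] * ex[0] + verts[k, 1] * ex[1] + verts[k, 2] * ex[2]
        y[k] = verts[k, 0] * ey[0] + verts[k, 1] * ey[1] + verts[k, 2] * ey[2]
        z[k] = verts[k, 0] * ez[0] + verts[k, 1] * ez[1] + verts[k, 2] * ez[2]
    rec = np.empty((max_crossings, 7))
    nc = 0
    for i in range(n):
        i1 = (i + 1) % n
        axi = x[i1] - x[i]
        ayi = y[i1] - y[i]
        li = np.sqrt(axi * axi + ayi * ayi)
        if li <= 1e-12:
            return 1, rec, 0
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            j1 = (j + 1) % n
            bxj = x[j1] - x[j]
            byj = y[j1] - y[j]
            lj = np.sqrt(bxj * bxj + byj * byj)
            if lj <= 1e-12:
                return 1, rec, 0
            den = axi * byj - ayi * bxj
            if np.abs(den) <= 1e-9 * li * lj:
                continue
            rx = x[j] - x[i]
            ry = y[j] - y[i]
            s = (rx * byj - ry * bxj) / den
            t = (ayi * rx - axi * ry) / den
            if s < 0.0 or s > 1.0 or t < 0.0 or t > 1.0:
                continue
            if s < 1e-9 or s > 1.0 - 1e-9 or t < 1e-9 or t > 1.0 - 1e-9:
                return 1, rec, 0
            za = z[i] + s * (z[i1] - z[i])
            zb = z[j] + t * (z[j1] - z[j])
            if np.abs(za - zb) <= 1e-9:
                return 1, rec, 0
            if nc >= max_crossings:
                return 2, rec, nc
            if za > zb:
                cr = axi * byj - ayi * bxj
            else:
                cr = bxj * ayi - byj * axi
            rec[nc, 0] = i
            rec[nc, 1] = j
            rec[nc, 2] = s
            rec[nc, 3] = t
            rec[nc, 4] = za
            rec[nc, 5] = zb
            rec[nc, 6] = 1.0 if cr > 0.0 else -1.0
            nc += 1
    return 0, rec, nc


@njit(cache=True)
def _modpow(a, e, p):
    r = 1
    a = a % p
    while e > 0:
        if e & 1:
            r = (r * a) % p
        a = (a * a) % p
        e >>= 1
    return r


@njit(cache=True)
def det_mod_p(mat, p):
    """Determinant of an integer matrix mod prime p."""
    n = mat.shape[0]
    if n == 0:
        return 1
    a = mat % p
    det = 1
    for col in range(n):
        piv = -1
        for r in range(col, n):
            if a[r, col] % p != 0:
                piv = r
                break
        if piv < 0:
            return 0
        if piv != col:
            for c in range(col, n):
                tmp = a[col, c]
                a[col, c] = a[piv, c]
                a[piv, c] = tmp
            det = (p - det) % p
        det = (det * a[col, col]) % p
        inv = _modpow(a[col, col], p - 2, p)
        for r in range(col + 1, n):
            if a[r, col] != 0:
                f = (a[r, col] * inv) % p
                for c in range(col, n):
                    a[r, c] = (a[r, c] - f * a[col, c]) % p
    return det % p


@njit(cache=True)
def alexander_matrix_mod(rec, nc, t, p):
    """Alexander matrix (mod p) at integer argument t from crossing records;
    rows are crossings, columns underpass-generator arcs."""
    keys = np.empty(2 * nc)
    cids = np.empty(2 * nc, np.int64)
    overs = np.zeros(2 * nc, np.bool_)
    for k in range(nc):
        a_over = rec[k, 4] > rec[k, 5]
        keys[2 * k] = rec[k, 0] + rec[k, 2]
        cids[2 * k] = k
        overs[2 * k] = a_over
        keys[2 * k + 1] = rec[k, 1] + rec[k, 3]
        cids[2 * k + 1] = k
        overs[2 * k + 1] = not a_over
    order = np.argsort(keys)
    arc_at = np.empty(2 * nc, np.int64)
    prov = 0
    for idx in range(2 * nc):
        pos = order[idx]
        arc_at[pos] = prov
        if not overs[pos]:
            prov += 1
    over_arc = np.empty(nc, np.int64)
    under_arc = np.empty(nc, np.int64)
    for pos in range(2 * nc):
        a = arc_at[pos] % nc
        k = cids[pos]
        if overs[pos]:
            over_arc[k] = a
        else:
            under_arc[k] = a
    mat = np.zeros((nc, nc), np.int64)
    tm = t % p
    for k in range(nc):
        j = under_arc[k]
        jp1 = (j + 1) % nc
        i = over_arc[k]
        if i == j or i == jp1:
            mat[k, j] = (mat[k, j] + p - 1) % p
            mat[k, jp1] = (mat[k, jp1] + 1) % p
        elif rec[k, 6] > 0.0:
            mat[k, j] = (mat[k, j] + 1) % p
            mat[k, jp1] = (mat[k, jp1] + p - tm) % p
            mat[k, i] = (mat[k, i] + tm - 1 + p) % p
        else:
            mat[k, j] = (mat[k, j] + p - tm) % p
            mat[k, jp1] = (mat[k, jp1] + 1) % p
            mat[k, i] = (mat[k, i] + tm - 1 + p) % p
    return mat


@njit(cache=True)
def alexander_fp2(verts, p1, p2, seed, need_d2):
    """(|Delta(-1)| mod p1 in min-form, odd part of |Delta(-2)|) of a
    closed polygon from a random regular projection of its KM reduction.

    The minor determinant at t = -2 equals +/- 2^k Delta(-2); its absolute
    value is reconstructed exactly from residues mod two 31-bit primes
    (it fits well below p1*p2/2 for diagrams up to ~50 crossings), and the
    odd part strips the projection-dependent unit.  Returns (-1, -1) when
    no regular projection is found or the diagram is too large for the
    reconstruction to be trusted.  With need_d2 false the second value is
    0 and only one determinant is computed.
    """
    red = km_reduce_verts(verts)
    m = red.shape[0]
    if m == 3:
        return 1, 1 if need_d2 else 0
    np.random.seed(seed)
    maxc = m * m
    for _attempt in range(8):
        v = np.random.standard_normal(3)
        nv = np.sqrt(_dot(v, v))
        if nv <= _EPS:
            continue
        ez = v / nv
        ref = np.zeros(3)
        if np.abs(ez[0]) < 0.9:
            ref[0] = 1.0
        else:
            ref[1] = 1.0
        ex = _cross(ref, ez)
        ex = ex / np.sqrt(_dot(ex, ex))
        ey = _cross(ez, ex)
        status, rec, nc = project_crossings(red, ex, ey, ez, maxc)
        if status != 0:
            continue
        if nc == 0:
            return 1, 1 if need_d2 else 0
        mat1 = alexander_matrix_mod(rec, nc, p1 - 1, p1)  # t = -1 mod p1
        d1 = det_mod_p(mat1[: nc - 1, : nc - 1].copy(), p1)
        if d1 > p1 - d1:
            d1 = p1 - d1
        if not need_d2:
            return d1, 0
        if nc > 50:
            return -1, -1  # 2^k could overflow the CRT range
        m1 = alexander_matrix_mod(rec, nc, p1 - 2, p1)  # t = -2 mod p1
        m2 = alexander_matrix_mod(rec, nc, p2 - 2, p2)
        r1 = det_mod_p(m1[: nc - 1, : nc - 1].copy(), p1)
        r2 = det_mod_p(m2[: nc - 1, : nc - 1].copy(), p2)
        # CRT: D = r1 + p1 * ((r2 - r1) / p1 mod p2), symmetric range
        inv = _modpow(p1 % p2, p2 - 2, p2)
        t = ((r2 - r1) % p2) * inv % p2
        big = r1 + p1 * t
        m12 = p1 * p2
        if big > m12 // 2:
            big = m12 - big
        if big < 0:
            big = -big
        while big > 0 and big % 2 == 0:
            big //= 2
        return d1, big
    return -1, -1


@njit(cache=True)
def alexander_det1_modp(verts, p, seed):
    """|Alexander determinant| mod p of a closed polygon from a random
    regular projection of its KM reduction; -1 if no regular projection is
    found (vanishingly rare)."""
    red = km_reduce_verts(verts)
    m = red.shape[0]
    if m == 3:
        return 1
    np.random.seed(seed)
    maxc = m * m
    for _attempt in range(8):
        v = np.random.standard_normal(3)
        nv = np.sqrt(_dot(v, v))
        if nv <= _EPS:
            continue
        ez = v / nv
        ref = np.zeros(3)
        if np.abs(ez[0]) < 0.9:
            ref[0] = 1.0
        else:
            ref[1] = 1.0
        ex = _cross(ref, ez)
        ex = ex / np.sqrt(_dot(ex, ex))
        ey = _cross(ez, ex)
        status, rec, nc = project_crossings(red, ex, ey, ez, maxc)
        if status != 0:
            continue
        if nc == 0:
            return 1
        mat = alexander_matrix_mod(rec, nc, p - 1, p)  # t = -1 mod p
        sub = mat[: nc - 1, : nc - 1].copy()
        d = det_mod_p(sub, p)
        if d > p - d:
            d = p - d
        return d
    return -1
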