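"""HOMFLY polynomial of oriented link diagrams given by Gauss codes.

Skein convention:  a P(L+) - a^{-1} P(L-) = z P(L0),  P(unknot) = 1,
so the k-component unlink has value delta^(k-1) with
delta = (a - a^{-1}) / z.

Polynomials are dicts {(a_exponent, z_exponent): integer coefficient};
exponents may be negative.  The algorithm recursively resolves the first
crossing met on an under-strand (which obstructs a descending diagram),
simplifying with Reidemeister I/II moves and memoising sub-diagrams.

Mirror symmetry: if D* is the mirror of D then
P(D*)(a, z) = P(D)(a^{-1}, -z), i.e. (i, j, c) -> (-i, j, (-1)^j c).
"""

from __future__ import annotations

DELTA = {(1, -1): 1, (-1, -1): -1}


def poly_add(p, q):
    out = dict(p)
    for k, v in q.items():
        out[k] = out.get(k, 0) + v
        if out[k] == 0:
            del out[k]
    return out


def poly_mono_mul(p, da, dz, coeff):
    return {(i + da, j + dz): c * coeff for (i, j), c in p.items()}

def poly_mul(p, q):
    out = {}
    for (i1, j1), c1 in p.items():
        for (i2, j2), c2 in q.items():
            k = (i1 + i2, j1 + j2)
            out[k] = out.get(k, 0) + c1 * c2
    return {k: v for k, v in out.items() if v != 0}


def delta_power(k):
    out = {(0, 0): 1}
    for _ in range(k):
        out = poly_mul(out, DELTA)
    return out


def mirror_poly(p):
    return {(-i, j): c * (-1) ** (j % 2) for (i, j), c in p.items()}


def _simplify(comps, signs):
    """Apply Reidemeister I and II deletions until stable; returns the new
    (comps, signs, n_free_loops) with crossing-free components removed."""
    comps = [list(c) for c in comps]
    changed = True
    while changed:
        changed = False
        # R1: a crossing whose two passes are cyclically adjacent in one component
        for ci, comp in enumerate(comps):
            n = len(comp)
            found = -1
            for pos in range(n):
                if n >= 2 and comp[pos][0] == comp[(pos + 1) % n][0]:
                    found = pos
                    break
            if found >= 0:
                cid = comp[found][0]
                comps[ci] = [e for e in comp if e[0] != cid]
                signs = {k: v for k, v in signs.items() if k != cid}
                changed = True
                break
        if changed:
            continue
        # R2: a bigon - crossings c,d adjacent in two places, one strand over
        # at both, the other under at both
        adj = {}
        for ci, comp in enumerate(comps):
            n = len(comp)
            for pos in range(n):
                if n < 2:
                    continue
                (c1, o1, *_), (c2, o2, *_) = comp[pos], comp[(pos + 1) % n]
                if c1 == c2:
                    continue
                key = frozenset((c1, c2))
                adj.setdefault(key, []).append((o1, o2))
        for key, occs in adj.items():
            if len(occs) < 2:
                continue
            both_over = any(o1 and o2 for o1, o2 in occs)
            both_under = any((not o1) and (not o2) for o1, o2 in occs)
            c, d = tuple(key)
            if both_over and both_under and signs[c] == -signs[d]:
                comps = [[e for e in comp if e[0] not in key] for comp in comps]
                signs = {k: v for k, v in signs.items() if k not in key}
                changed = True
                break
    free = sum(1 for c in comps if not c)
    comps = [c for c in comps if c]
    return comps, signs, free


def _canonical(comps, signs):
    rotated = []
    for comp in comps:
        n = len(comp)
        best = min(range(n), key=lambda r: tuple(comp[r:] + comp[:r]))
        rotated.append(tuple(comp[best:] + comp[:best]))
    rotated.sort()
    relabel = {}
    out = []
    for comp in rotated:
        rc = []
        for cid, over in comp:
            if cid not in relabel:
                relabel[cid] = len(relabel)
            rc.append((relabel[cid], over))
        out.append(tuple(rc))
    sg = tuple(signs[c] for c in sorted(relabel, key=relabel.get))
    return tuple(out), sg


def _first_bad_crossing(comps):
    seen = set()
    for ci, comp in enumerate(comps):
        for pos, (cid, over) in enumerate(comp):
            if cid not in seen:
                seen.add(cid)
                if not over:
                    return ci, pos
    return None


def _occurrences(comps, cid):
    occ = []
    for ci, comp in enumerate(comps):
        for pos, e in enumerate(comp):
            if e[0] == cid:
                occ.append((ci, pos))
    return occ


def _switch(comps, signs, cid):
    new = [[(c, (not o) if c == cid else o) for c, o in comp] for comp in comps]
    ns = dict(signs)
    ns[cid] = -ns[cid]
    return new, ns


def _smooth(comps, signs, cid):
    """Oriented smoothing: delete the crossing, reconnecting the strands."""
    (ci, pi), (cj, pj) = _occurrences(comps, cid)
    ns = {k: v for k, v in signs.items() if k != cid}
    if ci == cj:
        comp = comps[ci]
        i, j = sorted((pi, pj))
        a = comp[i + 1:j]
        b = comp[j + 1:] + comp[:i]
        rest = [c for k, c in enumerate(comps) if k != ci]
        return rest + [a, b], ns
    ca, cb = comps[ci], comps[cj]
    merged = ca[:pi] + cb[pj + 1:] + cb[:pj] + ca[pi + 1:]
    rest = [c for k, c in enumerate(comps) if k not in (ci, cj)]
    return rest + [merged], ns


def homfly_gauss(comps, signs, _memo=None):
    """HOMFLY polynomial of the oriented link diagram with components given
    as lists of (crossing id, is_over) and crossing signs in `signs`."""
    if _memo is None:
        _memo = {}
    comps, signs, free = _simplify(comps, signs)
    base = delta_power(free) if free else {(0, 0): 1}
    if not comps:
        # `free` loops total; unlink of `free` components
        return delta_power(max(free - 1, 0))
    key = _canonical(comps, signs)
    if key in _memo:
        p = _memo[key]
    else:
        bad = _first_bad_crossing(comps)
        if bad is None:
            p = delta_power(len(comps) - 1)
        else:
            cid = comps[bad[0]][bad[1]][0]
            sw_c, sw_s = _switch(comps, signs, cid)
            sm_c, sm_s = _smooth(comps, signs, cid)
            p_sw = homfly_gauss(sw_c, sw_s, _memo)
            p_sm = homfly_gauss(sm_c, sm_s, _memo)
            if signs[cid] > 0:
                # D is L+: P(D) = a^-2 P(Dsw) + a^-1 z P(D0)
                p = poly_add(poly_mono_mul(p_sw, -2, 0, 1),
                             poly_mono_mul(p_sm, -1, 1, 1))
            else:
                p = poly_add(poly_mono_mul(p_sw, 2, 0, 1),
                             poly_mono_mul(p_sm, 1, 1, -1))
        _memo[key] = p
    if free:
        p = poly_mul(p, base)
    return p


def homfly_from_entries(entries):
    """HOMFLY of a knot diagram given as a flat Gauss code
    [(cid, over, sign), ...] in traversal order."""
    comp = [(cid, bool(over)) for cid, over, _ in entries]
    signs = {}
    for cid, over, sign in entries:
        signs[cid] = int(sign)
    return homfly_gauss([comp], signs)


def poly_key(p):
    """Hashable canonical form of a polynomial dict."""
    return tuple(sorted((i, j, c) for (i, j), c in p.items() if c != 0))
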