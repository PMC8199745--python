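"""Parametric and diagrammatic realizations of small knots.

Torus knots and the figure-eight knot come from closed parametric curves.
Rational (2-bridge) knots are realized as 4-plats: four vertical strands
with twist regions prescribed by a continued-fraction expansion, closed by
caps at top and bottom.  The plat is returned as a closed 3-D polyline, so
all downstream topology uses the same projection machinery as everything
else.

Handedness convention: a knot variant is right-handed (+) when the signed
crossings of its reduced alternating diagram sum to a positive value (the
right-hand rule for crossing signs).  For torus knots this agrees with the
geometric handedness of the parametric curve.
"""

from __future__ import annotations

import numpy as np

# continued fractions and Alexander polynomials (Delta(1) = +1 normalisation)
# for the rational prime knots realized as 4-plats.
RATIONAL_KNOTS: dict[str, tuple[list[int], tuple[int, ...]]] = {
    "3.1": ([3], (1, -1, 1)),
    "4.1": ([2, 2], (-1, 3, -1)),
    "5.1": ([5], (1, -1, 1, -1, 1)),
    "5.2": ([3, 2], (2, -3, 2)),
    "6.1": ([4, 2], (-2, 5, -2)),
    "6.2": ([3, 1, 2], (-1, 3, -3, 3, -1)),
    "6.3": ([2, 1, 1, 2], (1, -3, 5, -3, 1)),
    "7.1": ([7], (1, -1, 1, -1, 1, -1, 1)),
    "7.2": ([5, 2], (3, -5, 3)),
    "7.3": ([4, 3], (2, -3, 3, -3, 2)),
    "7.4": ([3, 1, 3], (4, -7, 4)),
    "7.5": ([3, 2, 2], (2, -4, 5, -4, 2)),
    "7.6": ([2, 2, 1, 2], (-1, 5, -7, 5, -1)),
    "7.7": ([2, 1, 1, 1, 2], (1, -5, 9, -5, 1)),
    "8.1": ([6, 2], (-3, 7, -3)),
}

AMPHICHIRAL = {"0.1", "4.1", "6.3", "8.3"}


def cf_value(terms: list[int]) -> int:
    """Numerator p of the continued fraction [a1,...,am] evaluated as
    a_m + 1/(a_{m-1} + 1/(... + 1/a_1)); the 2-bridge knot determinant."""
    num, den = terms[0], 1
    for a in terms[1:]:
        num, den = a * num + den, num
    return abs(num)


def torus_knot_curve(p: int, q: int, n: int, right_handed: bool = False) -> np.ndarray:
    """Closed (p,q) torus-knot polyline with n vertices.  The default
    orientation of the parametric curve is left-handed for T(2,q)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = 2.0 + np.cos(q * t)
    z = np.sin(q * t)
    if right_handed:
        z = -z
    return np.stack([r * np.cos(p * t), r * np.sin(p * t), z], axis=1)


def figure_eight_curve(n: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.stack([(2.0 + np.cos(2.0 * t)) * np.cos(3.0 * t),
                     (2.0 + np.cos(2.0 * t)) * np.sin(3.0 * t),
                     np.sin(4.0 * t)], axis=1)


def circle_curve(n: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)


def _odd_length_cf(terms: list[int]) -> list[int]:
    """Equivalent continued fraction of odd length (plat closures of
    even-length fractions are 2-component links).  Uses the deep-end
    identities [a1, rest] = [1, a1-1, rest] and [1, a2, rest] = [a2+1, rest],
    which leave the fraction's value unchanged."""
    t = list(terms)
    if len(t) % 2 == 0:
        if t[0] > 1:
            t = [1, t[0] - 1] + t[1:]
        else:
            t = [t[1] + 1] + t[2:]
    assert len(t) % 2 == 1 and cf_value(t) == cf_value(terms)
    return t


def plat_curve(cf_terms: list[int], mirror: bool = False) -> np.ndarray:
    """Closed polyline of the 2-bridge knot with the given (all-positive)
    continued-fraction expansion, realized as a 4-plat."""
    cf_terms = _odd_length_cf(list(cf_terms))
    h = 0.35  # crossing depth offset
    strands = [[np.array([float(c), 0.0, 0.0])] for c in range(4)]
    occupant = list(range(4))  # occupant[column] = strand id
    y = 0.0
    for ridx, a in enumerate(cf_terms):
        cl = 1 if ridx % 2 == 0 else 0  # twist middle pair, then left pair
        cr = cl + 1
        sgn = 1.0 if ridx % 2 == 0 else -1.0
        for _ in range(abs(a)):
            sl, sr = occupant[cl], occupant[cr]
            ymid = y - 0.5
            ynew = y - 1.0
            strands[sl].append(np.array([0.5 * (cl + cr), ymid, sgn * h]))
            strands[sl].append(np.array([float(cr), ynew, 0.0]))
            strands[sr].append(np.array([0.5 * (cl + cr), ymid, -sgn * h]))
            strands[sr].append(np.array([float(cl), ynew, 0.0]))
            occupant[cl], occupant[cr] = sr, sl
            # bystander columns get a waypoint to keep edges short-ish
            for c in range(4):
                if c not in (cl, cr):
                    strands[occupant[c]].append(np.array([float(c), ynew, 0.0]))
            y = ynew
    ybot = y

    def cap(xa: float, xb: float, yref: float, up: bool, npts: int = 7):
        """Semicircular arc from x=xa to x=xb (in that traversal order)."""
        xs = 0.5 * (xa + xb)
        rr = 0.5 * abs(xb - xa)
        ang = np.linspace(0.0, np.pi, npts)[1:-1]
        pts = []
        for aa in ang:
            yy = yref + (np.sin(aa) * rr) * (1.0 if up else -1.0)
            pts.append(np.array([xs - rr * np.cos(aa), yy, 0.0]))
        if xa > xb:
            pts.reverse()
        return pts

    # assemble the closed loop: down a strand, bottom cap, up a strand, top cap...
    top_partner = {0: 1, 1: 0, 2: 3, 3: 2}
    bot_partner = {0: 1, 1: 0, 2: 3, 3: 2}
    start_col = {s: None for s in range(4)}
    end_col = {}
    for c in range(4):
        end_col[occupant[c]] = c
    for s in range(4):
        start_col[s] = int(round(strands[s][0][0]))
    pts: list[np.ndarray] = []
    visited = set()
    col = 0  # start at top of column 0, heading down
    going_down = True
    while True:
        if going_down:
            sid = [s for s in range(4) if start_col[s] == col][0]
            if sid in visited:
                break
            visited.add(sid)
            pts.extend(strands[sid])
            bcol = end_col[sid]
            nb = bot_partner[bcol]
            pts.extend(cap(float(bcol), float(nb), ybot, up=False))
            col = nb
            going_down = False
        else:
            sid = [s for s in range(4) if end_col[s] == col][0]
            if sid in visited:
                break
            visited.add(sid)
            pts.extend(list(reversed(strands[sid])))
            tcol = start_col[sid]
            nt = top_partner[tcol]
            pts.extend(cap(float(tcol), float(nt), 0.0, up=True))
            col = nt
            going_down = True
    if len(visited) != 4:
        raise ValueError(
            f"continued fraction {cf_terms} yields a link, not a knot")
    arr = np.array(pts)
    # drop consecutive duplicates
    keep = [0]
    for i in range(1, len(arr)):
        if np.linalg.norm(arr[i] - arr[keep[-1]]) > 1e-9:
            keep.append(i)
    if np.linalg.norm(arr[keep[-1]] - arr[keep[0]]) < 1e-9:
        keep.pop()
    arr = arr[keep]
    if mirror:
        arr = arr * np.array([1.0, 1.0, -1.0])
    return arr
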