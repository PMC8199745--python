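"""Exact Alexander-polynomial computation from Gauss codes.

The Alexander matrix is built from the underpass-generator presentation of
the knot group; its (n-1)x(n-1) minor determinant equals +/- t^k Delta(t).
The determinant is computed exactly (integer Bareiss elimination at integer
arguments, then Lagrange interpolation), and Delta is normalised so that the
lowest-order coefficient is the constant term and Delta(1) = 1.
"""

from __future__ import annotations

from fractions import Fraction


def int_det(m: list[list[int]]) -> int:
    """Exact determinant of an integer matrix (fraction-free Bareiss)."""
    a = [row[:] for row in m]
    n = len(a)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if a[k][k] == 0:
            for r in range(k + 1, n):
                if a[r][k] != 0:
                    a[k], a[r] = a[r], a[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                a[i][j] = (a[i][j] * a[k][k] - a[i][k] * a[k][j]) // prev
            a[i][k] = 0
        prev = a[k][k]
    return sign * a[n - 1][n - 1]


def _arc_assignment(entries):
    """Assign underpass-generator arcs to each traversal position."""
    nc = len(entries) // 2
    arc_at = []
    prov = 0
    for cid, over, sign in entries:
        arc_at.append(prov)
        if not over:
            prov += 1
    if prov != nc:
        raise ValueError("gauss code is not a knot diagram (bad underpass count)")
    return [a % nc for a in arc_at]


def alexander_polynomial(entries) -> tuple[int, ...]:
    """Normalised Alexander polynomial coefficients (c0, c1, ..., cd) of the
    knot with the given single-component Gauss code, lowest power first."""
    nc = len(entries) // 2
    if nc <= 1:
        return (1,)
    arcs = _arc_assignment(entries)
    over_arc = {}
    under_arc = {}
    signs = {}
    for pos, (cid, over, sign) in enumerate(entries):
        signs[cid] = sign
        if over:
            over_arc[cid] = arcs[pos]
        else:
            under_arc[cid] = arcs[pos]
    cids = sorted(under_arc)
    # matrix entries as (const, t-coefficient) pairs
    rows = []
    for cid in cids:
        row = [[0, 0] for _ in range(nc)]
        j = under_arc[cid]
        jp1 = (j + 1) % nc
        i = over_arc[cid]
        if i == j or i == jp1:
            row[j][0] -= 1
            row[jp1][0] += 1
        elif signs[cid] > 0:
            row[j][0] += 1
            row[jp1][1] -= 1
            row[i][0] -= 1
            row[i][1] += 1
        else:
            row[j][1] -= 1
            row[jp1][0] += 1
            row[i][0] -= 1
            row[i][1] += 1
        rows.append(row)
    # minor: drop last row and column; evaluate at nc integer points
    size = nc - 1
    points = list(range(2, 2 + nc))
    values = []
    for t in points:
        m = [[rows[r][c][0] + rows[r][c][1] * t for c in range(size)]
             for r in range(size)]
        values.append(int_det(m))
    coeffs = _lagrange_int(points, values)
    # strip the t^k unit factor
    lo = 0
    while lo < len(coeffs) and coeffs[lo] == 0:
        lo += 1
    if lo == len(coeffs):
        raise ValueError("vanishing Alexander determinant: invalid knot diagram")
    coeffs = coeffs[lo:]
    while coeffs and coeffs[-1] == 0:
        coeffs.pop()
    if sum(coeffs) < 0:
        coeffs = [-c for c in coeffs]
    if sum(coeffs) != 1:
        raise ValueError("Alexander normalisation failed: Delta(1) != +/-1")
    return tuple(coeffs)


def _lagrange_int(xs, ys):
    """Exact polynomial interpolation with integer result coefficients."""
    n = len(xs)
    coeffs = [Fraction(0)] * n
    for i in range(n):
        # basis poly prod_{j != i} (t - xj) / (xi - xj)
        basis = [Fraction(1)]
        denom = 1
        for j in range(n):
            if j == i:
                continue
            denom *= xs[i] - xs[j]
            new = [Fraction(0)] * (len(basis) + 1)
            for k, c in enumerate(basis):
                new[k] -= c * xs[j]
                new[k + 1] += c
            basis = new
        f = Fraction(ys[i], denom)
        for k, c in enumerate(basis):
            coeffs[k] += c * f
    out = []
    for c in coeffs:
        if c.denominator != 1:
            raise ValueError("interpolation did not yield integers")
        out.append(int(c))
    return out


def minor_det_at(entries, t: int) -> int:
    """Exact integer determinant of the Alexander minor evaluated at t.

    Equals +/- t^k Delta(t); at t = -1 the unit is +/-1 so the absolute
    value is the knot determinant, and at t = -2 the odd part of the
    absolute value is a projection-independent invariant (the unit only
    contributes powers of two)."""
    nc = len(entries) // 2
    if nc <= 1:
        return 1
    arcs = _arc_assignment(entries)
    over_arc = {}
    under_arc = {}
    signs = {}
    for pos, (cid, over, sign) in enumerate(entries):
        signs[cid] = sign
        if over:
            over_arc[cid] = arcs[pos]
        else:
            under_arc[cid] = arcs[pos]
    size = nc - 1
    rows = []
    for cid in sorted(under_arc):
        row = [0] * nc
        j = under_arc[cid]
        jp1 = (j + 1) % nc
        i = over_arc[cid]
        if i == j or i == jp1:
            row[j] -= 1
            row[jp1] += 1
        elif signs[cid] > 0:
            row[j] += 1
            row[jp1] -= t
            row[i] += t - 1
        else:
            row[j] -= t
            row[jp1] += 1
            row[i] += t - 1
        rows.append(row[:size])
    return int_det(rows[:size])


def odd_part(x: int) -> int:
    x = abs(int(x))
    while x and x % 2 == 0:
        x //= 2
    return x


def fast_fingerprint(entries) -> tuple[int, int]:
    """(|Delta(-1)|, odd part of |Delta(-2)|) via two integer minor
    determinants; avoids the full polynomial interpolation on large
    diagrams."""
    return abs(minor_det_at(entries, -1)), odd_part(minor_det_at(entries, -2))


def alexander_determinants(entries) -> tuple[int, int]:
    """(|Delta(-1)|, |Delta(-2)|) for a single-component Gauss code."""
    poly = alexander_polynomial(entries)
    d1 = abs(sum(c * (-1) ** k for k, c in enumerate(poly)))
    d2 = abs(sum(c * (-2) ** k for k, c in enumerate(poly)))
    return d1, d2
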