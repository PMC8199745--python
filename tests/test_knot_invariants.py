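"""Knot identification: Gauss codes, Alexander polynomial, HOMFLY, and the
fingerprint table, anchored on parametric fixtures of known type."""

import numpy as np
import pytest

from knotflux import knot_invariants as ki
from knotflux import _curves
from knotflux._homfly import (homfly_from_entries, mirror_poly, poly_key,
                              poly_mul)


@pytest.fixture(scope="module")
def trefoil_left():
    return _curves.torus_knot_curve(2, 3, 120)


def test_gauss_code_of_planar_polygon_is_empty():
    t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
    poly = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
    d = ki.gauss_code(poly, np.array([0.0, 0.0, 1.0]))
    assert d.n_crossings == 0


def _minimal_diagram(red, n_axes=10):
    best = None
    rng = np.random.default_rng(99)
    for _ in range(n_axes):
        d = ki.gauss_code(red, rng.standard_normal(3), rng=rng)
        if best is None or d.n_crossings < best.n_crossings:
            best = d
    return best


def test_trefoil_minimal_diagram_three_same_sign_crossings(trefoil_left):
    d = _minimal_diagram(ki.km_reduce(trefoil_left))
    assert d.n_crossings == 3
    signs = {s for _, _, s in d.entries}
    assert signs == {-1}  # left-handed trefoil: all negative crossings
    right = ki.km_reduce(_curves.torus_knot_curve(2, 3, 120,
                                                  right_handed=True))
    dr = _minimal_diagram(right)
    assert dr.n_crossings == 3
    assert {s for _, _, s in dr.entries} == {1}


def test_axis_reversal_flips_over_under_keeps_signs(trefoil_left):
    red = ki.km_reduce(trefoil_left)
    axis = np.array([0.13, 0.21, 0.93])
    d1 = ki.gauss_code(red, axis)
    d2 = ki.gauss_code(red, -axis)
    assert d1.n_crossings == d2.n_crossings
    assert sorted(s for _, _, s in d1.entries) == \
        sorted(s for _, _, s in d2.entries)
    # over/under flips: the multiset of (sign, over) pairs swaps over flag
    m1 = sorted((s, o) for _, o, s in d1.entries)
    m2 = sorted((s, not o) for _, o, s in d2.entries)
    assert m1 == m2


@pytest.mark.parametrize("curve_fn,expect_d1,expect_alex", [
    (lambda: _curves.circle_curve(50), 1, (1,)),
    (lambda: _curves.torus_knot_curve(2, 3, 120), 3, (1, -1, 1)),
    (lambda: _curves.figure_eight_curve(160), 5, (-1, 3, -1)),
    (lambda: _curves.torus_knot_curve(2, 5, 200), 5, (1, -1, 1, -1, 1)),
    (lambda: _curves.plat_curve([3, 2]), 7, (2, -3, 2)),
])
def test_alexander_polynomials_of_fixtures(curve_fn, expect_d1, expect_alex):
    red = ki.km_reduce(curve_fn())
    d = ki.gauss_code(red, np.array([0.11, 0.23, 0.96]))
    assert ki.alexander_polynomial(d) == expect_alex
    d1, _ = ki.alexander_determinants(d)
    assert d1 == expect_d1


def test_unknot_determinants():
    t = np.linspace(0, 2 * np.pi, 30, endpoint=False)
    circ = np.stack([np.cos(t), np.sin(t), 0.05 * np.sin(3 * t)], axis=1)
    d = ki.gauss_code(ki.km_reduce(circ), np.array([0.0, 0.0, 1.0]))
    assert ki.alexander_determinants(d) == (1, 1)


def test_homfly_unknot_and_mirror_rule(trefoil_left):
    assert homfly_from_entries([]) == {(0, 0): 1}
    red = ki.km_reduce(trefoil_left)
    d = ki.gauss_code(red, np.array([0.2, 0.1, 0.97]))
    h = ki.homfly(d)
    hm = ki.homfly(d.mirror())
    assert poly_key(mirror_poly(h)) == poly_key(hm)
    assert poly_key(h) != poly_key(hm)  # trefoil is chiral


def test_homfly_multiplicative_under_connected_sum():
    """The granny knot's HOMFLY is the square of the trefoil's."""
    red = ki.km_reduce(_curves.torus_knot_curve(2, 3, 120))
    d = ki.gauss_code(red, np.array([0.2, 0.1, 0.97]))
    h = ki.homfly(d)
    shift = max(c for c, _, _ in d.entries) + 1
    granny = ki.CrossingDiagram(tuple(
        list(d.entries) + [(c + shift, o, s) for c, o, s in d.entries]))
    assert poly_key(ki.homfly(granny)) == poly_key(poly_mul(h, h))


def test_figure_eight_is_amphichiral():
    red = ki.km_reduce(_curves.figure_eight_curve(160))
    d = ki.gauss_code(red, np.array([0.2, 0.1, 0.97]))
    h = ki.homfly(d)
    assert poly_key(mirror_poly(h)) == poly_key(h)


KNOWN_FIXTURES = [
    (lambda: _curves.circle_curve(60), "0.1"),
    (lambda: _curves.torus_knot_curve(2, 3, 120), "3.1-"),
    (lambda: _curves.torus_knot_curve(2, 3, 120, right_handed=True), "3.1+"),
    (lambda: _curves.figure_eight_curve(160), "4.1"),
    (lambda: _curves.torus_knot_curve(2, 5, 200), "5.1-"),
    (lambda: _curves.torus_knot_curve(2, 5, 200, right_handed=True), "5.1+"),
    (lambda: _curves.plat_curve([3, 2]), "5.2-"),
    (lambda: _curves.plat_curve([3, 2], mirror=True), "5.2+"),
    (lambda: _curves.plat_curve([7]), "7.1-"),
]


@pytest.mark.parametrize("curve_fn,label", KNOWN_FIXTURES)
def test_classification_is_projection_independent(curve_fn, label):
    curve = curve_fn()
    for seed in range(5):
        assert str(ki.classify_knot(curve, seed=seed)) == label


@pytest.mark.parametrize("curve_fn,label", KNOWN_FIXTURES)
def test_mirror_consistency(curve_fn, label):
    """Reflection flips chirality for chiral knots and leaves amphichiral
    knots unchanged."""
    curve = curve_fn() * np.array([1.0, 1.0, -1.0])
    got = str(ki.classify_knot(np.ascontiguousarray(curve), seed=1))
    want = str(ki.KnotType.from_string(label).mirror())
    assert got == want


def test_classification_invariances(rng, trefoil_left):
    base = str(ki.classify_knot(trefoil_left))
    # uniform scaling
    assert str(ki.classify_knot(trefoil_left * 37.5)) == base
    # cyclic relabeling
    rolled = np.roll(trefoil_left, 41, axis=0)
    assert str(ki.classify_knot(np.ascontiguousarray(rolled))) == base
    # rigid motion
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    moved = trefoil_left @ q.T + 5.0
    assert str(ki.classify_knot(np.ascontiguousarray(moved))) == base


def test_table_determinants_odd_and_match_continued_fractions():
    for entry in ki.knot_table():
        assert entry.det1 % 2 == 1
        base = entry.knot.label
        if base in _curves.RATIONAL_KNOTS and not entry.knot.composite:
            assert entry.det1 == _curves.cf_value(
                _curves.RATIONAL_KNOTS[base][0])


def test_composite_classification():
    """A granny-knot polygon classifies as a composite of two trefoils."""
    red = ki.km_reduce(_curves.torus_knot_curve(2, 3, 120))
    d = ki.gauss_code(red, np.array([0.2, 0.1, 0.97]))
    shift = max(c for c, _, _ in d.entries) + 1
    granny = ki.CrossingDiagram(tuple(
        list(d.entries) + [(c + shift, o, s) for c, o, s in d.entries]))
    kt = ki.classify_diagram(granny)
    assert kt.composite
    assert kt.label == "3.1-#3.1-"


def test_knot_type_string_roundtrip():
    for s in ["0.1", "3.1-", "3.1+", "4.1", "5.2+", "unknown",
              "3.1-#3.1-"]:
        assert str(ki.KnotType.from_string(s)) == s
    assert ki.KnotType.from_string("3.1-").mirror().name == "3.1+"
    assert ki.KnotType.from_string("4.1").mirror().name == "4.1"
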