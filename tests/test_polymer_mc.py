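"""Wormlike-chain construction, energies, stiffness calibration, and the
Metropolis sampler's conservation laws."""

import math

import numpy as np
import pytest

from knotflux import knot_invariants as ki
from knotflux import polymer_mc as pm
from knotflux._curves import torus_knot_curve, circle_curve
from conftest import random_ring


def test_chain_parameter_validation():
    par = pm.ChainParameters()
    assert par.n_segments == 204
    assert par.contour_length == pytest.approx(2040.0)
    assert par.lk0 == pytest.approx(6000 / 10.5)
    assert par.sigma is None
    assert pm.ChainParameters(delta_lk=-12).sigma == \
        pytest.approx(-12 / (6000 / 10.5))
    with pytest.raises(ValueError):
        pm.ChainParameters(segment_length=-1.0)
    with pytest.raises(ValueError):
        pm.ChainParameters(effective_diameter=-0.1)
    with pytest.raises(ValueError):
        pm.ChainParameters(n_bp=30)  # fewer than 3 segments


def test_build_ring_circle_template():
    ring = pm.build_ring_from_template(circle_curve(400), n=100, b=2.5)
    assert ring.n == 100
    assert np.allclose(ring.edge_lengths(), 2.5, rtol=1e-9)
    assert abs(ring.writhe()) < 1e-10
    assert np.allclose(ring.vertices[:, 2], ring.vertices[0, 2])


def test_build_ring_triangle_template():
    tri = np.array([[0.0, 0, 0], [4.0, 1.0, 0], [1.0, 3.0, 0.5]])
    ring = pm.build_ring_from_template(tri, n=3, b=1.0, check_topology=False)
    assert np.allclose(ring.edge_lengths(), 1.0, rtol=1e-9)


def test_build_ring_preserves_torus_knot():
    ring = pm.build_ring_from_template(torus_knot_curve(2, 3, 400),
                                       n=120, b=1.0)
    assert str(ki.classify_knot(ring.vertices)) == "3.1-"
    assert np.allclose(ring.edge_lengths(), 1.0, rtol=1e-9)


def test_bending_energy_regular_polygon_closed_form():
    par = pm.ChainParameters()
    g = pm.calibrated_stiffness(par)
    n = 204
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 10.0 / (2 * np.sin(np.pi / n))
    poly = np.stack([r * np.cos(t), r * np.sin(t), np.zeros(n)], axis=1)
    expected = g * n * (1 - np.cos(2 * np.pi / n))
    assert pm.bending_energy(poly, par) == pytest.approx(expected, rel=1e-12)
    assert pm.bending_energy(poly, par, stiffness=0.0) == 0.0


def test_bending_energy_matches_direct_resummation(rng):
    par = pm.ChainParameters()
    g = pm.calibrated_stiffness(par)
    ring = random_ring(50, rng, scale=30)
    total = 0.0
    n = len(ring)
    for i in range(n):
        a = ring[i] - ring[(i - 1) % n]
        b = ring[(i + 1) % n] - ring[i]
        cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        total += g * (1 - cos)
    assert pm.bending_energy(ring, par) == pytest.approx(total, abs=1e-12)


def test_twist_energy_values_and_errors():
    par0 = pm.ChainParameters(delta_lk=0)
    t = np.linspace(0, 2 * np.pi, 204, endpoint=False)
    r = 10.0 / (2 * np.sin(np.pi / 204))
    circ = np.stack([r * np.cos(t), r * np.sin(t), np.zeros(204)], axis=1)
    assert pm.twist_energy(circ, par0) == pytest.approx(0.0, abs=1e-12)
    par2 = pm.ChainParameters(delta_lk=-2)
    # 2 pi^2 (75/2040) * 4 kBT for a planar (Wr=0) circle
    assert pm.twist_energy(circ, par2) == \
        pytest.approx(2 * math.pi ** 2 * 75 / 2040 * 4, rel=1e-9)
    assert pm.twist_energy(circ, par2) == pytest.approx(2.9028, abs=1e-3)
    with pytest.raises(ValueError):
        pm.twist_energy(circ, pm.ChainParameters())


def test_twist_energy_minimal_at_rounded_writhe(rng):
    ring = random_ring(60, rng, scale=60)
    ring = pm.build_ring_from_template(ring, n=60, b=34.0,
                                       check_topology=False)
    wr = ring.writhe()
    energies = {}
    for dlk in range(int(round(wr)) - 4, int(round(wr)) + 5):
        par = pm.ChainParameters(n_bp=6000, delta_lk=dlk)
        energies[dlk] = pm.twist_energy(ring, par)
    best = min(energies, key=energies.get)
    assert best == int(round(wr))


def test_stiffness_calibration_formula():
    """g solves <cos theta> = coth g - 1/g = exp(-b/P)."""
    par = pm.ChainParameters()
    g = pm.calibrated_stiffness(par)
    target = math.exp(-10.0 / 50.0)
    assert 1 / math.tanh(g) - 1 / g == pytest.approx(target, abs=1e-12)
    assert 4.0 < g < 7.0  # near the stiff-chain estimate P/b = 5


def test_persistence_length_from_open_chain_decay(rng):
    """The tangent correlation of an open chain with the calibrated
    stiffness decays as exp(-s/P) with P within 5% of the target."""
    par = pm.ChainParameters()
    corr = pm.sample_open_chain_cosines(par, n_bonds=200, n_chains=6000,
                                        rng=rng)
    s = np.arange(1, len(corr) + 1)
    mask = corr > 0.15
    slope = np.polyfit(s[mask], np.log(corr[mask]), 1)[0]
    p_fit = -par.segment_length / slope
    assert abs(p_fit - 50.0) / 50.0 < 0.05


def test_crankshaft_trial_properties(rng):
    ring = pm.build_ring_from_template(circle_curve(300), n=80, b=3.0)
    out = pm.crankshaft_trial(ring, rng, max_angle=1.2)
    assert np.allclose(out.edge_lengths(), 3.0, rtol=1e-9)
    tiny = pm.crankshaft_trial(ring, rng, max_angle=1e-12)
    assert np.abs(tiny.vertices - ring.vertices).max() < 1e-9
    with pytest.raises(ValueError):
        pm.crankshaft_trial(ring, rng, max_angle=0.0)


def test_rigid_limit_freezes_conformation(params_small):
    """With enormous stiffness every energy-changing move is rejected and
    the ensemble stays at the starting conformation."""
    ens = pm.mc_sample(params_small, "0.1", n_samples=5, rng_seed=3,
                       equilibration=500, check_knot=False)
    start = pm.initial_ring("0.1", params_small).vertices
    g_huge = 1e14
    from knotflux._mckernel import mc_run
    verts = start.copy()
    n = len(verts)
    frozen = np.zeros(n, bool)
    na, _, _, _ = mc_run(verts, 2000, g_huge, 1.5, n // 3, 25.0, True,
                         frozen, False, 0.0, 0.0, 0.0, False, 1, 0,
                         2147483647, 2147483629, 77)
    assert np.abs(verts - start).max() < 1e-3 * params_small.segment_length
    assert ens.n_samples == 5  # the ordinary run still produced samples


def test_bond_angle_distribution_matches_boltzmann(params_small):
    """Sampled bond angles of a phantom unknotted ring follow the
    wormlike-chain law ~ exp(g cos t) sin t (KS test)."""
    from scipy.stats import kstest
    par = pm.ChainParameters(n_bp=3000, effective_diameter=0.0)
    g = pm.calibrated_stiffness(par)
    ens = pm.mc_sample(par, "0.1", n_samples=30, rng_seed=5,
                       check_knot=False, use_ev=False)
    cosines = []
    for k in range(ens.n_samples):
        v = ens.conformations[k]
        e = np.roll(v, -1, axis=0) - v
        el = np.linalg.norm(e, axis=1)
        cosines.extend(np.sum(e * np.roll(e, -1, axis=0), axis=1)
                       / (el * np.roll(el, -1)))
    cosines = np.array(cosines)

    def cdf(u):
        # integral of exp(g x) dx from -1 to u, normalised
        return (np.exp(g * np.asarray(u)) - np.exp(-g)) \
            / (np.exp(g) - np.exp(-g))

    stat = kstest(cosines[::7], cdf)  # thin to reduce correlation
    assert stat.pvalue > 0.01


def test_knot_conservation_and_edge_lengths(params_small):
    ens = pm.mc_sample(params_small, "3.1-", n_samples=12, rng_seed=6)
    for k in range(ens.n_samples):
        v = ens.conformations[k]
        el = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
        assert np.allclose(el, params_small.segment_length, rtol=1e-9)
        assert str(ki.classify_knot(v, seed=k)) == "3.1-"


def test_sampler_stationarity_two_starts(params_small):
    """Mean bending energy agrees between two runs started from different
    seeds (weak stationarity check)."""
    e1 = pm.mc_sample(params_small, "0.1", n_samples=60, rng_seed=1,
                      check_knot=False).bend_energies
    e2 = pm.mc_sample(params_small, "0.1", n_samples=60, rng_seed=999,
                      check_knot=False).bend_energies
    se = math.sqrt(e1.var() / len(e1) + e2.var() / len(e2))
    assert abs(e1.mean() - e2.mean()) < 4 * se


def test_mc_sample_argument_validation(params_small):
    with pytest.raises(ValueError):
        pm.mc_sample(params_small, "0.1", n_samples=0)
    with pytest.raises(ValueError):
        pm.mc_sample(params_small, "0.1", n_samples=1, equilibration=-5)
    with pytest.raises(ValueError):
        pm.mc_sample(params_small, "10.139-", n_samples=1)
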