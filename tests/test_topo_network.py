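"""Master-equation assembly, steady states, currents, source limits, and
pathway extraction, checked against closed forms and an ODE oracle."""

import numpy as np
import pytest

from knotflux import knot_invariants as ki
from knotflux import topo_network as tn
from knotflux.fixtures_io import toy_network
from knotflux.topoii_model import RateEstimate

S = tn.TopoState.from_string


def _net_from_rates(rates):
    states = sorted({a for a, _ in rates} | {b for _, b in rates},
                    key=str)
    return tn.TransitionNetwork(states, {(a, b): k
                                         for (a, b), k in rates.items()})


def test_build_network_from_point_mass_estimates():
    a, b = S("0.1"), S("3.1-")
    ests = [RateEstimate(state=a, j=1.0, q={b: 1.0}, n_conformations=10,
                         n_juxtaposed=10),
            RateEstimate(state=b, j=1.0, q={a: 1.0}, n_conformations=10,
                         n_juxtaposed=10)]
    net = tn.build_network(ests, k0=2.0)
    w = net.generator_matrix()
    assert np.allclose(w, 2.0 * np.array([[-1, 1], [1, -1]])) or \
        np.allclose(w, 2.0 * np.array([[-1, 1], [1, -1]])[::-1, ::-1])
    assert np.allclose(w.sum(axis=0), 0.0)


def test_build_network_matches_hand_multiplied_rates():
    a, b, c = S("0.1"), S("3.1-"), S("5.1-")
    ests = [
        RateEstimate(state=a, j=0.2, q={b: 0.75, c: 0.25},
                     n_conformations=100, n_juxtaposed=20),
        RateEstimate(state=b, j=0.5, q={a: 1.0}, n_conformations=100,
                     n_juxtaposed=50),
        RateEstimate(state=c, j=0.1, q={b: 0.6, a: 0.4},
                     n_conformations=100, n_juxtaposed=10),
    ]
    net = tn.build_network(ests, k0=3.0)
    assert np.isclose(net.rate(a, b), 3.0 * 0.2 * 0.75)
    assert np.isclose(net.rate(c, b), 3.0 * 0.1 * 0.6)
    assert np.isclose(net.rate(b, a), 1.5)
    w = net.generator_matrix()
    assert np.allclose(w.sum(axis=0), 0.0, atol=1e-14)


def test_column_sums_zero_for_random_networks(rng):
    states = [S(s) for s in ("0.1", "3.1-", "3.1+", "4.1")]
    rates = {}
    for a in states:
        for b in states:
            if a != b and rng.random() < 0.7:
                rates[(a, b)] = float(rng.random())
    net = tn.TransitionNetwork(states, rates)
    assert np.allclose(net.generator_matrix().sum(axis=0), 0.0, atol=1e-14)


def test_two_state_steady_state_analytic():
    net = toy_network("two_state", k12=2.0, k21=1.0)
    res = tn.steady_state(net)
    assert np.allclose(sorted(res.p_star), [1 / 3, 2 / 3], atol=1e-12)
    assert res.probability(S("0.1")) == pytest.approx(1 / 3, abs=1e-12)
    assert res.residual < 1e-12


def test_symmetric_rates_give_uniform_state_and_zero_currents():
    a, b, c = S("0.1"), S("3.1-"), S("4.1")
    net = _net_from_rates({(a, b): 1.3, (b, a): 1.3, (b, c): 0.7,
                           (c, b): 0.7, (a, c): 0.2, (c, a): 0.2})
    res = tn.steady_state(net)
    assert np.allclose(res.p_star, 1 / 3, atol=1e-10)
    assert all(abs(v) < 1e-12 for v in res.currents.values())
    assert tn.detailed_balance_residual(net, res.p_star) < 1e-12


def test_unidirectional_cycle_currents():
    net = toy_network("three_cycle", rate=1.0)
    res = tn.steady_state(net)
    assert np.allclose(res.p_star, 1 / 3, atol=1e-12)
    pos = [v for v in res.currents.values() if v > 0]
    assert np.allclose(pos, 1 / 3, atol=1e-12)
    # uniform p on a unidirectional cycle maximally violates detailed balance
    assert tn.detailed_balance_residual(net, res.p_star) == \
        pytest.approx(1 / 3, abs=1e-12)


def test_steady_state_matches_long_time_evolution(rng):
    """NESS equals the long-time limit of the master equation on random
    connected networks of up to 10 states."""
    for n in (4, 7, 10):
        labels = ["0.1", "3.1-", "3.1+", "4.1", "5.1-", "5.1+", "5.2-",
                  "5.2+", "6.1-", "6.1+"][:n]
        states = [S(s) for s in labels]
        rates = {}
        for i, a in enumerate(states[1:], start=1):
            rates[(a, states[i - 1])] = 0.2 + float(rng.random())
        for a in states:
            for b in states:
                if a != b and rng.random() < 0.4:
                    rates[(a, b)] = rates.get((a, b), 0.0) + float(rng.random())
        net = tn.TransitionNetwork(states, rates)
        res = tn.steady_state(net)
        p0 = np.zeros(n)
        p0[0] = 1.0
        traj = tn.evolve(net, p0, [0.0, 50.0, 2000.0])
        assert np.allclose(traj[-1], res.p_star, atol=1e-8)
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-10)


def test_evolve_two_state_closed_form():
    net = toy_network("two_state", k12=2.0, k21=1.0)
    k = 3.0  # relaxation rate k12 + k21
    times = np.linspace(0, 3, 7)
    p0 = np.array([1.0, 0.0])
    traj = tn.evolve(net, p0, times)
    p_inf = 1 / 3
    expected = p_inf + (1.0 - p_inf) * np.exp(-k * times)
    assert np.allclose(traj[:, 0], expected, atol=1e-8)


def test_evolve_zero_generator_is_identity():
    a, b = S("0.1"), S("3.1-")
    net = tn.TransitionNetwork([a, b], {})
    p0 = np.array([0.25, 0.75])
    traj = tn.evolve(net, p0, [0.0, 5.0, 10.0])
    assert np.allclose(traj, p0)


def test_evolve_rejects_bad_inputs():
    net = toy_network("two_state")
    with pytest.raises(ValueError):
        tn.evolve(net, np.array([-0.1, 1.1]), [0.0, 1.0])
    with pytest.raises(ValueError):
        tn.evolve(net, np.array([0.7, 0.7]), [0.0, 1.0])


def test_add_source_keeps_conservation_and_kS_zero_is_noop():
    net = toy_network("two_state")
    same = tn.add_source(net, S("0.1"), S("3.1-"), 0.0)
    assert same.rates == net.rates
    srced = tn.add_source(net, S("0.1"), S("3.1-"), 5.0)
    assert np.allclose(srced.generator_matrix().sum(axis=0), 0.0, atol=1e-13)
    with pytest.raises(KeyError):
        tn.add_source(net, S("7.1-"), S("3.1-"), 1.0)


def test_disconnected_network_raises():
    a, b, c, d = S("0.1"), S("3.1-"), S("5.1-"), S("5.2-")
    net = tn.TransitionNetwork([a, b, c, d],
                               {(a, b): 1.0, (b, a): 1.0, (c, d): 1.0,
                                (d, c): 1.0})
    with pytest.raises(ValueError):
        tn.steady_state(net)


def test_limit_source_current_two_state_analytic():
    """States {A, B} with A->B at rate kS and B->A at rate r: as kS grows,
    P*(A) -> 0 like 1/kS and the source current converges to r."""
    a, b = S("0.1"), S("3.1-")
    r = 0.7
    net = tn.TransitionNetwork([a, b], {(b, a): r})
    lim = tn.limit_source_current(net, a, b, rel_tol=1e-5)
    assert lim.source_current == pytest.approx(r, rel=1e-4)
    assert lim.result.probability(a) < 1e-4
    # P*(A) ~ 1/kS: log-log slope -1 +- 0.05
    logk = np.log(lim.ks_values[-5:])
    logp = np.log(lim.p_from[-5:])
    slope = np.polyfit(logk, logp, 1)[0]
    assert abs(slope + 1.0) < 0.05


def test_limit_source_current_nonsource_states_converged():
    net = toy_network("chain_with_source", ks=1.0, rate=1.0)
    base = tn.TransitionNetwork(list(net.states),
                                {k: v for k, v in net.rates.items()
                                 if k != (S("0.1"), S("5.1-"))})
    lim = tn.limit_source_current(base, S("0.1"), S("5.1-"), rel_tol=1e-5)
    res1 = lim.result
    # resolve at 10x the last kS: non-source probabilities stable
    res2 = tn.steady_state(tn.add_source(base, S("0.1"), S("5.1-"),
                                         float(lim.ks_values[-1]) * 10))
    for s in base.states:
        if str(s) == "0.1":
            continue
        assert res2.probability(s) == pytest.approx(
            res1.probability(s), rel=1e-3, abs=1e-9)


def test_extract_pathways_thresholds_and_kirchhoff():
    a, b, c = S("0.1"), S("5.1-"), S("3.1-")
    # source chain 0.1 -> 5.1- -> 3.1- -> 0.1 plus a weak side branch
    d = S("4.1")
    rates = {(b, c): 1.0, (c, a): 1.0, (b, d): 0.08, (d, a): 1.0}
    net = tn.TransitionNetwork([a, b, c, d], rates)
    lim = tn.limit_source_current(net, a, b)
    res = lim.result
    i_s = lim.source_current
    # Kirchhoff at the source state: outflow equals source current
    out = sum(v for (x, y), v in res.currents.items()
              if x == a and v > 0)
    assert out == pytest.approx(i_s, abs=1e-8 * max(i_s, 1))
    g = tn.extract_pathways(res, i_s)
    kinds = {(str(x), str(y)): data["klass"]
             for x, y, data in g.edges(data=True)}
    assert kinds[("5.1-", "3.1-")] == "dominant"
    assert kinds[("3.1-", "0.1")] == "dominant"
    # side branch carries ~7.4% of the current: subdominant
    assert kinds[("5.1-", "4.1")] == "subdominant"
    with pytest.raises(ValueError):
        tn.extract_pathways(res, 0.0)


def test_equilibrium_free_energy():
    k0 = ki.KnotType.from_string("0.1")
    k3 = ki.KnotType.from_string("3.1-")
    f = tn.equilibrium_free_energy({k0: 0.5, k3: 0.5})
    assert f[k3] == pytest.approx(0.0, abs=1e-14)
    f2 = tn.equilibrium_free_energy({k0: 1.0, k3: 0.0049})
    assert f2[k3] == pytest.approx(5.32, abs=0.01)
    # invariance under rescaling
    f3 = tn.equilibrium_free_energy({k0: 10.0, k3: 0.049})
    assert f3[k3] == pytest.approx(f2[k3], abs=1e-12)
    f4 = tn.equilibrium_free_energy({k0: 1.0, k3: 0.0})
    assert np.isinf(f4[k3])


def test_topo_state_roundtrip_and_mirror():
    s = S("3.1-@-2")
    assert s.delta_lk == -2
    assert str(s) == "3.1-@-2"
    assert str(s.mirror()) == "3.1+@+2"
    assert str(S("4.1")) == "4.1"
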