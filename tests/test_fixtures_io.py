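"""Fixture generators, toy networks, and file round trips."""

import numpy as np
import pytest

from knotflux import fixtures_io as fio
from knotflux import knot_invariants as ki
from knotflux import polymer_mc as pm
from knotflux import topo_network as tn


@pytest.mark.parametrize("spec,label", [
    (fio.FixtureSpec("circle", n_vertices=60), "0.1"),
    (fio.FixtureSpec("torus_knot", p=2, q=3, handedness="-",
                     n_vertices=120), "3.1-"),
    (fio.FixtureSpec("torus_knot", p=2, q=3, handedness="+",
                     n_vertices=120), "3.1+"),
    (fio.FixtureSpec("torus_knot", p=2, q=5, handedness="-",
                     n_vertices=200), "5.1-"),
    (fio.FixtureSpec("figure_eight", n_vertices=160), "4.1"),
    (fio.FixtureSpec("5.2-", n_vertices=150), "5.2-"),
])
def test_fixtures_classify_under_five_projections(spec, label):
    conf = fio.make_fixture(spec)
    assert conf.n == spec.n_vertices
    for seed in range(5):
        assert str(ki.classify_knot(conf.vertices, seed=seed)) == label


def test_fixture_errors():
    with pytest.raises(ValueError):
        fio.make_fixture(fio.FixtureSpec("torus_knot", p=2, q=4))
    with pytest.raises(ValueError):
        fio.make_fixture(fio.FixtureSpec("nosuch"))
    with pytest.raises(ValueError):
        # 3 vertices cannot carry a trefoil (below its stick number)
        fio.make_fixture(fio.FixtureSpec("torus_knot", p=2, q=3,
                                         n_vertices=5))


def test_toy_networks_analytic_steady_states():
    res = tn.steady_state(fio.toy_network("two_state", k12=2.0, k21=1.0))
    assert res.probability(tn.TopoState.from_string("0.1")) == \
        pytest.approx(1 / 3, abs=1e-12)
    res3 = tn.steady_state(fio.toy_network("three_cycle"))
    assert np.allclose(res3.p_star, 1 / 3, atol=1e-12)
    chain = fio.toy_network("chain_with_source", ks=1e6)
    res_c = tn.steady_state(chain)
    assert res_c.probability(tn.TopoState.from_string("0.1")) < 1e-4
    with pytest.raises(ValueError):
        fio.toy_network("nope")


def test_xyz_roundtrip(tmp_path, rng):
    par = pm.ChainParameters(n_bp=3000)
    ring = pm.initial_ring("3.1-", par)
    path = tmp_path / "conf.xyz"
    fio.write_xyz(path, [ring.vertices],
                  comments=["knot=3.1- delta_lk=None seed=7"])
    frames = fio.read_xyz(path)
    assert len(frames) == 1
    verts, meta = frames[0]
    assert np.abs(verts - ring.vertices).max() < 1e-12
    assert meta["knot"] == "3.1-"


def test_xyz_malformed_raises(tmp_path):
    p = tmp_path / "bad.xyz"
    p.write_text("notanumber\ncomment\n")
    with pytest.raises(ValueError):
        fio.read_xyz(p)


def test_ensemble_xyz_and_csv(tmp_path, params_small):
    ens = pm.mc_sample(params_small, "0.1", n_samples=4, rng_seed=2,
                       check_knot=False, equilibration=200)
    fio.write_xyz(tmp_path / "ens.xyz", ens)
    frames = fio.read_xyz(tmp_path / "ens.xyz")
    assert len(frames) == 4
    assert frames[0][1]["seed"] == "2"
    fio.write_ensemble_csv(tmp_path / "ens.csv", ens)
    import pandas as pd
    df = pd.read_csv(tmp_path / "ens.csv")
    assert list(df.columns) == ["sample", "bend_energy_kT", "writhe", "knot"]
    assert len(df) == 4


def test_rates_json_roundtrip(tmp_path):
    from knotflux.topoii_model import RateEstimate
    s = tn.TopoState.from_string
    est = RateEstimate(state=s("3.1-@-2"), j=0.01,
                       q={s("0.1@+0"): 0.75, s("5.1-@-4"): 0.25},
                       n_conformations=1000, n_juxtaposed=10,
                       se_j=0.003, se_q={s("0.1@+0"): 0.1})
    fio.write_rates_json(tmp_path / "r.json", [est], meta={"seed": 1})
    back = fio.read_rates_json(tmp_path / "r.json")[0]
    assert str(back.state) == "3.1-@-2"
    assert back.j == est.j
    assert {str(k): v for k, v in back.q.items()} == \
        {str(k): v for k, v in est.q.items()}
    assert back.n_juxtaposed == 10


def test_network_json_roundtrip_preserves_conservation(tmp_path):
    net = fio.toy_network("chain_with_source", ks=3.0)
    fio.write_network_json(tmp_path / "net.json", net)
    back = fio.read_network_json(tmp_path / "net.json")
    assert [str(s) for s in back.states] == [str(s) for s in net.states]
    w = back.generator_matrix()
    assert np.allclose(w.sum(axis=0), 0.0, atol=1e-13)
    assert back.source is not None and back.source[2] == 3.0


def test_ness_json_roundtrip(tmp_path):
    net = fio.toy_network("three_cycle")
    res = tn.steady_state(net)
    fio.write_ness_json(tmp_path / "ness.json", res)
    back = fio.read_ness_json(tmp_path / "ness.json")
    assert np.allclose(back.p_star, res.p_star)
    assert back.currents[(net.states[0], net.states[1])] == \
        pytest.approx(1 / 3, abs=1e-12)


def test_dot_export_contains_edges(tmp_path):
    a, b, c = (tn.TopoState.from_string(s) for s in ("0.1", "5.1-", "3.1-"))
    net = tn.TransitionNetwork([a, b, c], {(b, c): 1.0, (c, a): 1.0})
    lim = tn.limit_source_current(net, a, b)
    g = tn.extract_pathways(lim.result, lim.source_current)
    fio.write_pathways_dot(tmp_path / "p.dot", g)
    text = (tmp_path / "p.dot").read_text()
    assert text.count("->") == g.number_of_edges() == 3
    assert "digraph" in text


def test_params_yaml_roundtrip(tmp_path):
    par = pm.ChainParameters(n_bp=4200, delta_lk=-4)
    fio.save_params(tmp_path / "p.yaml", par)
    back = fio.load_params(tmp_path / "p.yaml")
    assert back == par


def test_shipped_reference_rates_load():
    """The cached reduced-sampling rate table parses and builds a valid,
    conservation-respecting network."""
    from importlib import resources
    from knotflux import topoii_model as tm
    with resources.as_file(resources.files("knotflux.data")
                           / "reference_rates.json") as path:
        ests = fio.read_rates_json(path)
    assert len(ests) == 5
    for est in ests:
        assert 0.0 <= est.j <= 1.0
        if est.n_juxtaposed:
            assert sum(est.q.values()) == pytest.approx(1.0, abs=1e-9)
    have = {str(e.state) for e in ests}
    full = ests + [tm.mirror_estimate(e) for e in ests
                   if str(e.state.mirror()) not in have]
    sink = tn.TopoState.from_string("0.1")
    net = tn.build_network(full, keep_absorbing=(sink,))
    assert sink in net.states
    assert np.allclose(net.generator_matrix().sum(axis=0), 0.0, atol=1e-15)
    assert tn.validate_one_passage(net) == []
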