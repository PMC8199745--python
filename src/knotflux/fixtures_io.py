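"""Deterministic knot fixtures, toy networks, and file I/O.

Fixture polygons (circle, torus knots, figure-eight, rational knots via
4-plats) realize knots of known type for tests and as Monte Carlo starting
conformations.  Toy transition networks with closed-form steady states
exercise the master-equation solver.  File formats are plain text: extended
XYZ for conformations, CSV for ensemble summaries, JSON for rate tables and
networks, DOT for pathway graphs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import _curves
from . import knot_invariants as ki
from .polymer_mc import ChainParameters, Ensemble, RingConformation
from .topo_network import (SteadyStateResult, TopoState, TransitionNetwork)
from .topoii_model import RateEstimate

__all__ = [
    "FixtureSpec", "make_fixture", "toy_network",
    "write_xyz", "read_xyz", "write_ensemble_csv",
    "write_rates_json", "read_rates_json",
    "write_network_json", "read_network_json",
    "write_ness_json", "read_ness_json", "write_pathways_dot",
    "load_params", "save_params",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parametric fixture request: circle, torus_knot(p,q,handedness),
    figure_eight, or a rational knot label present in the built-in table."""

    name: str
    p: int = 2
    q: int = 3
    handedness: str = "-"
    n_vertices: int = 120
    scale: float = 1.0


def make_fixture(spec: FixtureSpec | str, n_vertices: int | None = None,
                 scale: float | None = None) -> RingConformation:
    """Closed polygon of the requested knot type; raises ValueError when the
    requested resolution is too coarse to preserve the knot."""
    if isinstance(spec, str):
        spec = FixtureSpec(name=spec,
                           n_vertices=n_vertices or 120,
                           scale=scale or 1.0)
    name = spec.name
    if name == "circle":
        curve = _curves.circle_curve(spec.n_vertices)
        expect = "0.1"
    elif name == "torus_knot":
        if math.gcd(spec.p, spec.q) != 1:
            raise ValueError("torus knot requires gcd(p, q) = 1")
        curve = _curves.torus_knot_curve(
            spec.p, spec.q, spec.n_vertices,
            right_handed=(spec.handedness == "+"))
        expect = f"{spec.q}.1{spec.handedness}" if spec.q > 1 else "0.1"
    elif name == "figure_eight":
        curve = _curves.figure_eight_curve(spec.n_vertices)
        expect = "4.1"
    elif name.replace("+", "").replace("-", "") in _curves.RATIONAL_KNOTS:
        base = name.replace("+", "").replace("-", "")
        cf = _curves.RATIONAL_KNOTS[base][0]
        curve = _curves.plat_curve(cf)
        got = str(ki.classify_knot(curve, seed=3))
        want = name if name[-1] in "+-" else name
        if got != want and name[-1] in "+-":
            curve = _curves.plat_curve(cf, mirror=True)
        expect = name
    else:
        raise ValueError(f"unknown fixture {name!r}")
    if spec.n_vertices != curve.shape[0]:
        from .polymer_mc import _march_equal_chords
        curve = _march_equal_chords(curve, spec.n_vertices)
    curve = curve * spec.scale
    got = ki.classify_knot(curve, seed=3)
    want = ki.KnotType.from_string(expect)
    if str(got) != str(want):
        raise ValueError(
            f"fixture resolution too coarse: requested {want}, got {got} "
            f"at n_vertices={spec.n_vertices}")
    return RingConformation(curve)


def toy_network(name: str, **kwargs) -> TransitionNetwork:
    """Hand-specified networks with known analytic steady states."""
    A = TopoState(ki.KnotType.from_string("0.1"))
    B = TopoState(ki.KnotType.from_string("3.1-"))
    C = TopoState(ki.KnotType.from_string("5.1-"))
    if name == "two_state":
        k12 = kwargs.get("k12", 2.0)
        k21 = kwargs.get("k21", 1.0)
        return TransitionNetwork([A, B], {(A, B): k12, (B, A): k21})
    if name == "three_cycle":
        r = kwargs.get("rate", 1.0)
        return TransitionNetwork(
            [A, B, C], {(A, B): r, (B, C): r, (C, A): r})
    if name == "chain_with_source":
        ks = kwargs.get("ks", 10.0)
        r = kwargs.get("rate", 1.0)
        net = TransitionNetwork(
            [A, B, C], {(B, A): r, (C, B): r, (B, C): 0.1 * r})
        from .topo_network import add_source
        return add_source(net, A, C, ks)
    raise ValueError(f"unknown toy network {name!r}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_xyz(path, conformations, comments=None) -> None:
    """Extended XYZ: one frame per conformation; the comment line carries
    key=value metadata (knot label, delta_lk, seed)."""
    if isinstance(conformations, RingConformation):
        conformations = [conformations.vertices]
    elif isinstance(conformations, Ensemble):
        ens = conformations
        conformations = [ens.conformations[k] for k in range(ens.n_samples)]
        if comments is None:
            meta = f"knot={ens.knot_type} delta_lk={ens.delta_lk} " \
                   f"seed={ens.rng_seed}"
            comments = [meta] * len(conformations)
    with open(path, "w") as fh:
        for k, verts in enumerate(conformations):
            verts = np.asarray(getattr(verts, "vertices", verts))
            fh.write(f"{verts.shape[0]}\n")
            c = "" if comments is None else comments[k]
            fh.write(c + "\n")
            for v in verts:
                fh.write(f"C {float(v[0])!r} {float(v[1])!r} "
                         f"{float(v[2])!r}\n")


def read_xyz(path) -> list[tuple[np.ndarray, dict]]:
    """Frames of an extended XYZ file as (vertices, metadata) pairs."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"malformed XYZ at line {i + 1}: {exc}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = {}
        for tok in comment.split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        verts = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(f"malformed XYZ at line {i + 3 + k}")
            verts[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append((verts, meta))
        i += n + 2
    return frames


def write_ensemble_csv(path, ensemble: Ensemble) -> None:
    rows = []
    for k in range(ensemble.n_samples):
        rows.append({"sample": k,
                     "bend_energy_kT": ensemble.bend_energies[k],
                     "writhe": ensemble.writhes[k],
                     "knot": str(ensemble.knot_type)})
    pd.DataFrame(rows).to_csv(path, index=False)


def _estimate_to_dict(est: RateEstimate) -> dict:
    return {
        "state": str(est.state), "j": est.j,
        "q": {str(s): v for s, v in est.q.items()},
        "n_conformations": est.n_conformations,
        "n_juxtaposed": est.n_juxtaposed,
        "n_ambiguous": est.n_ambiguous,
        "se_j": est.se_j,
        "se_q": {str(s): v for s, v in est.se_q.items()},
    }


def _estimate_from_dict(d: dict) -> RateEstimate:
    return RateEstimate(
        state=TopoState.from_string(d["state"]), j=d["j"],
        q={TopoState.from_string(s): v for s, v in d["q"].items()},
        n_conformations=d["n_conformations"],
        n_juxtaposed=d["n_juxtaposed"],
        n_ambiguous=d.get("n_ambiguous", 0), se_j=d.get("se_j", 0.0),
        se_q={TopoState.from_string(s): v
              for s, v in d.get("se_q", {}).items()},
        flagged_zero=(d["n_juxtaposed"] == 0))


def write_rates_json(path, estimates, meta: dict | None = None) -> None:
    payload = {"meta": meta or {},
               "estimates": [_estimate_to_dict(e) for e in estimates]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_rates_json(path) -> list[RateEstimate]:
    with open(path) as fh:
        payload = json.load(fh)
    return [_estimate_from_dict(d) for d in payload["estimates"]]


def write_network_json(path, net: TransitionNetwork) -> None:
    payload = {
        "states": [str(s) for s in net.states],
        "rates": [{"from": str(a), "to": str(b), "k": k}
                  for (a, b), k in sorted(net.rates.items(),
                                          key=lambda kv: (str(kv[0][0]),
                                                          str(kv[0][1])))],
    }
    if net.source is not None:
        a, b, ks = net.source
        payload["source"] = {"from": str(a), "to": str(b), "ks": ks}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_network_json(path) -> TransitionNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    states = [TopoState.from_string(s) for s in payload["states"]]
    rates = {}
    for r in payload["rates"]:
        rates[(TopoState.from_string(r["from"]),
               TopoState.from_string(r["to"]))] = float(r["k"])
    src = None
    if "source" in payload:
        s = payload["source"]
        src = (TopoState.from_string(s["from"]),
               TopoState.from_string(s["to"]), float(s["ks"]))
    return TransitionNetwork(states, rates, source=src)


def write_ness_json(path, result: SteadyStateResult,
                    extra: dict | None = None) -> None:
    payload = {
        "states": [str(s) for s in result.states],
        "p_star": [float(p) for p in result.p_star],
        "currents": {f"{a}->{b}": v for (a, b), v in result.currents.items()},
        "source_current": result.source_current,
        "residual": result.residual,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ness_json(path) -> SteadyStateResult:
    with open(path) as fh:
        payload = json.load(fh)
    states = [TopoState.from_string(s) for s in payload["states"]]
    currents = {}
    for key, v in payload["currents"].items():
        a, b = key.split("->")
        currents[(TopoState.from_string(a), TopoState.from_string(b))] = v
    return SteadyStateResult(
        states=states, p_star=np.array(payload["p_star"]),
        currents=currents, source_current=payload.get("source_current", 0.0),
        residual=payload.get("residual", 0.0))


def write_pathways_dot(path, graph) -> None:
    """Pathway digraph as DOT: nodes annotated with P*, edges with the
    current ratio; dominant edges drawn solid, subdominant dashed."""
    lines = ["digraph pathways {"]
    for node, data in graph.nodes(data=True):
        label = f"{node}\\nP*={data.get('p_star', 0.0):.3g}"
        lines.append(f'  "{node}" [label="{label}"];')
    for a, b, data in graph.edges(data=True):
        style = "solid" if data.get("klass") == "dominant" else "dashed"
        lines.append(
            f'  "{a}" -> "{b}" [style={style}, '
            f'label="{data.get("ratio", 0.0):.2f}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def save_params(path, params: ChainParameters) -> None:
    d = {
        "n_bp": params.n_bp, "rise_per_bp": params.rise_per_bp,
        "segment_length": params.segment_length,
        "persistence_length": params.persistence_length,
        "effective_diameter": params.effective_diameter,
        "twist_rigidity": params.twist_rigidity,
        "helical_repeat": params.helical_repeat,
        "delta_lk": params.delta_lk,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def load_params(path) -> ChainParameters:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ChainParameters(**d)
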