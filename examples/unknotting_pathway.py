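"""Unknotting pathway of a continuously injected source knot.

Loads the shipped reduced-sampling rate table (hairpin-gate juxtaposition
frequencies j(K) and product distributions Q(K'|K)), completes mirror
states by symmetry, injects a 5.1- source knot at the large-rate limit,
and prints the non-equilibrium steady state and the dominant unknotting
pathway.  The source current iS_inf is the number of molecules per unit
time (in units of k0 c0) cycling source -> simpler knots -> unknot.
"""

from importlib import resources

from knotflux import fixtures_io as fio
from knotflux import topo_network as tn
from knotflux import topoii_model as tm

with resources.as_file(resources.files("knotflux.data")
                       / "reference_rates.json") as path:
    ests = fio.read_rates_json(path)
have = {str(e.state) for e in ests}
ests += [tm.mirror_estimate(e) for e in ests
         if str(e.state.mirror()) not in have]

sink = tn.TopoState.from_string("0.1")
net = tn.build_network(ests, keep_absorbing=(sink,))
# inject the most complex knot whose rates are resolved in the table
source = max((s for s in net.states if s != sink),
             key=lambda s: s.knot.crossing_number)
lim = tn.limit_source_current(net, "0.1", source)
res = lim.result

print("states and NESS probabilities (large-kS limit):")
for s, p in sorted(res.as_dict().items(), key=lambda kv: -kv[1]):
    if p > 1e-6:
        print(f"  {s!s:8s} P* = {p:.4f}")
print(f"\nlimit source current iS = {lim.source_current:.3e} (k0 c0 units)")

graph = tn.extract_pathways(res, lim.source_current)
print("dominant unknotting pathway (i*/iS > 0.1 solid, > 0.05 dashed):")
for a, b, data in graph.edges(data=True):
    mark = "==>" if data["klass"] == "dominant" else "-->"
    print(f"  {a!s:8s} {mark} {b!s:8s}  i*/iS = {data['ratio']:.2f}")
print(f"\nThe injected {source} decays stepwise towards the unknot: "
      "each arrow is a single enzyme-mediated strand passage.")
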