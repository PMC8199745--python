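"""Equilibrium knot spectrum of a nicked DNA circle by phantom sampling.

Equilibrium-segment-passage (ESP) sampling omits the topology check, so
chain segments pass freely through one another and the ring equilibrates
over knot types.  Classifying the stored samples yields the thermal
equilibrium knot probabilities, and -ln Peq(K)/Peq(0.1) is the knotting
free energy in kBT.  Excluded volume is switched off here to make knots
common enough for a quick demonstration.
"""

from knotflux import polymer_mc as pm
from knotflux import topoii_model as tm
from knotflux import topo_network as tn
from knotflux import knot_invariants as ki

params = pm.ChainParameters(n_bp=4000, effective_diameter=0.0)
spec = tm.esp_equilibrium(params, n_samples=600, rng_seed=7)

print(f"ESP ensemble: {params.n_bp} bp, N={params.n_segments}, "
      f"d={params.effective_diameter} (phantom chain), "
      f"{spec.n_samples} samples\n")
probs = {ki.KnotType.from_string(k): v
         for k, v in spec.probabilities().items()}
free = tn.equilibrium_free_energy(probs)
print(f"{'knot':10s} {'count':>6s} {'Peq':>8s} {'F/kBT':>7s}")
for kt, p in sorted(probs.items(), key=lambda kv: -kv[1]):
    f = free[kt]
    print(f"{kt!s:10s} {spec.counts[str(kt)]:6d} {p:8.4f} {f:7.2f}")
print("\nKnotting costs several kBT even without excluded volume; "
      "chiral knot pairs appear at equal rates within sampling error.")
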