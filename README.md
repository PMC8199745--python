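# knotflux

Non-equilibrium topological networks for DNA-topology simplification by
type-II topoisomerases.

Type-II topoisomerases pass one DNA double helix through a transient break
in another, changing the knot type K of a circular DNA and its linking
difference ΔLk in steps of two.  Using ATP, they hold knotting and
supercoiling *below* thermodynamic equilibrium ("topology simplification")
— remarkable because an enzyme far smaller than the DNA cannot see the
global knot type.  The accepted explanation is geometric: the enzyme bends
its bound "gate" (G) segment into a hairpin and only passes "transfer" (T)
segments that thread the hairpin from inside, which statistically biases
passages towards simpler topology.

`knotflux` implements this picture end to end for people who model DNA
topology:

* **`polymer_mc`** — Metropolis Monte Carlo of a closed, discrete wormlike
  chain (N segments of length b, bending stiffness calibrated to the
  persistence length P, hard-cylinder excluded volume d, optional harmonic
  twist energy `2π²(C/L)(ΔLk − Wr)²` with ΔTw = ΔLk − Wr by White's
  relation).  Crankshaft moves preserve edge lengths exactly; the knot
  type is held fixed by rejecting strand-passing trials.
* **`knot_invariants`** — knot identification for closed polygons:
  Koniaris–Muthukumar reduction, signed crossing diagrams, exact writhe
  (Gauss integral in closed form), Alexander polynomial/determinants, and
  HOMFLY (skein convention `a P(L+) − a⁻¹ P(L−) = z P(L0)`) for chirality.
* **`topoii_model`** — the hairpin G segment (a 120° bend across four
  chain edges), juxtaposition detection at the gate triangle, virtual
  strand passage, and the resulting rates `k(K,K′) = k0 · j(K) · Q(K′|K)`
  where j is the juxtaposition frequency and Q the conditional product
  distribution.  Equilibrium-segment-passage (ESP) sampling — no topology
  check, segments pass freely — gives the equilibrium knot spectrum.
* **`topo_network`** — the chemical master equation `dP/dt = W P` over
  states K or (K, ΔLk): steady states (null vector of W), probability
  currents `i*(a→b) = P*(a)k(a,b) − P*(b)k(b,a)`, detailed-balance
  residuals, source-knot injection with the large-rate limit, and
  extraction of unknotting pathways (states carrying ≥5% of the source
  current; dominant edges above 10%).
* **`fixtures_io`** — parametric knot fixtures (torus knots, figure-eight,
  rational knots as 4-plats), toy networks with closed-form steady states,
  and plain-text I/O (XYZ conformations, CSV summaries, JSON rate tables
  and networks, DOT pathway graphs).

## Worked example

Equilibrium knotting of a nicked 4-kbp circle without excluded volume
(`python examples/equilibrium_spectrum.py`):

```
ESP ensemble: 4000 bp, N=136, d=0.0 (phantom chain), 600 samples

knot        count      Peq   F/kBT
0.1           590   0.9833   -0.00
3.1-            4   0.0067    4.99
3.1+            4   0.0067    4.99
4.1             2   0.0033    5.69
```

The two trefoil chiralities appear at equal rates within sampling error,
and each added crossing costs roughly another kBT of knotting free energy.
At the standard conditions (6 kbp, b = 10 nm, d = 5 nm) the same ESP
pipeline at 12000 samples gives

```
Peq(3.1-)/Peq(0.1) = 0.0050 ± 0.0006
```

i.e. about one DNA circle in 200 carries a left-handed trefoil at
equilibrium — the quantity the enzyme network is measured against.
Injecting a 5.1- source knot into the hairpin-rate network
(`python examples/unknotting_pathway.py`) prints the stepwise pathway
`5.1- ==> 3.1- ==> 0.1` with the fraction of the source current carried by
each passage.

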