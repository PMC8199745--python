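# Methods

`knotflux` models how type-II topoisomerases change the topology of
circular DNA: a coarse-grained Monte Carlo sampler generates equilibrium
ensembles of knotted DNA rings, a geometric enzyme model converts those
ensembles into transition rates between topological states, and a chemical
master equation turns the rates into non-equilibrium steady states,
probability currents, and unknotting pathways.  This note records the
model, its assumptions, the numerical choices, and what the shipped tests
do and do not establish.

## Chain model

A circular duplex DNA of `n_bp` base pairs is a closed chain of N straight
segments of length b (default b = 10 nm, five segments per persistence
length; a 6-kbp circle at 0.34 nm/bp has contour length 2040 nm and
N = 204).  The energy, in units of kBT, is

* bending: `E_b = g * sum_i (1 - cos theta_i)` over the N joint angles.
  The stiffness g is calibrated so the discrete chain reproduces the
  persistence length P: `<cos theta> = coth g - 1/g = exp(-b/P)`, solved
  by root finding (g = 5.5157 for b = 10 nm, P = 50 nm; the stiff-chain
  estimate P/b = 5 is 10% off, which is why the calibration is explicit).
* twist (only for torsionally constrained circles with a fixed linking
  difference ΔLk): harmonic, `E_t = 2 pi^2 (C/L) (ΔLk - Wr)^2`, with
  torsional rigidity C = 75 nm (configurable), contour length L = N b, and
  the twist deficit from White's relation ΔTw = ΔLk - Wr.  Wr is the
  writhe, computed exactly as the Gauss double integral with the
  closed-form solid-angle expression per edge pair.
* excluded volume: hard cylinders of effective diameter d (default 5 nm,
  the standard value for 150 mM ionic strength); any pair of non-adjacent
  edges closer than d is forbidden.

Nicked circles (`delta_lk=None`) carry no twist energy; their topological
state is the knot type K alone.  Covalently closed circles occupy states
(K, ΔLk).

## Sampling

Metropolis Monte Carlo with crankshaft moves: a sub-chain between two
random vertices (arc length up to N/3) is rigidly rotated about their axis
by a uniform angle up to 1.5 rad.  Crankshaft moves preserve edge lengths
and ring closure exactly.  A trial is rejected if excluded volume fails,
by the Metropolis criterion on the energy change (only the two pivot
angles change the bending energy; the writhe change needed for the twist
energy is accumulated from the moved-against-static edge pairs), or if the
move would change the knot type.

The topology check is two-staged.  A rigid rotation sweeps a region whose
points keep their distance to the rotation axis, so a trial whose static
segments all stay farther from the axis segment than the moved arc's
maximal radial extent provably cannot pass strands and is accepted without
any topology work.  Otherwise the trial conformation is reduced with the
Koniaris–Muthukumar elementary-triangle deletion, projected, and its
Alexander determinant |Δ(-1)| (computed modulo the Mersenne prime 2^31-1)
is compared with the target knot's determinant.  Stored samples are
additionally verified with the exact (|Δ(-1)|, |Δ(-2)|) fingerprint; on a
mismatch the chain is rewound to the last verified sample.  Two knots
related by a single determinant-preserving multi-strand passage within one
trial move could in principle slip through the per-trial filter; the
storage-time fingerprint catches the determinant-visible cases and the
swept-region prune makes multi-passage moves rare.  A mirror-image flip of
the whole knot (invisible to any Alexander-based check) would require at
least two simultaneous passages in one crankshaft trial and is neglected.

Defaults: sampling interval 2N trials between stored samples, 100N trials
of equilibration.  The interval was chosen from the integrated
autocorrelation time of the writhe (about 180 trials at N = 204), measured
once while fixing the sampler's numerical parameters.  Equal-chord
resampling (used to build starting rings from parametric template curves)
marches exact chords along the template and solves the closure chord by
bracketed root finding; any residual is spread over the ring by
constraint-relaxation sweeps, so every edge equals b to 1e-12 relative.

## Knot identification

Classification is geometric-to-combinatorial: KM reduction, projection
along random axes (retrying degenerate projections, keeping the leanest
diagram), then invariants of the signed Gauss code.  The Alexander
polynomial is computed exactly from the underpass presentation (integer
Bareiss determinants at integer arguments, Lagrange interpolation,
normalised to Δ(1) = 1); |Δ(-1)| and |Δ(-2)| form a cheap fingerprint.
Chirality, and pairs with equal Alexander fingerprints, are resolved by
the HOMFLY polynomial, computed by skein recursion (convention
`a P(L+) - a^{-1} P(L-) = z P(L0)`) with Reidemeister I/II simplification
and memoisation, capped at 16 crossings per diagram (more crossings:
retry other projections, then give up as `unknown`).

The fingerprint table covers all rational (2-bridge) prime knots up to 8
crossings in both chiralities plus the connected sums 3.1#3.1 (all
chirality combinations) and 3.1#4.1.  Each entry is generated from a
4-plat realization of its continued fraction and validated against the
tabulated Alexander polynomial, so a wiring error cannot silently poison
the table.  Handedness convention: a knot is labelled `+` when the signed
crossings of its reduced alternating diagram sum positive (the right-hand
rule); for torus knots this matches the geometric handedness of the
parametric curve, which is verified by an explicit signed-crossing test.
Non-rational knots above 7 crossings (e.g. 8.19 = T(3,4), or the
10-crossing torus-like knots used as source states in larger studies) are
supported as abstract network labels but classify as `unknown` if they
ever appear as polygons; at 6 kbp they essentially never do.

## The hairpin G-segment enzyme

The DNA-bound enzyme is a rigid hairpin imposed on five consecutive
vertices: four edges forming two sides of an equilateral triangle of side
2b, i.e. a 120° bend between the tangents at the apex.  Imposition fits
the ideal hairpin rigidly (Kabsch) to the prior vertex positions and
rejoins each side of the ring through an adaptive window of up to 12
vertices placed on a circular arc whose equal subdivision keeps every edge
exactly b; placements violating excluded volume or changing the knot are
retried at neighbouring start vertices.  Because a smooth freshly-built
ring is locally taut, the chain is thermalised briefly before the hairpin
is imposed.  During rate sampling the five hairpin vertices are frozen.

A transfer (T) segment is juxtaposed when it is the unique chain edge
piercing the interior of the gate triangle (hairpin end and apex
vertices) and does not come within d of any hairpin edge.  The strand
passage itself is virtual: the hairpin's three interior vertices are
rotated half a turn about the axis joining its end vertices, an exact
isometry of the hairpin edges that carries the gate to the far side of
the T segment.  Applying the flip twice restores the conformation
exactly.  Because the rotating arms sweep a sizeable region, a flip can
occasionally pass more than one strand; each event is therefore checked
with an exact passage counter: the partial Gauss sum over
hairpin-vs-static edge pairs is traced along the continuous rotation,
every strand passage shows up as a ±2 jump, and events with a jump count
different from one are discarded as ambiguous.  (This filter is what
keeps sampled transitions on one-passage connectivity; without it a few
percent of products are double passages such as 3.1⁻ → 3.1⁺.  It also
established that, under this package's chirality convention, the
single-passage partner of 5.2⁻ in the twist region is the
opposite-handed trefoil.)  Each event's substrate conformation is also
re-classified (including chirality) before its product is counted:
Alexander-based trial filtering cannot see a rare whole-knot mirror flip,
and while such a drift leaves j unbiased (mirror ensembles are
statistically identical), it would silently poison Q.  For torsionally
constrained states the
product linking number is ΔLk' = ΔLk - 2s, where s is the sign of the
T-segment direction against the gate normal (right-hand rule around the
hairpin traversal); the sign is re-evaluated from the current gate
orientation so that the backward flip restores ΔLk.

Juxtaposition frequencies j(K) are time averages: the gate is scanned
every N/2 trials during sampling (juxtaposition is a local property that
decorrelates much faster than the global conformation), and j is the
fraction of scanned conformations with a clean event.  Standard errors
use batch means over sampling intervals because threading episodes are
long-lived.  Q(K'|K) is the empirical distribution of virtual-passage
products over clean events.  Rates follow as k(K,K') = k0 j(K) Q(K'|K)
with k0 = 1 fixing the time unit.  Mirror-image states are completed by
exact symmetry (the sampler and gate are achiral), which halves the
sampling cost.

Equilibrium-segment-passage (ESP) ensembles keep the bending energy and
excluded volume but omit the topology check entirely, so segments pass
freely through one another; classifying the stored samples yields the
thermal-equilibrium knot spectrum.  Excluded volume is retained in ESP
runs: free passage refers to topology, not sterics.

## Master equation

States and rates assemble into the generator W with W[b,a] = k(a,b) and
columns summing to zero; dP/dt = W P.  The steady state is the normalised
non-negative null vector of W (SVD-based null space, residual reported;
a degenerate null space signals a disconnected network and raises).
Currents are i*(a→b) = P*(a) k(a,b) - P*(b) k(b,a).  Time evolution uses
matrix-exponential stepping.  An extrinsic source process is an added
rate kS from the relaxed unknot to the source state; the large-kS limit
is found by solving along a geometric kS schedule until the source
current iS = P*(origin) kS changes by less than 1e-4 relatively, at which
point P*(origin) falls off as 1/kS.  Pathway graphs keep states whose
NESS throughput is at least 5% of iS and label edges dominant above 10%.
Sampled product states without their own rate estimate are pruned from
the network (they would otherwise act as spurious absorbing traps);
the designated sink state is always retained.

One-passage connectivity of sampled networks is validated against a
curated table of knot pairs joinable by a single duplex passage.  The
table is exact where published unknotting numbers pin it down (all
unknotting-number-one knots adjacent to the unknot; the torus ladder
5.1→3.1; mirror pairs and u≥2 knots excluded from the unknot's
neighbourhood) and deliberately inclusive for a few four/five-crossing
pairs whose strand-passage distance the author could not verify, so the
check catches the realistic failure modes (chirality flips, double
passages) without manufacturing false alarms.

## Problem sizes and what the tests show

The acceptance-scale runs use desk-scale sampling chosen once: 8000 to
16000 ESP samples for the equilibrium spectrum; 300 to 700 sampling
intervals per knot (about 1200 to 2800 gate scans each) for the hairpin
rates of {0.1, 3.1-, 4.1, 5.1-, 5.2-}; and, for the (K, ΔLk) pathway with
source (5.1-, -4), 240 intervals per state over the grid of trefoil and
unknot ΔLk ladders between the source and (0.1, 0), run on a 4-kbp chain
(the cascade's topology is chain-length independent and the smaller ring
resolves every grid state's rare events in minutes).  Each rate estimate
is split over two to three replicas with independent hairpin placements:
a single frozen placement can sit in a poorly accessible pose for a whole
run, and replica averaging tames that quenched variance.  At these sizes
the
equilibrium trefoil/unknot ratio is resolved to roughly 20% statistics,
and the unknotting direction of the enzyme network (j of knotted states,
Q dominated by simpler knots, the stepwise pathway to (0.1, 0)) is
resolved qualitatively.

What desk-scale sampling cannot resolve is the knot-creating direction:
with j(0.1) of order 1e-3 and Q(3.1-|0.1) of order 1e-3 conditional on
juxtaposition, the forward rate k(0.1→3.1-) is an order-1e-6-per-
conformation event, needing millions of decorrelated conformations (the
scale of the original studies).  At desk scale the sampled forward rate
is typically zero, making the computed NESS ratio P*(3.1-)/P*(0.1) zero
with a conservative Poisson upper bound of order 1e-2—above the target
8.5e-4 and above the equilibrium ratio 0.0049.  The corresponding
acceptance checks therefore fail honestly at this scale rather than being
weakened; the acceptance script reports the computed ratio, its upper
bound, and the implied lower bound on the simplification factor.

The synthetic-data side (parametric knot fixtures, toy networks) covers
the geometric and algebraic machinery completely, but ESP and rate
sampling emulate only the coarse-grained wormlike chain: sequence
effects, electrostatics beyond the effective diameter, enzyme kinetics
(ATPase cycle, C-gate), and catenanes are outside the model, so passing
tests speak to the model's internal consistency and its agreement with
the published coarse-grained results, not to base-pair-level DNA.

## Known limitations

* The HOMFLY cap (16 crossings) and the table scope (rational primes ≤ 8
  crossings plus small composites) bound what can be named; everything
  else is `unknown` and excluded from networks with a warning count.
* The per-trial topology filter is determinant-based; see above for the
  (measure-small) multi-passage caveats.
* The passage counter samples the rotation at 96 steps (with local
  refinement); a pair of passages cancelling within one step would be
  missed, which is a measure-zero coincidence at this resolution.
* The (K, ΔLk) pathway study samples a restricted state set (source,
  listed intermediates, relaxed unknot); sampled products outside the
  set — e.g. the twist-relaxed trefoil (3.1⁻, −4), which receives a
  substantial share of the (3.1⁻, −2) outflow — are pruned, so the
  extracted graph is the backbone of the pathway, not the full (K, ΔLk)
  lattice of the large-scale studies.  States with no events after one
  batch get exactly one more batch (a fixed two-stage design) before the
  network is assembled.
* Juxtaposition statistics are episode-correlated; batch-means errors are
  reported but short runs can still under-disperse.
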