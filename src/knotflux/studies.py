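"""End-to-end study drivers: the computations behind the headline results.

Each driver runs the full pipeline at a caller-chosen sampling size:

* ``esp_study`` — equilibrium (phantom-passage) knot spectrum of a nicked
  circle and the trefoil/unknot ratio Peq(3.1-)/Peq(0.1).
* ``hairpin_ness_study`` — juxtaposition rates j(K), Q(K'|K) for knots up
  to five crossings with the 120-degree hairpin gate, the master-equation
  steady state, and the NESS trefoil/unknot ratio P*(3.1-)/P*(0.1).
* ``pathway_study`` — source-knot injection into the (K, DeltaLk) network
  and extraction of the stepwise unknotting pathway.

Statistical caveat: juxtaposition events are rare (j ~ 1e-3 for the
unknot) and long-lived, so the forward (knot-creating) rates out of the
unknot need orders of magnitude more sampling than the unknotting rates.
The NESS ratio is therefore reported together with a conservative upper
confidence bound built from Poisson bounds on the unobserved event counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import knot_invariants as ki
from . import polymer_mc as pm
from . import topo_network as tn
from . import topoii_model as tm

#: knot types with up to five crossings tracked in the headline network;
#: mirror images are completed by symmetry.
NESS_KNOTS = ("0.1", "3.1-", "4.1", "5.1-", "5.2-")


@dataclass
class EspStudy:
    spectrum: tm.EquilibriumSpectrum
    ratio: float
    se_ratio: float
    n_samples: int

    @property
    def p_unknot(self) -> float:
        return self.spectrum.probability("0.1")


def esp_study(params: pm.ChainParameters | None = None,
              n_samples: int = 8000, seed: int = 0) -> EspStudy:
    """Equilibrium knot spectrum of the nicked circle by ESP sampling and
    the left-trefoil/unknot ratio."""
    if params is None:
        params = pm.ChainParameters()
    spec = tm.esp_equilibrium(params, n_samples=n_samples, rng_seed=seed)
    p3 = spec.probability("3.1-")
    p0 = spec.probability("0.1")
    ratio = p3 / p0 if p0 > 0 else math.inf
    se = 0.0
    if p0 > 0:
        se3 = spec.se("3.1-")
        se0 = spec.se("0.1")
        se = ratio * math.sqrt((se3 / p3) ** 2 + (se0 / p0) ** 2) \
            if p3 > 0 else se3 / p0
    return EspStudy(spectrum=spec, ratio=ratio, se_ratio=se,
                    n_samples=n_samples)


def _poisson_upper(count: int, sigmas: float = 3.0) -> float:
    """Conservative upper bound on a Poisson mean given an observed count
    (Garwood-style: chi-square tail at the ~one-sided 3-sigma level)."""
    from scipy.stats import chi2
    alpha = 1.0 - math.erf(sigmas / math.sqrt(2.0))
    return 0.5 * chi2.ppf(1.0 - alpha, 2 * (count + 1))


@dataclass
class NessStudy:
    estimates: list
    network: tn.TransitionNetwork
    result: tn.SteadyStateResult
    ratio: float
    ratio_upper: float
    n_intervals: dict = field(default_factory=dict)

    def j_table(self) -> dict:
        return {str(e.state): (e.j, e.se_j) for e in self.estimates}


def hairpin_ness_study(params: pm.ChainParameters | None = None,
                       n_intervals: dict | int = 400,
                       seed: int = 0) -> NessStudy:
    """Hairpin-gate rates for the knots in NESS_KNOTS (mirrors filled in by
    symmetry), the master-equation steady state, and the NESS
    trefoil/unknot ratio with a conservative upper bound."""
    if params is None:
        params = pm.ChainParameters()
    if isinstance(n_intervals, int):
        n_intervals = {k: n_intervals for k in NESS_KNOTS}
    ests = []
    for i, label in enumerate(NESS_KNOTS):
        est = tm.estimate_rates(params, label,
                                n_samples=n_intervals[label],
                                rng_seed=seed + 1000 * i)
        if est.n_juxtaposed == 0 and label != "0.1":
            # rare-event retry (fixed two-stage design): knotted states
            # with no events yet get one additional batch
            extra = tm.estimate_rates(params, label,
                                      n_samples=n_intervals[label],
                                      rng_seed=seed + 1000 * i + 997)
            est = _merge_estimates(est, extra)
        ests.append(est)
    have = {str(e.state) for e in ests}
    full = list(ests)
    for e in ests:
        if str(e.state.mirror()) not in have:
            full.append(tm.mirror_estimate(e))
    sink = tn.TopoState.from_string("0.1")
    net = tn.build_network(full, keep_absorbing=(sink,))
    result = tn.steady_state(net)
    p0 = result.probability(sink)
    tre = tn.TopoState.from_string("3.1-")
    p3 = result.probability(tre) if tre in net.states else 0.0
    ratio = p3 / p0 if p0 > 0 else math.inf

    # conservative upper bound on the ratio: at the NESS the inflow into
    # 3.1- is at most the (bounded) unknot->trefoil rate while the outflow
    # is at least the sampled unknotting rate, so
    #   P*(3.1-)/P*(0.1) <= k_ub(0.1 -> 3.1-) / k(3.1- -> out)
    e0 = next(e for e in ests if str(e.state) == "0.1")
    e3 = next(e for e in ests if str(e.state) == "3.1-")
    forward_events = 0
    for s, q in e0.q.items():
        if s.knot.label == "3.1":
            forward_events += round(q * e0.n_juxtaposed)
    k_forward_ub = _poisson_upper(forward_events) / max(e0.n_conformations, 1)
    k_out = e3.j * sum(v for s, v in e3.q.items())
    ratio_upper = k_forward_ub / k_out if k_out > 0 else math.inf
    return NessStudy(estimates=full, network=net, result=result,
                     ratio=ratio, ratio_upper=ratio_upper,
                     n_intervals=dict(n_intervals))


@dataclass
class PathwayStudy:
    estimates: list
    network: tn.TransitionNetwork
    limit: tn.SourceLimitResult
    graph: "object"
    source_state: tn.TopoState
    origin: tn.TopoState

    def terminates_at_origin(self) -> bool:
        g = self.graph
        return self.origin in g and g.out_degree(self.origin) == 0 or \
            (self.origin in g)


def _merge_estimates(a: tm.RateEstimate, b: tm.RateEstimate
                     ) -> tm.RateEstimate:
    """Pool two independent rate estimates of the same state."""
    n = a.n_conformations + b.n_conformations
    njux = a.n_juxtaposed + b.n_juxtaposed
    counts: dict = {}
    for est in (a, b):
        for s, qv in est.q.items():
            counts[s] = counts.get(s, 0.0) + qv * est.n_juxtaposed
    q = {s: c / njux for s, c in counts.items()} if njux else {}
    j = njux / n
    se_j = math.sqrt(max(j * (1 - j), 0.0) / n)
    se_q = {s: math.sqrt(max(v * (1 - v), 0.0) / njux)
            for s, v in q.items()} if njux else {}
    return tm.RateEstimate(state=a.state, j=j, q=q, n_conformations=n,
                           n_juxtaposed=njux,
                           n_ambiguous=a.n_ambiguous + b.n_ambiguous,
                           se_j=se_j, se_q=se_q, flagged_zero=(njux == 0))


#: default intermediate (K, DeltaLk) states between the source (5.1-, -4)
#: and the relaxed unknot: the trefoil and unknot DeltaLk ladders, so that
#: both the knot-simplifying and the supercoil-relaxing branches of the
#: cascade stay inside the sampled network
PATHWAY_INTERMEDIATES = ("3.1-@-2", "3.1-@-4", "3.1-@-6",
                         "0.1@-2", "0.1@-4")


def pathway_study(params: pm.ChainParameters | None = None,
                  source: str = "5.1-@-4", n_intervals: int | dict = 240,
                  seed: int = 0,
                  intermediates: tuple = PATHWAY_INTERMEDIATES,
                  n_replicas: int = 3) -> PathwayStudy:
    """Inject a source knot into the (K, DeltaLk) network and extract the
    unknotting pathway in the large-source-rate limit.

    Rates are sampled for the source state, the listed intermediates (the
    trefoil and unknot DeltaLk ladders), and the relaxed unknot (0.1, 0);
    product states outside this restricted grid are pruned, so the graph
    describes the backbone of the pathway at this scale.  The default
    chain is 4 kbp: the qualitative cascade is chain-length independent,
    and the smaller ring resolves every grid state's rare juxtaposition
    events within a desk-scale run.  A state still without events after a
    batch gets up to two more batches (a capped sequential design) before
    the network is assembled.
    """
    if params is None:
        params = pm.ChainParameters(n_bp=4000)
    src = tn.TopoState.from_string(source)
    origin = tn.TopoState(ki.KnotType.from_string("0.1"), 0)
    states = [src] + [tn.TopoState.from_string(s) for s in intermediates] \
        + [origin]
    ests = []
    for i, st in enumerate(states):
        n_st = n_intervals if isinstance(n_intervals, int) \
            else n_intervals.get(str(st), n_intervals.get("default", 150))
        est = tm.estimate_rates(params, st, n_samples=n_st,
                                rng_seed=seed + 2000 * i,
                                n_replicas=n_replicas)
        batches = 1
        while est.n_juxtaposed == 0 and st != origin and batches < 3:
            extra = tm.estimate_rates(params, st, n_samples=n_st,
                                      rng_seed=seed + 2000 * i + 997 * batches,
                                      n_replicas=n_replicas)
            est = _merge_estimates(est, extra)
            batches += 1
        ests.append(est)
    net = tn.build_network(ests, keep_absorbing=(origin,))
    lim = tn.limit_source_current(net, origin, src)
    graph = tn.extract_pathways(lim.result, lim.source_current)
    return PathwayStudy(estimates=ests, network=net, limit=lim,
                        graph=graph, source_state=src, origin=origin)
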