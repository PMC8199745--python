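"""Hairpin G-segment model of a type-II topoisomerase.

The DNA-bound enzyme is represented by a rigid hairpin imposed on five
consecutive chain vertices: four edges forming the two sides of an
equilateral triangle of side 2b, i.e. a 120-degree bend at the apex.  A
transfer (T) segment is juxtaposed when it pierces the interior of the
gate triangle spanned by the hairpin's end and apex vertices without
steric overlap.  A strand passage is performed virtually by rotating the
hairpin's interior vertices half a turn about the axis joining its end
vertices, which carries the gate to the far side of the T segment; the
product knot type is read off the deformed ring.

Juxtaposition frequencies j(K) and conditional product distributions
Q(K'|K), estimated over fixed-knot equilibrium ensembles, provide the
transition rates k(K,K') = k0 j(K) Q(K'|K) of the topological network.
Equilibrium-segment-passage (ESP) ensembles—sampled without any topology
check, so segments pass freely through one another—give the thermal
equilibrium knot spectrum for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import knot_invariants as ki
from . import polymer_mc as pm
from ._geometry import min_gap2_all
from .topo_network import TopoState

__all__ = [
    "HairpinSite", "JuxtapositionEvent", "RateEstimate",
    "EquilibriumSpectrum", "hairpin_template", "impose_hairpin",
    "find_juxtaposition", "virtual_passage", "estimate_rates",
    "esp_equilibrium", "mirror_estimate",
]

#: interior apex bend of the hairpin (angle between successive tangents)
APEX_BEND_DEGREES = 120.0


@dataclass(frozen=True)
class HairpinSite:
    """Placement of the rigid hairpin on the ring: five vertices starting
    at start_vertex spanning four edges (two sides of an equilateral
    triangle with a 120-degree bend at the apex)."""

    start_vertex: int
    n_vertices: int = 5

    def vertex_indices(self, n: int) -> list[int]:
        return [(self.start_vertex + k) % n for k in range(self.n_vertices)]

    def edge_indices(self, n: int) -> list[int]:
        return [(self.start_vertex + k) % n for k in range(self.n_vertices - 1)]

    def gate_triangle(self, verts: np.ndarray) -> np.ndarray:
        n = verts.shape[0]
        i0, _, i2, _, i4 = self.vertex_indices(n)
        return np.array([verts[i0], verts[i2], verts[i4]])


@dataclass(frozen=True)
class JuxtapositionEvent:
    """A T segment piercing the gate triangle.

    crossing_sign is the sign of the passage direction: +1 when the T-edge
    direction has positive component along the gate normal oriented by the
    hairpin traversal (right-hand rule), -1 otherwise.
    """

    t_segment_index: int
    crossing_sign: int


def hairpin_template(b: float) -> np.ndarray:
    """Ideal hairpin vertices in a local frame: two sides of an equilateral
    triangle of side 2b, apex up."""
    a = np.array([0.0, 0.0, 0.0])
    bpt = np.array([b, b * math.sqrt(3.0), 0.0])
    c = np.array([2.0 * b, 0.0, 0.0])
    return np.array([a, 0.5 * (a + bpt), bpt, 0.5 * (bpt + c), c])


def apex_bend_angle(verts: np.ndarray, site: HairpinSite) -> float:
    """Bend angle (degrees) between the tangents on either side of the
    hairpin apex; 120 for the ideal hairpin."""
    n = verts.shape[0]
    idx = site.vertex_indices(n)
    t1 = verts[idx[2]] - verts[idx[1]]
    t2 = verts[idx[3]] - verts[idx[2]]
    c = float(np.dot(t1, t2) / (np.linalg.norm(t1) * np.linalg.norm(t2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimising |R src + t - dst|."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, cd - r @ cs


def _reseat(anchor: np.ndarray, target: np.ndarray, orig: np.ndarray,
            b: float) -> np.ndarray | None:
    """Point at distance b from both anchor and target, closest to orig;
    None when the spheres do not intersect."""
    dvec = target - anchor
    dist = float(np.linalg.norm(dvec))
    if dist > 2.0 * b or dist < 1e-12:
        return None
    u = dvec / dist
    mid = anchor + 0.5 * dvec
    rho2 = b * b - 0.25 * dist * dist
    rho = math.sqrt(max(rho2, 0.0))
    w = orig - mid
    w_perp = w - np.dot(w, u) * u
    nw = float(np.linalg.norm(w_perp))
    if nw < 1e-12:
        ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 \
            else np.array([0.0, 1.0, 0.0])
        w_perp = np.cross(u, ref)
        nw = float(np.linalg.norm(w_perp))
    return mid + (rho / nw) * w_perp


def _bridge(anchor: np.ndarray, target: np.ndarray, mids: list[np.ndarray],
            b: float) -> list[np.ndarray] | None:
    """k intermediate vertices joining anchor to target with all k+1 edges
    of length exactly b, or None when |anchor - target| > (k+1) b.

    The vertices subdivide a circular arc: for chord D and k+1 equal
    chords of length b, the half-chord angle phi solves
    sin((k+1) phi) / sin(phi) = D / b, which has a unique root in
    (0, pi/(k+1)).  The arc bows towards the original vertex positions.
    """
    k = len(mids)
    dvec = target - anchor
    dist = float(np.linalg.norm(dvec))
    if dist > (k + 1) * b * (1.0 - 1e-12):
        return None
    u = dvec / max(dist, 1e-12)
    off = np.mean([m - (anchor + np.dot(m - anchor, u) * u) for m in mids],
                  axis=0)
    off -= np.dot(off, u) * u
    if float(np.linalg.norm(off)) < 1e-9:
        ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 \
            else np.array([0.0, 1.0, 0.0])
        off = np.cross(u, ref)
    w = off / float(np.linalg.norm(off))

    ratio = dist / b
    lo, hi = 1e-12, math.pi / (k + 1) - 1e-12
    for _ in range(200):
        phi = 0.5 * (lo + hi)
        val = math.sin((k + 1) * phi) / math.sin(phi)
        if val > ratio:
            lo = phi
        else:
            hi = phi
    phi = 0.5 * (lo + hi)
    radius = b / (2.0 * math.sin(phi))
    theta = 2.0 * (k + 1) * phi  # total subtended angle
    half = 0.5 * dist
    h = math.sqrt(max(radius * radius - half * half, 0.0))
    mid = 0.5 * (anchor + target)
    # centre on the -w side so the arc bulges towards +w; for theta > pi
    # the centre sits on the +w side instead
    centre = mid - h * w if theta <= math.pi else mid + h * w
    e1 = (anchor - centre) / radius
    e2 = w - np.dot(w, e1) * e1
    ne2 = float(np.linalg.norm(e2))
    if ne2 < 1e-12:
        e2 = u - np.dot(u, e1) * e1
        ne2 = float(np.linalg.norm(e2))
    e2 /= ne2
    # orient the sweep so it ends at the target
    for sgn in (1.0, -1.0):
        end = centre + radius * (math.cos(theta) * e1
                                 + sgn * math.sin(theta) * e2)
        if float(np.linalg.norm(end - target)) < 1e-6 * b:
            pts = []
            for i in range(1, k + 1):
                a = theta * i / (k + 1)
                pts.append(centre + radius * (math.cos(a) * e1
                                              + sgn * math.sin(a) * e2))
            return pts
    return None


def impose_hairpin(conf, params: pm.ChainParameters, start_vertex: int = 0,
                   max_shift: int = 6, d: float | None = None
                   ) -> tuple[pm.RingConformation, HairpinSite]:
    """Deform five consecutive vertices into the rigid hairpin geometry.

    The ideal hairpin is rigid-body fitted to the prior vertex positions;
    the two ring neighbours are then reseated so all edge lengths remain
    exactly b.  If the placement violates excluded volume or changes the
    knot type, nearby start vertices are tried; a ValueError is raised
    when no placement works.
    """
    verts0 = np.ascontiguousarray(getattr(conf, "vertices", conf),
                                  dtype=float)
    n = verts0.shape[0]
    if n < 10:
        raise ValueError("chain too short for a hairpin (need N >= 10)")
    b = params.segment_length
    if d is None:
        d = params.effective_diameter
    knot_before = ki.classify_knot(verts0, seed=17)
    template = hairpin_template(b)
    shifts = [0]
    for k in range(1, max_shift + 1):
        shifts.extend([k, -k])
    for shift in shifts:
        sv = (start_vertex + shift) % n
        site = HairpinSite(sv)
        idx = site.vertex_indices(n)
        verts = verts0.copy()
        r, t = _kabsch(template, verts[idx])
        placed = (template @ r.T) + t
        verts[idx] = placed
        # rejoin each side with an adaptive window of adjustable vertices
        left = right = None
        for k in (2, 3, 4, 6, 8, 10, 12):
            if left is None:
                left = _bridge(
                    verts0[(sv - k - 1) % n], placed[0],
                    [verts0[(sv - k + m) % n] for m in range(k)], b)
                kl = k
            if right is None:
                right = _bridge(
                    verts0[(sv + 5 + k) % n], placed[4],
                    [verts0[(sv + 4 + k - m) % n] for m in range(k)], b)
                kr = k
            if left is not None and right is not None:
                break
        if left is None or right is None:
            continue
        for m, pos in enumerate(left):
            verts[(sv - kl + m) % n] = pos
        for m, pos in enumerate(right):
            verts[(sv + 4 + kr - m) % n] = pos
        ring = pm.RingConformation(verts)
        if not ring.validate_edges(b, rtol=1e-8):
            continue
        if d > 0 and min_gap2_all(verts) < d * d:
            continue
        if str(ki.classify_knot(verts, seed=17)) != str(knot_before):
            continue
        return ring, site
    raise ValueError("could not place hairpin without excluded-volume "
                     "violation or knot change")


def find_juxtaposition(conf, site: HairpinSite,
                       d: float = 0.0) -> JuxtapositionEvent | None:
    """The unique T edge piercing the gate triangle's interior, or None.

    Hairpin edges and the two edges adjacent to the hairpin are excluded;
    so are events where the T edge overlaps (comes within d of) a hairpin
    edge, events with multiple piercing edges, and events where another
    segment sits inside the region swept by the virtual hairpin flip
    (those would amount to more than one strand passage).
    """
    from ._mckernel import gate_scan
    verts = np.ascontiguousarray(getattr(conf, "vertices", conf), dtype=float)
    e, s = gate_scan(verts, site.start_vertex % verts.shape[0], d * d)
    if e < 0:
        return None
    return JuxtapositionEvent(t_segment_index=int(e), crossing_sign=int(s))


def virtual_passage(conf, site: HairpinSite, event: JuxtapositionEvent,
                    delta_lk: int | None = None, classify_seed: int = 23
                    ) -> tuple[pm.RingConformation, TopoState]:
    """Pass the T segment through the gate by the virtual hairpin flip.

    The hairpin's interior vertices are rotated half a turn about the axis
    joining its end vertices—an exact isometry of the hairpin edges that
    carries the gate to the other side of the juxtaposed T segment.
    Applying the flip twice restores the original conformation.  Returns
    the deformed ring and the product state; when delta_lk is given the
    product linking number is DeltaLk - 2 * crossing_sign.
    """
    verts = np.ascontiguousarray(getattr(conf, "vertices", conf),
                                 dtype=float).copy()
    n = verts.shape[0]
    idx = site.vertex_indices(n)
    a = verts[idx[0]]
    u = verts[idx[4]] - a
    nu = float(np.linalg.norm(u))
    if nu < 1e-12:
        raise ValueError("degenerate hairpin axis")
    u = u / nu
    b_len = float(np.linalg.norm(verts[idx[1]] - verts[idx[0]]))
    # passage direction from the current gate orientation (so that flipping
    # back reverses the bookkeeping): sign of t_T . n with n the right-hand
    # normal of the gate traversal w0 -> w2 -> w4
    tri = site.gate_triangle(verts)
    normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    e = event.t_segment_index
    tdir = verts[(e + 1) % n] - verts[e]
    sign = 1 if float(np.dot(normal, tdir)) > 0 else -1
    for k in idx[1:4]:
        v = verts[k] - a
        verts[k] = a + 2.0 * np.dot(v, u) * u - v
    ring = pm.RingConformation(verts)
    if not ring.validate_edges(b_len, rtol=1e-7):
        raise ValueError("virtual passage broke edge-length constraints")
    product_knot = ki.classify_knot(verts, seed=classify_seed)
    dlk = None if delta_lk is None else delta_lk - 2 * sign
    return ring, TopoState(product_knot, dlk)


def flip_passage_count(conf, site: HairpinSite, n_steps: int = 96,
                       _depth: int = 0) -> int:
    """Number of strand passages performed by the virtual hairpin flip.

    As the hairpin rotates continuously about its end-to-end axis, the
    ring's writhe changes smoothly except for a jump of +-2 whenever a
    rotating edge passes through a static one.  Only hairpin-vs-static
    edge pairs contribute to the change, so the jump count (and hence the
    number of passages) is read off the partial Gauss sum along the
    rotation.  A clean juxtaposition event passes exactly one strand.
    """
    from ._geometry import writhe_edges_vs_rest
    verts = np.ascontiguousarray(getattr(conf, "vertices", conf),
                                 dtype=float)
    n = verts.shape[0]
    idx = site.vertex_indices(n)
    elist = np.array(site.edge_indices(n), dtype=np.int64)
    a = verts[idx[0]]
    u = verts[idx[4]] - a
    nu = float(np.linalg.norm(u))
    if nu < 1e-12:
        raise ValueError("degenerate hairpin axis")
    u = u / nu
    interior0 = verts[idx[1:4]].copy()
    work = verts.copy()

    def partial_sum(phi):
        c = math.cos(phi)
        s = math.sin(phi)
        for row, p in enumerate(interior0):
            v = p - a
            kv = np.cross(u, v)
            ku = float(np.dot(u, v))
            work[idx[1 + row]] = a + v * c + kv * s + u * ku * (1 - c)
        return float(writhe_edges_vs_rest(work, elist))

    passages = 0
    prev = partial_sum(0.0)
    for k in range(1, n_steps + 1):
        cur = partial_sum(math.pi * k / n_steps)
        jump = cur - prev
        if abs(jump) > 1.0:
            if abs(jump) > 3.0 and _depth < 4:
                # possibly several passages within one step: refine locally
                sub = 0
                pp = prev
                for m in range(1, 9):
                    cc = partial_sum(math.pi * (k - 1 + m / 8.0) / n_steps)
                    if abs(cc - pp) > 1.0:
                        sub += max(1, round(abs(cc - pp) / 2.0))
                    pp = cc
                passages += sub
            else:
                passages += max(1, round(abs(jump) / 2.0))
        prev = cur
    return passages


@dataclass
class RateEstimate:
    """Sampled juxtaposition frequency and product distribution of one
    topological state."""

    state: TopoState
    j: float
    q: dict[TopoState, float]
    n_conformations: int
    n_juxtaposed: int
    n_ambiguous: int = 0
    se_j: float = 0.0
    se_q: dict[TopoState, float] = field(default_factory=dict)
    flagged_zero: bool = False


def mirror_estimate(est: RateEstimate) -> RateEstimate:
    """Rate estimate of the mirror-image state: the achiral sampler gives
    j(K+) = j(K-) exactly, with the product distribution mirrored."""
    return RateEstimate(
        state=est.state.mirror(), j=est.j,
        q={s.mirror(): v for s, v in est.q.items()},
        n_conformations=est.n_conformations,
        n_juxtaposed=est.n_juxtaposed, n_ambiguous=est.n_ambiguous,
        se_j=est.se_j,
        se_q={s.mirror(): v for s, v in est.se_q.items()},
        flagged_zero=est.flagged_zero)


def estimate_rates(params: pm.ChainParameters, state, n_samples: int = 1000,
                   rng_seed: int = 0, sampling_interval: int | None = None,
                   equilibration: int | None = None,
                   overlap_distance: float | None = None,
                   n_replicas: int | None = None) -> RateEstimate:
    """Estimate j(K) and Q(K'|K) for one topological state.

    Samples the fixed-knot ring ensemble with the hairpin imposed (its five
    vertices frozen), detects gate-triangle juxtapositions in every stored
    conformation, and classifies the virtual-passage product of each
    juxtaposed one.

    Sampling is split over n_replicas independent runs, each with its own
    thermalisation and hairpin placement: a single frozen placement can
    stay in a poorly accessible pose for an entire run, so juxtaposition
    counts from one placement are strongly correlated and replica
    averaging reduces that quenched variance.
    """
    state = state if isinstance(state, TopoState) \
        else TopoState.from_string(str(state)) if isinstance(state, str) \
        else TopoState(state, None)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    par = pm.ChainParameters(
        n_bp=params.n_bp, rise_per_bp=params.rise_per_bp,
        segment_length=params.segment_length,
        persistence_length=params.persistence_length,
        effective_diameter=params.effective_diameter,
        twist_rigidity=params.twist_rigidity,
        helical_repeat=params.helical_repeat,
        delta_lk=state.delta_lk)
    if overlap_distance is None:
        overlap_distance = par.effective_diameter
    n_seg = par.n_segments
    if equilibration is None:
        equilibration = 60 * n_seg
    if n_replicas is None:
        n_replicas = 1 if n_samples < 120 else 2
    counts: dict[TopoState, int] = {}
    n_scans = 0
    n_jux = 0
    n_amb = 0
    all_rates = []
    per_rep = [n_samples // n_replicas] * n_replicas
    per_rep[0] += n_samples - sum(per_rep)
    seed_rng = np.random.default_rng(rng_seed + 104729)
    for rep, n_rep in enumerate(per_rep):
        rep_seed = rng_seed + 7919 * rep
        # thermalise without the hairpin first: the smooth starting ring
        # is locally taut, and the rigid hairpin needs local slack to be
        # rejoined; each replica gets its own placement
        pre = pm.mc_sample(par, state.knot, n_samples=1,
                           equilibration=30 * n_seg,
                           sampling_interval=1, rng_seed=rep_seed + 424243)
        ring0 = pm.RingConformation(pre.conformations[0].copy())
        ring0, site = impose_hairpin(ring0, par, start_vertex=0)
        # the gate is scanned several times per stored sample:
        # juxtaposition is a local, quickly decorrelating property, so
        # the extra scans multiply the event statistics cheaply
        ens = pm.mc_sample(par, state.knot, n_samples=n_rep,
                           sampling_interval=sampling_interval,
                           equilibration=equilibration, rng_seed=rep_seed,
                           frozen_vertices=site.vertex_indices(n_seg),
                           initial=ring0, gate_start=site.start_vertex,
                           overlap_distance=overlap_distance)
        n_scans += ens.n_scans
        for k in range(len(ens.event_verts)):
            t_edge = int(ens.event_edges[k])
            # a clean event passes exactly one strand: discard flips
            # whose writhe trace shows more than one +-2 jump
            if flip_passage_count(ens.event_verts[k], site) != 1:
                n_amb += 1
                continue
            # audit the substrate: the per-trial topology filter cannot
            # see chirality, so a (rare) mirror flip of the whole knot
            # would silently poison the product statistics
            src_knot = ki.classify_knot(
                ens.event_verts[k],
                seed=int(seed_rng.integers(1, 2 ** 30)))
            if str(src_knot) != str(state.knot):
                n_amb += 1
                continue
            ev = JuxtapositionEvent(t_segment_index=t_edge,
                                    crossing_sign=int(ens.event_signs[k]))
            _, product = virtual_passage(
                ens.event_verts[k], site, ev, delta_lk=state.delta_lk,
                classify_seed=int(seed_rng.integers(1, 2 ** 30)))
            counts[product] = counts.get(product, 0) + 1
        scans_per_interval = max(ens.n_scans / max(n_rep, 1), 1.0)
        all_rates.extend(ens.interval_events / scans_per_interval)
    n_scans = max(n_scans, 1)
    n_jux = sum(counts.values())
    j = n_jux / n_scans
    # batch-means standard error over sampling intervals (scans within an
    # interval are correlated)
    all_rates = np.asarray(all_rates)
    se_j = float(np.std(all_rates) / math.sqrt(max(len(all_rates), 1)))
    se_j = max(se_j, math.sqrt(max(j * (1.0 - j), 0.0) / n_scans))
    q = {s: c / n_jux for s, c in counts.items()} if n_jux else {}
    se_q = {s: math.sqrt(max(v * (1.0 - v), 0.0) / n_jux)
            for s, v in q.items()} if n_jux else {}
    return RateEstimate(state=state, j=j, q=q, n_conformations=n_scans,
                        n_juxtaposed=n_jux, n_ambiguous=n_amb, se_j=se_j,
                        se_q=se_q, flagged_zero=(n_jux == 0))


@dataclass
class EquilibriumSpectrum:
    """Knot-type frequencies of an equilibrium-segment-passage ensemble."""

    counts: dict[str, int]
    n_samples: int

    def probability(self, knot) -> float:
        return self.counts.get(str(knot), 0) / self.n_samples

    def probabilities(self) -> dict[str, float]:
        return {k: c / self.n_samples for k, c in self.counts.items()}

    def se(self, knot) -> float:
        p = self.probability(knot)
        return math.sqrt(max(p * (1.0 - p), 0.0) / self.n_samples)


def esp_equilibrium(params: pm.ChainParameters, n_samples: int = 1000,
                    rng_seed: int = 0, sampling_interval: int | None = None,
                    equilibration: int | None = None) -> EquilibriumSpectrum:
    """Equilibrium knot spectrum from an ESP ensemble: Metropolis sampling
    on bending energy and excluded volume with no topology check, so the
    chain changes knot type freely; every stored sample is classified."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ens = pm.mc_sample(params, "0.1", n_samples=n_samples,
                       sampling_interval=sampling_interval,
                       equilibration=equilibration, rng_seed=rng_seed,
                       check_knot=False)
    counts: dict[str, int] = {}
    seed_rng = np.random.default_rng(rng_seed + 15485863)
    for k in range(n_samples):
        verts = np.ascontiguousarray(ens.conformations[k])
        s = int(seed_rng.integers(1, 2 ** 30))
        if ki.fast_unknot_check(verts, seed=s):
            label = "0.1"
        else:
            label = str(ki.classify_knot(verts, seed=s))
        counts[label] = counts.get(label, 0) + 1
    return EquilibriumSpectrum(counts=counts, n_samples=n_samples)
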