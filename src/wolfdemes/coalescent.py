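"""Structured coalescent with heterochronous sampling, range expansion and
founder bottlenecks.

Backwards-in-time event engine.  Within each deme, every pair of lineages
coalesces at rate 1/K(t) where K is the mean pairwise coalescence time of
the deme (ky); each lineage migrates at total rate m (events/ky), with
destination uniform over the deme's neighbours.  Lineages enter the
simulation at their sample ages.  Under an expansion scenario, each
replaced deme has a colonization time at which its lineages first pass
through an instantaneous founder bottleneck and are then forced into a
source deme one hop closer to the origin.

This module builds full genealogies and is the readable reference
implementation; mass simulation for ABC uses the numerically identical
summary-statistic kernel in :mod:`wolfdemes._kernel`, which skips tree
construction.  The two are moment-matched in the test suite.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .demes import ColonizationSchedule, DemeGraph, EpochModel, colonization_schedule
from .samples import SampleSet

__all__ = [
    "ScenarioSpec",
    "Genealogy",
    "SimulationError",
    "simulate_genealogy",
    "apply_founder_bottleneck",
    "pairwise_tmrca",
]

FAMILIES = ("static", "bottleneck", "expansion", "expansion_bottleneck")

#: Default backwards time cap (ky) after which a run is declared
#: non-coalescing.  Unreachable in normal use for m >= 0.001 only on
#: desk-scale runs; mass ABC simulation raises it (see abc module).
DEFAULT_TIME_CAP_KY = 1e4


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the 16 demographic scenarios.

    family       : static | bottleneck | expansion | expansion_bottleneck
    m            : per-lineage migration rate, events per ky
    K            : deme scale (mean pairwise coalescence time, ky) for the
                   constant-size families
    epochs       : piecewise K (K1, K2, K3) for the bottleneck families
    origin, T, dT, x : expansion origin deme, start time (ky BP), per-step
                   interval (ky) and founder pairwise-coalescence
                   probability, for the expansion families
    """

    family: str
    m: float
    K: float | None = None
    epochs: EpochModel | None = None
    origin: str | None = None
    T: float | None = None
    dT: float | None = None
    x: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown scenario family {self.family!r}")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.has_epochs:
            if self.epochs is None:
                raise ValueError(f"{self.family} requires epochs (K1,K2,K3)")
            if self.K is not None:
                raise ValueError("give either K or epochs, not both")
        else:
            if self.K is None or self.K <= 0:
                raise ValueError(f"{self.family} requires K > 0")
            if self.epochs is not None:
                raise ValueError("give either K or epochs, not both")
        if self.has_expansion:
            missing = [n for n in ("origin", "T", "dT", "x") if getattr(self, n) is None]
            if missing:
                raise ValueError(f"{self.family} requires {missing}")
            if not 0.0 <= self.x <= 1.0:
                raise ValueError("x must be in [0, 1]")
        else:
            for n in ("origin", "T", "dT", "x"):
                if getattr(self, n) is not None:
                    raise ValueError(f"{n} only applies to expansion families")

    @property
    def has_expansion(self) -> bool:
        return self.family in ("expansion", "expansion_bottleneck")

    @property
    def has_epochs(self) -> bool:
        return self.family in ("bottleneck", "expansion_bottleneck")

    @property
    def label(self) -> str:
        return f"{self.family}[{self.origin}]" if self.has_expansion else self.family

    def K_profile(self) -> tuple[list[float], list[float]]:
        """(epoch start times, K values) with epoch 0 starting at t=0."""
        if self.has_epochs:
            return [0.0, *self.epochs.boundaries], list(self.epochs.sizes)
        return [0.0], [self.K]

    def schedule(self, graph: DemeGraph, neighbors_at_T: bool = True) -> ColonizationSchedule | None:
        if not self.has_expansion:
            return None
        return colonization_schedule(graph, self.origin, self.T, self.dT, neighbors_at_T)

    def params(self) -> dict[str, float]:
        """Flat parameter dict (natural scale)."""
        p = {"m": self.m}
        if self.has_epochs:
            p["K1"], p["K2"], p["K3"] = self.epochs.sizes
        else:
            p["K"] = self.K
        if self.has_expansion:
            p.update(T=self.T, dT=self.dT, x=self.x)
        return p


class Genealogy:
    """A dated rooted binary genealogy over a set of samples.

    Nodes 0..n-1 are tips (in sample order), nodes n..2n-2 internal.
    ``age`` holds node ages in ky BP (tips at sample ages), ``parent``
    the parent index (-1 at the root), ``node_deme`` the deme in which
    each coalescence happened (-1 when unknown, e.g. trees read from
    file).  Bottleneck coalescences share the colonization time, so
    parent ages are >= child ages (non-strict).
    """

    def __init__(self, tip_ids, age, parent, node_deme=None):
        self.tip_ids = list(tip_ids)
        self.age = np.asarray(age, dtype=float)
        self.parent = np.asarray(parent, dtype=np.int64)
        n = len(self.tip_ids)
        if len(self.age) != 2 * n - 1 or len(self.parent) != 2 * n - 1:
            raise ValueError("arrays must have length 2n-1")
        if node_deme is None:
            node_deme = np.full(2 * n - 1, -1, dtype=np.int64)
        self.node_deme = np.asarray(node_deme, dtype=np.int64)
        if (self.parent < 0).sum() != 1:
            raise ValueError("genealogy must have exactly one root")
        # parent older than child (ties allowed for bottleneck bursts)
        ok = self.parent >= 0
        if np.any(self.age[self.parent[ok]] < self.age[np.where(ok)[0]] - 1e-9):
            raise ValueError("parent younger than child")

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def tip_ages(self) -> dict[str, float]:
        return {tid: float(self.age[i]) for i, tid in enumerate(self.tip_ids)}

    # -- newick ---------------------------------------------------------

    def to_newick(self) -> str:
        """Newick with branch lengths in ky."""
        ch = self.children()

        def rec(u: int) -> str:
            if u < self.n_tips:
                lab = self.tip_ids[u]
            else:
                lab = ""
            if ch[u]:
                inner = ",".join(
                    f"{rec(c)}:{self.age[u] - self.age[c]:.10g}" for c in ch[u]
                )
                return f"({inner}){lab}"
            return str(lab)

        return rec(self.root) + ";"


def pairwise_tmrca(g: Genealogy) -> np.ndarray:
    """Symmetric matrix of pairwise TMRCAs (ky), in tip order.

    TMRCA(i, j) is the age of the most recent common ancestor of tips i
    and j; the diagonal is zero.
    """
    n = g.n_tips
    ch = g.children()
    out = np.zeros((n, n))
    # postorder accumulation of descendant-tip lists
    tips_below: list[list[int] | None] = [None] * len(g.parent)

    order = []
    stack = [g.root]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(ch[u])
    for u in reversed(order):
        if not ch[u]:
            tips_below[u] = [u] if u < n else []
            continue
        kids = [tips_below[c] for c in ch[u]]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    for j in kids[b]:
                        out[i, j] = out[j, i] = g.age[u]
        merged = []
        for k in kids:
            merged.extend(k)
        tips_below[u] = merged
    return out


def apply_founder_bottleneck(lineages, x: float, time: float, rng, merge_fn=None):
    """Instantaneous founder bottleneck over a list of lineage payloads.

    Realised as a burst of Kingman coalescence of intensity
    tau = -ln(1 - x), so that any fixed pair of lineages coalesces during
    the bottleneck with probability exactly 1 - exp(-tau) = x (the
    pairwise marginal of the Kingman coalescent is Exp(1) regardless of
    how many other lineages are present).  x = 1 collapses everything to
    a single survivor.

    Returns (survivors, merges): merges is a list of
    (payload_a, payload_b, merged_payload, time) records, all at age
    ``time``; merged payloads are built by ``merge_fn(a, b)`` (default:
    the tuple ``(a, b)``) and take part in further merging.  ``rng`` is a
    ``random.Random``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must be in [0, 1]")
    if merge_fn is None:
        merge_fn = lambda a, b: (a, b)  # noqa: E731
    pool = list(lineages)
    merges = []
    if x == 0.0 or len(pool) < 2:
        return pool, merges
    tau = math.inf if x == 1.0 else -math.log1p(-x)
    s = 0.0
    while len(pool) >= 2:
        k = len(pool)
        if tau is not math.inf:
            s += rng.expovariate(k * (k - 1) / 2.0)
            if s > tau:
                break
        i = int(rng.random() * k)
        j = int(rng.random() * (k - 1))
        if j >= i:
            j += 1
        if j < i:
            i, j = j, i
        a, b = pool[i], pool[j]
        pool[j] = pool[-1]
        pool.pop()
        merged = merge_fn(a, b)
        pool[i] = merged
        merges.append((a, b, merged, time))
    return pool, merges


@dataclass
class _EngineState:
    """Mutable state of one backwards-in-time run."""

    deme_lin: list[list[int]]  # node indices per deme
    k: list[int]
    k_tot: int = 0
    S2: int = 0  # sum over demes of C(k_d, 2)

    def add(self, d: int, node: int) -> None:
        self.deme_lin[d].append(node)
        self.S2 += self.k[d]
        self.k[d] += 1
        self.k_tot += 1

    def remove_at(self, d: int, i: int) -> int:
        lst = self.deme_lin[d]
        node = lst[i]
        lst[i] = lst[-1]
        lst.pop()
        self.k[d] -= 1
        self.S2 -= self.k[d]
        self.k_tot -= 1
        return node


def simulate_genealogy(
    graph: DemeGraph,
    scenario: ScenarioSpec,
    samples: SampleSet,
    seed: int,
    time_cap: float = DEFAULT_TIME_CAP_KY,
    neighbors_at_T: bool = True,
) -> Genealogy:
    """Simulate one genealogy for dated samples under a scenario.

    Deterministic given (graph, scenario, samples, seed).  Raises
    :class:`SimulationError` if the run exceeds ``time_cap`` ky without
    fully coalescing (e.g. m = 0 with samples in more than one deme and
    no expansion to gather them).
    """
    samples.validate_against(graph)
    n = len(samples)
    if n < 1:
        raise ValueError("need at least one sample")
    rng = random.Random(seed)
    adj = graph.adjacency_lists()
    n_demes = graph.n_demes
    sample_deme = samples.deme_indices(graph)
    ages = samples.ages

    K_times, K_vals = scenario.K_profile()
    m = scenario.m

    # structural events: (time, kind, payload); kind 0 activation,
    # 1 epoch switch, 2 colonization.  Activations first at equal times,
    # in sample order.
    events: list[tuple[float, int, object]] = []
    for i in sorted(range(n), key=lambda i: (ages[i], i)):
        events.append((float(ages[i]), 0, i))
    for ei, b in enumerate(K_times[1:], start=1):
        events.append((float(b), 1, ei))
    sched = scenario.schedule(graph, neighbors_at_T)
    if sched is not None:
        for t_c, deme, sources in sched.sorted_events():
            events.append(
                (float(t_c), 2, (graph.index(deme), tuple(graph.index(s) for s in sources)))
            )
    events.sort(key=lambda e: (e[0], e[1]))

    # genealogy bookkeeping
    total_nodes = 2 * n - 1
    age = np.zeros(total_nodes)
    parent = np.full(total_nodes, -1, dtype=np.int64)
    node_deme = np.full(total_nodes, -1, dtype=np.int64)
    age[:n] = ages
    next_node = n

    st = _EngineState(deme_lin=[[] for _ in range(n_demes)], k=[0] * n_demes)
    Kcur = K_vals[0]
    x = scenario.x if scenario.has_expansion else 0.0

    def merge(d: int, i: int, j: int, t: float) -> None:
        nonlocal next_node
        lst = st.deme_lin[d]
        a, b = lst[i], lst[j]
        u = next_node
        next_node += 1
        age[u] = t
        node_deme[u] = d
        parent[a] = u
        parent[b] = u
        # replace a by u, drop b
        lst[i] = u
        if j != len(lst) - 1:
            lst[j] = lst[-1]
        lst.pop()
        st.k[d] -= 1
        st.S2 -= st.k[d]
        st.k_tot -= 1

    t = 0.0
    ev_i = 0
    n_ev = len(events)
    while st.k_tot > 1 or ev_i < n_ev:
        t_next = events[ev_i][0] if ev_i < n_ev else math.inf
        total_rate = st.S2 / Kcur + m * st.k_tot
        te = t + rng.expovariate(total_rate) if total_rate > 0 else math.inf
        if te >= t_next:
            if ev_i >= n_ev:
                raise SimulationError(
                    "non-coalescing configuration: no events possible "
                    f"with {st.k_tot} lineages remaining"
                )
            t = t_next
            _, kind, payload = events[ev_i]
            ev_i += 1
            if kind == 0:  # activation
                i = payload
                st.add(int(sample_deme[i]), i)
            elif kind == 1:  # epoch switch
                Kcur = K_vals[payload]
            else:  # colonization: bottleneck then forced migration
                d, sources = payload
                if x > 0.0 and st.k[d] >= 2:
                    tau = math.inf if x == 1.0 else -math.log1p(-x)
                    s = 0.0
                    while st.k[d] >= 2:
                        kk = st.k[d]
                        if tau is not math.inf:
                            s += rng.expovariate(kk * (kk - 1) / 2.0)
                            if s > tau:
                                break
                        i = int(rng.random() * kk)
                        j = int(rng.random() * (kk - 1))
                        if j >= i:
                            j += 1
                        merge(d, min(i, j), max(i, j), t)
                lst = st.deme_lin[d]
                n_src = len(sources)
                while lst:
                    node = st.remove_at(d, len(lst) - 1)
                    dest = sources[int(rng.random() * n_src)] if n_src > 1 else sources[0]
                    st.add(dest, node)
            continue
        t = te
        if t > time_cap:
            raise SimulationError(
                f"simulation exceeded time cap of {time_cap:g} ky "
                "(non-coalescing configuration?)"
            )
        u = rng.random() * total_rate
        if u < m * st.k_tot:
            # migration of a uniformly chosen lineage
            j = int(u / m)
            if j >= st.k_tot:
                j = st.k_tot - 1
            d = 0
            while j >= st.k[d]:
                j -= st.k[d]
                d += 1
            node = st.remove_at(d, j)
            nb = adj[d]
            dest = nb[int(rng.random() * len(nb))]
            st.add(dest, node)
        else:
            # coalescence in a deme chosen proportional to C(k_d, 2)
            v = (u - m * st.k_tot) * Kcur
            d = 0
            while d < n_demes - 1:
                c = st.k[d] * (st.k[d] - 1) // 2
                if v < c:
                    break
                v -= c
                d += 1
            kk = st.k[d]
            i = int(rng.random() * kk)
            j = int(rng.random() * (kk - 1))
            if j >= i:
                j += 1
            merge(d, min(i, j), max(i, j), t)

    return Genealogy(samples.ids, age, parent, node_deme)
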