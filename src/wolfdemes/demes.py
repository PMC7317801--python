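"""Deme geography shared by all demographic scenarios.

The wolf range is discretised into seven demes separated by major
geographic barriers (oceans, mountain chains, deserts, LGM ice sheets).
Demes form a migration network: gene flow only happens along edges.
Range-expansion scenarios colonise this network outward from an origin
deme in fixed time steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import yaml

#: Canonical deme names, in fixed order.
DEMES = (
    "Europe",
    "MiddleEast",
    "CentralNorthEurasia",
    "EastEurasia",
    "Beringia",
    "ArcticNorthAmerica",
    "NorthAmerica",
)

#: Default adjacency (unordered pairs) of the migration network.
DEFAULT_EDGES = (
    ("Europe", "MiddleEast"),
    ("Europe", "CentralNorthEurasia"),
    ("MiddleEast", "CentralNorthEurasia"),
    ("CentralNorthEurasia", "EastEurasia"),
    ("CentralNorthEurasia", "Beringia"),
    ("EastEurasia", "Beringia"),
    ("Beringia", "NorthAmerica"),
    ("Beringia", "ArcticNorthAmerica"),
    ("NorthAmerica", "ArcticNorthAmerica"),
)

#: Deme -> summary-statistic group. The three northeast Eurasian demes and
#: the two American demes are pooled when computing summary statistics
#: (structure between them is still modelled explicitly).
DEFAULT_STAT_GROUPS = {
    "Europe": "EUR",
    "MiddleEast": "ME",
    "CentralNorthEurasia": "EAS",
    "EastEurasia": "EAS",
    "Beringia": "EAS",
    "ArcticNorthAmerica": "AME",
    "NorthAmerica": "AME",
}

#: Fixed order of the stat groups.
STAT_GROUPS = ("EUR", "ME", "EAS", "AME")


class DemeGraphError(ValueError):
    pass


@dataclass(frozen=True)
class DemeGraph:
    """A migration network of demes with a summary-statistic grouping.

    ``demes`` is an ordered tuple of deme names, ``edges`` a tuple of
    unordered name pairs, ``stat_groups`` maps each deme to its group
    label.  The graph must be connected.  The default seven-deme model is
    built by :func:`build_default_graph`; smaller graphs are permitted for
    experiments and validation.
    """

    demes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    stat_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.demes)) != len(self.demes):
            raise DemeGraphError("duplicate deme names")
        for a, b in self.edges:
            if a not in self.demes or b not in self.demes:
                raise DemeGraphError(f"edge ({a},{b}) references unknown deme")
            if a == b:
                raise DemeGraphError(f"self-loop on {a}")
        g = self.to_networkx()
        if len(self.demes) > 1 and not nx.is_connected(g):
            raise DemeGraphError("deme graph is not connected")
        for d in self.demes:
            if self.stat_groups and d not in self.stat_groups:
                raise DemeGraphError(f"deme {d} has no stat group")

    # -- basic queries -------------------------------------------------

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    def index(self, deme: str) -> int:
        try:
            return self.demes.index(deme)
        except ValueError:
            raise DemeGraphError(f"unknown deme: {deme!r}") from None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.demes)
        g.add_edges_from(self.edges)
        return g

    def neighbors(self, deme: str) -> tuple[str, ...]:
        self.index(deme)
        out = []
        for a, b in self.edges:
            if a == deme:
                out.append(b)
            elif b == deme:
                out.append(a)
        return tuple(out)

    def adjacency_lists(self) -> list[list[int]]:
        """Neighbour indices per deme index (engine representation)."""
        adj: list[list[int]] = [[] for _ in self.demes]
        for a, b in self.edges:
            ia, ib = self.index(a), self.index(b)
            adj[ia].append(ib)
            adj[ib].append(ia)
        return adj

    def hop_distances(self, origin: str) -> dict[str, int]:
        """BFS hop distance of every deme from ``origin``."""
        self.index(origin)
        return dict(nx.single_source_shortest_path_length(self.to_networkx(), origin))

    def group_index(self, deme: str) -> int:
        return STAT_GROUPS.index(self.stat_groups[deme])

    # -- serialisation -------------------------------------------------

    def to_config(self) -> dict:
        return {
            "demes": list(self.demes),
            "edges": [list(e) for e in self.edges],
            "stat_groups": dict(self.stat_groups),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "DemeGraph":
        return cls(
            demes=tuple(cfg["demes"]),
            edges=tuple(tuple(e) for e in cfg["edges"]),
            stat_groups=dict(cfg.get("stat_groups", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "DemeGraph":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)


def build_default_graph() -> DemeGraph:
    """The seven-deme Northern-Hemisphere wolf migration network."""
    return DemeGraph(demes=DEMES, edges=DEFAULT_EDGES, stat_groups=dict(DEFAULT_STAT_GROUPS))


@dataclass(frozen=True)
class EpochModel:
    """Piecewise-constant deme scale K(t) over three epochs.

    K is the mean pairwise coalescence time within a deme, in ky; the
    pairwise coalescence rate is 1/K.  Epoch 1 covers [0, 15) ky BP,
    epoch 2 [15, 40), epoch 3 [40, inf); sizes = (K1, K2, K3).
    """

    sizes: tuple[float, float, float]
    boundaries: tuple[float, float] = (15.0, 40.0)

    def __post_init__(self):
        if len(self.sizes) != len(self.boundaries) + 1:
            raise ValueError("need one K per epoch")
        if any(k <= 0 for k in self.sizes):
            raise ValueError("all K must be > 0")
        if not all(a < b for a, b in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("epoch boundaries must be strictly increasing")
        if any(b <= 0 for b in self.boundaries):
            raise ValueError("epoch boundaries must be positive")

    def K_at(self, t: float) -> float:
        """K in effect at time t (ky BP)."""
        for b, k in zip(self.boundaries, self.sizes):
            if t < b:
                return k
        return self.sizes[-1]


@dataclass(frozen=True)
class ColonizationSchedule:
    """Backwards-in-time replacement schedule of a range expansion.

    The expansion starts (forward in time) at ``T`` ky BP in ``origin``;
    the origin's neighbours are replaced at T itself and every further
    hop adds a delay of ``dT`` ky, so a deme at hop distance d is
    replaced at T - (d-1)*dT.  ``events`` maps each non-origin deme to
    (time, sources) where sources are its neighbours one hop closer to
    the origin (the demes that colonised it, i.e. the demes its lineages
    are forced into backwards in time).

    The alternative timing convention (neighbours replaced at T - dT) is
    available via ``colonization_schedule(..., neighbors_at_T=False)``.
    """

    origin: str
    T: float
    dT: float
    events: tuple[tuple[str, float, tuple[str, ...]], ...]

    def sorted_events(self) -> list[tuple[float, str, tuple[str, ...]]]:
        """Events as (time, deme, sources), ascending in time (backwards order)."""
        return sorted((t, d, s) for d, t, s in self.events)


def colonization_schedule(
    graph: DemeGraph,
    origin: str,
    T: float,
    dT: float,
    neighbors_at_T: bool = True,
) -> ColonizationSchedule:
    """Build the replacement schedule of an expansion out of ``origin``.

    Raises if dT <= 0 or if any replacement would happen at or before the
    present (event time <= 0), which would leave the expansion incomplete.
    """
    if dT <= 0:
        raise ValueError("dT must be > 0")
    if T <= 0:
        raise ValueError("T must be > 0")
    dist = graph.hop_distances(origin)
    offset = 1 if neighbors_at_T else 0
    events = []
    for deme in graph.demes:
        if deme == origin:
            continue
        d = dist[deme]
        t = T - (d - offset) * dT
        if t <= 0:
            raise ValueError(
                f"expansion incomplete: {deme} would be colonised at {t:.3f} ky BP"
            )
        sources = tuple(
            nb for nb in graph.neighbors(deme) if dist[nb] == d - 1
        )
        events.append((deme, t, sources))
    return ColonizationSchedule(origin=origin, T=T, dT=dT, events=tuple(events))
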