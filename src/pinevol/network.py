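"""Epoch-stamped protein-interaction networks and their evolutionary comparison.

A PIN (protein interaction network) here is an undirected graph over protein
identifiers in which self-pairs ("looped lines", homodimers) are first-class
edges.  Networks are stamped with a divergence time in million years ago (mya)
so that edge gains and losses between two epochs can be normalised into rates
per potential pair per mya.

Whole-genome duplications multiply every node; the polyploidy-aware rescaling
implemented here copies each node ``multiplicity`` times with all-versus-all
edge inheritance (every copy of A interacts with every copy of B whenever the
ancestors A and B interacted), which is the construction used to put networks
of different sizes on a common footing before comparing them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "Edge",
    "PIN",
    "OrthologMap",
    "NetworkComparison",
    "edge_key",
    "build_network",
    "density",
    "rescale_by_polyploidy",
    "compare_networks",
    "gain_loss_rates",
    "degree_and_hub_profile",
    "swap_protein",
    "subfunctionalization_check",
]

Edge = tuple[str, str]

DensityConvention = Literal["pairs", "pairs_noself", "matrix"]


def edge_key(a: str, b: str) -> Edge:
    """Canonical (sorted) form of an undirected edge; loops are (a, a)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PIN:
    """An undirected protein interaction network at one evolutionary epoch.

    Parameters
    ----------
    epoch_label:
        Free-text epoch name, e.g. ``"ePIN"``, ``"pre-PIN"``, ``"post-PIN"``.
    time_mya:
        Age of the epoch in million years ago (0 for extant networks).
    nodes, edges:
        Protein ids and canonical unordered pairs over them.  Self-pairs
        (homodimers) are permitted.
    edge_weights:
        Optional interaction strengths (e.g. Miller-unit deltas) per edge.
    """

    epoch_label: str
    time_mya: float
    nodes: frozenset[str]
    edges: frozenset[Edge]
    edge_weights: Optional[Mapping[Edge, float]] = None

    def __post_init__(self) -> None:
        if self.time_mya < 0:
            raise ValueError("time_mya must be >= 0")
        for a, b in self.edges:
            if a > b:
                raise ValueError(f"edge {(a, b)} is not in canonical order")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)} references unknown node")

    @staticmethod
    def from_edges(
        epoch_label: str,
        time_mya: float,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        edge_weights: Optional[Mapping[tuple[str, str], float]] = None,
    ) -> "PIN":
        canon = frozenset(edge_key(a, b) for a, b in edges)
        weights = None
        if edge_weights is not None:
            weights = {edge_key(a, b): w for (a, b), w in edge_weights.items()}
        return PIN(epoch_label, float(time_mya), frozenset(nodes), canon, weights)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def has_edge(self, a: str, b: str) -> bool:
        return edge_key(a, b) in self.edges

    def degree(self, node: str) -> int:
        """Number of distinct interaction partners; a self-pair counts once."""
        if node not in self.nodes:
            raise KeyError(node)
        partners = set()
        for a, b in self.edges:
            if a == node:
                partners.add(b)
            elif b == node:
                partners.add(a)
        return len(partners)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(epoch_label=self.epoch_label, time_mya=self.time_mya)
        g.add_nodes_from(sorted(self.nodes))
        for a, b in sorted(self.edges):
            w = None if self.edge_weights is None else self.edge_weights.get((a, b))
            if w is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, weight=float(w))
        return g


@dataclass(frozen=True)
class OrthologMap:
    """One-to-many correspondence between an ancestral and a descendant network.

    ``forward`` maps each ancestor id to the set of its descendant copies;
    every mapped descendant has exactly one ancestor.  Nodes absent from the
    map on either side are treated as unmapped and reported explicitly.
    """

    forward: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for anc, descs in self.forward.items():
            for d in descs:
                if d in seen:
                    raise ValueError(
                        f"descendant {d!r} mapped to both {seen[d]!r} and {anc!r}"
                    )
                seen[d] = anc

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        """Build from (ancestor, descendant) pairs."""
        fwd: dict[str, set[str]] = {}
        for anc, desc in pairs:
            fwd.setdefault(anc, set()).add(desc)
        return OrthologMap({a: frozenset(d) for a, d in fwd.items()})

    @staticmethod
    def identity(nodes: Iterable[str]) -> "OrthologMap":
        return OrthologMap({n: frozenset([n]) for n in nodes})

    @property
    def inverse(self) -> dict[str, str]:
        inv: dict[str, str] = {}
        for anc, descs in self.forward.items():
            for d in descs:
                inv[d] = anc
        return inv

    def ancestor_of(self, descendant: str) -> Optional[str]:
        return self.inverse.get(descendant)

    def descendants_of(self, ancestor: str) -> frozenset[str]:
        return self.forward.get(ancestor, frozenset())

    def unmapped(self, ancestors: Iterable[str], descendants: Iterable[str]) -> tuple[set[str], set[str]]:
        """(ancestors without descendants, descendants without ancestors)."""
        inv = self.inverse
        anc_un = {a for a in ancestors if not self.forward.get(a)}
        desc_un = {d for d in descendants if d not in inv}
        return anc_un, desc_un


@dataclass(frozen=True)
class NetworkComparison:
    """Edge-level comparison of an ancestral network ``a`` and descendant ``b``.

    ``conserved`` and ``gained`` are in descendant coordinates and partition
    b's edge set; ``lost`` is in ancestral coordinates (a lost edge has, by
    definition, no descendant image).  Rates are per potential pair of the
    descendant frame per mya of divergence.
    """

    conserved: frozenset[Edge]
    gained: frozenset[Edge]
    lost: frozenset[Edge]
    potential_edges: int
    divergence_mya: float
    gain_rate: float
    loss_rate: float
    density_a: float
    density_b: float

    def __post_init__(self) -> None:
        if self.conserved & self.gained:
            raise ValueError("conserved and gained must be disjoint")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")


def build_network(
    calls: Sequence,
    epoch_label: str,
    time_mya: float,
    mode_filter: Literal["dimeric", "mediated", "both"] = "both",
) -> tuple[PIN, list]:
    """Assemble a PIN from interaction calls.

    Nodes are every protein appearing in ``calls`` (including proteins from
    negative or excluded calls — they were tested); edges are the positive
    calls passing ``mode_filter``.  Auto-activation-excluded pairs are never
    edges; they are returned alongside the network for reporting.

    Returns
    -------
    (pin, excluded) where ``excluded`` is the list of autoactive-excluded calls.
    """
    if not calls:
        raise ValueError("calls must be non-empty")
    if mode_filter not in ("dimeric", "mediated", "both"):
        raise ValueError(f"unknown mode_filter {mode_filter!r}")
    nodes: set[str] = set()
    edges: set[Edge] = set()
    weights: dict[Edge, float] = {}
    excluded = []
    for call in calls:
        a, b = call.pair
        nodes.add(a)
        nodes.add(b)
        if call.status == "autoactive_excluded":
            excluded.append(call)
            continue
        if mode_filter != "both" and call.mode != mode_filter:
            continue
        if call.status == "positive":
            k = edge_key(a, b)
            edges.add(k)
            weights[k] = call.delta
    return PIN(epoch_label, float(time_mya), frozenset(nodes), frozenset(edges), weights), excluded


def _potential(n: int, convention: DensityConvention) -> int:
    if convention == "pairs":
        return n * (n + 1) // 2
    if convention == "pairs_noself":
        return n * (n - 1) // 2
    if convention == "matrix":
        return n * n
    raise ValueError(f"unknown density convention {convention!r}")


def density(pin: PIN, convention: DensityConvention = "pairs") -> float:
    """Observed / potential interactions.

    Conventions
    -----------
    ``pairs`` (default)
        Unordered pairs including self-pairs: potential = n(n+1)/2, every
        edge (loop or not) counts once.
    ``pairs_noself``
        Loops excluded from numerator and denominator: potential = n(n-1)/2.
    ``matrix``
        Symmetric-adjacency (ordered-pair) convention: potential = n^2, a
        non-loop edge counts twice and a loop once.  This is the convention
        under which all-versus-all polyploid rescaling preserves density
        exactly (see :func:`rescale_by_polyploidy`).
    """
    n = pin.n
    if n == 0:
        raise ValueError("density undefined for an empty node set")
    if convention == "pairs":
        observed = len(pin.edges)
    elif convention == "pairs_noself":
        observed = sum(1 for a, b in pin.edges if a != b)
        if n == 1:
            return 0.0
    elif convention == "matrix":
        observed = sum(1 if a == b else 2 for a, b in pin.edges)
    else:
        raise ValueError(f"unknown density convention {convention!r}")
    return observed / _potential(n, convention)


def copy_name(node: str, k: int) -> str:
    """Name of the k-th polyploid copy of ``node`` (1-based)."""
    return f"{node}~{k}"


def rescale_by_polyploidy(
    pin: PIN,
    multiplicity: int,
    keep: Optional[Iterable[str]] = None,
    target_size: Optional[int] = None,
) -> tuple[PIN, OrthologMap]:
    """Triplicate/duplicate a network and prune back to a comparison frame.

    Every node is copied ``multiplicity`` times and copies inherit edges
    all-versus-all: an ancestral edge (A, B) implies edges between every copy
    of A and every copy of B; an ancestral loop (A, A) implies every pair
    (including loops) among A's copies.  Afterwards nodes outside ``keep``
    are removed; alternatively ``target_size`` retains a deterministic prefix
    (lexicographically smallest copies, round-robin over ancestors) of that
    size.

    Returns the rescaled network and the ancestor->copy ortholog map
    (restricted to surviving copies).
    """
    if multiplicity < 2:
        raise ValueError("multiplicity must be >= 2")
    if keep is not None and target_size is not None:
        raise ValueError("give either keep or target_size, not both")
    all_copies = {
        copy_name(node, k): node
        for node in pin.nodes
        for k in range(1, multiplicity + 1)
    }
    if keep is not None:
        keep_set = set(keep)
        bad = keep_set - set(all_copies)
        if bad:
            raise ValueError(f"keep contains non-copy nodes: {sorted(bad)}")
    elif target_size is not None:
        if pin.n * multiplicity < target_size:
            raise ValueError("target_size exceeds copied node count")
        # Round-robin: first copy of every ancestor, then second, etc.,
        # ancestors in lexicographic order — deterministic redundant-node removal.
        ordered = [
            copy_name(node, k)
            for k in range(1, multiplicity + 1)
            for node in sorted(pin.nodes)
        ]
        keep_set = set(ordered[:target_size])
    else:
        keep_set = set(all_copies)

    edges: set[Edge] = set()
    for a, b in pin.edges:
        for i in range(1, multiplicity + 1):
            for j in range(1, multiplicity + 1):
                u, v = copy_name(a, i), copy_name(b, j)
                if u in keep_set and v in keep_set:
                    edges.add(edge_key(u, v))
    fwd: dict[str, set[str]] = {node: set() for node in pin.nodes}
    for cp, anc in all_copies.items():
        if cp in keep_set:
            fwd[anc].add(cp)
    omap = OrthologMap({a: frozenset(d) for a, d in fwd.items()})
    rescaled = PIN(
        f"{pin.epoch_label}x{multiplicity}",
        pin.time_mya,
        frozenset(keep_set),
        frozenset(edges),
    )
    return rescaled, omap


def compare_networks(a: PIN, b: PIN, omap: OrthologMap) -> NetworkComparison:
    """Classify descendant edges as conserved/gained and ancestral edges as lost.

    A descendant edge is conserved when the ancestral pair it maps onto is an
    edge of ``a``; otherwise (including edges with an unmapped endpoint) it is
    gained.  An ancestral edge is lost when none of its descendant-pair images
    is an edge of ``b``.  The potential-edge frame and densities are those of
    the descendant network.
    """
    divergence = a.time_mya - b.time_mya
    if divergence <= 0:
        raise ValueError("a must be strictly older than b (divergence <= 0)")
    inv = omap.inverse
    conserved: set[Edge] = set()
    gained: set[Edge] = set()
    for u, v in b.edges:
        anc_u, anc_v = inv.get(u), inv.get(v)
        if anc_u is not None and anc_v is not None and a.has_edge(anc_u, anc_v):
            conserved.add((u, v))
        else:
            gained.add((u, v))
    lost: set[Edge] = set()
    for x, y in a.edges:
        dx, dy = omap.descendants_of(x), omap.descendants_of(y)
        survives = any(
            b.has_edge(u, v) for u in dx for v in dy if not (x == y and u > v)
        )
        if not survives:
            lost.add((x, y))
    potential = _potential(b.n, "pairs")
    gain_rate = len(gained) / (potential * divergence)
    loss_rate = len(lost) / (potential * divergence)
    return NetworkComparison(
        conserved=frozenset(conserved),
        gained=frozenset(gained),
        lost=frozenset(lost),
        potential_edges=potential,
        divergence_mya=divergence,
        gain_rate=gain_rate,
        loss_rate=loss_rate,
        density_a=density(a),
        density_b=density(b),
    )


def gain_loss_rates(cmp: NetworkComparison) -> tuple[float, float]:
    """Gained (lost) interactions / (potential interactions x divergence time)."""
    if cmp.potential_edges <= 0:
        raise ValueError("potential_edges must be positive")
    if cmp.divergence_mya <= 0:
        raise ValueError("divergence_mya must be positive")
    gain = len(cmp.gained) / (cmp.potential_edges * cmp.divergence_mya)
    loss = len(cmp.lost) / (cmp.potential_edges * cmp.divergence_mya)
    return gain, loss


def degree_and_hub_profile(
    pin: PIN, hub_min: int = 5, island_max: int = 1
) -> dict[str, dict]:
    """Per-node degree, hub/intermediate/island class, and promiscuity index.

    Degree counts distinct partners (a homodimer loop counts once, as the
    node itself).  Promiscuity is degree / n, the fraction of possible
    partners including self — a node interacting with every protein in the
    network including itself scores 1.0.
    """
    if hub_min <= island_max:
        raise ValueError("hub_min must exceed island_max")
    if island_max < 0:
        raise ValueError("island_max must be >= 0")
    n = pin.n
    report: dict[str, dict] = {}
    for node in sorted(pin.nodes):
        deg = pin.degree(node)
        if deg >= hub_min:
            cls = "hub"
        elif deg <= island_max:
            cls = "island"
        else:
            cls = "intermediate"
        report[node] = {
            "degree": deg,
            "class": cls,
            "promiscuity": deg / n,
        }
    return report


def swap_protein(
    host: PIN,
    foreign_id: str,
    foreign_calls: Sequence,
    native_counterpart: Optional[str] = None,
) -> dict:
    """Evaluate a foreign protein's interaction pattern inside a host network.

    ``foreign_calls`` are interaction calls of the foreign protein against
    host nodes (the swap assay).  The report gives the foreign degree and
    promiscuity in the host frame and, when a native counterpart is named,
    the host-native degree for comparison — the readout used to decide
    whether promiscuity travels with the protein or with its partners.
    """
    if foreign_id in host.nodes:
        raise ValueError(f"foreign id {foreign_id!r} collides with a host node")
    partners: set[str] = set()
    for call in foreign_calls:
        a, b = call.pair
        other = b if a == foreign_id else a if b == foreign_id else None
        if other is None:
            raise ValueError(f"call {call.pair} does not involve {foreign_id!r}")
        if other not in host.nodes:
            raise ValueError(f"call partner {other!r} is not a host node")
        if call.status == "positive":
            partners.add(other)
    degree = len(partners)
    report = {
        "foreign_id": foreign_id,
        "host_epoch": host.epoch_label,
        "degree": degree,
        "promiscuity": degree / host.n,
        "partners": sorted(partners),
    }
    if native_counterpart is not None:
        report["native_counterpart"] = native_counterpart
        report["native_degree"] = host.degree(native_counterpart)
    return report


def subfunctionalization_check(
    ancestor_degree: int, descendant_degrees: Sequence[int]
) -> tuple[int, int]:
    """Additivity check for partitioned hub interactions after duplication.

    Returns (combined, deficit): combined is the summed descendant degree,
    deficit = ancestor_degree - combined.  A zero deficit means the ancestral
    partner set was exactly partitioned among the copies; a positive deficit
    is a net loss relative to additive partitioning.
    """
    if ancestor_degree < 0 or any(d < 0 for d in descendant_degrees):
        raise ValueError("degrees must be non-negative")
    combined = int(sum(descendant_degrees))
    return combined, int(ancestor_degree) - combined
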