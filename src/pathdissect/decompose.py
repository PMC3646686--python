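"""Network decomposition: connected/strongly connected components, bow-tie
pruning, material components, cycle decomposition and subnetwork clustering.

These operations dissect a large molecular map into smaller subnetworks that
are easier to interpret: the weakly connected pieces, the cyclic machinery
(SCCs and the bow-tie around them), the life cycle of each individual protein
(material components), the elementary feedback circuits, and clusters of
overlapping subnetworks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .netmodel import Network, parse_entity_name, MalformedNameError

#: Default cap on the number of enumerated cycles; exceeding it emits a
#: warning and truncates, because cycle counts explode on dense graphs.
DEFAULT_CYCLE_CAP = 100_000


@dataclass
class BowTiePartition:
    """Bow-tie dissection of a directed network.

    ``core`` is the union of non-trivial strongly connected components (size
    at least two, or a singleton with a self-loop).  ``input_part`` holds the
    nodes from which the core can be reached but which the core cannot reach
    back; ``output_part`` the nodes the core reaches but which cannot return
    to it.  Every remaining node (including all nodes of an acyclic network)
    goes to ``other``.
    """

    input_part: set[str] = field(default_factory=set)
    core: set[str] = field(default_factory=set)
    output_part: set[str] = field(default_factory=set)
    other: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "input": self.input_part,
            "core": self.core,
            "output": self.output_part,
            "other": self.other,
        }


@dataclass(frozen=True)
class Cycle:
    """An elementary directed circuit, stored without repeating the start node."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.nodes)


class SubnetworkSet(dict):
    """Label → :class:`Network` mapping produced by decomposition operations."""


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

def connected_components(net: Network) -> SubnetworkSet:
    """Weakly connected components as induced subnetworks (labelled cc1, cc2, ...)."""
    out = SubnetworkSet()
    comps = sorted(nx.weakly_connected_components(net.graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps, start=1):
        label = f"cc{i}"
        out[label] = net.induced_subnetwork(comp, name=label)
    return out


def strongly_connected_components(net: Network) -> list[set[str]]:
    """Maximal strongly connected node sets (a partition of all nodes).

    Sorted by smallest member id for determinism.
    """
    comps = [set(c) for c in nx.strongly_connected_components(net.graph)]
    return sorted(comps, key=lambda c: min(c))


def bowtie_partition(net: Network) -> BowTiePartition:
    """Prune the network into input fan, cyclic core, output fan and the rest."""
    core: set[str] = set()
    for comp in nx.strongly_connected_components(net.graph):
        if len(comp) > 1:
            core |= comp
        else:
            (node,) = comp
            if net.graph.has_edge(node, node):
                core.add(node)

    reaches_core: set[str] = set()
    reached_from_core: set[str] = set()
    if core:
        seed = next(iter(core))
        # reachability to/from any core node factors through the whole core
        # only for nodes connected to the same weak piece; compute exactly:
        reached_from_core = set().union(*(nx.descendants(net.graph, c) for c in core)) | core
        rev = net.graph.reverse(copy=False)
        reaches_core = set().union(*(nx.descendants(rev, c) for c in core)) | core
        del seed

    part = BowTiePartition(core=core)
    for node in net.node_ids - core:
        to_core = node in reaches_core
        from_core = node in reached_from_core
        if to_core and not from_core:
            part.input_part.add(node)
        elif from_core and not to_core:
            part.output_part.add(node)
        else:
            part.other.add(node)
    return part


# ---------------------------------------------------------------------------
# Material components
# ---------------------------------------------------------------------------

def material_components(net: Network) -> SubnetworkSet:
    """One subnetwork per protein base name, using node-name semantics.

    A species or complex node belongs to the component of protein P whenever P
    appears among its parsed members — as a free species, in any modification
    state or compartment, or inside a complex.  Reaction-kind nodes are exempt
    from name parsing and are pulled into every component containing at least
    one adjacent species; the component keeps all edges induced on its nodes.
    Components of proteins sharing a complex overlap by construction.
    """
    membership: dict[str, set[str]] = {}
    bad: list[str] = []
    reaction_nodes = net.nodes_of_kind("reaction")
    for nid in net.node_ids - reaction_nodes:
        try:
            entity = parse_entity_name(nid)
        except MalformedNameError:
            bad.append(nid)
            continue
        for base in entity.base_names:
            membership.setdefault(base, set()).add(nid)
    if bad:
        raise MalformedNameError(
            "cannot decompose: unparseable species names: " + ", ".join(sorted(bad))
        )
    out = SubnetworkSet()
    for base in sorted(membership):
        species = membership[base]
        reactions = {
            r
            for r in reaction_nodes
            if any(net.graph.has_edge(r, s) or net.graph.has_edge(s, r) for s in species)
        }
        out[base] = net.induced_subnetwork(species | reactions, name=base)
    return out


# ---------------------------------------------------------------------------
# Cycle decomposition
# ---------------------------------------------------------------------------

def _canonical_rotation(nodes: list[str]) -> tuple[str, ...]:
    """Rotate a circuit so it starts at its lexicographically smallest node."""
    pivot = min(range(len(nodes)), key=lambda i: nodes[i])
    return tuple(nodes[pivot:] + nodes[:pivot])


def enumerate_cycles(
    net: Network,
    max_len: Optional[int] = None,
    cap: int = DEFAULT_CYCLE_CAP,
) -> list[Cycle]:
    """All elementary directed circuits of length ≤ ``max_len``.

    Each circuit is reported once up to rotation, starting at its smallest
    node id.  When the count exceeds ``cap`` a warning is emitted and the list
    is truncated rather than failing — cycle counts can be astronomically
    large on dense maps.
    """
    if max_len is not None and max_len < 1:
        raise ValueError("max_len must be a positive integer")
    seen: set[tuple[str, ...]] = set()
    cycles: list[Cycle] = []
    truncated = False
    for raw in nx.simple_cycles(net.graph, length_bound=max_len):
        canon = _canonical_rotation(list(raw))
        if canon in seen:
            continue
        seen.add(canon)
        edges = tuple(
            (canon[i], canon[(i + 1) % len(canon)]) for i in range(len(canon))
        )
        cycles.append(Cycle(canon, edges))
        if len(cycles) >= cap:
            truncated = True
            break
    if truncated:
        warnings.warn(
            f"cycle enumeration truncated at cap={cap}; raise the cap or lower max_len",
            RuntimeWarning,
            stacklevel=2,
        )
    cycles.sort(key=lambda c: (len(c), c.nodes))
    return cycles


# ---------------------------------------------------------------------------
# Clustering of overlapping subnetworks
# ---------------------------------------------------------------------------

def intersection_percent(a: Network, b: Network) -> float:
    """Node overlap of two subnetworks as a percentage of the smaller one.

    With the min-size denominator, a subnetwork fully contained in another
    scores 100%.  Two empty networks score 0.
    """
    shared = len(a.node_ids & b.node_ids)
    denom = min(a.number_of_nodes(), b.number_of_nodes())
    if denom == 0:
        return 0.0
    return 100.0 * shared / denom


def cluster_subnetworks(subnets: SubnetworkSet, threshold_percent: float) -> SubnetworkSet:
    """Single-linkage agglomeration of overlapping subnetworks.

    Two subnetworks are linked when their intersection is non-empty and covers
    at least ``threshold_percent`` of the smaller one; clusters are the
    connected components of this link graph (links are computed once on the
    original inputs, never recomputed between merged clusters, which keeps the
    result independent of merge order).  Each cluster's output network is the
    node/edge union of its members and its label the '+'-joined member labels.
    """
    if not 0 <= threshold_percent <= 100:
        raise ValueError("threshold_percent must lie in [0, 100]")
    labels = sorted(subnets)
    link_graph = nx.Graph()
    link_graph.add_nodes_from(labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            a, b = subnets[la], subnets[lb]
            if not (a.node_ids & b.node_ids):
                continue
            if intersection_percent(a, b) >= threshold_percent:
                link_graph.add_edge(la, lb)
    out = SubnetworkSet()
    for comp in nx.connected_components(link_graph):
        members = sorted(comp)
        label = "+".join(members)
        union = Network(label)
        for m in members:
            union.graph.update(subnets[m].graph)
        out[label] = union
    return out


def filter_hubs(net: Network, max_degree: int) -> Network:
    """Drop nodes of total degree above ``max_degree`` (optional hub pre-filter
    before cycle decomposition; highly connected hubs inflate cycle counts)."""
    keep = [n for n in net.node_ids if net.graph.degree(n) <= max_degree]
    return net.induced_subnetwork(keep, name=f"{net.name}|nohubs")
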