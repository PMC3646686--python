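"""Semi-automatic modularization: wrap subnetworks into metanodes and link the
modules that share content.

A module graph abstracts a detailed molecular map into metanodes (one per
member subnetwork) joined by undirected links whenever two modules share nodes
or edges; the shared identities are kept as link evidence.  Whether a link
means activation or inhibition between modules is biological knowledge the
modeller supplies, so links here stay unsigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .netmodel import Network
from .decompose import SubnetworkSet


@dataclass(frozen=True)
class ModuleLink:
    """Undirected link between two modules with its sharing evidence."""

    module_a: str
    module_b: str
    shared_nodes: frozenset[str]
    shared_edges: frozenset[tuple[str, str, str]]

    @property
    def evidence_size(self) -> int:
        return len(self.shared_nodes) + len(self.shared_edges)


@dataclass
class ModuleGraph:
    """Metanode graph: module label → member network, plus evidence links."""

    modules: dict[str, Network] = field(default_factory=dict)
    links: list[ModuleLink] = field(default_factory=list)

    def linked_pairs(self) -> set[frozenset[str]]:
        return {frozenset((l.module_a, l.module_b)) for l in self.links}


def _compute_links(modules: dict[str, Network]) -> list[ModuleLink]:
    labels = sorted(modules)
    links = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            a, b = modules[la], modules[lb]
            shared_nodes = a.node_ids & b.node_ids
            shared_edges = a.edge_tuples() & b.edge_tuples()
            if shared_nodes or shared_edges:
                links.append(ModuleLink(la, lb, frozenset(shared_nodes), frozenset(shared_edges)))
    return links


def build_module_graph(subnets: SubnetworkSet) -> ModuleGraph:
    """One metanode per subnetwork; a link for every pair sharing content."""
    if not subnets:
        raise ValueError("need at least one subnetwork to modularize")
    modules = {label: subnets[label] for label in subnets}
    return ModuleGraph(modules=modules, links=_compute_links(modules))


def merge_modules(g: ModuleGraph, labels: list[str], new_label: str) -> ModuleGraph:
    """Replace the listed modules by the node/edge union of their members.

    Links are recomputed from scratch, so merging never loses any node or
    edge of the original map.
    """
    missing = [l for l in labels if l not in g.modules]
    if missing:
        raise KeyError(f"unknown module labels: {missing}")
    union = Network(new_label)
    for label in labels:
        union.graph.update(g.modules[label].graph)
    modules = {l: n for l, n in g.modules.items() if l not in set(labels)}
    modules[new_label] = union
    return ModuleGraph(modules=modules, links=_compute_links(modules))


def module_summary(g: ModuleGraph) -> pd.DataFrame:
    """Per-module node/edge counts and per-module link evidence totals."""
    rows = []
    for label in sorted(g.modules):
        net = g.modules[label]
        evidence = sum(l.evidence_size for l in g.links if label in (l.module_a, l.module_b))
        n_links = sum(1 for l in g.links if label in (l.module_a, l.module_b))
        rows.append(
            {
                "module": label,
                "nodes": net.number_of_nodes(),
                "edges": net.number_of_edges(),
                "links": n_links,
                "shared_items": evidence,
            }
        )
    return pd.DataFrame(rows, columns=["module", "nodes", "edges", "links", "shared_items"])


def module_metanetwork(g: ModuleGraph) -> Network:
    """The abstracted map itself: one node per module, one (undirected pair of)
    edge(s) per link, for export alongside the summary table."""
    meta = Network("modules")
    for label in sorted(g.modules):
        meta.add_node(label, kind="other")
    for link in g.links:
        meta.add_edge(link.module_a, link.module_b, interaction="shares", sign=None)
    return meta
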