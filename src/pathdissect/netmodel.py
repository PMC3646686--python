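"""Core graph data model, semantic entity naming, and network/annotation I/O.

Node identifiers follow the molecular-map naming convention used throughout the
package: complex members are joined by ``:``, post-translational modifications
follow ``|`` and the compartment comes after ``@``.  For example
``Cdc25|Pho@cytoplasm`` is the phosphorylated form of Cdc25 located in the
cytoplasm, and ``Cdc13:Cdc2|Thr167_pho@cytoplasm`` is a two-member complex whose
second member carries a Thr167 phosphorylation.

Networks are directed multigraphs (parallel edges with different interaction
labels are kept distinct) backed by :class:`networkx.MultiDiGraph`.  Supported
interchange formats are SIF, GraphML and XGMML; node annotation tables are
plain two-column TSV files mapping node id to a signed real value (for example
a tumour-vs-normal t statistic).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx

logger = logging.getLogger(__name__)

RESERVED_DELIMITERS = ("|", ":", "@")

#: Node kinds understood by the toolkit. ``species`` covers chemical species,
#: ``complex`` multi-member assemblies, ``reaction`` process nodes,
#: ``phenotype`` abstract read-outs (e.g. "proliferation"), ``gene`` genes.
NODE_KINDS = ("species", "complex", "reaction", "phenotype", "gene", "other")

#: Default mapping of SIF interaction labels to edge signs. Labels not listed
#: produce unsigned edges.
DEFAULT_SIGN_TABLE: dict[str, int] = {
    "activates": +1,
    "activation": +1,
    "activate": +1,
    "catalysis": +1,
    "inhibits": -1,
    "inhibition": -1,
    "inhibit": -1,
}


class MalformedNameError(ValueError):
    """Raised when an entity-name string violates the naming grammar."""


class NetworkFormatError(ValueError):
    """Raised on unreadable or malformed network/annotation files."""


# ---------------------------------------------------------------------------
# Semantic entity names
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesForm:
    """A single species in a particular modification state.

    Parameters
    ----------
    base_name : str
        Bare species name; must not contain the reserved delimiters.
    modifications : tuple of str
        Ordered modification tags, e.g. ``("Pho",)`` or ``("Thr167_pho",)``.
    """

    base_name: str
    modifications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.base_name:
            raise MalformedNameError("species base name must be non-empty")
        for delim in RESERVED_DELIMITERS:
            if delim in self.base_name:
                raise MalformedNameError(
                    f"base name {self.base_name!r} contains reserved delimiter {delim!r}"
                )

    def format(self) -> str:
        return "|".join((self.base_name, *self.modifications))


@dataclass(frozen=True)
class EntityName:
    """A parsed semantic node name: complex members plus optional compartment."""

    members: tuple[SpeciesForm, ...]
    compartment: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise MalformedNameError("entity name needs at least one member")

    @property
    def is_complex(self) -> bool:
        return len(self.members) > 1

    @property
    def base_names(self) -> tuple[str, ...]:
        return tuple(m.base_name for m in self.members)

    def format(self) -> str:
        s = ":".join(m.format() for m in self.members)
        if self.compartment is not None:
            s += "@" + self.compartment
        return s


def parse_entity_name(s: str) -> EntityName:
    """Parse an entity-name string into its semantic parts.

    The grammar splits on the last ``@`` (compartment), then on ``:`` (complex
    members), then on ``|`` within each member (base name followed by
    modification tags).  Whitespace around every token is trimmed, so the
    loosely-spaced form ``"Cdc25 |Pho@cytoplasm"`` parses identically to the
    canonical ``"Cdc25|Pho@cytoplasm"``.

    Raises
    ------
    MalformedNameError
        If the string, a member, or a base name is empty.
    """
    if not s or not s.strip():
        raise MalformedNameError("entity name is empty")
    compartment: Optional[str] = None
    body = s
    if "@" in s:
        body, _, comp = s.rpartition("@")
        compartment = comp.strip()
        if not body.strip():
            raise MalformedNameError(f"entity name {s!r} has no member part")
        if not compartment:
            raise MalformedNameError(f"entity name {s!r} has an empty compartment")
    members = []
    for raw_member in body.split(":"):
        if not raw_member.strip():
            raise MalformedNameError(f"entity name {s!r} contains an empty member")
        tokens = [tok.strip() for tok in raw_member.split("|")]
        base, mods = tokens[0], tokens[1:]
        if not base:
            raise MalformedNameError(f"member {raw_member!r} of {s!r} has an empty base name")
        if any(not m for m in mods):
            raise MalformedNameError(f"member {raw_member!r} of {s!r} has an empty modification")
        members.append(SpeciesForm(base, tuple(mods)))
    return EntityName(tuple(members), compartment)


def format_entity_name(e: EntityName) -> str:
    """Serialize an :class:`EntityName` to its canonical string (no spaces)."""
    return e.format()


def canonical_name(s: str) -> str:
    """Canonicalize a name string: ``canonical_name == format ∘ parse``."""
    return format_entity_name(parse_entity_name(s))


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    """A directed, optionally signed interaction between two nodes."""

    source: str
    target: str
    interaction: str = "interacts"
    sign: Optional[int] = None  # +1, -1 or None (unsigned)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (None, 1, -1):
            raise ValueError(f"edge sign must be +1, -1 or None, got {self.sign!r}")
        if not self.weight > 0:
            raise ValueError(f"edge weight must be positive, got {self.weight!r}")


class Network:
    """A named directed multigraph of typed nodes and signed/typed edges.

    Thin wrapper over :class:`networkx.MultiDiGraph` adding node kinds, edge
    sign/weight conventions, and set-algebra helpers.  Node attributes live in
    ``graph.nodes[nid]``; each edge carries ``interaction``, ``sign`` and
    ``weight`` attributes.
    """

    def __init__(self, name: str = "network") -> None:
        self.name = name
        self.graph = nx.MultiDiGraph(name=name)

    # -- construction -------------------------------------------------------
    def add_node(self, node_id: str, kind: str = "species", **attrs) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        self.graph.add_node(node_id, kind=kind, **attrs)

    def add_edge(
        self,
        source: str,
        target: str,
        interaction: str = "interacts",
        sign: Optional[int] = None,
        weight: float = 1.0,
        **attrs,
    ) -> None:
        """Add a directed edge; endpoints are created as species if absent."""
        Edge(source, target, interaction, sign, weight)  # validate
        for nid in (source, target):
            if nid not in self.graph:
                self.add_node(nid)
        self.graph.add_edge(
            source, target, interaction=interaction, sign=sign, weight=weight, **attrs
        )

    # -- inspection ---------------------------------------------------------
    @property
    def node_ids(self) -> set[str]:
        return set(self.graph.nodes)

    def node_kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id].get("kind", "species")

    def nodes_of_kind(self, *kinds: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind", "species") in kinds}

    def edges(self) -> Iterator[Edge]:
        for u, v, d in self.graph.edges(data=True):
            yield Edge(u, v, d.get("interaction", "interacts"), d.get("sign"), d.get("weight", 1.0))

    def edge_tuples(self) -> set[tuple[str, str, str]]:
        """(source, target, interaction) triples, the edge identity used by set algebra."""
        return {(u, v, d.get("interaction", "interacts")) for u, v, d in self.graph.edges(data=True)}

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_sign(self, source: str, target: str, key=None) -> Optional[int]:
        if key is None:
            key = next(iter(self.graph[source][target]))
        return self.graph[source][target][key].get("sign")

    # -- derived networks ---------------------------------------------------
    def induced_subnetwork(self, node_ids: Iterable[str], name: Optional[str] = None) -> "Network":
        """Subnetwork on ``node_ids`` with every edge whose endpoints survive."""
        keep = set(node_ids) & self.node_ids
        sub = Network(name or f"{self.name}|sub")
        sub.graph = self.graph.subgraph(keep).copy()
        sub.graph.name = sub.name
        return sub

    def copy(self, name: Optional[str] = None) -> "Network":
        out = Network(name or self.name)
        out.graph = self.graph.copy()
        out.graph.name = out.name
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return (
            f"<Network {self.name!r}: {self.number_of_nodes()} nodes, "
            f"{self.number_of_edges()} edges>"
        )


def network_intersection(a: Network, b: Network) -> Network:
    """Nodes present in both networks; edges whose (source, target, interaction)
    triple occurs in both.  Commutative and idempotent on node/edge identities."""
    out = Network(f"({a.name})&({b.name})")
    shared_nodes = a.node_ids & b.node_ids
    for nid in sorted(shared_nodes):
        out.graph.add_node(nid, **a.graph.nodes[nid])
    shared_edges = a.edge_tuples() & b.edge_tuples()
    for u, v, k, d in a.graph.edges(keys=True, data=True):
        if (u, v, d.get("interaction", "interacts")) in shared_edges:
            out.graph.add_edge(u, v, **d)
            shared_edges.discard((u, v, d.get("interaction", "interacts")))
    return out


def network_difference_double(a: Network, b: Network) -> tuple[Network, Network]:
    """The two one-sided differences ``(A − A∩B, B − A∩B)`` on node ids.

    Only edges with both endpoints surviving are kept, so the pair together
    with the intersection reconstructs each input's node set exactly.
    """
    shared = a.node_ids & b.node_ids
    left = a.induced_subnetwork(a.node_ids - shared, name=f"({a.name})-({b.name})")
    right = b.induced_subnetwork(b.node_ids - shared, name=f"({b.name})-({a.name})")
    return left, right


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Map from node id to a signed real experimental value."""

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, node_id: str) -> float:
        return self.values[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.values

    def __len__(self) -> int:
        return len(self.values)

    def scaled(self, c: float) -> "AnnotationTable":
        return AnnotationTable({k: c * v for k, v in self.values.items()})

    def unmatched_ids(self, net: Network) -> set[str]:
        """Annotation keys that do not name a node of ``net`` (reported, never dropped)."""
        return set(self.values) - net.node_ids


def read_annotations(path) -> AnnotationTable:
    """Read a two-column TSV (node id, signed real value).

    A first line whose second field is not numeric is treated as a header.
    Duplicate ids keep the last value, with a logged warning.
    """
    table: dict[str, float] = {}
    lines = FilePath(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) < 2:
            raise NetworkFormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
        node_id, raw = parts[0].strip(), parts[1].strip()
        try:
            value = float(raw)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise NetworkFormatError(
                f"{path}:{lineno}: non-numeric annotation value {raw!r}"
            ) from None
        if node_id in table:
            logger.warning("duplicate annotation for %r at line %d; last value wins", node_id, lineno)
        table[node_id] = value
    return AnnotationTable(table)


def write_annotations(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tvalue\n")
        for nid, val in table.values.items():
            fh.write(f"{nid}\t{val}\n")


# ---------------------------------------------------------------------------
# Network readers / writers
# ---------------------------------------------------------------------------

def read_network(path, format: str, sign_table: Optional[Mapping[str, int]] = None) -> Network:
    """Read a network file in SIF, GraphML or XGMML format.

    For SIF, interaction labels are mapped to edge signs through ``sign_table``
    (default :data:`DEFAULT_SIGN_TABLE`); unlisted labels give unsigned edges.
    GraphML/XGMML preserve node kinds and edge interaction/sign/weight
    attributes as written.
    """
    fmt = format.lower()
    if fmt == "sif":
        return _read_sif(path, sign_table)
    if fmt == "graphml":
        return _read_graphml(path)
    if fmt == "xgmml":
        return _read_xgmml(path)
    raise NetworkFormatError(f"unknown network format {format!r}")


def write_network(net: Network, path, format: str) -> None:
    fmt = format.lower()
    if fmt == "sif":
        _write_sif(net, path)
    elif fmt == "graphml":
        _write_graphml(net, path)
    elif fmt == "xgmml":
        _write_xgmml(net, path)
    else:
        raise NetworkFormatError(f"unknown network format {format!r}")


def _read_sif(path, sign_table: Optional[Mapping[str, int]]) -> Network:
    table = DEFAULT_SIGN_TABLE if sign_table is None else dict(sign_table)
    net = Network(FilePath(path).stem)
    try:
        text = FilePath(path).read_text()
    except OSError as exc:
        raise NetworkFormatError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        # tab-delimited when tabs are present (allows spaces in node names)
        fields = [f.strip() for f in (line.split("\t") if "\t" in line else line.split())]
        fields = [f for f in fields if f]
        if len(fields) == 1:
            net.add_node(fields[0])  # isolated node line
            continue
        if len(fields) < 3:
            raise NetworkFormatError(
                f"{path}:{lineno}: SIF line needs 'source interaction target...', got {line!r}"
            )
        source, interaction, targets = fields[0], fields[1], fields[2:]
        sign = table.get(interaction.lower())
        for target in targets:
            net.add_edge(source, target, interaction=interaction, sign=sign)
    return net


def _write_sif(net: Network, path) -> None:
    with open(path, "w") as fh:
        linked: set[str] = set()
        for u, v, d in sorted(
            net.graph.edges(data=True),
            key=lambda e: (e[0], e[1], e[2].get("interaction", "")),
        ):
            fh.write(f"{u}\t{d.get('interaction', 'interacts')}\t{v}\n")
            linked.update((u, v))
        for nid in sorted(net.node_ids - linked):
            fh.write(f"{nid}\n")


def _read_graphml(path) -> Network:
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except OSError as exc:
        raise NetworkFormatError(f"cannot read {path}: {exc}") from exc
    net = Network(g.graph.get("name", FilePath(path).stem))
    for nid, d in g.nodes(data=True):
        attrs = dict(d)
        kind = attrs.pop("kind", "species")
        net.add_node(str(nid), kind=kind, **attrs)
    for u, v, d in g.edges(data=True):
        attrs = dict(d)
        sign = attrs.pop("sign", None)
        net.add_edge(
            str(u),
            str(v),
            interaction=attrs.pop("interaction", "interacts"),
            sign=None if sign is None else int(sign),
            weight=float(attrs.pop("weight", 1.0)),
            **attrs,
        )
    return net


def _write_graphml(net: Network, path) -> None:
    g = nx.MultiDiGraph(name=net.name)
    for nid, d in net.graph.nodes(data=True):
        g.add_node(nid, **{k: v for k, v in d.items() if v is not None})
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, **{k: v for k, v in d.items() if v is not None})
    nx.write_graphml(g, path)


_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def _write_xgmml(net: Network, path) -> None:
    root = ET.Element("graph", {"label": net.name, "directed": "1", "xmlns": _XGMML_NS})
    for nid, d in sorted(net.graph.nodes(data=True)):
        node_el = ET.SubElement(root, "node", {"id": nid, "label": nid})
        for key, val in d.items():
            if val is None:
                continue
            ET.SubElement(node_el, "att", {"name": key, "value": str(val), "type": "string"})
    for u, v, d in net.graph.edges(data=True):
        edge_el = ET.SubElement(
            root, "edge", {"source": u, "target": v, "label": d.get("interaction", "interacts")}
        )
        for key, typ in (("interaction", "string"), ("sign", "integer"), ("weight", "real")):
            val = d.get(key)
            if val is None:
                continue
            ET.SubElement(edge_el, "att", {"name": key, "value": str(val), "type": typ})
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def _read_xgmml(path) -> Network:
    try:
        tree = ET.parse(path)
    except (OSError, ET.ParseError) as exc:
        raise NetworkFormatError(f"cannot read {path}: {exc}") from exc
    root = tree.getroot()
    ns = {"x": _XGMML_NS} if root.tag.startswith("{") else {}
    prefix = "x:" if ns else ""
    net = Network(root.get("label", FilePath(path).stem))
    for node_el in root.findall(f"{prefix}node", ns):
        nid = node_el.get("id") or node_el.get("label")
        attrs = {
            att.get("name"): att.get("value") for att in node_el.findall(f"{prefix}att", ns)
        }
        kind = attrs.pop("kind", "species")
        net.add_node(nid, kind=kind, **attrs)
    for edge_el in root.findall(f"{prefix}edge", ns):
        attrs = {
            att.get("name"): (att.get("value"), att.get("type", "string"))
            for att in edge_el.findall(f"{prefix}att", ns)
        }
        sign_raw = attrs.pop("sign", (None, None))[0]
        weight_raw = attrs.pop("weight", ("1.0", None))[0]
        interaction = attrs.pop("interaction", (edge_el.get("label", "interacts"), None))[0]
        net.add_edge(
            edge_el.get("source"),
            edge_el.get("target"),
            interaction=interaction,
            sign=None if sign_raw is None else int(sign_raw),
            weight=float(weight_raw),
            **{k: v for k, (v, _) in attrs.items()},
        )
    return net
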