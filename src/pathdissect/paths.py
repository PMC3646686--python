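"""Path-analysis algorithms: shortest paths, optimal plus suboptimal shortest
paths, and all non-self-intersecting paths, all directed with finite-radius
(maximum length) support.

Every algorithm returns :class:`Path` objects carrying the three quantities
downstream scoring needs: the length λ (number of edges), the sign σ (product
of edge signs, undefined if any edge is unsigned) and, once bound to an
annotation table, the annotation α of the first node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product as iter_product
from typing import Optional

import networkx as nx

from .netmodel import Network


class NegativeWeightError(ValueError):
    """Dijkstra requires non-negative edge weights."""


class UnknownNodeError(KeyError):
    """A source or target id does not name a node of the network."""


@dataclass(frozen=True)
class Path:
    """A directed non-self-intersecting path.

    ``edges`` stores (source, target, key) triples into the owning multigraph,
    so parallel edges between the same nodes give distinct paths.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, object], ...]
    sign: Optional[int]  # σ: product of edge signs; None if any edge unsigned
    annotation: Optional[float] = None  # α: value of the first node, if bound

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("a path needs at least one edge")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path is self-intersecting")
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError("edge count must be node count minus one")

    @property
    def length(self) -> int:
        """λ: the number of edges in the path."""
        return len(self.edges)

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    def with_annotation(self, alpha: float) -> "Path":
        return Path(self.nodes, self.edges, self.sign, alpha)

    def key(self) -> tuple:
        """Identity used for deduplication: node sequence plus edge keys."""
        return (self.nodes, tuple(k for _, _, k in self.edges))


def _check_endpoints(net: Network, source: str, target: str) -> None:
    for nid in (source, target):
        if nid not in net.graph:
            raise UnknownNodeError(f"node {nid!r} not in network {net.name!r}")
    if source == target:
        raise ValueError("source and target must differ (paths have length >= 1)")


def _path_sign(net: Network, edges) -> Optional[int]:
    sign = 1
    for u, v, k in edges:
        s = net.graph[u][v][k].get("sign")
        if s is None:
            return None
        sign *= s
    return sign


def _expand(net: Network, node_path: list[str], weighted: bool) -> list[Path]:
    """Expand a node sequence into one Path per choice of parallel edges.

    With weights, only minimum-weight parallel edges keep the path co-optimal.
    """
    choices = []
    for u, v in zip(node_path, node_path[1:]):
        data = net.graph[u][v]
        if weighted:
            wmin = min(d.get("weight", 1.0) for d in data.values())
            keys = [k for k, d in data.items() if d.get("weight", 1.0) == wmin]
        else:
            keys = list(data)
        choices.append([(u, v, k) for k in keys])
    out = []
    for combo in iter_product(*choices):
        out.append(Path(tuple(node_path), tuple(combo), _path_sign(net, combo)))
    return out


def _sorted(paths: list[Path]) -> list[Path]:
    return sorted(paths, key=lambda p: (p.length, p.nodes, tuple(map(str, (k for *_, k in p.edges)))))


def shortest_paths(
    net: Network, source: str, target: str, use_weights: bool = False
) -> list[Path]:
    """All co-optimal directed shortest paths from source to target (Dijkstra).

    Unit edge weights unless ``use_weights``; every tie is returned because
    downstream influence scoring needs the full path set, not one witness.
    An unreachable target yields an empty list; a negative weight is an error.
    """
    _check_endpoints(net, source, target)
    weight = "weight" if use_weights else None
    if use_weights and any(d.get("weight", 1.0) < 0 for _, _, d in net.graph.edges(data=True)):
        raise NegativeWeightError("negative edge weights are not supported")
    try:
        node_paths = list(nx.all_shortest_paths(net.graph, source, target, weight=weight))
    except nx.NetworkXNoPath:
        return []
    out: list[Path] = []
    seen: set[tuple[str, ...]] = set()
    for np_ in node_paths:
        key = tuple(np_)
        if key in seen:  # multigraph searches may repeat a node sequence
            continue
        seen.add(key)
        out.extend(_expand(net, np_, weighted=use_weights))
    return _sorted(out)


def suboptimal_shortest_paths(
    net: Network, source: str, target: str, use_weights: bool = False
) -> tuple[list[Path], list[Path]]:
    """Optimal shortest paths plus the suboptimal ones found by edge removal.

    Every edge lying on any optimal path is deleted one at a time (never
    cumulatively); the shortest paths of each edge-deleted network are pooled,
    deduplicated, and any path that was already optimal is excluded.
    """
    optimal = shortest_paths(net, source, target, use_weights)
    optimal_keys = {p.key() for p in optimal}
    used_edges = {e for p in optimal for e in p.edges}
    suboptimal: dict[tuple, Path] = {}
    for u, v, k in sorted(used_edges, key=str):
        pruned = net.copy()
        pruned.graph.remove_edge(u, v, k)
        for p in shortest_paths(pruned, source, target, use_weights):
            # re-anchor the path in the original network (same keys survive)
            p = Path(p.nodes, p.edges, _path_sign(net, p.edges))
            if p.key() not in optimal_keys:
                suboptimal.setdefault(p.key(), p)
    return optimal, _sorted(list(suboptimal.values()))


def all_nonself_paths(
    net: Network,
    source: str,
    target: str,
    max_len: int,
    cap: Optional[int] = None,
) -> list[Path]:
    """Every directed simple path of length ≤ ``max_len`` from source to target.

    A breadth-limited search over non-self-intersecting node sequences; the
    optional ``cap`` truncates the result with a warning since path counts can
    be very large on big networks.
    """
    if max_len < 1:
        raise ValueError("max_len must be a positive integer")
    _check_endpoints(net, source, target)
    out: list[Path] = []
    truncated = False
    seen: set[tuple[str, ...]] = set()
    for np_ in nx.all_simple_paths(net.graph, source, target, cutoff=max_len):
        key = tuple(np_)
        if key in seen:
            continue
        seen.add(key)
        for p in _expand(net, list(np_), weighted=False):
            out.append(p)
            if cap is not None and len(out) >= cap:
                truncated = True
                break
        if truncated:
            break
    if truncated:
        warnings.warn(
            f"path enumeration truncated at cap={cap}", RuntimeWarning, stacklevel=2
        )
    return _sorted(out)
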