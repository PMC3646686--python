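"""Independent brute-force oracles used to cross-check the library.

Everything here works on plain adjacency structures extracted from a Network
and uses only exhaustive search / transitive closure, never the algorithms
under test.
"""

from __future__ import annotations

from collections import deque


def simple_adjacency(net) -> dict[str, set[str]]:
    """Successor map ignoring parallel-edge multiplicity."""
    adj: dict[str, set[str]] = {n: set() for n in net.node_ids}
    for u, v, _ in net.edge_tuples():
        adj[u].add(v)
    return adj


def reachable_from(adj: dict[str, set[str]], start: str) -> set[str]:
    """Transitive closure of one node by plain BFS."""
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def oracle_scc(adj: dict[str, set[str]]) -> list[set[str]]:
    """SCCs via pairwise mutual reachability (O(n^2) BFS closures)."""
    closure = {n: reachable_from(adj, n) for n in adj}
    assigned: set[str] = set()
    comps: list[set[str]] = []
    for n in sorted(adj):
        if n in assigned:
            continue
        comp = {m for m in closure[n] if n in closure[m]}
        comps.append(comp)
        assigned |= comp
    return sorted(comps, key=lambda c: min(c))


def oracle_simple_paths(
    adj: dict[str, set[str]], source: str, target: str, max_len: int
) -> list[tuple[str, ...]]:
    """Exhaustive recursive enumeration of simple directed paths."""
    out: list[tuple[str, ...]] = []

    def walk(path: list[str]) -> None:
        if path[-1] == target and len(path) > 1:
            out.append(tuple(path))
            return
        if len(path) - 1 >= max_len:
            return
        for nxt in sorted(adj.get(path[-1], ())):
            if nxt not in path:
                walk(path + [nxt])

    walk([source])
    return sorted(out, key=lambda p: (len(p), p))


def oracle_cycles(adj: dict[str, set[str]]) -> set[tuple[str, ...]]:
    """All elementary circuits, canonicalized to start at their smallest node.

    DFS from every node, only keeping cycles whose start is the smallest
    member (which both dedupes rotations and bounds the search).
    """
    cycles: set[tuple[str, ...]] = set()

    def walk(start: str, path: list[str]) -> None:
        for nxt in sorted(adj.get(path[-1], ())):
            if nxt == start:
                cycles.add(tuple(path))
            elif nxt not in path and nxt > start:
                walk(start, path + [nxt])

    for n in sorted(adj):
        if n in adj.get(n, ()):
            cycles.add((n,))
        walk(n, [n])
    return cycles


def oracle_piquant(net, annotations, annotated, targets, max_len) -> dict[str, float]:
    """Direct sum of annotation * sign-product / length over every simple path."""
    adj = simple_adjacency(net)
    sign_of = {}
    for u, v, _ in net.edge_tuples():
        key = next(iter(net.graph[u][v]))
        sign_of[(u, v)] = net.graph[u][v][key].get("sign")
    scores = {t: 0.0 for t in targets}
    for t in targets:
        for a in annotated:
            if a == t:
                continue
            for path in oracle_simple_paths(adj, a, t, max_len):
                sign = 1
                for u, v in zip(path, path[1:]):
                    sign *= sign_of[(u, v)]
                scores[t] += annotations[a] * sign / (len(path) - 1)
    return scores
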