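"""Deterministic generators for test and demonstration inputs.

Everything here is a pure function of its arguments (including the seed), so
identical calls serialize bit-identically.  The generators cover the small
worked-example influence network, Erdős–Rényi random digraphs for
property-based checks, toy reaction networks exercising the
reaction-to-influence reduction, and a synthetic analogue of a cell-cycle
case study (a mid-size annotated influence network with phenotype targets).
No external map or expression dataset is downloaded; real data are emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .netmodel import AnnotationTable, Network
from .influence import CATALYSIS, INHIBITION, PRODUCT, REACTANT

FIXTURE_KINDS = ("fig_example", "random_digraph", "toy_reactions", "case_study_analogue")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a fixture; identical specs give identical output."""

    kind: str
    seed: int = 0
    parameters: tuple[tuple[str, Any], ...] = field(default_factory=tuple)


def make_fixture(spec: FixtureSpec):
    params = dict(spec.parameters)
    if spec.kind == "fig_example":
        return make_example_influence_network()
    if spec.kind == "random_digraph":
        return random_digraph(
            params.get("n", 10), params.get("p", 0.2), params.get("signed", True), spec.seed
        )
    if spec.kind == "toy_reactions":
        return toy_reaction_network(spec.seed)
    if spec.kind == "case_study_analogue":
        return case_study_analogue(spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def make_example_influence_network() -> tuple[Network, AnnotationTable]:
    """The small worked-example influence network: seven nodes, nine edges.

    The annotated node ``Ac`` carries the experimental value 2.0 and the
    target ``Ph`` is a phenotype read-out.  Exactly two non-self-intersecting
    paths lead from Ac to Ph: an all-activating one of length 3
    (Ac→A→B→Ph, sign +1) and one of length 5 passing through a single
    inhibition (Ac→C→D→E⊣B→Ph, sign −1), so the pathway-influence score of
    Ph is 2·(1/3) − 2·(1/5) = 0.2667 ≈ 0.27.  The two feedback edges from Ph
    close cycles without creating further Ac→Ph paths.
    """
    net = Network("example_influence")
    for nid in ("Ac", "A", "B", "C", "D", "E"):
        net.add_node(nid, kind="species")
    net.add_node("Ph", kind="phenotype")
    edges = [
        ("Ac", "A", +1),
        ("A", "B", +1),
        ("B", "Ph", +1),
        ("Ac", "C", +1),
        ("C", "D", +1),
        ("D", "E", +1),
        ("E", "B", -1),
        ("Ph", "Ac", +1),
        ("Ph", "D", +1),
    ]
    for u, v, s in edges:
        net.add_edge(u, v, interaction="activates" if s > 0 else "inhibits", sign=s)
    return net, AnnotationTable({"Ac": 2.0})


def random_digraph(n: int, p: float, signed: bool = True, seed: int = 0) -> Network:
    """Erdős–Rényi G(n, p) directed graph with optional uniform ±1 signs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    net = Network(f"er_n{n}_p{p}_s{seed}")
    names = [f"n{i:02d}" for i in range(n)]
    for name in names:
        net.add_node(name, kind="species")
    for u in names:
        for v in names:
            if u == v:
                continue
            if rng.random() < p:
                sign = int(rng.choice((-1, 1))) if signed else None
                label = (
                    "interacts" if sign is None else ("activates" if sign > 0 else "inhibits")
                )
                net.add_edge(u, v, interaction=label, sign=sign)
    return net


def toy_reaction_network(seed: int = 0) -> Network:
    """A small reaction network exercising every reduction rule.

    Contains an unregulated degradation (of X), a single-in/single-out
    intermediary (I between the A→I and I→B reactions, the latter catalysed
    by E), a catalysis and an inhibition modifier, plus one seed-dependent
    extra modifier so different seeds give structurally distinct instances.
    """
    rng = np.random.default_rng(seed)
    net = Network(f"toy_reactions_s{seed}")
    for s in ("A", "B", "I", "X", "E", "M", "S", "P"):
        net.add_node(s, kind="species")
    for r in ("R1", "R2", "R3", "R4"):
        net.add_node(r, kind="reaction")
    # A -> I (R1), then I -> B (R2) catalysed by E: I splices out
    net.add_edge("A", "R1", interaction=REACTANT)
    net.add_edge("R1", "I", interaction=PRODUCT)
    net.add_edge("I", "R2", interaction=REACTANT)
    net.add_edge("R2", "B", interaction=PRODUCT)
    net.add_edge("E", "R2", interaction=CATALYSIS)
    # unregulated degradation of X: disappears under rule 1
    net.add_edge("X", "R3", interaction=REACTANT)
    # S -> P (R4) inhibited by M
    net.add_edge("S", "R4", interaction=REACTANT)
    net.add_edge("R4", "P", interaction=PRODUCT)
    net.add_edge("M", "R4", interaction=INHIBITION)
    extra = f"Mod{int(rng.integers(0, 100)):02d}"
    net.add_node(extra, kind="species")
    net.add_edge(
        extra, "R4", interaction=CATALYSIS if rng.random() < 0.5 else INHIBITION
    )
    return net


def case_study_analogue(
    seed: int = 0, n_species: int = 30, n_annotated: int = 19, edge_p: float = 0.08
) -> tuple[Network, AnnotationTable, list[str]]:
    """A synthetic stand-in for a cell-cycle-style annotated influence network.

    Synthetic: emulates the shape of a real case study — a mid-size signed
    influence network, three phenotype markers wired downstream, and signed
    t-statistic-like annotations on a subset of species — without using any
    real map or expression data.  Returns (network, annotations, targets).
    """
    rng = np.random.default_rng(seed)
    net = random_digraph(n_species, edge_p, signed=True, seed=seed)
    species = sorted(net.node_ids)
    targets = ["phase_G1", "phase_S", "phase_M"]
    for t in targets:
        net.add_node(t, kind="phenotype")
        feeders = rng.choice(species, size=4, replace=False)
        for f in feeders:
            sign = int(rng.choice((-1, 1)))
            net.add_edge(
                str(f), t, interaction="activates" if sign > 0 else "inhibits", sign=sign
            )
    annotated = rng.choice(species, size=min(n_annotated, len(species)), replace=False)
    values = {str(a): float(np.round(rng.normal(0.0, 3.0), 3)) for a in sorted(annotated)}
    return net, AnnotationTable(values), targets
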