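"""Reduction of a biochemical reaction network to a signed influence network.

A reaction network is bipartite-style: species nodes connect to reaction nodes
through ``reactant`` edges (species → reaction), ``product`` edges (reaction →
species) and modifier edges labelled ``catalysis`` (positive regulation) or
``inhibition`` (negative regulation).  The reduction applies four
preprocessing rules, in order, to a fixpoint:

1. delete synthesis and degradation reactions with no modifier (non-regulated
   sources and sinks carry no regulatory information);
2. splice out intermediary species with exactly one producing and one
   consuming reaction;
3. merge the reaction pair around a spliced species when its inputs and
   outputs are distinct chemical species;
4. when the pair has the same species as input and output, the pair is a
   reversible reaction and collapses to a single degradation.

It then emits species-to-species signed edges: reactant → product carries +1,
a catalysing modifier carries +1 and an inhibiting modifier −1 onto every
product; a modifier of a degradation influences the degraded species with the
opposite of its sign (enhancing degradation lowers the species), and the
degradation itself appears as a −1 self-influence.  The output contains only
species/phenotype nodes, ready for pathway-influence scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .netmodel import Network

REACTANT = "reactant"
PRODUCT = "product"
CATALYSIS = "catalysis"
INHIBITION = "inhibition"
EDGE_ROLES = (REACTANT, PRODUCT, CATALYSIS, INHIBITION)


class ReactionNetworkError(ValueError):
    """Raised on unclassifiable edges or malformed reaction topology."""


@dataclass
class _Reaction:
    """Working record of one reaction during reduction."""

    name: str
    reactants: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    modifiers: list[tuple[str, int]] = field(default_factory=list)  # (species, ±1)
    degradation: bool = False  # rule-4 collapsed reversible pair


def _collect_reactions(net: Network) -> tuple[dict[str, _Reaction], set[str]]:
    reactions: dict[str, _Reaction] = {}
    species = net.node_ids - net.nodes_of_kind("reaction")
    for r in sorted(net.nodes_of_kind("reaction")):
        reactions[r] = _Reaction(r)
    for u, v, d in net.graph.edges(data=True):
        role = d.get("interaction", "")
        if role not in EDGE_ROLES:
            raise ReactionNetworkError(
                f"edge {u!r} -> {v!r} has unclassified label {role!r}; "
                f"expected one of {EDGE_ROLES}"
            )
        if role == REACTANT:
            if v not in reactions:
                raise ReactionNetworkError(f"reactant edge {u!r} -> {v!r} must point at a reaction")
            reactions[v].reactants.append(u)
        elif role == PRODUCT:
            if u not in reactions:
                raise ReactionNetworkError(f"product edge {u!r} -> {v!r} must leave a reaction")
            reactions[u].products.append(v)
        else:
            if v not in reactions:
                raise ReactionNetworkError(f"modifier edge {u!r} -> {v!r} must point at a reaction")
            reactions[v].modifiers.append((u, +1 if role == CATALYSIS else -1))
    return reactions, species


def reduce_reaction_network(net: Network) -> Network:
    """Apply the four reduction rules to a fixpoint and emit the signed
    influence network.

    Intermediary species are spliced only when they are the unique product of
    their producing reaction and the unique reactant of their consuming one;
    candidates entangled with multi-output/multi-input reactions or reaction
    self-loops are left in place with a warning rather than guessed at.
    """
    reactions, species = _collect_reactions(net)
    removed_species: set[str] = set()

    changed = True
    while changed:
        changed = False
        # rule 1: drop unregulated syntheses (no reactants) and degradations
        # (no products); only regulation is informative downstream
        for rname in sorted(reactions):
            r = reactions[rname]
            if (not r.reactants or not r.products) and not r.modifiers and not r.degradation:
                del reactions[rname]
                changed = True
        # rules 2-4: splice single-in/single-out intermediaries
        producers: dict[str, list[str]] = {}
        consumers: dict[str, list[str]] = {}
        modified: set[str] = set()
        for rname, r in reactions.items():
            for p in r.products:
                producers.setdefault(p, []).append(rname)
            for s in r.reactants:
                consumers.setdefault(s, []).append(rname)
            modified.update(m for m, _ in r.modifiers)
        for inter in sorted(species - removed_species):
            prod = producers.get(inter, [])
            cons = consumers.get(inter, [])
            if len(prod) != 1 or len(cons) != 1 or inter in modified:
                continue
            (r1name,), (r2name,) = prod, cons
            if r1name == r2name:
                warnings.warn(
                    f"species {inter!r} cycles through reaction {r1name!r}; left unspliced",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            r1, r2 = reactions[r1name], reactions[r2name]
            if r1.products != [inter] or r2.reactants != [inter]:
                warnings.warn(
                    f"species {inter!r} shares reactions with other species; left unspliced",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            merged = _Reaction(
                f"{r1name}+{r2name}",
                reactants=list(r1.reactants),
                products=list(r2.products),
                modifiers=list(r1.modifiers) + list(r2.modifiers),
            )
            if merged.reactants and sorted(merged.reactants) == sorted(merged.products):
                # rule 4: reversible pair A -> I -> A collapses to a degradation of A
                merged.products = []
                merged.degradation = True
            del reactions[r1name], reactions[r2name]
            reactions[merged.name] = merged
            removed_species.add(inter)
            changed = True
            break  # topology changed; rebuild the incidence maps

    out = Network(f"{net.name}|influence")
    for s in sorted(species - removed_species):
        out.add_node(s, kind=net.node_kind(s))
    for rname in sorted(reactions):
        r = reactions[rname]
        if r.degradation or not r.products:
            for a in r.reactants:
                out.add_edge(a, a, interaction="degradation", sign=-1)
                for m, s in r.modifiers:
                    out.add_edge(m, a, interaction="activates" if -s > 0 else "inhibits", sign=-s)
            continue
        for p in r.products:
            for a in r.reactants:
                out.add_edge(a, p, interaction="activates", sign=+1)
            for m, s in r.modifiers:
                out.add_edge(m, p, interaction="activates" if s > 0 else "inhibits", sign=s)
    return out


def assign_edge_signs(net: Network, table: dict[str, int]) -> Network:
    """Sign unsigned edges through an interaction-label → sign table.

    Already-signed edges are preserved untouched, so the operation is
    idempotent; an unsigned edge whose label is absent from the table is an
    error.
    """
    out = net.copy()
    for u, v, k, d in out.graph.edges(keys=True, data=True):
        if d.get("sign") is not None:
            continue
        label = d.get("interaction", "interacts")
        if label not in table:
            raise ReactionNetworkError(
                f"edge {u!r} -> {v!r}: label {label!r} is unsigned and not in the sign table"
            )
        d["sign"] = int(table[label])
    return out
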