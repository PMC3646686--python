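# Methods

## Scope and data model

`pathdissect` analyses directed molecular networks in which nodes are chemical
species, complexes, reactions, genes or phenotypes and edges carry an
interaction label, an optional sign (+1 activation, −1 inhibition) and a
positive weight (default 1.0, i.e. hop count). Networks are directed
multigraphs: parallel edges with different interaction labels are kept
distinct, because a pair of species can interact through more than one
mechanism with different signs.

Node identifiers are semantic. The grammar splits a name on the **last** `@`
(compartment), then on `:` (complex members, order preserved), then on `|`
within each member (base name followed by modification tags). Whitespace
around tokens is trimmed on input; the canonical serialization is
delimiter-tight, so `parse ∘ format` is the identity and `format` is
idempotent. Nested complexes are not representable (the member list is flat)
and no escaping rule exists for reserved characters inside a token: a gene
literally named `A|B` cannot be expressed. Empty members, base names,
modifications or compartments are rejected.

### Formats

SIF (whitespace- or tab-delimited; tab splitting is used whenever a tab is
present so node names may contain spaces), GraphML and XGMML are supported
for networks, TSV for annotation tables. SIF is a 3-column format and cannot
carry signs or weights; on read, signs are derived from a configurable
interaction→sign table (defaults: `activates`/`activation`/`catalysis` → +1,
`inhibits`/`inhibition` → −1, anything else unsigned). GraphML and XGMML
round-trip node ids, kinds, interaction labels, signs and weights losslessly.
Duplicate annotation ids keep the last value with a logged warning;
annotation ids that match no network node are reported, never silently
dropped.

## Decomposition

* **Connected / strongly connected components.** Weak components become
  induced subnetworks; SCCs use the standard linear-time algorithm (via
  networkx) and are cross-checked in the tests against an O(n²) pairwise
  mutual-reachability oracle.
* **Bow-tie pruning.** The core is the union of non-trivial SCCs (size ≥ 2,
  or a singleton with a self-loop). The input part contains nodes that reach
  the core but are unreachable from it; the output part nodes reachable from
  the core that cannot return. A fourth class, `other`, holds everything
  else — nodes unrelated to the core, nodes lying on core-to-core corridors
  between distinct SCCs, and the whole node set of an acyclic network (whose
  core is empty). The classical description names only three parts; the
  fourth is required for the partition to be total.
* **Material components.** One subnetwork per protein base name, computed
  purely from name semantics: a species/complex node belongs to component P
  whenever P occurs among its parsed members, in any modification state,
  compartment or complex. Reaction-kind nodes are exempt from parsing and
  are pulled into every component with at least one adjacent member species;
  the component keeps all induced edges. Components overlap wherever
  proteins share complexes — that is the point of the decomposition.
* **Cycle decomposition.** Elementary directed circuits with an optional
  length bound, each reported once, canonically rotated to start at its
  lexicographically smallest node. Enumeration is capped (default 100 000)
  with a warning rather than an error, since circuit counts grow
  exponentially on dense maps; an optional degree filter (`filter_hubs`)
  removes hubs beforehand. The exact "relevant cycle" selection of the
  original plugin is unspecified in the literature we follow; a bounded
  elementary-circuit enumeration is the documented substitute.
* **Clustering of subnetworks.** Two subnetworks are linked when their node
  intersection is non-empty and covers at least `threshold_percent` of the
  **smaller** one (so containment always scores 100%); clusters are connected
  components of the link graph, computed once on the original pairwise links
  and never recomputed between merged clusters, which makes the result
  independent of merge order. Cluster output = node/edge union; label =
  `+`-joined member labels.

## Path analysis

Three directed searches between a source and a target, all returning
non-self-intersecting paths sorted by (length, node sequence):

* **Shortest paths** (Dijkstra; unit weights unless requested otherwise).
  All co-optimal ties are returned, because influence scoring needs the path
  *set*. Negative weights are rejected; an unreachable target returns an
  empty list.
* **Optimal + suboptimal shortest paths.** Every edge lying on any optimal
  path is deleted one at a time — never cumulatively — and the shortest paths
  of each edge-deleted graph are pooled, deduplicated, and stripped of paths
  already optimal.
* **All non-self-intersecting paths** up to a maximal length (the finite
  radius), with an optional count cap that truncates with a warning.

With parallel edges, each choice of edge along a node sequence is a distinct
path; for weighted shortest paths only minimum-weight parallel edges keep a
path co-optimal.

## Pathway influence quantification

Given annotated nodes (signed experimental values α, e.g. t statistics of
tumour-vs-normal differential expression) and target nodes, paths are
extracted per (annotated, target) pair by one of the three searches above and
pooled with deduplication by path identity, giving paths k = 1..q. Each path
contributes

    α_k · σ_k · (1 / λ_k)

where α_k is the annotation of the path's **first** node (paths may pass
through other annotated nodes; their values are ignored), σ_k the product of
its edge signs, and λ_k its length in edges. The 1/λ damping encodes the
hypothesis that longer routes transmit less influence and requires no fitted
parameter. Per-pair scores sum the terms of that pair; per-target scores sum
over annotated nodes. A positive score predicts enhancement of the target, a
negative one inhibition.

Decisions worth noting:

* a node that is both annotated and target contributes no zero-length path
  (λ ≥ 1 always; the formula divides by λ);
* every edge on an extracted path must carry a sign — an unsigned edge is an
  error naming the edge, not a silent skip;
* suboptimal paths are weighted exactly like optimal ones: the formula treats
  all q extracted paths equally;
* scores are kept at full precision; the canonical small example prints
  2·(1/3) − 2·(1/5) = 0.2666… as 0.27 under round-half-even at two decimals.

The text report lists every path with α, σ, λ and its term, then per-pair and
per-target totals; the TSV report is an annotated-node × target matrix ready
for heatmap rendering.

## Reaction-network reduction

The reduction to a signed influence network applies four rules to a fixpoint,
in order, with lexicographic node order for determinism:

1. delete synthesis reactions (no reactants) and degradation reactions (no
   products) that have no modifier;
2. splice out intermediary species with exactly one producing and one
   consuming reaction;
3. merge the two reactions around a spliced species (reactants of the first,
   products of the second, modifiers of both) when inputs and outputs are
   distinct;
4. when inputs equal outputs the pair is a reversible reaction and collapses
   to a single degradation of that species.

Sign algebra (not fixed by the sources we follow, but required downstream):
reactant → product emits +1; a catalysing modifier +1 and an inhibiting one
−1 onto every product; a modifier of a degradation influences the degraded
species with the **negated** modifier sign (speeding up degradation lowers
the species) and the degradation itself appears as a −1 self-influence. A
rule-4 degradation is kept even when unmodified (it is a replacement, not an
original unregulated sink), so the self-influence survives.

Conservative splice: a species is only spliced when it is the unique product
of its producing reaction and the unique reactant of its consuming one, and
carries no modifier edge itself. Candidates entangled with
multi-product/multi-reactant reactions, or cycling through a single reaction,
are left in place with a warning — merging them would invent chemistry. In a
fully symmetric two-species reversible cycle both species qualify as the
intermediary; the lexicographically first is spliced.

The output contains only species/phenotype/gene nodes (never a reaction),
every output edge is signed, and the output node set is a subset of the input
species.

## Modularization

`build_module_graph` wraps each subnetwork into a metanode and links every
pair sharing nodes or edges, storing the shared identities as evidence; links
are symmetric and equal independently computed pairwise intersections.
`merge_modules` replaces modules by their node/edge union and recomputes all
links, so no node or edge of the original map is ever lost. Whether a link
means activation or inhibition between modules is expert knowledge the
modeller supplies; links stay unsigned.

## Synthetic data

All test inputs are generated, deterministically per seed:

* the **worked-example network** — seven nodes, nine edges, annotated node
  `Ac` = 2.0, phenotype target `Ph`, exactly two simple Ac→Ph paths
  (σ=+1/λ=3 and σ=−1/λ=5, sharing their final edge), plus two feedback edges
  from `Ph` that close cycles without creating further Ac→Ph paths. The
  published figure fixes these printed properties but not the exact wiring;
  this is one topology satisfying all of them, so only the printed
  properties, not edge-level identity with the original drawing, are
  guaranteed;
* **Erdős–Rényi digraphs** G(n, p) with uniform ±1 signs, used for all
  property-based and oracle-equivalence tests (n ≤ 12 keeps the O(n²)–O(n!)
  brute-force oracles exact and fast);
* a **toy reaction network** containing every motif the reduction rules
  touch (unregulated degradation, spliceable intermediary, catalysis and
  inhibition modifiers) plus one seed-dependent extra modifier;
* a **case-study analogue**: a 30-species signed random network with three
  downstream phenotype markers and 19 t-statistic-like annotations drawn
  from N(0, 3) — sizes mirror a published cell-cycle case study whose actual
  map and expression data are not redistributable. It emulates scale and
  shape only: real maps have hubs, motifs and correlated annotations that
  Erdős–Rényi graphs with i.i.d. values do not, so green tests establish
  algorithmic correctness, not biological recall.

## Known limitations

* No BioPAX/SBML/CellDesigner import; SIF/GraphML/XGMML only.
* Cycle enumeration is elementary-circuit based; no minimum cycle basis or
  "relevant cycle" selection.
* No statistical significance (permutation nulls) for influence scores.
* The reduction implements exactly the four printed preprocessing rules, not
  the full behaviour of any external conversion tool.
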