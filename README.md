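# pathdissect

Structural analysis of signed molecular networks: semantic decomposition of
large molecular maps, path analysis, bow-tie/cycle/SCC dissection, clustering
of overlapping subnetworks, modularization into linked metanodes, reduction of
biochemical reaction networks to signed influence networks, and quantification
of pathway influence on annotated networks.

It is aimed at systems biologists who curate or import large maps of cellular
processes (cell cycle, apoptosis, signalling) and need to extract meaningful
subnetworks from them, or to confront a map's wiring with experimental data
such as differential-expression statistics.

## The core score

Given a directed network whose edges carry activation (+1) or inhibition (−1)
signs, a set of *annotated* nodes carrying signed experimental values (e.g.
tumour-vs-normal t statistics) and a set of *target* nodes (genes or
phenotypes such as proliferation), paths k = 1, …, q are extracted from
annotated to target nodes (shortest, optimal+suboptimal shortest, or all
non-self-intersecting up to a maximal length) and the target's influence
score is

    score = Σ_k  α_k · σ_k · (1 / λ_k)

with α_k the annotation of the path's first node, σ_k the product of the edge
signs along the path, and λ_k the number of edges. Longer paths transmit less
influence (the 1/λ damping); a positive score predicts enhancement of the
target under the annotated condition, a negative score inhibition.

Node names are semantic: `Cdc25|Pho@cytoplasm` is phosphorylated Cdc25 in the
cytoplasm; `Cdc13:Cdc2|Thr167_pho@cytoplasm` a complex of Cdc13 with
Thr167-phosphorylated Cdc2. The decomposition functions exploit this grammar
(e.g. the *material component* of a protein collects every node containing it,
free or complexed, in any modification state or compartment).

## Worked example

The canonical small example: a seven-node, nine-edge influence network in
which the annotated node `Ac` (value 2.0) reaches the phenotype `Ph` through
exactly two paths — one activating of length 3, one net-inhibiting of
length 5.

```python
from pathdissect import PiquantConfig, fixtures, run_piquant, render_report

net, annotations = fixtures.make_example_influence_network()
cfg = PiquantConfig(annotated_nodes={"Ac"}, target_nodes={"Ph"},
                    method="all_nonself", max_len=10)
result = run_piquant(net, annotations, cfg)
print(render_report(result, "text"))
```

prints

```
Pathway influence quantification report
========================================

paths extracted (q): 2

per-path terms:
  idx	path	alpha	sigma	lambda	term
  1	Ac->A->B->Ph	2	+1	3	0.666667
  2	Ac->C->D->E->B->Ph	2	-1	5	-0.4

per-pair scores (annotated -> target):
  Ac -> Ph	0.266667	(rounded: 0.27)

per-target scores:
  Ph	0.266667	(rounded: 0.27)
```

The short activating route contributes 2·(+1)·(1/3) = 0.667, the long
inhibitory one 2·(−1)·(1/5) = −0.4; their sum 0.27 predicts a (weak) net
activation of the phenotype. The same run is available from the shell:

```sh
pathdissect fixtures --kind fig-example --out net.sif --annotations-out ann.tsv
pathdissect piquant --network net.sif --annotations ann.tsv --targets Ph --method all
```

Other subcommands: `convert` (SIF/GraphML/XGMML), `decompose`
(`--method cc|scc|bowtie|material|cycles|cluster`), `paths`, `reduce`
(reaction → influence network), `modularize`. See `pathdissect --help`.

## Acceptance script

`scripts/acceptance.py` rebuilds the worked example from scratch — generates
the seven-node network and its annotation, extracts all non-self-intersecting
paths, scores the phenotype target — and writes the rounded score as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the algorithms, their assumptions, the sign
algebra of the reaction-network reduction, what the synthetic generators do
and do not emulate, and known limitations.
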