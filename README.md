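# netsort

Hierarchy decomposition toolkit for directed signalling networks
(kinase–phosphatase networks in particular):

* **Vertex sorting** — collapse strongly connected components, run leaf
  removal on the condensation DAG and its transpose, and report a top-first
  level interval per node.
* **Bow-tie layers** — core (largest SCC), top (upstream regulators),
  bottom (downstream targets), peripheral, and a substrates group.
* **Global reaching centrality (GRC)** — how hierarchical a network is.
* **Five degree-constrained null models** — DPR, SDPR, IDPR, ODPR, DNPR —
  plus Erdős–Rényi graphs, with empirical p-values against any statistic.
* **Statistics** — randomization (permutation) test for layer means,
  hypergeometric enrichment/depletion, degree–property rank association,
  random-network layer profiles with percentile confidence intervals.
* **Robustness** — layer stability (Jaccard + hypergeometric overlap)
  under random edge addition/deletion.
* **Motifs & degrees** — feed-forward loop / 2-node feedback loop / bi-fan
  counts, betweenness bottlenecks, degree hubs, discrete power-law fitting
  (MLE + KS cut-off + bootstrap goodness of fit).
* **Kinase prediction** — consensus-motif matching of dynamic phosphosites
  against a gold-standard network.
* **Synthetic generators** — planted bow-ties with ground-truth layers,
  scale-free networks, layer-structured property tables; everything is
  testable offline.

## File formats

* **Edge list (TSV)** — columns `source`, `target`, `itype`
  (`P` = phosphorylation, `D` = dephosphorylation). Duplicate triples are
  dropped with a warning.
* **Node roles (TSV)** — columns `id`, `role` (`kinase` / `phosphatase` /
  `other`). Every edge source must be an enzyme; nodes appearing only in
  edges default to `other`.
* **Property table (TSV)** — first column `id`, remaining columns numeric
  (empty cell = missing; 0/1 columns are treated as boolean flags).
* **Layers (TSV output)** — `id`, `layer`, `level_min`, `level_max`,
  deterministic row order.
* All statistical results serialize to JSON with inputs, seed and p-value.

## CLI

```sh
netsort sort       --edges e.tsv --nodes n.tsv --layers-out layers.tsv --out summary.json
netsort grc        --edges e.tsv --nodes n.tsv
netsort randomize  --edges e.tsv --nodes n.tsv --scheme dpr --reps 100 --seed 1 --out-dir reps/
netsort motifs     --edges e.tsv --nodes n.tsv
netsort stats rt   --properties p.tsv --column abundance --group-a A1,A2 --group-b B1,B2
netsort stats ht   -k 4 -K 5 -n 4 -N 10
netsort stats profile --edges e.tsv --nodes n.tsv --properties p.tsv --column abundance --scheme dnpr
netsort robustness --edges e.tsv --nodes n.tsv --ks 40,80,120,160,200 --reps 100
netsort predict    --edges e.tsv --nodes n.tsv --motifs m.tsv --phosphosites s.tsv --sequences seq.tsv
netsort simulate bowtie --sizes 2,3,2,1,0 --edges-out e.tsv --nodes-out n.tsv
```

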