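# crosshub

Consensus hub-gene detection for two-disease transcriptomic crosstalk
studies, as a single tested pipeline:

* **Differential expression** per cohort — empirical-Bayes moderated t
  for log-intensity (array) studies, plug-in negative-binomial Wald with
  median-of-ratios size factors for count (RNA-seq-like) studies,
  Benjamini–Hochberg adjustment, and multi-probe duplicate collapse.
  DEG rule: adjusted p < 0.05 and |log2 fold change| ≥ 1.
* **Set overlap** — disease × tissue group merging, full Venn
  partitioning (all 2ⁿ−1 exclusive regions), and k-of-n shared-gene
  selection (default: genes in ≥ 3 of 4 groups → "module 1").
* **Enrichment** — exact hypergeometric upper-tail over-representation
  (log-space), one-sided Fisher and its conservative EASE variant,
  cross-disease common-term intersection, and selection of DEGs
  annotated to shared terms ("module 2").
* **Network hubs** — score-thresholded interaction graphs (default
  ≥ 0.40), Dice neighbor-overlap scores, five centralities (degree,
  harmonic closeness, betweenness, stress, maximal clique centrality),
  deterministic top-k rankings, and m-of-n consensus hub selection
  (top 20 per method, ≥ 3 methods).
* **Regulator layers** — miRNA target tables filtered at score > 80,
  hub-restricted bipartite networks, ≥ 4-target regulator selection,
  top-40 four-method consensus regulators, TF and drug–gene joins.
* **Synthetic data** — generators for every input (expression studies,
  PPI with planted hub cliques, annotations with planted enriched
  terms, regulator tables with planted high-score pairs) with full
  ground truth, so recovery is testable offline and with no downloads.

## CLI

```sh
# generate a complete synthetic input set + config
crosshub simulate --out demo --seed 1
# run the whole pipeline from that config
crosshub run --config demo/config.yaml
cat demo/out/report.json
```

Subcommands: `simulate`, `dge`, `overlap`, `enrich`, `network`, `hubs`,
`regulatory`, `run`, `report`. Exit codes: 0 success, 2 config error,
3 input parse error, 4 stage failure. All inputs and outputs are plain
text: TSV matrices/edge lists, GMT gene sets, SIF (read-only), JSON
reports with a sha256 manifest.

## Layout

```
src/crosshub/
  synthetic.py    input generators with planted ground truth
  dge.py          moderated t, NB Wald, BH, duplicate collapse
  overlap.py      group merge, Venn partition, k-of-n selection
  enrichment.py   hypergeometric/Fisher/EASE ORA, common terms
  network.py      graph build, five centralities, consensus hubs
  regulatory.py   miRNA/TF/drug bipartite layers
  io.py           strict TSV/GMT/SIF/regulator parsers and writers
  pipeline.py     config, stage orchestration, report + manifest
  cli.py          click command-line interface
  datasets.py     bundled worked-example ranking tables
tests/            unit, property and acceptance suites (oracle-first)
scripts/          acceptance.py
```
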