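# netpharm

An offline, fully tested network-pharmacology analysis pipeline:

1. **Target aggregation** — read four styles of gene/target tables
   (relevance-scored disease genes, drug→target pairs, plain gene lists),
   normalize symbols, merge them into one scored catalog, and intersect
   disease targets with compound targets (Venn step).
2. **PPI network construction** — build an undirected simple graph from a
   STRING-format edge list (`protein1`, `protein2`, `combined_score`
   0–1000), keeping edges at or above a confidence threshold
   (default 0.400).
3. **Centrality profiling** — degree, betweenness, closeness, eigenvector,
   LAC (local average connectivity) and MCC (maximal clique centrality),
   each validated against an independent brute-force oracle.
4. **Core extraction** — iterated median-threshold filtering: each round
   keeps only nodes strictly above the median on every selected centrality,
   recomputed on the shrinking subgraph (default: 2 rounds over the five
   non-MCC metrics).
5. **Hub ranking** — top-10 genes by Degree and by MCC on the *full*
   network, competition-ranked with shared ranks for ties; consensus by
   intersection; hub-neighborhood subnetwork export (GraphML / edge TSV).
6. **Enrichment** — hypergeometric over-representation analysis of the
   gene list against GMT pathway collections, with fold enrichment
   (m/k)/(K/N), Benjamini–Hochberg FDR and −log10(FDR).

A synthetic-data module generates every input the pipeline needs — scored
gene tables, a scale-free PPI edge list with planted hubs and sub-threshold
decoy edges, and GMT collections with planted enrichment at controllable
effect size — together with the ground truth for recovery testing.

## CLI

Each stage is a subcommand; `run` executes the whole workflow from a YAML
config.

```sh
# generate a synthetic scenario (7 files incl. truth.json)
netpharm simulate --out scenario/ --seed 1

# full pipeline
cat > cfg.yaml <<'YAML'
inputs:
  genecards: scenario/genecards.tsv
  drugbank: scenario/drugbank.tsv
  pharmgkb: scenario/pharmgkb.tsv
  pubchem: scenario/pubchem.tsv
  edges: scenario/string_edges.tsv
  gmt: scenario/pathways.gmt
output_dir: out
YAML
netpharm run --config cfg.yaml
```

`out/` then contains the merged catalog, the GraphML/TSV network, the
centrality table, the per-round core report and core subnetwork, both hub
rankings plus their consensus and neighborhood subnetwork, the enrichment
table, and `manifest.json` (input checksums, parameters, per-stage counts).

Stage subcommands: `aggregate`, `network`, `centrality`, `core`, `hubs`,
`enrich` — see `netpharm <cmd> --help`. Useful knobs: `--confidence`
(edge threshold), `--keep-isolates`, `--lcc-only`, `core --rounds/--metrics
/--comparison`, `hubs --method degree|mcc|both --top-k`,
`enrich --background --min-overlap`.

## Layout

```
src/netpharm/
  synthetic.py   scenario generator + writer (planted truth)
  catalog.py     source-table readers, merge, target intersection
  ppi.py         STRING edge parsing, graph build, export
  centrality.py  the six centrality measures
  core.py        iterated median-filter core extraction
  hubs.py        Degree/MCC ranking, consensus, hub subnetwork
  enrichment.py  GMT, hypergeometric ORA, BH-FDR, fold enrichment
  config.py      YAML run-config validation
  pipeline.py    end-to-end orchestration + manifest
  cli.py         click CLI (`netpharm`)
tests/           pytest suite; oracles.py holds independent brute-force
                 reimplementations used only for verification
scripts/acceptance.py
```
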