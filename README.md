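# pathcompendium

Assembly and structural analysis of multi-source signalling-pathway
compendia. The package merges pathway gene sets and per-database interaction
files (SIF or annotated TSV) into a single provenance-annotated ensemble
network, and provides the downstream analyses:

- **compendium_io** — pathway/interaction/annotation readers, molecular
  complex expansion, master-list filtering, canonical pair-level edge
  merging, deterministic round-tripping writers (SIF + TSV + JSON).
- **synthetic_data** — generator of compendia with planted ground truth:
  power-law pathway membership, controllable cross-source edge sharing
  (heavy-tailed edge weights), a within-pathway enrichment knob calibrated
  to the modularity statistic, and planted signalling scaffolds with bypass
  edges and one-step intermediates.
- **topology** — per-gene degree (both network-level mean conventions),
  betweenness (pair-normalized fractions), pathway-membership counts,
  hypergeometric Z enrichment scans over widening tip windows, quadrant
  partitioning.
- **pathway_similarity** — all-pairs Jaccard matrix with deterministic
  average-linkage leaf ordering.
- **edge_concordance** — edge-weight (supporting-database count)
  distributions and the directional cross-database edge-consistency matrix.
- **modularity** — internal/external pathway connectivity, gene-membership
  randomization null (pathway sizes and per-gene membership counts
  preserved), modularity score M = observed/expected − 1, Mann–Whitney
  significance, full (network × pathway source) matrix.
- **path_analysis** — directed views under annotation filters, all shortest
  paths, bounded simple-path enumeration by iterative DFS, fraction of
  paths through a required node (bypass fraction), one-intermediate
  scaffold expansion with feed-forward/feed-back/parallel classification,
  scaffold high-weight-edge enrichment.
- **cli** — `pathcompendium` command with `simulate`, `build`, `topology`,
  `similarity`, `concordance`, `modularity`, `paths` and all-in-one `run`
  subcommands; deterministic outputs with a sha256 manifest.

## CLI quickstart

```sh
# generate synthetic inputs with planted ground truth
pathcompendium simulate -c examples/sim.yaml -o out/compendium

# or build from real files
pathcompendium build --pathways pathways.tsv \
    -i CellMap=cellmap.sif:sif -i I2D=i2d.tsv:tsv -o out/compendium

# analyses read the written compendium directory
pathcompendium topology -c out/compendium -o out/topology
pathcompendium modularity -c out/compendium -o out/modularity --seed 1
pathcompendium paths -c out/compendium -q queries.yaml -o out/paths

# everything at once, from a single YAML config
pathcompendium run -c run.yaml
```

A `run.yaml` looks like:

```yaml
output_dir: out/run
seed: 1
simulate: {n_genes: 300, pathway_sources: [[dbP, 10]], n_edges_per_source: 600}
stages: {topology: true, similarity: true, concordance: true, modularity: true}
modularity: {n_randomizations: 100}
```

## Input formats

- **SIF**: `nodeA<TAB>relation<TAB>nodeB`, no header. Known relation verbs
  map to (direction, sign, mechanism); unknown verbs load as
  (undirected, unsigned, unknown) with the raw string preserved.
- **Annotated TSV edges**: header `gene_a`/`gene_b` plus the optional
  annotation columns above.
- **Pathway tables**: long-form TSV (`pathway_label`/`source_db`/`gene_id`)
  or GMT-like (`label<TAB>source_db<TAB>gene...`). Pathways are
  database-scoped and never merged by label.
- **Gene annotations**: TSV `gene_id`/`function_category`[/`alt_id`].
- **Identifier map**: two-column TSV, applied verbatim; unmapped ids pass
  through with a warning.
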