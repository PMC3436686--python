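output_dir: out/run
seed: 1
simulate:
  n_genes: 300
  pathway_sources: [[dbP1, 8]]
  interaction_sources: [dbI1, dbI2]
  pathway_size_range: [10, 25]
  n_edges_per_source: 400
  source_sharing: 0.15
stages:
  topology: true
  similarity: true
  concordance: true
  modularity: true
modularity:
  n_randomizations: 50
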