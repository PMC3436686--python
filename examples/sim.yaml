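n_genes: 300
pathway_sources: [[dbP1, 8], [dbP2, 4]]
interaction_sources: [dbI1, dbI2, dbI3]
pathway_size_range: [10, 25]
n_edges_per_source: 500
source_sharing: 0.15
internal_edge_enrichment: 1.5
seed: 1
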