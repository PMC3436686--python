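import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pathcompendium.model import (
    Compendium,
    GeneRecord,
    PathwayRecord,
    SourceAnnotation,
    add_annotation,
)


def make_compendium(pathway_specs, edge_specs, extra_sources=()):
    """Small in-memory compendium for unit tests.

    pathway_specs: iterable of (label, source_db, genes)
    edge_specs: iterable of (gene_a, gene_b, source_db) or
                (gene_a, gene_b, source_db, direction, sign, mechanism)
    """
    compendium = Compendium()
    compendium.pathway_sources = sorted({db for _, db, _ in pathway_specs})
    compendium.interaction_sources = sorted(
        {spec[2] for spec in edge_specs} | set(extra_sources)
    )
    for label, db, genes in pathway_specs:
        compendium.pathways.append(PathwayRecord(label, db, frozenset(genes)))
        for g in genes:
            compendium.genes.setdefault(g, GeneRecord(gene_id=g))
    for spec in edge_specs:
        a, b, db = spec[:3]
        direction, sign, mechanism = ("undirected", "unsigned", "unknown")
        if len(spec) > 3:
            direction, sign, mechanism = spec[3:6]
        for g in (a, b):
            compendium.genes.setdefault(g, GeneRecord(gene_id=g))
        add_annotation(
            compendium, a, b,
            SourceAnnotation(source_db=db, direction=direction, sign=sign, mechanism=mechanism),
        )
    compendium.recompute_derived()
    compendium.validate()
    return compendium


@pytest.fixture
def triangle_compendium():
    return make_compendium(
        [("P1", "dbP", {"A", "B", "C"})],
        [("A", "B", "dbI"), ("B", "C", "dbI"), ("A", "C", "dbI")],
    )


@pytest.fixture
def small_synthetic():
    from pathcompendium.synthetic_data import SyntheticConfig, generate_compendium

    config = SyntheticConfig(
        n_genes=120,
        pathway_sources=[("dbP1", 4), ("dbP2", 3)],
        interaction_sources=["dbI1", "dbI2", "dbI3"],
        pathway_size_range=(8, 15),
        n_edges_per_source=150,
        source_sharing=0.2,
        seed=42,
    )
    return generate_compendium(config)
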