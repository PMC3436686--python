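"""Core data model: genes, pathways, canonical edges and the merged compendium.

Edge identity is the unordered gene pair; direction, sign and mechanism are
per-source annotations attached to the canonical edge. Pathways are scoped to
their source database and never merged by label similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import networkx as nx

DIRECTIONS = ("forward", "reverse", "undirected")
SIGNS = ("positive", "negative", "unsigned")
MECHANISMS = ("direct", "indirect", "unknown")


class CompendiumError(ValueError):
    """Raised when a compendium invariant is violated."""


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Return the unordered pair in lexicographic order."""
    if gene_a <= gene_b:
        return (gene_a, gene_b)
    return (gene_b, gene_a)


@dataclass(frozen=True)
class SourceAnnotation:
    """Per-source evidence attached to a canonical edge.

    ``direction`` is relative to the canonical (lexicographic) pair order.
    ``dataset`` optionally names a sub-dataset inside an aggregating source
    (e.g. the individual screens bundled in a PPI meta-database).
    """

    source_db: str
    direction: str = "undirected"
    sign: str = "unsigned"
    mechanism: str = "unknown"
    raw: Optional[str] = None
    dataset: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise CompendiumError(f"invalid direction {self.direction!r}")
        if self.sign not in SIGNS:
            raise CompendiumError(f"invalid sign {self.sign!r}")
        if self.mechanism not in MECHANISMS:
            raise CompendiumError(f"invalid mechanism {self.mechanism!r}")

    def flipped(self) -> "SourceAnnotation":
        """Annotation as seen after swapping the endpoint order."""
        if self.direction == "forward":
            return replace(self, direction="reverse")
        if self.direction == "reverse":
            return replace(self, direction="forward")
        return self


@dataclass
class EdgeRecord:
    """A canonical gene-pair interaction with per-source annotations."""

    gene_a: str
    gene_b: str
    annotations: list[SourceAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            raise CompendiumError(
                f"edge ({self.gene_a},{self.gene_b}) not in canonical order"
            )
        if self.gene_a == self.gene_b:
            raise CompendiumError(f"self-loop on {self.gene_a}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def source_dbs(self) -> set[str]:
        return {a.source_db for a in self.annotations}

    @property
    def edge_weight(self) -> int:
        """Number of distinct source databases supporting the edge (K_E)."""
        return len(self.source_dbs)


@dataclass(frozen=True)
class PathwayRecord:
    """A database-scoped pathway: (label, source db) with its gene set."""

    pathway_label: str
    source_db: str
    genes: frozenset[str]

    @property
    def key(self) -> tuple[str, str]:
        return (self.pathway_label, self.source_db)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneRecord:
    gene_id: str
    alt_id: Optional[str] = None
    function_category: str = "other"
    source_pathway_dbs: set[str] = field(default_factory=set)
    pathway_maps: int = 0
    degree: int = 0
    betweenness: float = 0.0


@dataclass
class Compendium:
    """Merged multi-source gene / pathway / edge tables with provenance."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    pathways: list[PathwayRecord] = field(default_factory=list)
    edges: dict[tuple[str, str], EdgeRecord] = field(default_factory=dict)
    interaction_sources: list[str] = field(default_factory=list)
    pathway_sources: list[str] = field(default_factory=list)

    # -- derived-field maintenance -------------------------------------------------
    def recompute_derived(self) -> None:
        """Refresh pathway_maps, degree and per-gene pathway-source sets."""
        for g in self.genes.values():
            g.pathway_maps = 0
            g.degree = 0
            g.source_pathway_dbs = set()
        for pw in self.pathways:
            for gid in pw.genes:
                rec = self.genes[gid]
                rec.pathway_maps += 1
                rec.source_pathway_dbs.add(pw.source_db)
        for edge in self.edges.values():
            self.genes[edge.gene_a].degree += 1
            self.genes[edge.gene_b].degree += 1

    def validate(self) -> None:
        seen_keys: set[tuple[str, str]] = set()
        for pw in self.pathways:
            if pw.key in seen_keys:
                raise CompendiumError(f"duplicate pathway key {pw.key}")
            seen_keys.add(pw.key)
            if not pw.genes:
                raise CompendiumError(f"empty pathway {pw.key}")
            missing = pw.genes - self.genes.keys()
            if missing:
                raise CompendiumError(f"pathway {pw.key} references unknown genes {missing}")
            if pw.source_db not in self.pathway_sources:
                raise CompendiumError(f"unregistered pathway source {pw.source_db!r}")
        for key, edge in self.edges.items():
            if key != edge.key:
                raise CompendiumError(f"edge stored under wrong key {key}")
            if edge.gene_a not in self.genes or edge.gene_b not in self.genes:
                raise CompendiumError(f"edge {key} endpoint missing from gene table")
            if not edge.annotations:
                raise CompendiumError(f"edge {key} has no annotations")
            if not 1 <= edge.edge_weight <= len(self.interaction_sources):
                raise CompendiumError(f"edge {key} has invalid edge_weight")
            for ann in edge.annotations:
                if ann.source_db not in self.interaction_sources:
                    raise CompendiumError(
                        f"edge {key} annotated by unregistered source {ann.source_db!r}"
                    )
        for gid, rec in self.genes.items():
            expected_maps = sum(1 for pw in self.pathways if gid in pw.genes)
            if rec.pathway_maps != expected_maps:
                raise CompendiumError(f"stale pathway_maps for {gid}")
            expected_deg = sum(1 for e in self.edges if gid in e)
            if rec.degree != expected_deg:
                raise CompendiumError(f"stale degree for {gid}")

    # -- views ---------------------------------------------------------------------
    def graph(self) -> nx.Graph:
        """Undirected projection: one unit-weight edge per canonical pair."""
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g

    def edge_pairs_of_source(self, source_db: str) -> set[tuple[str, str]]:
        """Canonical pairs annotated by ``source_db``."""
        return {
            key
            for key, edge in self.edges.items()
            if any(a.source_db == source_db for a in edge.annotations)
        }

    def pathways_of_source(self, source_db: str) -> list[PathwayRecord]:
        return [pw for pw in self.pathways if pw.source_db == source_db]

    def iter_pathway_keys(self) -> Iterator[tuple[str, str]]:
        for pw in self.pathways:
            yield pw.key

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def add_annotation(
    compendium: Compendium,
    gene_a: str,
    gene_b: str,
    annotation: SourceAnnotation,
) -> None:
    """Attach an annotation to the canonical edge, creating it if needed.

    Endpoints are reordered canonically; a directed annotation given against
    the raw order is flipped to stay relative to the canonical order.
    """
    a, b = canonical_pair(gene_a, gene_b)
    if (a, b) != (gene_a, gene_b):
        annotation = annotation.flipped()
    edge = compendium.edges.get((a, b))
    if edge is None:
        compendium.edges[(a, b)] = EdgeRecord(a, b, [annotation])
    else:
        edge.annotations.append(annotation)


def edge_weights(compendium: Compendium) -> dict[tuple[str, str], int]:
    return {key: e.edge_weight for key, e in compendium.edges.items()}
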