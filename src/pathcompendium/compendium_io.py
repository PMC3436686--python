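"""Readers, writers and the ensemble merge.

Input dialects are deliberately small: long-form TSV or GMT-like pathway
tables, and SIF or annotated-TSV interaction files. Everything else (BioPAX,
SBML, PSI-MI...) is out of scope; reduce to SIF upstream.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Compendium,
    CompendiumError,
    EdgeRecord,
    GeneRecord,
    PathwayRecord,
    SourceAnnotation,
    add_annotation,
    canonical_pair,
)


class FormatError(ValueError):
    """Malformed input file (missing column, blank endpoint...)."""


@dataclass
class RawInteraction:
    """One interaction row as read from a source file, pre-canonicalization.

    ``direction`` is relative to the (gene_a, gene_b) order as written.
    """

    gene_a: str
    gene_b: str
    source_db: str
    direction: str = "undirected"
    sign: str = "unsigned"
    mechanism: str = "unknown"
    raw: Optional[str] = None
    dataset: Optional[str] = None


@dataclass
class LoadReport:
    """Per-source ingestion and filtering counters."""

    raw_counts: dict[str, int] = field(default_factory=dict)
    self_loops_dropped: dict[str, int] = field(default_factory=dict)
    outside_master_dropped: dict[str, int] = field(default_factory=dict)
    retained_counts: dict[str, int] = field(default_factory=dict)
    n_genes: int = 0
    n_pathways: int = 0
    n_canonical_edges: int = 0

    def to_dict(self) -> dict:
        return {
            "raw_counts": dict(sorted(self.raw_counts.items())),
            "self_loops_dropped": dict(sorted(self.self_loops_dropped.items())),
            "outside_master_dropped": dict(sorted(self.outside_master_dropped.items())),
            "retained_counts": dict(sorted(self.retained_counts.items())),
            "n_genes": self.n_genes,
            "n_pathways": self.n_pathways,
            "n_canonical_edges": self.n_canonical_edges,
        }


#: SIF relation strings with an agreed reading. Anything else maps to
#: (undirected, unsigned, unknown) with the raw string preserved.
DEFAULT_RELATION_MAP: dict[str, tuple[str, str, str]] = {
    "INTERACTS_WITH": ("undirected", "unsigned", "direct"),
    "IN_SAME_COMPONENT": ("undirected", "unsigned", "indirect"),
    "STATE_CHANGE": ("forward", "unsigned", "direct"),
    "SEQUENTIAL_CATALYSIS": ("forward", "unsigned", "indirect"),
    "CO_CONTROL": ("undirected", "unsigned", "indirect"),
    "METABOLIC_CATALYSIS": ("forward", "unsigned", "direct"),
    "controls-state-change-of": ("forward", "unsigned", "direct"),
    "controls-expression-of": ("forward", "unsigned", "indirect"),
    "interacts-with": ("undirected", "unsigned", "direct"),
    "in-complex-with": ("undirected", "unsigned", "direct"),
    "activates": ("forward", "positive", "direct"),
    "inhibits": ("forward", "negative", "direct"),
}

_PATHWAY_COLUMNS = ("pathway_label", "source_db", "gene_id")
_TSV_EDGE_COLUMNS = ("gene_a", "gene_b")


def read_pathway_table(path: str | Path, dialect: str = "long") -> list[PathwayRecord]:
    """Parse a pathway membership file into database-scoped records.

    ``dialect="long"`` expects a headered TSV with columns
    pathway_label / source_db / gene_id (one membership per row).
    ``dialect="gmt"`` expects one pathway per line:
    label <TAB> source_db <TAB> gene [<TAB> gene ...].
    """
    path = Path(path)
    groups: dict[tuple[str, str], set[str]] = {}
    order: list[tuple[str, str]] = []
    if dialect == "long":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            header = reader.fieldnames or []
            for col in _PATHWAY_COLUMNS:
                if col not in header:
                    raise FormatError(f"pathway table {path} missing column {col!r}")
            for row in reader:
                key = (row["pathway_label"], row["source_db"])
                if key not in groups:
                    groups[key] = set()
                    order.append(key)
                gene = (row["gene_id"] or "").strip()
                if gene:
                    groups[key].add(gene)
    elif dialect == "gmt":
        with path.open() as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or not parts[0]:
                    raise FormatError(f"malformed GMT line in {path}: {line!r}")
                key = (parts[0], parts[1])
                if key not in groups:
                    groups[key] = set()
                    order.append(key)
                groups[key].update(g for g in parts[2:] if g)
    else:
        raise FormatError(f"unknown pathway dialect {dialect!r}")

    records: list[PathwayRecord] = []
    for key in order:
        genes = groups[key]
        if not genes:
            warnings.warn(f"pathway {key} has an empty gene set; record rejected")
            continue
        records.append(PathwayRecord(key[0], key[1], frozenset(genes)))
    return records


def read_interactions(
    path: str | Path,
    source_db: str,
    dialect: str = "sif",
    relation_map: Optional[Mapping[str, tuple[str, str, str]]] = None,
) -> tuple[list[RawInteraction], dict[str, int]]:
    """Read one source database's interaction file.

    Returns the raw records plus a small counter dict (rows read, self-loops
    dropped). Unknown SIF relation strings never fail the load: they map to
    (undirected, unsigned, unknown) with the raw string kept.
    """
    path = Path(path)
    if relation_map is None:
        relation_map = DEFAULT_RELATION_MAP
    records: list[RawInteraction] = []
    counters = {"rows": 0, "self_loops_dropped": 0}

    if dialect == "sif":
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) == 1:  # space-delimited SIF variant
                    parts = line.split()
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: SIF line needs 3 fields")
                a, rel, b = parts[0].strip(), parts[1], parts[2].strip()
                if not a or not b:
                    raise FormatError(f"{path}:{lineno}: blank endpoint")
                counters["rows"] += 1
                if a == b:
                    counters["self_loops_dropped"] += 1
                    continue
                direction, sign, mechanism = relation_map.get(
                    rel, ("undirected", "unsigned", "unknown")
                )
                records.append(
                    RawInteraction(a, b, source_db, direction, sign, mechanism, raw=rel)
                )
    elif dialect == "tsv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            header = reader.fieldnames or []
            for col in _TSV_EDGE_COLUMNS:
                if col not in header:
                    raise FormatError(f"interaction table {path} missing column {col!r}")
            for row in reader:
                a = (row["gene_a"] or "").strip()
                b = (row["gene_b"] or "").strip()
                if not a or not b:
                    raise FormatError(f"{path}: blank endpoint in row {row}")
                counters["rows"] += 1
                if a == b:
                    counters["self_loops_dropped"] += 1
                    continue
                records.append(
                    RawInteraction(
                        a,
                        b,
                        source_db,
                        direction=row.get("direction") or "undirected",
                        sign=row.get("sign") or "unsigned",
                        mechanism=row.get("mechanism") or "unknown",
                        raw=row.get("raw") or None,
                        dataset=row.get("dataset") or None,
                    )
                )
    else:
        raise FormatError(f"unknown interaction dialect {dialect!r}")
    return records, counters


def expand_complex(
    members: Iterable[str], annotation: SourceAnnotation
) -> list[RawInteraction]:
    """Combinatorially expand a molecular complex into pairwise records.

    An n-member complex yields C(n, 2) undirected records inheriting the
    complex's source and mechanism.
    """
    members = sorted(set(members))
    if len(members) < 2:
        warnings.warn("complex with fewer than 2 members; nothing to expand")
        return []
    out: list[RawInteraction] = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            out.append(
                RawInteraction(
                    a,
                    b,
                    annotation.source_db,
                    direction="undirected",
                    sign="unsigned",
                    mechanism=annotation.mechanism,
                    raw=annotation.raw,
                    dataset=annotation.dataset,
                )
            )
    return out


def read_gene_annotations(path: str | Path) -> dict[str, dict[str, str]]:
    """TSV of gene_id / function_category [/ alt_id] keyed by gene_id."""
    path = Path(path)
    out: dict[str, dict[str, str]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("gene_id", "function_category"):
            if col not in header:
                raise FormatError(f"annotation table {path} missing column {col!r}")
        for row in reader:
            out[row["gene_id"]] = {
                "function_category": row["function_category"] or "other",
                "alt_id": row.get("alt_id") or None,
            }
    return out


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping input identifiers to canonical gene ids."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                out[parts[0]] = parts[1]
    return out


def _apply_id_map(gene: str, id_map: Optional[Mapping[str, str]]) -> str:
    if id_map is None:
        return gene
    return id_map.get(gene, gene)


def build_ensemble(
    pathways: Sequence[PathwayRecord],
    interaction_batches: Sequence[tuple[str, Sequence[RawInteraction]]],
    gene_annotations: Optional[Mapping[str, Mapping[str, Optional[str]]]] = None,
    id_map: Optional[Mapping[str, str]] = None,
) -> tuple[Compendium, LoadReport]:
    """Merge pathway and interaction inputs into a single Compendium.

    The master gene list is the union of the pathway gene sets; interactions
    are retained only when BOTH endpoints are on the master list. Edges are
    canonicalized on unordered pairs with per-source annotations concatenated.
    """
    if not pathways:
        raise CompendiumError("at least one pathway record is required")

    if id_map is not None:
        targets: dict[str, list[str]] = {}
        for src, dst in id_map.items():
            targets.setdefault(dst, []).append(src)
        collisions = {d: s for d, s in targets.items() if len(s) > 1}
        if collisions:
            warnings.warn(f"id_map collisions merged: {collisions}")
        pathways = [
            PathwayRecord(
                pw.pathway_label,
                pw.source_db,
                frozenset(_apply_id_map(g, id_map) for g in pw.genes),
            )
            for pw in pathways
        ]

    compendium = Compendium()
    compendium.pathway_sources = sorted({pw.source_db for pw in pathways})
    compendium.interaction_sources = [db for db, _ in interaction_batches]
    compendium.pathways = list(pathways)

    master: set[str] = set()
    for pw in pathways:
        master.update(pw.genes)
    for gid in sorted(master):
        ann = (gene_annotations or {}).get(gid, {})
        compendium.genes[gid] = GeneRecord(
            gene_id=gid,
            alt_id=ann.get("alt_id"),
            function_category=ann.get("function_category") or "other",
        )

    report = LoadReport(n_genes=len(master), n_pathways=len(pathways))
    for source_db, batch in interaction_batches:
        raw_n = 0
        dropped_loops = 0
        dropped_master = 0
        retained = 0
        for rec in batch:
            raw_n += 1
            a = _apply_id_map(rec.gene_a, id_map)
            b = _apply_id_map(rec.gene_b, id_map)
            if a == b:
                dropped_loops += 1
                continue
            if a not in master or b not in master:
                dropped_master += 1
                continue
            add_annotation(
                compendium,
                a,
                b,
                SourceAnnotation(
                    source_db=source_db,
                    direction=rec.direction,
                    sign=rec.sign,
                    mechanism=rec.mechanism,
                    raw=rec.raw,
                    dataset=rec.dataset,
                ),
            )
            retained += 1
        report.raw_counts[source_db] = raw_n
        report.self_loops_dropped[source_db] = dropped_loops
        report.outside_master_dropped[source_db] = dropped_master
        report.retained_counts[source_db] = retained

    report.n_canonical_edges = len(compendium.edges)
    compendium.recompute_derived()
    compendium.validate()
    return compendium, report


# ---------------------------------------------------------------------------
# On-disk layout (all plain text, deterministic ordering):
#   edges.sif            nodeA <TAB> pp <TAB> nodeB
#   nodes.tsv            per-gene attributes
#   edge_annotations.tsv one row per SourceAnnotation
#   pathways.tsv         long-form membership table
#   provenance.json      source registries + summary counts
# ---------------------------------------------------------------------------

_NODE_HEADER = ["gene_id", "alt_id", "function_category", "source_pathway_dbs", "pathway_maps", "degree"]
_EDGE_ANN_HEADER = ["gene_a", "gene_b", "source_db", "direction", "sign", "mechanism", "raw", "dataset"]


def write_compendium(compendium: Compendium, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": out_dir / "edges.sif",
        "nodes": out_dir / "nodes.tsv",
        "edge_annotations": out_dir / "edge_annotations.tsv",
        "pathways": out_dir / "pathways.tsv",
        "provenance": out_dir / "provenance.json",
    }

    with paths["sif"].open("w") as fh:
        for a, b in sorted(compendium.edges):
            fh.write(f"{a}\tpp\t{b}\n")

    with paths["nodes"].open("w") as fh:
        fh.write("\t".join(_NODE_HEADER) + "\n")
        for gid in sorted(compendium.genes):
            g = compendium.genes[gid]
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.alt_id or "",
                        g.function_category,
                        "|".join(sorted(g.source_pathway_dbs)),
                        str(g.pathway_maps),
                        str(g.degree),
                    ]
                )
                + "\n"
            )

    with paths["edge_annotations"].open("w") as fh:
        fh.write("\t".join(_EDGE_ANN_HEADER) + "\n")
        for a, b in sorted(compendium.edges):
            anns = compendium.edges[(a, b)].annotations
            for ann in sorted(
                anns,
                key=lambda x: (x.source_db, x.direction, x.sign, x.mechanism, x.raw or "", x.dataset or ""),
            ):
                fh.write(
                    "\t".join(
                        [a, b, ann.source_db, ann.direction, ann.sign, ann.mechanism, ann.raw or "", ann.dataset or ""]
                    )
                    + "\n"
                )

    with paths["pathways"].open("w") as fh:
        fh.write("\t".join(_PATHWAY_COLUMNS) + "\n")
        for pw in sorted(compendium.pathways, key=lambda p: p.key):
            for gid in sorted(pw.genes):
                fh.write(f"{pw.pathway_label}\t{pw.source_db}\t{gid}\n")

    provenance = {
        "interaction_sources": list(compendium.interaction_sources),
        "pathway_sources": list(compendium.pathway_sources),
        "n_genes": compendium.n_genes,
        "n_pathways": len(compendium.pathways),
        "n_canonical_edges": compendium.n_edges,
    }
    with paths["provenance"].open("w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_compendium(in_dir: str | Path) -> Compendium:
    """Inverse of :func:`write_compendium`; round-trips all tables exactly."""
    in_dir = Path(in_dir)
    with (in_dir / "provenance.json").open() as fh:
        provenance = json.load(fh)

    compendium = Compendium(
        interaction_sources=list(provenance["interaction_sources"]),
        pathway_sources=list(provenance["pathway_sources"]),
    )

    with (in_dir / "nodes.tsv").open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            compendium.genes[row["gene_id"]] = GeneRecord(
                gene_id=row["gene_id"],
                alt_id=row["alt_id"] or None,
                function_category=row["function_category"],
            )

    compendium.pathways = read_pathway_table(in_dir / "pathways.tsv", dialect="long")

    with (in_dir / "edge_annotations.tsv").open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = canonical_pair(row["gene_a"], row["gene_b"])
            edge = compendium.edges.get(key)
            ann = SourceAnnotation(
                source_db=row["source_db"],
                direction=row["direction"],
                sign=row["sign"],
                mechanism=row["mechanism"],
                raw=row["raw"] or None,
                dataset=row["dataset"] or None,
            )
            if edge is None:
                compendium.edges[key] = EdgeRecord(key[0], key[1], [ann])
            else:
                edge.annotations.append(ann)

    compendium.recompute_derived()
    compendium.validate()
    return compendium
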