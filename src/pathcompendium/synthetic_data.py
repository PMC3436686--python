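"""Synthetic compendium generator with planted ground truth.

Emulates the statistical structure of real multi-database inputs: power-law
pathway membership multiplicity, controllable cross-source edge sharing
(heavy-tailed edge weights), a within-pathway edge-enrichment knob mapping
directly onto the modularity statistic, and a planted linear signalling
scaffold with bypass edges and one-step intermediates.

All randomness flows from one seeded numpy generator; no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    Compendium,
    CompendiumError,
    GeneRecord,
    PathwayRecord,
    SourceAnnotation,
    add_annotation,
    canonical_pair,
)


class ConfigError(ValueError):
    """Infeasible or invalid synthetic configuration."""


@dataclass
class ScaffoldSpec:
    chain: list[str]
    n_bypass: int = 0
    n_intermediates: int = 0


@dataclass
class SyntheticConfig:
    n_genes: int = 300
    pathway_sources: list[tuple[str, int]] = field(default_factory=lambda: [("dbP1", 10)])
    interaction_sources: list[str] = field(default_factory=lambda: ["dbI1"])
    pathway_size_range: tuple[int, int] = (10, 30)
    membership_exponent: float = 2.0
    membership_cap: int = 20
    n_edges_per_source: int = 600
    internal_edge_enrichment: float = 1.0
    source_sharing: float = 0.1
    directed_fraction: float = 0.5
    sign_fractions: tuple[float, float, float] = (0.3, 0.2, 0.5)
    mechanism_fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    scaffold: Optional[ScaffoldSpec] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigError(f"invalid pathway_size_range {self.pathway_size_range}")
        if self.membership_exponent <= 1.0:
            raise ConfigError("membership_exponent must exceed 1")
        if self.membership_cap < 1:
            raise ConfigError("membership_cap must be >= 1")
        if self.internal_edge_enrichment < 0:
            raise ConfigError("internal_edge_enrichment must be >= 0")
        for p in (self.source_sharing, self.directed_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0,1]")
        for frac in (self.sign_fractions, self.mechanism_fractions):
            if len(frac) != 3 or abs(sum(frac) - 1.0) > 1e-9 or min(frac) < 0:
                raise ConfigError(f"fractions {frac} must be a non-negative triple summing to 1")
        if not self.interaction_sources:
            raise ConfigError("at least one interaction source required")
        if not self.pathway_sources:
            raise ConfigError("at least one pathway source required")
        max_pairs = self.n_genes * (self.n_genes - 1) // 2
        if self.n_edges_per_source > max_pairs:
            raise ConfigError(
                f"n_edges_per_source={self.n_edges_per_source} exceeds possible pairs {max_pairs}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "pathway_sources" in d:
            d["pathway_sources"] = [tuple(x) for x in d["pathway_sources"]]
        for key in ("pathway_size_range", "sign_fractions", "mechanism_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("scaffold") is not None and not isinstance(d["scaffold"], ScaffoldSpec):
            d["scaffold"] = ScaffoldSpec(**d["scaffold"])
        return cls(**d)


@dataclass
class PlantedTruth:
    per_pathway_internal_fraction: dict[str, float] = field(default_factory=dict)
    expected_modularity: dict[str, float] = field(default_factory=dict)
    internal_pair_fraction: float = 0.0
    scaffold_nodes: list[str] = field(default_factory=list)
    bypass_edges: list[tuple[str, str]] = field(default_factory=list)
    intermediates: list[tuple[str, str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_pathway_internal_fraction": self.per_pathway_internal_fraction,
            "expected_modularity": self.expected_modularity,
            "internal_pair_fraction": self.internal_pair_fraction,
            "scaffold_nodes": self.scaffold_nodes,
            "bypass_edges": [list(e) for e in self.bypass_edges],
            "intermediates": [list(t) for t in self.intermediates],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def planted_modularity(enrichment: float, internal_pair_fraction: float) -> float:
    """Expected modularity M implied by the enrichment knob.

    With a fraction q of gene pairs lying within some pathway, accepted
    internal pairs are ``e`` times as dense as cross pairs while the
    membership-randomized null sees the mixture (1-q) + q*e, so
    M = e / ((1-q) + q*e) - 1. At q -> 0 this reduces to e - 1.
    """
    q = internal_pair_fraction
    denom = (1.0 - q) + q * enrichment
    return enrichment / denom - 1.0


def enrichment_for_target_ratio(target: float, internal_pair_fraction: float) -> float:
    """Enrichment knob giving an observed/null internal-density ratio of
    ``target`` (i.e. planted M = target - 1), inverting planted_modularity."""
    q = internal_pair_fraction
    denom = 1.0 - target * q
    if denom <= 0:
        raise ConfigError(
            f"target ratio {target} infeasible at internal pair fraction {q:.3f}"
        )
    return target * (1.0 - q) / denom


def _pathway_key_str(label: str, source_db: str) -> str:
    return f"{label}@{source_db}"


def _sample_multiplicities(rng: np.random.Generator, config: SyntheticConfig, total: int) -> np.ndarray:
    """Per-gene membership counts: capped zipf, adjusted to sum exactly to total."""
    n = config.n_genes
    if total > n * config.membership_cap:
        raise ConfigError("total pathway memberships exceed gene capacity")
    mult = np.minimum(rng.zipf(config.membership_exponent, size=n), config.membership_cap)
    diff = int(mult.sum()) - total
    while diff > 0:
        # thin membership stubs uniformly (heavy genes absorb more trims),
        # preserving the shape of the multiplicity distribution
        p = mult / mult.sum()
        removed = rng.multinomial(diff, p)
        mult = np.maximum(mult - removed, 0)
        diff = int(mult.sum()) - total
    while diff < 0:
        candidates = np.flatnonzero(mult < config.membership_cap)
        give = rng.choice(candidates, size=min(-diff, len(candidates)), replace=False)
        mult[give] += 1
        diff = int(mult.sum()) - total
    return mult


def _assign_memberships(
    rng: np.random.Generator,
    config: SyntheticConfig,
    gene_ids: Sequence[str],
    sizes: Sequence[int],
) -> list[set[int]]:
    """Fill each pathway with distinct genes, weighted by remaining multiplicity."""
    remaining = _sample_multiplicities(rng, config, int(sum(sizes))).astype(float)
    if max(sizes, default=0) > config.n_genes:
        raise ConfigError("pathway size exceeds n_genes")
    memberships: list[set[int]] = []
    for s in sizes:
        candidates = np.flatnonzero(remaining > 0)
        if len(candidates) >= s:
            weights = remaining[candidates]
            chosen = rng.choice(candidates, size=s, replace=False, p=weights / weights.sum())
        else:
            # leftover multiplicity is concentrated on a few heavy genes;
            # top up uniformly from exhausted genes to keep the size exact
            others = np.flatnonzero(remaining <= 0)
            extra = rng.choice(others, size=s - len(candidates), replace=False)
            chosen = np.concatenate([candidates, extra])
        remaining[chosen] = np.maximum(remaining[chosen] - 1, 0.0)
        memberships.append(set(int(i) for i in chosen))
    return memberships


def _annotate(
    rng: np.random.Generator, config: SyntheticConfig, source_db: str
) -> SourceAnnotation:
    if rng.random() < config.directed_fraction:
        direction = "forward" if rng.random() < 0.5 else "reverse"
    else:
        direction = "undirected"
    sign = ("positive", "negative", "unsigned")[
        int(rng.choice(3, p=np.asarray(config.sign_fractions)))
    ]
    mechanism = ("direct", "indirect", "unknown")[
        int(rng.choice(3, p=np.asarray(config.mechanism_fractions)))
    ]
    return SourceAnnotation(source_db=source_db, direction=direction, sign=sign, mechanism=mechanism)


def generate_compendium(config: SyntheticConfig) -> tuple[Compendium, PlantedTruth]:
    """Generate a full compendium; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(config.n_genes)]

    # pathways ------------------------------------------------------------------
    lo, hi = config.pathway_size_range
    pathway_keys: list[tuple[str, str]] = []
    for db, n_pw in config.pathway_sources:
        for j in range(n_pw):
            pathway_keys.append((f"{db}_pathway_{j:03d}", db))
    sizes = [int(rng.integers(lo, hi + 1)) for _ in pathway_keys]
    memberships = _assign_memberships(rng, config, gene_ids, sizes)

    pathways = [
        PathwayRecord(label, db, frozenset(gene_ids[i] for i in member_idx))
        for (label, db), member_idx in zip(pathway_keys, memberships)
    ]

    master_idx = sorted(set().union(*memberships)) if memberships else []
    master = [gene_ids[i] for i in master_idx]
    gene_pathways: dict[str, set[int]] = {g: set() for g in master}
    for p_idx, member_idx in enumerate(memberships):
        for i in member_idx:
            gene_pathways[gene_ids[i]].add(p_idx)

    # edges ---------------------------------------------------------------------
    n_master = len(master)
    max_pairs = n_master * (n_master - 1) // 2
    if config.n_edges_per_source > max_pairs:
        raise ConfigError("n_edges_per_source exceeds possible pairs among realized genes")

    enrich = config.internal_edge_enrichment
    accept_norm = max(enrich, 1.0)
    per_source: dict[str, set[tuple[str, str]]] = {db: set() for db in config.interaction_sources}
    for db in config.interaction_sources:
        edges = per_source[db]
        guard = 0
        while len(edges) < config.n_edges_per_source:
            guard += 1
            if guard > 400 * config.n_edges_per_source + 10_000:
                raise ConfigError("edge sampling failed to converge; relax the config")
            i, j = rng.choice(n_master, size=2, replace=False)
            pair = canonical_pair(master[int(i)], master[int(j)])
            if pair in edges:
                continue
            internal = bool(gene_pathways[pair[0]] & gene_pathways[pair[1]])
            p_accept = (enrich if internal else 1.0) / accept_norm
            if rng.random() < p_accept:
                edges.add(pair)

    # cross-source sharing: independent Bernoulli copy of each ORIGINAL edge
    # into each other source (copies are never re-copied)
    if len(config.interaction_sources) > 1 and config.source_sharing > 0:
        originals = {db: sorted(pairs) for db, pairs in per_source.items()}
        for db in config.interaction_sources:
            for pair in originals[db]:
                for other in config.interaction_sources:
                    if other != db and rng.random() < config.source_sharing:
                        per_source[other].add(pair)

    compendium = Compendium(
        interaction_sources=list(config.interaction_sources),
        pathway_sources=[db for db, _ in config.pathway_sources],
        pathways=pathways,
    )
    for g in master:
        compendium.genes[g] = GeneRecord(gene_id=g)
    for db in config.interaction_sources:
        for pair in sorted(per_source[db]):
            add_annotation(compendium, pair[0], pair[1], _annotate(rng, config, db))
    compendium.recompute_derived()
    compendium.validate()

    # planted truth -------------------------------------------------------------
    internal_pairs: set[tuple[int, int]] = set()
    for member_idx in memberships:
        ordered = sorted(member_idx)
        for ii, a in enumerate(ordered):
            for b in ordered[ii + 1 :]:
                internal_pairs.add((a, b))
    q = len(internal_pairs) / max_pairs if max_pairs else 0.0

    truth = PlantedTruth(internal_pair_fraction=q)
    all_pairs = set(compendium.edges)
    for pw in pathways:
        p_in = p_ex = 0
        for a, b in all_pairs:
            a_in, b_in = a in pw.genes, b in pw.genes
            if a_in and b_in:
                p_in += 2
            elif a_in or b_in:
                p_ex += 1
        key = _pathway_key_str(pw.pathway_label, pw.source_db)
        total = p_in + p_ex
        truth.per_pathway_internal_fraction[key] = (p_in / total) if total else float("nan")
        truth.expected_modularity[key] = planted_modularity(enrich, q)
    return compendium, truth


def generate_scaffold_network(config: SyntheticConfig) -> tuple[Compendium, PlantedTruth]:
    """Generate a compendium around a planted directed signalling scaffold.

    Contains the chain's consecutive directed edges, ``n_bypass`` directed
    edges from the chain head that skip the second node, and
    ``n_intermediates`` one-step detours S_i -> X -> S_j between scaffold
    node pairs. All planted elements are recorded in the returned truth.
    """
    config.validate()
    if config.scaffold is None:
        raise ConfigError("config.scaffold is required")
    spec = config.scaffold
    chain = list(spec.chain)
    k = len(chain)
    if k < 3:
        raise ConfigError("scaffold chain must have length >= 3")
    if len(set(chain)) != k:
        raise ConfigError("scaffold chain nodes must be distinct")
    if spec.n_bypass > k - 2:
        raise ConfigError(f"n_bypass={spec.n_bypass} exceeds available skip targets {k - 2}")
    if spec.n_intermediates > k * (k - 1):
        raise ConfigError("n_intermediates exceeds available ordered scaffold pairs")

    rng = np.random.default_rng(config.seed)
    intermediates = [f"X{i:03d}" for i in range(spec.n_intermediates)]
    genes = chain + intermediates

    db = config.interaction_sources[0]
    pw_db = config.pathway_sources[0][0]
    compendium = Compendium(
        interaction_sources=[db],
        pathway_sources=[pw_db],
        pathways=[PathwayRecord("scaffold_pathway", pw_db, frozenset(genes))],
    )
    for g in genes:
        compendium.genes[g] = GeneRecord(gene_id=g)

    def planted(u: str, v: str) -> None:
        a, b = canonical_pair(u, v)
        direction = "forward" if (a, b) == (u, v) else "reverse"
        add_annotation(
            compendium, a, b,
            SourceAnnotation(source_db=db, direction=direction, sign="positive", mechanism="direct"),
        )

    truth = PlantedTruth(scaffold_nodes=chain)
    for u, v in zip(chain, chain[1:]):
        planted(u, v)

    skip_targets = rng.choice(np.arange(2, k), size=spec.n_bypass, replace=False)
    for j in sorted(int(x) for x in skip_targets):
        planted(chain[0], chain[j])
        truth.bypass_edges.append(canonical_pair(chain[0], chain[j]))

    ordered_pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    pick = rng.choice(len(ordered_pairs), size=spec.n_intermediates, replace=False)
    for x, idx in zip(intermediates, sorted(int(i) for i in pick)):
        i, j = ordered_pairs[idx]
        planted(chain[i], x)
        planted(x, chain[j])
        truth.intermediates.append((x, chain[i], chain[j]))

    compendium.recompute_derived()
    compendium.validate()
    return compendium, truth
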