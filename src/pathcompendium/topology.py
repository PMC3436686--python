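"""Per-gene structural metrics and the function-enrichment landscape."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .model import Compendium

REGIONS = ("maps_hi_bt_hi", "maps_lo_bt_hi", "maps_lo_bt_lo")
QUADRANTS = ("maps_hi_bt_hi", "maps_lo_bt_hi", "maps_lo_bt_lo", "maps_hi_bt_lo")


def compute_degrees(compendium: Compendium) -> tuple[dict[str, int], dict[str, float]]:
    """Per-gene degree over canonical edges plus network-level summary.

    Two mean-degree conventions are reported: ``mean_degree_paper`` is
    edges/nodes (E/N, the convention behind the published 26.8 figure) and
    ``mean_degree_graph`` is the graph-theoretic 2E/N.
    """
    degrees = {gid: 0 for gid in compendium.genes}
    for a, b in compendium.edges:
        degrees[a] += 1
        degrees[b] += 1
    n_nodes = len(degrees)
    n_edges = len(compendium.edges)
    summary = {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "mean_degree_paper": n_edges / n_nodes if n_nodes else math.nan,
        "mean_degree_graph": 2 * n_edges / n_nodes if n_nodes else math.nan,
    }
    return degrees, summary


def compute_betweenness(compendium: Compendium) -> dict[str, float]:
    """Betweenness centrality on the undirected projection, as a fraction.

    Unit edge lengths; endpoints excluded; pair-normalized so each value is
    the fraction of shortest paths passing through the gene.
    """
    graph = compendium.graph()
    return nx.betweenness_centrality(graph, normalized=True)


def compute_pathway_maps(compendium: Compendium) -> dict[str, int]:
    """Number of database-scoped pathways containing each gene."""
    maps = {gid: 0 for gid in compendium.genes}
    for pw in compendium.pathways:
        for gid in pw.genes:
            maps[gid] += 1
    return maps


def hypergeometric_z(N: int, R: int, n: int, r: int) -> float:
    """Standardized hypergeometric score (r - mu) / sigma.

    N population size, R positives in the population, n sample size, r
    positives in the sample. Degenerate cases with zero variance (n = N,
    R = 0 or R = N) return 0 by definition.
    """
    if N <= 1:
        raise ValueError("N must exceed 1")
    if not 0 <= R <= N:
        raise ValueError("require 0 <= R <= N")
    if not 0 < n <= N:
        raise ValueError("require 0 < n <= N")
    if not 0 <= r <= min(n, R):
        raise ValueError("require 0 <= r <= min(n, R)")
    p = R / N
    var = n * p * (1.0 - p) * (N - n) / (N - 1)
    if var == 0.0:
        return 0.0
    return (r - n * p) / math.sqrt(var)


@dataclass
class EnrichmentScan:
    region: str
    category: str
    window_sizes: list[int] = field(default_factory=list)
    window_fractions: list[float] = field(default_factory=list)
    z_scores: list[float] = field(default_factory=list)
    ranked_genes: list[str] = field(default_factory=list)


def _percentile_ranks(values: Sequence[float]) -> np.ndarray:
    return stats.rankdata(values, method="average") / len(values)


def rank_toward_tip(
    genes: Sequence[str],
    maps: Sequence[int],
    betweenness: Sequence[float],
    region: str,
) -> list[str]:
    """Deterministic ranking toward a region's tip.

    Score = product of percentile ranks in the region's preferred directions
    (a "hi" axis uses the ascending percentile, a "lo" axis the descending
    one); ties broken lexicographically by gene id.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    maps_arr = np.asarray(maps, dtype=float)
    bt_arr = np.asarray(betweenness, dtype=float)
    maps_pct = _percentile_ranks(maps_arr if "maps_hi" in region else -maps_arr)
    bt_pct = _percentile_ranks(bt_arr if "bt_hi" in region else -bt_arr)
    score = maps_pct * bt_pct
    order = sorted(range(len(genes)), key=lambda i: (-score[i], genes[i]))
    return [genes[i] for i in order]


def enrichment_scan(
    compendium: Compendium,
    region: str,
    category: str,
    n_windows: Optional[int] = None,
    min_window: int = 10,
    maps: Optional[dict[str, int]] = None,
    betweenness: Optional[dict[str, float]] = None,
) -> EnrichmentScan:
    """Z-score of category enrichment in successively widened tip windows."""
    if maps is None:
        maps = compute_pathway_maps(compendium)
    if betweenness is None:
        betweenness = compute_betweenness(compendium)
    genes = sorted(compendium.genes)
    categories = {compendium.genes[g].function_category for g in genes}
    if category not in categories:
        raise ValueError(f"category {category!r} absent from the annotation table")

    ranked = rank_toward_tip(
        genes, [maps[g] for g in genes], [betweenness[g] for g in genes], region
    )
    positive = np.array(
        [compendium.genes[g].function_category == category for g in ranked], dtype=int
    )
    N = len(ranked)
    R = int(positive.sum())
    cum = np.cumsum(positive)

    start = min(min_window, N)
    sizes = list(range(start, N + 1))
    if n_windows is not None and n_windows < len(sizes):
        idx = np.unique(np.linspace(0, len(sizes) - 1, n_windows).round().astype(int))
        sizes = [sizes[i] for i in idx]

    scan = EnrichmentScan(region=region, category=category, ranked_genes=ranked)
    for n in sizes:
        r = int(cum[n - 1])
        scan.window_sizes.append(n)
        scan.window_fractions.append(n / N)
        scan.z_scores.append(hypergeometric_z(N, R, n, r))
    return scan


def partition_landscape(
    compendium: Compendium,
    maps_threshold: float,
    bt_threshold: float,
    maps: Optional[dict[str, int]] = None,
    betweenness: Optional[dict[str, float]] = None,
) -> dict[str, str]:
    """Assign each gene a quadrant label by threshold comparison (hi = >=)."""
    if maps is None:
        maps = compute_pathway_maps(compendium)
    if betweenness is None:
        betweenness = compute_betweenness(compendium)
    labels = {}
    for gid in compendium.genes:
        maps_part = "maps_hi" if maps[gid] >= maps_threshold else "maps_lo"
        bt_part = "bt_hi" if betweenness[gid] >= bt_threshold else "bt_lo"
        labels[gid] = f"{maps_part}_{bt_part}"
    return labels
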