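"""Pathway modularity against a membership-preserving randomization null.

Connectivity accounting is endpoint-based: an edge internal to a pathway
contributes 2 to P_IN (both endpoints), an edge crossing the boundary
contributes 1 to P_EX, so P_T = P_IN + P_EX equals the member-gene degree
sum. The null randomizes the gene-pathway incidence structure while
preserving each pathway's size and each gene's membership count
(Pathway Maps); the modularity score is

    M = (P_IN / P_T) / (E_IN / E_T) - 1

so M = 0 for random structure and M = 1 for a two-fold internal excess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Compendium, PathwayRecord


@dataclass
class PathwayConnectivity:
    pathway_key: tuple[str, str]
    p_t: int
    p_in: int
    p_ex: int

    @property
    def ratio(self) -> Optional[float]:
        if self.p_t == 0:
            return None
        return self.p_in / self.p_t


@dataclass
class ModularityResult:
    pathway_key: tuple[str, str]
    observed_ratio: Optional[float]
    expected_ratio: Optional[float]
    m: Optional[float]
    n_randomizations: int
    seed: int


def pathway_connectivity(
    pathway: PathwayRecord, network: Iterable[tuple[str, str]]
) -> PathwayConnectivity:
    """Endpoint counts for one pathway against an edge set."""
    members = pathway.genes
    p_in = p_ex = 0
    for a, b in network:
        a_in, b_in = a in members, b in members
        if a_in and b_in:
            p_in += 2
        elif a_in or b_in:
            p_ex += 1
    return PathwayConnectivity(pathway.key, p_in + p_ex, p_in, p_ex)


def _connectivity_ratios(
    membership_sets: Sequence[frozenset[str] | set[str]],
    network: Sequence[tuple[str, str]],
) -> list[Optional[float]]:
    """P_IN/P_T per pathway, computed in one pass over the edge list."""
    gene_to_pw: dict[str, list[int]] = {}
    for idx, genes in enumerate(membership_sets):
        for g in genes:
            gene_to_pw.setdefault(g, []).append(idx)
    p_in = [0] * len(membership_sets)
    p_t = [0] * len(membership_sets)
    empty: list[int] = []
    for a, b in network:
        pa = gene_to_pw.get(a, empty)
        pb = gene_to_pw.get(b, empty)
        for idx in pa:
            p_t[idx] += 1
        for idx in pb:
            p_t[idx] += 1
        if pa and pb:
            for idx in set(pa).intersection(pb):
                p_in[idx] += 2
    return [(p_in[i] / p_t[i]) if p_t[i] else None for i in range(len(membership_sets))]


def randomize_memberships(
    pathways: Sequence[PathwayRecord],
    seed: int | np.random.Generator = 0,
    n_swaps: Optional[int] = None,
    max_attempt_factor: int = 20,
) -> list[PathwayRecord]:
    """Randomize gene lists preserving pathway sizes and per-gene Maps.

    Performs random pairwise membership swaps on the gene-pathway bipartite
    incidence structure; a swap is applied only when it creates no duplicate
    membership. If the attempt budget is exhausted before the requested
    number of applied swaps a diagnostic warning is emitted (a table with no
    degrees of freedom, e.g. identical pathways, is returned unchanged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sets = [set(pw.genes) for pw in pathways]
    entries: list[tuple[int, str]] = [
        (p_idx, g) for p_idx, genes in enumerate(sets) for g in sorted(genes)
    ]
    n_entries = len(entries)
    if len(pathways) < 2 or n_entries < 2:
        return list(pathways)
    if n_swaps is None:
        n_swaps = 10 * n_entries

    applied = 0
    attempts = 0
    budget = max_attempt_factor * n_swaps
    chunk = 4096
    buffer = rng.integers(0, n_entries, size=(chunk, 2)).tolist()
    while applied < n_swaps:
        attempts += 1
        if attempts > budget:
            if applied < n_swaps:
                warnings.warn(
                    f"membership randomization applied {applied}/{n_swaps} swaps "
                    f"in {budget} attempts; structure may be under-mixed"
                )
            break
        if not buffer:
            buffer = rng.integers(0, n_entries, size=(chunk, 2)).tolist()
        i, j = buffer.pop()
        p1, g1 = entries[i]
        p2, g2 = entries[j]
        if p1 == p2 or g1 == g2 or g1 in sets[p2] or g2 in sets[p1]:
            continue
        sets[p1].discard(g1)
        sets[p2].discard(g2)
        sets[p1].add(g2)
        sets[p2].add(g1)
        entries[i] = (p1, g2)
        entries[j] = (p2, g1)
        applied += 1

    return [
        PathwayRecord(pw.pathway_label, pw.source_db, frozenset(genes))
        for pw, genes in zip(pathways, sets)
    ]


def modularity_scores(
    pathways: Sequence[PathwayRecord],
    network: Iterable[tuple[str, str]],
    n_randomizations: int = 100,
    seed: int = 0,
    pooled: bool = False,
) -> list[ModularityResult]:
    """Modularity for every pathway against one edge set.

    The expected ratio comes from ``n_randomizations`` full-table membership
    randomizations; per-pathway means by default, a pooled
    sum(P_IN)/sum(P_T) per randomization with ``pooled=True``.
    """
    network = sorted(set(network))
    rng = np.random.default_rng(seed)
    observed = _connectivity_ratios([pw.genes for pw in pathways], network)

    null_ratios: list[list[float]] = [[] for _ in pathways]
    pooled_ratios: list[float] = []
    for _ in range(n_randomizations):
        randomized = randomize_memberships(pathways, rng)
        ratios = _connectivity_ratios([pw.genes for pw in randomized], network)
        if pooled:
            gene_to = [set(pw.genes) for pw in randomized]
            tot_in = tot_t = 0
            for genes in gene_to:
                pc = pathway_connectivity(
                    PathwayRecord("_", "_", frozenset(genes)), network
                )
                tot_in += pc.p_in
                tot_t += pc.p_t
            if tot_t:
                pooled_ratios.append(tot_in / tot_t)
        for idx, r in enumerate(ratios):
            if r is not None:
                null_ratios[idx].append(r)

    results: list[ModularityResult] = []
    pooled_mean = float(np.mean(pooled_ratios)) if pooled and pooled_ratios else None
    for idx, pw in enumerate(pathways):
        obs = observed[idx]
        if pooled:
            exp = pooled_mean
        else:
            exp = float(np.mean(null_ratios[idx])) if null_ratios[idx] else None
        if obs is None or exp is None or exp == 0.0:
            m = None
        else:
            m = obs / exp - 1.0
        results.append(
            ModularityResult(pw.key, obs, exp, m, n_randomizations, seed)
        )
    return results


def modularity_score(
    pathway: PathwayRecord,
    pathways: Sequence[PathwayRecord],
    network: Iterable[tuple[str, str]],
    n_randomizations: int = 100,
    seed: int = 0,
) -> ModularityResult:
    """Modularity of one pathway; the null still randomizes the full table."""
    results = modularity_scores(pathways, network, n_randomizations, seed)
    for res in results:
        if res.pathway_key == pathway.key:
            return res
    raise ValueError(f"pathway {pathway.key} not in table")


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """Rank-sum U and p-value; exact for small tie-free samples.

    Degenerate comparison of identical constant samples returns p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        return u, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ModularityMatrix:
    networks: list[str]  # rows: per-source networks plus "Ensemble"
    pathway_dbs: list[str]  # columns
    mean_m: pd.DataFrame
    p_values: pd.DataFrame
    per_pathway: dict[tuple[str, str], list[ModularityResult]] = field(default_factory=dict)
    row_order: list[int] = field(default_factory=list)


def modularity_matrix(
    compendium: Compendium,
    n_randomizations: int = 100,
    seed: int = 0,
    alternative: str = "greater",
) -> ModularityMatrix:
    """Mean M and Mann-Whitney p per (interaction network x pathway source).

    Rows are each interaction source's own network plus the merged Ensemble;
    columns are pathway source databases. The p-value compares the
    per-pathway observed-ratio distribution with the per-pathway
    expected-ratio distribution.
    """
    networks = {db: sorted(compendium.edge_pairs_of_source(db)) for db in compendium.interaction_sources}
    networks["Ensemble"] = sorted(compendium.edges)
    row_names = list(compendium.interaction_sources) + ["Ensemble"]
    col_names = list(compendium.pathway_sources)

    mean_m = pd.DataFrame(np.nan, index=row_names, columns=col_names)
    p_values = pd.DataFrame(np.nan, index=row_names, columns=col_names)
    per_pathway: dict[tuple[str, str], list[ModularityResult]] = {}

    for net_name in row_names:
        edge_set = networks[net_name]
        for pw_db in col_names:
            pathways = compendium.pathways_of_source(pw_db)
            if not pathways or not edge_set:
                continue
            results = modularity_scores(
                pathways, edge_set, n_randomizations=n_randomizations, seed=seed
            )
            per_pathway[(net_name, pw_db)] = results
            ms = [r.m for r in results if r.m is not None]
            obs = [r.observed_ratio for r in results if r.observed_ratio is not None]
            exp = [r.expected_ratio for r in results if r.expected_ratio is not None]
            if ms:
                mean_m.loc[net_name, pw_db] = float(np.mean(ms))
            if obs and exp:
                _, p = mann_whitney_u(obs, exp, alternative=alternative)
                p_values.loc[net_name, pw_db] = p

    profile = np.nan_to_num(mean_m.to_numpy(), nan=0.0)
    if len(row_names) > 2:
        from .pathway_similarity import cluster_order

        dist = np.sqrt(((profile[:, None, :] - profile[None, :, :]) ** 2).sum(axis=2))
        sim = 1.0 - dist / max(dist.max(), 1e-12)
        row_order = cluster_order(sim)
    else:
        row_order = list(range(len(row_names)))
    return ModularityMatrix(row_names, col_names, mean_m, p_values, per_pathway, row_order)
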