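"""Edge Weight distributions and the directional cross-database
Edge Consistency matrix.

Both statistics live at the canonical-pair level: direction and sign are
ignored when deciding whether two databases report "the same" interaction.
A database's gene set is induced from its edges (interaction sources carry
no independent gene roster).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import Compendium
from .pathway_similarity import cluster_order


def edge_weight_distribution(
    compendium: Compendium, restrict_to_source: Optional[str] = None
) -> pd.DataFrame:
    """Histogram of K_E (number of supporting databases) over canonical edges.

    With ``restrict_to_source``, the histogram instead counts, for each edge
    carried by that source, the number of distinct sub-datasets reported by
    it (the meta-database case); the source's annotations must then carry
    dataset tags.
    """
    if restrict_to_source is None:
        weights = [e.edge_weight for e in compendium.edges.values()]
    else:
        if restrict_to_source not in compendium.interaction_sources:
            raise ValueError(f"unregistered source {restrict_to_source!r}")
        weights = []
        any_dataset = False
        for edge in compendium.edges.values():
            datasets = {
                a.dataset
                for a in edge.annotations
                if a.source_db == restrict_to_source and a.dataset is not None
            }
            if datasets:
                any_dataset = True
                weights.append(len(datasets))
        if not any_dataset:
            raise ValueError(
                f"source {restrict_to_source!r} carries no per-dataset sub-annotations"
            )
    values, counts = np.unique(np.asarray(weights, dtype=int), return_counts=True)
    total = counts.sum()
    df = pd.DataFrame(
        {"edge_weight": values, "count": counts, "fraction": counts / total}
    )
    assert int(df["count"].sum()) == len(weights)
    return df


def edge_consistency(
    edges_i: Iterable[tuple[str, str]],
    edges_j: Iterable[tuple[str, str]],
    genes_j: Optional[set[str]] = None,
) -> Optional[float]:
    """Directional consistency C_E(i,j) between two edge sets.

    E(i) = edges of i with both endpoints among j's genes (induced from j's
    edges unless ``genes_j`` is given); the returned value is the fraction of
    those also present in j. Undefined (None) when E(i) is empty.
    """
    edges_i = set(edges_i)
    edges_j = set(edges_j)
    if genes_j is None:
        genes_j = {g for pair in edges_j for g in pair}
    qualifying = {e for e in edges_i if e[0] in genes_j and e[1] in genes_j}
    if not qualifying:
        return None
    return len(qualifying & edges_j) / len(qualifying)


def compendium_edge_consistency(
    compendium: Compendium, db_i: str, db_j: str
) -> Optional[float]:
    for db in (db_i, db_j):
        if db not in compendium.interaction_sources:
            raise ValueError(f"unregistered interaction source {db!r}")
    return edge_consistency(
        compendium.edge_pairs_of_source(db_i), compendium.edge_pairs_of_source(db_j)
    )


@dataclass
class ConsistencyMatrix:
    db_names: list[str]
    values: np.ndarray  # NaN marks undefined cells
    leaf_order: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.db_names, columns=self.db_names)


def consistency_matrix(compendium: Compendium) -> ConsistencyMatrix:
    """All ordered-pair consistencies, with a clustered row ordering.

    Rows are clustered on euclidean distance between row profiles (the same
    average-linkage contract as pathway similarity); NaN cells are treated
    as 0 for clustering only.
    """
    dbs = list(compendium.interaction_sources)
    if len(dbs) < 2:
        raise ValueError("need at least 2 interaction sources")
    edge_sets = {db: compendium.edge_pairs_of_source(db) for db in dbs}
    n = len(dbs)
    values = np.full((n, n), np.nan)
    for i, db_i in enumerate(dbs):
        for j, db_j in enumerate(dbs):
            if i == j:
                values[i, j] = 1.0
                continue
            c = edge_consistency(edge_sets[db_i], edge_sets[db_j])
            values[i, j] = np.nan if c is None else c
    profile = np.nan_to_num(values, nan=0.0)
    dist = np.sqrt(((profile[:, None, :] - profile[None, :, :]) ** 2).sum(axis=2))
    sim = 1.0 - dist / max(dist.max(), 1e-12)
    return ConsistencyMatrix(db_names=dbs, values=values, leaf_order=cluster_order(sim))
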