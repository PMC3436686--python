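"""Bounded simple-path enumeration, bypass classification and scaffold
expansion on the directed view of a compendium.

Path length counts edges; paths are simple (no node revisited) — without
that restriction bounded counts diverge in dense signalling graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
from scipy.stats import hypergeom

from .model import Compendium, SourceAnnotation, canonical_pair

DEFAULT_MAX_LENGTH_CAP = 8
DEFAULT_COUNT_CEILING = 10_000_000


@dataclass
class EdgeFilter:
    """Predicate over per-source annotations selecting arcs for the view."""

    directed_only: bool = True
    sources: Optional[set[str]] = None
    mechanisms: Optional[set[str]] = None
    signs: Optional[set[str]] = None

    def admits(self, ann: SourceAnnotation) -> bool:
        if self.directed_only and ann.direction == "undirected":
            return False
        if self.sources is not None and ann.source_db not in self.sources:
            return False
        if self.mechanisms is not None and ann.mechanism not in self.mechanisms:
            return False
        if self.signs is not None and ann.sign not in self.signs:
            return False
        return True


@dataclass
class PathQuery:
    source: str
    target: str
    max_length: int = 4
    required_node: Optional[str] = None
    first_hop_only: bool = False
    count_ceiling: int = DEFAULT_COUNT_CEILING
    max_length_cap: int = DEFAULT_MAX_LENGTH_CAP

    def validate(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target must differ")
        if not 1 <= self.max_length <= self.max_length_cap:
            raise ValueError(
                f"max_length must lie in [1, {self.max_length_cap}]"
            )


@dataclass
class PathEnumeration:
    counts_by_length: dict[int, int] = field(default_factory=dict)
    cumulative_counts: dict[int, int] = field(default_factory=dict)
    shortest_length: Optional[int] = None
    shortest_paths: list[list[str]] = field(default_factory=list)
    through_fraction: Optional[float] = None
    truncated: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts_by_length.values())


def directed_view(compendium: Compendium, edge_filter: Optional[EdgeFilter] = None) -> nx.DiGraph:
    """Directed graph with one arc per ordered pair admitted by the filter.

    A canonical edge contributes a forward arc, a reverse arc, or (for
    undirected annotations when allowed) both; parallel support from several
    sources collapses onto one arc.
    """
    if edge_filter is None:
        edge_filter = EdgeFilter()
    graph = nx.DiGraph()
    graph.add_nodes_from(compendium.genes)
    for (a, b), edge in compendium.edges.items():
        for ann in edge.annotations:
            if not edge_filter.admits(ann):
                continue
            if ann.direction == "forward":
                graph.add_edge(a, b)
            elif ann.direction == "reverse":
                graph.add_edge(b, a)
            else:
                graph.add_edge(a, b)
                graph.add_edge(b, a)
    return graph


def shortest_paths(
    graph: nx.DiGraph, source: str, target: str
) -> tuple[Optional[int], list[list[str]]]:
    """Length of and ALL distinct shortest paths, lexicographically sorted."""
    for node in (source, target):
        if node not in graph:
            raise ValueError(f"node {node!r} not in graph")
    if not nx.has_path(graph, source, target):
        return None, []
    paths = sorted(nx.all_shortest_paths(graph, source, target))
    return len(paths[0]) - 1, paths


def _count_simple_paths(
    graph: nx.DiGraph,
    source: str,
    target: str,
    max_length: int,
    required_node: Optional[str] = None,
    first_hop_only: bool = False,
    count_ceiling: int = DEFAULT_COUNT_CEILING,
) -> tuple[dict[int, int], dict[int, int], bool]:
    """Iterative bounded DFS counting simple paths by exact length.

    Returns (counts_by_length, through_counts_by_length, truncated). The
    through counts tally paths containing ``required_node`` anywhere (or as
    the first hop when ``first_hop_only``).
    """
    counts = {length: 0 for length in range(1, max_length + 1)}
    through = {length: 0 for length in range(1, max_length + 1)}
    if source not in graph or target not in graph:
        return counts, through, False

    adjacency = {u: sorted(graph.successors(u)) for u in graph.nodes}
    on_path = {source}
    path = [source]
    # stack of iterators mirrors the recursion; no recursion depth issues
    stack = [iter(adjacency[source])]
    total = 0
    truncated = False
    while stack:
        children = stack[-1]
        nxt = next(children, None)
        if nxt is None:
            stack.pop()
            on_path.discard(path.pop())
            continue
        if nxt in on_path:
            continue
        length = len(path)  # length of the candidate path in edges
        if nxt == target:
            counts[length] += 1
            total += 1
            if required_node is not None:
                if first_hop_only:
                    hit = (path + [nxt])[1] == required_node
                else:
                    hit = required_node in on_path or nxt == required_node
                if hit:
                    through[length] += 1
            if total >= count_ceiling:
                truncated = True
                break
            continue
        if length < max_length:
            path.append(nxt)
            on_path.add(nxt)
            stack.append(iter(adjacency[nxt]))
    return counts, through, truncated


def enumerate_paths(graph: nx.DiGraph, query: PathQuery) -> PathEnumeration:
    """Count simple paths of each exact length 1..max_length."""
    query.validate()
    counts, through, truncated = _count_simple_paths(
        graph,
        query.source,
        query.target,
        query.max_length,
        required_node=query.required_node,
        first_hop_only=query.first_hop_only,
        count_ceiling=query.count_ceiling,
    )
    result = PathEnumeration(counts_by_length=counts, truncated=truncated)
    running = 0
    for length in range(1, query.max_length + 1):
        running += counts[length]
        result.cumulative_counts[length] = running
    if query.source in graph and query.target in graph:
        result.shortest_length, result.shortest_paths = shortest_paths(
            graph, query.source, query.target
        )
    if query.required_node is not None:
        total = result.total
        result.through_fraction = (
            sum(through.values()) / total if total > 0 else None
        )
    return result


def through_fraction(graph: nx.DiGraph, query: PathQuery) -> Optional[float]:
    """Fraction of bounded simple paths containing the required node.

    None (flagged undefined) when no path exists within the bound. The
    bypass fraction is 1 minus this value.
    """
    if query.required_node is None:
        raise ValueError("query.required_node is required")
    if query.required_node not in graph:
        raise ValueError(f"required node {query.required_node!r} not in graph")
    return enumerate_paths(graph, query).through_fraction


@dataclass
class ScaffoldExpansion:
    chain: list[str]
    links: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (intermediate gene, from scaffold node, to scaffold node, class)

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for x, *_ in self.links:
            if x not in seen:
                seen.append(x)
        return seen


def classify_detour(i: int, j: int) -> str:
    """Class of a one-step detour from scaffold position i to position j."""
    if j == i + 1:
        return "parallel"
    if i < j - 1:
        return "feed-forward"
    return "feed-back"


def expand_scaffold(
    graph: nx.DiGraph, chain: Sequence[str], hop_limit: int = 1
) -> ScaffoldExpansion:
    """Non-scaffold genes bridging ANY ordered scaffold pair in one step.

    For every gene X outside the chain with arcs S_i -> X and X -> S_j the
    link (X, S_i, S_j) is reported with its detour class; distinct genes are
    counted once by ``.genes``.
    """
    if hop_limit != 1:
        raise NotImplementedError("only one-step intermediates are supported")
    chain = list(chain)
    missing = [g for g in chain if g not in graph]
    if missing:
        raise ValueError(f"scaffold genes missing from graph: {missing}")
    chain_set = set(chain)
    expansion = ScaffoldExpansion(chain=chain)
    candidates: set[str] = set()
    for s in chain:
        candidates.update(graph.successors(s))
    for x in sorted(candidates - chain_set):
        ins = [i for i, s in enumerate(chain) if graph.has_edge(s, x)]
        outs = [j for j, s in enumerate(chain) if graph.has_edge(x, s)]
        for i in ins:
            for j in outs:
                if i == j:
                    continue
                expansion.links.append(
                    (x, chain[i], chain[j], classify_detour(i, j))
                )
    return expansion


def scaffold_edge_enrichment(
    compendium: Compendium,
    chain: Sequence[str],
    high_weight_threshold: int,
) -> tuple[float, list[int]]:
    """Upper-tail hypergeometric p for high-weight edges along the scaffold.

    Population: all canonical edges; successes: edges with
    K_E >= threshold; sample: the chain's consecutive edges.
    """
    chain = list(chain)
    pairs = [canonical_pair(a, b) for a, b in zip(chain, chain[1:])]
    missing = [p for p in pairs if p not in compendium.edges]
    if missing:
        raise ValueError(f"scaffold edges missing from compendium: {missing}")
    sample_weights = [compendium.edges[p].edge_weight for p in pairs]
    population = [e.edge_weight for e in compendium.edges.values()]
    n_pop = len(population)
    n_success = sum(1 for w in population if w >= high_weight_threshold)
    n_sample = len(pairs)
    r = sum(1 for w in sample_weights if w >= high_weight_threshold)
    p = float(hypergeom.sf(r - 1, n_pop, n_success, n_sample))
    return p, sample_weights
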