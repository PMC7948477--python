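"""Pathway over-representation and the Jaccard-weighted crosstalk graph.

Over-representation of a query gene set in each pathway is tested with the
upper-tail hypergeometric probability P(X >= k) of drawing k or more pathway
members when n query genes are sampled without replacement from a universe
of N genes containing K pathway members.  P-values are BH-adjusted across
the tested pathways; the significance gate is p < p_max (default 0.05), with
the companion FDR level recorded alongside.

Significant pathways become nodes of a crosstalk graph whose edges are
weighted by the Jaccard index of the pathways' *detected* member sets
(members restricted to the proteins actually observed in the experiment);
edges below ``j_min`` (default 0.1) are discarded.  Modules are communities
found by deterministic greedy modularity maximization on the weighted graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import PathwayCollection
from .differential import compute_qvalues


class EnrichmentWarning(UserWarning):
    pass


def hypergeom_pvalue(k: int, K: int, n: int, N: int, tail: str = "upper") -> float:
    """Hypergeometric tail probability for pathway over-representation.

    ``upper`` (default): P(X >= k), the over-representation tail.
    ``lower``: P(X <= k), the depletion tail.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    dist = stats.hypergeom(M=N, n=K, N=n)
    tiny = float(np.nextafter(0, 1))  # keep p in (0, 1] even at extreme underflow
    if tail == "upper":
        return float(min(1.0, max(dist.sf(k - 1), tiny)))
    if tail == "lower":
        return float(min(1.0, max(dist.cdf(k), tiny)))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


@dataclass
class EnrichmentResult:
    """Per-pathway over-representation statistics.

    ``table`` is indexed by pathway name with columns ``k`` (overlap), ``K``
    (pathway size within the universe), ``n`` (query size), ``N`` (universe
    size), ``p_value``, ``q_value``, ``significant`` and ``overlap`` (the
    overlapping members, ';'-joined).
    """

    table: pd.DataFrame
    universe: set = field(default_factory=set)
    query: set = field(default_factory=set)
    dropped_query_genes: int = 0
    p_max: float = 0.05
    q_report: float = 0.15

    @property
    def significant_pathways(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def to_tsv(self, path) -> None:
        from .containers import FLOAT_FMT

        self.table.to_csv(path, sep="\t", index_label="pathway",
                          float_format=FLOAT_FMT)


def enrich_pathways(
    query,
    collection: PathwayCollection,
    universe,
    p_max: float = 0.05,
    q_report: float = 0.15,
    tail: str = "upper",
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` in every pathway.

    Query members outside the universe are dropped (count reported on the
    result); pathways with no universe member are skipped.  BH q-values are
    computed across the tested pathways and ``significant`` is p < p_max.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query_in = set(query) & universe
    dropped = len(set(query)) - len(query_in)
    if not query_in:
        raise ValueError("query is empty after intersection with the universe")

    N, n = len(universe), len(query_in)
    rows = []
    for pw in collection:
        members_in = pw.members & universe
        if not members_in:
            continue
        overlap = query_in & members_in
        k, K = len(overlap), len(members_in)
        rows.append({
            "pathway": pw.name,
            "k": k, "K": K, "n": n, "N": N,
            "p_value": hypergeom_pvalue(k, K, n, N, tail=tail),
            "overlap": ";".join(sorted(overlap)),
        })
    columns = ["k", "K", "n", "N", "p_value", "q_value", "significant", "overlap"]
    if rows:
        table = pd.DataFrame(rows).set_index("pathway")
        table["q_value"] = compute_qvalues(table["p_value"].to_numpy())
        table["significant"] = table["p_value"] < p_max
        table = table[columns]
    else:
        table = pd.DataFrame(columns=columns, index=pd.Index([], name="pathway"))
    return EnrichmentResult(table=table, universe=universe, query=query_in,
                            dropped_query_genes=dropped, p_max=p_max,
                            q_report=q_report)


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; errors when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def build_pathway_graph(
    results: EnrichmentResult,
    collection: PathwayCollection,
    detected,
    j_min: float = 0.1,
) -> nx.Graph:
    """Crosstalk graph over significant pathways, edges weighted by the
    Jaccard index of their detected member sets.

    Each node carries ``detected_members`` (the pathway's members that were
    observed, as a sorted tuple), ``size``, ``p_value`` and ``q_value``.
    Edges with J < ``j_min`` are discarded.  Pathways with no detected
    member are excluded with a warning; no significant pathways yields an
    empty graph with a warning, not an error.
    """
    detected = set(detected)
    if not detected:
        raise ValueError("detected set must be non-empty")
    graph = nx.Graph(j_min=j_min)
    names = results.significant_pathways
    if not names:
        warnings.warn("no significant pathways; returning empty graph",
                      EnrichmentWarning, stacklevel=2)
        return graph
    node_sets = {}
    for name in names:
        s = collection[name].members & detected
        if not s:
            warnings.warn(f"pathway {name!r} has no detected members; excluded",
                          EnrichmentWarning, stacklevel=2)
            continue
        node_sets[name] = s
        graph.add_node(
            name,
            detected_members=tuple(sorted(s)),
            size=len(s),
            p_value=float(results.table.at[name, "p_value"]),
            q_value=float(results.table.at[name, "q_value"]),
        )
    for a, b in combinations(sorted(node_sets), 2):
        j = jaccard(node_sets[a], node_sets[b])
        if j >= j_min:
            graph.add_edge(a, b, weight=j)
    return graph


def detect_modules(graph: nx.Graph, resolution: float = 1.0, seed: int = 0) -> dict:
    """Assign each pathway node to a module via greedy modularity maximization.

    The agglomeration is deterministic, so ``seed`` only fixes the API;
    isolated nodes form singleton modules.  Module ids ``M1, M2, ...`` are
    assigned in a stable order: decreasing module size, ties broken by the
    lexicographically smallest member.
    """
    if graph.number_of_nodes() == 0:
        return {}
    isolated = [v for v in graph.nodes if graph.degree(v) == 0]
    core = graph.subgraph(v for v in graph.nodes if graph.degree(v) > 0)
    communities: list[frozenset] = []
    if core.number_of_nodes() > 0:
        if core.number_of_edges() > 0 and core.number_of_nodes() > 1:
            communities = [
                frozenset(c)
                for c in nx.community.greedy_modularity_communities(
                    core, weight="weight", resolution=resolution
                )
            ]
        else:  # pragma: no cover - a positive-degree subgraph always has edges
            communities = [frozenset([v]) for v in core.nodes]
    communities += [frozenset([v]) for v in isolated]
    communities.sort(key=lambda c: (-len(c), min(c)))
    assignment = {}
    for i, comm in enumerate(communities, start=1):
        for v in comm:
            assignment[v] = f"M{i}"
    return assignment
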