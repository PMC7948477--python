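"""Interactome closest-distance proximity with a degree-preserving null.

The statistic is the closest distance

    d_c(S, T) = (1/|S|) * sum over s in S of min over t in T of d(s, t)

where d(s, t) is the unweighted shortest-path length on the PPI network.
Its significance is assessed against a null distribution obtained by
replacing S (and/or T) with random node sets matched to the observed set's
degree profile: nodes are grouped into base-2 logarithmic degree bins,
adjacent bins are merged until each holds a minimum number of nodes, and
each observed member is replaced by a draw (without replacement) from its
bin.  Degree matching matters because hubs are close to everything on a
scale-free network, so an unmatched null would overstate proximity.

The empirical p-value uses the (r+1)/(n+1) pseudocount convention, one-sided
toward small distances (proximity, not avoidance).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import read_network as load_network  # noqa: F401  (re-exported)


class ProximityWarning(UserWarning):
    pass


def map_to_network(genes, network: nx.Graph):
    """Partition ``genes`` into network members and an (ordered) unmapped list."""
    nodes = set(network.nodes)
    genes = set(genes)
    mapped = genes & nodes
    unmapped = sorted(genes - nodes)
    if genes and not mapped:
        warnings.warn("none of the genes map to the network",
                      ProximityWarning, stacklevel=2)
    return mapped, unmapped


def induced_subnetwork(network: nx.Graph, genes) -> nx.Graph:
    """Subgraph induced on ``genes`` ∩ nodes, with component sizes recorded."""
    sub = network.subgraph(set(genes) & set(network.nodes)).copy()
    sub.graph["component_sizes"] = sorted(
        (len(c) for c in nx.connected_components(sub)), reverse=True
    )
    return sub


def _adjacency(network: nx.Graph) -> dict:
    return {u: list(network[u]) for u in network.nodes}


def _dist_to_set(adj: dict, targets) -> dict:
    """Multi-source BFS: distance from every reachable node to the nearest target."""
    dist = {t: 0 for t in targets}
    frontier = list(targets)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def _closest_distance(adj: dict, S, T):
    dist = _dist_to_set(adj, T)
    terms = []
    excluded = []
    for s in sorted(S):
        if s in dist:
            terms.append(dist[s])
        else:
            excluded.append(s)
    if not terms:
        raise ValueError("no source node can reach any target node")
    return float(np.mean(terms)), excluded


def closest_distance(network: nx.Graph, S, T):
    """Mean over sources of the shortest-path distance to the nearest target.

    Returns ``(d_c, excluded)`` where ``excluded`` lists source nodes with no
    path to any target (they are left out of the mean and reported).  Sources
    that are themselves targets contribute 0.
    """
    S, T = set(S), set(T)
    nodes = set(network.nodes)
    if not S or not T:
        raise ValueError("S and T must be non-empty")
    stray = (S | T) - nodes
    if stray:
        raise ValueError(
            f"{len(stray)} gene(s) not in the network (map_to_network first): "
            f"{sorted(stray)[:5]}"
        )
    return _closest_distance(_adjacency(network), S, T)


@dataclass
class DegreeBins:
    """Base-2 logarithmic degree bins, merged to a minimum occupancy.

    ``bin_of`` maps node -> merged-bin index; ``members`` maps merged-bin
    index -> sorted node list.
    """

    bin_of: dict
    members: dict

    @classmethod
    def from_network(cls, network: nx.Graph, min_bin_size: int = 10) -> "DegreeBins":
        raw: dict[int, list] = {}
        for node in network.nodes:
            deg = network.degree(node)
            b = int(math.floor(math.log2(deg))) if deg > 0 else -1
            raw.setdefault(b, []).append(node)
        merged: list[list] = []
        current: list = []
        for b in sorted(raw):
            current.extend(raw[b])
            if len(current) >= min_bin_size:
                merged.append(current)
                current = []
        if current:
            if merged:
                merged[-1].extend(current)
            else:
                merged.append(current)
        bin_of, members = {}, {}
        for i, nodes in enumerate(merged):
            members[i] = sorted(nodes)
            for v in nodes:
                bin_of[v] = i
        return cls(bin_of=bin_of, members=members)

    def sample_like(self, template, rng: np.random.Generator) -> set:
        """Random node set matching the template's binned degree profile."""
        need: dict[int, int] = {}
        for v in template:
            if v not in self.bin_of:
                raise ValueError(f"template node {v!r} not in the network")
            b = self.bin_of[v]
            need[b] = need.get(b, 0) + 1
        out: set = set()
        for b in sorted(need):
            pool = self.members[b]
            if need[b] > len(pool):  # cannot happen when template ⊆ nodes
                raise ValueError(f"degree bin {b} smaller than requested sample")
            idx = rng.choice(len(pool), size=need[b], replace=False)
            out.update(pool[i] for i in idx)
        return out


def degree_matched_sample(network: nx.Graph, template, seed: int,
                          min_bin_size: int = 10) -> set:
    """Seeded draw of a node set degree-matched (by log2 bins) to ``template``."""
    bins = DegreeBins.from_network(network, min_bin_size=min_bin_size)
    rng = np.random.default_rng(seed)
    return bins.sample_like(set(template), rng)


@dataclass
class ProximityResult:
    """Observed closest distance, its degree-preserving null, and significance."""

    observed_dc: float
    s_size: int
    t_size: int
    excluded_sources: list
    null_mean: float
    null_sd: float
    n_randomizations: int
    z_score: float  # NaN when null_sd == 0
    empirical_p: float
    seed: int
    randomize: str
    null_values: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "observed_dc": self.observed_dc,
            "s_size": self.s_size,
            "t_size": self.t_size,
            "excluded_sources": list(self.excluded_sources),
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_randomizations": self.n_randomizations,
            "z_score": None if math.isnan(self.z_score) else self.z_score,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "randomize": self.randomize,
        }

    def to_json(self, path, null_path=None) -> None:
        payload = self.to_dict()
        if null_path is not None:
            from pathlib import Path

            payload["null_distribution_file"] = Path(null_path).name
            with open(null_path, "w") as fh:
                fh.write("null_dc\n")
                for v in self.null_values:
                    fh.write(f"{v:.17g}\n")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def proximity_test(
    network: nx.Graph,
    S,
    T,
    n_randomizations: int = 200,
    seed: int = 0,
    randomize: str = "S",
    min_bin_size: int = 10,
    max_retries_per_draw: int = 20,
) -> ProximityResult:
    """Closest-distance proximity of S to T with a degree-preserving null.

    For each of ``n_randomizations`` draws the chosen set(s) are replaced by
    degree-matched samples and d_c recomputed; the one-sided empirical
    p-value is (r+1)/(n+1) with r the number of null distances <= observed.
    A draw whose sources are all unreachable is redrawn up to a bounded
    retry budget.
    """
    if randomize not in ("S", "T", "both"):
        raise ValueError("randomize must be 'S', 'T' or 'both'")
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    S, T = set(S), set(T)
    adj = _adjacency(network)
    stray = (S | T) - set(adj)
    if not S or not T:
        raise ValueError("S and T must be non-empty")
    if stray:
        raise ValueError(f"{len(stray)} gene(s) not in the network")

    observed, excluded = _closest_distance(adj, S, T)
    bins = DegreeBins.from_network(network, min_bin_size=min_bin_size)
    rng = np.random.default_rng(seed)

    # With T fixed, the distance-to-target field is computed once and each
    # null draw only averages over a resampled S.
    dist_fixed_T = _dist_to_set(adj, T) if randomize == "S" else None

    null = np.empty(n_randomizations)
    for i in range(n_randomizations):
        for _attempt in range(max_retries_per_draw):
            s_draw = bins.sample_like(S, rng) if randomize in ("S", "both") else S
            t_draw = bins.sample_like(T, rng) if randomize in ("T", "both") else T
            if randomize == "S":
                terms = [dist_fixed_T[s] for s in s_draw if s in dist_fixed_T]
                if terms:
                    null[i] = float(np.mean(terms))
                    break
            else:
                try:
                    null[i], _ = _closest_distance(adj, s_draw, t_draw)
                    break
                except ValueError:
                    continue
        else:
            raise ValueError(
                f"randomization draw {i} failed reachability "
                f"{max_retries_per_draw} times"
            )

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_randomizations > 1 else 0.0
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
    else:
        z = float("nan")
        warnings.warn("null distribution has zero spread; z-score undefined",
                      ProximityWarning, stacklevel=2)
    r = int(np.sum(null <= observed + 1e-12))
    empirical_p = (r + 1) / (n_randomizations + 1)

    return ProximityResult(
        observed_dc=observed,
        s_size=len(S),
        t_size=len(T),
        excluded_sources=excluded,
        null_mean=null_mean,
        null_sd=null_sd,
        n_randomizations=n_randomizations,
        z_score=z,
        empirical_p=empirical_p,
        seed=seed,
        randomize=randomize,
        null_values=null,
    )
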