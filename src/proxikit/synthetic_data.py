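"""Synthetic study generator: networks, pathways, abundances, planted geometry.

Every generator is a pure function of its parameters and a seed, and returns
a :class:`SyntheticTruth` record of what was planted so downstream stages can
be scored for recovery:

* ``generate_network`` — a scale-free (preferential-attachment) graph as a
  desk-scale stand-in for a human protein–protein interaction network.  The
  heavy-tailed degree distribution is what makes degree-preserving nulls
  non-trivial, so it is the one topological feature the stand-in must have.
* ``generate_pathways`` — named gene sets over a universe, with consecutive
  pairs sharing a controlled number of members so Jaccard crosstalk edges
  exist by design.
* ``generate_abundance`` — a log-normal intensity model: log2 intensity =
  protein baseline + condition effect + donor intercept + batch offset +
  noise.  Effects are additive on the log2 scale, so fold changes are exact
  in the noiseless limit.
* ``plant_proximal_sets`` — source/target gene sets placed at a known
  closest-distance radius, the recovery fixture for the proximity statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceMatrix


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset, for recovery scoring."""

    planted_enriched_ids: set = field(default_factory=set)
    effect_log2fc: float = 0.0
    planted_source_set: set = field(default_factory=set)
    planted_target_set: set = field(default_factory=set)
    planted_radius: int = 0
    generator_params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "planted_enriched_ids": sorted(self.planted_enriched_ids),
            "effect_log2fc": self.effect_log2fc,
            "planted_source_set": sorted(self.planted_source_set),
            "planted_target_set": sorted(self.planted_target_set),
            "planted_radius": self.planted_radius,
            "generator_params": self.generator_params,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_enriched_ids=set(d["planted_enriched_ids"]),
            effect_log2fc=d["effect_log2fc"],
            planted_source_set=set(d["planted_source_set"]),
            planted_target_set=set(d["planted_target_set"]),
            planted_radius=d["planted_radius"],
            generator_params=d["generator_params"],
            seed=d["seed"],
        )

    def merged(self, other: "SyntheticTruth") -> "SyntheticTruth":
        """Combine two truth records (e.g. abundance truth + proximity truth)."""
        return SyntheticTruth(
            planted_enriched_ids=self.planted_enriched_ids | other.planted_enriched_ids,
            effect_log2fc=self.effect_log2fc or other.effect_log2fc,
            planted_source_set=self.planted_source_set | other.planted_source_set,
            planted_target_set=self.planted_target_set | other.planted_target_set,
            planted_radius=max(self.planted_radius, other.planted_radius),
            generator_params={**self.generator_params, **other.generator_params},
            seed=self.seed,
        )


def _node_label(i: int, n_nodes: int) -> str:
    width = max(4, len(str(n_nodes)))
    return f"G{i + 1:0{width}d}"


def generate_network(n_nodes: int, edges_per_node: int, seed: int) -> nx.Graph:
    """Scale-free undirected graph via preferential attachment.

    Guarantees a connected simple graph (no self-loops, no parallel edges)
    with a heavy-tailed degree distribution.  Node identifiers are strings
    like ``"G0001"``.
    """
    if edges_per_node < 1:
        raise ValueError("edges_per_node must be >= 1")
    if n_nodes <= edges_per_node:
        raise ValueError(
            f"n_nodes ({n_nodes}) must exceed edges_per_node ({edges_per_node})"
        )
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=seed)
    mapping = {i: _node_label(i, n_nodes) for i in g.nodes}
    return nx.relabel_nodes(g, mapping)


def generate_pathways(
    universe,
    n_pathways: int,
    size_min: int,
    size_max: int,
    overlap_fraction: float,
    seed: int,
):
    """Generate named gene sets with designed overlap between consecutive pairs.

    Each consecutive pathway pair shares ``ceil(overlap_fraction * size_min)``
    members, so Jaccard-weighted crosstalk edges exist by construction.  The
    returned truth records the designed shared members per pair under
    ``generator_params['designed_overlaps']``.
    """
    from .containers import Pathway, PathwayCollection

    universe = sorted(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if size_min < 2:
        raise ValueError("size_min must be >= 2")
    if size_min > size_max:
        raise ValueError("size_min must not exceed size_max")
    if size_max > len(universe):
        raise ValueError("size_max exceeds universe size")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_shared = math.ceil(overlap_fraction * size_min)
    pathways = []
    designed: dict[str, list[str]] = {}
    prev_members: list[str] = []
    for i in range(n_pathways):
        name = f"PW{i + 1:03d}"
        size = int(rng.integers(size_min, size_max + 1))
        if i > 0 and n_shared > 0:
            idx = rng.choice(len(prev_members), size=n_shared, replace=False)
            shared = sorted(prev_members[j] for j in idx)
        else:
            shared = []
        pool = [g for g in universe if g not in shared]
        idx = rng.choice(len(pool), size=size - len(shared), replace=False)
        members = set(shared) | {pool[j] for j in idx}
        pathways.append(Pathway(name=name, source="synthetic", members=frozenset(members)))
        if i > 0:
            designed[f"PW{i:03d}|{name}"] = shared
        prev_members = sorted(members)

    truth = SyntheticTruth(
        generator_params={
            "n_pathways": n_pathways,
            "size_min": size_min,
            "size_max": size_max,
            "overlap_fraction": overlap_fraction,
            "designed_overlaps": designed,
        },
        seed=seed,
    )
    return PathwayCollection(pathways), truth


def generate_abundance(
    n_proteins: int,
    donors: int,
    conditions,
    planted_fraction: float,
    effect_log2fc: float,
    noise_sd: float,
    batch_sd: float,
    seed: int,
    *,
    enriched_condition: str | None = None,
    donor_sd: float = 0.0,
    n_batches: int = 2,
    baseline_mean: float = 20.0,
    baseline_sd: float = 2.0,
    protein_ids=None,
    planted_ids=None,
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Simulate a multi-condition, multi-donor protein abundance matrix.

    Log2 intensities are built additively: protein baseline ~ N(baseline_mean,
    baseline_sd), plus ``effect_log2fc`` for planted proteins in the enriched
    condition (last condition label by default), plus a donor intercept
    ~ N(0, donor_sd), a batch offset ~ N(0, batch_sd) shared by all samples
    processed in a batch, and sample noise ~ N(0, noise_sd).  Intensities are
    2**log2, so the matrix is log-normal on the linear scale.  Unique-peptide
    counts are uniform on {1..10}.
    """
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    if donors < 3:
        raise ValueError("need at least 3 donors")
    if noise_sd < 0 or batch_sd < 0 or donor_sd < 0:
        raise ValueError("standard deviations must be non-negative")

    if protein_ids is None:
        protein_ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    else:
        protein_ids = list(protein_ids)
        if len(protein_ids) != n_proteins:
            raise ValueError("protein_ids length must equal n_proteins")

    n_planted = math.floor(planted_fraction * n_proteins)
    if planted_ids is None:
        if n_planted < 1:
            raise ValueError("planted_fraction * n_proteins must be >= 1")
    else:
        planted_ids = set(planted_ids)
        if not planted_ids <= set(protein_ids):
            raise ValueError("planted_ids must be a subset of protein_ids")

    if enriched_condition is None:
        enriched_condition = conditions[-1]
    if enriched_condition not in conditions:
        raise ValueError(f"enriched_condition {enriched_condition!r} not in conditions")

    rng = np.random.default_rng(seed)
    if planted_ids is None:
        idx = rng.choice(n_proteins, size=n_planted, replace=False)
        planted_ids = {protein_ids[i] for i in sorted(idx)}

    donor_labels = [f"D{j + 1:02d}" for j in range(donors)]
    sample_ids = [f"{d}_{c}" for d in donor_labels for c in conditions]

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    donor_eff = rng.normal(0.0, donor_sd, size=donors) if donor_sd > 0 else np.zeros(donors)
    batch_of_donor = [f"B{(j % n_batches) + 1}" for j in range(donors)]
    batch_labels = sorted(set(batch_of_donor))
    batch_eff = dict(
        zip(batch_labels, rng.normal(0.0, batch_sd, size=len(batch_labels))
            if batch_sd > 0 else np.zeros(len(batch_labels)))
    )
    noise = rng.normal(0.0, noise_sd, size=(n_proteins, len(sample_ids))) \
        if noise_sd > 0 else np.zeros((n_proteins, len(sample_ids)))
    peptide_counts = rng.integers(1, 11, size=n_proteins)

    planted_mask = np.array([p in planted_ids for p in protein_ids])
    log2 = np.empty((n_proteins, len(sample_ids)))
    col = 0
    for j, d in enumerate(donor_labels):
        for c in conditions:
            effect = np.where(planted_mask & (c == enriched_condition), effect_log2fc, 0.0)
            log2[:, col] = (
                baseline + effect + donor_eff[j] + batch_eff[batch_of_donor[j]] + noise[:, col]
            )
            col += 1

    intensities = pd.DataFrame(2.0 ** log2, index=protein_ids, columns=sample_ids)
    sample_meta = pd.DataFrame(
        {
            "donor": [d for d in donor_labels for _ in conditions],
            "condition": [c for _ in donor_labels for c in conditions],
            "batch": [batch_of_donor[j] for j in range(donors) for _ in conditions],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    unique_peptides = pd.Series(peptide_counts, index=protein_ids, name="unique_peptides")

    truth = SyntheticTruth(
        planted_enriched_ids=set(planted_ids),
        effect_log2fc=effect_log2fc,
        generator_params={
            "n_proteins": n_proteins,
            "donors": donors,
            "conditions": conditions,
            "planted_fraction": planted_fraction,
            "noise_sd": noise_sd,
            "batch_sd": batch_sd,
            "donor_sd": donor_sd,
            "enriched_condition": enriched_condition,
            "n_batches": n_batches,
        },
        seed=seed,
    )
    return AbundanceMatrix(intensities, sample_meta, unique_peptides), truth


def plant_proximal_sets(
    network: nx.Graph,
    source_size: int,
    target_size: int,
    radius: int,
    seed: int,
    max_retries: int = 50,
):
    """Plant disjoint source/target sets with every source within ``radius``
    edges of at least one target.

    With ``radius == 0`` the sources are a subset of the targets (closest
    distance exactly 0).  Fails if the graph cannot host the geometry after
    ``max_retries`` re-drawn target sets.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    nodes = sorted(network.nodes)
    if source_size + target_size > len(nodes) and radius >= 1:
        raise ValueError("source_size + target_size exceeds node count")
    rng = np.random.default_rng(seed)

    if radius == 0:
        if source_size > target_size:
            raise ValueError("radius=0 requires source_size <= target_size")
        t_idx = rng.choice(len(nodes), size=target_size, replace=False)
        target = sorted(nodes[i] for i in t_idx)
        s_idx = rng.choice(target_size, size=source_size, replace=False)
        source = {target[i] for i in s_idx}
        target = set(target)
    else:
        for _ in range(max_retries):
            t_idx = rng.choice(len(nodes), size=target_size, replace=False)
            target = {nodes[i] for i in t_idx}
            # nodes at distance 1..radius from the target set
            dist = {t: 0 for t in target}
            frontier = sorted(target)
            candidates: list[str] = []
            for d in range(1, radius + 1):
                nxt = []
                for u in frontier:
                    for v in network[u]:
                        if v not in dist:
                            dist[v] = d
                            nxt.append(v)
                candidates.extend(nxt)
                frontier = nxt
            candidates = sorted(candidates)
            if len(candidates) >= source_size:
                s_idx = rng.choice(len(candidates), size=source_size, replace=False)
                source = {candidates[i] for i in s_idx}
                break
        else:
            raise ValueError(
                f"could not place {source_size} sources within radius {radius} "
                f"of {target_size} targets after {max_retries} attempts"
            )

    truth = SyntheticTruth(
        planted_source_set=set(source),
        planted_target_set=set(target),
        planted_radius=radius,
        generator_params={
            "source_size": source_size,
            "target_size": target_size,
            "radius": radius,
        },
        seed=seed,
    )
    return set(source), set(target), truth
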