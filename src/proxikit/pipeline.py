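"""End-to-end orchestration: simulate → quantify → differential → enrich →
pathway graph → proximity, from a single declarative config.

Every stage writes plain-text artifacts into the run directory and the run
finishes with a ``manifest.json`` listing each artifact with its SHA-256
hash, per-stage counts, the seed and the package version.  The manifest
contains no timestamps, so an identical config and seed reproduce the run
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from .containers import AbundanceMatrix
from .differential import attach_fold_changes, call_enriched, multigroup_test
from .enrichment import build_pathway_graph, detect_modules, enrich_pathways
from .io import write_gene_list, write_gmt, write_network
from .proximity import proximity_test
from .quant import filter_by_unique_peptides, sum_normalize
from .synthetic_data import (
    SyntheticTruth,
    generate_abundance,
    generate_network,
    generate_pathways,
    plant_proximal_sets,
)

STAGES = ("simulate", "quantify", "differential", "enrich", "pathway_graph", "proximity")

DEFAULT_SIMULATE = {
    "n_nodes": 500,
    "edges_per_node": 3,
    "donors": 9,
    "conditions": ["NF", "F", "C"],
    "planted_fraction": 0.1,
    "effect_log2fc": 1.5,
    "noise_sd": 0.3,
    "batch_sd": 0.1,
    "donor_sd": 0.0,
    "n_pathways": 12,
    "size_min": 10,
    "size_max": 25,
    "overlap_fraction": 0.3,
    "source_size": 15,
    "target_size": 15,
    "radius": 1,
}

DEFAULT_THRESHOLDS = {
    "min_unique": 2,
    "q_max": 0.1,
    "fc_min": 1.0,
    "p_max": 0.05,
    "j_min": 0.1,
    "n_randomizations": 200,
}

_THRESHOLD_RANGES = {
    "min_unique": (1, 100),
    "q_max": (0.0, 1.0),
    "fc_min": (0.0, float("inf")),
    "p_max": (0.0, 1.0),
    "j_min": (0.0, 1.0),
    "n_randomizations": (1, 10**6),
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative run configuration (thresholds, simulation params, seed)."""

    seed: int = 0
    outdir: str = "proxikit_run"
    method: str = "auto"
    batch_covariate: bool = True
    simulate: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.simulate = {**DEFAULT_SIMULATE, **(self.simulate or {})}
        self.thresholds = {**DEFAULT_THRESHOLDS, **(self.thresholds or {})}
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold(s): {sorted(unknown)}")
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            v = self.thresholds[key]
            if not lo <= v <= hi:
                raise ValueError(f"threshold {key}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "outdir": self.outdir,
            "method": self.method,
            "batch_covariate": self.batch_covariate,
            "simulate": self.simulate,
            "thresholds": self.thresholds,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_study(config: RunConfig):
    """Generate a coherent synthetic study: a scale-free network whose nodes
    are the quantified proteins, pathway sets over those nodes (the first one
    planted as the enriched-source set), planted proximal source/target
    geometry, and an abundance matrix whose planted enriched proteins include
    the planted pathway's members.
    """
    import numpy as np

    from .containers import Pathway, PathwayCollection

    p = config.simulate
    seed = config.seed
    network = generate_network(p["n_nodes"], p["edges_per_node"], seed)
    nodes = sorted(network.nodes)

    source, target, prox_truth = plant_proximal_sets(
        network, p["source_size"], p["target_size"], p["radius"], seed + 1
    )
    collection, pw_truth = generate_pathways(
        nodes, p["n_pathways"], p["size_min"], p["size_max"],
        p["overlap_fraction"], seed + 2,
    )
    planted_pw = Pathway(name="PW_PLANTED", source="synthetic",
                         members=frozenset(source))
    collection = PathwayCollection([planted_pw, *collection.pathways])

    n_planted = int(p["planted_fraction"] * p["n_nodes"])
    rng = np.random.default_rng(seed + 3)
    pool = [g for g in nodes if g not in source]
    extra = max(0, n_planted - len(source))
    idx = rng.choice(len(pool), size=extra, replace=False)
    planted_ids = set(source) | {pool[i] for i in idx}

    matrix, ab_truth = generate_abundance(
        n_proteins=p["n_nodes"],
        donors=p["donors"],
        conditions=p["conditions"],
        planted_fraction=p["planted_fraction"],
        effect_log2fc=p["effect_log2fc"],
        noise_sd=p["noise_sd"],
        batch_sd=p["batch_sd"],
        seed=seed + 4,
        donor_sd=p["donor_sd"],
        protein_ids=nodes,
        planted_ids=planted_ids,
    )
    truth = ab_truth.merged(prox_truth).merged(pw_truth)
    truth.seed = seed
    return network, collection, matrix, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "method": config.method,
            "batch_covariate": config.batch_covariate,
            "simulate": config.simulate,
            "thresholds": thr,
        },
        "stages": {},
    }

    def record(stage: str, files: dict, counts: dict, status: str = "ok") -> None:
        # paths are stored relative to the run directory so that identical
        # config+seed reruns are byte-identical wherever they land
        manifest["stages"][stage] = {
            "status": status,
            "files": {
                label: {
                    "path": str(Path(p).relative_to(outdir)),
                    "sha256": _sha256(p),
                }
                for label, p in files.items()
            },
            "counts": counts,
        }

    def skip(stage: str, reason: str) -> None:
        manifest["stages"][stage] = {"status": f"skipped: {reason}",
                                     "files": {}, "counts": {}}

    # -- simulate ---------------------------------------------------------
    try:
        network, collection, matrix, truth = simulate_study(config)
        files = {}
        net_path = outdir / "network.tsv"
        write_network(network, net_path)
        files["network"] = net_path
        gmt_path = outdir / "pathways.gmt"
        write_gmt(collection, gmt_path)
        files["pathways"] = gmt_path
        files.update({f"abundance_{k}": v for k, v in matrix.to_dir(outdir / "abundance").items()})
        truth_path = outdir / "truth.json"
        truth.to_json(truth_path)
        files["truth"] = truth_path
        tgt_path = outdir / "targets.txt"
        write_gene_list(truth.planted_target_set, tgt_path)
        files["targets"] = tgt_path
        record("simulate", files, {
            "n_nodes": network.number_of_nodes(),
            "n_edges": network.number_of_edges(),
            "n_pathways": len(collection),
            "n_proteins": len(matrix.protein_ids),
            "n_planted": len(truth.planted_enriched_ids),
        })
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc

    # -- quantify ---------------------------------------------------------
    try:
        filtered = filter_by_unique_peptides(matrix, thr["min_unique"])
        normalized = sum_normalize(filtered, scope="per_sample")
        files = {f"quantified_{k}": v
                 for k, v in normalized.to_dir(outdir / "quantified").items()}
        record("quantify", files, {
            "proteins_in": len(matrix.protein_ids),
            "proteins_retained": len(normalized.protein_ids),
            "min_unique": thr["min_unique"],
        })
    except Exception as exc:  # noqa: BLE001
        raise StageError("quantify", str(exc)) from exc

    # -- differential -----------------------------------------------------
    try:
        result = multigroup_test(normalized, method=config.method,
                                 batch_covariate=config.batch_covariate)
        reference = normalized.conditions[0]
        attach_fold_changes(result, normalized, reference)
        comparisons = [(c, reference) for c in normalized.conditions if c != reference]
        call = call_enriched(result, thr["q_max"], thr["fc_min"], comparisons)
        diff_path = outdir / "differential.tsv"
        result.to_tsv(diff_path)
        enriched_path = outdir / "enriched_proteins.txt"
        write_gene_list(call.genes, enriched_path)
        record("differential", {"differential": diff_path, "enriched": enriched_path}, {
            "n_tested": len(result.table),
            "n_enriched": len(call.genes),
            "reference": reference,
            "q_max": thr["q_max"],
            "fc_min": thr["fc_min"],
        })
    except Exception as exc:  # noqa: BLE001
        raise StageError("differential", str(exc)) from exc

    detected = set(normalized.protein_ids)
    if not call.genes:
        record("enrich", {}, {}, status="error: empty query (no enriched proteins)")
        skip("pathway_graph", "no enriched proteins")
        skip("proximity", "no enriched proteins")
        return _finish(manifest, outdir)

    # -- enrich -----------------------------------------------------------
    try:
        universe = collection.universe() & detected
        enr = enrich_pathways(call.genes, collection, universe, p_max=thr["p_max"])
        enr_path = outdir / "enrichment.tsv"
        enr.to_tsv(enr_path)
        record("enrich", {"enrichment": enr_path}, {
            "n_pathways_tested": len(enr.table),
            "n_significant": len(enr.significant_pathways),
            "universe_size": len(universe),
            "query_size": len(enr.query),
        })
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", str(exc)) from exc

    # -- pathway graph ----------------------------------------------------
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            graph = build_pathway_graph(enr, collection, detected, j_min=thr["j_min"])
        modules = detect_modules(graph)
        edges_path = outdir / "pathway_edges.tsv"
        with open(edges_path, "w") as fh:
            fh.write("pathway_A\tpathway_B\tjaccard\n")
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
                fh.write(f"{a}\t{b}\t{graph[a][b]['weight']:.17g}\n")
        nodes_path = outdir / "pathway_nodes.tsv"
        with open(nodes_path, "w") as fh:
            fh.write("pathway\tmodule\tsize\tp_value\tq_value\n")
            for v in sorted(graph.nodes):
                d = graph.nodes[v]
                fh.write(f"{v}\t{modules.get(v, '')}\t{d['size']}\t"
                         f"{d['p_value']:.17g}\t{d['q_value']:.17g}\n")
        gml_path = outdir / "pathway_graph.graphml"
        export = nx.Graph()
        for v in graph.nodes:
            d = graph.nodes[v]
            export.add_node(v, size=d["size"], p_value=d["p_value"],
                            q_value=d["q_value"], module=modules.get(v, ""),
                            detected_members=";".join(d["detected_members"]))
        for a, b in graph.edges:
            export.add_edge(a, b, weight=graph[a][b]["weight"])
        nx.write_graphml(export, gml_path)
        record("pathway_graph",
               {"edges": edges_path, "nodes": nodes_path, "graphml": gml_path}, {
                   "n_nodes": graph.number_of_nodes(),
                   "n_edges": graph.number_of_edges(),
                   "n_modules": len(set(modules.values())),
                   "j_min": thr["j_min"],
               })
    except Exception as exc:  # noqa: BLE001
        raise StageError("pathway_graph", str(exc)) from exc

    # -- proximity --------------------------------------------------------
    if not enr.significant_pathways:
        skip("proximity", "no significant pathway to use as source set")
        return _finish(manifest, outdir)
    try:
        top = enr.table["p_value"].idxmin()
        source = set(collection[top].members) & detected
        result = proximity_test(
            network, source, truth.planted_target_set,
            n_randomizations=thr["n_randomizations"],
            seed=config.seed + 5, randomize="S",
        )
        prox_path = outdir / "proximity.json"
        null_path = outdir / "proximity_null.tsv"
        result.to_json(prox_path, null_path=null_path)
        record("proximity", {"proximity": prox_path, "null": null_path}, {
            "source_pathway": top,
            "observed_dc": result.observed_dc,
            "empirical_p": result.empirical_p,
            "n_randomizations": result.n_randomizations,
        })
    except Exception as exc:  # noqa: BLE001
        raise StageError("proximity", str(exc)) from exc

    return _finish(manifest, outdir)


def _finish(manifest: dict, outdir: Path) -> dict:
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
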