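"""Plain-text I/O: GMT pathway collections, edge lists, gene lists.

All formats are tab-separated text so that artifacts diff cleanly and
round-trip bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .containers import Pathway, PathwayCollection

# Tokens that mark a header row in a two-column edge list.
_HEADER_TOKENS = {
    "source", "target", "from", "to", "node1", "node2", "nodea", "nodeb",
    "protein1", "protein2", "proteina", "proteinb", "gene1", "gene2",
    "genea", "geneb", "interactor_a", "interactor_b",
}


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file: name <tab> description <tab> member... per line."""
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 f"description and at least one member")
            name, source, *members = fields
            members = [m for m in members if m]
            pathways.append(Pathway(name=name, source=source, members=frozenset(members)))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, p.source, *sorted(p.members)]) + "\n")


def read_network(path) -> nx.Graph:
    """Load an undirected PPI network from a two-column edge list.

    Whitespace/tab separated, optional header, extra columns ignored.
    Self-loops are dropped and duplicate edges collapsed; the counts are
    recorded in ``graph.graph['self_loops_dropped']`` and
    ``graph.graph['duplicates_collapsed']``.
    """
    path = Path(path)
    graph = nx.Graph()
    self_loops = 0
    duplicates = 0
    n_data_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, "
                                 f"got {len(fields)}")
            a, b = fields[0], fields[1]
            if n_data_lines == 0 and {a.lower(), b.lower()} <= _HEADER_TOKENS:
                n_data_lines += 1  # header row
                continue
            n_data_lines += 1
            if a == b:
                self_loops += 1
                continue
            if graph.has_edge(a, b):
                duplicates += 1
                continue
            graph.add_edge(a, b)
    if graph.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges found")
    graph.graph["self_loops_dropped"] = self_loops
    graph.graph["duplicates_collapsed"] = duplicates
    return graph


def write_network(graph: nx.Graph, path) -> None:
    """Write an edge list with a header, edges in sorted order for determinism."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines and '#' comments skipped."""
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
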