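"""Organism→feature networks and Cytoscape-compatible exports.

Two directed bipartite networks summarize a record set, both with
organisms as sources (rendered as diamonds by convention) and features as
targets (circles):

* **compound mode** — one edge per gene cluster to its most similar known
  compound, weighted by the percentage of homologous genes; clusters with
  no known match all point at a single ``unknown`` node (weight 0), whose
  size in a rendering reflects the unexplored fraction of the dataset.
* **pop mode** — one edge per organism→pair, weighted by how often the
  organism's clusters emit that pair.

Graphs are :class:`networkx.MultiDiGraph` so parallel cluster→compound
edges are preserved; node degree (direction-blind incident edge count) is
stored as a node attribute and drives subsetting.  Exports are SIF and
GraphML plus a node-attribute sidecar TSV; layout is left to the viewer.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx

from .exceptions import ConfigError
from .ingest import RecordSet, pops_for

SHAPE_ORGANISM = "diamond"
SHAPE_FEATURE = "circle"

UNKNOWN_NODE = "unknown"

RELATION_COMPOUND = "homolog_of"
RELATION_POP = "has_pop"

NETWORK_MODES = ("compound", "pop")
FORMATS = ("sif", "graphml")


def _set_degrees(g: nx.MultiDiGraph, freeze: bool = False) -> None:
    # "degree" always reflects the current graph; "degree_full", frozen at
    # build time, is what degree filtering thresholds on, so subsetting a
    # subset at the same threshold changes nothing.
    for node, deg in g.degree():
        g.nodes[node]["degree"] = int(deg)
        if freeze:
            g.nodes[node]["degree_full"] = int(deg)


def build_network(
    rs: RecordSet,
    mode: str = "compound",
    policy: str = "strict",
    n_gram_size: int = 2,
) -> nx.MultiDiGraph:
    """Build the organism→compound or organism→pair network from records."""
    if mode not in NETWORK_MODES:
        raise ConfigError(f"mode must be one of {NETWORK_MODES}, got {mode!r}")
    g = nx.MultiDiGraph(mode=mode)
    if mode == "compound":
        for r in rs.records:
            org = r.organism or r.genome_accession
            g.add_node(org, shape=SHAPE_ORGANISM)
            if r.known_match is not None:
                target = r.known_match.compound_name
                weight = float(r.known_match.identity_percent)
            else:
                target = UNKNOWN_NODE
                weight = 0.0
            g.add_node(target, shape=SHAPE_FEATURE)
            g.add_edge(
                org, target, relation=RELATION_COMPOUND, weight=weight, cluster_key=r.cluster_key
            )
    else:
        counts: dict[tuple[str, str], int] = {}
        order: list[tuple[str, str]] = []
        for r in rs.records:
            org = r.organism or r.genome_accession
            g.add_node(org, shape=SHAPE_ORGANISM)
            for key, n in pops_for(r, policy=policy, n_gram_size=n_gram_size).counts.items():
                if (org, key) not in counts:
                    counts[(org, key)] = 0
                    order.append((org, key))
                counts[(org, key)] += n
        for org, key in order:
            g.add_node(key, shape=SHAPE_FEATURE)
            g.add_edge(org, key, relation=RELATION_POP, weight=float(counts[(org, key)]))
    _set_degrees(g, freeze=True)
    return g


def filter_by_degree(
    n: nx.MultiDiGraph, min_edges: int = 5, keep_first_neighbors: bool = False
) -> nx.MultiDiGraph:
    """Subset to nodes with at least ``min_edges`` incident edges (inclusive).

    With ``keep_first_neighbors`` the direct neighbors of every retained
    node are kept as well, so a high-degree hub keeps its periphery.
    The threshold applies to each node's degree in the originally built
    network (``degree_full``); the ``degree`` attribute of the returned
    subgraph is recomputed.  At a fixed threshold without neighbor
    expansion the operation is therefore idempotent.
    """
    if min_edges < 0:
        raise ConfigError(f"min_edges must be >= 0, got {min_edges}")
    kept = {
        node
        for node, deg in n.degree()
        if n.nodes[node].get("degree_full", deg) >= min_edges
    }
    if keep_first_neighbors:
        neighbors = set()
        for node in kept:
            neighbors |= set(n.successors(node)) | set(n.predecessors(node))
        kept |= neighbors
    sub = n.subgraph(kept).copy()
    _set_degrees(sub)
    return sub


def _ordered_copy(g: nx.MultiDiGraph) -> nx.MultiDiGraph:
    out = nx.MultiDiGraph(**g.graph)
    for node in sorted(g.nodes):
        out.add_node(node, **g.nodes[node])
    for u, v, data in sorted(
        g.edges(data=True), key=lambda e: (e[0], e[1], sorted(e[2].items()))
    ):
        out.add_edge(u, v, **data)
    return out


def write_network(n: nx.MultiDiGraph, path, format: str = "sif") -> None:
    """Write SIF (source, relation, target — one line per edge) or GraphML.

    Nodes and edges are emitted in sorted order so output bytes are
    deterministic for a given network.
    """
    if format not in FORMATS:
        raise ConfigError(f"format must be one of {FORMATS}, got {format!r}")
    if format == "sif":
        lines = sorted(
            f"{u}\t{data.get('relation', 'linked_to')}\t{v}"
            for u, v, data in n.edges(data=True)
        )
        with open(path, "w", encoding="utf-8") as fh:
            for line in lines:
                fh.write(line + "\n")
    else:
        nx.write_graphml(_ordered_copy(n), path, named_key_ids=True)


def read_network_graphml(path) -> nx.MultiDiGraph:
    return nx.read_graphml(path, force_multigraph=True)


def write_node_attributes(n: nx.MultiDiGraph, path) -> None:
    """Sidecar TSV (id, shape, degree) for renderers without GraphML support."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tshape\tdegree\n")
        for node in sorted(n.nodes):
            data = n.nodes[node]
            fh.write(f"{node}\t{data.get('shape', '')}\t{data.get('degree', 0)}\n")
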