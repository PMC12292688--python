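"""Protein–protein interaction graph construction and export.

Edges come in as STRING-style TSV (``protein1``, ``protein2``,
``combined_score`` on the 0–1000 integer scale; 400 ⇔ confidence 0.400).
The graph is an undirected simple :class:`networkx.Graph`; the combined
score is kept as edge metadata only — all centrality math downstream is
unweighted. Provenance (threshold, source path) lives in ``G.graph``.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from netpharm.errors import ParseError, ParameterError

logger = logging.getLogger(__name__)

InteractionEdge = namedtuple("InteractionEdge", ["a", "b", "combined_score"])

EDGE_COLUMNS = ("protein1", "protein2", "combined_score")


def read_string_edges(path: str | Path) -> list[InteractionEdge]:
    """Read a STRING-format edge TSV into deduplicated undirected edges.

    Self-loops are dropped (count logged); duplicate unordered pairs are
    collapsed keeping the maximum combined score.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    for column in EDGE_COLUMNS:
        if column not in table.columns:
            raise ParseError(f"{path}: missing column {column!r}")

    edges: dict[tuple[str, str], int] = {}
    self_loops = 0
    for i, row in enumerate(table.itertuples(index=False), start=2):
        a = str(row.protein1).strip().upper()
        b = str(row.protein2).strip().upper()
        raw = str(row.combined_score).strip()
        try:
            score = int(raw)
        except ValueError:
            raise ParseError(
                f"{path}: line {i}: combined_score {raw!r} is not an integer"
            ) from None
        if a == b:
            self_loops += 1
            continue
        key = (a, b) if a <= b else (b, a)
        edges[key] = max(score, edges.get(key, score))
    if self_loops:
        logger.info("%s: dropped %d self-loop rows", path, self_loops)
    return [InteractionEdge(a, b, s) for (a, b), s in sorted(edges.items())]


def build_graph(
    edges: Sequence[InteractionEdge],
    gene_list: Iterable[str],
    threshold: float = 0.400,
    *,
    keep_isolates: bool = False,
    lcc_only: bool = False,
    source: str | None = None,
) -> nx.Graph:
    """Build the PPI graph from scored edges restricted to a gene list.

    Keeps edges with ``combined_score >= round(1000 * threshold)`` (the
    inclusive STRING convention) and both endpoints in ``gene_list``.
    Isolated in-list genes are excluded unless ``keep_isolates``; with
    ``lcc_only`` only the largest connected component is retained.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"confidence threshold {threshold} outside [0, 1]")
    gene_list = frozenset(gene_list)
    cutoff = round(1000 * threshold)

    g = nx.Graph(
        confidence_threshold=threshold,
        score_cutoff=cutoff,
        source=str(source) if source else None,
    )
    if keep_isolates:
        g.add_nodes_from(sorted(gene_list))
    for a, b, score in edges:
        if score >= cutoff and a in gene_list and b in gene_list:
            if g.has_edge(a, b):
                score = max(score, g.edges[a, b]["combined_score"])
            g.add_edge(a, b, combined_score=score)
    if g.number_of_edges() == 0:
        logger.warning(
            "no edges survive threshold %.3f over %d genes", threshold, len(gene_list)
        )
    if lcc_only and g.number_of_nodes():
        largest = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
        g = g.subgraph(largest).copy()
    return g


def graph_edges(g: nx.Graph) -> list[InteractionEdge]:
    """Graph edges as sorted, canonically ordered InteractionEdge tuples."""
    out = []
    for a, b, data in g.edges(data=True):
        if b < a:
            a, b = b, a
        out.append(InteractionEdge(a, b, data.get("combined_score", 0)))
    return sorted(out)


def export_graph(g: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Export the graph for external viewers (Cytoscape-loadable).

    ``graphml`` writes GraphML; ``edge-tsv`` writes the three-column STRING
    layout, which round-trips through :func:`read_string_edges`.
    """
    path = Path(path)
    if g.number_of_nodes() == 0:
        raise ParameterError(
            "refusing to export an empty graph; review the confidence threshold"
        )
    if fmt == "graphml":
        export = nx.Graph()
        export.add_nodes_from(g.nodes())
        export.add_edges_from(g.edges(data=True))
        nx.write_graphml(export, path)
    elif fmt == "edge-tsv":
        frame = pd.DataFrame(graph_edges(g), columns=list(EDGE_COLUMNS))
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ParameterError(f"unknown export format {fmt!r}; use graphml or edge-tsv")
    return path
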