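"""Thresholded protein–protein interaction graph and topology statistics.

Edges carry a STRING-style combined confidence score in [0, 1]; building the
network keeps edges with score >= 0.700 (inclusive), collapses duplicate
undirected pairs to their maximum score, and drops self-loops.  The graph is
treated as unweighted afterwards; the score survives only as edge metadata.
Reported statistics: average node degree 2E/N, network-average local
clustering coefficient, and the degree-ranked hub list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

COMBINED_SCORE_THRESHOLD = 0.700


@dataclass
class InteractionNetwork:
    """Simple undirected graph with the threshold that produced it."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_edge_tsv(path: str | Path) -> pd.DataFrame:
    """Read a STRING-export-style TSV (two id columns + combined_score)."""
    path = Path(path)
    rows = []
    lines = path.read_text().splitlines()
    start = 0
    if lines and not _is_edge_row(lines[0]):
        start = 1  # tolerate a header line
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{lineno}: expected 3 tab-separated fields")
        try:
            score = float(parts[2])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: bad combined_score {parts[2]!r}") from exc
        rows.append((parts[0], parts[1], score))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])


def _is_edge_row(line: str) -> bool:
    parts = line.split("\t")
    if len(parts) < 3:
        return False
    try:
        float(parts[2])
    except ValueError:
        return False
    return True


def build_network(edge_list, min_combined: float = COMBINED_SCORE_THRESHOLD,
                  isolated_nodes=()) -> InteractionNetwork:
    """Build the thresholded simple graph from an edge table.

    ``edge_list`` is a DataFrame with columns (node_a, node_b,
    combined_score) or an iterable of such triples.  Edges with score >=
    ``min_combined`` are retained; duplicate unordered pairs keep the maximum
    score; self-loops are dropped with a warning.  ``isolated_nodes`` adds
    explicitly listed nodes even if no retained edge touches them.
    """
    if isinstance(edge_list, pd.DataFrame):
        triples = edge_list[["node_a", "node_b", "combined_score"]].itertuples(index=False)
    else:
        triples = edge_list
    g = nx.Graph()
    for a, b, score in triples:
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"combined_score {score} outside [0, 1] for edge ({a}, {b})")
        if a == b:
            logger.warning("dropping self-loop on node %s", a)
            continue
        if score < min_combined:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], score)
        else:
            g.add_edge(a, b, combined_score=score)
    g.add_nodes_from(isolated_nodes)
    return InteractionNetwork(graph=g, threshold=min_combined)


def average_degree(network: InteractionNetwork) -> float:
    """Average node degree, 2E/N."""
    if network.n_nodes == 0:
        raise ValidationError("average_degree undefined on an empty graph")
    return 2.0 * network.n_edges / network.n_nodes


def avg_clustering(network: InteractionNetwork, include_low_degree: bool = True) -> float:
    """Network-average local clustering coefficient.

    Nodes with degree < 2 contribute 0 when ``include_low_degree`` (the
    common network-average convention) and are excluded from the mean
    otherwise.
    """
    if network.n_nodes == 0:
        raise ValidationError("avg_clustering undefined on an empty graph")
    g = network.graph
    if include_low_degree:
        return float(nx.average_clustering(g, count_zeros=True))
    eligible = [v for v, d in g.degree() if d >= 2]
    if not eligible:
        raise ValidationError("no node has degree >= 2; exclusion-mean undefined")
    local = nx.clustering(g, eligible)
    return float(sum(local.values()) / len(eligible))


def hub_rank(network: InteractionNetwork, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by degree (descending), ties broken by node id ascending."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    degrees = sorted(network.graph.degree(), key=lambda item: (-item[1], str(item[0])))
    if k > len(degrees):
        logger.warning("k=%d exceeds the %d nodes; returning all", k, len(degrees))
        k = len(degrees)
    return degrees[:k]


def topology_report(network: InteractionNetwork) -> dict:
    """Topology summary written by the network stage."""
    return {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "threshold": network.threshold,
        "avg_degree": average_degree(network) if network.n_nodes else None,
        "avg_clustering": avg_clustering(network) if network.n_nodes else None,
        "degree_table": {str(v): int(d) for v, d in
                         sorted(network.graph.degree(), key=lambda it: (-it[1], str(it[0])))},
    }
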