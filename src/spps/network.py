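"""Protein partner network: predicted hits merged with known PPIs.

After a Single Query run, the neighborhood of the query is assembled
into a simple undirected graph: predicted query-partner edges carry the
calibrated probability as weight, known interactions among the included
proteins carry weight 1.0, and nodes are tagged by role (query,
predicted partner, or known neighbor pulled in by ring expansion).
"""

from __future__ import annotations

from typing import Iterable, List

import networkx as nx
import pandas as pd

from .exceptions import UnknownProteinError, ValidationError
from .protein_db import ProteinDatabase
from .search import PartnerHit

ROLE_QUERY = "query"
ROLE_PREDICTED = "predicted_partner"
ROLE_KNOWN = "known_neighbor"

PROVENANCE_PREDICTED = "predicted"
PROVENANCE_KNOWN = "known"
PROVENANCE_BOTH = "known+predicted"

EDGE_COLUMNS = ["source", "target", "provenance", "weight"]
NODE_COLUMNS = ["node", "role"]


def build_network(
    query_id: str,
    hits: Iterable[PartnerHit],
    db: ProteinDatabase,
    depth: int = 1,
) -> nx.Graph:
    """Assemble the partner network around *query_id*.

    Nodes are the query, the hit partners, and ``depth`` expansion
    rings of known partners of already-included nodes (default one
    ring).  Edges are the predicted query-hit edges plus every known
    interaction among included nodes.  A predicted edge that is also
    known gets provenance ``known+predicted`` with the predicted
    weight retained.
    """
    if query_id not in db:
        raise UnknownProteinError(f"query id {query_id!r} not in database")
    if not 0 <= depth <= 2:
        raise ValidationError("expansion depth must be 0, 1 or 2")

    g = nx.Graph()
    g.add_node(query_id, role=ROLE_QUERY)
    hits = list(hits)
    for h in hits:
        if h.partner_id == query_id:
            continue
        g.add_node(h.partner_id, role=ROLE_PREDICTED)
        g.add_edge(query_id, h.partner_id,
                   provenance=PROVENANCE_PREDICTED, weight=h.probability)

    # ring expansion over known partners
    frontier = sorted(g.nodes)
    for _ in range(depth):
        ring = []
        for node in frontier:
            if node not in db:
                continue
            for partner in sorted(db.annotation(node).known_partners):
                if partner not in g and partner in db:
                    g.add_node(partner, role=ROLE_KNOWN)
                    ring.append(partner)
        frontier = ring

    # known edges among every included node
    for node in sorted(g.nodes):
        if node not in db:
            continue
        for partner in sorted(db.annotation(node).known_partners):
            if partner not in g or partner == node:
                continue
            if g.has_edge(node, partner):
                if g.edges[node, partner]["provenance"] == PROVENANCE_PREDICTED:
                    g.edges[node, partner]["provenance"] = PROVENANCE_BOTH
            else:
                g.add_edge(node, partner,
                           provenance=PROVENANCE_KNOWN, weight=1.0)
    return g


def _sorted_edge_rows(g: nx.Graph) -> List[dict]:
    rows = []
    for u, v, attrs in g.edges(data=True):
        a, b = sorted((u, v))
        rows.append({
            "source": a,
            "target": b,
            "provenance": attrs["provenance"],
            "weight": attrs["weight"],
        })
    rows.sort(key=lambda r: (r["source"], r["target"]))
    return rows


def export_graph(g: nx.Graph, path, format: str = "tsv") -> None:
    """Write the graph as an edge-list TSV or GraphML.

    The TSV has columns source, target, provenance, weight with
    deterministic (lexicographic) row order; GraphML carries the same
    node and edge attributes.  Both round-trip through
    :func:`import_graph`.
    """
    if format == "tsv":
        pd.DataFrame(_sorted_edge_rows(g), columns=EDGE_COLUMNS).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown graph export format {format!r}")


def export_node_table(g: nx.Graph, path) -> None:
    """Write the node table (node, role) as TSV in lexicographic order."""
    rows = [{"node": n, "role": attrs.get("role", "")}
            for n, attrs in sorted(g.nodes(data=True))]
    pd.DataFrame(rows, columns=NODE_COLUMNS).to_csv(path, sep="\t", index=False)


def import_graph(path, format: str = "tsv") -> nx.Graph:
    """Re-read a graph written by :func:`export_graph`.

    The TSV route restores edges and their attributes (isolated nodes
    are not represented in an edge list); the GraphML route restores
    the full graph.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target,
                       provenance=row.provenance, weight=float(row.weight))
        return g
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValidationError(f"unknown graph import format {format!r}")
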