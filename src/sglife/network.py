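"""Protein-protein interaction network over the classified SG proteome.

The graph unions physical interactions from a STRING-style links file
(combined score > 0.7, i.e. > 700 on STRING's 0-1000 scale) and a
BioPlex-style pairwise table, restricted to the classified node set
(early / late / invariable). Topology metrics follow the usual definitions:
raw degree, density 2E/(N(N-1)), average shortest path over connected pairs,
and Newman-Girvan modularity Q for a partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "build_graph",
    "network_metrics",
    "modularity",
    "greedy_communities",
]


@dataclass
class Partition:
    community_of_node: dict[object, int]
    q: float

    @property
    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for n, c in self.community_of_node.items():
            out.setdefault(c, set()).add(n)
        return [out[c] for c in sorted(out)]


def read_node_table(path: str | Path) -> dict[str, str]:
    """Node table TSV with columns ``node`` and ``group`` (early/late/invariable)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "node" not in df.columns or "group" not in df.columns:
        raise ValueError(f"node table {path} needs 'node' and 'group' columns")
    return dict(zip(df["node"].str.strip(), df["group"].str.strip()))


def build_graph(
    node_groups: Mapping[str, str] | str | Path,
    string_links: str | Path | None = None,
    bioplex: str | Path | None = None,
    score_threshold: float = 0.7,
) -> tuple[nx.Graph, dict[str, int]]:
    """Union STRING (score-thresholded) and BioPlex edges over classified nodes.

    STRING ``combined_score`` is on the 0-1000 scale; edges are kept when
    score/1000 strictly exceeds ``score_threshold``. Edges touching nodes
    outside the classified set are dropped (counted under ``skipped``).
    Returns the graph (nodes carry a ``group`` attribute, edges a ``sources``
    set) and a small report of node/edge/skip counts.
    """
    groups = node_groups if isinstance(node_groups, Mapping) else read_node_table(node_groups)
    g = nx.Graph()
    for node, grp in groups.items():
        g.add_node(node, group=grp)
    skipped = 0

    def add_edge(u: str, v: str, source: str) -> None:
        nonlocal skipped
        if u == v:
            return
        if u not in groups or v not in groups:
            skipped += 1
            return
        if g.has_edge(u, v):
            g[u][v]["sources"].add(source)
        else:
            g.add_edge(u, v, sources={source})

    if string_links is not None:
        df = pd.read_csv(string_links, sep=r"\s+", dtype={"protein1": str, "protein2": str})
        for col in ("protein1", "protein2", "combined_score"):
            if col not in df.columns:
                raise ValueError(f"STRING links file lacks column {col!r}")
        kept = df[df["combined_score"].astype(float) > score_threshold * 1000]
        for u, v in zip(kept["protein1"], kept["protein2"]):
            add_edge(u.strip(), v.strip(), "string")
    if bioplex is not None:
        df = pd.read_csv(bioplex, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("BioPlex table needs two gene-symbol columns")
        a_col, b_col = df.columns[:2]
        for u, v in zip(df[a_col], df[b_col]):
            add_edge(str(u).strip(), str(v).strip(), "bioplex")

    comps = sorted(nx.connected_components(g), key=len, reverse=True) if len(g) else []
    report = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "largest_component": len(comps[0]) if comps else 0,
        "skipped_edges": skipped,
    }
    return g, report


def network_metrics(g: nx.Graph, subset: Iterable | None = None) -> dict:
    """Degree per node, density, and average shortest path on a (sub)graph.

    The average shortest path is taken over connected node pairs only, so a
    disconnected subnetwork still gets a finite value.
    """
    sub = g.subgraph(set(subset)) if subset is not None else g
    n = sub.number_of_nodes()
    if n == 0:
        raise ValueError("empty node subset")
    degrees = dict(sub.degree())
    if n < 2:
        raise ValueError("density and path length need at least 2 nodes")
    density = 2.0 * sub.number_of_edges() / (n * (n - 1))
    total, pairs = 0.0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(sub):
        for d in lengths.values():
            if d > 0:
                total += d
                pairs += 1
    avg_path = total / pairs if pairs else float("nan")
    return {
        "degree": degrees,
        "density": density,
        "average_shortest_path": avg_path,
        "n_nodes": n,
        "n_edges": sub.number_of_edges(),
    }


def modularity(g: nx.Graph, partition: Mapping | Sequence[set]) -> float:
    """Newman-Girvan modularity Q = sum_c [ e_c/m - (d_c / 2m)^2 ].

    ``partition`` is either a node->community mapping or a list of node sets.
    Edgeless graphs get Q = 0 by convention.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if isinstance(partition, Mapping):
        com_of = dict(partition)
        com_sets: dict[object, set] = {}
        for node, c in com_of.items():
            com_sets.setdefault(c, set()).add(node)
        communities = list(com_sets.values())
    else:
        communities = [set(c) for c in partition]
        com_of = {n: i for i, c in enumerate(communities) for n in c}
    covered = set(com_of)
    if covered != set(g.nodes):
        raise ValueError("partition must cover all nodes exactly")
    if len(com_of) != sum(len(c) for c in communities):
        raise ValueError("communities must be disjoint")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    deg = dict(g.degree())
    for c in communities:
        e_c = sum(1 for u, v in g.edges(c) if u in c and v in c)
        d_c = sum(deg[n] for n in c)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def greedy_communities(g: nx.Graph, seed: int = 0) -> Partition:
    """Greedy (CNM-style) modularity maximization; deterministic for a given
    graph. Edgeless graphs return singleton communities with Q = 0."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        com = {n: i for i, n in enumerate(sorted(g.nodes, key=str))}
        return Partition(community_of_node=com, q=0.0)
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    com_of = {n: i for i, c in enumerate(comms) for n in c}
    return Partition(community_of_node=com_of, q=modularity(g, comms))
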