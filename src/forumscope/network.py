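"""Directed weighted interaction network and its structural metrics.

Users are nodes; an arc ``u -> v`` records that ``u`` commented in a thread
opened by ``v`` or replied addressing ``v``, with the arc weight counting
the number of such acts.  Efficiency, density and component structure are
computed on topology only (weights matter to community detection, not to
these metrics).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import networkx as nx
import pandas as pd

__all__ = [
    "build_interaction_network",
    "network_efficiency",
    "network_density",
    "weakly_connected_components",
    "degree_sequence",
    "read_edgelist",
    "write_edgelist",
]


def build_interaction_network(tables) -> nx.DiGraph:
    """Build the user-interaction graph from forum tables.

    Arc ``u -> v`` with weight = (#comments by ``u`` in threads opened by
    ``v``, excluding ``u``'s own thread-opening floor-1 comment) +
    (#replies by ``u`` addressed to ``v``).  Self-interactions are dropped.
    """
    graph = nx.DiGraph()
    comments = tables.comments
    openers = comments.loc[comments["floor"] == 1].set_index("post_id")["author_id"]

    followups = comments.loc[comments["floor"] > 1]
    post_author = followups["post_id"].map(openers)
    for (u, v), count in (
        pd.DataFrame({"u": followups["author_id"], "v": post_author}).dropna().groupby(["u", "v"]).size().items()
    ):
        _add_arc(graph, u, v, int(count))

    for (u, v), count in tables.replies.groupby(["author_id", "reply_to_whom"]).size().items():
        _add_arc(graph, u, v, int(count))
    return graph


def _add_arc(graph: nx.DiGraph, u: str, v: str, weight: int) -> None:
    if u == v:
        return
    if graph.has_edge(u, v):
        graph[u][v]["weight"] += weight
    else:
        graph.add_edge(u, v, weight=weight)


def network_efficiency(graph: nx.Graph) -> float:
    """Mean reciprocal shortest-path length over unordered node pairs.

    E = 2/(n(n-1)) * sum_{i<j} 1/d(i,j), with d the unweighted shortest-path
    length on the undirected projection; unreachable pairs contribute 0.
    A graph with fewer than two nodes has efficiency 0.
    """
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    undirected = graph.to_undirected(as_view=False)
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(undirected):
        total += sum(1.0 / d for d in lengths.values() if d > 0)
    # each unordered pair was visited from both ends
    return total / (n * (n - 1))


def network_density(graph: nx.DiGraph) -> float:
    """Distinct arcs divided by n(n-1) (directed convention); 0 when n < 2."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return graph.number_of_edges() / (n * (n - 1))


def weakly_connected_components(graph: nx.Graph) -> tuple[list[set], set]:
    """Partition nodes into weak-connectivity classes.

    Returns ``(components, largest)``.  Components are sorted by decreasing
    size with ties broken by the lexicographically smallest member, so the
    flagged largest component is deterministic.
    """
    if graph.is_directed():
        comps = [set(c) for c in nx.weakly_connected_components(graph)]
    else:
        comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(str(m) for m in c)))
    largest = comps[0] if comps else set()
    return comps, largest


def degree_sequence(
    graph: nx.DiGraph, mode: Literal["in", "out", "total"] = "total"
) -> tuple[dict, pd.DataFrame]:
    """Exact per-node degrees plus a degree -> node-count frequency table."""
    if mode == "in" and graph.is_directed():
        degrees = dict(graph.in_degree())
    elif mode == "out" and graph.is_directed():
        degrees = dict(graph.out_degree())
    elif mode == "total":
        degrees = dict(graph.degree())
    else:
        raise ValueError(f"unknown degree mode {mode!r}")
    counts = pd.Series(list(degrees.values()), dtype=int).value_counts().sort_index()
    table = counts.rename_axis("degree").reset_index(name="n_nodes")
    return degrees, table


def write_edgelist(graph: nx.DiGraph, path: str | Path) -> None:
    """Write arcs as lines ``source target weight``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u} {v} {data.get('weight', 1)}\n")


def read_edgelist(path: str | Path) -> nx.DiGraph:
    graph = nx.DiGraph()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        u, v, w = line.split()
        graph.add_edge(u, v, weight=int(w))
    return graph
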