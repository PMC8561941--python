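"""The tripartite lncRNA-miRNA-disease heterogeneous network (LMDN).

Nodes are namespaced by entity class — ``l:<name>``, ``m:<name>``,
``d:<name>`` — so a symbol naming both an lncRNA and a miRNA cannot collapse
into one node.  Edges are undirected and unweighted, one per unique
association; only cross-class edges (lncRNA-disease, lncRNA-miRNA,
miRNA-disease) can occur by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ContractError
from .io_data import AssociationTable

CLASS_PREFIX = {"lncRNA": "l", "miRNA": "m", "disease": "d"}
PREFIX_CLASS = {v: k for k, v in CLASS_PREFIX.items()}


def node_id(entity_class: str, name: str) -> str:
    try:
        return f"{CLASS_PREFIX[entity_class]}:{name}"
    except KeyError:
        raise ContractError(f"unknown entity class {entity_class!r}") from None


def node_class(nid: str) -> str:
    return PREFIX_CLASS[nid.split(":", 1)[0]]


def node_name(nid: str) -> str:
    return nid.split(":", 1)[1]


@dataclass(frozen=True)
class HeterogeneousGraph:
    """Undirected graph with sorted adjacency and integer node indexing.

    ``nodes`` is the sorted tuple of namespaced node ids; ``neighbors[i]`` is
    the sorted integer-index array of node i's neighbors.  The integer view
    keeps the second-order walk and alias-table machinery fast; the string
    view is the public interface.
    """

    nodes: tuple[str, ...]
    neighbors: tuple[np.ndarray, ...]

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def edge_count(self) -> int:
        return sum(len(a) for a in self.neighbors) // 2

    def adjacency(self, nid: str) -> tuple[str, ...]:
        """Sorted neighbor ids of a node."""
        i = self.index[nid]
        return tuple(self.nodes[j] for j in self.neighbors[i])

    def degree(self, nid: str) -> int:
        return len(self.neighbors[self.index[nid]])

    def has_edge(self, u: str, v: str) -> bool:
        idx = self.index
        i, j = idx[u], idx[v]
        pos = int(np.searchsorted(self.neighbors[i], j))
        return pos < len(self.neighbors[i]) and self.neighbors[i][pos] == j


def graph_from_edges(edges, extra_nodes=()) -> HeterogeneousGraph:
    """Generic undirected graph from an iterable of (u, v) id pairs.

    No class-pair checking is applied; use :func:`build_lmdn` for the
    tripartite network.  Intended for walk/embedding tests and ad-hoc graphs.
    """
    node_set: set[str] = set(extra_nodes)
    edge_set: set[tuple[str, str]] = set()
    for u, v in edges:
        if u == v:
            raise ContractError(f"self-loop at {u!r}")
        node_set.update((u, v))
        edge_set.add((u, v) if u < v else (v, u))
    return _graph_from_edges(node_set, edge_set)


def _graph_from_edges(node_set: set[str], edges: set[tuple[str, str]]) -> HeterogeneousGraph:
    nodes = tuple(sorted(node_set))
    idx = {n: i for i, n in enumerate(nodes)}
    adj: list[set[int]] = [set() for _ in nodes]
    for u, v in edges:
        adj[idx[u]].add(idx[v])
        adj[idx[v]].add(idx[u])
    neighbors = tuple(np.array(sorted(s), dtype=np.int64) for s in adj)
    return HeterogeneousGraph(nodes, neighbors)


def build_lmdn(
    lnc_dis: AssociationTable,
    lnc_mir: AssociationTable,
    mir_dis: AssociationTable,
) -> HeterogeneousGraph:
    """Union the three association tables into one tripartite graph."""
    expected = [("lncRNA", "disease"), ("lncRNA", "miRNA"), ("miRNA", "disease")]
    tables = [lnc_dis, lnc_mir, mir_dis]
    for table, (lt, rt) in zip(tables, expected):
        if (table.left_type, table.right_type) != (lt, rt):
            raise ContractError(
                f"expected a {lt}-{rt} table, got {table.left_type}-{table.right_type}"
            )
    node_set: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for table in tables:
        lp = CLASS_PREFIX[table.left_type]
        rp = CLASS_PREFIX[table.right_type]
        for left, right in table.pairs:
            u, v = f"{lp}:{left}", f"{rp}:{right}"
            node_set.update((u, v))
            edges.add((u, v) if u < v else (v, u))
    return _graph_from_edges(node_set, edges)


def degree_summary(graph: HeterogeneousGraph) -> dict:
    """Per-class node counts, edge counts by class pair, isolated nodes."""
    node_counts = {c: 0 for c in CLASS_PREFIX}
    pair_counts = {"ld": 0, "lm": 0, "md": 0}
    isolated: list[str] = []
    idx = graph.index
    for nid in graph.nodes:
        node_counts[node_class(nid)] += 1
        if len(graph.neighbors[idx[nid]]) == 0:
            isolated.append(nid)
    for i, nid in enumerate(graph.nodes):
        pi = nid[0]
        for j in graph.neighbors[i]:
            if i < j:
                key = "".join(sorted((pi, graph.nodes[j][0])))
                pair_counts[{"dl": "ld", "lm": "lm", "dm": "md"}[key]] += 1
    return {
        "nodes_by_class": node_counts,
        "edges_by_class_pair": pair_counts,
        "edge_count": graph.edge_count,
        "isolated_nodes": isolated,
    }


def write_graph_tsv(graph: HeterogeneousGraph, path: str | Path) -> None:
    """Edge list with a class-pair column; lossless round trip."""
    with io.open(path, "w", encoding="utf-8") as fh:
        for i, u in enumerate(graph.nodes):
            for j in graph.neighbors[i]:
                if i < j:
                    v = graph.nodes[j]
                    fh.write(f"{u}\t{v}\t{u[0]}{v[0]}\n")


def read_graph_tsv(path: str | Path) -> HeterogeneousGraph:
    node_set: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with io.open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            u, v = line.rstrip("\n").split("\t")[:2]
            node_set.update((u, v))
            edges.add((u, v) if u < v else (v, u))
    return _graph_from_edges(node_set, edges)
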