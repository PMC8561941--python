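"""Second-order biased random walks with alias sampling (node2vec).

A walk at node v that arrived from node t chooses the next node x among v's
neighbors with unnormalized weight alpha_pq(t, x):

    1/p  if d(t, x) = 0   (step back to t)
    1    if d(t, x) = 1   (x is also a neighbor of t)
    1/q  if d(t, x) = 2   (x moves away from t)

where d is shortest-path distance.  p controls the tendency to backtrack and
q trades off breadth-first against depth-first exploration; at p = q = 1 the
walk reduces to the uniform (DeepWalk) random walk.  Because x is always a
neighbor of v, d(t, x) is 0 iff x = t, 1 iff x is adjacent to t, else 2 —
no search is needed.  Per-edge categorical distributions are precomputed into
alias tables for O(1) sampling, and the resulting walk corpus is fed to a
skip-gram trainer to produce the nonlinear node features.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ContractError
from .lmdn_graph import HeterogeneousGraph
from . import skipgram

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkConfig:
    """Walk and embedding hyperparameters.

    Defaults follow the standard node2vec/word2vec settings: p = q = 1,
    10 walks of length 80 per node, window 10, 5 negative samples, 5 epochs.
    ``dimensions`` defaults to 16, the embedding size that combined best with
    the SVD features in the reference configuration.
    """

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 10
    dimensions: int = 16
    window: int = 10
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ContractError("p and q must be positive")
        if self.walk_length < 1 or self.walks_per_node < 1 or self.dimensions < 1:
            raise ContractError(
                "walk_length, walks_per_node and dimensions must be >= 1"
            )


@dataclass(frozen=True)
class NodeEmbeddings:
    """d-dimensional vectors for every node that appeared in the corpus."""

    vectors: Mapping[str, np.ndarray]
    d: int


def unnormalized_bias(d_tx: int, p: float, q: float) -> float:
    """alpha_pq for a candidate at shortest-path distance d_tx from the
    previous node (0, 1 or 2)."""
    if d_tx == 0:
        return 1.0 / p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / q
    raise ContractError(f"d_tx must be 0, 1 or 2, got {d_tx}")


def transition_distribution(
    graph: HeterogeneousGraph,
    prev: str | None,
    cur: str,
    p: float,
    q: float,
) -> dict[str, float]:
    """Exact next-step distribution over the neighbors of ``cur``.

    With no previous node (first step of a walk) the distribution is uniform.
    """
    idx = graph.index
    ci = idx[cur]
    nbrs = graph.neighbors[ci]
    if len(nbrs) == 0:
        raise ContractError(f"walk dead end: node {cur!r} has no neighbors")
    names = [graph.nodes[j] for j in nbrs]
    if prev is None:
        u = 1.0 / len(nbrs)
        return {x: u for x in names}
    pi = idx[prev]
    prev_nbrs = graph.neighbors[pi]
    if int(np.searchsorted(prev_nbrs, ci)) >= len(prev_nbrs) or prev_nbrs[
        int(np.searchsorted(prev_nbrs, ci))
    ] != ci:
        raise ContractError(f"prev {prev!r} is not adjacent to cur {cur!r}")
    weights = _edge_weights(graph, pi, ci, p, q)
    total = weights.sum()
    return {x: float(w / total) for x, w in zip(names, weights)}


def _edge_weights(
    graph: HeterogeneousGraph, prev_i: int, cur_i: int, p: float, q: float
) -> np.ndarray:
    """Unnormalized alpha_pq weights over neighbors of cur, given prev."""
    nbrs = graph.neighbors[cur_i]
    prev_nbrs = graph.neighbors[prev_i]
    weights = np.full(len(nbrs), 1.0 / q)
    adjacent_to_prev = np.isin(nbrs, prev_nbrs, assume_unique=True)
    weights[adjacent_to_prev] = 1.0
    weights[nbrs == prev_i] = 1.0 / p
    return weights


class AliasSampler:
    """O(1) sampling from a fixed categorical distribution (alias method)."""

    __slots__ = ("prob", "alias")

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.size == 0:
            raise ContractError("empty distribution")
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ContractError("probabilities must be nonnegative and sum to 1")
        n = probs.size
        scaled = probs * n
        self.prob = np.ones(n)
        self.alias = np.arange(n)
        small = [i for i in range(n) if scaled[i] < 1.0]
        large = [i for i in range(n) if scaled[i] >= 1.0]
        scaled = scaled.copy()
        while small and large:
            s = small.pop()
            l = large.pop()
            self.prob[s] = scaled[s]
            self.alias[s] = l
            scaled[l] = scaled[l] - (1.0 - scaled[s])
            (small if scaled[l] < 1.0 else large).append(l)
        for i in large + small:
            self.prob[i] = 1.0

    def sample(self, rng: np.random.Generator) -> int:
        n = self.prob.size
        i = int(rng.integers(n))
        return i if rng.random() < self.prob[i] else int(self.alias[i])

    def probabilities(self) -> np.ndarray:
        """Analytically reconstruct the categorical distribution the table
        encodes (exact, not sampled)."""
        n = self.prob.size
        out = self.prob / n
        np.add.at(out, self.alias, (1.0 - self.prob) / n)
        return out


@dataclass(frozen=True)
class AliasTables:
    """First-step (per node) and second-order (per directed edge) samplers."""

    first_step: dict[int, AliasSampler] = field(default_factory=dict)
    second_order: dict[tuple[int, int], AliasSampler] = field(default_factory=dict)


def build_alias_tables(
    graph: HeterogeneousGraph, p: float, q: float
) -> AliasTables:
    """Precompute alias samplers for every node and every directed edge."""
    if len(graph.nodes) == 0:
        raise ContractError("empty graph")
    tables = AliasTables()
    for i, nbrs in enumerate(graph.neighbors):
        if len(nbrs) == 0:
            continue
        tables.first_step[i] = AliasSampler(np.full(len(nbrs), 1.0 / len(nbrs)))
        for prev_i in nbrs:
            w = _edge_weights(graph, int(prev_i), i, p, q)
            tables.second_order[(int(prev_i), i)] = AliasSampler(w / w.sum())
    return tables


def generate_walks(
    graph: HeterogeneousGraph,
    config: WalkConfig,
    tables: AliasTables | None = None,
) -> list[list[str]]:
    """Simulate ``walks_per_node`` biased walks from every non-isolated node.

    Start order is shuffled each pass; isolated nodes are skipped with a
    warning.  Each walk has walk_length + 1 nodes (start included) and every
    consecutive pair is an edge.  Deterministic given ``config.seed``.
    """
    if tables is None:
        tables = build_alias_tables(graph, config.p, config.q)
    rng = np.random.default_rng(config.seed)
    starts = np.array(
        [i for i in range(len(graph.nodes)) if len(graph.neighbors[i]) > 0],
        dtype=np.int64,
    )
    n_isolated = len(graph.nodes) - len(starts)
    if n_isolated:
        logger.warning("skipping %d isolated node(s) with no walks", n_isolated)
    if len(starts) == 0:
        raise ContractError("graph has no non-isolated node to walk from")
    walks: list[list[str]] = []
    for _ in range(config.walks_per_node):
        order = rng.permutation(starts)
        for start in order:
            walk = [int(start)]
            cur = int(start)
            prev = -1
            for _ in range(config.walk_length):
                sampler = (
                    tables.first_step[cur]
                    if prev < 0
                    else tables.second_order[(prev, cur)]
                )
                nxt = int(graph.neighbors[cur][sampler.sample(rng)])
                walk.append(nxt)
                prev, cur = cur, nxt
            walks.append([graph.nodes[i] for i in walk])
    return walks


def train_embeddings(
    corpus: Sequence[Sequence[str]], config: WalkConfig
) -> NodeEmbeddings:
    """Embed the walk corpus with skip-gram + negative sampling.

    Single-worker and fully seeded, so identical corpus + config yield
    identical vectors.
    """
    if not corpus:
        raise ContractError("empty walk corpus")
    vectors = skipgram.train_skipgram(
        corpus,
        dimensions=config.dimensions,
        window=config.window,
        epochs=config.epochs,
        negative=config.negative,
        alpha=config.alpha,
        seed=config.seed,
    )
    return NodeEmbeddings(vectors, config.dimensions)


def embed_graph(graph: HeterogeneousGraph, config: WalkConfig) -> NodeEmbeddings:
    """Walks + training in one call."""
    return train_embeddings(generate_walks(graph, config), config)


def write_corpus(corpus: Sequence[Sequence[str]], path: str | Path) -> None:
    """One walk per line, space-separated node ids."""
    with io.open(path, "w", encoding="utf-8") as fh:
        for walk in corpus:
            fh.write(" ".join(walk) + "\n")


def read_corpus(path: str | Path) -> list[list[str]]:
    with io.open(path, "r", encoding="utf-8") as fh:
        return [line.split() for line in fh if line.strip()]


def write_embeddings(emb: NodeEmbeddings, path: str | Path) -> None:
    """word2vec text format: header "<count> <dim>", then one node per line."""
    with io.open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb.vectors)} {emb.d}\n")
        for nid in sorted(emb.vectors):
            vals = " ".join(repr(float(v)) for v in emb.vectors[nid])
            fh.write(f"{nid} {vals}\n")


def read_embeddings(path: str | Path) -> NodeEmbeddings:
    with io.open(path, "r", encoding="utf-8") as fh:
        count, d = map(int, fh.readline().split())
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.split()
            vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
    if len(vectors) != count or any(v.size != d for v in vectors.values()):
        raise ContractError("embedding file header inconsistent with contents")
    return NodeEmbeddings(vectors, d)
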