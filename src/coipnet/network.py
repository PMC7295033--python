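"""Score-thresholded interaction graphs, Markov Clustering, and a
resampling test for within-set edge enrichment.

Markov Clustering (MCL) partitions a graph by simulating random-walk
flow: the column-stochastic transition matrix is alternately expanded
(matrix power, letting flow spread) and inflated (entrywise power with
column renormalization, strengthening strong currents) until the flow
matrix reaches a fixed point, whose attractor rows define the
clusters.  Scores weight the walk; every node gets a self-loop (weight
= its maximum incident score, or 1.0 when isolated) so columns are
always stochastic.  Clusters smaller than ``min_size`` are reported as
unclustered, matching the convention of a minimum cluster size of 7
used for published interactome maps with a 0.9 confidence cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np


@dataclass
class ClusterAssignment:
    clusters: list[frozenset[str]]
    unclustered: frozenset[str]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster in self.clusters:
            if cluster & seen:
                raise ValueError("clusters must be pairwise disjoint")
            seen |= cluster
        if seen & self.unclustered:
            raise ValueError("unclustered nodes overlap a cluster")

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set(self.unclustered)
        for cluster in self.clusters:
            out |= cluster
        return frozenset(out)


def validate_graph(graph: nx.Graph) -> None:
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        score = data.get("score")
        if score is None or not (0.0 <= score <= 1.0):
            raise ValueError(f"edge ({u!r}, {v!r}) needs a score in [0, 1], got {score}")


def threshold_graph(graph: nx.Graph, s: float = 0.9) -> nx.Graph:
    """Retain edges with score >= s (inclusive); isolated nodes retained."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"score cutoff must lie in [0, 1], got {s}")
    validate_graph(graph)
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from(
        (u, v, data) for u, v, data in graph.edges(data=True) if data["score"] >= s
    )
    return out


def _mcl_matrix(
    matrix: np.ndarray,
    inflation: float,
    expansion: int,
    prune: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    m = matrix / matrix.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsums = inflated.sum(axis=0, keepdims=True)
        dead = colsums == 0  # pruning emptied a column: restore its self-loop
        if dead.any():
            for j in np.nonzero(dead[0])[0]:
                inflated[j, j] = 1.0
            colsums = inflated.sum(axis=0, keepdims=True)
        new = inflated / colsums
        if np.abs(new - m).max() < tol:
            return new
        m = new
    raise RuntimeError(f"MCL did not converge within {max_iter} iterations")


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 200,
    min_size: int = 7,
) -> ClusterAssignment:
    """Markov Clustering of a score-weighted simple graph.

    Runs per connected component (flow never crosses components), reads
    clusters from attractor rows of the converged matrix, merges
    overlapping attractor systems, and relegates clusters below
    ``min_size`` to ``unclustered``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    validate_graph(graph)

    clusters: list[frozenset[str]] = []
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1:
            clusters.append(frozenset(nodes))
            continue
        index = {node: i for i, node in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)))
        for u, v, data in graph.subgraph(component).edges(data=True):
            a[index[u], index[v]] = a[index[v], index[u]] = data["score"]
        loop = a.max(axis=0)
        loop[loop == 0] = 1.0
        np.fill_diagonal(a, loop)
        m = _mcl_matrix(a, inflation, expansion, prune, tol, max_iter)

        attractors = [i for i in range(len(nodes)) if m[i, i] > prune]
        raw = [frozenset(np.nonzero(m[i] > prune)[0]) for i in attractors]
        merged = _merge_overlapping(raw)
        assigned = set().union(*merged) if merged else set()
        for i in range(len(nodes)):  # flow split exactly between attractors
            if i not in assigned:
                merged.append(frozenset([i]))
        clusters.extend(frozenset(nodes[i] for i in group) for group in merged)

    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    kept = [c for c in clusters if len(c) >= min_size]
    unclustered = frozenset().union(*(c for c in clusters if len(c) < min_size)) if any(
        len(c) < min_size for c in clusters
    ) else frozenset()
    return ClusterAssignment(
        clusters=kept,
        unclustered=frozenset(unclustered),
        parameters={
            "inflation": inflation,
            "expansion": expansion,
            "prune": prune,
            "tol": tol,
            "max_iter": max_iter,
            "min_size": min_size,
        },
    )


def _merge_overlapping(groups: list[frozenset[int]]) -> list[frozenset[int]]:
    merged: list[set[int]] = []
    for group in groups:
        hit = [m for m in merged if m & group]
        for m in hit:
            merged.remove(m)
        merged.append(set(group).union(*hit) if hit else set(group))
    return [frozenset(m) for m in merged]


def edge_enrichment_permutation(
    graph: nx.Graph,
    node_subset: Sequence[str],
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Resampling test: is the subset's internal edge count excessive?

    The null resamples uniformly-random node sets of the same size and
    counts their internal edges; the empirical p-value is
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    subset = set(node_subset)
    nodes = list(graph.nodes)
    missing = subset - set(nodes)
    if missing:
        raise ValueError(f"subset node(s) not in graph: {sorted(missing)[:5]}")
    if len(subset) > len(nodes):
        raise ValueError("subset larger than the graph")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = sum(1 for u, v in graph.edges if u in subset and v in subset)
    size = len(subset)
    null = np.empty(n_perm, dtype=np.int64)
    node_arr = np.array(nodes, dtype=object)
    adjacency = {node: set(graph.neighbors(node)) for node in nodes}
    for i in range(n_perm):
        draw = set(rng.choice(node_arr, size=size, replace=False))
        null[i] = sum(len(adjacency[node] & draw) for node in draw) // 2
    p = float((1 + int((null >= observed).sum())) / (1 + n_perm))
    return {
        "observed": int(observed),
        "expected": float(null.mean()),
        "p": p,
        "n_perm": int(n_perm),
        "subset_size": size,
    }
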