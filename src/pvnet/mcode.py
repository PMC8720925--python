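"""Molecular complex detection (MCODE) on protein–protein interaction graphs.

The algorithm proceeds in three stages:

1. *Vertex weighting.* For each vertex ``v`` with degree >= ``degree_cutoff``
   take the subgraph induced on the closed neighborhood N[v], find its
   highest k-core (the largest k with a non-empty k-core), and set
   ``weight(v) = k_max * density(highest k-core)`` with the loop-free
   density 2E / (n(n-1)). Vertices below the degree cutoff get weight 0.
2. *Complex prediction.* Repeatedly seed from the unvisited vertex of
   highest weight and grow breadth-first up to ``max_depth``, admitting an
   unvisited neighbor ``u`` iff
   ``weight(u) >= weight(seed) * (1 - node_score_cutoff)``;
   admitted vertices are marked visited.
3. *Post-processing.* Candidates whose induced subgraph contains no k-core
   with ``k >= k_core`` are discarded; the optional *haircut* iteratively
   removes vertices of degree < 2 within the cluster, and the optional
   *fluff* adds unvisited neighbors whose closed-neighborhood density
   exceeds ``fluff_density_cutoff`` (fluffed vertices may be shared between
   clusters).

A cluster's score is density x size of its induced subgraph. All
tie-breaks (seed choice, traversal order, output order) are lexicographic,
so results are deterministic for a given graph and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "McodeParams",
    "Cluster",
    "k_core_subgraph",
    "vertex_weighting",
    "predict_complexes",
    "cluster_table",
    "write_clusters",
]


@dataclass(frozen=True)
class McodeParams:
    """Parameter set of the complex-detection run (plug-in style defaults)."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0 or self.max_depth < 0:
            raise ValueError("degree_cutoff and max_depth must be >= 0")
        if not (0.0 <= self.node_score_cutoff <= 1.0):
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if not (0.0 <= self.fluff_density_cutoff <= 1.0):
            raise ValueError("fluff_density_cutoff must be in [0, 1]")


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def k_core_subgraph(network: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph in which every vertex has internal degree >= k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if network.number_of_nodes() == 0:
        return nx.Graph()
    return nx.k_core(network, k).copy()


def _highest_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """(k_max, highest k-core) of ``g``; k_max = 0 for edgeless graphs."""
    core_num = nx.core_number(g)
    k_max = max(core_num.values())
    core = g.subgraph([v for v, c in core_num.items() if c >= k_max])
    return k_max, core


def vertex_weighting(network: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """Core-weighted local density score for every vertex."""
    weights: dict[str, float] = {}
    for v in network.nodes:
        if network.degree[v] < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = network.subgraph([v, *network.neighbors(v)])
        k_max, core = _highest_core(nbhd)
        weights[v] = k_max * _density(core)
    return weights


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]
    seed_node: str
    score: float
    n_nodes: int
    n_edges: int
    fluffed: frozenset[str] = field(default_factory=frozenset)


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    members = set(members)
    while True:
        sub = g.subgraph(members)
        low = [v for v in members if sub.degree[v] < 2]
        if not low:
            return members
        members -= set(low)


def predict_complexes(
    network: nx.Graph,
    weights: dict[str, float] | None = None,
    params: McodeParams = McodeParams(),
) -> list[Cluster]:
    """Run seeded complex growth over the whole graph.

    Returns clusters sorted by descending score, ties broken by the smaller
    seed id. Without fluff the clusters are pairwise vertex-disjoint.
    """
    if weights is None:
        weights = vertex_weighting(network, params.degree_cutoff)

    visited: set[str] = set()
    order = sorted(network.nodes, key=lambda v: (-weights[v], v))
    clusters: list[Cluster] = []

    for seed in order:
        if seed in visited:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt: list[str] = []
            for v in frontier:
                for u in sorted(network.neighbors(v)):
                    if u in visited:
                        continue
                    if weights[u] >= threshold:
                        visited.add(u)
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1

        # post-processing
        if k_core_subgraph(network.subgraph(members), params.k_core).number_of_nodes() == 0:
            continue
        if params.haircut:
            members = _haircut(network, members)
        fluffed: set[str] = set()
        if params.fluff:
            for v in sorted(members):
                for u in sorted(network.neighbors(v)):
                    if u in members or u in visited:
                        continue
                    nbhd = network.subgraph([u, *network.neighbors(u)])
                    if _density(nbhd) > params.fluff_density_cutoff:
                        fluffed.add(u)
            members = members | fluffed
        if len(members) < 2:
            continue
        sub = network.subgraph(members)
        clusters.append(
            Cluster(
                members=frozenset(members),
                seed_node=seed,
                score=_density(sub) * sub.number_of_nodes(),
                n_nodes=sub.number_of_nodes(),
                n_edges=sub.number_of_edges(),
                fluffed=frozenset(fluffed),
            )
        )

    clusters.sort(key=lambda c: (-c.score, c.seed_node))
    return clusters


def cluster_table(clusters: list[Cluster]) -> pd.DataFrame:
    """Deterministic tabular summary (rank, score, sizes, seed, members)."""
    rows = [
        {
            "rank": i + 1,
            "score": round(c.score, 6),
            "n_nodes": c.n_nodes,
            "n_edges": c.n_edges,
            "seed": c.seed_node,
            "members": ",".join(sorted(c.members)),
        }
        for i, c in enumerate(clusters)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "score", "n_nodes", "n_edges", "seed", "members"]
    )


def write_clusters(clusters: list[Cluster], out_dir: str | Path) -> Path:
    """Write the summary TSV plus one member-list file per cluster."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / "clusters.tsv"
    cluster_table(clusters).to_csv(table_path, sep="\t", index=False)
    for i, c in enumerate(clusters):
        (out / f"cluster_{i + 1:02d}_members.txt").write_text(
            "\n".join(sorted(c.members)) + "\n"
        )
    return table_path
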