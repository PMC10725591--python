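"""Score-thresholded PPI graphs and MCODE molecular-complex detection.

Edges arrive as STRING-export style 3-column TSVs (node1, node2,
combined_score); only edges with score strictly above the threshold (default
0.4) are kept.  MCODE then weights each vertex by the density of the highest
k-core of its closed neighborhood times that core number, seeds complexes
from high-weight vertices, and grows them over neighbors whose weight stays
within ``node_score_cutoff`` of the seed.  Confidence scores are used for
thresholding only; the algorithm runs on the unweighted thresholded graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx


@dataclass
class PpiGraph:
    graph: nx.Graph
    score_threshold: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class McodeComplex:
    members: list[str]
    seed: str
    density: float
    score: float
    rank: int = 0

    @property
    def size(self) -> int:
        return len(self.members)


def load_edges(path: str | Path, score_threshold: float = 0.4) -> PpiGraph:
    """Parse an edge TSV, keeping edges with combined_score > threshold.

    The inequality is strict; nodes that lose all edges remain in the node
    set as isolates.  Duplicate undirected edges collapse to one; self-loops
    are rejected.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad score {raw!r}") from None
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on {a!r}")
            g.add_node(a)
            g.add_node(b)
            if score > score_threshold:
                g.add_edge(a, b, combined_score=score)
    return PpiGraph(graph=g, score_threshold=score_threshold)


def graph_from_edges(
    edges: list[tuple[str, str, float]], score_threshold: float = 0.4
) -> PpiGraph:
    """In-memory counterpart of :func:`load_edges`."""
    g = nx.Graph()
    for a, b, score in edges:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        g.add_node(a)
        g.add_node(b)
        if score > score_threshold:
            g.add_edge(a, b, combined_score=score)
    return PpiGraph(graph=g, score_threshold=score_threshold)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The k-core with the largest k that is nonempty, and that k."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_numbers = nx.core_number(g)
    k = max(core_numbers.values())
    return k, g.subgraph([v for v, c in core_numbers.items() if c >= k])


def mcode_vertex_weights(ppi: PpiGraph, degree_cutoff: int = 2) -> dict[str, float]:
    """Core-clustering-coefficient × highest-core-number vertex weights.

    Vertices below the degree cutoff get weight 0; otherwise the closed
    neighborhood's highest k-core is found and the weight is k times the
    density of that core subgraph.
    """
    g = ppi.graph
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph([v, *g.neighbors(v)])
        k, core = _highest_k_core(closed)
        weights[v] = k * _density(core)
    return weights


def mcode_complexes(
    ppi: PpiGraph,
    weights: dict[str, float] | None = None,
    node_score_cutoff: float = 0.2,
    degree_cutoff: int = 2,
    haircut: bool = True,
    fluff: bool = False,
) -> list[McodeComplex]:
    """Seeded greedy growth of dense complexes, ranked by density × size.

    Seeds are taken in descending weight (ties by node id); expansion admits
    unvisited neighbors whose weight is >= (1 - node_score_cutoff) times the
    seed weight.  Visited vertices never join a later complex, so complexes
    are node-disjoint.  Haircut removes singly-connected vertices; complexes
    of size < 2 are discarded.  The fluff stage is not implemented (off in
    the workflow this follows).
    """
    if fluff:
        raise NotImplementedError("fluff stage is not implemented")
    g = ppi.graph
    if weights is None:
        weights = mcode_vertex_weights(ppi, degree_cutoff=degree_cutoff)
    order = sorted(weights, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    complexes: list[McodeComplex] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            v = frontier.pop(0)
            for u in sorted(g.neighbors(v)):
                if u in visited:
                    continue
                if weights[u] >= threshold:
                    visited.add(u)
                    members.add(u)
                    frontier.append(u)
        sub = g.subgraph(members).copy()
        if haircut:
            sub.remove_nodes_from([v for v in list(sub) if sub.degree(v) < 2])
        if sub.number_of_nodes() < 2:
            continue
        dens = _density(sub)
        complexes.append(
            McodeComplex(
                members=sorted(sub.nodes),
                seed=seed,
                density=dens,
                score=dens * sub.number_of_nodes(),
            )
        )
    complexes.sort(key=lambda c: (-c.score, -c.size, c.seed))
    for i, c in enumerate(complexes, 1):
        c.rank = i
    return complexes


def complexes_table(complexes: list[McodeComplex]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "rank": c.rank,
                "score": c.score,
                "density": c.density,
                "size": c.size,
                "seed": c.seed,
                "members": ";".join(c.members),
            }
            for c in complexes
        ],
        columns=["rank", "score", "density", "size", "seed", "members"],
    )
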