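"""Interaction-network construction, centralities, and consensus hubs.

Five ranking methods are supported: degree, closeness (reciprocal
distances, so disconnected graphs remain rankable), betweenness (Brandes,
unnormalized), stress (count of shortest paths through a vertex), and
maximal clique centrality (MCC: sum of (|C| - 1)! over the maximal
cliques containing a vertex). Edge scores are used only for
thresholding; every path computation is unweighted. Rankings break score
ties lexicographically by gene symbol so top-k lists are reproducible.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import UndefinedScoreError

DEFAULT_EDGE_THRESHOLD = 0.40
DEFAULT_TOP_K = 20
DEFAULT_MIN_METHODS = 3
MCC_VERTEX_GUARD = 5000

METHOD_DEGREE = "degree"
METHOD_CLOSENESS = "closeness"
METHOD_BETWEENNESS = "betweenness"
METHOD_STRESS = "stress"
METHOD_MCC = "mcc"
ALL_METHODS = (
    METHOD_DEGREE,
    METHOD_CLOSENESS,
    METHOD_BETWEENNESS,
    METHOD_STRESS,
    METHOD_MCC,
)
#: the four ranking methods used for module hub detection
HUB_METHODS = (METHOD_MCC, METHOD_DEGREE, METHOD_CLOSENESS, METHOD_BETWEENNESS)
#: the four ranking methods used for regulator (e.g. miRNA) hubs
REGULATOR_METHODS = (
    METHOD_DEGREE,
    METHOD_BETWEENNESS,
    METHOD_CLOSENESS,
    METHOD_STRESS,
)


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected score-thresholded gene graph (no self-loops)."""

    graph: nx.Graph = field(repr=False)
    score_threshold: float = DEFAULT_EDGE_THRESHOLD

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, v: str) -> frozenset[str]:
        return frozenset(self.graph.neighbors(v))

    def subgraph(self, vertices: Iterable[str]) -> "InteractionNetwork":
        keep = set(vertices) & set(self.graph.nodes)
        return InteractionNetwork(
            graph=nx.Graph(self.graph.subgraph(keep)),
            score_threshold=self.score_threshold,
        )

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, float(data.get("score", 1.0))))
        out.sort()
        return out


@dataclass(frozen=True)
class CentralityRanking:
    """Scores plus the deterministic order they induce."""

    method: str
    scores: Mapping[str, float]
    order: tuple[str, ...]

    @classmethod
    def from_scores(
        cls, method: str, scores: Mapping[str, float]
    ) -> "CentralityRanking":
        order = tuple(sorted(scores, key=lambda v: (-scores[v], v)))
        return cls(method=method, scores=dict(scores), order=order)


@dataclass(frozen=True)
class ConsensusHubSet:
    top_k: int
    min_methods: int
    per_method_top: Mapping[str, tuple[str, ...]]
    support: Mapping[str, int]
    hubs: frozenset[str]


def build_network(
    edges: Iterable[tuple[str, str, float]],
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    vertices: Iterable[str] | None = None,
) -> InteractionNetwork:
    """Keep edges with score >= threshold (boundary inclusive).

    Self-loops are discarded; on duplicate pairs the maximum score wins.
    ``vertices``, when given, adds isolated vertices that survived no
    edge.
    """
    graph = nx.Graph()
    if vertices is not None:
        graph.add_nodes_from(str(v) for v in vertices)
    for u, v, score in edges:
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"edge score out of [0,1]: {u}-{v} {score}")
        if u == v:
            continue
        if score < threshold:
            continue
        u, v = str(u), str(v)
        if graph.has_edge(u, v):
            graph[u][v]["score"] = max(graph[u][v]["score"], score)
        else:
            graph.add_edge(u, v, score=score)
    return InteractionNetwork(graph=graph, score_threshold=threshold)


def neighbor_overlap_score(net: InteractionNetwork, u: str, v: str) -> float:
    """Dice coefficient of the two open neighborhoods.

    Raises :class:`UndefinedScoreError` when both neighborhoods are
    empty (0/0).
    """
    if u not in net.graph or v not in net.graph:
        raise KeyError(f"vertex not in network: {u if u not in net.graph else v}")
    nu = net.neighbors(u)
    nv = net.neighbors(v)
    denom = len(nu) + len(nv)
    if denom == 0:
        raise UndefinedScoreError(
            f"neighbor overlap undefined for isolated pair ({u}, {v})"
        )
    return 2.0 * len(nu & nv) / denom


def degree_centrality(net: InteractionNetwork) -> CentralityRanking:
    scores = {v: float(d) for v, d in net.graph.degree()}
    return CentralityRanking.from_scores(METHOD_DEGREE, scores)


def closeness_centrality(net: InteractionNetwork) -> CentralityRanking:
    """Reciprocal-distance (harmonic) closeness; unreachable pairs add 0."""
    scores = {v: float(s) for v, s in nx.harmonic_centrality(net.graph).items()}
    return CentralityRanking.from_scores(METHOD_CLOSENESS, scores)


def betweenness_centrality(net: InteractionNetwork) -> CentralityRanking:
    """Unnormalized shortest-path betweenness (Brandes), unweighted."""
    scores = nx.betweenness_centrality(net.graph, normalized=False)
    return CentralityRanking.from_scores(
        METHOD_BETWEENNESS, {v: float(s) for v, s in scores.items()}
    )


def stress_centrality(net: InteractionNetwork) -> CentralityRanking:
    """Number of shortest paths through each vertex.

    All unordered source-target pairs are considered and path endpoints
    are excluded. Computed by a Brandes-style accumulation: for a source
    ``s``, the number of s-shortest paths through ``v`` equals
    ``sigma_sv * phi(v)`` where ``phi(v) = sum_{w in succ(v)} (1 + phi(w))``
    counts shortest-path continuations beyond ``v``.
    """
    graph = net.graph
    stress = {v: 0.0 for v in graph.nodes}
    for source in graph.nodes:
        dist: dict[str, int] = {source: 0}
        sigma: dict[str, float] = {source: 1.0}
        successors: dict[str, list[str]] = {v: [] for v in graph.nodes}
        order: list[str] = []
        queue = deque([source])
        while queue:
            u = queue.popleft()
            order.append(u)
            for w in graph.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0.0
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    successors[u].append(w)
        phi = {v: 0.0 for v in order}
        for u in reversed(order):
            for w in successors[u]:
                phi[u] += 1.0 + phi[w]
        for v in order:
            if v != source:
                stress[v] += sigma[v] * phi[v]
    # each unordered pair was visited from both endpoints
    return CentralityRanking.from_scores(
        METHOD_STRESS, {v: s / 2.0 for v, s in stress.items()}
    )


def mcc_centrality(
    net: InteractionNetwork, allow_large: bool = False
) -> CentralityRanking:
    """Maximal clique centrality: sum of (|C| - 1)! over maximal cliques.

    Maximal cliques are enumerated with Bron-Kerbosch plus pivoting.
    Singleton "cliques" are excluded, so isolated vertices score 0 and a
    vertex whose neighbors are mutually non-adjacent scores its degree.
    Enumeration is exponential in the worst case; graphs beyond
    ``MCC_VERTEX_GUARD`` vertices require ``allow_large=True``.
    """
    graph = net.graph
    if graph.number_of_nodes() > MCC_VERTEX_GUARD and not allow_large:
        raise ValueError(
            f"graph has {graph.number_of_nodes()} vertices "
            f"(> {MCC_VERTEX_GUARD}); pass allow_large=True to force MCC"
        )
    scores = {v: 0.0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        weight = float(math.factorial(len(clique) - 1))
        for v in clique:
            scores[v] += weight
    return CentralityRanking.from_scores(METHOD_MCC, scores)


_CENTRALITY_FUNCS = {
    METHOD_DEGREE: degree_centrality,
    METHOD_CLOSENESS: closeness_centrality,
    METHOD_BETWEENNESS: betweenness_centrality,
    METHOD_STRESS: stress_centrality,
    METHOD_MCC: mcc_centrality,
}


def compute_rankings(
    net: InteractionNetwork, methods: Sequence[str] = HUB_METHODS
) -> list[CentralityRanking]:
    """One :class:`CentralityRanking` per requested method."""
    unknown = set(methods) - set(_CENTRALITY_FUNCS)
    if unknown:
        raise ValueError(f"unknown centrality methods: {sorted(unknown)}")
    return [_CENTRALITY_FUNCS[m](net) for m in methods]


def top_k(ranking: CentralityRanking, k: int) -> tuple[str, ...]:
    if k < 0:
        raise ValueError("k must be nonnegative")
    return ranking.order[:k]


def consensus_hubs(
    rankings: Sequence[CentralityRanking],
    top_k_size: int = DEFAULT_TOP_K,
    min_methods: int = DEFAULT_MIN_METHODS,
) -> ConsensusHubSet:
    """Genes appearing in the top-k of at least ``min_methods`` rankings."""
    if min_methods > len(rankings):
        raise ValueError(
            f"min_methods={min_methods} exceeds {len(rankings)} rankings"
        )
    methods = [r.method for r in rankings]
    if len(methods) != len(set(methods)):
        raise ValueError("duplicate ranking methods supplied")
    per_method_top = {r.method: top_k(r, top_k_size) for r in rankings}
    support: dict[str, int] = {}
    for genes in per_method_top.values():
        for gene in genes:
            support[gene] = support.get(gene, 0) + 1
    hubs = frozenset(g for g, c in support.items() if c >= min_methods)
    return ConsensusHubSet(
        top_k=top_k_size,
        min_methods=min_methods,
        per_method_top=per_method_top,
        support=support,
        hubs=hubs,
    )
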