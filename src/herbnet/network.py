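"""Weighted herb co-occurrence networks and Louvain module detection.

Two herbs are linked if they appear together in at least one prescription;
the edge weight is the number of prescriptions containing both. Dose is
never considered. Community structure is found by maximizing the weighted
modularity

    Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / (2m)] δ(c_i, c_j)

with A the weighted adjacency, k the weighted degrees, m the total edge
weight and γ the resolution. The Louvain optimizer is implemented here (the
gain arithmetic is deliberately local and testable against a naive
evaluation of the formula): repeated passes of greedy local moves over a
seed-shuffled node order, followed by community aggregation, until no move
improves Q. Ties between candidate communities break toward the smaller
community id, so runs are reproducible for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Hashable, Mapping

import networkx as nx

from .corpus import Corpus


class NetworkError(ValueError):
    """Raised on degenerate network inputs (e.g. modularity of an edgeless graph)."""


@dataclass
class CoOccurrenceNetwork:
    """Undirected weighted co-occurrence graph plus the isolated herbs.

    ``graph`` holds only herbs with at least one edge; herbs that never
    co-occur with another herb are listed in ``isolated`` and are excluded
    from modularity analysis.
    """

    graph: nx.Graph
    isolated: frozenset[str] = frozenset()

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edge_weight(self, a: str, b: str) -> int:
        return self.graph[a][b]["weight"] if self.graph.has_edge(a, b) else 0


@dataclass
class ModulePartition:
    """Herb -> module assignment with its modularity score."""

    assignment: dict[str, int]
    q: float
    resolution: float = 1.0
    seed: int | None = None

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for label in self.assignment.values():
            out[label] = out.get(label, 0) + 1
        return out

    def members(self, label: int) -> frozenset[str]:
        return frozenset(h for h, m in self.assignment.items() if m == label)


def build_cooccurrence_network(corpus: Corpus) -> CoOccurrenceNetwork:
    """Count all herb-pair co-occurrences and assemble the weighted graph."""
    if corpus.n == 0:
        raise NetworkError("cannot build a network from an empty corpus")
    weights: dict[tuple[str, str], int] = {}
    seen: set[str] = set()
    for t in corpus.transactions():
        seen |= t
        for a, b in combinations(sorted(t), 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    g = nx.Graph()
    for (a, b), w in weights.items():
        g.add_edge(a, b, weight=w)
    isolated = frozenset(seen - set(g.nodes))
    return CoOccurrenceNetwork(g, isolated)


def modularity(network: CoOccurrenceNetwork | nx.Graph,
               assignment: Mapping[Hashable, int],
               resolution: float = 1.0) -> float:
    """Weighted modularity Q of a partition, at resolution γ.

    The assignment must cover every non-isolated node. Self-loops (which
    arise only in aggregated graphs, never in co-occurrence networks) count
    their full weight on the diagonal of A and twice in the degree.
    """
    g = network.graph if isinstance(network, CoOccurrenceNetwork) else network
    if g.number_of_edges() == 0:
        raise NetworkError("modularity is undefined for a graph with no edges")
    missing = [v for v in g.nodes if v not in assignment]
    if missing:
        raise NetworkError(f"assignment misses node(s) {sorted(map(str, missing))[:5]}")

    two_m = 0.0
    for _, _, w in g.edges(data="weight", default=1.0):
        two_m += 2.0 * w
    q = 0.0
    degree = dict(g.degree(weight="weight"))  # self-loop counts twice
    for u, v, w in g.edges(data="weight", default=1.0):
        if assignment[u] == assignment[v]:
            # A_uv + A_vu for u != v; a self-loop sits on the diagonal with
            # A_uu = 2w under the degree convention above — 2w either way.
            q += 2.0 * w
    for u in g.nodes:
        for v in g.nodes:
            if assignment[u] == assignment[v]:
                q -= resolution * degree[u] * degree[v] / two_m
    return q / two_m


class _LouvainState:
    """Mutable community bookkeeping for one level of Louvain."""

    def __init__(self, adj: dict[Hashable, dict[Hashable, float]]):
        self.adj = adj
        self.nodes = sorted(adj, key=str)
        self.community = {v: i for i, v in enumerate(self.nodes)}
        # weighted degree incl. 2x self-loop; community totals
        self.degree = {
            v: sum(w for u, w in adj[v].items() if u != v) + 2.0 * adj[v].get(v, 0.0)
            for v in self.nodes
        }
        self.selfloop = {v: adj[v].get(v, 0.0) for v in self.nodes}
        self.tot = {self.community[v]: self.degree[v] for v in self.nodes}
        self.two_m = sum(self.degree.values())

    def neighbor_community_weights(self, v: Hashable) -> dict[int, float]:
        out: dict[int, float] = {}
        for u, w in self.adj[v].items():
            if u == v:
                continue
            c = self.community[u]
            out[c] = out.get(c, 0.0) + w
        return out


def _one_level(adj: dict[Hashable, dict[Hashable, float]], resolution: float,
               rng: random.Random) -> tuple[dict[Hashable, int], bool]:
    """Greedy local-move phase. Returns (community map, any_move_made)."""
    st = _LouvainState(adj)
    improved = False
    moved = True
    while moved:
        moved = False
        order = list(st.nodes)
        rng.shuffle(order)
        for v in order:
            c_old = st.community[v]
            k_v = st.degree[v]
            links = st.neighbor_community_weights(v)
            # detach v from its community
            st.tot[c_old] -= k_v
            # gain of inserting v into community c:
            #   ΔQ = k_{v,c}/m − γ · tot_c · k_v / (2 m²)
            # (constant terms cancel across candidates, incl. re-insertion)
            best_c, best_gain = c_old, links.get(c_old, 0.0) - (
                resolution * st.tot[c_old] * k_v / st.two_m
            )
            for c in sorted(links):
                if c == c_old:
                    continue
                gain = links[c] - resolution * st.tot[c] * k_v / st.two_m
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and c < best_c
                ):
                    best_c, best_gain = c, gain
            st.community[v] = best_c
            st.tot[best_c] = st.tot.get(best_c, 0.0) + k_v
            if best_c != c_old:
                moved = improved = True
    return dict(st.community), improved


def _aggregate(adj: dict[Hashable, dict[Hashable, float]],
               community: Mapping[Hashable, int]) -> dict[int, dict[int, float]]:
    """Collapse communities into super-nodes; internal weight becomes a self-loop."""
    new: dict[int, dict[int, float]] = {}
    for v, nbrs in adj.items():
        cv = community[v]
        row = new.setdefault(cv, {})
        for u, w in nbrs.items():
            cu = community[u]
            if cu == cv:
                # each undirected internal edge visited from both ends;
                # self-loops visited once with their full weight
                row[cv] = row.get(cv, 0.0) + (w if u == v else w / 2.0)
            else:
                row[cu] = row.get(cu, 0.0) + w
        new.setdefault(cv, row)
    return new


def louvain_partition(network: CoOccurrenceNetwork, resolution: float = 1.0,
                      seed: int = 0) -> ModulePartition:
    """Two-phase Louvain modularity maximization on the co-occurrence graph.

    Isolated herbs are excluded before optimization. The node sweep order is
    shuffled by ``seed`` each pass; equal-gain ties go to the smaller
    community id, so the result is deterministic for a fixed seed.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        raise NetworkError("Louvain requires at least one edge")
    rng = random.Random(seed)

    adj: dict[Hashable, dict[Hashable, float]] = {
        v: {u: float(d.get("weight", 1.0)) for u, d in g.adj[v].items()} for v in g.nodes
    }
    # node -> community at the finest level, composed across aggregations
    mapping: dict[str, Hashable] = {v: v for v in g.nodes}
    while True:
        community, improved = _one_level(adj, resolution, rng)
        mapping = {v: community[mapping[v]] for v in mapping}
        if not improved:
            break
        adj = _aggregate(adj, community)
        if len(adj) == 1:
            break

    labels = {v: mapping[v] for v in g.nodes}
    q = modularity(network, labels, resolution)
    part = ModulePartition(_as_int_labels(labels), q, resolution, seed)
    return canonicalize_labels(part)


def _as_int_labels(labels: Mapping[Hashable, Hashable]) -> dict[Hashable, int]:
    uniq = {c: i for i, c in enumerate(sorted(set(labels.values()), key=str))}
    return {v: uniq[c] for v, c in labels.items()}


def canonicalize_labels(partition: ModulePartition) -> ModulePartition:
    """Renumber modules 1..k by descending size, ties by smallest member id.

    Idempotent; the grouping itself is unchanged.
    """
    groups: dict[int, list[str]] = {}
    for herb, label in partition.assignment.items():
        groups.setdefault(label, []).append(herb)
    order = sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c])))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    assignment = {h: relabel[c] for h, c in partition.assignment.items()}
    return ModulePartition(assignment, partition.q, partition.resolution, partition.seed)


def annotate_graph(network: CoOccurrenceNetwork, partition: ModulePartition | None,
                   corpus: Corpus) -> nx.Graph:
    """Copy of the graph with module / meridian / category node attributes."""
    g = network.graph.copy()
    for v in g.nodes:
        if partition is not None and v in partition.assignment:
            g.nodes[v]["module"] = int(partition.assignment[v])
        ann = corpus.annotations.get(v)
        if ann is not None:
            g.nodes[v]["meridians"] = "|".join(sorted(ann.meridians))
            g.nodes[v]["category"] = int(ann.category)
            g.nodes[v]["latin_name"] = ann.latin_name
    return g


def export_network(network: CoOccurrenceNetwork, corpus: Corpus,
                   partition: ModulePartition | None, basepath: str | Path) -> list[Path]:
    """Write GraphML and GEXF files (``<basepath>.graphml`` / ``.gexf``)."""
    g = annotate_graph(network, partition, corpus)
    base = Path(basepath)
    paths = [base.with_suffix(".graphml"), base.with_suffix(".gexf")]
    nx.write_graphml(g, paths[0])
    nx.write_gexf(g, paths[1])
    return paths
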