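"""Seed-anchored subnetwork extraction from an inferred network.

Two complementary heuristics:

* ``snbuilder_extract`` — neighbourhood expansion: starting from the seed
  genes, each round admits candidates whose neighbourhood overlaps the
  current member set strongly enough (or that touch at least two seeds).
  Expansion is unweighted (adjacency only; edge weights were already
  thresholded upstream).
* ``gena_extract`` — cohesive greedy growth: repeatedly add the neighbour
  that most improves the weighted cohesion W_in/(W_in + W_out) of the
  member set, stopping at a local optimum or a size cap.  This tends to
  produce smaller, functionally cohesive modules.

Both are deterministic: candidates are processed, and ties broken, in
lexicographic gene-ID order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .io import EdgeList

__all__ = ["Subnetwork", "snbuilder_extract", "gena_extract", "write_subnetwork"]


@dataclass
class Subnetwork:
    """A seed-anchored node set with its induced edges."""

    nodes: list[str]
    edges: EdgeList
    seeds: list[str]

    def __post_init__(self) -> None:
        self.nodes = sorted(set(self.nodes))
        node_set = set(self.nodes)
        for a, b, _ in self.edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge {a!r}--{b!r} endpoint outside node set")
        for s in self.seeds:
            if s not in node_set:
                raise ValueError(f"seed {s!r} missing from node set")


def _build_graph(net: EdgeList) -> nx.Graph:
    g = nx.Graph()
    for a, b, s in net:
        g.add_edge(a, b, weight=float(s))
    return g


def _present_seeds(graph: nx.Graph, seeds) -> list[str]:
    seeds = list(dict.fromkeys(seeds))
    present = [s for s in seeds if s in graph]
    if not present:
        missing = ", ".join(repr(s) for s in seeds)
        raise ValueError(f"no seed gene found in network (missing: {missing})")
    return present


def _induced(net: EdgeList, nodes: set[str], seeds: list[str]) -> Subnetwork:
    edges = [(a, b, s) for a, b, s in net if a in nodes and b in nodes]
    return Subnetwork(sorted(nodes), EdgeList(edges, cutoff=net.cutoff), sorted(seeds))


def snbuilder_extract(
    net: EdgeList,
    seeds,
    expand_rounds: int = 2,
    inclusion_fraction: float = 0.5,
) -> Subnetwork:
    """Neighbourhood-expansion extraction around seed genes.

    A candidate joins when the overlap between its neighbour set and the
    current member set — |N(c) ∩ M| / min(|N(c)|, |M|) — reaches
    ``inclusion_fraction``, or when it is adjacent to at least two seeds.
    Candidates are processed in lexicographic order and admissions take
    effect immediately, so later candidates see the grown member set.
    Expansion stops after ``expand_rounds`` rounds or at a fixed point.
    """
    if expand_rounds < 1:
        raise ValueError("expand_rounds must be ≥ 1")
    if not (0.0 < inclusion_fraction <= 1.0):
        raise ValueError("inclusion_fraction must be in (0, 1]")
    graph = _build_graph(net)
    present = _present_seeds(graph, seeds)
    seed_set = set(present)
    members = set(present)
    for _ in range(expand_rounds):
        candidates = sorted(
            {nb for m in members for nb in graph.neighbors(m)} - members
        )
        added = False
        for c in candidates:
            nbrs = set(graph.neighbors(c))
            overlap = len(nbrs & members) / min(len(nbrs), len(members))
            if overlap >= inclusion_fraction or len(nbrs & seed_set) >= 2:
                members.add(c)
                added = True
        if not added:
            break
    return _induced(net, members, present)


def _cohesion(graph: nx.Graph, members: set[str]) -> float:
    w_in = 0.0
    w_out = 0.0
    for m in members:
        for nb, data in graph[m].items():
            if nb in members:
                w_in += data["weight"]  # counted twice, cancels in the ratio scale
            else:
                w_out += data["weight"]
    w_in /= 2.0
    total = w_in + w_out
    return w_in / total if total > 0 else 0.0


def gena_extract(net: EdgeList, seeds, max_size: int = 100) -> Subnetwork:
    """Greedy cohesion-maximizing extraction around seed genes.

    Cohesion of a node set is W_in/(W_in + W_out), with W_in the total edge
    weight inside the set and W_out the total weight crossing its boundary.
    The best-improving neighbour is added until no addition improves
    cohesion or ``max_size`` is reached; ties break lexicographically.
    """
    if max_size < 1:
        raise ValueError("max_size must be ≥ 1")
    graph = _build_graph(net)
    present = _present_seeds(graph, seeds)
    members = set(present)
    current = _cohesion(graph, members)
    while len(members) < max_size:
        candidates = sorted(
            {nb for m in members for nb in graph.neighbors(m)} - members
        )
        best_gain = 0.0
        best_node = None
        for c in candidates:
            gain = _cohesion(graph, members | {c}) - current
            if gain > best_gain:
                best_gain = gain
                best_node = c
        if best_node is None:
            break
        members.add(best_node)
        current += best_gain
    return _induced(net, members, present)


def write_subnetwork(sub: Subnetwork, edges_path, nodes_path, **edge_kwargs) -> None:
    """Write the induced edges (Cytoscape tab text) and a node sidecar.

    The sidecar is ``node<TAB>seed|member`` per line, marking query seeds.
    """
    from .io import write_edge_list

    write_edge_list(sub.edges, edges_path, **edge_kwargs)
    seed_set = set(sub.seeds)
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for node in sub.nodes:
            fh.write(f"{node}\t{'seed' if node in seed_set else 'member'}\n")
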