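"""Synthetic regulatory topologies, expression compendia, and the benchmark.

The generator emulates the classic synthetic-benchmark recipe for network
inference: take a curated-looking regulatory topology (here: a randomly
grown scale-free-ish DAG standing in for an E. coli-derived seed network),
sample a connected subnetwork of k genes by neighbour addition, and
simulate steady-state expression through saturating Hill kinetics with a
two-stage noise model — multiplicative lognormal "biological" noise on the
activity, then additive Gaussian "experimental" noise on the log2 scale.

The benchmark design follows the two-group sample-size sweep: Group A
compendia of 30–90 samples, Group B of 100–1000, 50-gene subnetworks, all
seven association estimators run through the full CLR pipeline and scored
by AUC against the sampled topology's undirected skeleton.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .clr import clr_transform, network_pair_scores, standardize_scores
from .association import METHODS, association_matrix
from .evaluation import roc_auc
from .io import ExpressionMatrix, _load_text

__all__ = [
    "TopologyEdge",
    "RegulatoryTopology",
    "BenchmarkResult",
    "make_seed_topology",
    "sample_subnetwork_topology",
    "simulate_expression",
    "run_benchmark",
    "read_topology",
    "write_topology",
    "GROUP_A_SIZES",
    "GROUP_B_SIZES",
]

GROUP_A_SIZES = (30, 40, 50, 60, 70, 80, 90)
GROUP_B_SIZES = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)

SIGNS = ("activate", "repress")
HILL_COEFFS = (1, 2, 4)


@dataclass
class TopologyEdge:
    """A signed directed regulatory edge with optional Hill kinetics.

    ``k`` is the half-saturation constant and ``h`` the Hill coefficient of
    the edge's transfer function; they are fixed at topology creation and
    filled in deterministically at simulation time when absent (e.g. after
    reading a plain three-column topology file).
    """

    regulator: str
    target: str
    sign: str
    k: float | None = None
    h: int | None = None

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}, got {self.sign!r}")
        if self.regulator == self.target:
            raise ValueError(f"self-regulation on {self.regulator!r}")


@dataclass
class RegulatoryTopology:
    """A signed directed regulatory network used as simulator ground truth."""

    genes: list[str]
    edges: list[TopologyEdge]

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene identifiers in topology")
        seen = set()
        for e in self.edges:
            if e.regulator not in gene_set or e.target not in gene_set:
                raise ValueError(f"edge {e.regulator}->{e.target} references unknown gene")
            key = (e.regulator, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge {e.regulator}->{e.target}")
            seen.add(key)

    @property
    def source_genes(self) -> list[str]:
        targets = {e.target for e in self.edges}
        return [g for g in self.genes if g not in targets]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def undirected_edge_set(self) -> set[tuple[str, str]]:
        """The undirected skeleton used as benchmark ground truth."""
        return {tuple(sorted((e.regulator, e.target))) for e in self.edges}


def make_seed_topology(
    n_genes: int,
    seed: int,
    repression_fraction: float = 0.3,
    source_fraction: float = 0.1,
) -> RegulatoryTopology:
    """Grow a scale-free-ish acyclic seed topology.

    Genes are laid out in a fixed order; the first ~``source_fraction`` are
    sources (no regulators).  Each later gene draws one or two regulators
    from earlier genes with probability proportional to current out-degree
    plus one (preferential attachment), which yields the heavy-tailed
    out-degree distribution characteristic of curated regulatory networks.
    About ``repression_fraction`` of edges repress.  The construction is a
    DAG whose undirected skeleton is connected, so every gene is reachable
    from a source.  Deterministic given ``seed``.
    """
    if n_genes < 20:
        raise ValueError(f"need at least 20 genes, got {n_genes}")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    n_src = max(2, math.ceil(source_fraction * n_genes))
    out_deg = np.zeros(n_genes, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    edge_set: set[tuple[int, int]] = set()

    def add_edge(r: int, t: int) -> None:
        edges.append((r, t))
        edge_set.add((r, t))
        out_deg[r] += 1

    for t in range(n_src, n_genes):
        n_parents = 1 + int(rng.random() < 0.6)
        n_parents = min(n_parents, t)
        weights = out_deg[:t] + 1.0
        parents = rng.choice(t, size=n_parents, replace=False, p=weights / weights.sum())
        for r in sorted(int(p) for p in parents):
            add_edge(r, t)

    # childless sources would be isolated; give each a random downstream target
    for s in range(n_src):
        if out_deg[s] == 0:
            choices = [t for t in range(n_src, n_genes) if (s, t) not in edge_set]
            add_edge(s, int(rng.choice(choices)))

    # stitch any remaining undirected components onto gene 0's component,
    # always via a non-source member so the source census is preserved
    g = nx.Graph()
    g.add_nodes_from(range(n_genes))
    g.add_edges_from(edges)
    comps = sorted(nx.connected_components(g), key=min)
    for comp in comps[1:]:
        t = min(x for x in comp if x >= n_src)
        add_edge(0, t)

    topo_edges = []
    for r, t in edges:
        sign = "repress" if rng.random() < repression_fraction else "activate"
        topo_edges.append(
            TopologyEdge(
                regulator=genes[r],
                target=genes[t],
                sign=sign,
                k=float(rng.uniform(0.2, 0.8)),
                h=int(rng.choice(HILL_COEFFS)),
            )
        )
    return RegulatoryTopology(genes, topo_edges)


def sample_subnetwork_topology(
    topology: RegulatoryTopology, k: int, seed: int
) -> RegulatoryTopology:
    """Sample a connected k-gene induced subnetwork by neighbour addition.

    Starting from one random gene, a uniformly random neighbour of the
    current set joins until k genes are collected; induced edges (with
    their kinetic parameters) are kept.
    """
    n = topology.n_genes
    if k < 2:
        raise ValueError(f"subnetwork size must be ≥ 2, got {k}")
    if k > n:
        raise ValueError(f"cannot sample {k} genes from a {n}-gene topology")
    if k == n:
        return RegulatoryTopology(list(topology.genes), list(topology.edges))
    rng = np.random.default_rng(seed)
    adj: dict[str, set[str]] = {g: set() for g in topology.genes}
    for e in topology.edges:
        adj[e.regulator].add(e.target)
        adj[e.target].add(e.regulator)
    chosen = {topology.genes[int(rng.integers(n))]}
    while len(chosen) < k:
        frontier = sorted({nb for g in chosen for nb in adj[g]} - chosen)
        if not frontier:  # disconnected parent topology: restart elsewhere
            frontier = sorted(set(topology.genes) - chosen)
        chosen.add(frontier[int(rng.integers(len(frontier)))])
    genes = [g for g in topology.genes if g in chosen]
    edges = [e for e in topology.edges if e.regulator in chosen and e.target in chosen]
    return RegulatoryTopology(genes, edges)


def _break_cycles(topology: RegulatoryTopology) -> list[TopologyEdge]:
    """Drop edges that close a directed cycle, in insertion order."""
    g = nx.DiGraph()
    g.add_nodes_from(topology.genes)
    kept = []
    dropped = 0
    for e in topology.edges:
        if g.has_node(e.target) and nx.has_path(g, e.target, e.regulator):
            dropped += 1
            continue
        g.add_edge(e.regulator, e.target)
        kept.append(e)
    if dropped:
        warnings.warn(f"dropped {dropped} cycle-closing edge(s)", stacklevel=3)
    return kept


def _hill(x: np.ndarray, k: float, h: int, sign: str) -> np.ndarray:
    xh = x**h
    kh = k**h
    if sign == "activate":
        return xh / (kh + xh)
    return kh / (kh + xh)


def simulate_expression(
    topology: RegulatoryTopology,
    m: int,
    bio_noise: float = 0.1,
    exp_noise: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate m steady-state expression profiles through Hill kinetics.

    Per sample, source-gene activities are drawn Uniform(0.05, 1); every
    target's activity is the product of one Hill term per regulator
    (activation x^h/(K^h + x^h), repression K^h/(K^h + x^h)).  Activities
    then receive multiplicative lognormal biological noise (sd
    ``bio_noise`` on the natural-log scale) and, after log2 transformation,
    additive Gaussian experimental noise (sd ``exp_noise``).  Noise is
    applied at the measurement stage and does not propagate through the
    cascade.  Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError(f"need at least 1 sample, got {m}")
    if bio_noise < 0 or exp_noise < 0:
        raise ValueError("noise standard deviations must be ≥ 0")
    rng = np.random.default_rng(seed)
    edges = _break_cycles(topology)
    genes = topology.genes
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    # fill in kinetic parameters for edges lacking them (file-loaded topologies)
    params = []
    for e in edges:
        k = e.k if e.k is not None else float(rng.uniform(0.2, 0.8))
        h = e.h if e.h is not None else int(rng.choice(HILL_COEFFS))
        params.append((idx[e.regulator], idx[e.target], e.sign, k, h))

    dag = nx.DiGraph()
    dag.add_nodes_from(range(n))
    dag.add_edges_from((r, t) for r, t, *_ in params)
    if not nx.is_directed_acyclic_graph(dag):  # guarded by _break_cycles
        raise RuntimeError("simulation graph is not acyclic after cycle breaking")
    order = list(nx.topological_sort(dag))

    parents: dict[int, list[tuple[int, str, float, int]]] = {i: [] for i in range(n)}
    for r, t, sign, k, h in params:
        parents[t].append((r, sign, k, h))

    activity = np.empty((n, m), dtype=np.float64)
    source_draws = rng.uniform(0.05, 1.0, size=(n, m))
    for i in order:
        if not parents[i]:
            activity[i] = source_draws[i]
        else:
            act = np.ones(m, dtype=np.float64)
            for r, sign, k, h in parents[i]:
                act *= _hill(activity[r], k, h, sign)
            activity[i] = act

    if bio_noise > 0:
        activity = activity * np.exp(bio_noise * rng.standard_normal((n, m)))
    values = np.log2(activity)
    if exp_noise > 0:
        values = values + exp_noise * rng.standard_normal((n, m))
    sample_ids = [f"S{j + 1:04d}" for j in range(m)]
    return ExpressionMatrix(list(genes), sample_ids, values)


@dataclass
class BenchmarkResult:
    """Per-replicate AUCs of the sample-size sweep, with group summaries."""

    records: pd.DataFrame = field(repr=False)

    def per_replicate(self) -> pd.DataFrame:
        return self.records.copy()

    def group_means(self) -> pd.DataFrame:
        """Mean AUC per (group, method) over all sizes and replicates."""
        return (
            self.records.groupby(["group", "method"], sort=True)["auc"]
            .mean()
            .unstack("method")
        )

    def size_means(self) -> pd.DataFrame:
        """Mean AUC per (group, size, method): one row per benchmark cell."""
        return (
            self.records.groupby(["group", "size", "method"], sort=True)["auc"]
            .agg(["mean", "count"])
            .reset_index()
        )

    def overall_means(self) -> pd.Series:
        """Mean AUC per method over every dataset in both groups."""
        return self.records.groupby("method")["auc"].mean().sort_values(ascending=False)


def run_benchmark(
    group_a_sizes=GROUP_A_SIZES,
    group_b_sizes=GROUP_B_SIZES,
    k: int = 50,
    methods=tuple(sorted(METHODS)),
    replicates: int = 20,
    seed: int = 0,
    master_genes: int = 200,
    bio_noise: float = 0.1,
    exp_noise: float = 0.1,
    mic_max_samples: int = 200,
) -> BenchmarkResult:
    """Run the two-group sample-size benchmark for the chosen estimators.

    For every (group, size, replicate): sample a fresh connected k-gene
    subnetwork of the master topology, simulate a compendium of that size,
    run each estimator through the full CLR pipeline (no threshold), and
    score the standardized pair scores by AUC against the subnetwork's
    undirected skeleton.  MIC — whose grid optimization cost grows steeply
    with m — is evaluated only for sizes ≤ ``mic_max_samples``.
    Deterministic given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be ≥ 1")
    for name in methods:
        if name not in METHODS:
            raise ValueError(
                f"unknown method {name!r}; valid methods: {', '.join(sorted(METHODS))}"
            )
    rng = np.random.default_rng(seed)
    master = make_seed_topology(master_genes, seed=int(rng.integers(2**31)))
    rows = []
    for group, sizes in (("A", tuple(group_a_sizes)), ("B", tuple(group_b_sizes))):
        for size in sizes:
            for rep in range(replicates):
                sub_seed = int(rng.integers(2**31))
                sim_seed = int(rng.integers(2**31))
                sub = sample_subnetwork_topology(master, k, seed=sub_seed)
                reference = sub.undirected_edge_set()
                expr = simulate_expression(
                    sub, size, bio_noise=bio_noise, exp_noise=exp_noise, seed=sim_seed
                )
                for name in methods:
                    if name == "mic" and size > mic_max_samples:
                        continue
                    assoc = association_matrix(expr, name)
                    z = standardize_scores(clr_transform(assoc))
                    auc = roc_auc(network_pair_scores(z), reference)
                    rows.append(
                        {
                            "group": group,
                            "size": size,
                            "replicate": rep,
                            "method": name,
                            "auc": auc,
                        }
                    )
    return BenchmarkResult(pd.DataFrame(rows))


def write_topology(topology: RegulatoryTopology, path) -> None:
    """Write ``regulator<TAB>target<TAB>sign`` lines (kinetics not persisted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in topology.edges:
            fh.write(f"{e.regulator}\t{e.target}\t{e.sign}\n")


def read_topology(source) -> RegulatoryTopology:
    """Read a three-column signed edge list; genes appear in first-seen order."""
    genes: list[str] = []
    seen: set[str] = set()
    edges = []
    for lineno, ln in enumerate(_load_text(source).splitlines(), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != 3:
            raise ValueError(f"line {lineno}: expected regulator/target/sign")
        r, t, sign = (f.strip() for f in fields)
        for g in (r, t):
            if g not in seen:
                seen.add(g)
                genes.append(g)
        edges.append(TopologyEdge(regulator=r, target=t, sign=sign))
    if not edges:
        raise ValueError("topology file contains no edges")
    return RegulatoryTopology(genes, edges)
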