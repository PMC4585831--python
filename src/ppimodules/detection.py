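"""Topological module detection and partition quality.

Three pluggable detectors partition the PPI graph into disjoint
topological modules:

``default``
    Greedy multi-level modularity maximization (Louvain-style local
    moving and aggregation) followed by a deterministic single-node
    refinement pass that accepts moves which strictly raise Newman
    modularity Q.  The refinement re-attaches poorly placed nodes and
    helps retain sparse and small modules.
``mcl``
    Markov Clustering: expansion (matrix squaring) alternating with
    inflation (entrywise power and column renormalization) on the
    column-stochastic adjacency matrix with self-loops; clusters are read
    from attractor rows.
``rwr``
    Random walk with restart from a seed set: each node is assigned to
    the seed with maximal stationary affinity.

Partitions are scored with Newman modularity
``Q = sum_c [ L_c / m - (d_c / 2m)^2 ]`` where ``m`` is the total edge
count, ``L_c`` the number of intra-module edges of module ``c`` and
``d_c`` the summed degree of its nodes.  Nodes outside every module
contribute as singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ppimodules.netio import ProteinNetwork

logger = logging.getLogger(__name__)

#: Module-size threshold separating large from small topological modules.
MIN_MODULE_SIZE = 3

UNASSIGNED_LABEL = "unassigned"


class ConfigurationError(ValueError):
    """Unknown detector name or invalid detector parameters."""


class DegenerateInputError(ValueError):
    """Input on which the requested quantity is undefined (e.g. no edges)."""


@dataclass(frozen=True)
class TopologicalModule:
    """A disjoint protein group found by graph clustering."""

    module_id: int
    proteins: frozenset[str]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("module must contain at least one protein")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class ModulePartition:
    """Disjoint topological modules over (a subset of) a network's nodes."""

    modules: list[TopologicalModule]
    network_ref: ProteinNetwork
    method_name: str = "default"
    #: module_id of the catch-all group for nodes unreachable from any
    #: RWR seed; None when every node was properly assigned.
    unassigned_id: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            if seen & mod.proteins:
                raise ValueError("modules must be pairwise disjoint")
            seen |= mod.proteins
        extra = seen - self.network_ref.proteins
        if extra:
            raise ValueError(f"module proteins not in network: {sorted(extra)[:5]}")

    def large_modules(self) -> list[TopologicalModule]:
        """Modules with at least :data:`MIN_MODULE_SIZE` proteins."""
        return [m for m in self.modules if len(m) >= MIN_MODULE_SIZE]

    def small_modules(self) -> list[TopologicalModule]:
        return [m for m in self.modules if len(m) < MIN_MODULE_SIZE]

    def labels(self) -> dict[str, int]:
        """protein -> module_id over all assigned nodes."""
        return {p: m.module_id for m in self.modules for p in m.proteins}


def _partition_from_groups(
    groups: list[set[str]],
    network: ProteinNetwork,
    method_name: str,
    unassigned: set[str] | None = None,
) -> ModulePartition:
    """Number groups deterministically (by size desc, then lexicographic)."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    modules = [
        TopologicalModule(module_id=i, proteins=frozenset(g))
        for i, g in enumerate(ordered)
    ]
    unassigned_id = None
    if unassigned:
        unassigned_id = len(modules)
        modules.append(
            TopologicalModule(module_id=unassigned_id, proteins=frozenset(unassigned))
        )
    return ModulePartition(
        modules=modules,
        network_ref=network,
        method_name=method_name,
        unassigned_id=unassigned_id,
    )


def modularity(network: ProteinNetwork, partition: ModulePartition) -> float:
    """Newman modularity Q of a partition.

    Nodes of the network missing from every module are treated as
    singleton modules.  Raises :class:`DegenerateInputError` on an
    edgeless network, where Q is undefined.
    """
    g = network.graph
    m = g.number_of_edges()
    if m == 0:
        raise DegenerateInputError("modularity undefined for a network with no edges")
    labels = partition.labels()
    next_id = max(labels.values(), default=-1) + 1
    for node in g.nodes:
        if node not in labels:
            labels[node] = next_id
            next_id += 1
    intra: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for u, v in g.edges:
        if labels[u] == labels[v]:
            intra[labels[u]] = intra.get(labels[u], 0) + 1
    for node, deg in g.degree:
        degsum[labels[node]] = degsum.get(labels[node], 0) + deg
    q = 0.0
    for c, d_c in degsum.items():
        q += intra.get(c, 0) / m - (d_c / (2.0 * m)) ** 2
    return q


def _canonical_graph(network: ProteinNetwork) -> nx.Graph:
    """Copy with deterministic node/edge insertion order."""
    g = nx.Graph()
    g.add_nodes_from(sorted(network.graph.nodes))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in network.graph.edges))
    return g


def _refine_partition(g: nx.Graph, groups: list[set[str]], max_passes: int = 10) -> list[set[str]]:
    """Greedy single-node moves that strictly increase Q.

    Nodes are visited in sorted order; a node moves to the adjacent
    community with the largest strictly positive modularity gain
    (ties to the lowest community index).  Deterministic.
    """
    m = g.number_of_edges()
    if m == 0:
        return groups
    comm_of = {n: i for i, grp in enumerate(groups) for n in grp}
    deg = dict(g.degree)
    degsum = [sum(deg[n] for n in grp) for grp in groups]
    two_m = 2.0 * m
    for _ in range(max_passes):
        moved = False
        for node in sorted(g.nodes):
            c_old = comm_of[node]
            k = deg[node]
            # edges from node into each adjacent community
            links: dict[int, int] = {}
            for nb in g.neighbors(node):
                links[comm_of[nb]] = links.get(comm_of[nb], 0) + 1
            base_old = links.get(c_old, 0) / m - (
                2.0 * k * (degsum[c_old] - k)
            ) / (two_m**2)
            best_gain, best_c = 0.0, c_old
            for c_new in sorted(links):
                if c_new == c_old:
                    continue
                gain = (
                    links[c_new] / m
                    - (2.0 * k * degsum[c_new]) / (two_m**2)
                    - base_old
                )
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c_new
            if best_c != c_old:
                groups[c_old].discard(node)
                groups[best_c].add(node)
                degsum[c_old] -= k
                degsum[best_c] += k
                comm_of[node] = best_c
                moved = True
        if not moved:
            break
    return [grp for grp in groups if grp]


def greedy_modularity_cluster(network: ProteinNetwork, seed: int = 0) -> ModulePartition:
    """Default detector: multi-level greedy modularity plus node-move refinement."""
    g = _canonical_graph(network)
    if g.number_of_edges() == 0:
        groups = [{n} for n in sorted(g.nodes)]
    else:
        groups = [set(c) for c in nx.community.louvain_communities(g, seed=seed)]
        groups = _refine_partition(g, groups)
    return _partition_from_groups(groups, network, "default")


def mcl_cluster(
    network: ProteinNetwork,
    inflation: float = 2.0,
    max_iters: int = 100,
    prune_tol: float = 1e-8,
) -> ModulePartition:
    """Markov Clustering of the network.

    Self-loops of weight 1 are added before column normalization.  The
    iteration alternates expansion (matrix self-multiplication) and
    inflation (entrywise power ``inflation`` then column renormalization),
    pruning entries below ``prune_tol``, and stops when the largest change
    between successive matrices falls below ``prune_tol`` or after
    ``max_iters`` iterations (with a logged warning).  Clusters are read
    from attractor rows; a node claimed by several attractors goes to the
    lowest-numbered cluster.
    """
    if inflation <= 1:
        raise ConfigurationError("MCL inflation must be > 1")
    nodes = sorted(network.graph.nodes)
    if not nodes:
        raise DegenerateInputError("cannot cluster an empty network")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    mat = np.eye(n)
    for u, v in network.graph.edges:
        mat[index[u], index[v]] = 1.0
        mat[index[v], index[u]] = 1.0
    mat /= mat.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iters):
        new = mat @ mat
        new = np.power(new, inflation)
        new[new < prune_tol] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if np.abs(new - mat).max() < prune_tol:
            mat = new
            converged = True
            break
        mat = new
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iters)
    # attractors: nodes with positive mass on their own row
    attractors = [i for i in range(n) if mat[i, i] > prune_tol]
    assigned: dict[int, int] = {}
    clusters: list[set[str]] = []
    for a in attractors:
        members = set(np.nonzero(mat[a] > prune_tol)[0])
        members.add(a)
        overlapping = sorted({assigned[i] for i in members if i in assigned})
        if overlapping:
            target = overlapping[0]
        else:
            target = len(clusters)
            clusters.append(set())
        for i in members:
            if i not in assigned:
                assigned[i] = target
                clusters[target].add(nodes[i])
    for i in range(n):  # numerical stragglers become singletons
        if i not in assigned:
            clusters.append({nodes[i]})
    return _partition_from_groups([c for c in clusters if c], network, "mcl")


def rwr_cluster(
    network: ProteinNetwork,
    seeds: set[str],
    restart: float = 0.4,
    tol: float = 1e-10,
    max_iters: int = 10000,
) -> ModulePartition:
    """Random-walk-with-restart clustering from a seed set.

    For each seed ``s`` the stationary affinity vector of
    ``p <- (1 - restart) * W p + restart * e_s`` is computed (``W`` the
    column-normalized adjacency), iterating until the L1 change drops
    below ``tol``.  Each node is assigned to the seed of maximal
    affinity, ties going to the lexicographically smaller seed.  Nodes
    unreachable from every seed land in a designated unassigned module.
    """
    if not seeds:
        raise ConfigurationError("RWR requires a non-empty seed set")
    missing = set(seeds) - network.graph.nodes.keys()
    if missing:
        raise ConfigurationError(f"seeds not in network: {sorted(missing)[:5]}")
    if not 0.0 < restart < 1.0:
        raise ConfigurationError("restart probability must be in (0, 1)")
    nodes = sorted(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v in network.graph.edges:
        adj[index[u], index[v]] = 1.0
        adj[index[v], index[u]] = 1.0
    colsum = adj.sum(axis=0, keepdims=True)
    colsum[colsum == 0] = 1.0
    w = adj / colsum
    seed_list = sorted(seeds)
    affinity = np.zeros((len(seed_list), n))
    for si, s in enumerate(seed_list):
        e = np.zeros(n)
        e[index[s]] = 1.0
        p = e.copy()
        for _ in range(max_iters):
            p_new = (1.0 - restart) * (w @ p) + restart * e
            if np.abs(p_new - p).sum() < tol:
                p = p_new
                break
            p = p_new
        affinity[si] = p
    groups: list[set[str]] = [set() for _ in seed_list]
    unassigned: set[str] = set()
    for node in nodes:
        col = affinity[:, index[node]]
        if col.max() <= 0.0:
            unassigned.add(node)
            continue
        groups[int(np.argmax(col))].add(node)  # argmax ties -> first = lexicographic
    if unassigned:
        logger.info("%d nodes unreachable from every seed", len(unassigned))
    return _partition_from_groups(
        [g for g in groups if g], network, "rwr", unassigned=unassigned
    )


def detect_modules(
    network: ProteinNetwork,
    method: str = "default",
    params: dict | None = None,
    seed: int = 0,
) -> ModulePartition:
    """Partition the network with the named detector.

    ``method`` is one of ``default``, ``mcl`` or ``rwr``.  All detectors
    are deterministic given ``seed``; the seed only matters for ``rwr``
    when no explicit seed nodes are supplied (a random sample of
    ``round(sqrt(n))`` nodes is then drawn).
    """
    params = dict(params or {})
    if network.n_proteins == 0:
        raise DegenerateInputError("cannot detect modules in an empty network")
    if method == "default":
        return greedy_modularity_cluster(network, seed=seed)
    if method == "mcl":
        return mcl_cluster(network, **params)
    if method == "rwr":
        seed_nodes = params.pop("seeds", None)
        if not seed_nodes:
            rng = np.random.default_rng(seed)
            nodes = sorted(network.graph.nodes)
            k = max(2, int(round(np.sqrt(len(nodes)))))
            k = min(k, len(nodes))
            seed_nodes = set(rng.choice(nodes, size=k, replace=False).tolist())
        return rwr_cluster(network, seeds=set(seed_nodes), **params)
    raise ConfigurationError(f"unknown detector {method!r}")


def write_partition(partition: ModulePartition, path) -> None:
    """Write (protein_id, module_id, method) TSV, sorted for stable output."""
    rows = sorted(
        (p, m.module_id, partition.method_name)
        for m in partition.modules
        for p in m.proteins
    )
    pd.DataFrame(rows, columns=["protein_id", "module_id", "method"]).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path, network: ProteinNetwork) -> ModulePartition:
    """Read an externally computed clustering (e.g. real NeTA output)."""
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "module_id": int})
    groups: dict[int, set[str]] = {}
    for p, mid in zip(table["protein_id"], table["module_id"]):
        groups.setdefault(int(mid), set()).add(str(p))
    method = str(table["method"].iloc[0]) if "method" in table and len(table) else "external"
    modules = [
        TopologicalModule(module_id=mid, proteins=frozenset(g))
        for mid, g in sorted(groups.items())
    ]
    return ModulePartition(modules=modules, network_ref=network, method_name=method)
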