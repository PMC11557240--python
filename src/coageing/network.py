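"""Directed interdependency networks.

A node *depends on* its dependees (its inputs) and is depended upon by its
dependents.  During ageing, a functional node fails when strictly more than
half of its dependees are dysfunctional, so the dependee list of every node
is the unit of fragility here.

Networks are grown one node at a time by uniform random attachment: each new
node connects inwards to one uniformly chosen existing node (gaining a
dependee) and outwards to another independently chosen existing node (gaining
a dependent).  This guarantees every node is reachable from the seed in both
directions, so no disconnected sub-network can arise at growth time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DependencyNetwork",
    "grow_network",
    "replicate_topology",
    "single_node_network",
    "write_edgelist",
    "read_edgelist",
]


@dataclass
class DependencyNetwork:
    """Directed dependency topology.

    ``dependees[i]`` lists the nodes that node ``i`` depends on;
    ``dependents[i]`` lists the nodes that depend on node ``i``.  The two
    adjacency structures are exact inverses of each other and contain no
    self-edges.
    """

    n_nodes: int
    dependees: list[list[int]]
    dependents: list[list[int]]
    seed_size: int = 2

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("a network needs at least one node")
        if len(self.dependees) != self.n_nodes or len(self.dependents) != self.n_nodes:
            raise ValueError("adjacency lists must have one entry per node")

    # -- derived structure -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return sum(len(d) for d in self.dependees)

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield (dependee, dependent) pairs."""
        for node, deps in enumerate(self.dependees):
            for dep in deps:
                yield (dep, node)

    def dependee_counts(self) -> np.ndarray:
        return np.array([len(d) for d in self.dependees], dtype=np.int32)

    def dependee_matrix(self) -> sp.csr_array:
        """Sparse ``M`` with ``M[i, j] = 1`` iff ``j`` is a dependee of ``i``."""
        rows, cols = [], []
        for node, deps in enumerate(self.dependees):
            rows.extend([node] * len(deps))
            cols.extend(deps)
        data = np.ones(len(rows), dtype=np.int32)
        return sp.csr_array(
            (data, (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64))),
            shape=(self.n_nodes, self.n_nodes),
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        seen = set()
        for node, deps in enumerate(self.dependees):
            if node in deps:
                raise ValueError(f"self-edge at node {node}")
            if len(set(deps)) != len(deps):
                raise ValueError(f"duplicate dependee at node {node}")
            for dep in deps:
                if node not in self.dependents[dep]:
                    raise ValueError("dependees/dependents are not inverse")
                seen.add((dep, node))
        n_inv = sum(len(d) for d in self.dependents)
        if n_inv != len(seen):
            raise ValueError("dependents contain edges absent from dependees")
        for node in range(self.seed_size, self.n_nodes):
            if not any(d < node for d in self.dependees[node]):
                raise ValueError(f"node {node} has no lower-id dependee")
            if not any(d < node for d in self.dependents[node]):
                raise ValueError(f"node {node} has no lower-id dependent")
        if self.n_nodes > 1 and not self._weakly_connected():
            raise ValueError("network is not weakly connected")

    def _weakly_connected(self) -> bool:
        adj = [set(a) | set(b) for a, b in zip(self.dependees, self.dependents)]
        seen = {0}
        stack = [0]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == self.n_nodes


def grow_network(n_nodes: int, rng_seed: int) -> DependencyNetwork:
    """Grow a dependency network by uniform random in/out attachment.

    Starts from a two-node seed in which each node depends on the other, then
    adds nodes one at a time.  Node ``k`` picks one uniform existing node as
    its dependee (inward link) and, independently, one as its dependent
    (outward link); the two picks may coincide, producing a 2-cycle.
    Self-edges and parallel edges are impossible by construction (the new node
    carries exactly one fresh edge in each direction).

    Deterministic given ``rng_seed``; node ids are 0..n_nodes-1 in insertion
    order.
    """
    if n_nodes < 2:
        raise ValueError("grow_network requires n_nodes >= 2")
    rng = np.random.default_rng(rng_seed)
    dependees: list[list[int]] = [[1], [0]]
    dependents: list[list[int]] = [[1], [0]]
    for k in range(2, n_nodes):
        inward = int(rng.integers(k))   # k depends on `inward`
        outward = int(rng.integers(k))  # `outward` depends on k
        dependees.append([inward])
        dependents[inward].append(k)
        dependees[outward].append(k)
        dependents.append([outward])
    return DependencyNetwork(n_nodes, dependees, dependents, seed_size=2)


def single_node_network() -> DependencyNetwork:
    """Degenerate one-node network (no edges, hence no propagation).

    Useful as an analytically solvable limit: with repair 0 and no antagonist
    the lifespan is geometric with the intrinsic damage rate.
    """
    return DependencyNetwork(1, [[]], [[]], seed_size=1)


def replicate_topology(
    net: DependencyNetwork,
    mode: str,
    cohort_size: int,
    rng_seed: int = 0,
) -> list[DependencyNetwork]:
    """Produce the per-individual topologies for a cohort.

    ``mode="shared"`` returns ``cohort_size`` references to the one topology
    (all members of a species structurally identical); ``mode="randomized"``
    regrows an independent topology per individual with the same node count,
    deterministically from ``rng_seed``.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if mode == "shared":
        return [net] * cohort_size
    if mode == "randomized":
        seeds = np.random.default_rng(rng_seed).integers(2**31, size=cohort_size)
        return [grow_network(net.n_nodes, int(s)) for s in seeds]
    raise ValueError(f"unknown topology mode {mode!r}")


def write_edgelist(net: DependencyNetwork, path) -> None:
    """Write one ``dependee<TAB>dependent`` pair per line, 0-based ids."""
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={net.n_nodes} seed_size={net.seed_size}\n")
        for dep, node in net.edges():
            fh.write(f"{dep}\t{node}\n")


def read_edgelist(path) -> DependencyNetwork:
    n_nodes = None
    seed_size = 2
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "n_nodes":
                        n_nodes = int(val)
                    elif key == "seed_size":
                        seed_size = int(val)
                continue
            a, b = line.split()
            edges.append((int(a), int(b)))
    if n_nodes is None:
        n_nodes = 1 + max(max(e) for e in edges)
    dependees: list[list[int]] = [[] for _ in range(n_nodes)]
    dependents: list[list[int]] = [[] for _ in range(n_nodes)]
    for dep, node in edges:
        dependees[node].append(dep)
        dependents[dep].append(node)
    return DependencyNetwork(n_nodes, dependees, dependents, seed_size=seed_size)
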