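"""Minimum spanning tree construction (Kruskal on 1−PLI) and tree metrics.

Metric conventions:

* degree K_i — edge count at node i
* betweenness BC_i — ordered pairs of other nodes whose unique tree path
  crosses i, normalized by (N−1)(N−2); BC of the star center is 1
* eccentricity E_i — longest hop distance from i, normalized by M = N−1
* diameter D — max hop distance / M
* leaf fraction Lf — L/M with L the number of degree-1 nodes
* tree hierarchy Th — L/(2·M·BC_max)
* kappa — ⟨k²⟩/⟨k⟩, the degree-distribution divergence
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, mean_pli
from .exceptions import ContentError, MetricUndefinedError, ParameterError


@dataclass
class WeightMatrix:
    """Symmetric dissimilarity weights w = 1 − PLI; diagonal ignored."""

    values: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContentError("weight matrix must be square")
        # equal_nan: non-finite entries are caught later with a clearer error
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ContentError("weight matrix must be symmetric")
        self.values = v


@dataclass
class SpanningTree:
    """An N-node, (N−1)-edge connected acyclic subgraph."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    node_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ContentError(
                f"tree on {self.n_nodes} nodes must have {self.n_nodes - 1} edges, "
                f"got {len(self.edges)}"
            )
        if not self._connected():
            raise ContentError("edge set does not connect all nodes")

    def _connected(self) -> bool:
        adj = self.adjacency()
        seen = {0}
        queue = deque([0])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return len(seen) == self.n_nodes

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


@dataclass
class NodeMetrics:
    degree: np.ndarray  # K_i, int
    betweenness: np.ndarray  # BC_i in [0, 1]
    eccentricity: np.ndarray  # E_i, hop ecc / M


@dataclass
class TreeMetrics:
    degree_max: float
    bc_max: float
    diameter: float
    ecc_mean: float
    leaf_fraction: float
    tree_hierarchy: float
    kappa: float
    mean_pli: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_pli": self.mean_pli,
            "bc_max": self.bc_max,
            "diameter": self.diameter,
            "eccentricity": self.ecc_mean,
            "degree_max": self.degree_max,
            "leaf_fraction": self.leaf_fraction,
            "tree_hierarchy": self.tree_hierarchy,
            "kappa": self.kappa,
        }


#: Metric names in reporting order.
METRIC_NAMES = (
    "mean_pli", "bc_max", "diameter", "eccentricity",
    "degree_max", "leaf_fraction", "tree_hierarchy", "kappa",
)


def to_weights(cm: ConnectivityMatrix) -> WeightMatrix:
    """Transform PLI to dissimilarity: w_ij = 1 − PLI_ij."""
    values = 1.0 - cm.values
    np.fill_diagonal(values, 0.0)
    return WeightMatrix(values=values, channel_labels=list(cm.channel_labels))


class _DisjointSet:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def kruskal_mst(wm: WeightMatrix) -> SpanningTree:
    """Kruskal's algorithm: scan edges in ascending weight, skip cycle-formers.

    Equal-weight edges are ordered lexicographically by (i, j) so degenerate
    inputs produce a bit-reproducible tree.
    """
    n = wm.values.shape[0]
    if n < 2:
        raise ParameterError("MST needs at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    weights = wm.values[iu, ju]
    if not np.all(np.isfinite(weights)):
        raise ParameterError("non-finite edge weight in weight matrix")
    order = np.lexsort((ju, iu, weights))

    dsu = _DisjointSet(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j, w = int(iu[k]), int(ju[k]), float(weights[k])
        if dsu.union(i, j):
            edges.append((i, j, w))
            if len(edges) == n - 1:
                break
    return SpanningTree(n_nodes=n, edges=edges, node_labels=list(wm.channel_labels))


def _distances(tree: SpanningTree, weighted: bool = False) -> np.ndarray:
    """All-pairs tree distances via BFS from every node.

    Hop counts by default; with ``weighted`` the unique path's edge weights
    are summed instead.
    """
    n = tree.n_nodes
    weights: dict[tuple[int, int], float] = {}
    for i, j, w in tree.edges:
        weights[(i, j)] = weights[(j, i)] = w if weighted else 1.0
    adj = tree.adjacency()
    dist = np.full((n, n), -1.0)
    for source in range(n):
        dist[source, source] = 0.0
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if dist[source, v] < 0:
                    dist[source, v] = dist[source, u] + weights[(u, v)]
                    queue.append(v)
    return dist


def _subtree_betweenness(tree: SpanningTree) -> np.ndarray:
    """BC via component sizes: a pair (h, j) routes through i iff h and j
    fall in different components of the tree with i removed."""
    n = tree.n_nodes
    adj = tree.adjacency()
    # iterative post-order from root 0 to get subtree sizes
    parent = [-1] * n
    order: list[int] = []
    stack = [0]
    seen = [False] * n
    seen[0] = True
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    size = [1] * n
    for u in reversed(order):
        if parent[u] >= 0:
            size[parent[u]] += size[u]

    denom = (n - 1) * (n - 2)
    bc = np.zeros(n)
    for i in range(n):
        comp_sizes = [size[v] for v in adj[i] if parent[v] == i]
        if parent[i] >= 0:
            comp_sizes.append(n - 1 - sum(comp_sizes))
        same = sum(s * (s - 1) for s in comp_sizes)
        bc[i] = (denom - same) / denom
    return bc


def node_metrics(t: SpanningTree, distance: str = "hops") -> NodeMetrics:
    """Degree, normalized betweenness and normalized eccentricity."""
    if distance not in ("hops", "weighted"):
        raise ParameterError(f"unknown distance convention {distance!r}")
    if t.n_nodes < 3:
        raise MetricUndefinedError("betweenness undefined for trees with < 3 nodes")
    n, m = t.n_nodes, t.n_nodes - 1
    degree = np.zeros(n, dtype=np.int64)
    for i, j, _ in t.edges:
        degree[i] += 1
        degree[j] += 1
    dist = _distances(t, weighted=distance == "weighted")
    ecc = dist.max(axis=1) / m
    bc = _subtree_betweenness(t)
    return NodeMetrics(degree=degree, betweenness=bc, eccentricity=ecc)


def tree_metrics(
    t: SpanningTree,
    nm: NodeMetrics,
    mean_pli: float = float("nan"),
    distance: str = "hops",
) -> TreeMetrics:
    """The seven tree-level metrics plus the carried mean PLI."""
    m = t.n_nodes - 1
    degree = nm.degree.astype(np.float64)
    leaves = int((nm.degree == 1).sum())
    bc_max = float(nm.betweenness.max())
    if bc_max == 0:
        raise MetricUndefinedError("tree hierarchy undefined when BC_max = 0")
    dist = _distances(t, weighted=distance == "weighted")
    return TreeMetrics(
        degree_max=float(degree.max()),
        bc_max=bc_max,
        diameter=float(dist.max()) / m,
        ecc_mean=float(nm.eccentricity.mean()),
        leaf_fraction=leaves / m,
        tree_hierarchy=leaves / (2.0 * m * bc_max),
        kappa=float((degree**2).mean() / degree.mean()),
        mean_pli=mean_pli,
    )


def plot_tree(
    t: SpanningTree,
    positions: np.ndarray | None = None,
    path: str | None = None,
    ax=None,
):
    """2-D sensor-layout edge plot of a spanning tree (convenience output).

    ``positions`` is (n_nodes, 2); without it, nodes are placed on a circle.
    Edge colour encodes 1 − weight (stronger coupling drawn darker).
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if positions is None:
        angles = 2 * np.pi * np.arange(t.n_nodes) / t.n_nodes
        positions = np.column_stack([np.cos(angles), np.sin(angles)])
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (t.n_nodes, 2):
        raise ParameterError("positions must be (n_nodes, 2)")

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for i, j, w in t.edges:
        strength = np.clip(1.0 - w, 0.0, 1.0)
        ax.plot(
            positions[[i, j], 0],
            positions[[i, j], 1],
            color=str(0.85 * (1.0 - strength)),
            lw=0.5 + 2.5 * strength,
            zorder=1,
        )
    ax.scatter(positions[:, 0], positions[:, 1], s=18, color="tab:red", zorder=2)
    for idx, label in enumerate(t.node_labels):
        ax.annotate(label, positions[idx], fontsize=5, ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def metrics_for_subject(cm: ConnectivityMatrix, distance: str = "hops") -> TreeMetrics:
    """Full composition: weights → Kruskal MST → node metrics → tree metrics."""
    tree = kruskal_mst(to_weights(cm))
    nm = node_metrics(tree, distance=distance)
    return tree_metrics(tree, nm, mean_pli=mean_pli(cm), distance=distance)
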