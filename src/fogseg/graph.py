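"""Skeleton graph for the 9-marker lower-limb configuration.

The spatial graph convolution operates on a small anatomical graph over the
selected markers.  The neighbor set of every node (its 1-hop neighborhood
including a self-loop) is split into three partitions following the spatial
partitioning strategy used for skeleton action recognition:

* **root** — the node itself and neighbors at the same hop distance from the
  body's gravity-center node,
* **centripetal** — neighbors closer to the center,
* **centrifugal** — neighbors farther from the center.

Each binary partition matrix is then row-degree normalized (``Λ_p^{-1} A_p``);
rows with zero degree are left zero.  For the lower-limb marker set the
center node is the sacrum (mid-PSIS), the trunk-most marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque

import numpy as np

__all__ = [
    "SkeletonGraph",
    "build_graph",
    "partition_adjacency",
    "default_graph",
    "DEFAULT_NODE_NAMES",
    "DEFAULT_EDGES",
]

#: Canonical 9-marker lower-limb configuration, in graph-index order:
#: sacrum (mid-PSIS), left/right ASIS, left/right lateral femoral condyle,
#: left/right lateral malleolus, left/right second metatarsal head.
DEFAULT_NODE_NAMES = (
    "SACR", "LASI", "RASI", "LKNE", "RKNE", "LANK", "RANK", "LTOE", "RTOE",
)

#: Anatomical chains: pelvis triangle then each leg from hip to toe.
DEFAULT_EDGES = (
    ("SACR", "LASI"), ("SACR", "RASI"),
    ("LASI", "LKNE"), ("LKNE", "LANK"), ("LANK", "LTOE"),
    ("RASI", "RKNE"), ("RKNE", "RANK"), ("RANK", "RTOE"),
)


class GraphConnectivityError(ValueError):
    """Raised when the skeleton graph is not connected."""


@dataclass
class SkeletonGraph:
    """Node set, edges, hop distances and the P=3 partitioned adjacency."""

    node_names: tuple
    edges: frozenset          # of frozenset({i, j}) index pairs
    center_node: int
    hop_distance: np.ndarray = field(repr=False)   # [N, N] int
    partitions: np.ndarray = field(repr=False)     # [3, N, N] normalized

    @property
    def num_nodes(self) -> int:
        return len(self.node_names)

    def adjacency(self) -> np.ndarray:
        """Binary adjacency with self-loops."""
        n = self.num_nodes
        a = np.eye(n)
        for e in self.edges:
            i, j = tuple(e)
            a[i, j] = a[j, i] = 1.0
        return a


def _bfs_hops(n: int, neighbors) -> np.ndarray:
    hops = np.full((n, n), -1, dtype=int)
    for src in range(n):
        hops[src, src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v in neighbors[u]:
                if hops[src, v] < 0:
                    hops[src, v] = hops[src, u] + 1
                    q.append(v)
    return hops


def build_graph(node_names=DEFAULT_NODE_NAMES, edges=None,
                center_node=0) -> SkeletonGraph:
    """Construct a :class:`SkeletonGraph` and its partitioned adjacency.

    Parameters
    ----------
    node_names : ordered node labels (graph indices follow this order).
    edges : iterable of edges given as index pairs or name pairs; defaults
        to the anatomical chains of the 9-marker configuration.
    center_node : index or name of the gravity-center reference node.

    Raises
    ------
    GraphConnectivityError
        If the resulting undirected graph is not connected.
    """
    node_names = tuple(node_names)
    n = len(node_names)
    index = {name: i for i, name in enumerate(node_names)}
    if edges is None:
        if node_names != tuple(DEFAULT_NODE_NAMES):
            raise ValueError("a custom node list requires an explicit edge list")
        edges = DEFAULT_EDGES
    if isinstance(center_node, str):
        center_node = index[center_node]
    if not 0 <= center_node < n:
        raise ValueError(f"center node index {center_node} out of range")

    pairs = set()
    for e in edges:
        i, j = e
        if isinstance(i, str):
            i = index[i]
        if isinstance(j, str):
            j = index[j]
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge {e!r} references an invalid node index")
        if i == j:
            continue
        pairs.add(frozenset((i, j)))

    neighbors = [[] for _ in range(n)]
    for e in pairs:
        i, j = tuple(e)
        neighbors[i].append(j)
        neighbors[j].append(i)
    hops = _bfs_hops(n, neighbors)
    if (hops < 0).any():
        raise GraphConnectivityError("skeleton graph is not connected")

    graph = SkeletonGraph(node_names=node_names, edges=frozenset(pairs),
                          center_node=center_node, hop_distance=hops,
                          partitions=np.zeros((3, n, n)))
    graph.partitions = partition_adjacency(graph)
    return graph


def partition_adjacency(graph: SkeletonGraph) -> np.ndarray:
    """Root / centripetal / centrifugal partition matrices, row-normalized.

    For every ordered pair ``(i, j)`` with ``hop(i, j) <= 1`` (the 1-hop
    neighborhood with self-loops), the entry is assigned to exactly one of
    the three partitions by comparing the hop distances of ``i`` and ``j``
    to the center node.  Each binary partition is then normalized by its
    per-row degree; the three un-normalized matrices sum to A + I.
    """
    n = graph.num_nodes
    hops = graph.hop_distance
    d_center = hops[:, graph.center_node]
    raw = np.zeros((3, n, n))
    for i in range(n):
        for j in range(n):
            if hops[i, j] > 1:
                continue
            if d_center[j] == d_center[i]:
                raw[0, i, j] = 1.0
            elif d_center[j] < d_center[i]:
                raw[1, i, j] = 1.0
            else:
                raw[2, i, j] = 1.0
    out = np.zeros_like(raw)
    for p in range(3):
        deg = raw[p].sum(axis=1)
        nz = deg > 0
        out[p][nz] = raw[p][nz] / deg[nz, None]
    return out


def default_graph() -> SkeletonGraph:
    """The canonical 9-marker lower-limb graph (center = sacrum)."""
    return build_graph()


def graph_from_spec(path) -> SkeletonGraph:
    """Build a graph from a YAML/JSON specification file.

    Expected keys: ``nodes`` (ordered name list), ``edges`` (list of
    two-name pairs), ``center`` (node name).
    """
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    for key in ("nodes", "edges", "center"):
        if key not in spec:
            raise ValueError(f"graph spec is missing the {key!r} key")
    return build_graph(node_names=spec["nodes"],
                       edges=[tuple(e) for e in spec["edges"]],
                       center_node=spec["center"])
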