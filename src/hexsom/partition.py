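"""Partition a trained map into contiguous gene meta-clusters.

Seeds are the local minima of a per-node scalar field (by default the map
distance / U-matrix, whose minima mark cluster interiors).  The remaining
nodes are then grouped either with the nearest seed in input space
("nearest", not guaranteed contiguous) or by greedy region growing over the
map adjacency ("grow", every meta-cluster is a connected patch of the map).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hexgrid import HexMapSpec
from .mapstats import NodeScalarField, umatrix
from .trainer import Codebook

__all__ = ["MetaClustering", "find_seeds", "partition_nearest", "partition_grow",
           "partition_map"]


@dataclass
class MetaClustering:
    """Per-node meta-cluster labels (1..K) with one seed node per cluster."""

    labels: np.ndarray
    seeds: list[int]
    method: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > len(self.seeds):
            raise ValueError("labels must lie in 1..K")
        for c, s in enumerate(self.seeds, start=1):
            if self.labels[s - 1] != c:
                raise ValueError(f"seed {s} must carry its own cluster label {c}")

    @property
    def n_clusters(self) -> int:
        return len(self.seeds)

    def gene_labels(self, bmu: np.ndarray) -> np.ndarray:
        """Meta-cluster label per gene, via each gene's BMU node."""
        return self.labels[np.asarray(bmu, dtype=int) - 1]


def find_seeds(field: NodeScalarField, spec: HexMapSpec | None = None) -> list[int]:
    """Local minima of a node field, one representative per equal-value plateau.

    A plateau (connected set of nodes sharing one value) is a minimum when no
    adjacent outside node has a smaller value; its lowest-index member is the
    seed.  At least one seed always exists (the global-minimum plateau).
    """
    spec = spec or field.spec
    v = field.values
    M = spec.node_count
    seen = np.zeros(M, dtype=bool)
    seeds: list[int] = []
    for start in range(M):
        if seen[start]:
            continue
        # flood-fill the equal-value plateau containing `start`
        plateau = [start]
        seen[start] = True
        stack = [start]
        is_min = True
        while stack:
            j = stack.pop()
            for n in spec.adjacency[j]:
                n0 = n - 1
                if v[n0] == v[j]:
                    if not seen[n0]:
                        seen[n0] = True
                        plateau.append(n0)
                        stack.append(n0)
                elif v[n0] < v[j]:
                    is_min = False
        if is_min:
            seeds.append(min(plateau) + 1)
    return sorted(seeds)


def partition_nearest(codebook: Codebook, seeds: list[int]) -> MetaClustering:
    """Label every node with the input-space-nearest seed prototype.

    Ties go to the lowest seed index.  Clusters need not be contiguous on
    the map.
    """
    _check_seeds(codebook.spec, seeds)
    P = codebook.prototypes
    S = P[[s - 1 for s in seeds]]
    d = np.linalg.norm(P[:, None, :] - S[None, :, :], axis=2)
    labels = np.argmin(d, axis=1) + 1  # argmin takes the first (lowest) seed on ties
    for c, s in enumerate(seeds, start=1):
        labels[s - 1] = c
    return MetaClustering(labels=labels, seeds=list(seeds), method="nearest")


def partition_grow(
    codebook: Codebook, spec: HexMapSpec | None = None, seeds: list[int] | None = None
) -> MetaClustering:
    """Greedy region growing from the seeds, guaranteeing contiguity.

    Each cluster starts at its seed.  Repeatedly, over every pair of an
    unassigned node u adjacent (on the map) to a node already in cluster c,
    the pair with the smallest input-space distance between u's prototype and
    c's seed prototype is assigned; ties break on the lower node index, then
    the lower cluster id.  Terminates with all nodes assigned and every
    cluster connected under the map adjacency.
    """
    spec = spec or codebook.spec
    if seeds is None:
        seeds = find_seeds(umatrix(codebook), spec)
    _check_seeds(spec, seeds)
    P = codebook.prototypes
    M = spec.node_count
    K = len(seeds)
    seed_proto = P[[s - 1 for s in seeds]]
    # distance of every node's prototype to every seed prototype
    d = np.linalg.norm(P[:, None, :] - seed_proto[None, :, :], axis=2)
    labels = np.zeros(M, dtype=int)
    for c, s in enumerate(seeds, start=1):
        labels[s - 1] = c
    import heapq

    heap: list[tuple[float, int, int]] = []
    def push_frontier(assigned: int) -> None:
        c = labels[assigned]
        for n in spec.adjacency[assigned]:
            n0 = n - 1
            if labels[n0] == 0:
                heapq.heappush(heap, (d[n0, c - 1], n0, c))

    for s in seeds:
        push_frontier(s - 1)
    remaining = M - K
    while remaining:
        dist, u, c = heapq.heappop(heap)
        if labels[u] != 0:
            continue  # stale entry
        labels[u] = c
        remaining -= 1
        push_frontier(u)
    return MetaClustering(labels=labels, seeds=list(seeds), method="grow")


def partition_map(
    codebook: Codebook,
    field: NodeScalarField | None = None,
    method: str = "grow",
) -> MetaClustering:
    """Seed from a field (default: the U-matrix) and partition the map."""
    field = field or umatrix(codebook)
    seeds = find_seeds(field, codebook.spec)
    if method == "grow":
        return partition_grow(codebook, codebook.spec, seeds)
    if method == "nearest":
        return partition_nearest(codebook, seeds)
    raise ValueError(f"unknown partition method {method!r}")


def _check_seeds(spec: HexMapSpec, seeds: list[int]) -> None:
    if not seeds:
        raise ValueError("seeds must be non-empty")
    for s in seeds:
        spec._check_index(s)
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
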