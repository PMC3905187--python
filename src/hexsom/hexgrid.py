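"""Supra-hexagonal lattice: node numbering, geometry and adjacency.

The map is a bounded hexagonal disc built from concentric circles of small
hexagons around a centre node.  Circle 1 is the centre alone; circle k >= 2
contains 6*(k-1) hexagons, so a map of radius r has 1 + 3*r*(r-1) nodes.
Nodes are numbered from 1 at the centre, circle by circle outward; within a
circle numbering starts at the cell on the positive-x axis and proceeds
anti-clockwise.

Cells are addressed with axial coordinates (q, r) and embedded in the plane
"pointy-top": x = q + r/2, y = r*sqrt(3)/2, which puts adjacent hexagons at
Cartesian distance exactly 1.  The lattice is a bounded disc — there is no
wrap-around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HexCoord",
    "HexMapSpec",
    "node_count",
    "build_map",
    "coord_to_cartesian",
    "hex_distance",
    "output_distance",
    "export_map_spec",
]

SQRT3_2 = math.sqrt(3.0) / 2.0

# Axial steps taken anti-clockwise when walking a circle that starts on the
# positive-x axis: NW, W, SW, SE, E, NE.
_RING_DIRECTIONS = ((-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1))
_NEIGHBOR_STEPS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


@dataclass(frozen=True)
class HexCoord:
    """Axial hexagonal coordinate (column q, row r)."""

    q: int
    r: int

    def distance_to_origin(self) -> int:
        return (abs(self.q) + abs(self.r) + abs(self.q + self.r)) // 2


def _check_radius(radius: int) -> int:
    if isinstance(radius, bool) or not isinstance(radius, (int, np.integer)):
        raise ValueError(f"radius must be an integer, got {radius!r}")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    return int(radius)


def node_count(radius: int) -> int:
    """Number of nodes of a supra-hexagonal map with the given radius.

    The radius counts concentric circles including the centre, so
    ``node_count(1) == 1`` and ``node_count(8) == 169``.
    """
    radius = _check_radius(radius)
    return 1 + 3 * radius * (radius - 1)


def coord_to_cartesian(c: HexCoord) -> tuple[float, float]:
    """Pointy-top planar embedding; adjacent cells sit at distance 1."""
    return (c.q + c.r / 2.0, c.r * SQRT3_2)


def hex_distance(a: HexCoord, b: HexCoord) -> int:
    """Hexagonal (cube) lattice distance between two axial cells."""
    dq, dr = a.q - b.q, a.r - b.r
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


@dataclass
class HexMapSpec:
    """The supra-hexagonal lattice: indexing, geometry and adjacency.

    Attributes
    ----------
    radius:
        Number of concentric circles, centre counted as circle 1.
    coords:
        List of :class:`HexCoord`, position k holds node index k+1.
    xy:
        ``(node_count, 2)`` float array of Cartesian node positions.
    adjacency:
        Per-node sorted tuples of adjacent node indices (1-based).
    """

    radius: int
    coords: list[HexCoord]
    xy: np.ndarray
    adjacency: list[tuple[int, ...]]
    _coord_to_index: dict[tuple[int, int], int] = field(repr=False, default_factory=dict)

    @property
    def node_count(self) -> int:
        return len(self.coords)

    def index_to_coord(self, index: int) -> HexCoord:
        self._check_index(index)
        return self.coords[index - 1]

    def coord_to_index(self, c: HexCoord) -> int:
        return self._coord_to_index[(c.q, c.r)]

    def circle_of(self, index: int) -> int:
        """Circle number (centre = 1) that a node belongs to."""
        return self.index_to_coord(index).distance_to_origin() + 1

    def _check_index(self, index: int) -> None:
        if not (1 <= index <= self.node_count):
            raise ValueError(
                f"node index {index} out of range 1..{self.node_count}"
            )


def build_map(radius: int) -> HexMapSpec:
    """Construct the supra-hexagonal lattice of the given radius.

    Node 1 is the centre (0, 0); each further circle is numbered
    anti-clockwise starting from its cell on the positive-x axis, axial
    ``(k-1, 0)`` for circle k.
    """
    radius = _check_radius(radius)
    coords: list[HexCoord] = [HexCoord(0, 0)]
    for k in range(2, radius + 1):
        s = k - 1
        q, r = s, 0
        for dq, dr in _RING_DIRECTIONS:
            for _ in range(s):
                coords.append(HexCoord(q, r))
                q, r = q + dq, r + dr
    assert len(coords) == node_count(radius)

    lookup = {(c.q, c.r): i + 1 for i, c in enumerate(coords)}
    xy = np.array([coord_to_cartesian(c) for c in coords], dtype=float)
    adjacency: list[tuple[int, ...]] = []
    for c in coords:
        nbrs = sorted(
            lookup[(c.q + dq, c.r + dr)]
            for dq, dr in _NEIGHBOR_STEPS
            if (c.q + dq, c.r + dr) in lookup
        )
        adjacency.append(tuple(nbrs))
    return HexMapSpec(
        radius=radius,
        coords=coords,
        xy=xy,
        adjacency=adjacency,
        _coord_to_index=lookup,
    )


def output_distance(i: int, j: int, spec: HexMapSpec) -> float:
    """Euclidean distance between two nodes in the 2D output plane."""
    spec._check_index(i)
    spec._check_index(j)
    return float(np.hypot(*(spec.xy[i - 1] - spec.xy[j - 1])))


def output_distance_matrix(spec: HexMapSpec) -> np.ndarray:
    """All pairwise output-space distances, shape (M, M)."""
    diff = spec.xy[:, None, :] - spec.xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def export_map_spec(spec: HexMapSpec, nodes_path, edges_path) -> None:
    """Write the lattice as two TSVs: node table and adjacency edge list."""
    import pandas as pd

    nodes = pd.DataFrame(
        {
            "index": np.arange(1, spec.node_count + 1),
            "q": [c.q for c in spec.coords],
            "r": [c.r for c in spec.coords],
            "x": spec.xy[:, 0],
            "y": spec.xy[:, 1],
            "circle": [c.distance_to_origin() + 1 for c in spec.coords],
        }
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges = [
        (i, j)
        for i, nbrs in enumerate(spec.adjacency, start=1)
        for j in nbrs
        if i < j
    ]
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(
        edges_path, sep="\t", index=False
    )
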