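"""Node-level statistics of a trained map and deterministic SVG rendering.

Two families of map diagnostics: single-value properties per node (map
distance / U-matrix, hit histogram) and the within-node prototype patterns.
Rendering emits plain SVG — one hexagon polygon per node plus a colour bar —
so output is byte-deterministic and testable on primitive counts, never on
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hexgrid import SQRT3_2, HexMapSpec
from .trainer import Codebook, InputMatrix, TIE_TOL, _bmu_indices

__all__ = [
    "NodeScalarField",
    "Mapping",
    "umatrix",
    "hit_histogram",
    "node_patterns",
    "render_map",
]


@dataclass
class NodeScalarField:
    """A scalar value attached to every map node."""

    values: np.ndarray
    spec: HexMapSpec
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.node_count,):
            raise ValueError(
                f"field length {self.values.shape} != node count "
                f"{self.spec.node_count}"
            )


@dataclass
class Mapping:
    """Per-gene best-matching-node assignment plus per-node hit counts.

    ``bmu`` holds the 1-based winner node per gene; ``ties`` the full list of
    co-minimal nodes (always containing the winner); ``hits`` counts genes
    whose winner is each node, so hits sums to the number of genes.
    """

    bmu: np.ndarray
    ties: list[list[int]]
    hits: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.bmu = np.asarray(self.bmu, dtype=int)
        self.hits = np.asarray(self.hits, dtype=int)
        if int(self.hits.sum()) != len(self.bmu):
            raise ValueError("hit counts must sum to the number of genes")
        for b, t in zip(self.bmu, self.ties):
            if b not in t:
                raise ValueError("winner must be a member of its tie list")

    @property
    def node_count(self) -> int:
        return len(self.hits)


def umatrix(codebook: Codebook) -> NodeScalarField:
    """Map distance (U-matrix): per node, the mean input-space Euclidean
    distance from its prototype to the prototypes of adjacent nodes.

    A radius-1 map has no adjacency; its single value is 0 by convention.
    """
    spec = codebook.spec
    P = codebook.prototypes
    values = np.zeros(spec.node_count)
    for j, nbrs in enumerate(spec.adjacency):
        if nbrs:
            values[j] = np.linalg.norm(
                P[[n - 1 for n in nbrs]] - P[j], axis=1
            ).mean()
    return NodeScalarField(values, spec, label="umatrix")


def hit_histogram(input: InputMatrix, codebook: Codebook) -> Mapping:
    """Assign every gene to its BMU (recording ties) and count hits."""
    X = input.values
    P = codebook.prototypes
    if X.shape[1] != P.shape[1]:
        raise ValueError("input and codebook dimensions do not match")
    d = np.linalg.norm(X[:, None, :] - P[None, :, :], axis=2)
    dmin = d.min(axis=1)
    bmu = np.empty(X.shape[0], dtype=int)
    ties: list[list[int]] = []
    for i in range(X.shape[0]):
        t = np.flatnonzero(d[i] <= dmin[i] + TIE_TOL) + 1
        bmu[i] = t[0]
        ties.append([int(x) for x in t])
    hits = np.bincount(bmu - 1, minlength=codebook.spec.node_count)
    return Mapping(bmu=bmu, ties=ties, hits=hits, gene_ids=list(input.row_ids))


@dataclass
class NodePatterns:
    """Prototype vectors per node with a flag for patterns crossing zero."""

    vectors: np.ndarray
    spans_zero: np.ndarray
    col_ids: list[str]


def node_patterns(codebook: Codebook) -> NodePatterns:
    """Per-node prototype patterns; ``spans_zero`` is strict (min < 0 < max)."""
    P = codebook.prototypes
    spans = (P.min(axis=1) < 0) & (P.max(axis=1) > 0)
    return NodePatterns(vectors=P.copy(), spans_zero=spans, col_ids=list(codebook.col_ids))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_HEX_ANGLES = np.pi / 180.0 * (np.arange(6) * 60.0 + 30.0)  # pointy-top
_HEX_RX = np.cos(_HEX_ANGLES) / (2.0 * SQRT3_2)
_HEX_RY = np.sin(_HEX_ANGLES) / (2.0 * SQRT3_2)


def _colours(values: np.ndarray, diverging: bool) -> list[str]:
    from matplotlib import colormaps
    from matplotlib.colors import Normalize, TwoSlopeNorm, to_hex

    vmin, vmax = float(values.min()), float(values.max())
    if diverging:
        lim = max(abs(vmin), abs(vmax)) or 1.0
        norm = TwoSlopeNorm(vcenter=0.0, vmin=-lim, vmax=lim)
        cmap = colormaps["RdBu_r"]
    else:
        if vmax <= vmin:
            vmax = vmin + 1.0
        norm = Normalize(vmin=vmin, vmax=vmax)
        cmap = colormaps["viridis"]
    return [to_hex(cmap(norm(v))) for v in values]


def render_map(
    field: NodeScalarField,
    out_path,
    colour_scale: str = "auto",
    scale: float = 40.0,
) -> str:
    """Render a per-node scalar field as an SVG hexagon map with a colour bar.

    ``colour_scale`` is "sequential", "diverging", or "auto" (diverging iff
    the field spans zero, anchored at 0).  Output is byte-deterministic for
    fixed input.  Returns the SVG text (also written to ``out_path`` when it
    is not None).
    """
    values = field.values
    if colour_scale == "auto":
        diverging = bool(values.min() < 0 < values.max())
    elif colour_scale in ("sequential", "diverging"):
        diverging = colour_scale == "diverging"
    else:
        raise ValueError(f"unknown colour scale {colour_scale!r}")
    fills = _colours(values, diverging)

    xy = field.spec.xy
    pad = 1.0
    x0, x1 = xy[:, 0].min() - pad, xy[:, 0].max() + pad
    y0, y1 = xy[:, 1].min() - pad, xy[:, 1].max() + pad
    bar_w = 1.5  # colour-bar gutter in map units
    width = (x1 - x0 + bar_w) * scale
    height = (y1 - y0) * scale

    def sx(x: float) -> float:
        return (x - x0) * scale

    def sy(y: float) -> float:
        return (y1 - y) * scale  # flip: SVG y grows downward

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.2f}" '
        f'height="{height:.2f}" viewBox="0 0 {width:.2f} {height:.2f}">',
        f"<title>{field.label or 'node field'}</title>",
    ]
    for j in range(field.spec.node_count):
        cx, cy = xy[j]
        pts = " ".join(
            f"{sx(cx + rx):.3f},{sy(cy + ry):.3f}"
            for rx, ry in zip(_HEX_RX, _HEX_RY)
        )
        lines.append(
            f'<polygon class="node" points="{pts}" fill="{fills[j]}" '
            'stroke="#555555" stroke-width="0.5"/>'
        )
    # colour bar: 32 stacked rectangles on the right
    nseg = 32
    vmin, vmax = float(values.min()), float(values.max())
    if diverging:
        lim = max(abs(vmin), abs(vmax)) or 1.0
        vmin, vmax = -lim, lim
    elif vmax <= vmin:
        vmax = vmin + 1.0
    seg_vals = np.linspace(vmin, vmax, nseg)
    seg_cols = _colours(seg_vals, diverging)
    bx = (x1 - x0 + 0.4) * scale
    bh = height / nseg
    for k in range(nseg):
        lines.append(
            f'<rect class="cbar" x="{bx:.3f}" y="{height - (k + 1) * bh:.3f}" '
            f'width="{0.4 * scale:.3f}" height="{bh + 0.5:.3f}" '
            f'fill="{seg_cols[k]}"/>'
        )
    for v, frac in ((vmin, 0.0), (vmax, 1.0)):
        ty = height - frac * height
        ty = min(max(ty, 10.0), height - 2.0)
        lines.append(
            f'<text x="{bx + 0.45 * scale:.3f}" y="{ty:.3f}" '
            f'font-size="10" font-family="sans-serif">{v:.3g}</text>'
        )
    lines.append("</svg>")
    doc = "\n".join(lines) + "\n"
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write(doc)
    return doc
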