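"""Overlay additional per-gene data layers onto a trained map.

Each gene contributes its overlay values to every map node, weighted by the
neighbourhood kernel evaluated at the output-space distance from the gene's
best-matching node(s); when a gene has several co-minimal best-matching
nodes its unit weight is split equally across them.  The per-node overlaid
value is the kernel-weighted accumulation divided by the kernel-weighted hit
count, so overlaying a constant column returns that constant everywhere the
weighted hits are defined — and a 0/1 logical column yields, per node, the
(kernel-smoothed) probability that the node's genes carry the annotation.

In the compact-support limit (bubble kernel, sigma < 1) this reduces to the
rigid per-BMU group mean that kernel weighting generalises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hexgrid import HexMapSpec, output_distance_matrix
from .mapstats import Mapping
from .trainer import Codebook, InputMatrix, KERNELS

__all__ = ["OverlayResult", "weighted_hits", "overlay_data", "overlay_as_codebook",
           "UNDEFINED_EPS", "DEFAULT_OVERLAY_SIGMA"]

#: weighted-hit threshold below which a node's overlay value is undefined
UNDEFINED_EPS = 1e-9

#: default kernel width — the terminal fine-tune neighbourhood of training
DEFAULT_OVERLAY_SIGMA = 1.0


@dataclass
class OverlayResult:
    """Kernel-normalised overlay values per node, plus the weighted hits."""

    values: np.ndarray  # (M, D'); NaN where undefined
    weighted_hits: np.ndarray  # (M,)
    col_ids: list[str]
    undefined_mask: np.ndarray  # (M,) bool
    spec: HexMapSpec

    def __post_init__(self) -> None:
        defined = ~self.undefined_mask
        if not np.isfinite(self.values[defined]).all():
            raise ValueError("overlay values must be finite where defined")
        if (self.weighted_hits < 0).any():
            raise ValueError("weighted hits must be non-negative")


def _gene_node_weights(
    mapping: Mapping, spec: HexMapSpec, kernel: str, sigma: float
) -> np.ndarray:
    """(G, M) matrix of per-gene kernel weights over all nodes.

    Row i is the mean over the gene's co-best nodes b of
    kernel(output_distance(b, .), sigma) — the equal fractional tie split.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    K = KERNELS[kernel](output_distance_matrix(spec), float(sigma))
    G = len(mapping.bmu)
    W = np.empty((G, spec.node_count))
    for i, ties in enumerate(mapping.ties):
        W[i] = K[[t - 1 for t in ties]].mean(axis=0)
    return W


def weighted_hits(
    mapping: Mapping,
    spec: HexMapSpec,
    kernel: str = "gaussian",
    sigma: float = DEFAULT_OVERLAY_SIGMA,
) -> np.ndarray:
    """Neighbourhood-kernel-weighted hit counts per node.

    With a bubble kernel of sigma < 1 this is the plain hit histogram (plus
    fractional shares for tied genes).
    """
    return _gene_node_weights(mapping, spec, kernel, sigma).sum(axis=0)


def overlay_data(
    mapping: Mapping,
    spec: HexMapSpec,
    additional: InputMatrix,
    kernel: str = "gaussian",
    sigma: float = DEFAULT_OVERLAY_SIGMA,
) -> OverlayResult:
    """Overlay an additional genes x columns matrix onto the trained map.

    ``additional`` may cover a subset of the training genes, but every one of
    its rows must name a training gene.  Nodes whose weighted hits fall below
    ``UNDEFINED_EPS`` are flagged undefined (NaN values).
    """
    index = {g: i for i, g in enumerate(mapping.gene_ids)}
    unknown = [g for g in additional.row_ids if g not in index]
    if unknown:
        raise ValueError(
            f"{len(unknown)} overlay gene id(s) absent from the trained map: "
            f"{unknown[:10]}"
        )
    rows = [index[g] for g in additional.row_ids]
    W = _gene_node_weights(mapping, spec, kernel, sigma)[rows]
    h = W.sum(axis=0)
    A = W.T @ additional.values  # (M, D') accumulated values
    undefined = h < UNDEFINED_EPS
    values = np.full_like(A, np.nan)
    np.divide(A, h[:, None], out=values, where=~undefined[:, None])
    return OverlayResult(
        values=values,
        weighted_hits=h,
        col_ids=list(additional.col_ids),
        undefined_mask=undefined,
        spec=spec,
    )


def overlay_as_codebook(result: OverlayResult, spec: HexMapSpec | None = None) -> Codebook:
    """Repackage an overlay as an artificial codebook over the overlay columns.

    The result can then drive the sample-landscape machinery (component
    reordering of the overlaid samples).  Undefined nodes are imputed as the
    mean of their defined map neighbours, iterating until every node is
    filled; a map with no defined node at all is an error.
    """
    spec = spec or result.spec
    values = result.values.copy()
    defined = ~result.undefined_mask.copy()
    if not defined.any():
        raise ValueError("cannot build a codebook: every node is undefined")
    while not defined.all():
        progressed = False
        newly = []
        for j in np.flatnonzero(~defined):
            nbrs = [n - 1 for n in spec.adjacency[j] if defined[n - 1]]
            if nbrs:
                values[j] = values[nbrs].mean(axis=0)
                newly.append(j)
                progressed = True
        if not progressed:  # disconnected undefined region (cannot happen on a disc)
            raise RuntimeError("imputation made no progress")
        for j in newly:
            defined[j] = True
    return Codebook(prototypes=values, spec=spec, col_ids=list(result.col_ids))
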