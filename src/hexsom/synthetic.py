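"""Synthetic genes x samples fixtures with planted cluster structure.

Emulates the statistical shape the map method assumes: most genes do not
change (a background fraction drawn around zero — the mass that settles at
the map centre), while the rest fall into a few clusters of co-varying
genes whose centroids stand clear of the noise.  Matched overlay columns
(logical annotation indicators or cluster-shifted numeric levels) allow the
overlay machinery to be exercised without external datasets.

Defaults: 600 genes, 6 samples, 4 clusters, background fraction 0.3,
centroid scale tau = 3, noise scale sigma_n = 0.3 — a desk-scale regime in
which the planted clusters are separable but not trivially so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trainer import InputMatrix

__all__ = ["SyntheticSpec", "SyntheticResult", "generate", "generate_overlay"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-cluster generative model."""

    n_genes: int = 600
    n_samples: int = 6
    n_clusters: int = 4
    background_fraction: float = 0.3
    centroid_scale: float = 3.0
    noise_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")
        if self.n_genes < self.n_clusters:
            raise ValueError("need at least one gene per cluster")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValueError("background_fraction must be in [0, 1]")
        if self.noise_scale < 0 or self.centroid_scale < 0:
            raise ValueError("scales must be non-negative")


@dataclass
class SyntheticResult:
    """Generated matrix plus ground truth (label 0 marks background genes)."""

    matrix: InputMatrix
    labels: np.ndarray
    centroids: np.ndarray
    overlays: dict[str, np.ndarray] = field(default_factory=dict)


def generate(spec: SyntheticSpec) -> SyntheticResult:
    """Draw a genes x samples matrix with planted Gaussian clusters.

    Background genes are Normal(0, sigma_n^2) per component.  The remaining
    genes split as evenly as possible across the clusters; each cluster's
    centroid is drawn once from Normal(0, tau^2) per component and its genes
    are centroid + Normal(0, sigma_n^2).  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    G, S, C = spec.n_genes, spec.n_samples, spec.n_clusters
    n_bg = int(round(spec.background_fraction * G))
    n_fg = G - n_bg
    labels = np.zeros(G, dtype=int)
    X = np.empty((G, S))
    X[:n_bg] = rng.normal(0.0, spec.noise_scale, size=(n_bg, S))
    centroids = rng.normal(0.0, spec.centroid_scale, size=(C, S))
    sizes = np.full(C, n_fg // C)
    sizes[: n_fg % C] += 1
    pos = n_bg
    for c in range(C):
        n = int(sizes[c])
        X[pos : pos + n] = centroids[c] + rng.normal(
            0.0, spec.noise_scale, size=(n, S)
        )
        labels[pos : pos + n] = c + 1
        pos += n
    matrix = InputMatrix(
        values=X,
        row_ids=[f"g{i + 1}" for i in range(G)],
        col_ids=[f"s{j + 1}" for j in range(S)],
    )
    return SyntheticResult(matrix=matrix, labels=labels, centroids=centroids)


def generate_overlay(
    labels: np.ndarray,
    mode: str = "logical",
    p_in: float = 0.9,
    p_out: float = 0.1,
    clusters: tuple[int, ...] | None = None,
    shift: float = 2.0,
    noise_scale: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """An overlay column statistically tied to the planted cluster labels.

    logical — each gene gets 1 with probability ``p_in`` when its label is
    in the designated cluster set (default: cluster 1), ``p_out`` otherwise;
    emulates promoter-class indicator vectors.  numeric — Gaussian levels
    shifted by ``shift`` for the designated clusters, emulating a matched
    expression layer; ``shift = 0`` makes the column independent of labels.
    """
    labels = np.asarray(labels, dtype=int)
    if mode not in ("logical", "numeric"):
        raise ValueError(f"unknown overlay mode {mode!r}")
    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise ValueError("p_in and p_out must be probabilities")
    if clusters is None:
        clusters = (1,)
    member = np.isin(labels, list(clusters))
    rng = np.random.default_rng(seed)
    if mode == "logical":
        p = np.where(member, p_in, p_out)
        return (rng.random(labels.shape) < p).astype(float)
    base = rng.normal(0.0, noise_scale, size=labels.shape)
    return base + shift * member
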