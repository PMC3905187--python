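"""Sample landscape: lay samples out on a small 2D square lattice.

The sample-wise vectors of the codebook (or of the raw input matrix) — or
their pairwise similarity matrix, which is far cheaper when the matrix is
tall — are fed to a small sheet-topology SOM on a near-square grid.  Each
sample lands at its best-matching cell; geometric proximity on the lattice
then reflects profile similarity, and reading the lattice in row-major order
gives a display ordering for per-sample component maps.

Supported pairwise metrics: pearson, spearman (Pearson on average ranks),
kendall (tau-b), cosine similarity, euclidean and cityblock distance, and
mutual information (plug-in estimate on equal-width bins, in bits).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau, rankdata

from .trainer import Codebook, InputMatrix, KERNELS, TrainConfig, _bmu_indices

logger = logging.getLogger("hexsom")

__all__ = [
    "SimilarityMatrix",
    "SampleLandscape",
    "METRICS",
    "sample_vectors",
    "similarity_matrix",
    "train_landscape",
    "reorder_components",
]

METRICS = (
    "pearson",
    "spearman",
    "kendall",
    "euclidean",
    "cityblock",
    "cosine",
    "mutual_information",
)

#: metrics whose values are similarities (self-value 1) vs distances (self 0)
_CORRELATION_LIKE = {"pearson", "spearman", "kendall", "cosine"}


@dataclass
class SimilarityMatrix:
    """Pairwise S x S sample similarity (or distance) under one metric."""

    values: np.ndarray
    metric: str
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        S = len(self.ids)
        if self.values.shape != (S, S):
            raise ValueError("similarity matrix must be S x S")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    def as_feature_vectors(self) -> np.ndarray:
        """Rows of the matrix, used as S-dimensional sample features."""
        return self.values.copy()


@dataclass
class SampleLandscape:
    """Placement of samples on an (nx, ny) square lattice, one per cell."""

    nx: int
    ny: int
    placement: dict[str, tuple[int, int]]
    order: list[str]

    def __post_init__(self) -> None:
        cells = list(self.placement.values())
        if len(set(cells)) != len(cells):
            raise ValueError("one sample per cell")
        for i, j in cells:
            if not (0 <= i < self.nx and 0 <= j < self.ny):
                raise ValueError(f"cell ({i}, {j}) outside {self.nx} x {self.ny} lattice")


def sample_vectors(source: Codebook | InputMatrix) -> tuple[np.ndarray, list[str]]:
    """One feature vector per sample: the transpose of the source matrix.

    For a codebook the features are the M node prototypes' components; for an
    input matrix they are the G gene values.
    """
    if isinstance(source, Codebook):
        return source.prototypes.T.copy(), list(source.col_ids)
    if isinstance(source, InputMatrix):
        return source.values.T.copy(), list(source.col_ids)
    raise TypeError(f"unsupported source type {type(source).__name__}")


def _mi_bits(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Plug-in mutual information in bits on equal-width marginal bins."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float((p[nz] * np.log2(p[nz] / outer[nz])).sum())


def similarity_matrix(
    vectors: np.ndarray, metric: str, ids: list[str] | None = None
) -> SimilarityMatrix:
    """Pairwise sample similarity/distance matrix under the chosen metric.

    A zero-variance vector under a correlation-family metric yields 0 for
    its off-diagonal entries, with a warning (the diagonal stays at the
    metric's self-similarity).
    """
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2 or V.shape[1] < 2:
        raise ValueError("need an S x F matrix with F >= 2")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    S, F = V.shape
    ids = [str(i) for i in range(S)] if ids is None else list(ids)

    const = np.isclose(V.std(axis=1), 0.0)
    if const.any() and metric in _CORRELATION_LIKE - {"cosine"}:
        logger.warning(
            "%d zero-variance sample vector(s); their %s values set to 0",
            int(const.sum()), metric,
        )

    if metric in ("euclidean", "cityblock"):
        M = cdist(V, V, metric=metric)
        np.fill_diagonal(M, 0.0)
    elif metric == "cosine":
        norms = np.linalg.norm(V, axis=1)
        zero = norms == 0
        if zero.any():
            logger.warning("%d zero-norm vector(s); cosine set to 0", int(zero.sum()))
        safe = np.where(zero, 1.0, norms)
        M = (V @ V.T) / np.outer(safe, safe)
        M[zero, :] = 0.0
        M[:, zero] = 0.0
        np.fill_diagonal(M, 1.0)
    elif metric in ("pearson", "spearman"):
        W = np.apply_along_axis(rankdata, 1, V) if metric == "spearman" else V
        Wc = W - W.mean(axis=1, keepdims=True)
        sd = np.linalg.norm(Wc, axis=1)
        safe = np.where(sd == 0, 1.0, sd)
        M = (Wc @ Wc.T) / np.outer(safe, safe)
        M[const, :] = 0.0
        M[:, const] = 0.0
        np.fill_diagonal(M, 1.0)
    elif metric == "kendall":
        M = np.ones((S, S))
        for a in range(S):
            for b in range(a + 1, S):
                if const[a] or const[b]:
                    tau = 0.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        tau = kendalltau(V[a], V[b]).statistic
                    if not np.isfinite(tau):
                        tau = 0.0
                M[a, b] = M[b, a] = tau
    else:  # mutual_information
        bins = max(2, math.ceil(math.sqrt(F)))
        M = np.zeros((S, S))
        for a in range(S):
            for b in range(a, S):
                M[a, b] = M[b, a] = _mi_bits(V[a], V[b], bins)
    return SimilarityMatrix(values=M, metric=metric, ids=ids)


def _lattice_dims(S: int) -> tuple[int, int]:
    nx = math.ceil(math.sqrt(S))
    ny = math.ceil(S / nx)
    return nx, ny


def _grid_xy(nx: int, ny: int) -> np.ndarray:
    """Row-major integer cell centres of an nx x ny sheet."""
    return np.array([(i, j) for j in range(ny) for i in range(nx)], dtype=float)


def train_landscape(
    source: np.ndarray | SimilarityMatrix,
    ids: list[str] | None = None,
    seed: int = 0,
) -> SampleLandscape:
    """Train a small square-lattice SOM on sample features and place samples.

    ``source`` is either an S x F feature matrix (e.g. from
    :func:`sample_vectors`) or a :class:`SimilarityMatrix`, whose rows then
    serve as the S-dimensional features.  Placement is each sample's BMU
    cell; collisions are resolved deterministically — samples are processed
    in order of decreasing BMU margin (runner-up distance minus winner
    distance) and a colliding sample moves to the nearest free cell
    (Euclidean, ties broken row-major).
    """
    if isinstance(source, SimilarityMatrix):
        V = source.as_feature_vectors()
        ids = list(source.ids)
    else:
        V = np.asarray(source, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(V.shape[0])]
    S = V.shape[0]
    if S < 1:
        raise ValueError("need at least one sample")
    nx, ny = _lattice_dims(S)
    if S == 1:
        return SampleLandscape(nx=1, ny=1, placement={ids[0]: (0, 0)}, order=list(ids))

    xy = _grid_xy(nx, ny)
    M = nx * ny
    side = max(nx, ny)
    cfg = TrainConfig.default(side, seed=seed)
    proto = _train_sheet(V, xy, cfg)

    d = np.linalg.norm(V[:, None, :] - proto[None, :, :], axis=2)
    order_d = np.sort(d, axis=1)
    margin = order_d[:, 1] - order_d[:, 0] if M > 1 else np.zeros(S)
    # most confident samples claim their cells first; ties by sample id
    proc = sorted(range(S), key=lambda i: (-margin[i], ids[i]))
    taken: set[tuple[int, int]] = set()
    placement: dict[str, tuple[int, int]] = {}
    for i in proc:
        bcell = xy[int(np.argmin(d[i]))]
        cands = sorted(
            (tuple(int(v) for v in c) for c in xy if tuple(int(v) for v in c) not in taken),
            key=lambda c: (np.hypot(c[0] - bcell[0], c[1] - bcell[1]), c[1], c[0]),
        )
        cell = cands[0]
        taken.add(cell)
        placement[ids[i]] = cell
    order = sorted(ids, key=lambda s: (placement[s][1], placement[s][0], s))
    return SampleLandscape(nx=nx, ny=ny, placement=placement, order=order)


def _train_sheet(V: np.ndarray, xy: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """Batch-train prototypes on an explicit sheet geometry."""
    M = xy.shape[0]
    rng = np.random.default_rng(cfg.seed)
    proto = _sheet_linear_init(V, xy)
    if proto is None:
        lo, hi = V.min(axis=0), V.max(axis=0)
        proto = rng.uniform(0.0, 1.0, size=(M, V.shape[1])) * (hi - lo) + lo
    diff = xy[:, None, :] - xy[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    kern = KERNELS[cfg.kernel]
    for phase in cfg.phases:
        for e in range(phase.epochs):
            if phase.epochs > 1:
                sigma = phase.sigma_start + (phase.sigma_end - phase.sigma_start) * e / (
                    phase.epochs - 1
                )
            else:
                sigma = phase.sigma_start
            K = kern(D, sigma)
            bmu = _bmu_indices(proto, V)
            W = K[bmu]
            denom = W.sum(axis=0)
            dead = denom <= 0
            upd = proto.copy()
            np.divide(W.T @ V, denom[:, None], out=upd, where=~dead[:, None])
            proto = upd
    return proto


def _sheet_linear_init(V: np.ndarray, xy: np.ndarray) -> np.ndarray | None:
    mean = V.mean(axis=0)
    Vc = V - mean
    U, s, Vt = np.linalg.svd(Vc, full_matrices=False)
    if (s > 1e-12 * max(s[0] if len(s) else 0.0, 1.0)).sum() < 2:
        return None
    axes = Vt[:2]
    for k in range(2):
        j = np.argmax(np.abs(axes[k]))
        if axes[k][j] < 0:
            axes[k] = -axes[k]
    proj = Vc @ axes.T
    proto = np.tile(mean, (xy.shape[0], 1)).astype(float)
    for k in range(2):
        g = xy[:, k]
        span = g.max() - g.min()
        t = (g - g.min()) / span if span > 0 else np.zeros_like(g)
        lo, hi = proj[:, k].min(), proj[:, k].max()
        proto += np.outer(lo + t * (hi - lo), axes[k])
    return proto


def reorder_components(
    codebook: Codebook, landscape: SampleLandscape
) -> list[str]:
    """Display order of samples: landscape cells row-major, ties by id.

    Used to arrange the per-sample component maps around the landscape frame.
    Raises if the codebook's sample ids and the landscape's disagree.
    """
    if set(codebook.col_ids) != set(landscape.placement):
        missing = set(codebook.col_ids) ^ set(landscape.placement)
        raise ValueError(f"sample id mismatch: {sorted(missing)}")
    return sorted(
        codebook.col_ids,
        key=lambda s: (landscape.placement[s][1], landscape.placement[s][0], s),
    )
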