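"""Self-organising map training over the supra-hexagonal lattice.

The trainer converts a genes x samples matrix into a codebook matrix: one
prototype vector (same dimension as the input rows) per map node.  Training
pulls each prototype toward the input rows whose best-matching unit (BMU)
lies nearby in output space, with "nearby" defined by a neighbourhood kernel
of shrinking width sigma.  Two classical updates are provided:

batch       m_j <- sum_i k(d(bmu_i, j), sigma) x_i / sum_i k(d(bmu_i, j), sigma)
sequential  m_j <- m_j + alpha k(d(bmu_i, j), sigma) (x_i - m_j)

Both run through an ordered list of phases (typically a rough phase with a
wide kernel followed by a fine-tune phase); sigma and the learning rate
alpha interpolate linearly within each phase.  In the sigma -> 0 limit the
batch update degenerates to one Lloyd step of k-means with the map nodes as
centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hexgrid import HexMapSpec, build_map, node_count, output_distance_matrix

__all__ = [
    "InputMatrix",
    "Codebook",
    "TrainPhase",
    "TrainConfig",
    "TrainResult",
    "KERNELS",
    "kernel_value",
    "initialize",
    "find_bmu",
    "train",
    "train_batch",
    "train_sequential",
    "train_on_matrix",
    "quantization_error",
    "auto_radius",
    "TIE_TOL",
]

logger = logging.getLogger("hexsom")

#: absolute tolerance for detecting co-minimal BMU distances
TIE_TOL = 1e-12


@dataclass
class InputMatrix:
    """A genes x samples numeric matrix with row and column identifiers."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("input matrix must be 2D and non-empty")
        if not np.isfinite(self.values).all():
            raise ValueError("input matrix contains non-finite values")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length does not match matrix")
        if len(self.col_ids) != self.values.shape[1]:
            raise ValueError("col_ids length does not match matrix")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class Codebook:
    """Per-node prototype vectors of a (trained) map."""

    prototypes: np.ndarray  # (M, D)
    spec: HexMapSpec
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if self.prototypes.shape[0] != self.spec.node_count:
            raise ValueError(
                "codebook rows must equal node count: "
                f"{self.prototypes.shape[0]} != {self.spec.node_count}"
            )
        if not np.isfinite(self.prototypes).all():
            raise ValueError("codebook contains non-finite values")


@dataclass(frozen=True)
class TrainPhase:
    epochs: int
    sigma_start: float
    sigma_end: float
    alpha_start: float = 0.0
    alpha_end: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.sigma_start >= self.sigma_end > 0):
            raise ValueError("phases require sigma_start >= sigma_end > 0")


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``alpha`` values are used only by the sequential algorithm.  The default
    schedule is two phases: rough (10 epochs, sigma max(r/2, 1) -> 1,
    alpha 0.5 -> 0.05) then fine-tune (40 epochs, sigma held at 1,
    alpha 0.05 -> 0.01).  The neighbourhood never shrinks below one lattice
    step: with a narrower kernel the batch update degenerates to independent
    per-node k-means and the map loses its topological smoothing.
    """

    algorithm: str = "batch"
    kernel: str = "gaussian"
    phases: list[TrainPhase] = field(default_factory=list)
    init: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("batch", "sequential"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.init not in ("linear", "uniform"):
            raise ValueError(f"unknown init {self.init!r}")

    @classmethod
    def default(cls, radius: int, **overrides) -> "TrainConfig":
        phases = [
            TrainPhase(10, max(radius / 2.0, 1.0), 1.0, 0.5, 0.05),
            TrainPhase(40, 1.0, 1.0, 0.05, 0.01),
        ]
        overrides.setdefault("phases", phases)
        return cls(**overrides)


@dataclass
class TrainResult:
    codebook: Codebook
    mapping: "Mapping"  # noqa: F821 - defined in mapstats
    qe_trace: np.ndarray


# ---------------------------------------------------------------------------
# neighbourhood kernels
# ---------------------------------------------------------------------------

def _gaussian(d: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-(d**2) / (2.0 * sigma**2))


def _bubble(d: np.ndarray, sigma: float) -> np.ndarray:
    return (d <= sigma).astype(float)


def _cutgaussian(d: np.ndarray, sigma: float) -> np.ndarray:
    return _gaussian(d, sigma) * (d <= sigma)


def _epanechnikov(d: np.ndarray, sigma: float) -> np.ndarray:
    return np.maximum(0.0, 1.0 - (d / sigma) ** 2)


KERNELS = {
    "gaussian": _gaussian,
    "bubble": _bubble,
    "cutgaussian": _cutgaussian,
    "epanechnikov": _epanechnikov,
}


def kernel_value(kernel: str, d, sigma: float):
    """Neighbourhood weight in [0, 1] at output-space distance ``d``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}")
    d = np.asarray(d, dtype=float)
    out = KERNELS[kernel](d, float(sigma))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def auto_radius(n_genes: int, cap: int = 15) -> int:
    """Smallest radius with node_count >= 5 * sqrt(G), capped at ``cap``.

    Standard SOM sizing heuristic (about 5 sqrt(G) nodes) adapted to the
    supra-hexagonal node-count formula.
    """
    target = 5.0 * np.sqrt(n_genes)
    r = 1
    while node_count(r) < target and r < cap:
        r += 1
    return r


def initialize(
    input: InputMatrix,
    spec: HexMapSpec,
    method: str = "linear",
    seed: int = 0,
) -> Codebook:
    """Initial codebook, either PCA-plane ("linear") or componentwise uniform.

    Linear initialisation spreads the prototypes over the plane spanned by
    the first two principal directions of the data, scaled to the data's
    extent along each direction; it falls back to uniform when the data has
    rank < 2.
    """
    if method not in ("linear", "uniform"):
        raise ValueError(f"unknown init method {method!r}")
    X = input.values
    M = spec.node_count
    if method == "linear":
        proto = _linear_init(X, spec)
        if proto is not None:
            return Codebook(proto, spec, list(input.col_ids))
        logger.warning("linear init: data rank < 2, falling back to uniform")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    proto = rng.uniform(0.0, 1.0, size=(M, X.shape[1])) * (hi - lo) + lo
    return Codebook(proto, spec, list(input.col_ids))


def _linear_init(X: np.ndarray, spec: HexMapSpec) -> np.ndarray | None:
    mean = X.mean(axis=0)
    Xc = X - mean
    # deterministic SVD-based principal directions with a sign convention
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if (s > 1e-12 * max(s[0], 1.0)).sum() < 2:
        return None
    axes = Vt[:2]
    for k in range(2):  # fix sign: largest-|.| loading positive
        j = np.argmax(np.abs(axes[k]))
        if axes[k][j] < 0:
            axes[k] = -axes[k]
    proj = Xc @ axes.T  # (G, 2) data coordinates in the PC plane
    grid = spec.xy.copy()
    proto = np.tile(mean, (spec.node_count, 1)).astype(float)
    for k in range(2):
        g = grid[:, k]
        span = g.max() - g.min()
        if span <= 0:
            t = np.zeros_like(g)
        else:
            t = (g - g.min()) / span  # 0..1 across the map
        lo, hi = proj[:, k].min(), proj[:, k].max()
        proto += np.outer(lo + t * (hi - lo), axes[k])
    return proto


# ---------------------------------------------------------------------------
# BMU search
# ---------------------------------------------------------------------------

def find_bmu(codebook: Codebook, v: np.ndarray) -> tuple[int, list[int]]:
    """Best-matching node for a vector, with co-minimal ties.

    Returns ``(winner, ties)`` where ties lists every node whose prototype
    distance is within ``TIE_TOL`` of the minimum and the winner is the
    lowest-index tie.  Indices are 1-based.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (codebook.prototypes.shape[1],):
        raise ValueError(
            f"vector dimension {v.shape} does not match codebook "
            f"D={codebook.prototypes.shape[1]}"
        )
    d = np.linalg.norm(codebook.prototypes - v, axis=1)
    dmin = d.min()
    ties = np.flatnonzero(d <= dmin + TIE_TOL) + 1
    return int(ties[0]), [int(t) for t in ties]


def _bmu_indices(prototypes: np.ndarray, X: np.ndarray) -> np.ndarray:
    """0-based BMU row indices for every row of X (lowest index wins ties)."""
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ prototypes.T
        + (prototypes**2).sum(axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def quantization_error(input: InputMatrix, codebook: Codebook) -> float:
    """Mean Euclidean distance from each input row to its BMU prototype."""
    X = input.values
    if X.shape[1] != codebook.prototypes.shape[1]:
        raise ValueError("input and codebook dimensions do not match")
    bmu = _bmu_indices(codebook.prototypes, X)
    return float(np.linalg.norm(X - codebook.prototypes[bmu], axis=1).mean())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _phase_values(start: float, end: float, step: int, steps: int) -> float:
    if steps <= 1:
        return float(start)
    return float(start + (end - start) * step / (steps - 1))


def train(input: InputMatrix, spec: HexMapSpec, config: TrainConfig) -> TrainResult:
    """Train with the configured algorithm (dispatches batch/sequential)."""
    if config.algorithm == "batch":
        return train_batch(input, spec, config)
    return train_sequential(input, spec, config)


def _finish(input: InputMatrix, codebook: Codebook, qe: list[float]) -> TrainResult:
    from .mapstats import hit_histogram

    mapping = hit_histogram(input, codebook)
    return TrainResult(codebook=codebook, mapping=mapping, qe_trace=np.array(qe))


def train_batch(
    input: InputMatrix, spec: HexMapSpec, config: TrainConfig
) -> TrainResult:
    """Batch SOM training: per epoch, prototypes become kernel-weighted means.

    Nodes receiving zero total weight keep their previous prototype (a
    warning is logged when that happens under a compact-support kernel).
    Deterministic given the seed and input row order.
    """
    if config.algorithm != "batch":
        raise ValueError("config.algorithm must be 'batch'")
    if not config.phases:
        raise ValueError("config.phases must be non-empty")
    X = input.values
    codebook = initialize(input, spec, config.init, config.seed)
    proto = codebook.prototypes.copy()
    D = output_distance_matrix(spec)
    kern = KERNELS[config.kernel]
    qe: list[float] = []
    for phase in config.phases:
        for e in range(phase.epochs):
            sigma = _phase_values(phase.sigma_start, phase.sigma_end, e, phase.epochs)
            K = kern(D, sigma)  # (M, M) node-to-node weights
            bmu = _bmu_indices(proto, X)
            W = K[bmu]  # (G, M): weight of gene i on node j
            denom = W.sum(axis=0)
            numer = W.T @ X
            dead = denom <= 0.0
            if dead.any():
                logger.warning(
                    "batch epoch: %d node(s) received zero kernel weight; "
                    "prototypes kept",
                    int(dead.sum()),
                )
            upd = proto.copy()
            np.divide(numer, denom[:, None], out=upd, where=~dead[:, None])
            proto = upd
            cb = Codebook(proto, spec, list(input.col_ids))
            qe.append(quantization_error(input, cb))
    return _finish(input, Codebook(proto, spec, list(input.col_ids)), qe)


def train_sequential(
    input: InputMatrix, spec: HexMapSpec, config: TrainConfig
) -> TrainResult:
    """Sequential (online) SOM training with a seeded shuffle per epoch."""
    if config.algorithm != "sequential":
        raise ValueError("config.algorithm must be 'sequential'")
    if not config.phases:
        raise ValueError("config.phases must be non-empty")
    X = input.values
    G = X.shape[0]
    codebook = initialize(input, spec, config.init, config.seed)
    proto = codebook.prototypes.copy()
    D = output_distance_matrix(spec)
    kern = KERNELS[config.kernel]
    rng = np.random.default_rng(config.seed + 1)
    qe: list[float] = []
    for phase in config.phases:
        total = phase.epochs * G
        step = 0
        for _ in range(phase.epochs):
            order = rng.permutation(G)
            for i in order:
                sigma = _phase_values(phase.sigma_start, phase.sigma_end, step, total)
                alpha = _phase_values(phase.alpha_start, phase.alpha_end, step, total)
                step += 1
                if alpha == 0.0:
                    continue
                x = X[i]
                b = int(np.argmin(np.linalg.norm(proto - x, axis=1)))
                k = kern(D[b], sigma)
                proto += alpha * k[:, None] * (x - proto)
            cb = Codebook(proto, spec, list(input.col_ids))
            qe.append(quantization_error(input, cb))
    return _finish(input, Codebook(proto, spec, list(input.col_ids)), qe)


def train_on_matrix(
    input: InputMatrix,
    radius: int | None = None,
    config: TrainConfig | None = None,
    **config_overrides,
) -> TrainResult:
    """Convenience wrapper: build the map (auto radius by default) and train."""
    r = auto_radius(input.n_genes) if radius is None else radius
    spec = build_map(r)
    if config is None:
        config = TrainConfig.default(r, **config_overrides)
    return train(input, spec, config)
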