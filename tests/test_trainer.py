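"""SOM training: kernels, initialisation, BMU search, batch/sequential updates."""

import math

import numpy as np
import pytest

import hexsom as hx
from hexsom.trainer import (
    Codebook,
    InputMatrix,
    TrainConfig,
    TrainPhase,
    auto_radius,
    find_bmu,
    initialize,
    kernel_value,
    quantization_error,
    train_batch,
    train_sequential,
)

from conftest import random_codebook, random_input


class TestKernels:
    @pytest.mark.parametrize(
        "kernel, d, sigma, expected",
        [
            ("gaussian", 0.0, 1.0, 1.0),
            ("gaussian", 1.0, 1.0, math.exp(-0.5)),
            ("gaussian", 2.0, 1.0, math.exp(-2.0)),
            ("bubble", 0.9, 1.0, 1.0),
            ("bubble", 1.1, 1.0, 0.0),
            ("cutgaussian", 1.0, 1.0, math.exp(-0.5)),
            ("cutgaussian", 1.5, 1.0, 0.0),
            ("epanechnikov", 0.5, 1.0, 0.75),
            ("epanechnikov", 1.0, 1.0, 0.0),
            ("epanechnikov", 3.0, 1.0, 0.0),
        ],
    )
    def test_closed_forms(self, kernel, d, sigma, expected):
        assert kernel_value(kernel, d, sigma) == pytest.approx(expected)

    @pytest.mark.parametrize("kernel", ["gaussian", "bubble", "cutgaussian", "epanechnikov"])
    def test_range_zero_one(self, kernel):
        d = np.linspace(0, 10, 101)
        w = kernel_value(kernel, d, 2.0)
        assert np.all((w >= 0) & (w <= 1))
        assert kernel_value(kernel, 0.0, 2.0) == 1.0

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            kernel_value("gaussian", 1.0, 0.0)
        with pytest.raises(ValueError):
            kernel_value("nope", 1.0, 1.0)


class TestInitialize:
    def test_uniform_degenerate_range_copies_the_row(self, map_r3):
        v = np.array([2.0, -1.0, 0.5])
        im = InputMatrix(np.tile(v, (5, 1)), [f"g{i}" for i in range(5)], list("abc"))
        cb = initialize(im, map_r3, "uniform", seed=0)
        assert np.allclose(cb.prototypes, v)

    def test_uniform_reproducible_from_seed(self, map_r3):
        rng = np.random.default_rng(1)
        im = random_input(20, 3, rng)
        a = initialize(im, map_r3, "uniform", seed=42).prototypes
        b = initialize(im, map_r3, "uniform", seed=42).prototypes
        c = initialize(im, map_r3, "uniform", seed=43).prototypes
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_linear_init_prototypes_lie_in_data_affine_span(self, map_r3):
        # rank-2 data: residual of prototypes to the data's affine span ~ 0
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 5))
        coeff = rng.normal(size=(30, 2))
        X = coeff @ basis + 1.7
        im = InputMatrix(X, [f"g{i}" for i in range(30)], [f"s{j}" for j in range(5)])
        cb = initialize(im, map_r3, "linear", seed=0)
        centred = cb.prototypes - X.mean(axis=0)
        # independent span projection via SVD of the centred data
        U, s, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        span = Vt[s > 1e-9]
        residual = centred - (centred @ span.T) @ span
        assert np.abs(residual).max() < 1e-9

    def test_linear_falls_back_to_uniform_on_rank_deficient_data(self, map_r3):
        v = np.array([1.0, 2.0, 3.0])
        im = InputMatrix(
            np.outer(np.arange(1, 7), v), [f"g{i}" for i in range(6)], list("abc")
        )  # rank 1
        cb = initialize(im, map_r3, "linear", seed=5)
        assert np.isfinite(cb.prototypes).all()  # falls back, no crash

    def test_empty_input_rejected(self, map_r3):
        with pytest.raises(ValueError):
            InputMatrix(np.empty((0, 3)), [], list("abc"))


class TestFindBMU:
    def test_exact_prototype_wins(self, map_r3):
        rng = np.random.default_rng(0)
        cb = random_codebook(map_r3, 4, rng)
        cb.prototypes[4] = np.array([9.0, 9.0, 9.0, 9.0])
        winner, ties = find_bmu(cb, np.array([9.0, 9.0, 9.0, 9.0]))
        assert winner == 5 and ties == [5]

    def test_tie_goes_to_lowest_index(self, map_r3):
        rng = np.random.default_rng(1)
        cb = random_codebook(map_r3, 3, rng)
        v = np.array([5.0, 5.0, 5.0])
        cb.prototypes[2] = v + 0.1
        cb.prototypes[8] = v + 0.1
        winner, ties = find_bmu(cb, v)
        assert winner == 3 and ties == [3, 9]

    def test_matches_brute_force_on_200_random_pairs(self, map_r3):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cb = random_codebook(map_r3, 3, rng)
            v = rng.normal(size=3)
            winner, _ = find_bmu(cb, v)
            brute = min(
                range(1, map_r3.node_count + 1),
                key=lambda j: float(np.linalg.norm(cb.prototypes[j - 1] - v)),
            )
            assert winner == brute

    def test_dimension_mismatch_rejected(self, map_r3):
        cb = random_codebook(map_r3, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            find_bmu(cb, np.zeros(4))


class TestQuantizationError:
    def test_zero_when_rows_equal_prototypes(self, map_r3):
        rng = np.random.default_rng(2)
        cb = random_codebook(map_r3, 3, rng)
        im = InputMatrix(cb.prototypes[:5].copy(), [f"g{i}" for i in range(5)],
                         cb.col_ids)
        assert quantization_error(im, cb) == 0.0

    def test_equals_brute_force(self, map_r3):
        rng = np.random.default_rng(3)
        cb = random_codebook(map_r3, 2, rng)
        im = random_input(10, 2, rng)
        brute = np.mean([
            min(np.linalg.norm(row - p) for p in cb.prototypes)
            for row in im.values
        ])
        assert quantization_error(im, cb) == pytest.approx(brute, abs=1e-12)


def _one_epoch_config(kernel, sigma, algorithm="batch", init="uniform", seed=0):
    return TrainConfig(
        algorithm=algorithm,
        kernel=kernel,
        phases=[TrainPhase(1, sigma, sigma, 1.0, 1.0)],
        init=init,
        seed=seed,
    )


class TestTrainBatch:
    def test_identical_rows_collapse_prototypes(self, map_r3):
        v = np.array([1.0, -2.0, 0.5])
        im = InputMatrix(np.tile(v, (8, 1)), [f"g{i}" for i in range(8)], list("abc"))
        res = train_batch(im, map_r3, _one_epoch_config("gaussian", 2.0))
        assert np.allclose(res.codebook.prototypes, v)

    def test_delta_kernel_epoch_is_one_lloyd_step(self, map_r3):
        # sigma below the lattice spacing makes the bubble kernel a delta at
        # the BMU: the batch update must equal one k-means Lloyd step with
        # the initial prototypes as centroids (empty clusters keep theirs)
        rng = np.random.default_rng(11)
        im = random_input(30, 3, rng)
        cfg = _one_epoch_config("bubble", 0.45, seed=11)
        init = initialize(im, map_r3, "uniform", seed=11).prototypes
        res = train_batch(im, map_r3, cfg)
        assign = np.array([
            np.argmin(np.linalg.norm(init - row, axis=1)) for row in im.values
        ])
        lloyd = init.copy()
        for j in range(map_r3.node_count):
            members = im.values[assign == j]
            if len(members):
                lloyd[j] = members.mean(axis=0)
        assert np.abs(res.codebook.prototypes - lloyd).max() < 1e-9

    def test_qe_trace_non_increasing_in_fine_tune(self, planted_fixture, trained_fixture):
        # batch at fixed sigma is not strictly monotone in quantization
        # error; allow plateau jitter far below the signal scale
        ft = trained_fixture.qe_trace[10:]
        assert np.all(np.diff(ft) <= 1e-3)

    def test_prototypes_stay_in_affine_span_with_linear_init(self, map_r3):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        im = InputMatrix(X, [f"g{i}" for i in range(40)], list("abc"))
        cfg = TrainConfig(phases=[TrainPhase(5, 2.0, 1.0)], init="linear")
        res = train_batch(im, map_r3, cfg)
        # batch prototypes are convex combinations of data rows: affine span
        mean = X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
        span = Vt[s > 1e-9]
        centred = res.codebook.prototypes - mean
        residual = centred - (centred @ span.T) @ span
        assert np.abs(residual).max() < 1e-9

    def test_sign_flip_symmetric_data_gives_symmetric_codebook(self):
        rng = np.random.default_rng(2)
        half = rng.normal(size=(150, 4))
        X = np.vstack([half, -half])
        im = InputMatrix(X, [f"g{i}" for i in range(300)], list("abcd"))
        res = hx.train_on_matrix(im, radius=4, seed=2)
        P = res.codebook.prototypes
        assert abs(P.mean()) < 0.05 * P.std()
        assert P.min() == pytest.approx(-P.max(), rel=0.05)

    def test_deterministic_given_seed(self, map_r3):
        rng = np.random.default_rng(9)
        im = random_input(25, 3, rng)
        cfg = TrainConfig(phases=[TrainPhase(3, 2.0, 1.0)], init="uniform", seed=3)
        a = train_batch(im, map_r3, cfg)
        b = train_batch(im, map_r3, cfg)
        assert np.array_equal(a.codebook.prototypes, b.codebook.prototypes)
        assert np.array_equal(a.mapping.bmu, b.mapping.bmu)


class TestTrainSequential:
    def test_zero_alpha_leaves_codebook_at_init(self, map_r3):
        rng = np.random.default_rng(5)
        im = random_input(12, 3, rng)
        cfg = TrainConfig(
            algorithm="sequential",
            phases=[TrainPhase(2, 1.0, 1.0, 0.0, 0.0)],
            init="uniform",
            seed=4,
        )
        res = train_sequential(im, map_r3, cfg)
        init = initialize(im, map_r3, "uniform", seed=4).prototypes
        assert np.array_equal(res.codebook.prototypes, init)

    def test_single_row_single_node_full_rate_update(self):
        spec = hx.build_map(1)
        im = InputMatrix(np.array([[3.0, -1.0]]), ["g0"], ["a", "b"])
        cfg = _one_epoch_config("gaussian", 1.0, algorithm="sequential", seed=1)
        res = train_sequential(im, spec, cfg)
        assert np.allclose(res.codebook.prototypes, [[3.0, -1.0]])

    def test_bit_identical_across_runs(self, map_r3):
        rng = np.random.default_rng(6)
        im = random_input(15, 2, rng)
        cfg = TrainConfig(
            algorithm="sequential",
            phases=[TrainPhase(3, 2.0, 1.0, 0.3, 0.05)],
            init="uniform",
            seed=8,
        )
        a = train_sequential(im, map_r3, cfg)
        b = train_sequential(im, map_r3, cfg)
        assert np.array_equal(a.codebook.prototypes, b.codebook.prototypes)
        assert np.array_equal(a.qe_trace, b.qe_trace)


class TestSelfOrganisation:
    def test_same_cluster_genes_land_closer_than_cross_cluster(
        self, planted_fixture, trained_fixture
    ):
        from hexsom.hexgrid import output_distance_matrix

        labels = planted_fixture.labels
        bmu = trained_fixture.mapping.bmu
        D = output_distance_matrix(trained_fixture.codebook.spec)
        fg = labels > 0
        lab, pos = labels[fg], bmu[fg] - 1
        same, diff = [], []
        dmat = D[np.ix_(pos, pos)]
        eq = lab[:, None] == lab[None, :]
        iu = np.triu_indices(len(lab), k=1)
        same = dmat[iu][eq[iu]]
        diff = dmat[iu][~eq[iu]]
        assert same.mean() < diff.mean()


def test_auto_radius_heuristic():
    # smallest radius with node count >= 5 sqrt(G), capped at 15
    assert auto_radius(600) == 7
    assert auto_radius(1) == 2  # node_count(2) = 7 >= 5 * sqrt(1)
    assert auto_radius(10**8) == 15
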