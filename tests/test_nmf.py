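import numpy as np
import pandas as pd
import pytest

from lungplast.io import ExpressionMatrix, ValidationError
from lungplast.nmf import (
    NMFModel,
    _multiplicative_fit,
    assign_clusters,
    fit_nmf,
    project_onto_W,
)


def raw_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale_tag="raw"
    )


class TestFitNMF:
    def test_exact_rank_one_recovery(self, rng):
        u = rng.uniform(1, 2, size=20)
        v = rng.uniform(1, 2, size=6)
        matrix = raw_matrix(np.outer(u, v))
        model = fit_nmf(matrix, rank=1, n_restarts=3, seed=0)
        relative = model.reconstruction_error / np.linalg.norm(matrix.values, "fro")
        assert relative < 1e-6

    def test_objective_trace_non_increasing(self, rng):
        matrix = raw_matrix(rng.uniform(0, 5, size=(30, 8)))
        model = fit_nmf(matrix, rank=3, n_restarts=2, max_iter=200, seed=1)
        trace = np.asarray(model.objective_trace)
        assert (np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0)).all()

    def test_study_clusters_perfectly_by_cell_type(self, study):
        """Rank-3 factorization separates the three planted cell types."""
        matrix, annotation = study
        model = fit_nmf(matrix, rank=3, n_restarts=20, seed=7)
        clusters = assign_clusters(model)
        table = pd.crosstab(annotation.groups, pd.Series(clusters))
        assert table.shape == (3, 3)
        purity = table.max(axis=1).sum() / matrix.shape[1]
        assert purity == 1.0
        assert sorted(table.max(axis=0)) == [3, 3, 3]

    def test_best_restart_beats_single_restart(self, rng):
        matrix = raw_matrix(rng.uniform(0, 5, size=(40, 9)))
        single = fit_nmf(matrix, rank=3, n_restarts=1, seed=4)
        multi = fit_nmf(matrix, rank=3, n_restarts=8, seed=4)
        assert multi.reconstruction_error <= single.reconstruction_error + 1e-12

    def test_objective_matches_sklearn_within_one_percent(self, rng):
        from sklearn.decomposition import NMF as SKNMF

        matrix = raw_matrix(rng.uniform(0, 5, size=(50, 9)))
        model = fit_nmf(matrix, rank=3, n_restarts=10, seed=2)
        best = np.inf
        for seed in range(10):
            sk = SKNMF(
                n_components=3, init="random", random_state=seed, max_iter=2000, tol=1e-9
            )
            w = sk.fit_transform(matrix.values)
            err = np.linalg.norm(matrix.values - w @ sk.components_, "fro")
            best = min(best, err)
        assert model.reconstruction_error <= best * 1.01

    def test_update_rule_permutation_equivariance(self, rng):
        """Permuting V and the init permutes the fitted factors exactly."""
        v = rng.uniform(0, 5, size=(20, 6))
        w0 = rng.uniform(0.1, 1, size=(20, 3))
        h0 = rng.uniform(0.1, 1, size=(3, 6))
        rows = rng.permutation(20)
        cols = rng.permutation(6)
        w_a, h_a, _ = _multiplicative_fit(v, w0.copy(), h0.copy(), 50, 0)
        w_b, h_b, _ = _multiplicative_fit(
            v[np.ix_(rows, cols)], w0[rows].copy(), h0[:, cols].copy(), 50, 0
        )
        assert np.allclose(w_a[rows], w_b)
        assert np.allclose(h_a[:, cols], h_b)

    def test_rank_bounds_validated(self, rng):
        matrix = raw_matrix(rng.uniform(0, 1, size=(5, 4)))
        with pytest.raises(ValidationError):
            fit_nmf(matrix, rank=5)
        with pytest.raises(ValidationError):
            fit_nmf(matrix, rank=0)

    def test_log_scale_input_shifted(self, rng):
        matrix = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(20, 5)),
                index=[f"g{i}" for i in range(20)],
                columns=[f"s{j}" for j in range(5)],
            ),
            scale_tag="log2",
        )
        model = fit_nmf(matrix, rank=2, n_restarts=2, seed=0)
        assert model.shift > 0
        assert (model.W.to_numpy() >= 0).all()


class TestAssignClusters:
    def _model_with_H(self, h):
        h = np.asarray(h, dtype=float)
        k, n = h.shape
        return NMFModel(
            W=pd.DataFrame(np.ones((4, k)), columns=[f"F{i}" for i in range(k)]),
            H=pd.DataFrame(h, index=[f"F{i}" for i in range(k)],
                           columns=[f"s{j}" for j in range(n)]),
            rank=k,
            seed=0,
        )

    def test_argmax_assignment(self):
        model = self._model_with_H([[0.1], [0.8], [0.1]])
        assert assign_clusters(model) == {"s0": "F1"}

    def test_tie_resolves_to_lowest_factor(self):
        model = self._model_with_H([[0.5], [0.5], [0.0]])
        assert assign_clusters(model) == {"s0": "F0"}

    def test_sample_weights_sum_to_one(self, rng):
        h = rng.uniform(0.1, 1, size=(3, 5))
        weights = self._model_with_H(h).sample_weights
        assert np.allclose(weights.sum(axis=0), 1.0)


class TestProjectOntoW:
    def test_self_projection_recovers_training_weights(self, rng):
        matrix = raw_matrix(rng.uniform(0, 5, size=(60, 8)))
        model = fit_nmf(matrix, rank=3, n_restarts=5, seed=3, tol=1e-9, max_iter=5000)
        projected = project_onto_W(model.W, matrix, seed=3, tol=1e-10, max_iter=5000)
        assert np.allclose(
            projected.to_numpy(), model.sample_weights.to_numpy(), atol=1e-3
        )

    def test_single_factor_column_recovers_one_hot(self, rng):
        matrix = raw_matrix(rng.uniform(0, 5, size=(60, 8)))
        model = fit_nmf(matrix, rank=3, n_restarts=5, seed=3)
        column = raw_matrix(
            model.W[["F1"]].to_numpy(), genes=model.W.index.tolist(), samples=["probe"]
        )
        projected = project_onto_W(model.W, column, seed=0, tol=1e-10, max_iter=5000)[
            "probe"
        ]
        assert projected["F1"] == pytest.approx(1.0, abs=1e-3)

    def test_zero_profile_projects_to_zero(self, rng):
        matrix = raw_matrix(rng.uniform(0, 5, size=(30, 6)))
        model = fit_nmf(matrix, rank=2, n_restarts=3, seed=5)
        zeros = raw_matrix(
            np.zeros((30, 1)), genes=model.W.index.tolist(), samples=["blank"]
        )
        projected = project_onto_W(model.W, zeros, seed=0)
        assert np.allclose(projected.to_numpy(), 0.0)

    def test_insufficient_gene_overlap_rejected(self, rng):
        matrix = raw_matrix(rng.uniform(0, 5, size=(30, 6)))
        model = fit_nmf(matrix, rank=2, n_restarts=2, seed=5)
        other = raw_matrix(
            rng.uniform(0, 5, size=(10, 2)), genes=[f"other{i}" for i in range(10)]
        )
        with pytest.raises(ValidationError, match="cover"):
            project_onto_W(model.W, other)
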