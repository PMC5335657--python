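import numpy as np
import pytest

from longisel import (
    FitConfig,
    SimulationSpec,
    WeightStack,
    build_graphs,
    fit,
    generate,
    objective,
)
from longisel.graphs import l21_reweight_diag, laplacian, subject_similarity
from longisel.optimizer import (
    regularizer_feature,
    regularizer_score,
    regularizer_subject,
    solve_sylvester_step,
)


def double_sum_rows(sim, w):
    """Oracle: sum_{u,v} sim_uv * ||w_u - w_v||^2 over all ordered pairs."""
    n = sim.shape[0]
    total = 0.0
    for u in range(n):
        for v in range(n):
            total += sim[u, v] * np.sum((w[u] - w[v]) ** 2)
    return total


def kron_sylvester(a, b, q):
    """Dense vectorization oracle: (I (x) A + B' (x) I) vec(W) = vec(Q)."""
    f, c = q.shape
    lhs = np.kron(np.eye(c), a) + np.kron(b.T, np.eye(f))
    return np.linalg.solve(lhs, q.flatten(order="F")).reshape((f, c), order="F")


class TestWeightStack:
    def test_unfold_fold_roundtrip(self, rng):
        w = WeightStack(rng.normal(size=(3, 5, 2)))
        back = WeightStack.from_unfolded(w.unfolded, 3)
        np.testing.assert_array_equal(back.per_time, w.per_time)

    def test_unfolded_layout(self, rng):
        w = WeightStack(rng.normal(size=(2, 4, 3)))
        np.testing.assert_array_equal(w.unfolded[:, :3], w.per_time[0])
        np.testing.assert_array_equal(w.unfolded[:, 3:], w.per_time[1])

    def test_row_norm_zero_iff_inactive_everywhere(self):
        per_time = np.zeros((2, 3, 2))
        per_time[1, 2, 0] = 4.0
        norms = WeightStack(per_time).row_norms()
        assert norms[0] == 0 and norms[1] == 0 and norms[2] == 4.0


class TestRegularizers:
    def test_constant_rows_give_zero(self, rng):
        sim = subject_similarity(rng.normal(size=(4, 3)))
        lap = laplacian(sim)
        w = np.tile(rng.normal(size=(1, 2)), (4, 1))
        assert regularizer_feature(w, lap) == pytest.approx(0.0, abs=1e-12)

    def test_two_feature_closed_form(self):
        # similarity 0.5 between the two features, rows differing by a unit vector
        sim = np.array([[1.0, 0.5], [0.5, 1.0]])
        lap = laplacian(sim)
        w = np.array([[1.0, 0.0], [0.0, 0.0]])  # row difference has norm 1
        assert regularizer_feature(w, lap) == pytest.approx(0.5, abs=1e-12)

    def test_feature_trace_equals_half_double_sum(self, rng):
        sim = subject_similarity(rng.normal(size=(5, 3)))
        lap = laplacian(sim)
        w = rng.normal(size=(5, 3))
        assert regularizer_feature(w, lap) == pytest.approx(
            0.5 * double_sum_rows(sim, w), abs=1e-10
        )

    def test_subject_zero_weights(self, rng):
        x = rng.normal(size=(6, 4))
        lap = laplacian(subject_similarity(x))
        assert regularizer_subject(np.zeros((4, 2)), x, lap) == 0.0

    def test_identical_subjects_contribute_zero(self, rng):
        x = rng.normal(size=(2, 3))
        x[1] = x[0]
        sim = subject_similarity(x)
        lap = laplacian(sim)
        w = rng.normal(size=(3, 2))
        # only pair (0,1) exists and has zero predicted-score distance
        assert regularizer_subject(w, x, lap) == pytest.approx(0.0, abs=1e-10)

    def test_subject_trace_equals_half_double_sum(self, rng):
        x = rng.normal(size=(5, 4))
        sim = subject_similarity(x)
        lap = laplacian(sim)
        w = rng.normal(size=(4, 2))
        assert regularizer_subject(w, x, lap) == pytest.approx(
            0.5 * double_sum_rows(sim, x @ w), abs=1e-10
        )

    def test_score_single_column_is_zero(self, rng):
        lap = laplacian(np.ones((1, 1)))
        assert regularizer_score(rng.normal(size=(4, 1)), lap) == 0.0

    def test_identical_weight_columns_give_zero(self, rng):
        col = rng.normal(size=(4, 1))
        w = np.hstack([col, col])
        sim = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert regularizer_score(w, laplacian(sim)) == pytest.approx(0.0, abs=1e-12)

    def test_score_trace_equals_half_double_sum(self, rng):
        sim = subject_similarity(rng.normal(size=(3, 5)))
        w = rng.normal(size=(4, 3))
        assert regularizer_score(w, laplacian(sim)) == pytest.approx(
            0.5 * double_sum_rows(sim, w.T), abs=1e-10
        )

    def test_dimension_mismatch(self, rng):
        lap = laplacian(subject_similarity(rng.normal(size=(3, 2))))
        with pytest.raises(ValueError):
            regularizer_feature(rng.normal(size=(4, 2)), lap)


class TestObjective:
    def test_zero_weights(self, rng):
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(2, 5, 2))
        w = WeightStack(np.zeros((2, 3, 2)))
        cfg = FitConfig(lambda1=1.0, lambda2=1.0)
        graphs = build_graphs(x, y)
        assert objective(x, y, w, cfg, graphs) == pytest.approx(np.sum(y**2))

    def test_pure_loss_when_unregularized(self, rng):
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(2, 5, 2))
        w = WeightStack(rng.normal(size=(2, 3, 2)))
        cfg = FitConfig(lambda1=0.0, lambda2=0.0)
        graphs = build_graphs(x, y)
        expected = sum(
            np.sum((y[t] - x @ w.per_time[t]) ** 2) for t in range(2)
        )
        assert objective(x, y, w, cfg, graphs) == pytest.approx(expected)

    def test_matches_full_loop_oracle(self, rng):
        from longisel.graphs import feature_similarity, score_similarity

        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(2, 5, 2))
        w = WeightStack(rng.normal(size=(2, 3, 2)))
        lam1, lam2 = 0.7, 1.3
        cfg = FitConfig(lambda1=lam1, lambda2=lam2)
        graphs = build_graphs(x, y)

        sim_f = feature_similarity(x)
        sim_s = subject_similarity(x)
        expected = 0.0
        for t in range(2):
            wt = w.per_time[t]
            resid = y[t] - x @ wt
            for i in range(5):
                for j in range(2):
                    expected += resid[i, j] ** 2
            sim_c = score_similarity(y[t])
            expected += lam1 * (
                0.5 * double_sum_rows(sim_f, wt)
                + 0.5 * double_sum_rows(sim_s, x @ wt)
                + 0.5 * double_sum_rows(sim_c, wt.T)
            )
        for i in range(3):
            expected += lam2 * np.linalg.norm(w.unfolded[i])
        assert objective(x, y, w, cfg, graphs) == pytest.approx(expected, abs=1e-9)


class TestSylvester:
    def test_reduces_to_linear_solve_when_b_zero(self, rng):
        a = rng.normal(size=(4, 4))
        a = a @ a.T + np.eye(4)
        q = rng.normal(size=(4, 2))
        w = solve_sylvester_step(a, np.zeros((2, 2)), q)
        np.testing.assert_allclose(w, np.linalg.solve(a, q), atol=1e-10)

    def test_scalar_case(self):
        w = solve_sylvester_step(np.array([[2.0]]), np.array([[3.0]]), np.array([[10.0]]))
        assert w[0, 0] == pytest.approx(2.0)

    def test_matches_kronecker_oracle(self, rng):
        a = rng.normal(size=(8, 8))
        a = a @ a.T + 0.5 * np.eye(8)
        b = rng.normal(size=(3, 3))
        b = b @ b.T
        q = rng.normal(size=(8, 3))
        np.testing.assert_allclose(
            solve_sylvester_step(a, b, q), kron_sylvester(a, b, q), atol=1e-9
        )

    def test_singular_system_raises(self):
        # A and -B share eigenvalue 0
        a = np.zeros((2, 2))
        b = np.zeros((1, 1))
        q = np.ones((2, 1))
        with pytest.raises(ValueError, match="ridge"):
            solve_sylvester_step(a, b, q)


class TestFit:
    def test_ols_limit(self, rng):
        x = rng.normal(size=(30, 5))
        y = rng.normal(size=(3, 30, 2))
        result = fit(x, y, FitConfig(lambda1=0.0, lambda2=0.0))
        for t in range(3):
            ols = np.linalg.solve(x.T @ x, x.T @ y[t])
            np.testing.assert_allclose(result.weights.per_time[t], ols, atol=1e-6)

    @pytest.mark.parametrize("lam1", [0.0, 0.1, 1.0, 10.0])
    @pytest.mark.parametrize("lam2", [0.0, 0.1, 1.0, 10.0])
    def test_monotone_descent_grid(self, small_cohort, lam1, lam2):
        result = fit(small_cohort.x, small_cohort.y, FitConfig(lambda1=lam1, lambda2=lam2))
        trace = np.asarray(result.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_converges_on_synthetic_default(self):
        cohort = generate(
            SimulationSpec(n_subjects=100, n_features=93, n_scores=2, n_timepoints=4, seed=5)
        )
        result = fit(cohort.x, cohort.y, FitConfig(lambda1=0.1, lambda2=1.0))
        assert result.converged
        assert result.n_iter < 50

    def test_trace_lengths_and_row_norms(self, small_cohort):
        result = fit(small_cohort.x, small_cohort.y, FitConfig(lambda1=0.1, lambda2=1.0))
        assert len(result.objective_trace) == result.n_iter + 1
        np.testing.assert_allclose(
            result.row_norms, result.weights.row_norms(), atol=1e-12
        )

    def test_permutation_equivariance(self, rng):
        x = rng.normal(size=(25, 8))
        y = rng.normal(size=(2, 25, 2))
        cfg = FitConfig(lambda1=0.5, lambda2=0.5)
        base = fit(x, y, cfg)
        perm = rng.permutation(8)
        permuted = fit(x[:, perm], y, cfg)
        for t in range(2):
            np.testing.assert_allclose(
                permuted.weights.per_time[t],
                base.weights.per_time[t][perm],
                atol=1e-8,
            )
        graphs = build_graphs(x, y, None)
        obj_base = objective(x, y, base.weights, cfg, graphs)
        graphs_p = build_graphs(x[:, perm], y, None)
        obj_perm = objective(x[:, perm], y, permuted.weights, cfg, graphs_p)
        assert obj_perm == pytest.approx(obj_base, rel=1e-9, abs=1e-9)

    def test_joint_row_sparsity_structure(self, small_cohort):
        result = fit(small_cohort.x, small_cohort.y, FitConfig(lambda1=0.1, lambda2=50.0))
        per_time_max = np.abs(result.weights.per_time).max(axis=(0, 2))
        assert np.all(per_time_max <= 10.0 * result.row_norms + 1e-12)

    def test_shrinkage_with_lambda2(self, small_cohort):
        sums = []
        for lam2 in [0.0, 1.0, 10.0, 100.0, 1000.0]:
            result = fit(small_cohort.x, small_cohort.y, FitConfig(lambda1=0.1, lambda2=lam2))
            sums.append(result.row_norms.sum())
        assert all(a >= b - 1e-9 for a, b in zip(sums, sums[1:]))

    def test_l21_fixed_point_identity(self, small_cohort):
        cfg = FitConfig(lambda1=0.1, lambda2=1.0, tol=1e-14, max_iter=200)
        result = fit(small_cohort.x, small_cohort.y, cfg)
        unfolded = result.weights.unfolded
        d = np.diag(l21_reweight_diag(unfolded, cfg.epsilon_l21))
        norms = np.linalg.norm(unfolded, axis=1)
        ok = norms > 1e-6  # non-degenerate rows
        np.testing.assert_allclose(2.0 * d[ok] * norms[ok], 1.0, atol=1e-8)

    def test_subject_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            fit(rng.normal(size=(10, 3)), rng.normal(size=(2, 11, 2)), FitConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(lambda1=-1.0)
        with pytest.raises(ValueError):
            FitConfig(max_iter=0)
        with pytest.raises(ValueError):
            FitConfig(tol=0.0)
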