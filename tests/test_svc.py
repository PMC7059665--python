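"""SMO solver against analytic solutions and a dense-QP oracle; one-vs-one
voting; the log-decade grid search."""

import numpy as np
import pytest
from scipy.optimize import minimize

from hsistress.svc import (BinarySVCModel, RBFSupportVectorClassifier,
                           decision_value, default_grid, dual_objective,
                           grid_search, rbf_kernel, solve_binary_svc,
                           train_multiclass_svc)


def qp_dual_oracle(X, y, C, gamma):
    """Independent dense solve of the SVC dual (test-only oracle).

    Uses libsvm (via scikit-learn) to obtain the optimal multipliers and
    evaluates the dual objective from them; entirely independent of the
    package's SMO code path.
    """
    from sklearn.svm import SVC

    K = rbf_kernel(X, X, gamma)
    Q = np.outer(y, y) * K
    ref = SVC(C=C, gamma=gamma, tol=1e-10, max_iter=-1).fit(X, y)
    a = np.zeros(len(y))
    a[ref.support_] = np.abs(ref.dual_coef_[0])
    return 0.5 * a @ Q @ a - a.sum(), a


def slsqp_dual_oracle(X, y, C, gamma):
    """Generic convex-QP solve of the dual via SLSQP."""
    K = rbf_kernel(X, X, gamma)
    Q = np.outer(y, y) * K
    n = len(y)
    res = minimize(lambda a: 0.5 * a @ Q @ a - a.sum(),
                   np.zeros(n),
                   jac=lambda a: Q @ a - 1.0,
                   bounds=[(0.0, C)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                 "jac": lambda a: y}],
                   method="SLSQP", options={"maxiter": 3000, "ftol": 1e-14})
    assert res.success
    return res.fun, res.x


def _random_binary_problem(rng):
    n = int(rng.integers(6, 26))
    X = rng.normal(size=(n, int(rng.integers(1, 5))))
    y = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    C = float(rng.choice([0.1, 1.0, 10.0]))
    gamma = float(rng.choice([0.1, 0.5, 2.0]))
    return X, y, C, gamma


class TestRbfKernel:
    def test_zero_distance_is_one(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 3.0) == pytest.approx(1.0)

    def test_unit_distance_closed_form(self):
        assert rbf_kernel([0.0], [1.0], 1.0) == pytest.approx(np.exp(-1),
                                                              abs=1e-12)

    def test_symmetry(self, rng):
        u, v = rng.normal(size=4), rng.normal(size=4)
        assert rbf_kernel(u, v, 0.7) == pytest.approx(rbf_kernel(v, u, 0.7))

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            rbf_kernel([0.0], [1.0], 0.0)


class TestBinarySolver:
    def test_analytic_two_point_problem(self):
        """Two points at distance 1, huge C: the equality-constrained dual
        maximizes 2a - a^2 (1 - e^-1), so a = 1/(1 - e^-1) and b = 0."""
        X = np.array([[0.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = solve_binary_svc(X, y, C=1e6, gamma=1.0, tol=1e-8)
        expected = 1.0 / (1.0 - np.exp(-1.0))
        np.testing.assert_allclose(model.alpha, expected, atol=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        assert decision_value(model, np.array([0.5])) == pytest.approx(
            0.0, abs=1e-10)

    def test_duplicated_points_leave_decision_unchanged(self):
        X1 = np.array([[0.0], [1.0]])
        y1 = np.array([-1.0, 1.0])
        X2 = np.array([[0.0], [1.0], [0.0], [1.0]])
        y2 = np.array([-1.0, 1.0, -1.0, 1.0])
        m1 = solve_binary_svc(X1, y1, C=1e6, gamma=1.0, tol=1e-10)
        m2 = solve_binary_svc(X2, y2, C=1e6, gamma=1.0, tol=1e-10)
        for x in np.linspace(-1, 2, 7):
            assert decision_value(m2, np.array([x])) == pytest.approx(
                decision_value(m1, np.array([x])), abs=1e-6)

    def test_dual_objective_matches_qp_oracle_on_12_sample_fixture(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(12, 3))
        y = np.array([-1.0] * 6 + [1.0] * 6)
        model = solve_binary_svc(X, y, C=1.0, gamma=0.5, tol=1e-8)
        obj = dual_objective(model, X, y)
        ref, _ = qp_dual_oracle(X, y, 1.0, 0.5)
        assert obj == pytest.approx(ref, abs=1e-6)
        generic, _ = slsqp_dual_oracle(X, y, 1.0, 0.5)
        assert obj == pytest.approx(generic, abs=1e-6)

    def test_dual_feasibility_and_stationarity(self, rng):
        for _ in range(5):
            X, y, C, gamma = _random_binary_problem(rng)
            model = solve_binary_svc(X, y, C, gamma, tol=1e-6)
            assert np.all(model.alpha >= -1e-12)
            assert np.all(model.alpha <= C + 1e-12)
            assert abs(model.alpha @ y) < 1e-8
            assert model.kkt_violation <= 1e-6

    def test_free_support_vectors_sit_on_margin(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-1, 0.6, size=(10, 2)),
                       rng.normal(1, 0.6, size=(10, 2))])
        y = np.array([-1.0] * 10 + [1.0] * 10)
        tol = 1e-8
        model = solve_binary_svc(X, y, C=1.0, gamma=0.5, tol=tol)
        free = (model.alpha > 1e-6) & (model.alpha < 1.0 - 1e-6)
        assert free.any()
        f = model.decision_function(X[free])
        np.testing.assert_allclose(y[free] * f, 1.0, atol=1e-6)

    def test_far_query_decays_to_bias(self):
        model = solve_binary_svc(np.array([[0.0], [1.0]]),
                                 np.array([-1.0, 1.0]), 10.0, 1.0)
        far = decision_value(model, np.array([1e4]))
        assert far == pytest.approx(model.bias, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            solve_binary_svc(np.zeros((3, 1)), np.ones(3), 1.0, 1.0)

    def test_dimension_mismatch_rejected(self):
        model = solve_binary_svc(np.array([[0.0], [1.0]]),
                                 np.array([-1.0, 1.0]), 1.0, 1.0)
        with pytest.raises(ValueError, match="dimension"):
            model.decision_function(np.zeros((1, 2)))

    def test_input_scaling_with_compensated_gamma_is_invariant(self, rng):
        X, y, C, gamma = _random_binary_problem(rng)
        s = 3.7
        m1 = solve_binary_svc(X, y, C, gamma, tol=1e-10)
        m2 = solve_binary_svc(X * s, y, C, gamma / s**2, tol=1e-10)
        query = rng.normal(size=(5, X.shape[1]))
        np.testing.assert_allclose(m2.decision_function(query * s),
                                   m1.decision_function(query), atol=1e-8)


class TestOracleSweep:
    def test_objective_matches_oracle_on_many_random_fixtures(self):
        """>= 20 random problems with n <= 25: SMO dual objective within
        1e-6 of the dense-QP solution."""
        rng = np.random.default_rng(2024)
        for _ in range(22):
            X, y, C, gamma = _random_binary_problem(rng)
            model = solve_binary_svc(X, y, C, gamma, tol=1e-9)
            obj = dual_objective(model, X, y)
            ref, _ = qp_dual_oracle(X, y, C, gamma)
            assert obj == pytest.approx(ref, abs=1e-6)

    def test_decision_values_match_libsvm(self):
        """Cross-check against the independent libsvm implementation."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(-1, 0.8, size=(12, 2)),
                       rng.normal(1, 0.8, size=(12, 2))])
        y = np.array([-1.0] * 12 + [1.0] * 12)
        mine = solve_binary_svc(X, y, C=2.0, gamma=0.5, tol=1e-10)
        ref = SVC(C=2.0, gamma=0.5, tol=1e-10).fit(X, y)
        query = rng.normal(size=(10, 2))
        np.testing.assert_allclose(mine.decision_function(query),
                                   ref.decision_function(query), atol=1e-5)


def _separated_three_class(rng, n_per=8, spread=0.1):
    centers = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
    X = np.vstack([c + rng.normal(0, spread, size=(n_per, 2))
                   for c in centers])
    y = np.repeat([1, 2, 3], n_per)
    return X, y


class TestMulticlass:
    def test_three_classes_give_three_machines(self, rng):
        X, y = _separated_three_class(rng)
        model = train_multiclass_svc(X, y, C=10.0, gamma=0.5)
        assert set(model.machines_) == {(1, 2), (1, 3), (2, 3)}

    def test_two_classes_reduce_to_binary(self, rng):
        X, y = _separated_three_class(rng)
        sel = y != 3
        model = train_multiclass_svc(X[sel], y[sel], C=10.0, gamma=0.5)
        binary = solve_binary_svc(X[sel], np.where(y[sel] == 1, 1.0, -1.0),
                                  10.0, 0.5, class_pair=(1, 2))
        machine = model.machines_[(1, 2)]
        query = rng.normal(size=(5, 2))
        np.testing.assert_allclose(machine.decision_function(query),
                                   binary.decision_function(query), atol=1e-8)

    def test_separated_classes_perfect_training_accuracy(self, rng):
        X, y = _separated_three_class(rng)
        model = train_multiclass_svc(X, y, C=100.0, gamma=0.5)
        assert np.array_equal(model.predict(X), y)

    def test_prediction_invariant_to_sample_order(self, rng):
        X, y = _separated_three_class(rng)
        model = train_multiclass_svc(X, y, C=10.0, gamma=0.5)
        query = rng.normal(size=(6, 2)) * 3
        perm = rng.permutation(6)
        np.testing.assert_array_equal(model.predict(query)[perm],
                                      model.predict(query[perm]))

    def _tied_vote_model(self, biases):
        """Hand-built ensemble whose machines output constant decisions."""
        model = RBFSupportVectorClassifier(C=1.0, gamma=1.0)
        model.classes_ = np.array([1, 2, 3])
        model.n_features_in_ = 1
        model.machines_ = {}
        for pair, bias in zip(((1, 2), (1, 3), (2, 3)), biases):
            model.machines_[pair] = BinarySVCModel(
                support_vectors=np.zeros((1, 1)), dual_coef=np.zeros(1),
                bias=bias, gamma=1.0, cost=1.0, class_pair=pair)
        return model

    def test_cyclic_tie_resolved_by_confidence_then_smallest_label(self):
        # votes 1-1-1: (1,2)->1, (1,3)->3, (2,3)->2
        x = np.zeros((1, 1))
        model = self._tied_vote_model([+1.0, -1.0, +0.5])
        # confidences: label1 = 1.0, label3 = 1.0, label2 = 0.5 -> {1,3} -> 1
        assert model.predict(x)[0] == 1
        model = self._tied_vote_model([+0.5, -1.0, +1.0])
        # confidences: label1 = 0.5, label3 = 1.0, label2 = 1.0 -> {2,3} -> 2
        assert model.predict(x)[0] == 2
        model = self._tied_vote_model([+1.0, -1.0, +1.0])
        # all confidences equal -> smallest label wins
        assert model.predict(x)[0] == 1

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError, match="classes"):
            train_multiclass_svc(rng.normal(size=(4, 2)), np.ones(4), 1.0, 1.0)


class TestGridSearch:
    def test_default_grid_has_289_cells(self):
        grid = default_grid()
        assert len(grid) == 289
        decades = sorted({c for c, _ in grid})
        assert decades[0] == 1e-8 and decades[-1] == 1e8

    def test_single_cell_grid_is_chosen(self, rng):
        X, y = _separated_three_class(rng)
        res = grid_search((X, y), (X, y), grid=[(3.0, 0.25)])
        assert res.best_C == 3.0 and res.best_gamma == 0.25

    def test_separated_fixture_reaches_perfect_validation(self, rng):
        X, y = _separated_three_class(rng, n_per=6)
        Xv, yv = _separated_three_class(rng, n_per=3)
        res = grid_search((X, y), (Xv, yv),
                          grid=default_grid(-4, 4))
        assert res.best_val_accuracy == 1.0

    def test_tie_break_prefers_smaller_parameters(self, rng):
        X, y = _separated_three_class(rng)
        grid = [(10.0, 0.5), (1.0, 0.5), (1.0, 0.1)]
        res = grid_search((X, y), (X, y), grid=grid)
        # all cells reach 100/100; smallest C then smallest gamma wins
        assert (res.best_C, res.best_gamma) == (1.0, 0.1)

    def test_training_accuracy_nondecreasing_in_C(self):
        """Soft-margin relaxation: larger C penalizes training errors more."""
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-1.0, 1.0, size=(15, 2)),
                       rng.normal(1.0, 1.0, size=(15, 2))])
        y = np.repeat([1, 2], 15)
        accs = []
        for C in [10.0 ** n for n in range(-2, 5)]:
            model = train_multiclass_svc(X, y, C=C, gamma=0.5)
            accs.append((model.predict(X) == y).mean())
        assert np.all(np.diff(accs) >= -1e-12)
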