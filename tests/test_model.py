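"""Lambda grid, patch-pooled lasso, grouped CV, and Fibrosis Scores."""

import numpy as np
import pytest

from fibroscore.errors import InvalidArgumentError, ShapeError
from fibroscore.model import (
    FibrosisModel,
    FibrosisScoreRegressor,
    evaluate_scores,
    fit_lasso_patchwise,
    make_lambda_grid,
    predict_fibrosis_score,
    select_lambda_grouped_cv,
)


class TestLambdaGrid:
    def test_default_grid_endpoints_and_size(self):
        g = make_lambda_grid()
        assert g.n == 16
        assert g.values[0] == pytest.approx(1e-5)
        assert g.values[-1] == pytest.approx(1e3)

    def test_log_spacing_has_constant_ratio(self):
        g = make_lambda_grid()
        ratios = g.values[1:] / g.values[:-1]
        assert np.allclose(ratios, 10 ** (8 / 15))

    def test_two_point_grid(self):
        g = make_lambda_grid(2, -1, 1)
        assert np.allclose(g.values, [0.1, 10.0])

    def test_rejects_degenerate_grid(self):
        with pytest.raises(InvalidArgumentError):
            make_lambda_grid(1)


def _linear_patch_data(rng, n_biopsies=25, patches=20, D=5, noise=0.5):
    """Patch matrices with a planted linear biopsy-level signal."""
    w = np.array([3.0, -2.0, 1.0, 0.0, 0.0])[:D]
    mats, labels = [], []
    for _ in range(n_biopsies):
        center = rng.normal(0, 1, D)
        M = center + rng.normal(0, 0.3, (patches, D))
        mats.append(M)
        labels.append(25 + center @ w + rng.normal(0, noise))
    return mats, np.array(labels)


class TestLassoFit:
    def test_zero_penalty_matches_normal_equations(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=25, patches=20, D=5)
        model = fit_lasso_patchwise(mats, labels, lam=0.0)
        # oracle: OLS by normal equations on the standardized pooled rows
        X = np.vstack(mats)
        y = np.concatenate([np.full(20, lab) for lab in labels])
        Z = (X - X.mean(0)) / X.std(0)
        A = np.column_stack([np.ones(len(Z)), Z])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_strong_penalty_collapses_to_training_mean(self, rng):
        mats, labels = _linear_patch_data(rng)
        model = fit_lasso_patchwise(mats, labels, lam=1e3)
        assert np.all(model.coefficients == 0.0)
        fs = predict_fibrosis_score(model, rng.normal(0, 5, (30, 5)))
        assert fs.score == pytest.approx(labels.mean())  # patch-replicated mean
        assert np.allclose(fs.patch_predictions, labels.mean())

    def test_constant_labels_give_flat_model(self, rng):
        mats, _ = _linear_patch_data(rng, n_biopsies=6)
        model = fit_lasso_patchwise(mats, np.full(6, 30.0), lam=0.1)
        assert np.all(model.coefficients == 0.0)
        assert model.intercept == 30.0

    def test_sparsity_nonincreasing_along_grid(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=30, D=5, noise=2.0)
        counts = [
            int(np.count_nonzero(fit_lasso_patchwise(mats, labels, lam=l).coefficients))
            for l in make_lambda_grid().values
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_model_json_round_trip(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=8)
        model = fit_lasso_patchwise(mats, labels, lam=0.05)
        back = FibrosisModel.from_json(model.to_json())
        assert np.allclose(back.coefficients, model.coefficients)
        assert back.lam == model.lam


class TestGroupedCV:
    def test_two_patients_give_two_partitioning_folds(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=6)
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        lam, table = select_lambda_grouped_cv(mats, labels, groups, seed=3)
        assert sorted(table["fold"].unique().tolist()) == [0, 1]
        tested = set()
        for _, sub in table.groupby("fold"):
            pats = set(sub["test_patients"].iloc[0].split(","))
            assert not pats & tested or pats.isdisjoint(tested)
            tested |= pats
        assert tested == {"A", "B"}

    def test_folds_never_share_a_patient(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=30)
        groups = np.repeat([f"P{i}" for i in range(10)], 3)
        lam, table = select_lambda_grouped_cv(mats, labels, groups, seed=1)
        all_pat = set(groups)
        for _, sub in table.groupby("fold"):
            test_pats = set(sub["test_patients"].iloc[0].split(","))
            # train set is the complement; sharing would be a fold overlap
            assert test_pats < all_pat

    def test_equal_cv_errors_break_toward_larger_lambda(self, rng):
        # constant labels make every lambda's held-out error identical
        mats, _ = _linear_patch_data(rng, n_biopsies=6)
        groups = np.array(["A", "A", "B", "B", "C", "C"])
        lam, _ = select_lambda_grouped_cv(mats, np.full(6, 20.0), groups, seed=0)
        assert lam == pytest.approx(1e3)

    def test_interior_optimum_with_planted_signal_and_noise(self):
        # a sparse strong signal among many noise features with noisy
        # labels: the near-OLS end overfits and the constant-mean end
        # underfits, so the CV minimum should fall strictly inside the grid
        hits = 0
        grid = make_lambda_grid().values
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            mats, labels = [], []
            w = np.concatenate([[6.0, -4.0, 3.0], np.zeros(57)])
            for _ in range(18):
                center = rng.normal(0, 1, 60)
                mats.append(center + rng.normal(0, 1.0, (8, 60)))
                labels.append(25 + center @ w + rng.normal(0, 4.0))
            groups = np.repeat([f"P{i}" for i in range(6)], 3)
            lam, _ = select_lambda_grouped_cv(mats, np.array(labels), groups, seed=rep)
            hits += grid[0] < lam < grid[-1]
        assert hits >= 16  # interior optimum in >= 80% of replicates

    def test_single_patient_rejected(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=3)
        with pytest.raises(InvalidArgumentError):
            select_lambda_grouped_cv(mats, labels, ["A", "A", "A"], seed=0)


class TestScores:
    def test_score_is_mean_of_patch_predictions(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=8)
        model = fit_lasso_patchwise(mats, labels, lam=0.01)
        fs = predict_fibrosis_score(model, mats[0])
        assert fs.score == pytest.approx(fs.patch_predictions.mean(), rel=1e-14)

    def test_score_invariant_to_patch_order(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=8)
        model = fit_lasso_patchwise(mats, labels, lam=0.01)
        perm = rng.permutation(mats[0].shape[0])
        assert predict_fibrosis_score(model, mats[0]).score == pytest.approx(
            predict_fibrosis_score(model, mats[0][perm]).score
        )

    def test_dimension_mismatch_is_shape_error(self, rng):
        mats, labels = _linear_patch_data(rng, n_biopsies=6)
        model = fit_lasso_patchwise(mats, labels, lam=0.1)
        with pytest.raises(ShapeError):
            predict_fibrosis_score(model, rng.normal(size=(10, 7)))

    def test_evaluate_scores_trivial_correlations(self):
        labels = [10.0, 20.0, 30.0, 40.0]
        assert evaluate_scores(labels, labels).rho == pytest.approx(1.0)
        assert evaluate_scores(labels[::-1], labels).rho == pytest.approx(-1.0)
        with pytest.raises(InvalidArgumentError):
            evaluate_scores([1.0, 2.0], [2.0, 1.0])

    def test_estimator_supports_sklearn_param_protocol(self):
        est = FibrosisScoreRegressor(lam=0.5)
        assert est.get_params()["lam"] == 0.5
        est.set_params(lam=1.0)
        assert est.lam == 1.0
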