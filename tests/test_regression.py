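"""Bounded-variable least squares, selection, contributions and VIF."""

import numpy as np
import pandas as pd
import pytest

from expr_attributor.regression import (
    DesignSpec,
    RankDeficientError,
    contributions,
    fit_bounded,
    infer_ols,
    predict,
    select_model,
    vif,
)
from expr_attributor.synthetic import SimulationConfig, simulate_cohort
from expr_attributor.tf_activity import compute_activity, select_unique_targets


def _frame(arr, names):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=names, index=[f"P{i}" for i in range(len(arr))])


def grid_bvls_oracle(y, X, box=(0.0, 5.0), step=1e-3):
    """Brute-force oracle: minimize ||y - b0 - X b||^2 over a coefficient
    grid with the intercept profiled out in closed form."""
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    g = np.arange(box[0], box[1] + step / 2, step)
    H = Xc.T @ Xc
    c = Xc.T @ yc
    best_val, best_b = np.inf, None
    for b1 in g:  # chunk over the first coordinate to bound memory
        vals = (
            H[0, 0] * b1**2
            + 2 * H[0, 1] * b1 * g
            + H[1, 1] * g**2
            - 2 * (c[0] * b1 + c[1] * g)
        )
        j = int(np.argmin(vals))
        if vals[j] < best_val:
            best_val, best_b = vals[j], np.array([b1, g[j]])
    b0 = float(y.mean() - X.mean(axis=0) @ best_b)
    return b0, best_b


class TestFitBounded:
    def test_matches_ols_when_bounds_inactive(self):
        rng = np.random.default_rng(0)
        X = rng.normal(4, 1, size=(60, 3))
        y = 1.0 + X @ np.array([0.8, 1.2, 0.5]) + rng.normal(0, 0.3, 60)
        Xf = _frame(X, ["a", "b", "c"])
        spec = DesignSpec.nonnegative(["a", "b", "c"], free=())
        b0, betas = fit_bounded(pd.Series(y, index=Xf.index), Xf, spec)
        ols = infer_ols(pd.Series(y, index=Xf.index), Xf)
        assert b0 == pytest.approx(ols.params["const"], abs=1e-8)
        assert np.allclose(betas, ols.params.drop("const"), atol=1e-8)

    def test_unbounded_equals_ols_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(40, 2))
        y = X @ np.array([-1.5, 2.0]) + rng.normal(0, 0.5, 40)
        Xf = _frame(X, ["a", "b"])
        spec = DesignSpec.unbounded(["a", "b"])
        b0, betas = fit_bounded(pd.Series(y, index=Xf.index), Xf, spec)
        design = np.column_stack([np.ones(40), X])
        closed = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose([b0, *betas], closed, atol=1e-8)

    def test_negative_slope_pinned_at_zero(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = pd.Series(5.0 - 2.0 * x, index=[f"P{i}" for i in range(4)])
        Xf = _frame(x[:, None], ["a"])
        spec = DesignSpec.nonnegative(["a"], free=())
        b0, betas = fit_bounded(y, Xf, spec)
        assert betas["a"] == 0.0  # exactly at the bound
        assert b0 == pytest.approx(y.mean())

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(0, 1, size=(30, 2))
        y = 0.5 + X @ np.array([1.2, -0.7]) + rng.normal(0, 0.4, 30)
        Xf = _frame(X, ["a", "b"])
        spec = DesignSpec(
            ["a", "b"], {"a": 0.0, "b": 0.0}, {"a": 5.0, "b": 5.0}
        )
        _, betas = fit_bounded(pd.Series(y, index=Xf.index), Xf, spec)
        _, grid_b = grid_bvls_oracle(y, X)
        assert np.allclose(betas, grid_b, atol=1e-3)

    def test_rank_deficient_error(self):
        X = np.ones((10, 2))
        Xf = _frame(X, ["a", "b"])
        y = pd.Series(np.arange(10.0), index=Xf.index)
        with pytest.raises(RankDeficientError):
            fit_bounded(y, Xf, DesignSpec.unbounded(["a", "b"]))


class TestInferOls:
    def test_exact_line(self):
        Xf = _frame(np.array([[0.0], [1.0], [2.0]]), ["x"])
        y = pd.Series([1.0, 3.0, 5.0], index=Xf.index)
        res = infer_ols(y, Xf)
        assert res.params["const"] == pytest.approx(1.0)
        assert res.params["x"] == pytest.approx(2.0)

    def test_noise_free_r2_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(20, 2))
        y = 2.0 + X @ np.array([1.0, -1.0])
        Xf = _frame(X, ["a", "b"])
        res = infer_ols(pd.Series(y, index=Xf.index), Xf)
        assert res.rsquared == pytest.approx(1.0)
        assert np.allclose(res.resid, 0, atol=1e-10)

    def test_null_pvalues_calibrated(self):
        """Coefficient p-values are uniform when y is independent of X."""
        rng = np.random.default_rng(4)
        hits, reps = 0, 400
        for _ in range(reps):
            X = _frame(rng.normal(0, 1, size=(50, 1)), ["x"])
            y = pd.Series(rng.normal(0, 1, 50), index=X.index)
            hits += infer_ols(y, X).pvalues["x"] < 0.05
        # binomial(400, .05): 3.3 sigma band
        assert abs(hits / reps - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / reps)


class TestSelectModel:
    def _recovery_inputs(self, seed):
        bundle, truth = simulate_cohort(SimulationConfig(seed=seed))
        sets = select_unique_targets(
            truth.regulons,
            truth.config.tf_names,
            exclude=[bundle.target_gene_id],
            expressed=bundle.mrna.feature_ids,
        )
        activity = compute_activity(bundle.mrna, sets)
        return bundle.target_expression, activity.T, truth

    def test_recovers_true_active_set(self):
        y, X, truth = self._recovery_inputs(seed=0)
        spec = DesignSpec.nonnegative(list(X.columns), free=("BRD4",))
        fit = select_model(y, X, spec, alpha=0.001)
        assert sorted(fit.selected) == sorted(truth.config.true_beta)
        assert (fit.pvalues < 0.001).all()

    def test_all_noise_gives_intercept_only(self):
        rng = np.random.default_rng(5)
        X = _frame(rng.normal(4, 1, size=(200, 5)), list("abcde"))
        y = pd.Series(rng.normal(0, 1, 200), index=X.index)
        spec = DesignSpec.nonnegative(list(X.columns), free=())
        fit = select_model(y, X, spec, alpha=0.001)
        assert fit.intercept_only or len(fit.selected) == 0
        assert fit.beta0 == pytest.approx(y.mean())
        assert fit.r2 == 0.0

    def test_invariant_to_column_order(self):
        y, X, _ = self._recovery_inputs(seed=1)
        spec = DesignSpec.nonnegative(list(X.columns), free=("BRD4",))
        fit1 = select_model(y, X, spec, alpha=0.001)
        shuffled = X[list(X.columns[::-1])]
        spec2 = DesignSpec.nonnegative(list(shuffled.columns), free=("BRD4",))
        fit2 = select_model(y, shuffled, spec2, alpha=0.001)
        assert sorted(fit1.selected) == sorted(fit2.selected)
        assert np.allclose(
            fit1.betas.sort_index(), fit2.betas.sort_index(), atol=1e-10
        )

    def test_residual_mean_near_zero(self):
        y, X, _ = self._recovery_inputs(seed=2)
        spec = DesignSpec.nonnegative(list(X.columns), free=("BRD4",))
        fit = select_model(y, X, spec, alpha=0.001)
        assert abs(fit.residuals.mean()) < 1e-8 * y.std()


class TestPredict:
    def test_training_identity(self):
        y, X, _ = TestSelectModel()._recovery_inputs(seed=3)
        spec = DesignSpec.nonnegative(list(X.columns), free=("BRD4",))
        fit = select_model(y, X, spec)
        yhat = predict(fit, X)
        assert np.allclose(yhat, y - fit.residuals, atol=1e-10)

    def test_zero_activities_give_intercept(self):
        y, X, _ = TestSelectModel()._recovery_inputs(seed=3)
        spec = DesignSpec.nonnegative(list(X.columns), free=("BRD4",))
        fit = select_model(y, X, spec)
        zeros = X.iloc[:3] * 0.0
        assert np.allclose(predict(fit, zeros), fit.beta0)

    def test_missing_column_error(self):
        y, X, _ = TestSelectModel()._recovery_inputs(seed=3)
        spec = DesignSpec.nonnegative(list(X.columns), free=("BRD4",))
        fit = select_model(y, X, spec)
        with pytest.raises(ValueError, match="missing"):
            predict(fit, X.drop(columns=fit.selected[:1]))


class TestContributions:
    def _fit(self, betas, X):
        from expr_attributor.regression import FitResult

        return FitResult(
            beta0=0.0,
            betas=pd.Series(betas),
            pvalues=pd.Series({k: 0.0 for k in betas}),
            r2=1.0,
            fit_pvalue=0.0,
            residuals=pd.Series(0.0, index=X.index),
            selected=list(betas),
            alpha=0.001,
        )

    def test_single_variable_always_100(self):
        X = _frame([[2.0], [5.0], [0.1]], ["a"])
        table = contributions(self._fit({"a": 1.5}, X), X)
        assert np.allclose(table.per_patient["a"], 100.0)

    def test_equal_terms_split_evenly(self):
        X = _frame([[3.0, 2.0]], ["a", "b"])
        table = contributions(self._fit({"a": 2.0, "b": 3.0}, X), X)
        assert np.allclose(table.per_patient.iloc[0], [50.0, 50.0])

    def test_negative_term_pattern(self):
        # beta1*x1 = 2, beta2*x2 = -1 -> +200% and -100%, summing to 100%
        X = _frame([[2.0, 1.0]], ["a", "b"])
        table = contributions(self._fit({"a": 1.0, "b": -1.0}, X), X)
        assert np.allclose(table.per_patient.iloc[0], [200.0, -100.0])

    def test_row_sums_100(self):
        rng = np.random.default_rng(6)
        X = _frame(rng.normal(4, 1, size=(50, 3)), ["a", "b", "c"])
        table = contributions(self._fit({"a": 0.5, "b": 1.0, "c": -0.2}, X), X)
        assert np.allclose(table.per_patient.sum(axis=1), 100.0, atol=1e-6)

    def test_near_zero_denominator_flagged(self):
        X = _frame([[1.0, -1.0], [2.0, 1.0]], ["a", "b"])
        table = contributions(self._fit({"a": 1.0, "b": 1.0}, X), X)
        assert table.undefined_samples == ["P0"]
        assert np.isfinite(table.mean).all()


class TestVif:
    def test_orthogonal_predictors_vif_one(self):
        X = _frame(
            np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float), ["a", "b"]
        )
        report = vif(X)
        assert np.allclose(report.table["vif"], 1.0)

    def test_aux_r2_075_gives_vif_4(self):
        x1 = np.array([1.0, -1.0, 1.0, -1.0])
        e = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x1
        x2 = np.sqrt(3.0) * x1 + e  # aux R^2 = 3/(3+1) = 0.75 exactly
        report = vif(_frame(np.column_stack([x1, x2]), ["a", "b"]))
        assert np.allclose(report.table["vif"], 4.0)
        assert np.allclose(report.table["aux_r2"], 0.75)

    def test_perfect_collinearity_flagged_inf(self):
        x1 = np.arange(10.0)
        report = vif(_frame(np.column_stack([x1, 2 * x1]), ["a", "b"]))
        assert np.isinf(report.table["vif"]).all()
        assert report.table["flag_vif_gt10"].all()

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, size=(30, 3))
        X[:, 2] += 0.7 * X[:, 0]
        r1 = vif(_frame(X, ["a", "b", "c"]))
        r2 = vif(_frame(X * np.array([2.0, 0.5, 10.0]) + 3.0, ["a", "b", "c"]))
        assert np.allclose(r1.table["vif"], r2.table["vif"], atol=1e-8)
        assert (r1.table["vif"] >= 1.0 - 1e-12).all()
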