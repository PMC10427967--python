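"""Regression suite: tuning, same-family selection, importances, LOO-R^2."""

import numpy as np
import pandas as pd
import pytest

from mscpotency.core import ValidationError
from mscpotency.models import (
    FAMILIES,
    FittedModel,
    ModelSpec,
    fit_family,
    importance,
    importance_by_class,
    loo_r2,
    plsr_vip,
    select_features,
    tune,
)


def _linear_data(seed=0, n=10, p=8, noise=0.0, slopes=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), index=[f"L{i}" for i in range(n)],
                     columns=[f"f{j}" for j in range(p)])
    slopes = slopes if slopes is not None else {"f0": 3.0}
    y = sum(b * X[f] for f, b in slopes.items()) + rng.normal(0, noise, n)
    return X, pd.Series(y, index=X.index)


class TestTune:
    def test_single_point_grid(self):
        X, y = _linear_data()
        spec = ModelSpec("LASSO", grid={"alpha": [0.5]}, cv_folds=5)
        assert tune(spec, X, y) == {"alpha": 0.5}

    def test_lasso_prefers_small_alpha_on_linear_data(self):
        """alpha=1000 forces the null model; CV must pick the small alpha."""
        X, y = _linear_data()
        spec = ModelSpec("LASSO", grid={"alpha": [0.001, 1000.0]}, cv_folds=5)
        assert tune(spec, X, y) == {"alpha": 0.001}

    def test_deterministic_at_fixed_seed(self):
        X, y = _linear_data(seed=3, noise=0.5)
        for fam in ("LASSO", "PLSR", "RF"):
            spec = ModelSpec(fam, cv_folds=5, seed=7)
            assert tune(spec, X, y) == tune(ModelSpec(fam, cv_folds=5, seed=7), X, y)

    def test_too_many_folds_rejected(self):
        X, y = _linear_data(n=4)
        with pytest.raises(ValidationError, match="cv_folds"):
            tune(ModelSpec("LASSO", cv_folds=5), X, y)


class TestSelectFeatures:
    def test_lasso_finds_planted_feature(self):
        X, y = _linear_data(seed=1, n=10, p=30, noise=0.05)
        spec = ModelSpec("LASSO")
        selected = select_features(spec, X, y, {"alpha": 0.1})
        assert "f0" in selected
        assert len(selected) < 30

    def test_all_noise_strong_penalty_falls_back_to_full_set(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        y = pd.Series(rng.normal(size=10), index=X.index)
        selected = select_features(ModelSpec("LASSO"), X, y, {"alpha": 1e6})
        assert selected == list("abcde")

    def test_plsr_vip_single_feature_is_one(self):
        X, y = _linear_data(p=1)
        spec = ModelSpec("PLSR", grid={"n_components": [1]})
        selected = select_features(spec, X, y, {"n_components": 1})
        assert selected == ["f0"]
        from mscpotency.models import make_estimator
        est = make_estimator("PLSR", {"n_components": 1}, 10, 1, 0)
        est.fit(X.to_numpy(), y.to_numpy())
        assert plsr_vip(est)[0] == pytest.approx(1.0, abs=1e-9)

    def test_tree_selection_modes(self):
        X, y = _linear_data(seed=4, n=10, p=40, noise=0.1)
        spec = ModelSpec("RF", seed=0)
        params = {"n_estimators": 100, "max_depth": None}
        mean_sel = select_features(spec, X, y, params, tree_selection="mean")
        nonzero_sel = select_features(spec, X, y, params, tree_selection="nonzero")
        assert set(mean_sel) <= set(nonzero_sel)
        assert "f0" in mean_sel


class TestImportance:
    def test_single_feature_gets_all_importance(self):
        X, y = _linear_data(p=1)
        imp = importance(ModelSpec("LASSO"), X, y, {"alpha": 0.01})
        assert imp["f0"] == pytest.approx(1.0)

    def test_linear_coefficient_normalization(self):
        """Coefficients (2, -1) normalize to importances (2/3, 1/3)."""
        n = 40
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = pd.Series(2.0 * X["a"] - 1.0 * X["b"], index=X.index)
        imp = importance(ModelSpec("LASSO"), X, y, {"alpha": 1e-6})
        assert imp["a"] == pytest.approx(2 / 3, abs=1e-3)
        assert imp["b"] == pytest.approx(1 / 3, abs=1e-3)

    def test_duplicated_informative_features_share_rf_importance(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=30)
        X = pd.DataFrame({
            "t1": base + rng.normal(0, 0.01, 30),
            "t2": base + rng.normal(0, 0.01, 30),
            "noise": rng.normal(size=30),
        })
        y = pd.Series(base, index=X.index)
        imp = importance(ModelSpec("RF", seed=0), X, y,
                         {"n_estimators": 200, "max_depth": None})
        assert 0.2 <= imp["t1"] <= 0.8
        assert 0.2 <= imp["t2"] <= 0.8

    def test_permutation_equivariance(self):
        X, y = _linear_data(seed=7, p=6, noise=0.2)
        imp = importance(ModelSpec("LASSO"), X, y, {"alpha": 0.05})
        perm = list(reversed(X.columns))
        imp_perm = importance(ModelSpec("LASSO"), X[perm], y, {"alpha": 0.05})
        for f in X.columns:
            assert imp[f] == pytest.approx(imp_perm[f], abs=1e-9)


class TestLooR2:
    def test_noiseless_linear_near_perfect(self):
        # LASSO with alpha -> 0 approaches OLS on 8 features
        X, y = _linear_data(seed=8, noise=0.0)
        assert loo_r2(ModelSpec("LASSO"), X, y, {"alpha": 1e-4}) >= 0.99
        # PLSR with full rank on the informative features is exactly OLS
        X2, y2 = _linear_data(seed=8, p=2, noise=0.0,
                              slopes={"f0": 3.0, "f1": -2.0})
        assert loo_r2(ModelSpec("PLSR"), X2, y2, {"n_components": 2}) >= 0.99

    def test_shuffled_response_not_predictable(self):
        vals = []
        for seed in range(8):
            X, y = _linear_data(seed=seed, noise=0.0)
            rng = np.random.default_rng(1000 + seed)
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            vals.append(loo_r2(ModelSpec("LASSO"), X, y_perm, {"alpha": 0.01}))
        assert np.median(vals) <= 0.0

    def test_upper_bound_and_zero_variance_error(self):
        X, y = _linear_data(noise=0.0)
        assert loo_r2(ModelSpec("LASSO"), X, y, {"alpha": 1e-4}) <= 1.0
        with pytest.raises(ValidationError, match="zero variance"):
            loo_r2(ModelSpec("LASSO"), X, pd.Series(1.0, index=X.index),
                   {"alpha": 0.1})


class TestFitFamily:
    def test_full_pipeline_invariants(self):
        X, y = _linear_data(seed=9, p=12, noise=0.2,
                            slopes={"f0": 3.0, "f1": -2.0})
        m = fit_family("LASSO", X, y, seed=0)
        assert isinstance(m, FittedModel)
        assert sum(m.importance.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(m.selected_features) <= set(X.columns)
        assert m.loo_r2 <= 1.0
        assert {"f0", "f1"} <= set(m.selected_features)

    def test_determinism(self):
        X, y = _linear_data(seed=10, p=15, noise=0.3)
        a = fit_family("RF", X, y, seed=5)
        b = fit_family("RF", X, y, seed=5)
        assert a.params == b.params
        assert a.selected_features == b.selected_features
        assert a.loo_r2 == b.loo_r2
        assert a.importance == b.importance


class TestImportanceByClass:
    def _meta(self, classes):
        return pd.DataFrame({"chem_class": pd.Series(classes)})

    def _model(self, imp):
        return FittedModel(family="LASSO", params={}, selected_features=list(imp),
                           importance=imp, loo_r2=0.5, n_features_in=len(imp))

    def test_single_class_sums_to_one(self):
        m = self._model({"a": 0.4, "b": 0.6})
        out = importance_by_class({"LASSO": m}, self._meta({"a": "PC", "b": "PC"}))
        assert out.loc["PC", "LASSO"] == pytest.approx(1.0)

    def test_two_class_split_bookkeeping(self):
        m = self._model({"a": 0.5, "b": 0.2, "c": 0.3})
        meta = self._meta({"a": "PC", "b": "PC", "c": "SM"})
        out = importance_by_class({"LASSO": m}, meta)
        assert out.loc["PC", "LASSO"] == pytest.approx(0.7)
        assert out.loc["SM", "LASSO"] == pytest.approx(0.3)

    def test_feature_order_invariance(self):
        imp = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}
        meta = self._meta({"a": "PC", "b": "SM", "c": "PC", "d": "SM"})
        fwd = importance_by_class({"L": self._model(imp)}, meta)
        rev = importance_by_class(
            {"L": self._model(dict(reversed(list(imp.items()))))}, meta)
        pd.testing.assert_frame_equal(fwd, rev)
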