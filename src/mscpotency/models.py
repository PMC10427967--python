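"""Six-family regression suite with grid-search CV, same-family feature
selection, normalized importances, and leave-one-out R^2.

Families: PLSR, linear SVR, random forest (RF), gradient-boosted regression
(GBR), decision tree (DT) and LASSO — all scikit-learn estimators. Each is
tuned by exhaustive grid search with seeded k-fold CV scored by R^2, then
feature-selected with its own importance notion (LASSO: nonzero
coefficients; trees/ensembles: nonzero impurity importance; PLSR: VIP >= 1;
SVR: coefficients covering the top 50% of absolute-coefficient mass),
retuned on the kept subset, and evaluated by pooled leave-one-out R^2 with
hyperparameters and feature subset held fixed across folds.

Feature columns are standardized (z-scored) on entry; importances are
magnitudes of coefficients on that standardized axis (VIP for PLSR, impurity
importances for trees), normalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold, ParameterGrid
from sklearn.svm import LinearSVR
from sklearn.tree import DecisionTreeRegressor

from .core import CompositeScore, ValidationError, logger

FAMILIES = ("PLSR", "SVR", "RF", "GBR", "DT", "LASSO")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LASSO": {"alpha": list(np.round(np.logspace(-3, 1, 7), 6))},
    "PLSR": {"n_components": [1, 2, 3, 4]},
    "SVR": {"C": [0.1, 1.0, 10.0], "epsilon": [0.01, 0.1]},
    "RF": {"n_estimators": [100, 500], "max_depth": [2, 3, None]},
    "GBR": {"n_estimators": [100, 500], "max_depth": [2, 3, None]},
    "DT": {"max_depth": [2, 3, 5, None]},
}


@dataclass
class ModelSpec:
    """One regression family plus its tuning grid and CV settings."""

    family: str
    grid: Mapping[str, Sequence] | None = None
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValidationError("hyperparameter grid must be non-empty")


@dataclass
class FittedModel:
    """A tuned, feature-selected fit of one family."""

    family: str
    params: dict
    selected_features: list[str]
    importance: dict[str, float]
    loo_r2: float
    n_features_in: int

    def __post_init__(self) -> None:
        total = sum(self.importance.values())
        if self.importance and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"importances sum to {total}, not 1")
        if any(v < 0 for v in self.importance.values()):
            raise ValidationError("importances must be non-negative")
        if self.loo_r2 > 1.0 + 1e-12:
            raise ValidationError("LOO-R^2 cannot exceed 1")


# ---------------------------------------------------------------------------
# estimator construction / importances
# ---------------------------------------------------------------------------

def make_estimator(family: str, params: Mapping, n_samples: int, n_features: int, seed: int):
    params = dict(params)
    if family == "LASSO":
        return Lasso(alpha=params["alpha"], max_iter=50_000)
    if family == "PLSR":
        k = min(int(params["n_components"]), max(1, n_samples - 1), max(1, n_features))
        return PLSRegression(n_components=k, scale=False)
    if family == "SVR":
        return LinearSVR(C=params["C"], epsilon=params["epsilon"],
                         max_iter=50_000, random_state=seed, dual="auto")
    if family == "RF":
        return RandomForestRegressor(n_estimators=params["n_estimators"],
                                     max_depth=params["max_depth"], random_state=seed)
    if family == "GBR":
        return GradientBoostingRegressor(n_estimators=params["n_estimators"],
                                         max_depth=params["max_depth"], random_state=seed)
    if family == "DT":
        return DecisionTreeRegressor(max_depth=params["max_depth"], random_state=seed)
    raise ValidationError(f"unknown family {family!r}")


def plsr_vip(pls: PLSRegression) -> np.ndarray:
    """Variable importance in projection for a fitted PLSR model."""
    t = pls.x_scores_
    w = pls.x_weights_
    q = pls.y_loadings_
    p = w.shape[0]
    ssy = (t**2).sum(axis=0) * (q**2).sum(axis=0)  # explained SS per component
    wnorm = w / np.linalg.norm(w, axis=0, keepdims=True).clip(min=1e-300)
    return np.sqrt(p * (wnorm**2 @ ssy) / ssy.sum())


def raw_importance(family: str, est, X: np.ndarray) -> np.ndarray:
    """Family-specific non-negative raw importances, one per input feature."""
    if family == "LASSO":
        return np.abs(np.ravel(est.coef_))
    if family == "SVR":
        return np.abs(np.ravel(est.coef_))
    if family == "PLSR":
        return plsr_vip(est)
    return np.asarray(est.feature_importances_, dtype=float)


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = sd.mask(sd == 0, 1.0)
    return (X - mu) / sd


def _as_series(y: CompositeScore | pd.Series) -> pd.Series:
    return y.scores if isinstance(y, CompositeScore) else y


def _predict(est, X: np.ndarray) -> np.ndarray:
    return np.ravel(est.predict(X))


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def tune(spec: ModelSpec, X: pd.DataFrame, y: CompositeScore | pd.Series) -> dict:
    """Exhaustive grid search, seeded shuffled k-fold, mean CV-R^2 objective.

    Ties go to the earlier grid point. Raises if cv_folds > n_samples.
    """
    yv = _as_series(y).loc[X.index].to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    n = len(yv)
    if spec.cv_folds > n:
        raise ValidationError(f"cv_folds={spec.cv_folds} exceeds n_samples={n}")
    kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(kf.split(Xv))

    best_params, best_score = None, -np.inf
    for params in ParameterGrid(dict(spec.grid)):
        scores = []
        for tr, te in folds:
            est = make_estimator(spec.family, params, len(tr), Xv.shape[1], spec.seed)
            est.fit(Xv[tr], yv[tr])
            pred = _predict(est, Xv[te])
            sst = ((yv[te] - yv[te].mean()) ** 2).sum()
            if sst == 0:
                scores.append(0.0)
            else:
                scores.append(1.0 - ((yv[te] - pred) ** 2).sum() / sst)
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_params, best_score = dict(params), mean_score
    return best_params


# ---------------------------------------------------------------------------
# same-family feature selection
# ---------------------------------------------------------------------------

def select_features(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: CompositeScore | pd.Series,
    params: Mapping,
    tree_selection: str = "mean",
) -> list[str]:
    """Keep features the family itself deems informative; fall back to the
    full set (logged) if the rule selects nothing.

    Rules: LASSO keeps nonzero coefficients; PLSR keeps VIP >= 1; SVR keeps
    the coefficients covering the top 50% of absolute-coefficient mass.
    Impurity-importance families (RF/GBR/DT) keep features above the mean
    importance (scikit-learn's ``SelectFromModel`` default) when
    ``tree_selection="mean"``, or any nonzero importance with ``"nonzero"``
    — ensembles at this sample size give almost every feature a tiny
    nonzero importance, so the nonzero rule barely selects.
    """
    if tree_selection not in ("mean", "nonzero"):
        raise ValidationError(f"unknown tree_selection {tree_selection!r}")
    yv = _as_series(y).loc[X.index].to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    est = make_estimator(spec.family, params, *Xv.shape, spec.seed)
    est.fit(Xv, yv)
    imp = raw_importance(spec.family, est, Xv)

    if spec.family == "PLSR":
        keep = imp >= 1.0
    elif spec.family == "SVR":
        order = np.argsort(-imp, kind="stable")
        total = imp.sum()
        keep = np.zeros(len(imp), dtype=bool)
        if total > 0:
            cum = 0.0
            for j in order:
                keep[j] = True
                cum += imp[j]
                if cum >= 0.5 * total:
                    break
    elif spec.family == "LASSO":
        keep = imp > 0
    else:  # RF, GBR, DT impurity importances
        keep = imp > (imp.mean() if tree_selection == "mean" else 0.0)
    if not keep.any():
        logger.warning(
            "%s feature selection kept nothing; falling back to the full set",
            spec.family,
        )
        return list(X.columns)
    return [f for f, k in zip(X.columns, keep) if k]


def importance(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: CompositeScore | pd.Series,
    params: Mapping,
) -> pd.Series:
    """Normalized (sum-1) importances of the columns of ``X``."""
    yv = _as_series(y).loc[X.index].to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    est = make_estimator(spec.family, params, *Xv.shape, spec.seed)
    est.fit(Xv, yv)
    imp = raw_importance(spec.family, est, Xv)
    total = imp.sum()
    if total == 0:
        logger.warning("%s: all-zero importances; using a uniform split", spec.family)
        imp = np.ones_like(imp)
        total = imp.sum()
    return pd.Series(imp / total, index=X.columns)


# ---------------------------------------------------------------------------
# leave-one-out R^2
# ---------------------------------------------------------------------------

def loo_r2(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: CompositeScore | pd.Series,
    params: Mapping,
) -> float:
    """Pooled leave-one-out R^2 with fixed hyperparameters and features.

    1 - sum((y_i - yhat_i)^2) / sum((y_i - ybar)^2) over held-out
    predictions; <= 1, unbounded below.
    """
    yv = _as_series(y).loc[X.index].to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    n = len(yv)
    if n < 3:
        raise ValidationError("loo_r2 needs >= 3 samples")
    sst = ((yv - yv.mean()) ** 2).sum()
    if sst == 0:
        raise ValidationError("response has zero variance")
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        est = make_estimator(spec.family, params, n - 1, Xv.shape[1], spec.seed)
        est.fit(Xv[mask], yv[mask])
        preds[i] = _predict(est, Xv[[i]])[0]
    return float(1.0 - ((yv - preds) ** 2).sum() / sst)


# ---------------------------------------------------------------------------
# full per-family pipeline
# ---------------------------------------------------------------------------

def fit_family(
    family: str,
    X: pd.DataFrame,
    y: CompositeScore | pd.Series,
    seed: int = 0,
    cv_folds: int = 5,
    grid: Mapping | None = None,
    retune_after_selection: bool = True,
    standardize: bool = True,
    tree_selection: str = "mean",
) -> FittedModel:
    """tune -> same-family selection -> (re)tune on the subset -> importance
    -> LOO-R^2, all deterministic at a fixed seed."""
    spec = ModelSpec(family=family, grid=grid, cv_folds=cv_folds, seed=seed)
    Xs = _standardize(X) if standardize else X.copy()

    params = tune(spec, Xs, y)
    selected = select_features(spec, Xs, y, params, tree_selection=tree_selection)
    Xsel = Xs[selected]
    if retune_after_selection and len(selected) < Xs.shape[1]:
        params = tune(spec, Xsel, y)
    imp = importance(spec, Xsel, y, params)
    r2 = loo_r2(spec, Xsel, y, params)
    return FittedModel(
        family=family,
        params=params,
        selected_features=selected,
        importance=imp.to_dict(),
        loo_r2=r2,
        n_features_in=X.shape[1],
    )


def fit_suite(
    X: pd.DataFrame,
    y: CompositeScore | pd.Series,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    cv_folds: int = 5,
    grids: Mapping[str, Mapping] | None = None,
) -> dict[str, FittedModel]:
    """Fit every requested family on the same line-level matrix."""
    grids = grids or {}
    out = {}
    for fam in families:
        out[fam] = fit_family(fam, X, y, seed=seed, cv_folds=cv_folds,
                              grid=grids.get(fam))
        logger.info("%s: LOO-R^2=%.3f, %d features selected",
                    fam, out[fam].loo_r2, len(out[fam].selected_features))
    return out


def importance_by_class(
    fitted: Mapping[str, FittedModel],
    feature_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Sum normalized importances within each chemical class, per family.

    Rows are chem_class values, columns families; each column sums to 1.
    """
    records = {}
    for fam, model in fitted.items():
        cls_sum: dict[str, float] = {}
        for fid, w in model.importance.items():
            cls = feature_meta.loc[fid, "chem_class"]
            cls_sum[cls] = cls_sum.get(cls, 0.0) + w
        records[fam] = cls_sum
    out = pd.DataFrame(records).fillna(0.0)
    return out.sort_index()
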