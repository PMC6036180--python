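"""Age prediction by nested cross-validation with a stacked ensemble.

Outer folds (default K_O = 10) estimate generalization; within each outer
training set every base regressor is tuned by repeated inner
cross-validation (default K_I = 10, R = 5 repeats) with a grid search and
the one-standard-error rule (most parsimonious setting within one SE of the
minimum mean RMSE).  The base regressors' pooled inner held-out predictions
train a general linear model (ordinary least squares) whose coefficients
combine the base predictions into the fold's stacked prediction for the
held-out subjects.  Concatenating outer folds gives exactly one unbiased
prediction per subject, from which BrainAGE (predicted minus chronological
age) is derived.

Base regressor families: elastic net, radial-kernel support-vector
regression, random forest, gradient-boosted trees, and Gaussian-process
regression with a polynomial kernel.  Penalized/kernel methods see
z-scored features (statistics fit on the outer training split only); tree
methods see raw features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import DotProduct
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold, RepeatedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

__all__ = ["NCVConfig", "FoldModels", "NCVResult", "make_folds", "tune_inner",
           "fit_stack", "run_ncv", "compute_metrics", "brainage",
           "learning_curve", "DEFAULT_GRIDS", "FAST_GRIDS"]

METADATA_COLUMNS = ("age", "sex")

# Hyperparameter grids, ordered most-parsimonious first (the order the
# one-SE rule consults).  "Simple" means more regularized, shallower,
# fewer rounds, or lower polynomial degree.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "enet": [{"alpha": a, "l1_ratio": l}
             for a in (1.0, 0.1, 0.01, 0.001) for l in (1.0, 0.5, 0.1)],
    "svr": [{"C": c} for c in (1.0, 10.0, 100.0)],
    "rf": [{"max_features": "sqrt"}, {"max_features": 0.33}],
    "xgb": [{"max_depth": d, "learning_rate": lr, "n_estimators": n}
            for d in (2, 4, 6) for n in (100, 300) for lr in (0.3, 0.1, 0.05)],
    "gp": [{"degree": 1}, {"degree": 2}, {"degree": 3}],
}

# Reduced grids for desk-scale runs (small synthetic cohorts).
FAST_GRIDS: dict[str, list[dict]] = {
    "enet": [{"alpha": 1.0, "l1_ratio": 0.5}, {"alpha": 0.01, "l1_ratio": 0.5}],
    "svr": [{"C": 10.0}],
    "rf": [{"max_features": "sqrt"}],
    "xgb": [{"max_depth": 3, "learning_rate": 0.1, "n_estimators": 100}],
    "gp": [{"degree": 1}],
}


@dataclass
class NCVConfig:
    """Nested-cross-validation configuration.

    Defaults mirror the full protocol (K_O = K_I = 10, R = 5, K_Ens = 10);
    :meth:`fast` returns a desk-scale variant with reduced grids and inner
    resampling for small synthetic cohorts.
    """

    k_outer: int = 10
    k_inner: int = 10
    repeats: int = 5
    k_ens: int = 10
    methods: list[str] = field(
        default_factory=lambda: ["enet", "svr", "rf", "xgb", "gp"])
    grids: dict[str, list[dict]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRIDS.items()})
    n_trees: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_outer, self.k_inner, self.k_ens) < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for m in self.methods:
            if m not in self.grids or not self.grids[m]:
                raise ValueError(f"empty or missing grid for method {m!r}")

    @classmethod
    def fast(cls, seed: int = 0, methods: list[str] | None = None,
             k_outer: int = 5) -> "NCVConfig":
        return cls(k_outer=k_outer, k_inner=5, repeats=1, k_ens=5,
                   methods=methods or ["enet", "svr", "rf", "xgb", "gp"],
                   grids={k: list(v) for k, v in FAST_GRIDS.items()},
                   n_trees=100, seed=seed)


def _scale_by_sqrt_p(X):
    return X / np.sqrt(X.shape[1])


def make_estimator(method: str, params: dict, seed: int, n_trees: int = 300):
    """Instantiate a base regressor (with its scaling front-end)."""
    if method == "enet":
        return Pipeline([("scale", StandardScaler()),
                         ("model", ElasticNet(max_iter=5000, **params))])
    if method == "svr":
        return Pipeline([("scale", StandardScaler()),
                         ("model", SVR(kernel="rbf", gamma="scale",
                                       epsilon=0.1, **params))])
    if method == "rf":
        return RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                     n_jobs=1, **params)
    if method == "xgb":
        from xgboost import XGBRegressor

        return XGBRegressor(tree_method="hist", n_jobs=1, random_state=seed,
                            verbosity=0, **params)
    if method == "gp":
        kernel = DotProduct(sigma_0=1.0) ** params["degree"]
        return Pipeline([
            ("scale", StandardScaler()),
            ("shrink", FunctionTransformer(_scale_by_sqrt_p)),
            ("model", GaussianProcessRegressor(kernel=kernel, alpha=1.0,
                                               optimizer=None,
                                               normalize_y=True,
                                               random_state=seed)),
        ])
    raise ValueError(f"unknown method {method!r}")


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded, size-balanced fold assignment (labels 0..k-1 per subject)."""
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


@dataclass
class TuneResult:
    params: dict
    scores: list[tuple[dict, float, float]]  # (params, mean RMSE, SE)
    inner_pred: np.ndarray  # pooled held-out predictions at selected params
    inner_age: np.ndarray
    inner_rmse: float


def tune_inner(X: np.ndarray, y: np.ndarray, method: str, grid: list[dict],
               k_inner: int, repeats: int, seed: int, n_trees: int = 300,
               splits: list | None = None) -> TuneResult:
    """Grid search with repeated inner CV and the one-SE rule.

    ``grid`` must be ordered most-parsimonious first.  For each grid point
    the mean and standard error of RMSE over the K_I x R resamples is
    computed; the first grid point whose mean RMSE is within one SE of the
    minimum is selected.  A failing fit scores +inf.  Held-out predictions
    pooled over all resamples at the selected point are returned for
    stack training.
    """
    if splits is None:
        rkf = RepeatedKFold(n_splits=k_inner, n_repeats=repeats,
                            random_state=seed % (2 ** 31))
        splits = list(rkf.split(X))
    stats, preds = [], []
    for gi, params in enumerate(grid):
        rmses, pred_pool, age_pool = [], [], []
        try:
            for tr, te in splits:
                est = make_estimator(method, params, seed, n_trees)
                est.fit(X[tr], y[tr])
                p = est.predict(X[te])
                rmses.append(float(np.sqrt(np.mean((y[te] - p) ** 2))))
                pred_pool.append(p)
                age_pool.append(y[te])
            rmses = np.asarray(rmses)
            stats.append((params, float(rmses.mean()),
                          float(rmses.std(ddof=1) / np.sqrt(rmses.size))
                          if rmses.size > 1 else 0.0))
            preds.append((np.concatenate(pred_pool), np.concatenate(age_pool)))
        except Exception as exc:
            logger.warning("method %s params %s failed: %s", method, params, exc)
            stats.append((params, float("inf"), 0.0))
            preds.append((None, None))

    means = np.array([s[1] for s in stats])
    if not np.isfinite(means).any():
        raise RuntimeError(f"all grid points failed for method {method}")
    best = int(np.argmin(means))
    threshold = stats[best][1] + stats[best][2]
    chosen = next(i for i in range(len(grid)) if means[i] <= threshold)
    pred, age = preds[chosen]
    return TuneResult(params=stats[chosen][0], scores=stats,
                      inner_pred=pred, inner_age=age,
                      inner_rmse=stats[chosen][1])


@dataclass
class StackModel:
    """GLM combiner: intercept plus one coefficient per base method."""

    methods: list[str]
    intercept: float
    coef: np.ndarray
    cv_rmse: float

    def predict(self, base_preds: np.ndarray) -> np.ndarray:
        return self.intercept + base_preds @ self.coef


# Shrinkage ladder for the GLM solve, relative to the mean diagonal of the
# (non-intercept) Gram matrix.  0 is plain OLS; the K_Ens CV picks the value.
_STACK_RIDGE_LADDER = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)


def _ols(A: np.ndarray, y: np.ndarray, lam_rel: float = 0.0) -> np.ndarray:
    gram = A.T @ A
    scale = float(np.mean(np.diag(gram)[1:]))
    cond = np.linalg.cond(gram)
    if lam_rel == 0.0 and (not np.isfinite(cond) or cond > 1e10):
        logger.warning("collinear base predictions: ridge fallback")
        lam_rel = 1e-8
    if lam_rel > 0.0:
        penalty = lam_rel * scale * np.eye(A.shape[1])
        penalty[0, 0] = 0.0  # no penalty on the intercept
        gram = gram + penalty
    return np.linalg.solve(gram, A.T @ y)


def fit_stack(inner_preds: dict[str, np.ndarray], ages: np.ndarray,
              k_ens: int = 10, seed: int = 0) -> StackModel:
    """Fit the GLM stack on pooled inner-resample predictions.

    The GLM is fit under ``k_ens``-fold cross-validation: the CV selects the
    solve's shrinkage from a small ladder (plain OLS plus light ridge
    levels — base predictions are strongly collinear by construction, so an
    unshrunk solve can be noise-dominated), and the selected solve is refit
    on all rows.  The CV RMSE of the selected solve is reported.  Exactly
    singular prediction matrices additionally fall back to a tiny ridge.
    """
    methods = list(inner_preds)
    if len(methods) < 2:
        raise ValueError("stacking needs at least two base methods")
    P = np.column_stack([inner_preds[m] for m in methods])
    A = np.column_stack([np.ones(len(ages)), P])

    kf = KFold(n_splits=k_ens, shuffle=True, random_state=seed % (2 ** 31))
    splits = list(kf.split(A))
    cv_rmse = []
    for lam in _STACK_RIDGE_LADDER:
        sq = []
        for tr, te in splits:
            b = _ols(A[tr], ages[tr], lam)
            sq.append(np.mean((ages[te] - A[te] @ b) ** 2))
        cv_rmse.append(float(np.sqrt(np.mean(sq))))
    best = int(np.argmin(cv_rmse))
    beta = _ols(A, ages, _STACK_RIDGE_LADDER[best])
    return StackModel(methods=methods, intercept=float(beta[0]),
                      coef=beta[1:], cv_rmse=cv_rmse[best])


@dataclass
class FoldModels:
    """Everything fitted within one outer fold."""

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    params: dict[str, dict]
    estimators: dict[str, Any]
    stack: StackModel
    inner_rmse: dict[str, float]


@dataclass
class NCVResult:
    """Outer-fold predictions, fold models, metrics and BrainAGE."""

    predictions: pd.DataFrame
    fold_models: list[FoldModels]
    metrics: dict
    feature_names: list[str]
    config: NCVConfig


def compute_metrics(pred: np.ndarray, age: np.ndarray) -> dict[str, float]:
    """R^2 (1 - SSresid/SStotal), MAE, RMSE and Pearson r."""
    pred = np.asarray(pred, dtype=float)
    age = np.asarray(age, dtype=float)
    if pred.shape != age.shape or not (np.isfinite(pred).all()
                                       and np.isfinite(age).all()):
        raise ValueError("pred and age must be equal-length finite vectors")
    ss_tot = float(np.sum((age - age.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("age has zero variance")
    resid = age - pred
    return {
        "r2": 1.0 - float(np.sum(resid ** 2)) / ss_tot,
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "pearson_r": float(np.corrcoef(pred, age)[0, 1])
        if pred.std() > 0 else 0.0,
    }


def brainage(pred: np.ndarray, age: np.ndarray) -> np.ndarray:
    """BrainAGE: predicted age minus chronological age, per subject."""
    return np.asarray(pred, dtype=float) - np.asarray(age, dtype=float)


def _fold_summary(per_fold: list[dict]) -> dict:
    keys = per_fold[0].keys()
    return {k: {"mean": float(np.mean([f[k] for f in per_fold])),
                "sd": float(np.std([f[k] for f in per_fold], ddof=1))
                if len(per_fold) > 1 else 0.0}
            for k in keys}


def run_ncv(table: pd.DataFrame, cfg: NCVConfig | None = None) -> NCVResult:
    """Run the full nested cross-validation on a FeatureTable.

    ``table`` must contain an ``age`` column; ``sex`` (if present) is
    carried through for stratified reporting but never modeled.  Returns
    one outer-fold prediction per subject, per-fold models, pooled and
    per-fold metrics for the stack and each base method.
    """
    cfg = cfg or NCVConfig()
    if "age" not in table.columns:
        raise ValueError("table must contain an 'age' column")
    feature_names = [c for c in table.columns if c not in METADATA_COLUMNS]
    X = table[feature_names].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature table contains NaNs")
    y = table["age"].to_numpy(dtype=np.float64)
    n = len(y)

    rng = np.random.default_rng(cfg.seed)
    fold_seed = int(rng.integers(2 ** 31))
    folds = make_folds(n, cfg.k_outer, fold_seed)

    pred_stack = np.full(n, np.nan)
    base_pred = {m: np.full(n, np.nan) for m in cfg.methods}
    fold_models: list[FoldModels] = []
    for l in range(cfg.k_outer):
        te = np.where(folds == l)[0]
        tr = np.where(folds != l)[0]
        if te.size < 2 or tr.size < 2:
            raise ValueError(f"outer fold {l} has fewer than 2 subjects")
        fold_rng = np.random.default_rng([cfg.seed, l])
        inner_seed = int(fold_rng.integers(2 ** 31))
        rkf = RepeatedKFold(n_splits=cfg.k_inner, n_repeats=cfg.repeats,
                            random_state=inner_seed)
        splits = list(rkf.split(X[tr]))

        params, estimators, inner_preds, inner_rmse = {}, {}, {}, {}
        inner_age = None
        for m in cfg.methods:
            m_seed = int(fold_rng.integers(2 ** 31))
            tuned = tune_inner(X[tr], y[tr], m, cfg.grids[m], cfg.k_inner,
                               cfg.repeats, m_seed, cfg.n_trees, splits=splits)
            params[m] = tuned.params
            inner_preds[m] = tuned.inner_pred
            inner_rmse[m] = tuned.inner_rmse
            inner_age = tuned.inner_age
            est = make_estimator(m, tuned.params, m_seed, cfg.n_trees)
            est.fit(X[tr], y[tr])
            estimators[m] = est
            base_pred[m][te] = est.predict(X[te])

        stack_seed = int(fold_rng.integers(2 ** 31))
        stack = fit_stack(inner_preds, inner_age, cfg.k_ens, stack_seed)
        P_te = np.column_stack([base_pred[m][te] for m in cfg.methods])
        pred_stack[te] = stack.predict(P_te)
        fold_models.append(FoldModels(fold=l, train_idx=tr, test_idx=te,
                                      params=params, estimators=estimators,
                                      stack=stack, inner_rmse=inner_rmse))

    assert not np.isnan(pred_stack).any()
    predictions = pd.DataFrame({
        "age": y,
        "predicted_age": pred_stack,
        "brainage": brainage(pred_stack, y),
        "outer_fold": folds,
    }, index=table.index)
    if "sex" in table.columns:
        predictions["sex"] = table["sex"].to_numpy()
    for m in cfg.methods:
        predictions[f"pred_{m}"] = base_pred[m]

    per_fold = [compute_metrics(pred_stack[folds == l], y[folds == l])
                for l in range(cfg.k_outer)]
    metrics = {
        "stack": {"pooled": compute_metrics(pred_stack, y),
                  "per_fold": _fold_summary(per_fold)},
        "base": {},
    }
    for m in cfg.methods:
        pf = [compute_metrics(base_pred[m][folds == l], y[folds == l])
              for l in range(cfg.k_outer)]
        metrics["base"][m] = {
            "pooled": compute_metrics(base_pred[m], y),
            "per_fold": _fold_summary(pf),
            "inner_rmse_mean": float(np.mean(
                [fm.inner_rmse[m] for fm in fold_models])),
        }
    return NCVResult(predictions=predictions, fold_models=fold_models,
                     metrics=metrics, feature_names=feature_names, config=cfg)


def metrics_by_group(predictions: pd.DataFrame, column: str = "sex") -> dict:
    """Stratified pooled metrics (a reporting option, not a modeling change)."""
    out = {}
    for value, sub in predictions.groupby(column):
        out[str(value)] = compute_metrics(sub["predicted_age"].to_numpy(),
                                          sub["age"].to_numpy())
    return out


def learning_curve(table: pd.DataFrame, cfg: NCVConfig, sample_sizes,
                   seeds) -> pd.DataFrame:
    """Pooled R^2 of the full NCV at subsampled cohort sizes.

    For each (size, seed): subsample without replacement, rerun the NCV,
    record the stack's pooled R^2.  Sizes below 2 * K_O are skipped with a
    warning.
    """
    from dataclasses import replace as _replace

    rows = []
    for size in sample_sizes:
        if size < 2 * cfg.k_outer:
            logger.warning("size %d < 2*K_O; skipped", size)
            continue
        if size > len(table):
            raise ValueError(f"size {size} exceeds cohort size {len(table)}")
        for seed in seeds:
            if size == len(table):
                sub = table
            else:
                rng = np.random.default_rng([seed, size])
                idx = rng.choice(len(table), size=size, replace=False)
                sub = table.iloc[np.sort(idx)]
            res = run_ncv(sub, _replace(cfg, seed=seed))
            rows.append({"size": size, "seed": seed,
                         "r2": res.metrics["stack"]["pooled"]["r2"]})
    return pd.DataFrame(rows)
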