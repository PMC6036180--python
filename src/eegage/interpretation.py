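"""Fold-averaged feature importance, partial dependence, spatial aggregation.

Importance is computed per outer fold from the fitted base models and
combined with the normalized absolute stack weights: linear models
contribute absolute coefficients, tree ensembles their impurity
importances, and kernel/GP models seeded permutation importance.  Each
model's scores are normalized to sum 1 before combination (raw scales are
incomparable), and each fold's combined vector is rescaled to sum exactly
100.  Averaging across folds gives the reported score; each feature also
carries its marginal Pearson correlation with age.

Partial-dependence curves sweep one feature over quantile-spaced grid
points of the fold's training range while all other features keep their
observed values; consistency across folds is summarized as the mean
pairwise Pearson correlation between fold curves on a common grid.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

from .features import parse_feature_name
from .modeling import FoldModels, NCVResult

logger = logging.getLogger(__name__)

__all__ = ["importance", "pdp", "pdp_all_folds", "pdp_consistency",
           "spatial_importance", "domain_shares", "band_shares"]


def _model_importance(method: str, est, X: np.ndarray, y: np.ndarray,
                      seed: int, n_repeats: int = 1) -> np.ndarray:
    """Nonnegative, sum-1 importance vector for one fitted base model."""
    if method == "enet":
        raw = np.abs(est.named_steps["model"].coef_)
    elif method in ("rf", "xgb"):
        raw = np.asarray(est.feature_importances_, dtype=float)
    else:  # kernel / GP: permutation importance on the training fold
        pi = permutation_importance(est, X, y, n_repeats=n_repeats,
                                    random_state=seed % (2 ** 31),
                                    scoring="neg_mean_squared_error")
        raw = np.maximum(pi.importances_mean, 0.0)
    raw = np.maximum(raw, 0.0)
    total = raw.sum()
    if total <= 0:
        return np.full(raw.size, 1.0 / raw.size)
    return raw / total


def _fold_importance(fm: FoldModels, X: np.ndarray, y: np.ndarray,
                     seed: int, n_repeats: int) -> np.ndarray:
    w = np.abs(fm.stack.coef)
    w = w / w.sum() if w.sum() > 0 else np.full(w.size, 1.0 / w.size)
    combined = np.zeros(X.shape[1])
    for wi, m in zip(w, fm.stack.methods):
        est = fm.estimators[m]
        Xtr, ytr = X[fm.train_idx], y[fm.train_idx]
        combined += wi * _model_importance(m, est, Xtr, ytr, seed)
    return 100.0 * combined / combined.sum()


def importance(ncv: NCVResult, table: pd.DataFrame,
               n_repeats: int = 1) -> pd.DataFrame:
    """Stack-weighted, fold-normalized importance table.

    Returns a DataFrame indexed by feature name with one ``fold_<l>``
    column per outer fold (each summing to 100), their mean, and the
    feature's Pearson correlation with age.
    """
    X = table[ncv.feature_names].to_numpy(dtype=np.float64)
    y = table["age"].to_numpy(dtype=np.float64)
    out = {}
    for fm in ncv.fold_models:
        seed = ncv.config.seed * 1000 + fm.fold
        out[f"fold_{fm.fold}"] = _fold_importance(fm, X, y, seed, n_repeats)
    imp = pd.DataFrame(out, index=ncv.feature_names)
    imp["mean"] = imp.mean(axis=1)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.array([np.corrcoef(X[:, i], y)[0, 1] if sd[i] > 0 else 0.0
                      for i in range(X.shape[1])])
    imp["pearson_r_age"] = np.nan_to_num(r)
    imp.index.name = "feature"
    return imp.sort_values("mean", ascending=False)


def _stack_predict(fm: FoldModels, X: np.ndarray) -> np.ndarray:
    P = np.column_stack([fm.estimators[m].predict(X) for m in fm.stack.methods])
    return fm.stack.predict(P)


def pdp(fm: FoldModels, train: np.ndarray, feature_idx: int,
        grid: np.ndarray | None = None, grid_size: int = 25
        ) -> tuple[np.ndarray, np.ndarray]:
    """Partial dependence of one fold's stack on one feature.

    ``grid`` defaults to ``grid_size`` quantile-spaced points over the
    fold's observed feature range.  Returns ``(grid, mean prediction)``.
    """
    col = train[:, feature_idx]
    if np.ptp(col) == 0:
        raise ValueError("constant feature has no partial dependence")
    if grid is None:
        qs = np.linspace(0.0, 1.0, grid_size)
        grid = np.unique(np.quantile(col, qs))
    curve = np.empty(grid.size)
    Xmod = train.copy()
    for g, v in enumerate(grid):
        Xmod[:, feature_idx] = v
        curve[g] = _stack_predict(fm, Xmod).mean()
    return grid, curve


def pdp_all_folds(ncv: NCVResult, table: pd.DataFrame, feature: str,
                  grid_size: int = 25) -> pd.DataFrame:
    """Per-fold PDP curves on a common (whole-table quantile) grid."""
    X = table[ncv.feature_names].to_numpy(dtype=np.float64)
    idx = ncv.feature_names.index(feature)
    qs = np.linspace(0.0, 1.0, grid_size)
    grid = np.unique(np.quantile(X[:, idx], qs))
    rows = []
    for fm in ncv.fold_models:
        _, curve = pdp(fm, X[fm.train_idx], idx, grid=grid)
        for v, c in zip(grid, curve):
            rows.append({"feature": feature, "fold": fm.fold,
                         "grid_value": v, "prediction": c})
    return pd.DataFrame(rows)


def pdp_consistency(curves: pd.DataFrame) -> float:
    """Mean pairwise Pearson correlation between fold PDP curves.

    ``curves`` is the long-format output of :func:`pdp_all_folds` (a common
    grid).  Pairs involving a flat curve are skipped.
    """
    folds = sorted(curves["fold"].unique())
    if len(folds) < 2:
        raise ValueError("need curves from at least 2 folds")
    mat = {f: curves.loc[curves["fold"] == f].sort_values("grid_value")
           ["prediction"].to_numpy() for f in folds}
    cors = []
    for i, fi in enumerate(folds):
        for fj in folds[i + 1:]:
            a, b = mat[fi], mat[fj]
            if a.std() == 0 or b.std() == 0:
                logger.warning("flat PDP curve: pair (%s, %s) skipped", fi, fj)
                continue
            cors.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(cors)) if cors else 0.0


def _parse_frame(imp: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name, mean_imp in imp["mean"].items():
        try:
            domain, feat, band, channel = parse_feature_name(name)
        except ValueError:
            logger.warning("unparseable feature name %r excluded", name)
            continue
        rows.append({"feature": name, "domain": domain, "stat": feat,
                     "band": band, "channel": channel, "importance": mean_imp})
    return pd.DataFrame(rows)


def spatial_importance(imp: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mean importance per (channel, band) cell, one grid per domain."""
    parsed = _parse_frame(imp)
    grids = {}
    for domain, sub in parsed.groupby("domain"):
        grids[domain] = sub.pivot_table(index="channel", columns="band",
                                        values="importance", aggfunc="mean")
    return grids


def domain_shares(imp: pd.DataFrame) -> pd.Series:
    """Percent of total importance per feature domain (sums to 100)."""
    parsed = _parse_frame(imp)
    share = parsed.groupby("domain")["importance"].sum()
    return 100.0 * share / share.sum()


def band_shares(imp: pd.DataFrame, exclude_broadband: bool = True) -> pd.Series:
    """Percent of total importance per frequency band (sums to 100)."""
    parsed = _parse_frame(imp)
    if exclude_broadband:
        parsed = parsed[parsed["band"] != "broadband"]
    share = parsed.groupby("band")["importance"].sum()
    return 100.0 * share / share.sum()
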