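"""Unsupervised feature reduction: near-zero-variance and correlation filters.

The correlation filter reproduces the classic caret ``findCorrelation``
procedure: repeatedly locate the remaining pair with the highest absolute
Pearson correlation and, if it reaches the cutoff, drop the member with the
larger mean absolute correlation against all remaining columns.  Both
filters are response-blind (the ``age``/``sex`` metadata columns are never
consulted and always kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ReductionReport", "drop_low_variance", "find_correlated",
           "reduce_features", "METADATA_COLUMNS"]

METADATA_COLUMNS = ("age", "sex")


@dataclass
class ReductionReport:
    """Kept/dropped feature names with the reason for each drop."""

    kept: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    threshold: float | None = None

    def summary(self) -> dict:
        return {"n_kept": len(self.kept), "n_dropped": len(self.dropped),
                "threshold": self.threshold}


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def drop_low_variance(table: pd.DataFrame, freq_cut: float = 95.0 / 5.0,
                      unique_cut: float = 10.0
                      ) -> tuple[pd.DataFrame, ReductionReport]:
    """Remove constant and near-zero-variance columns.

    A column is near-zero-variance when the frequency ratio of its most
    common to second most common value exceeds ``freq_cut`` AND its percent
    of unique values is below ``unique_cut`` (the standard two-criterion
    rule); constant columns are always removed.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    cols = _feature_columns(table)
    dropped: dict[str, str] = {}
    for c in cols:
        v = table[c].to_numpy()
        uniq, counts = np.unique(v, return_counts=True)
        if uniq.size == 1:
            dropped[c] = "low_variance"
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        pct_unique = 100.0 * uniq.size / v.size
        if freq_ratio > freq_cut and pct_unique < unique_cut:
            dropped[c] = "low_variance"
    kept = [c for c in cols if c not in dropped]
    if not kept:
        raise ValueError("all feature columns removed as low-variance")
    report = ReductionReport(kept=kept, dropped=dropped)
    out = table[[c for c in table.columns if c not in dropped]]
    return out, report


def find_correlated(table: pd.DataFrame, cutoff: float = 0.9
                    ) -> tuple[pd.DataFrame, ReductionReport]:
    """Iteratively remove one member of every highly correlated pair.

    While any remaining pair has ``|r| >= cutoff``: take the pair with the
    globally highest ``|r|`` and drop the member with the larger mean
    absolute correlation against all remaining columns.  Ties (in pair
    location or mean correlation) break toward the earlier column position.
    NaN correlations (degenerate columns) are treated as 0.
    """
    cols = _feature_columns(table)
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlation filtering")
    X = table[cols].to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    if np.isnan(corr).any():
        logger.warning("NaN correlations treated as 0 (degenerate columns)")
        corr = np.nan_to_num(corr, nan=0.0)
    a = np.abs(corr)
    np.fill_diagonal(a, 0.0)

    p = len(cols)
    active = np.ones(p, dtype=bool)
    dropped: dict[str, str] = {}
    work = a.copy()
    while True:
        flat = np.argmax(work)  # first occurrence = earliest row-major tie-break
        i, j = divmod(int(flat), p)
        if work[i, j] < cutoff:
            break
        i, j = min(i, j), max(i, j)
        mean_i = work[i, active].sum() / (active.sum() - 1)
        mean_j = work[j, active].sum() / (active.sum() - 1)
        victim, other = (i, j) if mean_i >= mean_j else (j, i)
        dropped[cols[victim]] = f"correlated_with:{cols[other]}"
        active[victim] = False
        work[victim, :] = 0.0
        work[:, victim] = 0.0

    kept = [c for k, c in enumerate(cols) if active[k]]
    report = ReductionReport(kept=kept, dropped=dropped, threshold=cutoff)
    out = table[[c for c in table.columns
                 if c in METADATA_COLUMNS or c in set(kept)]]
    return out, report


def reduce_features(table: pd.DataFrame, cutoff: float = 0.9,
                    freq_cut: float = 95.0 / 5.0, unique_cut: float = 10.0
                    ) -> tuple[pd.DataFrame, ReductionReport]:
    """Low-variance filtering followed by correlation filtering."""
    t1, rep1 = drop_low_variance(table, freq_cut, unique_cut)
    t2, rep2 = find_correlated(t1, cutoff)
    dropped = {**rep1.dropped, **rep2.dropped}
    return t2, ReductionReport(kept=rep2.kept, dropped=dropped, threshold=cutoff)
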