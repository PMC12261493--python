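"""Evaluation metrics for affinity regression.

Covers the DTA-specific suite -- concordance index (CI), the external
validation statistic rm², and threshold-binarized AUPR -- plus the usual
regression metrics (MSE, RMSE, MAE, R², Pearson, Spearman).

CI conventions: only pairs with distinct true affinities count; a tied
prediction on such a pair scores 0.5, a correctly ordered one 1, a
misordered one 0.  Both an O(n²) reference path and an O(n log n)
Fenwick-tree path are provided and agree exactly (identical integer
counts, identical final division).

rm² = r² · (1 − sqrt(|r² − r0²|)), where r² is the squared Pearson
correlation of predictions and observations and r0² is the coefficient of
determination of the regression of observed on predicted *through the
origin* -- the standard external-validation form in the QSAR/DTA
literature; the absolute difference guards the square root.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import average_precision_score

__all__ = [
    "UndefinedMetricError",
    "concordance_index",
    "rm2",
    "aupr",
    "regression_metrics",
    "MetricReport",
    "full_report",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined on the given inputs (e.g. zero variance)."""


def _validated(y_true, y_pred, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=np.float64).ravel()
    yp = np.asarray(y_pred, dtype=np.float64).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size < min_len:
        raise ValueError(f"need at least {min_len} observations, got {yt.size}")
    if not (np.all(np.isfinite(yt)) and np.all(np.isfinite(yp))):
        raise ValueError("inputs must be finite")
    return yt, yp


def concordance_index(y_true, y_pred, method: str = "fast") -> float:
    """Probability that predictions order a random distinct-truth pair correctly."""
    yt, yp = _validated(y_true, y_pred, 2)
    if method == "brute":
        conc, ties, total = _ci_counts_brute(yt, yp)
    elif method == "fast":
        conc, ties, total = _ci_counts_fast(yt, yp)
    else:
        raise ValueError("method must be 'fast' or 'brute'")
    if total == 0:
        raise UndefinedMetricError("CI undefined: all true values are equal")
    return (conc + 0.5 * ties) / total


def _ci_counts_brute(yt: np.ndarray, yp: np.ndarray) -> tuple[int, int, int]:
    conc = ties = total = 0
    n = yt.size
    for i in range(n):
        for j in range(i + 1, n):
            if yt[i] == yt[j]:
                continue
            total += 1
            hi, lo = (i, j) if yt[i] > yt[j] else (j, i)
            if yp[hi] > yp[lo]:
                conc += 1
            elif yp[hi] == yp[lo]:
                ties += 1
    return conc, ties, total


def _ci_counts_fast(yt: np.ndarray, yp: np.ndarray) -> tuple[int, int, int]:
    """Sort by truth, sweep with a Fenwick tree over prediction ranks."""
    n = yt.size
    order = np.lexsort((yp, yt))
    yt_s, yp_s = yt[order], yp[order]
    ranks = {v: r + 1 for r, v in enumerate(np.unique(yp))}
    r_s = np.array([ranks[v] for v in yp_s], dtype=np.int64)
    m = len(ranks)
    tree_lt = _Fenwick(m)  # counts of inserted prediction ranks
    conc = ties = 0
    i = 0
    inserted = 0
    while i < n:
        j = i
        while j < n and yt_s[j] == yt_s[i]:
            j += 1
        for k in range(i, j):  # all previously inserted have strictly smaller truth
            below = tree_lt.prefix(r_s[k] - 1)
            at = tree_lt.prefix(r_s[k]) - below
            conc += below
            ties += at
        for k in range(i, j):
            tree_lt.add(r_s[k])
            inserted += 1
        i = j
    # total pairs with distinct truths
    _, counts = np.unique(yt, return_counts=True)
    total = n * (n - 1) // 2 - int(np.sum(counts * (counts - 1) // 2))
    return conc, ties, total


class _Fenwick:
    def __init__(self, n: int) -> None:
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def add(self, i: int) -> None:
        while i <= self.n:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return int(s)


def rm2(y_true, y_pred) -> float:
    """External-validation statistic r² · (1 − sqrt(|r² − r0²|))."""
    yt, yp = _validated(y_true, y_pred, 3)
    if np.var(yt) == 0 or np.var(yp) == 0:
        raise UndefinedMetricError("rm2 undefined: zero variance input")
    r = np.corrcoef(yt, yp)[0, 1]
    r_sq = r * r
    # regression of observed on predicted through the origin
    k = float(np.dot(yt, yp) / np.dot(yp, yp))
    ss_res0 = float(np.sum((yt - k * yp) ** 2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r0_sq = 1.0 - ss_res0 / ss_tot
    return float(r_sq * (1.0 - np.sqrt(abs(r_sq - r0_sq))))


def aupr(y_true, y_pred, threshold: float) -> float:
    """Area under the precision-recall curve after binarizing the truth.

    Positives are ``y_true >= threshold`` (closed bound); predictions are
    used directly as scores.  Step interpolation (average precision), no
    trapezoids.
    """
    yt, yp = _validated(y_true, y_pred, 2)
    pos = yt >= threshold
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUPR undefined: single-class truth ({n_pos} positives, {n_neg} negatives)"
        )
    return float(average_precision_score(pos, yp))


def regression_metrics(y_true, y_pred) -> dict:
    """Textbook error and correlation metrics.

    The error metrics are always defined; the correlation-based entries
    (r2, pearson, spearman) are ``None`` when either vector has zero
    variance, where they are mathematically undefined.
    """
    yt, yp = _validated(y_true, y_pred, 2)
    err = yt - yp
    mse = float(np.mean(err**2))
    out = {
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mae": float(np.mean(np.abs(err))),
    }
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0 or np.var(yp) == 0:
        out["r2"] = out["pearson"] = out["spearman"] = None
        return out
    out["r2"] = 1.0 - float(np.sum(err**2)) / ss_tot
    out["pearson"] = float(_stats.pearsonr(yt, yp).statistic)
    out["spearman"] = float(_stats.spearmanr(yt, yp).statistic)
    return out


@dataclass(frozen=True)
class MetricReport:
    mse: float
    rmse: float
    mae: float
    r2: float
    pearson: float
    spearman: float
    ci: float
    rm2: float
    aupr: Optional[float] = None
    aupr_threshold: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def full_report(y_true, y_pred, aupr_threshold: Optional[float] = None) -> MetricReport:
    """All metrics in one pass; AUPR only when a threshold is supplied and
    both classes are present."""
    reg = regression_metrics(y_true, y_pred)
    area = thr = None
    if aupr_threshold is not None:
        try:
            area, thr = aupr(y_true, y_pred, aupr_threshold), aupr_threshold
        except UndefinedMetricError:
            area, thr = None, aupr_threshold
    return MetricReport(
        ci=concordance_index(y_true, y_pred),
        rm2=rm2(y_true, y_pred),
        aupr=area,
        aupr_threshold=thr,
        **reg,
    )
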