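"""VP/NP decoding from surprisal (and tROI power) features.

A linear-kernel maximum-margin classifier (SVC, C=1) with leave-one-out
cross-validation; feature columns are standardized on the training rows of
each fold only.  Rows with missing features are dropped and counted.  The
companion statistics are a Kolmogorov-Smirnov normality check (statistic
computed against a normal with the sample mean/SD; Lilliefors-calibrated
p-value) and a one-way two-group ANOVA (F = t**2).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.diagnostic import kstest_normal

FEATURE_COLUMNS = ("artcl_surprisal", "nounverb_surprisal", "troi_power")


@dataclass
class DecodingResult:
    score: float
    predictions: np.ndarray
    labels: np.ndarray
    n_dropped: int
    n_skipped_folds: int = 0


def build_feature_matrix(
    table: pd.DataFrame,
    troi_power: np.ndarray | None = None,
    columns: tuple[str, ...] = ("artcl_surprisal", "nounverb_surprisal"),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Assemble (X, y, n_dropped) from a surprisal table.

    ``troi_power`` (one value per table row) adds the ``troi_power`` column
    when requested in ``columns``.  Rows with any missing entry are dropped.
    """
    work = table.copy()
    if troi_power is not None:
        work["troi_power"] = np.asarray(troi_power, float)
    unknown = [c for c in columns if c not in work.columns]
    if unknown:
        raise ValueError(f"unknown feature columns: {unknown}")
    X = work[list(columns)].to_numpy(float)
    y = work["condition"].to_numpy()
    ok = np.isfinite(X).all(axis=1)
    return X[ok], y[ok], int((~ok).sum())


def loocv_svm(
    X: np.ndarray,
    y: np.ndarray,
    c_param: float = 1.0,
    seed: int = 0,
) -> DecodingResult:
    """Leave-one-out linear SVM; score = fraction of held-out rows correct."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with at least 2 rows each")
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    evaluated = np.ones(n, dtype=bool)
    skipped = 0
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {i}: training set lost a class; fold skipped", stacklevel=2)
            evaluated[i] = False
            skipped += 1
            continue
        clf = make_pipeline(
            StandardScaler(), SVC(kernel="linear", C=c_param, random_state=seed)
        )
        clf.fit(X[train], y[train])
        preds[i] = clf.predict(X[i: i + 1])[0]
    score = float(np.mean(preds[evaluated] == y[evaluated]))
    return DecodingResult(
        score=score, predictions=preds, labels=y, n_dropped=0, n_skipped_folds=skipped
    )


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """KS statistic against N(sample mean, sample SD), calibrated p-value."""
    x = np.asarray(values, float)
    if len(x) < 5:
        raise ValueError("need at least 5 values")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    stat, p = kstest_normal(x, dist="norm")
    return float(stat), float(p)


def anova_condition(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """One-way two-group ANOVA (F = t**2 for two groups)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    pooled_var = np.concatenate([a - a.mean(), b - b.mean()]).var(ddof=0)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero within-group variance; p below machine epsilon", stacklevel=2)
        return float("inf"), float(np.finfo(float).tiny)
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)
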