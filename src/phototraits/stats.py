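"""Correlation screening and cross-validated trait prediction.

Two analyses link the per-user photograph features to the trait scores:

1. A Pearson correlation screen of every (trait, feature) pair with the
   two-sided p-value from the t transform t = r·√((n−2)/(1−r²)); pairs
   are flagged significant at p < 0.05 with no multiple-testing
   correction.  Missing feature values (e.g. emotion means for users
   with no detected faces) are handled by pairwise deletion.

2. 10-fold cross-validated prediction of each trait from the full
   numeric feature set, reporting the root mean square error per fold
   and its unweighted mean.  Within each fold, missing feature cells
   are imputed with training-fold means and features are standardised
   by training-fold mean/sd, so no information leaks from held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "CorrelationResult",
    "PredictionResult",
    "correlate",
    "fold_indices",
    "crossval_rmse",
    "correlation_table",
    "rmse_table",
]

ALPHA = 0.05

#: model name -> constructor(seed); forest follows the regression
#: convention of p/3 candidate features per split, 500 trees.
MODELS = {
    "linear_regression": lambda seed: LinearRegression(),
    "random_forest": lambda seed: RandomForestRegressor(
        n_estimators=500, max_features=1.0 / 3.0, random_state=seed, n_jobs=1
    ),
    "intercept": lambda seed: DummyRegressor(strategy="mean"),
}


@dataclass(frozen=True)
class CorrelationResult:
    trait: str
    feature: str
    r: float
    p: float
    significant: bool
    n: int
    note: str = ""


@dataclass(frozen=True)
class PredictionResult:
    trait: str
    model: str
    fold_rmse: tuple[float, ...]
    rmse: float
    seed: int


def correlate(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pearson-correlate every trait column with every feature column.

    ``features`` and ``traits`` each carry a ``user_id`` column; rows are
    matched on it (inner join).  Returns a tidy table with columns
    trait, feature, r, p, significant, n, note.  Zero-variance features
    yield r = NaN with a note rather than an error.
    """
    merged = traits.merge(features, on="user_id", suffixes=("_trait", "_feat"))
    trait_cols = [c for c in traits.columns if c != "user_id"]
    feat_cols = [c for c in features.columns if c != "user_id"]
    results = []
    for t in trait_cols:
        tc = t + "_trait" if t + "_trait" in merged.columns else t
        for f in feat_cols:
            fc = f + "_feat" if f + "_feat" in merged.columns else f
            pair = merged[[tc, fc]].dropna()
            n = len(pair)
            if n < 3:
                results.append(CorrelationResult(t, f, np.nan, np.nan, False, n,
                                                 "fewer than 3 complete pairs"))
                continue
            x = pair[tc].to_numpy(float)
            y = pair[fc].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                results.append(CorrelationResult(t, f, np.nan, np.nan, False, n,
                                                 "zero variance"))
                continue
            r, p = sps.pearsonr(x, y)
            results.append(
                CorrelationResult(t, f, float(r), float(p), bool(p < alpha), n)
            )
    return pd.DataFrame([r.__dict__ for r in results])


def fold_indices(
    n: int, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold split of ``range(n)`` into near-equal
    parts; returns (train, test) index pairs whose test sets partition
    the rows exactly."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    return list(KFold(n_splits=k, shuffle=True, random_state=seed).split(
        np.empty((n, 1))))


def crossval_rmse(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    model: str = "linear_regression",
    k: int = 10,
    seed: int = 0,
    trait: str = "",
) -> PredictionResult:
    """k-fold cross-validated RMSE of predicting ``y`` from ``X``.

    Folds are a seeded uniform shuffle into k near-equal parts (no
    stratification).  Per fold the pipeline (train-mean imputation →
    standardisation → model fit) sees only training rows; the reported
    ``rmse`` is the unweighted mean of the k fold RMSEs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per y entry")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    fold_rmse = []
    for train, test in fold_indices(X.shape[0], k, seed):
        pipe = Pipeline([
            ("impute", SimpleImputer(strategy="mean", keep_empty_features=True)),
            ("scale", StandardScaler()),
            ("model", MODELS[model](seed)),
        ])
        pipe.fit(X[train], y[train])
        resid = y[test] - pipe.predict(X[test])
        fold_rmse.append(float(np.sqrt(np.mean(resid ** 2))))
    return PredictionResult(
        trait=trait,
        model=model,
        fold_rmse=tuple(fold_rmse),
        rmse=float(np.mean(fold_rmse)),
        seed=seed,
    )


def correlation_table(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy correlation results into a traits × features table of
    correlation strings with a ``*`` star on p < 0.05 cells."""
    if results.empty:
        raise ValueError("no correlation results to tabulate")

    def cell(row):
        if np.isnan(row.r):
            return ""
        return f"{row.r:.3f}*" if row.significant else f"{row.r:.3f}"

    tab = results.assign(cell=[cell(r) for r in results.itertuples()])
    return tab.pivot(index="trait", columns="feature", values="cell")


def rmse_table(results: list[PredictionResult]) -> pd.DataFrame:
    """Traits × models table of mean cross-validated RMSEs."""
    if not results:
        raise ValueError("no prediction results to tabulate")
    df = pd.DataFrame(
        [{"trait": r.trait, "model": r.model, "rmse": r.rmse} for r in results]
    )
    return df.pivot(index="trait", columns="model", values="rmse")
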