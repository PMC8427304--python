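"""End-to-end orchestration: simulate/extract → aggregate → score →
correlate → predict.

These helpers chain the module-level pieces the way the study design
prescribes, so a whole analysis (or a replicate of it) is one call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import build_user_features
from .psychometrics import TRAITS, score_survey
from .stats import PredictionResult, correlate, crossval_rmse
from .synth import (
    SyntheticCohort,
    SyntheticCohortConfig,
    extract_cohort_pixel_features,
    simulate_cohort,
    strong_effects,
)

__all__ = [
    "cohort_feature_table",
    "analyze_cohort",
    "run_round_trip",
    "sign_recovery",
    "predict_all_traits",
]


def cohort_feature_table(cohort: SyntheticCohort,
                         min_photos: int = 30) -> pd.DataFrame:
    """Render + extract pixel features and aggregate everything into the
    per-user feature table."""
    pix = extract_cohort_pixel_features(cohort)
    return build_user_features(
        cohort.manifest, pix, cohort.annotations, cohort.faces,
        min_photos=min_photos,
    )


def analyze_cohort(
    cohort: SyntheticCohort, min_photos: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full analysis of one cohort.

    Returns ``(users, traits, corr)``: the per-user feature table, the
    scored traits, and the tidy trait × feature correlation screen.
    """
    users = cohort_feature_table(cohort, min_photos=min_photos)
    traits = score_survey(cohort.survey)
    corr = correlate(users.drop(columns=["user_id"]).assign(
        user_id=users["user_id"]), traits)
    return users, traits, corr


def run_round_trip(config: SyntheticCohortConfig | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """One simulate → extract → aggregate → score → correlate replicate;
    returns the tidy correlation table."""
    cohort = simulate_cohort(config, seed=seed)
    _, _, corr = analyze_cohort(cohort)
    return corr


def sign_recovery(
    corr: pd.DataFrame, config: SyntheticCohortConfig, threshold: float = 0.2
) -> dict[tuple[str, str], bool]:
    """For each configured strong effect, whether the correlation screen
    recovered it as significant with the configured sign."""
    out = {}
    for trait, feature, sign in strong_effects(config, threshold):
        row = corr[(corr.trait == trait) & (corr.feature == feature)]
        if len(row) != 1:
            raise ValueError(f"missing correlation cell ({trait}, {feature})")
        r = row.iloc[0]
        out[(trait, feature)] = bool(r.significant and np.sign(r.r) == sign)
    return out


def predict_all_traits(
    users: pd.DataFrame,
    traits: pd.DataFrame,
    models: tuple[str, ...] = ("linear_regression", "random_forest"),
    k: int = 10,
    seed: int = 0,
) -> list[PredictionResult]:
    """Cross-validated RMSE for every trait and model, predicting from
    the full numeric feature set (including n_photos)."""
    merged = traits.merge(users, on="user_id")
    feat_cols = [c for c in users.columns if c != "user_id"]
    X = merged[feat_cols].to_numpy(float)
    results = []
    for trait in TRAITS:
        y = merged[trait].to_numpy(float)
        for model in models:
            results.append(
                crossval_rmse(X, y, model=model, k=k, seed=seed, trait=trait)
            )
    return results
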