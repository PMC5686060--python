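"""The MS-DSS severity model.

A gradient-boosted regression (squared-error loss, depth-2 trees,
shrinkage 0.001, half-sample bagging per tree, tree count picked by
five-fold cross-validation) maps first-visit features to the
therapy-adjusted CombiWISE progression slope.  The prediction itself is
the MS-DSS score, in CombiWISE units/year of predicted untreated
progression.

Relative influence of a feature is its share of the total squared-error
improvement across all splits of the ensemble, normalized to sum to 100.
Retraining on only the features whose influence exceeds a threshold
(4.0 by default) yields the reduced model.

Missing feature values (COMRIS-CTD, onset-to-first-therapy for
never-treated patients, unknown family history) are handled by a
missingness indicator plus median imputation before the tree learner;
this strategy is recorded in the model metadata, and indicator-column
influence is folded back into the parent feature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import joblib
import numpy as np
import pandas as pd
import sklearn
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .cohort import PatientRecord, SchemaError, ValidationError
from .scales import compute_combiwise
from .therapy import EfficacyModel, adjust_cross_sectional, cumulative_efficacy
from .trajectories import retained_visits

__all__ = [
    "FEATURE_NAMES",
    "SeverityModel",
    "build_features",
    "features_frame",
    "train",
    "relative_influence",
    "reduce_and_retrain",
    "predict_msdss",
    "evaluate",
    "save_model",
    "load_model",
]

FEATURE_NAMES = [
    "adj_cw_per_age",
    "measured_cw",
    "comris_ctd",
    "onset_to_first_therapy_years",
    "adj_minus_measured_cw",
    "age",
    "family_history",
    "sex",
    "race",
    "smoking",
    "n_short_dmts",
    "cumulative_efficacy_followup",
    "therapy_type",
]

#: features that may legitimately be missing and get a missingness indicator
MISSINGABLE = ["comris_ctd", "onset_to_first_therapy_years", "family_history"]

THERAPY_TYPE_CODE = {"none_or_unknown": 0, "low_only": 1, "high_only": 2, "both": 3}

SHORT_DMT_YEARS = 0.5  # epochs shorter than 6 months count as short exposures

DEFAULT_HYPERPARAMETERS = {
    "interaction_depth": 2,
    "shrinkage": 0.001,
    "bag_fraction": 0.5,
    "min_node_size": 10,  # minimum observations per terminal node
    "cv_folds": 5,
    "tree_grid": (100, 200, 400, 800, 1600, 3200, 6400, 12800, 20000),
}


def _therapy_type(p: PatientRecord) -> str:
    classes = {e.efficacy_class for e in p.treatments} - {"none_or_unknown"}
    if not classes:
        return "none_or_unknown"
    if classes == {"low"}:
        return "low_only"
    if classes == {"high"}:
        return "high_only"
    return "both"


def build_features(
    p: PatientRecord,
    efficacy_model: EfficacyModel | None = None,
    anchor: str = "first_visit",
) -> dict[str, float]:
    """Candidate feature vector from data at and before the anchor visit.

    ``anchor`` is ``"first_visit"`` or ``"last_visit"`` (the latter for
    retrospective application to called-back patients).  Missing data are
    propagated as NaN, never imputed here.
    """
    efficacy_model = efficacy_model or EfficacyModel()
    kept = retained_visits(p)
    if not kept:
        raise ValidationError(
            f"patient {p.patient_id}: no usable visit to anchor features on"
        )
    if anchor == "first_visit":
        visit = kept[0]
    elif anchor == "last_visit":
        visit = kept[-1]
    else:
        raise ValidationError(f"anchor must be first_visit or last_visit, got {anchor!r}")
    measured = compute_combiwise(visit)
    adj = adjust_cross_sectional(measured, p.treatments, visit.visit_age, efficacy_model)
    if p.treatments:
        first_start = min(e.start_age for e in p.treatments)
        onset_to_therapy = first_start - p.onset_age
    else:
        onset_to_therapy = math.nan
    if len(kept) >= 2:
        eff_followup = cumulative_efficacy(
            p.treatments, kept[0].visit_age, kept[-1].visit_age, efficacy_model
        ).value
    else:
        eff_followup = 0.0
    return {
        "adj_cw_per_age": adj.adjusted / visit.visit_age,
        "measured_cw": measured,
        "comris_ctd": math.nan if visit.comris_ctd is None else float(visit.comris_ctd),
        "onset_to_first_therapy_years": onset_to_therapy,
        "adj_minus_measured_cw": adj.adjusted - measured,
        "age": visit.visit_age,
        "family_history": math.nan if p.family_history is None else float(p.family_history),
        "sex": 1.0 if p.sex == "male" else 0.0,
        "race": 1.0 if p.race == "white" else 0.0,
        "smoking": 1.0 if p.smoking == "yes" else 0.0,
        "n_short_dmts": float(sum(e.duration < SHORT_DMT_YEARS for e in p.treatments)),
        "cumulative_efficacy_followup": eff_followup,
        "therapy_type": float(THERAPY_TYPE_CODE[_therapy_type(p)]),
    }


def features_frame(
    patients: list[PatientRecord],
    efficacy_model: EfficacyModel | None = None,
    anchor: str = "first_visit",
) -> pd.DataFrame:
    """Feature matrix (one row per patient, indexed by patient id)."""
    rows = {p.patient_id: build_features(p, efficacy_model, anchor) for p in patients}
    return pd.DataFrame.from_dict(rows, orient="index")[FEATURE_NAMES]


# ---------------------------------------------------------------------------
# model


@dataclass
class SeverityModel:
    """Trained boosted-tree MS-DSS regressor with its metadata."""

    feature_names: list[str]
    hyperparameters: dict
    estimator: GradientBoostingRegressor | None
    imputation_medians: dict[str, float]
    n_trees: int
    seed: int
    reduced: bool = False
    constant_prediction: float | None = None  # degenerate single-value target
    missing_value_strategy: str = "indicator_plus_median"
    cv_errors: dict[int, float] = field(default_factory=dict)

    @property
    def is_trained(self) -> bool:
        return self.estimator is not None or self.constant_prediction is not None


def _indicator_columns(feature_names: list[str]) -> list[str]:
    return [f for f in MISSINGABLE if f in feature_names]


def _design_matrix(
    X: pd.DataFrame, feature_names: list[str], medians: dict[str, float]
) -> np.ndarray:
    missing = [f for f in feature_names if f not in X.columns]
    if missing:
        raise SchemaError(f"feature(s) absent from input: {missing}")
    cols = []
    for f in feature_names:
        col = X[f].to_numpy(dtype=float)
        filled = np.where(np.isnan(col), medians.get(f, 0.0), col)
        cols.append(filled)
    for f in _indicator_columns(feature_names):
        cols.append(np.isnan(X[f].to_numpy(dtype=float)).astype(float))
    return np.column_stack(cols)


def _cv_tree_count(
    X: np.ndarray, y: np.ndarray, hp: dict, seed: int
) -> tuple[int, dict[int, float]]:
    grid = sorted(int(g) for g in hp["tree_grid"])
    if len(grid) == 1:
        return grid[0], {}
    folds = min(hp["cv_folds"], len(y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = {g: 0.0 for g in grid}
    for fold_i, (tr, te) in enumerate(kf.split(X)):
        gbr = GradientBoostingRegressor(
            n_estimators=grid[-1],
            max_depth=hp["interaction_depth"],
            learning_rate=hp["shrinkage"],
            subsample=hp["bag_fraction"],
            min_samples_leaf=hp["min_node_size"],
            random_state=seed + fold_i,
        )
        gbr.fit(X[tr], y[tr])
        for stage, pred in enumerate(gbr.staged_predict(X[te]), start=1):
            if stage in errors:
                errors[stage] += float(np.mean((pred - y[te]) ** 2))
    cv_curve = {g: errors[g] / folds for g in grid}
    best = min(grid, key=lambda g: (cv_curve[g], g))
    return best, cv_curve


def train(
    features: pd.DataFrame,
    targets,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> SeverityModel:
    """Fit the boosted severity model; tree count by 5-fold CV over a grid."""
    hp = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        hp.update(hyperparameters)
    y = np.asarray(targets, dtype=float)
    if len(y) != len(features):
        raise ValidationError("features and targets differ in length")
    if not np.all(np.isfinite(y)):
        raise ValidationError("targets must be finite")
    feature_names = list(features.columns)
    medians = {
        f: float(np.nanmedian(features[f].to_numpy(dtype=float)))
        if not np.all(np.isnan(features[f].to_numpy(dtype=float)))
        else 0.0
        for f in feature_names
    }
    if np.ptp(y) == 0:
        return SeverityModel(
            feature_names=feature_names,
            hyperparameters=hp,
            estimator=None,
            imputation_medians=medians,
            n_trees=0,
            seed=seed,
            constant_prediction=float(y[0]) if len(y) else 0.0,
        )
    X = _design_matrix(features, feature_names, medians)
    n_trees, cv_curve = _cv_tree_count(X, y, hp, seed)
    gbr = GradientBoostingRegressor(
        n_estimators=n_trees,
        max_depth=hp["interaction_depth"],
        learning_rate=hp["shrinkage"],
        subsample=hp["bag_fraction"],
        min_samples_leaf=hp["min_node_size"],
        random_state=seed,
    )
    gbr.fit(X, y)
    return SeverityModel(
        feature_names=feature_names,
        hyperparameters=hp,
        estimator=gbr,
        imputation_medians=medians,
        n_trees=n_trees,
        seed=seed,
        cv_errors=cv_curve,
    )


def relative_influence(m: SeverityModel) -> pd.Series:
    """Per-feature influence percentages (summing to 100 for a non-degenerate fit).

    Missingness-indicator columns are folded into their parent features so
    the result is expressed over the declared feature list.
    """
    if not m.is_trained:
        raise ValidationError("model is not trained")
    if m.estimator is None:  # constant-target model: no splits, no influence
        return pd.Series(0.0, index=m.feature_names)
    importances = m.estimator.feature_importances_
    values = pd.Series(0.0, index=m.feature_names)
    k = len(m.feature_names)
    for i, f in enumerate(m.feature_names):
        values[f] += importances[i]
    for j, f in enumerate(_indicator_columns(m.feature_names)):
        values[f] += importances[k + j]
    total = values.sum()
    if total <= 0:
        return values * 0.0
    return 100.0 * values / total


def reduce_and_retrain(
    m: SeverityModel,
    features: pd.DataFrame,
    targets,
    threshold: float = 4.0,
    seed: int | None = None,
) -> SeverityModel:
    """Retrain on the features whose relative influence exceeds ``threshold``."""
    infl = relative_influence(m)
    kept = [f for f in m.feature_names if infl[f] > threshold]
    if not kept:
        raise ValidationError(
            f"no feature exceeds relative influence {threshold}; lower the threshold"
        )
    reduced = train(
        features[kept],
        targets,
        hyperparameters=m.hyperparameters,
        seed=m.seed if seed is None else seed,
    )
    reduced.reduced = True
    return reduced


def predict_msdss(m: SeverityModel, f) -> np.ndarray | float:
    """MS-DSS score(s): predicted therapy-adjusted CombiWISE slope (units/y)."""
    if not m.is_trained:
        raise ValidationError("model is not trained")
    single = isinstance(f, (dict, pd.Series))
    frame = pd.DataFrame([f]) if single else pd.DataFrame(f)
    if m.constant_prediction is not None:
        out = np.full(len(frame), m.constant_prediction)
    else:
        X = _design_matrix(frame, m.feature_names, m.imputation_medians)
        out = m.estimator.predict(X)
    return float(out[0]) if single else out


class Evaluation(NamedTuple):
    r: float
    p_value: float
    n: int


def evaluate(m: SeverityModel, features: pd.DataFrame, targets) -> Evaluation:
    """Pearson correlation of predictions against therapy-adjusted slopes."""
    y = np.asarray(targets, dtype=float)
    if len(y) < 3:
        raise ValidationError("need at least 3 paired observations")
    preds = np.asarray(predict_msdss(m, features), dtype=float)
    if np.std(preds) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined: a vector has zero variance")
    r, p = stats.pearsonr(preds, y)
    return Evaluation(r=float(r), p_value=float(p), n=len(y))


# ---------------------------------------------------------------------------
# persistence


def save_model(m: SeverityModel, path) -> None:
    """Serialize the model plus a JSON metadata sidecar next to it."""
    path = Path(path)
    joblib.dump(m, path)
    infl = relative_influence(m)
    meta = {
        "feature_names": m.feature_names,
        "hyperparameters": {
            k: list(v) if isinstance(v, tuple) else v for k, v in m.hyperparameters.items()
        },
        "n_trees": m.n_trees,
        "seed": m.seed,
        "reduced": m.reduced,
        "missing_value_strategy": m.missing_value_strategy,
        "relative_influence": {k: float(v) for k, v in infl.items()},
        "versions": {"sklearn": sklearn.__version__, "numpy": np.__version__},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> SeverityModel:
    return joblib.load(Path(path))
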