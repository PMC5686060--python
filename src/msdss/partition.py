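"""Stratified training/validation partitioning and stability analysis.

The 2:1 split stratifies on four first-visit variables: race, sex, and
above/below-median dichotomies of therapy-adjusted CombiWISE/age and age
at first visit (medians over the full cohort; ties fall in the lower bin).
Crossing the four binary variables yields up to 16 cells; within each
nonempty cell, round(2n/3) patients (half-up) are drawn uniformly into
the training arm.

``partition_stability`` repeats model training over many fully random
(non-stratified) 2:1 splits and summarizes the distribution of validation
correlations, a scaled-down version of the repeated-partition robustness
check used to judge how sensitive the severity model is to the particular
split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ValidationError

__all__ = ["PartitionSpec", "stratified_split", "partition_stability"]

log = logging.getLogger(__name__)

STRATA_COLUMNS = ["race", "sex", "adj_cw_per_age", "first_visit_age"]


@dataclass(frozen=True)
class PartitionSpec:
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    median_tie_rule: str = "lower"  # patients at the median join the lower bin


def _n_train(n: int, fraction: float) -> int:
    return int(math.floor(fraction * n + 0.5))  # round half up


def stratified_split(
    features: pd.DataFrame, spec: PartitionSpec | None = None
) -> tuple[list[str], list[str]]:
    """Split patient ids 2:1 within 16 strata cells.

    ``features`` must be indexed by patient id with columns ``race``,
    ``sex`` (any binary coding), ``adj_cw_per_age`` and ``first_visit_age``
    (continuous; dichotomized at the full-cohort median).  Returns
    ``(training_ids, validation_ids)``, deterministic given the seed.
    """
    spec = spec or PartitionSpec()
    if len(features) == 0:
        raise ValidationError("cannot split an empty cohort")
    missing = [c for c in STRATA_COLUMNS if c not in features.columns]
    if missing:
        raise ValidationError(f"stratification variables missing: {missing}")
    cells: dict[tuple, list[str]] = {}
    med_cw = float(features["adj_cw_per_age"].median())
    med_age = float(features["first_visit_age"].median())
    for pid, row in features.iterrows():
        if spec.median_tie_rule == "lower":
            cw_bin = row["adj_cw_per_age"] <= med_cw
            age_bin = row["first_visit_age"] <= med_age
        else:
            cw_bin = row["adj_cw_per_age"] < med_cw
            age_bin = row["first_visit_age"] < med_age
        cell = (str(row["race"]), str(row["sex"]), bool(cw_bin), bool(age_bin))
        cells.setdefault(cell, []).append(str(pid))
    rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    validation: list[str] = []
    for cell in sorted(cells):
        ids = sorted(cells[cell])
        order = rng.permutation(len(ids))
        k = _n_train(len(ids), spec.train_fraction)
        train.extend(ids[i] for i in order[:k])
        validation.extend(ids[i] for i in order[k:])
    return sorted(train), sorted(validation)


def partition_stability(
    features: pd.DataFrame,
    targets: pd.Series,
    fit_predict,
    n_partitions: int = 100,
    seed: int = 0,
    train_fraction: float = 2.0 / 3.0,
) -> dict:
    """Distribution of validation correlations over random 2:1 splits.

    For each replicate, a fully random (non-stratified) split is drawn, the
    model is trained via ``fit_predict(train_X, train_y, test_X, seed)``
    and the Pearson correlation of its predictions with the validation
    targets is recorded.  Replicates whose correlation is undefined (a
    constant vector) contribute 0; replicates where the model raises are
    dropped and counted.
    """
    ids = np.asarray(features.index)
    if len(ids) < 3:
        raise ValidationError("need at least 3 patients for stability analysis")
    rng = np.random.default_rng(seed)
    correlations: list[float] = []
    n_dropped = 0
    n_undefined = 0
    for rep in range(n_partitions):
        order = rng.permutation(len(ids))
        k = _n_train(len(ids), train_fraction)
        train_ids, test_ids = ids[order[:k]], ids[order[k:]]
        rep_seed = int(rng.integers(0, 2**31 - 1))
        try:
            preds = np.asarray(
                fit_predict(
                    features.loc[train_ids],
                    targets.loc[train_ids],
                    features.loc[test_ids],
                    rep_seed,
                ),
                dtype=float,
            )
            truth = targets.loc[test_ids].to_numpy(dtype=float)
            if np.ptp(preds) == 0 or np.ptp(truth) == 0:
                r = math.nan
            else:
                r = float(stats.pearsonr(preds, truth)[0])
            if math.isnan(r):
                n_undefined += 1
                correlations.append(0.0)
            else:
                correlations.append(r)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            log.warning("stability replicate %d failed: %s", rep, exc)
            n_dropped += 1
    arr = np.asarray(correlations, dtype=float)
    quantiles = {}
    if len(arr):
        qs = np.quantile(arr, [0.025, 0.25, 0.5, 0.75, 0.975])
        quantiles = dict(zip(["q2.5", "q25", "q50", "q75", "q97.5"], map(float, qs)))
    return {
        "mean": float(arr.mean()) if len(arr) else math.nan,
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "quantiles": quantiles,
        "n_partitions": n_partitions,
        "n_effective": len(arr),
        "n_dropped": n_dropped,
        "n_undefined": n_undefined,
        "correlations": arr,
    }
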