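"""Per-patient progression slopes.

Visits flagged as exacerbations are excluded before anything else, since
much exacerbation-related disability is transient and would inflate
sustained progression.  A patient is eligible for slope estimation with
three or more retained CombiWISE-computable visits spanning at least one
year, or two or more spanning at least three years.  Slopes are ordinary
least squares fits of the scale value against age at visit; R-squared is
reported when residual variation is defined (at least three points and a
nonconstant response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import PatientRecord, ValidationError, Visit
from .scales import combiwise_computable, compute_combiwise
from .therapy import EfficacyModel, adjust_slope, cumulative_efficacy

__all__ = [
    "TrajectorySummary",
    "retained_visits",
    "eligible",
    "fit_slope",
    "adjust_trajectory",
    "paired_r2_summary",
]


@dataclass
class TrajectorySummary:
    """OLS fit of one disability scale against age for one patient."""

    patient_id: str
    scale_name: str  # "EDSS" or "CombiWISE"
    slope: float  # scale units per year
    intercept: float  # fitted scale value at the first retained visit age
    r_squared: float  # NaN when residual variation is undefined
    n_visits: int
    span_years: float
    adjusted_slope: float | None = None


def retained_visits(p: PatientRecord) -> list[Visit]:
    """Non-exacerbation visits at which CombiWISE is computable."""
    return [v for v in p.visits if not v.exacerbation and combiwise_computable(v)]


def eligible(p: PatientRecord) -> bool:
    """Follow-up sufficiency: >=3 retained visits over >=1 y, or >=2 over >=3 y."""
    kept = retained_visits(p)
    if len(kept) < 2:
        return False
    span = kept[-1].visit_age - kept[0].visit_age
    return (len(kept) >= 3 and span >= 1.0) or span >= 3.0


def _scale_value(v: Visit, scale_name: str) -> float:
    if scale_name == "CombiWISE":
        return compute_combiwise(v)
    if scale_name == "EDSS":
        return v.edss
    raise ValidationError(f"unknown scale {scale_name!r}")


def fit_slope(p: PatientRecord, scale_name: str = "CombiWISE") -> TrajectorySummary:
    """Least-squares progression slope over the retained visits."""
    kept = retained_visits(p)
    if len(kept) < 2:
        raise ValidationError(
            f"patient {p.patient_id}: {len(kept)} usable visit(s); need at least 2"
        )
    ages = np.array([v.visit_age for v in kept], dtype=float)
    values = np.array([_scale_value(v, scale_name) for v in kept], dtype=float)
    x = ages - ages.mean()
    y = values - values.mean()
    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    fitted = values.mean() + slope * x
    ss_res = float(np.sum((values - fitted) ** 2))
    ss_tot = float(y @ y)
    if len(kept) >= 3 and ss_tot > 0:
        r_squared = 1.0 - ss_res / ss_tot
    else:
        r_squared = math.nan
    return TrajectorySummary(
        patient_id=p.patient_id,
        scale_name=scale_name,
        slope=slope,
        intercept=float(values.mean() + slope * (ages[0] - ages.mean())),
        r_squared=r_squared,
        n_visits=len(kept),
        span_years=float(ages[-1] - ages[0]),
    )


def adjust_trajectory(
    t: TrajectorySummary, p: PatientRecord, model: EfficacyModel | None = None
) -> TrajectorySummary:
    """Populate the therapy-adjusted slope for a CombiWISE trajectory.

    Cumulative efficacy is evaluated over the first-to-last retained visit
    window (treatment outside the follow-up does not dilute the slope
    adjustment) and the measured slope is shifted to the predicted
    untreated slope.
    """
    if t.scale_name != "CombiWISE":
        raise ValidationError("therapy adjustment is defined for CombiWISE slopes only")
    kept = retained_visits(p)
    eff = cumulative_efficacy(p.treatments, kept[0].visit_age, kept[-1].visit_age, model)
    adjusted = adjust_slope(t.slope, eff)
    return replace(t, adjusted_slope=adjusted.adjusted)


@dataclass
class PairedR2Summary:
    mean_difference: float
    ci_low: float
    ci_high: float
    differences: np.ndarray
    n: int


def paired_r2_summary(
    cw_fits: list[TrajectorySummary], edss_fits: list[TrajectorySummary]
) -> PairedR2Summary:
    """Paired comparison of variance explained: CombiWISE minus EDSS.

    Patients with an undefined R-squared on either scale (fewer than three
    points or a constant response) are excluded.  Returns the mean paired
    difference with a 95% t-interval; the interval degenerates to the mean
    when the differences have zero variance.
    """
    edss_by_id = {t.patient_id: t for t in edss_fits}
    diffs = []
    for t in cw_fits:
        other = edss_by_id.get(t.patient_id)
        if other is None:
            continue
        if math.isnan(t.r_squared) or math.isnan(other.r_squared):
            continue
        diffs.append(t.r_squared - other.r_squared)
    if not diffs:
        raise ValidationError("no patients with defined R-squared on both scales")
    d = np.asarray(diffs, dtype=float)
    mean = float(d.mean())
    n = len(d)
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    if sd > 0:
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    else:
        half = 0.0
    return PairedR2Summary(
        mean_difference=mean, ci_low=mean - half, ci_high=mean + half, differences=d, n=n
    )
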