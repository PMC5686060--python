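"""Age-dependent therapy-efficacy calculus.

Disease-modifying therapies are dichotomized into low- and high-efficacy
classes.  A meta-analysis of randomized trials supplies, for each class, a
linear model of percent efficacy against the mean age on treatment::

    low  : Eff% = -1.50 * mean_age +  83.71
    high : Eff% = -4.34 * mean_age + 206.39

Untreated or unknown-drug periods carry zero efficacy, and negative
predicted efficacies are clamped to zero.  The per-epoch fractions are
combined into a duration-weighted cumulative efficacy over a time window,
which is then used to undo the treatment effect:

* progression slopes: ``adjusted = measured / (1 - Eff)`` for worsening
  patients, ``adjusted = measured * (1 - Eff)`` for improving patients;
* cross-sectional CombiWISE: ``adjusted = measured / (1 - Eff(0, age))``
  with the window anchored at birth because true disease onset cannot be
  observed.

Both adjustments shift the measured value toward the untreated
counterfactual, never below the measurement itself.

The high-efficacy line exceeds 100% below roughly age 24.5, which would
make ``1 - Eff`` non-positive; per-epoch efficacy is therefore capped (at
0.95 by default) before weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cohort import TreatmentEpoch, ValidationError

__all__ = [
    "EfficacyModel",
    "CumulativeEfficacy",
    "AdjustedMeasure",
    "epoch_efficacy",
    "cumulative_efficacy",
    "adjust_slope",
    "adjust_cross_sectional",
]

log = logging.getLogger(__name__)

#: (age slope, intercept) of percent efficacy per class
DEFAULT_CLASS_COEFFICIENTS = {
    "none_or_unknown": (0.0, 0.0),
    "low": (-1.50, 83.71),
    "high": (-4.34, 206.39),
}


@dataclass(frozen=True)
class EfficacyModel:
    """Per-class linear efficacy-vs-age models, as fractions after scaling."""

    class_coefficients: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COEFFICIENTS)
    )
    cap: float = 0.95  # per-epoch ceiling on the efficacy fraction

    def percent_at(self, efficacy_class: str, mean_age: float) -> float:
        try:
            slope, intercept = self.class_coefficients[efficacy_class]
        except KeyError:
            raise ValidationError(f"unknown efficacy class {efficacy_class!r}") from None
        return slope * mean_age + intercept


@dataclass(frozen=True)
class CumulativeEfficacy:
    """Duration-weighted mean efficacy fraction over a window [t0, tn]."""

    t0: float
    tn: float
    value: float


@dataclass(frozen=True)
class AdjustedMeasure:
    """A measured value together with its therapy-adjusted counterpart."""

    measured: float
    adjusted: float
    efficacy_used: float


def epoch_efficacy(epoch: TreatmentEpoch, model: EfficacyModel | None = None) -> float:
    """Efficacy fraction of one epoch, evaluated at its mean age.

    The class line gives percent efficacy at ``(start + end) / 2``; the
    result is divided by 100 and clamped to ``[0, cap]``.
    """
    model = model or EfficacyModel()
    epoch.validate()
    mean_age = 0.5 * (epoch.start_age + epoch.end_age)
    frac = model.percent_at(epoch.efficacy_class, mean_age) / 100.0
    if frac < 0.0:
        return 0.0
    if frac > model.cap:
        log.info(
            "epoch efficacy %.4f at mean age %.1f capped at %.2f",
            frac,
            mean_age,
            model.cap,
        )
        return model.cap
    return frac


def cumulative_efficacy(
    epochs: list[TreatmentEpoch],
    t0: float,
    tn: float,
    model: EfficacyModel | None = None,
) -> CumulativeEfficacy:
    """Duration-weighted cumulative efficacy over ``[t0, tn]``.

    Epochs are clipped to the window before their mean age is evaluated;
    periods not covered by any epoch contribute zero efficacy.
    """
    model = model or EfficacyModel()
    if not tn > t0:
        raise ValidationError(f"window end {tn} must exceed start {t0}")
    weighted = 0.0
    for e in epochs:
        start = max(e.start_age, t0)
        end = min(e.end_age, tn)
        if end <= start:
            continue
        clipped = TreatmentEpoch(start, end, e.efficacy_class)
        weighted += (end - start) * epoch_efficacy(clipped, model)
    return CumulativeEfficacy(t0=t0, tn=tn, value=weighted / (tn - t0))


def _eff_value(eff: CumulativeEfficacy | float) -> float:
    value = eff.value if isinstance(eff, CumulativeEfficacy) else float(eff)
    if not 0.0 <= value < 1.0:
        raise ValidationError(f"cumulative efficacy {value} outside [0, 1)")
    return value


def adjust_slope(measured_slope: float, eff: CumulativeEfficacy | float) -> AdjustedMeasure:
    """Therapy-adjusted progression slope (the predicted untreated slope).

    Worsening patients (positive slope) progress at only ``1 - Eff`` of
    their untreated rate, so the measurement is divided by ``1 - Eff``;
    improving patients (negative slope) recover faster on therapy, so the
    measurement is multiplied by ``1 - Eff``.  A zero slope is unchanged.
    """
    e = _eff_value(eff)
    if measured_slope > 0:
        adjusted = measured_slope / (1.0 - e)
    elif measured_slope < 0:
        adjusted = measured_slope * (1.0 - e)
    else:
        adjusted = 0.0
    return AdjustedMeasure(measured=measured_slope, adjusted=adjusted, efficacy_used=e)


def adjust_cross_sectional(
    cw: float,
    epochs: list[TreatmentEpoch],
    visit_age: float,
    model: EfficacyModel | None = None,
) -> AdjustedMeasure:
    """Adjust a cross-sectional CombiWISE for all treatment before the visit.

    Uses the cumulative efficacy from birth to ``visit_age`` (disease onset
    is unobservable, so the window is anchored at birth) and shifts the
    measurement upward: ``adjusted = cw / (1 - Eff(0, visit_age))``.
    """
    if cw < 0:
        raise ValidationError(f"CombiWISE must be nonnegative, got {cw}")
    if not visit_age > 0:
        raise ValidationError(f"visit_age must be positive, got {visit_age}")
    eff = cumulative_efficacy(epochs, 0.0, visit_age, model)
    adjusted = cw / (1.0 - eff.value)
    return AdjustedMeasure(measured=cw, adjusted=adjusted, efficacy_used=eff.value)
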