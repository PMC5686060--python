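"""Disability scales: CombiWISE, CombiWISE/age, and rank-based severity.

CombiWISE is a continuous 0-100 composite of four instruments::

    CombiWISE = 33.166 + 3.803*EDSS - 0.407*SNRS
              + 2.409*log2(T25FW) + 18.056*T25FW_FAIL
              + 1.305*log2(NDH-9HPT) + 10.751*NDH_FAIL

where T25FW and NDH-9HPT are times in seconds and the FAIL indicators are
1 for a failed test.  For a failed timed test the log term is evaluated at
the test ceiling (180 s for the walk, 300 s for the peg test) and the fail
bonus is added; this keeps the score continuous across the pass/fail
boundary.

MSSS-style severity scores rank a patient's EDSS within a reference
distribution conditioned on disease duration (MSSS) or age (ARMSS) and
rescale the rank to the open interval (0, 10).  The reference here is
built locally from the supplied cohort; a user-supplied
:class:`ReferenceDistribution` (e.g. from published global tables) can be
passed instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cohort import (
    NDH_9HPT_LIMIT,
    T25FW_LIMIT,
    PatientRecord,
    ValidationError,
    Visit,
)

__all__ = [
    "COMBIWISE_COEFFICIENTS",
    "ReferenceDistribution",
    "compute_combiwise",
    "combiwise_from_components",
    "compute_cw_per_age",
    "build_reference",
    "compute_rank_severity",
]

log = logging.getLogger(__name__)

COMBIWISE_COEFFICIENTS = {
    "intercept": 33.166,
    "edss": 3.803,
    "snrs": -0.407,
    "log2_t25fw": 2.409,
    "t25fw_fail": 18.056,
    "log2_ndh_9hpt": 1.305,
    "ndh_9hpt_fail": 10.751,
}


def combiwise_from_components(
    edss: float,
    snrs: float,
    t25fw_seconds: float | None,
    t25fw_fail: int,
    ndh_9hpt_seconds: float | None,
    ndh_9hpt_fail: int,
    clip: bool = True,
) -> float:
    """Evaluate the CombiWISE composite from its four component scales."""
    c = COMBIWISE_COEFFICIENTS

    def timed_term(seconds, fail, limit, coef, bonus, name):
        if fail:
            if seconds is not None and not (isinstance(seconds, float) and math.isnan(seconds)):
                raise ValidationError(
                    f"{name}: a recorded time ({seconds} s) is inconsistent with a fail "
                    "flag; failed tests carry no time"
                )
            return coef * math.log2(limit) + bonus
        if seconds is None or (isinstance(seconds, float) and math.isnan(seconds)):
            raise ValidationError(f"{name}: time missing and test not marked as failed")
        if seconds <= 0:
            raise ValidationError(f"{name}: time must be positive, got {seconds}")
        if seconds > limit:
            raise ValidationError(
                f"{name}: {seconds} s exceeds the {limit:.0f} s limit; mark the test failed"
            )
        return coef * math.log2(seconds)

    value = (
        c["intercept"]
        + c["edss"] * edss
        + c["snrs"] * snrs
        + timed_term(
            t25fw_seconds, t25fw_fail, T25FW_LIMIT, c["log2_t25fw"], c["t25fw_fail"], "t25fw"
        )
        + timed_term(
            ndh_9hpt_seconds,
            ndh_9hpt_fail,
            NDH_9HPT_LIMIT,
            c["log2_ndh_9hpt"],
            c["ndh_9hpt_fail"],
            "ndh_9hpt",
        )
    )
    if clip and not (0.0 <= value <= 100.0):
        clipped = min(max(value, 0.0), 100.0)
        log.info("CombiWISE value %.4f clipped to %.1f", value, clipped)
        return clipped
    return value


def compute_combiwise(v: Visit) -> float:
    """CombiWISE score for one visit, clipped to the 0-100 scale."""
    return combiwise_from_components(
        v.edss,
        v.snrs,
        v.t25fw_seconds,
        v.t25fw_fail,
        v.ndh_9hpt_seconds,
        v.ndh_9hpt_fail,
    )


def combiwise_computable(v: Visit) -> bool:
    """True if the visit carries everything CombiWISE needs."""
    try:
        compute_combiwise(v)
    except ValidationError:
        return False
    return True


def compute_cw_per_age(cw: float, age: float) -> float:
    """CombiWISE divided by age: a cross-sectional severity proxy."""
    if not age > 0:
        raise ValidationError(f"age must be positive, got {age}")
    return cw / age


# ---------------------------------------------------------------------------
# rank-conditional severity (MSSS / ARMSS style)


@dataclass
class ReferenceDistribution:
    """Binned reference EDSS distribution for rank-based severity scores.

    ``bin_edges`` has length ``len(bins) + 1``; ``bins[i]`` holds the EDSS
    multiset of patients whose conditioning value fell in
    ``[bin_edges[i], bin_edges[i+1])`` (last bin right-inclusive).
    """

    conditioning_variable: str  # "disease_duration" or "age"
    bin_edges: np.ndarray
    bins: list[np.ndarray]
    min_count: int = 5

    def bin_index(self, key: float) -> int:
        edges = self.bin_edges
        if key < edges[0] or key > edges[-1]:
            raise ValidationError(
                f"{self.conditioning_variable}={key} outside reference range "
                f"[{edges[0]}, {edges[-1]}]"
            )
        idx = int(np.searchsorted(edges, key, side="right") - 1)
        return min(idx, len(self.bins) - 1)


DEFAULT_BIN_WIDTH = {"disease_duration": 1.0, "age": 5.0}


def build_reference(
    patients: list[PatientRecord],
    conditioning: str = "disease_duration",
    bin_width: float | None = None,
    min_count: int = 5,
) -> ReferenceDistribution:
    """Bin first-visit EDSS by disease duration or age.

    Bins with fewer than ``min_count`` patients are merged with their
    neighbours (outward sweep from both ends) so every scored bin carries a
    usable sample.
    """
    if conditioning not in DEFAULT_BIN_WIDTH:
        raise ValidationError(
            f"conditioning must be 'disease_duration' or 'age', got {conditioning!r}"
        )
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH[conditioning]
    keys, edss = [], []
    for p in patients:
        if not p.visits:
            continue
        first = p.visits[0]
        key = (
            first.visit_age - p.onset_age
            if conditioning == "disease_duration"
            else first.visit_age
        )
        keys.append(key)
        edss.append(first.edss)
    if not keys:
        raise ValidationError("cannot build a reference from an empty cohort")
    keys = np.asarray(keys, dtype=float)
    edss = np.asarray(edss, dtype=float)
    lo = math.floor(keys.min() / bin_width) * bin_width
    n_bins = max(1, math.ceil((keys.max() - lo) / bin_width + 1e-12))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], keys.max())
    idx = np.clip(np.searchsorted(edges, keys, side="right") - 1, 0, n_bins - 1)
    bins = [edss[idx == i] for i in range(n_bins)]

    # merge under-filled bins into their neighbours, sweeping from the ends
    merged_bins: list[np.ndarray] = []
    merged_edges = [edges[0]]
    acc = np.array([], dtype=float)
    for i, b in enumerate(bins):
        acc = np.concatenate([acc, b])
        last = i == n_bins - 1
        if len(acc) >= min_count or last:
            merged_bins.append(acc)
            merged_edges.append(edges[i + 1])
            acc = np.array([], dtype=float)
    if len(merged_bins) > 1 and len(merged_bins[-1]) < min_count:
        merged_bins[-2] = np.concatenate([merged_bins[-2], merged_bins[-1]])
        merged_bins.pop()
        merged_edges.pop(-2)
    if len(merged_bins) == 1 and len(merged_bins[0]) < min_count:
        raise ValidationError(
            f"only {len(merged_bins[0])} patients available; need at least "
            f"{min_count} per usable bin"
        )
    return ReferenceDistribution(
        conditioning_variable=conditioning,
        bin_edges=np.asarray(merged_edges, dtype=float),
        bins=merged_bins,
        min_count=min_count,
    )


def compute_rank_severity(edss: float, key: float, ref: ReferenceDistribution) -> float:
    """Severity in (0, 10): scaled average tied rank of ``edss`` in its bin.

    The score is ``10 * rank / (N + 1)`` where ``N`` is the bin count and
    ``rank`` is the average tied rank of ``edss`` within the bin's EDSS
    multiset (the index value is added to the multiset first when it is not
    already represented).
    """
    values = ref.bins[ref.bin_index(key)]
    n = len(values)
    if n < ref.min_count:
        raise ValidationError(
            f"reference bin holds {n} < {ref.min_count} patients; rebuild with wider bins"
        )
    matches = np.isclose(values, edss)
    if matches.any():
        pool = values
    else:
        pool = np.concatenate([values, [edss]])
        matches = np.isclose(pool, edss)
    # average tied rank = (#below) + (#tied + 1) / 2
    below = np.sum(pool < edss)
    tied = int(matches.sum())
    rank = below + (tied + 1) / 2.0
    return 10.0 * rank / (len(pool) + 1)
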