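"""Cohort data model and delimited-file I/O.

Three UTF-8 CSV files describe a cohort: ``demographics.csv`` (one row per
patient), ``visits.csv`` (one row per clinic encounter) and
``treatments.csv`` (one row per contiguous treatment epoch).  The time axis
everywhere is age in decimal years; if files carry calendar dates instead,
ages are derived at read time as (date - birth_date) / 365.25.

Raw measurements are validated against their instrument ranges on read:
EDSS on its legal grid (0, then 1.0-10.0 in 0.5 steps), SNRS as an integer
in [0, 100], the Timed 25-Foot Walk capped at 180 s and the non-dominant
hand 9-Hole Peg Test at 300 s (times beyond the cap must be recorded as a
failed test instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "Visit",
    "TreatmentEpoch",
    "PatientRecord",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "EDSS_GRID",
    "T25FW_LIMIT",
    "NDH_9HPT_LIMIT",
    "FAMILY_HISTORY_ORDINAL",
    "DRUG_EFFICACY_CLASS",
]


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ValidationError(ValueError):
    """A value violates its documented clinical range or invariant."""


T25FW_LIMIT = 180.0  # seconds; walk attempts beyond 3 min are failures
NDH_9HPT_LIMIT = 300.0  # seconds; peg-test attempts beyond 5 min are failures

# Legal EDSS values: 0, then 1.0 through 10.0 in half-point steps.
EDSS_GRID = frozenset([0.0] + [x / 2.0 for x in range(2, 21)])

EFFICACY_CLASSES = ("none_or_unknown", "low", "high")

SEX_VALUES = ("female", "male")
RACE_VALUES = ("white", "other")
SMOKING_VALUES = ("yes", "no_or_unknown")

# Family history of MS, ordinal coding. Long labels follow the clinical
# questionnaire wording; short tokens are the canonical file format.
FAMILY_HISTORY_ORDINAL = {
    "none": 0,
    "no": 0,
    "mild": 1,
    "mild (1 distant relative with ms)": 1,
    "moderate": 2,
    "moderate (>1 distant relative with ms)": 2,
    "strong": 3,
    "strong (first degree relative with definite ms)": 3,
    "unknown": None,
}
FAMILY_HISTORY_TOKEN = {0: "none", 1: "mild", 2: "moderate", 3: "strong", None: "unknown"}

# Disease-modifying therapies dichotomized into low- vs high-efficacy
# classes (drugs with below/above-average residual efficacy in randomized
# trials). Drugs not listed map to none_or_unknown (zero efficacy).
DRUG_EFFICACY_CLASS = {
    "glatiramer acetate": "low",
    "teriflunomide": "low",
    "interferon beta": "low",
    "interferon beta-1a": "low",
    "interferon beta-1b": "low",
    "dimethyl fumarate": "low",
    "fingolimod": "low",
    "natalizumab": "high",
    "daclizumab": "high",
    "alemtuzumab": "high",
    "mitoxantrone": "high",
    "ocrelizumab": "high",
}


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class Visit:
    """One clinic encounter's raw scale measurements and flags."""

    visit_age: float
    edss: float
    snrs: float
    t25fw_seconds: float | None = None
    t25fw_fail: int = 0
    ndh_9hpt_seconds: float | None = None
    ndh_9hpt_fail: int = 0
    exacerbation: int = 0
    comris_ctd: float | None = None

    def __post_init__(self) -> None:
        self.visit_age = float(self.visit_age)
        self.edss = float(self.edss)
        self.snrs = float(self.snrs)
        self.t25fw_fail = int(self.t25fw_fail)
        self.ndh_9hpt_fail = int(self.ndh_9hpt_fail)
        self.exacerbation = int(self.exacerbation)
        if self.t25fw_seconds is not None:
            self.t25fw_seconds = float(self.t25fw_seconds)
        if self.ndh_9hpt_seconds is not None:
            self.ndh_9hpt_seconds = float(self.ndh_9hpt_seconds)
        if self.comris_ctd is not None:
            self.comris_ctd = float(self.comris_ctd)

    def validate(self, where: str = "") -> None:
        ctx = f" ({where})" if where else ""
        if not self.visit_age > 0:
            raise ValidationError(f"visit_age must be positive, got {self.visit_age}{ctx}")
        if self.edss not in EDSS_GRID:
            raise ValidationError(
                f"edss={self.edss} is not on the legal EDSS grid "
                f"(0, then 1.0-10.0 in 0.5 steps){ctx}"
            )
        if not (0 <= self.snrs <= 100) or float(self.snrs) != int(self.snrs):
            raise ValidationError(f"snrs={self.snrs} must be an integer in [0, 100]{ctx}")
        for name, value, limit in (
            ("t25fw_seconds", self.t25fw_seconds, T25FW_LIMIT),
            ("ndh_9hpt_seconds", self.ndh_9hpt_seconds, NDH_9HPT_LIMIT),
        ):
            if _is_missing(value):
                continue
            if value <= 0:
                raise ValidationError(f"{name}={value} must be > 0{ctx}")
            if value > limit:
                raise ValidationError(
                    f"{name}={value} exceeds the {limit:.0f} s test limit; "
                    f"record the test as failed instead{ctx}"
                )
        for name, flag in (
            ("t25fw_fail", self.t25fw_fail),
            ("ndh_9hpt_fail", self.ndh_9hpt_fail),
            ("exacerbation", self.exacerbation),
        ):
            if flag not in (0, 1):
                raise ValidationError(f"{name}={flag} must be 0 or 1{ctx}")
        if not _is_missing(self.comris_ctd) and self.comris_ctd < 0:
            raise ValidationError(f"comris_ctd={self.comris_ctd} must be nonnegative{ctx}")


@dataclass
class TreatmentEpoch:
    """A contiguous treatment interval on one efficacy class."""

    start_age: float
    end_age: float
    efficacy_class: str = "none_or_unknown"

    @property
    def duration(self) -> float:
        return self.end_age - self.start_age

    def validate(self, where: str = "") -> None:
        ctx = f" ({where})" if where else ""
        if not self.start_age >= 0:
            raise ValidationError(f"start_age={self.start_age} must be >= 0{ctx}")
        if not self.end_age > self.start_age:
            raise ValidationError(
                f"end_age={self.end_age} must exceed start_age={self.start_age}{ctx}"
            )
        if self.efficacy_class not in EFFICACY_CLASSES:
            raise ValidationError(
                f"efficacy_class={self.efficacy_class!r} not one of {EFFICACY_CLASSES}{ctx}"
            )


@dataclass
class PatientRecord:
    """Demographics plus ordered visits and treatment epochs for one patient."""

    patient_id: str
    sex: str
    race: str
    smoking: str
    family_history: int | None  # ordinal 0-3, None = unknown
    onset_age: float
    visits: list[Visit] = field(default_factory=list)
    treatments: list[TreatmentEpoch] = field(default_factory=list)

    def validate(self) -> None:
        pid = self.patient_id
        if self.sex not in SEX_VALUES:
            raise ValidationError(f"patient {pid}: sex={self.sex!r} not in {SEX_VALUES}")
        if self.race not in RACE_VALUES:
            raise ValidationError(f"patient {pid}: race={self.race!r} not in {RACE_VALUES}")
        if self.smoking not in SMOKING_VALUES:
            raise ValidationError(
                f"patient {pid}: smoking={self.smoking!r} not in {SMOKING_VALUES}"
            )
        if self.family_history is not None and self.family_history not in (0, 1, 2, 3):
            raise ValidationError(
                f"patient {pid}: family_history={self.family_history} not ordinal 0-3 or unknown"
            )
        if not self.onset_age >= 0:
            raise ValidationError(f"patient {pid}: onset_age={self.onset_age} must be >= 0")
        ages = [v.visit_age for v in self.visits]
        for i, v in enumerate(self.visits):
            v.validate(where=f"patient {pid}, visit row {i}")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError(f"patient {pid}: visit ages must be strictly increasing")
        if ages and self.onset_age > ages[0]:
            raise ValidationError(
                f"patient {pid}: onset_age={self.onset_age} exceeds first visit age {ages[0]}"
            )
        epochs = sorted(self.treatments, key=lambda e: e.start_age)
        for i, e in enumerate(epochs):
            e.validate(where=f"patient {pid}, treatment row {i}")
        for a, b in zip(epochs, epochs[1:]):
            if b.start_age < a.end_age - 1e-12:
                raise ValidationError(
                    f"patient {pid}: overlapping treatment epochs "
                    f"[{a.start_age}, {a.end_age}] and [{b.start_age}, {b.end_age}]"
                )


# ---------------------------------------------------------------------------
# reading

_DEMO_REQUIRED = ["patient_id", "sex", "race", "smoking", "family_history", "onset_age"]
_VISIT_REQUIRED = [
    "patient_id",
    "edss",
    "snrs",
    "t25fw_seconds",
    "t25fw_fail",
    "ndh_9hpt_seconds",
    "ndh_9hpt_fail",
    "exacerbation",
    "comris_ctd",
]
_TREAT_REQUIRED = ["patient_id"]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _age_from_dates(date, birth_date) -> float:
    return (pd.Timestamp(date) - pd.Timestamp(birth_date)).days / 365.25


def _opt_float(x) -> float | None:
    if _is_missing(x) or (isinstance(x, str) and not x.strip()):
        return None
    return float(x)


def _family_history_from_label(label, pid) -> int | None:
    if _is_missing(label):
        return None
    key = str(label).strip().lower()
    if key not in FAMILY_HISTORY_ORDINAL:
        raise ValidationError(f"patient {pid}: unrecognized family_history label {label!r}")
    return FAMILY_HISTORY_ORDINAL[key]


def read_cohort(
    visits_path,
    treatments_path,
    demographics_path,
) -> list[PatientRecord]:
    """Read and validate a cohort from its three CSV files.

    Returns one :class:`PatientRecord` per row of the demographics file,
    with visits and treatment epochs attached and sorted by age.  Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError`
    for out-of-range values, naming the patient and field.
    """
    demo = pd.read_csv(demographics_path, float_precision="round_trip")
    visits = pd.read_csv(visits_path, float_precision="round_trip")
    treats = pd.read_csv(treatments_path, float_precision="round_trip")
    _check_columns(demo, _DEMO_REQUIRED, demographics_path)
    _check_columns(visits, _VISIT_REQUIRED, visits_path)
    _check_columns(treats, _TREAT_REQUIRED, treatments_path)
    if "visit_age" not in visits.columns and "visit_date" not in visits.columns:
        raise SchemaError(f"{visits_path}: need either a visit_age or a visit_date column")
    if (
        "start_age" not in treats.columns or "end_age" not in treats.columns
    ) and ("start_date" not in treats.columns or "end_date" not in treats.columns):
        raise SchemaError(
            f"{treatments_path}: need start_age/end_age or start_date/end_date columns"
        )

    demo = demo.astype({"patient_id": str})
    visits = visits.astype({"patient_id": str})
    treats = treats.astype({"patient_id": str})

    birth = {}
    if "birth_date" in demo.columns:
        birth = {r.patient_id: r.birth_date for r in demo.itertuples()}

    def age_of(row, age_col, date_col, pid, path):
        if age_col in row.index and not _is_missing(row.get(age_col)):
            return float(row[age_col])
        if date_col in row.index and not _is_missing(row.get(date_col)):
            if pid not in birth or _is_missing(birth[pid]):
                raise SchemaError(
                    f"{path}: patient {pid} has {date_col} but no birth_date in demographics"
                )
            return _age_from_dates(row[date_col], birth[pid])
        raise ValidationError(f"{path}: patient {pid} row lacks {age_col}/{date_col}")

    patients: list[PatientRecord] = []
    for row in demo.itertuples(index=False):
        pid = row.patient_id
        p = PatientRecord(
            patient_id=pid,
            sex=str(row.sex).strip().lower(),
            race=str(row.race).strip().lower(),
            smoking=str(row.smoking).strip().lower(),
            family_history=_family_history_from_label(row.family_history, pid),
            onset_age=float(row.onset_age),
        )
        vrows = visits[visits["patient_id"] == pid]
        for i, (_, vr) in enumerate(vrows.iterrows()):
            p.visits.append(
                Visit(
                    visit_age=age_of(vr, "visit_age", "visit_date", pid, visits_path),
                    edss=float(vr["edss"]),
                    snrs=float(vr["snrs"]),
                    t25fw_seconds=_opt_float(vr["t25fw_seconds"]),
                    t25fw_fail=int(vr["t25fw_fail"]),
                    ndh_9hpt_seconds=_opt_float(vr["ndh_9hpt_seconds"]),
                    ndh_9hpt_fail=int(vr["ndh_9hpt_fail"]),
                    exacerbation=int(vr["exacerbation"]),
                    comris_ctd=_opt_float(vr["comris_ctd"]),
                )
            )
        p.visits.sort(key=lambda v: v.visit_age)
        trows = treats[treats["patient_id"] == pid]
        for _, tr in trows.iterrows():
            if "efficacy_class" in tr.index and not _is_missing(tr.get("efficacy_class")):
                cls = str(tr["efficacy_class"]).strip().lower()
            elif "drug_name" in tr.index and not _is_missing(tr.get("drug_name")):
                cls = DRUG_EFFICACY_CLASS.get(
                    str(tr["drug_name"]).strip().lower(), "none_or_unknown"
                )
            else:
                cls = "none_or_unknown"
            p.treatments.append(
                TreatmentEpoch(
                    start_age=age_of(tr, "start_age", "start_date", pid, treatments_path),
                    end_age=age_of(tr, "end_age", "end_date", pid, treatments_path),
                    efficacy_class=cls,
                )
            )
        p.treatments.sort(key=lambda e: e.start_age)
        p.validate()
        patients.append(p)
    return patients


# ---------------------------------------------------------------------------
# writing

def _none_to_nan(x):
    return float("nan") if x is None else x


def write_cohort(patients: list[PatientRecord], out_dir) -> dict[str, Path]:
    """Write a cohort to ``demographics.csv``, ``visits.csv``, ``treatments.csv``.

    The written files round-trip through :func:`read_cohort` field-for-field.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo_rows, visit_rows, treat_rows = [], [], []
    for p in patients:
        demo_rows.append(
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "race": p.race,
                "smoking": p.smoking,
                "family_history": FAMILY_HISTORY_TOKEN[p.family_history],
                "onset_age": p.onset_age,
            }
        )
        for v in p.visits:
            visit_rows.append(
                {
                    "patient_id": p.patient_id,
                    "visit_age": v.visit_age,
                    "edss": v.edss,
                    "snrs": v.snrs,
                    "t25fw_seconds": _none_to_nan(v.t25fw_seconds),
                    "t25fw_fail": v.t25fw_fail,
                    "ndh_9hpt_seconds": _none_to_nan(v.ndh_9hpt_seconds),
                    "ndh_9hpt_fail": v.ndh_9hpt_fail,
                    "exacerbation": v.exacerbation,
                    "comris_ctd": _none_to_nan(v.comris_ctd),
                }
            )
        for e in p.treatments:
            treat_rows.append(
                {
                    "patient_id": p.patient_id,
                    "start_age": e.start_age,
                    "end_age": e.end_age,
                    "efficacy_class": e.efficacy_class,
                }
            )
    paths = {
        "demographics": out / "demographics.csv",
        "visits": out / "visits.csv",
        "treatments": out / "treatments.csv",
    }
    pd.DataFrame(demo_rows, columns=_DEMO_REQUIRED).to_csv(paths["demographics"], index=False)
    pd.DataFrame(
        visit_rows,
        columns=["patient_id", "visit_age"] + _VISIT_REQUIRED[1:],
    ).to_csv(paths["visits"], index=False)
    pd.DataFrame(
        treat_rows, columns=["patient_id", "start_age", "end_age", "efficacy_class"]
    ).to_csv(paths["treatments"], index=False)
    return paths


def copy_patient(p: PatientRecord) -> PatientRecord:
    """Deep copy of a patient record (visits and epochs included)."""
    return replace(
        p,
        visits=[replace(v) for v in p.visits],
        treatments=[replace(e) for e in p.treatments],
    )
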