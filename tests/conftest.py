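import numpy as np
import pytest

from msdss.cohort import PatientRecord, Visit
from msdss.simulate import GeneratorConfig, generate


def make_visit(age, cw_like=30.0, **overrides):
    """A valid visit whose components roughly correspond to ``cw_like``."""
    fields = dict(
        visit_age=age,
        edss=float(np.clip(round(cw_like / 10 * 2) / 2, 0, 10)) or 0.0,
        snrs=int(np.clip(round(100 - cw_like), 0, 100)),
        t25fw_seconds=6.0,
        t25fw_fail=0,
        ndh_9hpt_seconds=20.0,
        ndh_9hpt_fail=0,
        exacerbation=0,
        comris_ctd=10.0,
    )
    if fields["edss"] == 0.5:  # 0.5 is not on the legal grid
        fields["edss"] = 1.0
    fields.update(overrides)
    return Visit(**fields)


def make_patient(patient_id, visit_ages, onset_age=30.0, treatments=(), **overrides):
    fields = dict(
        patient_id=patient_id,
        sex="female",
        race="white",
        smoking="yes",
        family_history=0,
        onset_age=onset_age,
        visits=[make_visit(a) for a in visit_ages],
        treatments=list(treatments),
    )
    fields.update(overrides)
    return PatientRecord(**fields)


@pytest.fixture(scope="session")
def seed1_cohort():
    """The reference synthetic cohort: 201 patients, seed 1."""
    return generate(GeneratorConfig(n_patients=201, seed=1))


@pytest.fixture(scope="session")
def eligibility_fixture():
    """Twelve patients covering the eligibility boundary cases.

    Returns (patients, expected) where expected[i] is whether patient i
    qualifies for slope estimation: >=3 usable visits spanning >=1 y, or
    >=2 spanning >=3 y, after dropping exacerbation visits.
    """
    cases = []

    def add(pid, ages, exac_flags=None, expected=False):
        p = make_patient(pid, ages)
        if exac_flags:
            for idx in exac_flags:
                p.visits[idx].exacerbation = 1
        cases.append((p, expected))

    add("E01", [50.0, 50.4, 50.99], expected=False)  # 3 visits, span 0.99 y
    add("E02", [50.0, 50.4, 51.0], expected=True)  # 3 visits, span exactly 1.0 y
    add("E03", [40.0, 42.99], expected=False)  # 2 visits, span 2.99 y
    add("E04", [40.0, 43.0], expected=True)  # 2 visits, span exactly 3.0 y
    add("E05", [40.0, 43.2], expected=True)  # 2 visits, span 3.2 y
    add("E06", [50.0, 50.2, 50.6], expected=False)  # 3 visits, span 0.6 y
    add("E07", [50.0, 50.5, 51.0, 51.5], expected=True)  # 4 visits, 1.5 y
    # 4 visits but 2 exacerbations leave 2 visits spanning 1.5 y
    add("E08", [50.0, 50.5, 51.0, 51.5], exac_flags=[1, 2], expected=False)
    # 4 visits, 1 exacerbation leaves 3 visits spanning 1.5 y
    add("E09", [50.0, 50.5, 51.0, 51.5], exac_flags=[1], expected=True)
    # exacerbations at the ends shrink the span below 1 y
    add("E10", [50.0, 50.3, 50.8, 52.0], exac_flags=[3], expected=False)
    add("E11", [40.0], expected=False)  # a single visit
    # 2 exacerbations leave 2 visits spanning 3.5 y
    add("E12", [40.0, 40.5, 41.0, 43.5], exac_flags=[1, 2], expected=True)

    patients = [c[0] for c in cases]
    expected = [c[1] for c in cases]
    return patients, expected
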