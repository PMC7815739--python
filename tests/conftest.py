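import numpy as np
import pytest

from dpaclf.cohort import Ascites, Cohort, LabPanel, PatientRecord, Timepoint

ALL_TIMEPOINTS = [Timepoint.ADMISSION, Timepoint.DAY3, Timepoint.WEEK1, Timepoint.WEEK2]


def make_panel(timepoint="admission", **overrides):
    """A mid-severity valid panel; override any field."""
    base = dict(
        timepoint=timepoint,
        tb=15.0,
        cr=1.0,
        pta=35.0,
        inr=1.8,
        na=135.0,
        albumin=3.0,
        he_stage=1,
        wbc=8.0,
        map=85.0,
        pao2_fio2=400.0,
        ascites=Ascites.MILD,
        on_vasopressors=False,
        on_renal_replacement=False,
    )
    base.update(overrides)
    return LabPanel(**base)


def make_record(patient_id="p1", panels=None, **overrides):
    base = dict(
        patient_id=patient_id,
        age=50.0,
        sex="M",
        wgo_type=2,
        etiology_alcohol_only=0,
        hbv=1,
        panels=panels if panels is not None else [make_panel(tp) for tp in ALL_TIMEPOINTS],
        survival_days=90.0,
        death90=0,
        transplant90=0,
        complete=1,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def full_record():
    return make_record()


@pytest.fixture
def toy_cohort():
    """Three patients with panels at all four timepoints, varied outcomes."""
    return Cohort(records=[
        make_record("a", survival_days=2.0, death90=1),
        make_record("b", survival_days=5.0, death90=1),
        make_record("c", survival_days=20.0, death90=1),
    ])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210119)
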