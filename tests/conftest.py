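import datetime as dt

import pytest
from hypothesis import settings

from vaxcov.records import ChildRecord, CovariateSet, DoseEvent
from vaxcov.schedule import default_schedule

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

BIRTH = dt.date(2010, 1, 1)

# Per-dose ages (days since birth) that satisfy every window of the default
# schedule: first doses inside their age windows, later doses at gaps inside
# their interval windows.
APPROPRIATE_AGES = {
    "BCG1": 0,
    "HepB1": 0,
    "HepB2": 30,
    "HepB3": 100,
    "OPV1": 60,
    "OPV2": 90,
    "OPV3": 120,
    "DPT1": 90,
    "DPT2": 120,
    "DPT3": 150,
    "MCV1": 250,
}


def split_label(label):
    antigen = label.rstrip("0123456789")
    return antigen, int(label[len(antigen):])


def make_child(
    child_id="c1",
    ages=APPROPRIATE_AGES,
    birth=BIRTH,
    age_months=17,
    certificate=True,
    card=False,
    covariates=None,
):
    """A ChildRecord whose doses sit at the given ages (days since birth).

    ``ages`` maps dose label -> age in days, or None for an undated
    (missing) entry; omit a label to omit the dose entirely.
    """

    def events():
        return tuple(
            DoseEvent(*split_label(lbl), birth + dt.timedelta(days=a) if a is not None else None)
            for lbl, a in ages.items()
        )

    return ChildRecord(
        child_id=child_id,
        birth_date=birth,
        age_months_at_survey=age_months,
        covariates=covariates,
        certificate=events() if certificate else None,
        card=events() if card else None,
    )


def make_covariates(**overrides):
    base = dict(
        caregiver_relation="mother",
        caregiver_age_band="25-34",
        caregiver_gender="female",
        caregiver_occupation="worker",
        caregiver_education="middle_school",
        knowledge_score=12,
        attitude_score=8,
        family_income_band="3000-5000",
        child_age_band="12-35",
        child_sex="male",
        hukou="guangdong",
        residence="renting_house",
        birth_place="county_hospital_or_above",
    )
    base.update(overrides)
    return CovariateSet(**base)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()
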