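"""Shared fixtures and builders for the test suite."""

import datetime

import pytest

from wsitrend import (
    DAA,
    WARFARIN,
    DrugDictionary,
    DrugSpec,
    LabRecord,
    PrescriptionRecord,
    StudyConfig,
)

D0 = datetime.date(2015, 1, 1)


def d(n: int) -> datetime.date:
    """Day n of the test calendar (day 0 = 2015-01-01)."""
    return D0 + datetime.timedelta(days=n)


def rx(
    patient="P1",
    drug="WARF",
    cls=WARFARIN,
    s=0,
    e=0,
    upd=1.0,
    ud=1.0,
) -> PrescriptionRecord:
    return PrescriptionRecord(patient, drug, cls, d(s), d(e), upd, ud)


def lab(patient="P1", test="PT-INR", day=0, value=2.0) -> LabRecord:
    return LabRecord(patient, test, d(day), value)


@pytest.fixture
def dictionary() -> DrugDictionary:
    """Two-regimen drug dictionary: a 12-week and an 8-week DAA (one withdrawn)."""
    return DrugDictionary(
        [
            DrugSpec("WARF", "warfarin potassium", WARFARIN),
            DrugSpec("DAA-A", "regimen A", DAA, designated_duration_days=84),
            DrugSpec("DAA-B", "regimen B", DAA, designated_duration_days=56, marketed=False),
        ]
    )


@pytest.fixture
def config() -> StudyConfig:
    return StudyConfig(
        study_start=datetime.date(2010, 1, 1),
        study_end=datetime.date(2017, 12, 31),
    )
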