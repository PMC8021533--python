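"""Domain types and tabular I/O.

The pipeline consumes three plain-text inputs:

* ``prescriptions.csv`` — one row per dispensed prescription interval
  (``patient_id,drug_id,start_date,end_date,units_per_day,unit_dosage``),
* ``labs.csv`` — one row per laboratory measurement
  (``patient_id,test_code,date,value``), and
* a YAML study configuration carrying the analysis thresholds plus the drug
  dictionary (each direct-acting antiviral regimen with the designated
  treatment duration from its package insert, and the warfarin products).

All dates are ISO-8601 calendar dates and every prescription interval is a
closed, day-granular interval ``[start_date, end_date]``.  Loading is strict:
a malformed row aborts the load with an error naming the offending row.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "WARFARIN",
    "DAA",
    "LAB_TESTS",
    "DERIVED_SERIES",
    "TableLoadError",
    "ConfigError",
    "PrescriptionRecord",
    "LabRecord",
    "DrugSpec",
    "DrugDictionary",
    "StudyConfig",
    "load_config",
    "write_config",
    "load_prescriptions",
    "write_prescriptions",
    "load_labs",
    "write_labs",
]

# Drug classes
WARFARIN = "warfarin"
DAA = "daa"

#: Laboratory panel: coagulability (PT-INR), liver-function tests, the FIB-4
#: fibrosis index (consumed as a reported value, never derived from its
#: components here), platelet count and hepatitis-C viral load.  All are
#: ratio-scaled and must be strictly positive.
LAB_TESTS = ("PT-INR", "AST", "ALT", "ALP", "GGT", "FIB4", "PLT", "HCV_RNA")

#: Series derived from PT-INR rows during outcome analysis (not loadable).
DERIVED_SERIES = ("WARFARIN_DOSE", "WSI")

PRESCRIPTION_COLUMNS = (
    "patient_id",
    "drug_id",
    "start_date",
    "end_date",
    "units_per_day",
    "unit_dosage",
)
LAB_COLUMNS = ("patient_id", "test_code", "date", "value")


class TableLoadError(ValueError):
    """A delimited input table failed validation; the message names rows."""


class ConfigError(ValueError):
    """The study configuration or drug dictionary is invalid."""


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensed prescription interval.

    ``units_per_day`` times ``unit_dosage`` gives the daily dose in mg/day
    contributed by this record on every day of ``[start_date, end_date]``.
    ``in_study_window`` flags whether the interval intersects the configured
    study period; out-of-window rows are retained but flagged.
    """

    patient_id: str
    drug_id: str
    drug_class: str
    start_date: datetime.date
    end_date: datetime.date
    units_per_day: float
    unit_dosage: float
    in_study_window: bool = True

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"prescription start {self.start_date} after end {self.end_date}"
            )
        for name in ("units_per_day", "unit_dosage"):
            v = getattr(self, name)
            if not (v >= 0.0 and v == v and v != float("inf")):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.drug_class not in (WARFARIN, DAA):
            raise ValueError(f"unknown drug class {self.drug_class!r}")

    @property
    def daily_dose_mg(self) -> float:
        return self.units_per_day * self.unit_dosage

    def covers(self, day: datetime.date) -> bool:
        return self.start_date <= day <= self.end_date


@dataclass(frozen=True)
class LabRecord:
    """One laboratory measurement in the test's native units."""

    patient_id: str
    test_code: str
    date: datetime.date
    value: float

    def __post_init__(self) -> None:
        if self.test_code not in LAB_TESTS:
            raise ValueError(f"unknown test code {self.test_code!r}")
        if not (self.value == self.value and abs(self.value) != float("inf")):
            raise ValueError(f"lab value must be finite, got {self.value!r}")
        if self.value <= 0:
            raise ValueError(
                f"{self.test_code} is ratio-scaled; nonpositive value "
                f"{self.value!r} rejected"
            )


@dataclass(frozen=True)
class DrugSpec:
    """A drug dictionary entry.

    For DAA regimens ``designated_duration_days`` is the treatment duration
    designated in the package insert (e.g. 84 days for a 12-week regimen) and
    drives the completion rule.  ``marketed`` is metadata only: withdrawn
    regimens are processed identically.
    """

    drug_id: str
    name: str
    drug_class: str
    designated_duration_days: int | None = None
    marketed: bool = True

    def __post_init__(self) -> None:
        if self.drug_class not in (WARFARIN, DAA):
            raise ValueError(f"unknown drug class {self.drug_class!r}")
        if self.drug_class == DAA:
            if self.designated_duration_days is None or self.designated_duration_days < 1:
                raise ValueError(
                    f"DAA regimen {self.drug_id!r} needs designated_duration_days >= 1"
                )


class DrugDictionary:
    """Resolves drug identifiers to :class:`DrugSpec` entries."""

    def __init__(self, specs: Iterable[DrugSpec]):
        self._specs: dict[str, DrugSpec] = {}
        for spec in specs:
            if spec.drug_id in self._specs:
                raise ConfigError(f"duplicate drug_id {spec.drug_id!r} in dictionary")
            self._specs[spec.drug_id] = spec
        if not any(s.drug_class == WARFARIN for s in self._specs.values()):
            raise ConfigError("drug dictionary lists no warfarin product")

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._specs

    def __len__(self) -> int:
        return len(self._specs)

    def spec_for(self, drug_id: str) -> DrugSpec:
        try:
            return self._specs[drug_id]
        except KeyError:
            raise KeyError(f"drug_id {drug_id!r} not in dictionary") from None

    def class_of(self, drug_id: str) -> str:
        return self.spec_for(drug_id).drug_class

    @property
    def specs(self) -> tuple[DrugSpec, ...]:
        return tuple(self._specs.values())

    @property
    def daa_specs(self) -> tuple[DrugSpec, ...]:
        return tuple(s for s in self._specs.values() if s.drug_class == DAA)


@dataclass
class StudyConfig:
    """Analysis thresholds, all in whole days.

    Defaults mirror the study design: prescriptions separated by at most a
    30-day gap form one treatment episode; a DAA episode more than 15 days
    shorter than its designated duration counts as non-completion; follow-up
    anchors 12 weeks (84 days) after DAA completion; a lab value is accepted
    for an anchor if recorded on the anchor date or within the previous 30
    days.  ``lab_window`` selects the retrospective lookback (primary) or a
    symmetric +/- ``symmetric_window_days`` alternative.
    ``require_inr_and_dose`` controls whether eligibility demands both a
    PT-INR and a computable warfarin daily dose at every anchor (conjunctive,
    primary) or either one (disjunctive).
    """

    study_start: datetime.date = datetime.date(2010, 1, 1)
    study_end: datetime.date = datetime.date(2017, 12, 31)
    gap_days: int = 30
    completion_allowance_days: int = 15
    followup_days: int = 84
    lookback_days: int = 30
    lab_window: str = "retrospective"
    symmetric_window_days: int = 14
    require_inr_and_dose: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.study_start > self.study_end:
            raise ConfigError("study_start must not be after study_end")
        for name in (
            "gap_days",
            "completion_allowance_days",
            "lookback_days",
            "symmetric_window_days",
        ):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.followup_days < 1:
            raise ConfigError("followup_days must be >= 1")
        if self.lab_window not in ("retrospective", "symmetric"):
            raise ConfigError(
                f"lab_window must be 'retrospective' or 'symmetric', got {self.lab_window!r}"
            )


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def _coerce_date(value, context: str) -> datetime.date:
    if isinstance(value, datetime.datetime):
        return value.date()
    if isinstance(value, datetime.date):
        return value
    if isinstance(value, str):
        try:
            return datetime.date.fromisoformat(value)
        except ValueError:
            pass
    raise ConfigError(f"{context}: expected ISO date, got {value!r}")


def load_config(path: str | Path) -> tuple[StudyConfig, DrugDictionary]:
    """Read the YAML study configuration and drug dictionary."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    study_raw = dict(raw.get("study", {}))
    for key in ("study_start", "study_end"):
        if key in study_raw:
            study_raw[key] = _coerce_date(study_raw[key], key)
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(study_raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown study keys {sorted(unknown)}")
    study = StudyConfig(**study_raw)

    drugs_raw = raw.get("drugs")
    if not drugs_raw:
        raise ConfigError(f"{path}: 'drugs' list is required")
    specs = []
    for i, entry in enumerate(drugs_raw):
        try:
            specs.append(DrugSpec(**entry))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: drugs[{i}]: {exc}") from exc
    return study, DrugDictionary(specs)


def write_config(study: StudyConfig, dictionary: DrugDictionary, path: str | Path) -> None:
    """Write a study configuration + drug dictionary readable by load_config."""
    study_dict = dataclasses.asdict(study)
    study_dict["study_start"] = study.study_start.isoformat()
    study_dict["study_end"] = study.study_end.isoformat()
    drugs = []
    for spec in dictionary.specs:
        d = dataclasses.asdict(spec)
        if spec.drug_class == WARFARIN:
            d.pop("designated_duration_days")
        drugs.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump({"study": study_dict, "drugs": drugs}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Prescription / lab tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableLoadError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != tuple(columns):
        raise TableLoadError(
            f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}"
        )
    return df


def _parse_date(text: str, path, row: int, col: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(text)
    except ValueError:
        raise TableLoadError(f"{path}: row {row}: malformed {col} {text!r}") from None


def _parse_float(text: str, path, row: int, col: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise TableLoadError(f"{path}: row {row}: non-numeric {col} {text!r}") from None


def load_prescriptions(
    path: str | Path,
    dictionary: DrugDictionary,
    study: StudyConfig | None = None,
) -> list[PrescriptionRecord]:
    """Load and validate the prescription table.

    Every ``drug_id`` must resolve in the drug dictionary.  When a
    :class:`StudyConfig` is given, rows whose interval does not intersect the
    closed study window are retained but flagged ``in_study_window=False``.
    Row numbers in errors count data rows from 1 (header excluded).
    """
    df = _read_table(path, PRESCRIPTION_COLUMNS)
    records: list[PrescriptionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.drug_id not in dictionary:
            raise TableLoadError(f"{path}: row {i}: unknown drug_id {row.drug_id!r}")
        start = _parse_date(row.start_date, path, i, "start_date")
        end = _parse_date(row.end_date, path, i, "end_date")
        upd = _parse_float(row.units_per_day, path, i, "units_per_day")
        dose = _parse_float(row.unit_dosage, path, i, "unit_dosage")
        in_window = True
        if study is not None:
            in_window = start <= study.study_end and end >= study.study_start
        try:
            rec = PrescriptionRecord(
                patient_id=str(row.patient_id),
                drug_id=str(row.drug_id),
                drug_class=dictionary.class_of(row.drug_id),
                start_date=start,
                end_date=end,
                units_per_day=upd,
                unit_dosage=dose,
                in_study_window=in_window,
            )
        except ValueError as exc:
            raise TableLoadError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_prescriptions(records: Iterable[PrescriptionRecord], path: str | Path) -> None:
    rows = [
        (
            r.patient_id,
            r.drug_id,
            r.start_date.isoformat(),
            r.end_date.isoformat(),
            repr(r.units_per_day),
            repr(r.unit_dosage),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PRESCRIPTION_COLUMNS)).to_csv(path, index=False)


def load_labs(path: str | Path) -> list[LabRecord]:
    """Load the laboratory table, sorted by (patient_id, test_code, date).

    The sort is stable: same-day repeat measurements keep their file order,
    which later fixes the deterministic same-day tie-break (last wins).
    """
    df = _read_table(path, LAB_COLUMNS)
    records: list[LabRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        date = _parse_date(row.date, path, i, "date")
        value = _parse_float(row.value, path, i, "value")
        try:
            rec = LabRecord(
                patient_id=str(row.patient_id),
                test_code=str(row.test_code),
                date=date,
                value=value,
            )
        except ValueError as exc:
            raise TableLoadError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    records.sort(key=lambda r: (r.patient_id, r.test_code, r.date))
    return records


def write_labs(records: Iterable[LabRecord], path: str | Path) -> None:
    rows = [
        (r.patient_id, r.test_code, r.date.isoformat(), repr(r.value))
        for r in records
    ]
    pd.DataFrame(rows, columns=list(LAB_COLUMNS)).to_csv(path, index=False)
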