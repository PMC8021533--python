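"""Synthetic longitudinal EHR generator with ground-truth eligibility labels.

Emulates the statistical structure the analysis assumes: per-patient
warfarin and DAA prescription streams with benign refill gaps (to exercise
episode merging), irregular laboratory sampling around the three anchors,
and configurable time-point effects per test.  Every patient is assigned
either the *eligible* archetype — a warfarin episode containing a completed
DAA episode, warfarin persisting 12 weeks past completion, and PT-INR plus
dose observable at every anchor — or exactly one cascade-failure archetype:

* ``no_overlap``      — the DAA episode is not contained in any warfarin
                        episode (starts after warfarin ends, or overruns it);
* ``early_daa_stop``  — the DAA episode is more than the allowance shorter
                        than the regimen's designated duration;
* ``warfarin_stop``   — warfarin ends after DAA completion but before T3;
* ``missing_labs``    — no PT-INR within the lookback window of one anchor.

Each failure archetype violates only its targeted criterion, so the selection
cascade's output can be compared against the generated labels exactly.

Laboratory values follow a multiplicative lognormal model: a between-patient
level around the T1 target mean, and T2/T3 values equal to the patient's own
T1 value times the configured effect multiplier times a smaller
within-patient trajectory noise.  Both noises are mean-one lognormals, so the
population mean at each timepoint equals target x multiplier and the
per-patient proportion against T1 is centred on the multiplier — the
quantity the trend summaries estimate.  Default multipliers are calibrated
to the reported cohort trends: PT-INR and WSI dip at treatment completion
and rebound 12 weeks later, the daily dose moves oppositely, AST/ALT fall by
~42.5% and stay low, GGT and FIB-4 fall by ~20% then partially rebound, ALP
and platelets stay flat, and the viral load drops by 95% and stays there.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .io_tables import (
    DAA,
    LAB_TESTS,
    WARFARIN,
    DrugDictionary,
    DrugSpec,
    LabRecord,
    PrescriptionRecord,
    StudyConfig,
    write_config,
    write_labs,
    write_prescriptions,
)

__all__ = [
    "ARCHETYPES",
    "GeneratorConfigError",
    "TestProfile",
    "RegimenSpec",
    "GeneratorConfig",
    "load_generator_config",
    "generate_records",
    "generate",
    "write_dataset",
    "recover_effects",
]

ARCHETYPES = ("no_overlap", "early_daa_stop", "warfarin_stop", "missing_labs")

_DAY = datetime.timedelta(days=1)


class GeneratorConfigError(ValueError):
    """The generator configuration is invalid or infeasible."""


@dataclass(frozen=True)
class TestProfile:
    """Latent-value model for one test.

    ``mean_t1`` is the target population mean at T1 (native units); ``cv``
    the between-patient coefficient of variation of the T1 level;
    ``mult_t2``/``mult_t3`` the effect multipliers applied to the patient's
    T1 value; ``within_cv`` the within-patient trajectory CV at T2/T3.
    """

    mean_t1: float
    cv: float
    mult_t2: float
    mult_t3: float
    within_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("mean_t1", "cv", "mult_t2", "mult_t3", "within_cv"):
            try:
                object.__setattr__(self, name, float(getattr(self, name)))
            except (TypeError, ValueError):
                raise GeneratorConfigError(
                    f"{name} must be numeric, got {getattr(self, name)!r}"
                ) from None
        if self.mean_t1 <= 0 or self.mult_t2 <= 0 or self.mult_t3 <= 0:
            raise GeneratorConfigError("means and multipliers must be > 0")
        if self.cv < 0 or self.within_cv < 0:
            raise GeneratorConfigError("CVs must be >= 0")


@dataclass(frozen=True)
class RegimenSpec:
    drug_id: str
    designated_duration_days: int
    marketed: bool = True


def _default_profiles() -> dict[str, TestProfile]:
    # T1 means are typical for anticoagulated chronic hepatitis C patients;
    # T2/T3 multipliers are ratios of the reported cohort means/trends.
    return {
        "PT-INR": TestProfile(1.96, 0.15, 1.72 / 1.96, 1.0, within_cv=0.05),
        "AST": TestProfile(60.0, 0.10, 0.575, 0.575),
        "ALT": TestProfile(55.0, 0.10, 0.575, 0.575),
        "ALP": TestProfile(300.0, 0.10, 1.0, 1.0),
        "GGT": TestProfile(50.0, 0.10, 0.80, 0.95),
        "FIB4": TestProfile(3.5, 0.10, 0.80, 0.95),
        "PLT": TestProfile(15.0, 0.10, 1.0, 1.0),
        "HCV_RNA": TestProfile(2.0e6, 0.30, 0.05, 0.05, within_cv=0.10),
    }


def _default_dose_profile() -> TestProfile:
    return TestProfile(2.36, 0.25, 2.48 / 2.36, 2.39 / 2.36, within_cv=0.03)


def _default_regimens() -> tuple[RegimenSpec, ...]:
    # 12-, 8- and 24-week interferon-free regimens; one withdrawn from market
    # to exercise the marketed-is-metadata rule.
    return (
        RegimenSpec("LDV-SOF", 84, True),
        RegimenSpec("GLE-PIB", 56, True),
        RegimenSpec("DCV-ASV", 168, False),
    )


def _default_failure_probs() -> dict[str, float]:
    return {a: 0.1 for a in ARCHETYPES}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 200
    p_eligible: float = 0.6
    seed: int = 0
    failure_probs: dict[str, float] = field(default_factory=_default_failure_probs)
    regimens: tuple[RegimenSpec, ...] = field(default_factory=_default_regimens)
    completion_allowance_days: int = 15
    gap_days: int = 30
    followup_days: int = 84
    lookback_days: int = 30
    mean_intervisit_days: int = 14
    p_exact_anchor: float = 0.5
    p_lab_present: float = 0.9
    profiles: dict[str, TestProfile] = field(default_factory=_default_profiles)
    dose_profile: TestProfile = field(default_factory=_default_dose_profile)
    study_start: datetime.date = datetime.date(2010, 1, 1)
    study_end: datetime.date = datetime.date(2017, 12, 31)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise GeneratorConfigError("n_patients must be >= 0")
        probs = [self.p_eligible] + [self.failure_probs.get(a, 0.0) for a in ARCHETYPES]
        if any(p < 0 or p > 1 for p in probs):
            raise GeneratorConfigError("probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise GeneratorConfigError(
                f"p_eligible + failure probabilities must sum to 1, got {sum(probs)}"
            )
        unknown = set(self.failure_probs) - set(ARCHETYPES)
        if unknown:
            raise GeneratorConfigError(f"unknown failure archetypes {sorted(unknown)}")
        if not self.regimens:
            raise GeneratorConfigError("at least one DAA regimen is required")
        for reg in self.regimens:
            if reg.designated_duration_days < self.completion_allowance_days + 28:
                raise GeneratorConfigError(
                    f"regimen {reg.drug_id}: designated duration too short for the "
                    f"allowance; early-termination archetype would be degenerate"
                )
        if self.mean_intervisit_days < 1:
            raise GeneratorConfigError("mean_intervisit_days must be >= 1")
        if not (0.0 <= self.p_exact_anchor <= 1.0 and 0.0 <= self.p_lab_present <= 1.0):
            raise GeneratorConfigError("p_exact_anchor/p_lab_present must lie in [0, 1]")
        span = (self.study_end - self.study_start).days
        max_d = max(r.designated_duration_days for r in self.regimens)
        if span < max_d + self.followup_days + 450:
            raise GeneratorConfigError(
                "study window too short to place warfarin-contained DAA episodes "
                "with 12-week follow-up and lab sampling; lab availability is "
                "impossible for eligible patients"
            )
        missing = set(LAB_TESTS) - set(self.profiles)
        if missing:
            raise GeneratorConfigError(f"profiles missing for tests {sorted(missing)}")

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            study_start=self.study_start,
            study_end=self.study_end,
            gap_days=self.gap_days,
            completion_allowance_days=self.completion_allowance_days,
            followup_days=self.followup_days,
            lookback_days=self.lookback_days,
            random_seed=self.seed,
        )

    def drug_dictionary(self) -> DrugDictionary:
        specs = [DrugSpec("WARF", "warfarin potassium", WARFARIN)]
        for reg in self.regimens:
            specs.append(
                DrugSpec(
                    reg.drug_id,
                    reg.drug_id,
                    DAA,
                    designated_duration_days=reg.designated_duration_days,
                    marketed=reg.marketed,
                )
            )
        return DrugDictionary(specs)


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a generator configuration from YAML (all keys optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise GeneratorConfigError(f"{path}: top level must be a mapping")
    kwargs = dict(raw)
    if "profiles" in kwargs:
        kwargs["profiles"] = {
            test: TestProfile(**entry) for test, entry in kwargs["profiles"].items()
        }
    if "dose_profile" in kwargs:
        kwargs["dose_profile"] = TestProfile(**kwargs["dose_profile"])
    if "regimens" in kwargs:
        kwargs["regimens"] = tuple(RegimenSpec(**entry) for entry in kwargs["regimens"])
    for key in ("study_start", "study_end"):
        if key in kwargs and isinstance(kwargs[key], str):
            kwargs[key] = datetime.date.fromisoformat(kwargs[key])
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(kwargs) - known
    if unknown:
        raise GeneratorConfigError(f"{path}: unknown keys {sorted(unknown)}")
    return GeneratorConfig(**kwargs)


# ---------------------------------------------------------------------------
# Latent values
# ---------------------------------------------------------------------------

def _lognormal_mean_one(rng: np.random.Generator, cv: float) -> float:
    """Draw from a lognormal with mean 1 and coefficient of variation ~cv."""
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _latent_triple(rng: np.random.Generator, profile: TestProfile) -> tuple[float, float, float]:
    v1 = profile.mean_t1 * _lognormal_mean_one(rng, profile.cv)
    v2 = v1 * profile.mult_t2 * _lognormal_mean_one(rng, profile.within_cv)
    v3 = v1 * profile.mult_t3 * _lognormal_mean_one(rng, profile.within_cv)
    return v1, v2, v3


# ---------------------------------------------------------------------------
# Prescription stream construction
# ---------------------------------------------------------------------------

def _chunk_interval(
    rng: np.random.Generator,
    start: datetime.date,
    end: datetime.date,
    gap_days: int,
    protect: frozenset[datetime.date],
) -> list[tuple[datetime.date, datetime.date]]:
    """Cut [start, end] into refill-sized chunks separated by benign gaps.

    Gaps never exceed min(gap_days, 12) days, so merging with the study gap
    rule always reconstructs the original interval; gaps that would uncover a
    protected date (a planned dose-measurement day) are suppressed.
    """
    max_gap = min(gap_days, 12)
    chunks = []
    cursor = start
    while cursor <= end:
        length = int(rng.integers(21, 36))
        chunk_end = min(cursor + (length - 1) * _DAY, end)
        chunks.append((cursor, chunk_end))
        if chunk_end == end:
            break
        gap = int(rng.integers(0, max_gap + 1))
        if gap and any(chunk_end < p <= chunk_end + gap * _DAY for p in protect):
            gap = 0
        nxt = chunk_end + (gap + 1) * _DAY
        if nxt > end:
            nxt = chunk_end + _DAY
        cursor = nxt
    return chunks


def _warfarin_records(
    rng: np.random.Generator,
    patient: str,
    w_start: datetime.date,
    w_end: datetime.date,
    dose_segments: list[tuple[datetime.date, datetime.date, float]],
    gap_days: int,
    protect: frozenset[datetime.date],
) -> list[PrescriptionRecord]:
    records = []
    for seg_start, seg_end, dose in dose_segments:
        seg_start = max(seg_start, w_start)
        seg_end = min(seg_end, w_end)
        if seg_start > seg_end:
            continue
        for s, e in _chunk_interval(rng, seg_start, seg_end, gap_days, protect):
            records.append(
                PrescriptionRecord(patient, "WARF", WARFARIN, s, e, dose, 1.0)
            )
    return records


def _daa_records(
    rng: np.random.Generator,
    patient: str,
    regimen: RegimenSpec,
    start: datetime.date,
    end: datetime.date,
    gap_days: int,
) -> list[PrescriptionRecord]:
    return [
        PrescriptionRecord(patient, regimen.drug_id, DAA, s, e, 1.0, 100.0)
        for s, e in _chunk_interval(rng, start, end, gap_days, frozenset())
    ]


def _mid(a: datetime.date, b: datetime.date) -> datetime.date:
    return a + ((b - a) // 2)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_records(
    config: GeneratorConfig,
) -> tuple[list[PrescriptionRecord], list[LabRecord], pd.DataFrame]:
    """Generate prescription and lab records plus the ground-truth table.

    Deterministic given ``config.seed``.  The ground-truth table has one row
    per patient: ``eligible``, ``archetype``, the regimen, the true anchors,
    and the latent value of every summarized series at every timepoint (the
    values carried by the anchor-window lab records, so for eligible
    patients the pipeline's extracted values match the latents exactly).
    """
    rng = np.random.default_rng(config.seed)
    span = (config.study_end - config.study_start).days
    names = ("eligible",) + ARCHETYPES
    probs = np.array(
        [config.p_eligible] + [config.failure_probs.get(a, 0.0) for a in ARCHETYPES]
    )
    probs = probs / probs.sum()

    prescriptions: list[PrescriptionRecord] = []
    labs: list[LabRecord] = []
    truth_rows: list[dict] = []

    for i in range(config.n_patients):
        patient = f"P{i:05d}"
        archetype = str(rng.choice(names, p=probs))
        regimen = config.regimens[int(rng.integers(len(config.regimens)))]
        designated = regimen.designated_duration_days
        allowance = config.completion_allowance_days

        pre = int(rng.integers(30, 181))  # warfarin lead-in before T1
        lo = pre + 40
        hi = span - (designated + config.followup_days + 220)
        t1 = config.study_start + int(rng.integers(lo, hi)) * _DAY

        if archetype == "early_daa_stop":
            dur = designated - allowance - int(rng.integers(1, 22))
        elif archetype == "no_overlap":
            dur = designated
        else:
            dur = designated - int(rng.integers(0, allowance + 1))

        w_start = t1 - pre * _DAY
        if archetype == "no_overlap" and rng.integers(2) == 0:
            # variant: warfarin ends first, DAA starts strictly after it
            w_end = w_start + int(rng.integers(60, 150)) * _DAY
            t1 = w_end + int(rng.integers(1, 100)) * _DAY
            t2 = t1 + (dur - 1) * _DAY
            t3 = t2 + config.followup_days * _DAY
        else:
            t2 = t1 + (dur - 1) * _DAY
            t3 = t2 + config.followup_days * _DAY
            if archetype == "no_overlap":
                # variant: DAA overruns the warfarin episode end
                w_end = t1 + int(rng.integers(10, min(dur - 1, 60))) * _DAY
            elif archetype == "warfarin_stop":
                w_end = t2 + int(rng.integers(0, config.followup_days)) * _DAY
            else:
                w_end = t3 + int(rng.integers(0, 121)) * _DAY

        anchors = (t1, t2, t3)

        # PT-INR measurement dates per anchor (None = deliberately missing)
        miss_idx = int(rng.integers(3)) if archetype == "missing_labs" else -1
        m_dates: list[datetime.date | None] = []
        for j, a in enumerate(anchors):
            if j == miss_idx:
                m_dates.append(None)
                continue
            if config.lookback_days == 0 or rng.random() < config.p_exact_anchor:
                m_dates.append(a)
            else:
                back = int(rng.integers(1, min(10, config.lookback_days) + 1))
                m_dates.append(a - back * _DAY)

        # Warfarin dose segments switch halfway between measurement dates so
        # the dose on each measurement date is that timepoint's latent dose.
        d1, d2, d3 = _latent_triple(rng, config.dose_profile)
        b12 = _mid(m_dates[0] or t1, m_dates[1] or t2)
        b23 = _mid(m_dates[1] or t2, m_dates[2] or t3)
        segments = [
            (w_start, b12, d1),
            (b12 + _DAY, b23, d2),
            (b23 + _DAY, w_end, d3),
        ]
        protect = frozenset(
            d for d in m_dates if d is not None and w_start <= d <= w_end
        )
        prescriptions.extend(
            _warfarin_records(rng, patient, w_start, w_end, segments, config.gap_days, protect)
        )
        prescriptions.extend(
            _daa_records(rng, patient, regimen, t1, t2, config.gap_days)
        )

        # Latent lab values and anchor-window lab records
        latents = {test: _latent_triple(rng, config.profiles[test]) for test in LAB_TESTS}
        for j, a in enumerate(anchors):
            m = m_dates[j]
            if m is not None:
                labs.append(LabRecord(patient, "PT-INR", m, latents["PT-INR"][j]))
            for test in LAB_TESTS:
                if test == "PT-INR":
                    continue
                if rng.random() < config.p_lab_present:
                    back = int(rng.integers(0, min(10, config.lookback_days) + 1))
                    labs.append(
                        LabRecord(patient, test, a - back * _DAY, latents[test][j])
                    )

        # Scatter visits outside every anchor window (they never shadow the
        # anchor measurements under either lab-window mode)
        lo_day = w_start - 30 * _DAY
        hi_day = t3 + 60 * _DAY
        n_days = (hi_day - lo_day).days
        cap = max(1, min(6, n_days // (4 * config.mean_intervisit_days)))
        for test in LAB_TESTS:
            for _ in range(int(rng.integers(0, cap + 1))):
                d = lo_day + int(rng.integers(0, n_days + 1)) * _DAY
                if any(abs((d - a).days) <= config.lookback_days for a in anchors):
                    continue
                j = int(np.argmin([abs((d - a).days) for a in anchors]))
                value = latents[test][j] * _lognormal_mean_one(rng, 0.05)
                labs.append(LabRecord(patient, test, d, value))

        row = {
            "patient_id": patient,
            "eligible": archetype == "eligible",
            "archetype": archetype,
            "daa_regimen": regimen.drug_id,
            "t1": t1.isoformat(),
            "t2": t2.isoformat(),
            "t3": t3.isoformat(),
            "daa_duration_days": dur,
        }
        for j, tp in enumerate(("T1", "T2", "T3")):
            for test in LAB_TESTS:
                row[f"{test}_{tp}"] = latents[test][j]
            dose = (d1, d2, d3)[j]
            row[f"WARFARIN_DOSE_{tp}"] = dose
            row[f"WSI_{tp}"] = latents["PT-INR"][j] / dose
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    if truth.empty:
        truth = pd.DataFrame(
            columns=["patient_id", "eligible", "archetype", "daa_regimen",
                     "t1", "t2", "t3", "daa_duration_days"]
        )
    return prescriptions, labs, truth


def generate(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tables in the pipeline's CSV schemas plus the ground truth."""
    prescriptions, labs, truth = generate_records(config)
    rx_df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "drug_id": r.drug_id,
                "start_date": r.start_date.isoformat(),
                "end_date": r.end_date.isoformat(),
                "units_per_day": r.units_per_day,
                "unit_dosage": r.unit_dosage,
            }
            for r in prescriptions
        ],
        columns=["patient_id", "drug_id", "start_date", "end_date",
                 "units_per_day", "unit_dosage"],
    )
    labs_df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "test_code": r.test_code,
                "date": r.date.isoformat(),
                "value": r.value,
            }
            for r in labs
        ],
        columns=["patient_id", "test_code", "date", "value"],
    )
    return rx_df, labs_df, truth


def write_dataset(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a ready-to-run dataset directory.

    Emits ``prescriptions.csv``, ``labs.csv``, ``ground_truth.csv`` and a
    ``config.yaml`` holding the matching study configuration and drug
    dictionary.  Byte-identical for identical configurations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prescriptions, labs, truth = generate_records(config)
    paths = {
        "prescriptions": out_dir / "prescriptions.csv",
        "labs": out_dir / "labs.csv",
        "ground_truth": out_dir / "ground_truth.csv",
        "config": out_dir / "config.yaml",
    }
    write_prescriptions(prescriptions, paths["prescriptions"])
    write_labs(labs, paths["labs"])
    truth.to_csv(paths["ground_truth"], index=False)
    write_config(config.study_config(), config.drug_dictionary(), paths["config"])
    return paths


def recover_effects(summary: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Compare recovered mean-of-proportion against the configured multipliers.

    One row per summarized series and post-baseline timepoint:
    ``configured_pct`` (100 x multiplier; for WSI the PT-INR multiplier over
    the dose multiplier), ``recovered_pct`` (the summary's
    mean-of-proportion) and the absolute error in percentage points.
    """
    multipliers: dict[str, tuple[float, float]] = {
        test: (p.mult_t2, p.mult_t3) for test, p in config.profiles.items()
    }
    dp = config.dose_profile
    ip = config.profiles["PT-INR"]
    multipliers["WARFARIN_DOSE"] = (dp.mult_t2, dp.mult_t3)
    multipliers["WSI"] = (ip.mult_t2 / dp.mult_t2, ip.mult_t3 / dp.mult_t3)

    rows = []
    for series, (m2, m3) in multipliers.items():
        for timepoint, mult in (("T2", m2), ("T3", m3)):
            sub = summary[
                (summary["test_code"] == series) & (summary["timepoint"] == timepoint)
            ]
            recovered = float(sub["mean_of_proportion_pct"].iloc[0]) if len(sub) else float("nan")
            rows.append(
                {
                    "test_code": series,
                    "timepoint": timepoint,
                    "configured_pct": 100.0 * mult,
                    "recovered_pct": recovered,
                    "abs_error_pct": abs(recovered - 100.0 * mult),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["test_code", "timepoint", "configured_pct", "recovered_pct", "abs_error_pct"],
    )
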