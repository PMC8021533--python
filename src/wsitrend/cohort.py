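"""Eligibility cascade and attrition ledger.

Patients enter the analysis cohort only if, in order:

0. they were prescribed both warfarin and a DAA at least once during the
   study period;
1. a DAA treatment episode is wholly contained within a single warfarin
   episode (strict interval containment, not mere overlap) — the earliest
   such DAA episode defines the anchors T1 (DAA start), T2 (DAA end) and
   T3 = T2 + 12 weeks;
2. the DAA episode is not more than the allowance (15 days) shorter than the
   regimen's designated treatment duration (completion);
3. warfarin continues through T3 (persistence);
4. a PT-INR measurement and a computable warfarin daily dose exist at every
   anchor (exact date, or via the lookback window).

The attrition ledger records the patients remaining after each step, i.e.
the study's selection flow chart.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .episodes import (
    ContractViolation,
    TreatmentEpisode,
    build_episodes,
    episode_duration_days,
)
from .io_tables import (
    DAA,
    WARFARIN,
    DrugDictionary,
    DrugSpec,
    LabRecord,
    PrescriptionRecord,
    StudyConfig,
)
from .outcomes import daily_dose, select_lab

__all__ = [
    "AnchorSet",
    "LedgerStep",
    "AttritionLedger",
    "find_concurrent",
    "check_completion",
    "check_persistence",
    "check_lab_availability",
    "run_cascade",
    "render_flowchart",
    "cohort_frame",
]

STEP_LABELS = (
    "prescribed both warfarin and a DAA during the study period",
    "DAA episode contained within a warfarin episode",
    "completed the DAA treatment (within allowance)",
    "continued warfarin for 12 weeks after DAA completion",
    "PT-INR and warfarin daily dose available at T1, T2 and T3",
)


@dataclass(frozen=True)
class AnchorSet:
    """Per-patient analysis anchors derived from the qualifying DAA episode."""

    patient_id: str
    daa_episode: TreatmentEpisode
    warfarin_episode: TreatmentEpisode
    t1: datetime.date
    t2: datetime.date
    t3: datetime.date

    def __post_init__(self) -> None:
        if not (self.t1 <= self.t2 < self.t3):
            raise ValueError("anchors must satisfy t1 <= t2 < t3")


@dataclass(frozen=True)
class LedgerStep:
    step_label: str
    patients_remaining: int
    patients_excluded: int


class AttritionLedger:
    """Ordered counts of patients surviving each selection step."""

    def __init__(self) -> None:
        self.steps: list[LedgerStep] = []

    def add(self, label: str, remaining: int, previous: int) -> None:
        self.steps.append(LedgerStep(label, remaining, previous - remaining))

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": i,
                    "step_label": s.step_label,
                    "patients_remaining": s.patients_remaining,
                    "patients_excluded": s.patients_excluded,
                }
                for i, s in enumerate(self.steps)
            ],
            columns=["step", "step_label", "patients_remaining", "patients_excluded"],
        )

    def export(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def find_concurrent(
    warfarin_episodes: Sequence[TreatmentEpisode],
    daa_episodes: Sequence[TreatmentEpisode],
    followup_days: int,
) -> AnchorSet | None:
    """Anchor set from the earliest DAA episode contained in a warfarin episode.

    Containment is strict: ``warfarin.start <= daa.start`` and
    ``daa.end <= warfarin.end``.  Episodes of one patient are disjoint, so at
    most one warfarin episode can contain a given DAA episode.  Returns None
    when no DAA episode is contained (the patient is excluded at step 1).
    """
    for daa in sorted(daa_episodes, key=lambda e: (e.start_date, e.drug_key)):
        for warf in warfarin_episodes:
            if warf.start_date <= daa.start_date and daa.end_date <= warf.end_date:
                t3 = daa.end_date + datetime.timedelta(days=followup_days)
                return AnchorSet(
                    patient_id=daa.patient_id,
                    daa_episode=daa,
                    warfarin_episode=warf,
                    t1=daa.start_date,
                    t2=daa.end_date,
                    t3=t3,
                )
    return None


def check_completion(
    episode: TreatmentEpisode, spec: DrugSpec, allowance_days: int
) -> bool:
    """True iff the episode is not more than ``allowance_days`` shorter than
    the regimen's designated duration (e.g. designated 84, allowance 15:
    durations >= 69 days complete, 68 days and below do not)."""
    if spec.drug_id != episode.drug_key:
        raise ContractViolation(
            f"episode regimen {episode.drug_key!r} does not match spec {spec.drug_id!r}"
        )
    if spec.designated_duration_days is None:
        raise ContractViolation(f"{spec.drug_id!r} has no designated duration")
    return episode_duration_days(episode) >= spec.designated_duration_days - allowance_days


def check_persistence(
    warfarin_episode: TreatmentEpisode, anchor: AnchorSet, followup_days: int
) -> bool:
    """True iff warfarin continues at least until T3 (inclusive boundary)."""
    t3 = anchor.t2 + datetime.timedelta(days=followup_days)
    return warfarin_episode.end_date >= t3


def check_lab_availability(
    labs: Sequence[LabRecord],
    prescriptions: Sequence[PrescriptionRecord],
    anchor: AnchorSet,
    config: StudyConfig,
) -> bool:
    """True iff the anchor triple is analyzable.

    At each of T1, T2, T3 a PT-INR must be selectable (exact date or via the
    configured lab window) and a positive warfarin daily dose computable on
    the PT-INR measurement date.  With ``require_inr_and_dose=False`` either
    one suffices (the dose is then evaluated on the anchor date itself when
    no PT-INR exists).
    """
    ptinr = sorted(
        (r for r in labs if r.patient_id == anchor.patient_id and r.test_code == "PT-INR"),
        key=lambda r: r.date,
    )
    for anchor_date in (anchor.t1, anchor.t2, anchor.t3):
        rec = select_lab(
            ptinr,
            anchor_date,
            config.lookback_days,
            window=config.lab_window,
            symmetric_days=config.symmetric_window_days,
        )
        dose_date = rec.date if rec is not None else anchor_date
        dose = daily_dose(prescriptions, dose_date)
        has_inr = rec is not None
        has_dose = dose is not None and dose > 0
        ok = (has_inr and has_dose) if config.require_inr_and_dose else (has_inr or has_dose)
        if not ok:
            return False
    return True


def run_cascade(
    prescriptions: Iterable[PrescriptionRecord],
    labs: Sequence[LabRecord],
    config: StudyConfig,
    dictionary: DrugDictionary,
) -> tuple[list[AnchorSet], AttritionLedger]:
    """Apply the full eligibility cascade; returns (cohort, attrition ledger).

    Deterministic and invariant to the order of input rows: patients are
    processed in sorted identifier order and every step is a pure predicate.
    """
    prescriptions = list(prescriptions)
    rx_by_patient: dict[str, list[PrescriptionRecord]] = {}
    for rec in prescriptions:
        rx_by_patient.setdefault(rec.patient_id, []).append(rec)
    labs_by_patient: dict[str, list[LabRecord]] = {}
    for lab in labs:
        labs_by_patient.setdefault(lab.patient_id, []).append(lab)

    ledger = AttritionLedger()
    all_patients = sorted(rx_by_patient)

    # Step 0: at least one prescription of each class intersecting the window.
    step0 = [
        p
        for p in all_patients
        if any(r.drug_class == WARFARIN and r.in_study_window for r in rx_by_patient[p])
        and any(r.drug_class == DAA and r.in_study_window for r in rx_by_patient[p])
    ]
    ledger.add(STEP_LABELS[0], len(step0), len(all_patients))

    episodes = build_episodes(
        (r for p in step0 for r in rx_by_patient[p]), config.gap_days
    )

    # Step 1: concurrent exposure (containment) -> anchors.
    anchors: dict[str, AnchorSet] = {}
    for patient in step0:
        eps = episodes.get(patient, [])
        warf = [e for e in eps if e.drug_class == WARFARIN]
        daa = [e for e in eps if e.drug_class == DAA]
        anchor = find_concurrent(warf, daa, config.followup_days)
        if anchor is not None:
            anchors[patient] = anchor
    step1 = [p for p in step0 if p in anchors]
    ledger.add(STEP_LABELS[1], len(step1), len(step0))

    # Step 2: DAA completion within allowance.
    step2 = [
        p
        for p in step1
        if check_completion(
            anchors[p].daa_episode,
            dictionary.spec_for(anchors[p].daa_episode.drug_key),
            config.completion_allowance_days,
        )
    ]
    ledger.add(STEP_LABELS[2], len(step2), len(step1))

    # Step 3: warfarin persistence through T3.
    step3 = [
        p
        for p in step2
        if check_persistence(anchors[p].warfarin_episode, anchors[p], config.followup_days)
    ]
    ledger.add(STEP_LABELS[3], len(step3), len(step2))

    # Step 4: PT-INR + dose available at all anchors.
    step4 = [
        p
        for p in step3
        if check_lab_availability(
            labs_by_patient.get(p, []), rx_by_patient[p], anchors[p], config
        )
    ]
    ledger.add(STEP_LABELS[4], len(step4), len(step3))

    return [anchors[p] for p in step4], ledger


def render_flowchart(ledger: AttritionLedger) -> str:
    """Plain-text attrition flow chart."""
    lines = []
    for i, step in enumerate(ledger):
        lines.append(f"[{step.patients_remaining:>6}] {step.step_label}")
        nxt = ledger.steps[i + 1] if i + 1 < len(ledger) else None
        if nxt is not None:
            lines.append(f"    |-- excluded: {nxt.patients_excluded}")
            lines.append("    v")
    return "\n".join(lines)


def cohort_frame(cohort: Iterable[AnchorSet]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": a.patient_id,
            "daa_regimen": a.daa_episode.drug_key,
            "t1": a.t1.isoformat(),
            "t2": a.t2.isoformat(),
            "t3": a.t3.isoformat(),
            "daa_duration_days": episode_duration_days(a.daa_episode),
            "warfarin_start": a.warfarin_episode.start_date.isoformat(),
            "warfarin_end": a.warfarin_episode.end_date.isoformat(),
        }
        for a in cohort
    ]
    columns = [
        "patient_id",
        "daa_regimen",
        "t1",
        "t2",
        "t3",
        "daa_duration_days",
        "warfarin_start",
        "warfarin_end",
    ]
    return pd.DataFrame(rows, columns=columns)
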