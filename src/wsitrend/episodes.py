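"""Treatment-episode (drug-era) construction.

Consecutive prescription records for one patient and one drug key are merged
into a single continuous treatment episode whenever the next prescription
starts within ``gap_days`` days after the end date of the previous
prescription period (inclusive of day ``gap_days``).  Overlapping records
merge unconditionally.  Warfarin products are pooled into one episode stream
per patient; DAA episodes are keyed by regimen, because the completion rule
compares each episode against its own regimen's designated duration, so two
different regimens never merge.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io_tables import DAA, WARFARIN, PrescriptionRecord

__all__ = [
    "ContractViolation",
    "TreatmentEpisode",
    "episode_key",
    "merge_episodes",
    "episode_duration_days",
    "build_episodes",
    "episodes_frame",
    "export_episodes",
]


class ContractViolation(ValueError):
    """An operation was called outside its contract (mixed patients/keys)."""


def episode_key(record: PrescriptionRecord) -> str:
    """Merge key: the class for warfarin (products pooled), the regimen for DAAs."""
    return WARFARIN if record.drug_class == WARFARIN else record.drug_id


@dataclass(frozen=True)
class TreatmentEpisode:
    """A gap-merged continuous exposure interval for one patient x drug key."""

    patient_id: str
    drug_class: str
    drug_key: str
    start_date: datetime.date
    end_date: datetime.date
    source_records: tuple[PrescriptionRecord, ...]

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("episode start after end")

    @property
    def n_records(self) -> int:
        return len(self.source_records)


def merge_episodes(
    records: Sequence[PrescriptionRecord], gap_days: int
) -> list[TreatmentEpisode]:
    """Merge prescription records of one patient and one drug key into episodes.

    Two consecutive records (by start date) belong to the same episode iff
    ``next.start_date - prev.end_date <= gap_days``; an episode spans the
    minimum start to the maximum end of its members.  Output is sorted by
    start date and episodes are separated by start-to-end gaps > gap_days.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be >= 0")
    if not records:
        return []
    patients = {r.patient_id for r in records}
    keys = {episode_key(r) for r in records}
    if len(patients) > 1 or len(keys) > 1:
        raise ContractViolation(
            f"merge_episodes requires one patient and one drug key, "
            f"got patients={sorted(patients)} keys={sorted(keys)}"
        )
    ordered = sorted(records, key=lambda r: (r.start_date, r.end_date))
    episodes: list[TreatmentEpisode] = []
    bucket = [ordered[0]]
    cur_end = ordered[0].end_date
    for rec in ordered[1:]:
        if (rec.start_date - cur_end).days <= gap_days:
            bucket.append(rec)
            cur_end = max(cur_end, rec.end_date)
        else:
            episodes.append(_finish(bucket))
            bucket = [rec]
            cur_end = rec.end_date
    episodes.append(_finish(bucket))
    return episodes


def _finish(bucket: list[PrescriptionRecord]) -> TreatmentEpisode:
    return TreatmentEpisode(
        patient_id=bucket[0].patient_id,
        drug_class=bucket[0].drug_class,
        drug_key=episode_key(bucket[0]),
        start_date=min(r.start_date for r in bucket),
        end_date=max(r.end_date for r in bucket),
        source_records=tuple(bucket),
    )


def episode_duration_days(episode: TreatmentEpisode) -> int:
    """Inclusive day count of the episode: end - start + 1."""
    return (episode.end_date - episode.start_date).days + 1


def build_episodes(
    records: Iterable[PrescriptionRecord], gap_days: int
) -> dict[str, list[TreatmentEpisode]]:
    """Build episodes for every patient and drug key in ``records``.

    Returns a mapping patient_id -> episodes (all drug keys, sorted by start
    date then drug key).
    """
    grouped: dict[tuple[str, str], list[PrescriptionRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.patient_id, episode_key(rec)), []).append(rec)
    out: dict[str, list[TreatmentEpisode]] = {}
    for (patient, _key), group in grouped.items():
        out.setdefault(patient, []).extend(merge_episodes(group, gap_days))
    for patient in out:
        out[patient].sort(key=lambda e: (e.start_date, e.drug_key))
    return out


def episodes_frame(episodes: Iterable[TreatmentEpisode]) -> pd.DataFrame:
    """Audit table of episodes (one row each)."""
    rows = [
        {
            "patient_id": e.patient_id,
            "drug_key": e.drug_key,
            "drug_class": e.drug_class,
            "start_date": e.start_date.isoformat(),
            "end_date": e.end_date.isoformat(),
            "n_records": e.n_records,
            "duration_days": episode_duration_days(e),
        }
        for e in episodes
    ]
    columns = [
        "patient_id",
        "drug_key",
        "drug_class",
        "start_date",
        "end_date",
        "n_records",
        "duration_days",
    ]
    return pd.DataFrame(rows, columns=columns)


def export_episodes(episodes: Iterable[TreatmentEpisode], path: str | Path) -> None:
    episodes_frame(episodes).to_csv(path, index=False)
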