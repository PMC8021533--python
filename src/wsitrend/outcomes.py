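"""Time-anchored outcome extraction and trend summaries.

For each cohort patient, outcomes are read at three anchors: T1 (start of
DAA treatment), T2 (completion) and T3 (12 weeks after completion).  A lab
value is taken on the exact anchor date when available, otherwise the most
recent measurement within the lookback window.  The warfarin daily dose is
the sum over all warfarin prescription records covering the PT-INR
measurement date of units_per_day x unit_dosage (mg/day), and the warfarin
sensitivity index (WSI) is PT-INR divided by that daily dose — a
dose-adjusted measure of anticoagulation response.

Summaries report, per test and timepoint, the mean and sample standard
deviation of the raw values and of the per-patient proportion relative to T1
(in percent); the T1 proportion is 100% with SD 0 by construction.
"""

from __future__ import annotations

import datetime
import math
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import (
    DERIVED_SERIES,
    LAB_TESTS,
    WARFARIN,
    LabRecord,
    PrescriptionRecord,
    StudyConfig,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import AnchorSet

__all__ = [
    "TIMEPOINTS",
    "SUMMARY_SERIES",
    "DomainError",
    "PipelineContractError",
    "select_lab",
    "daily_dose",
    "compute_wsi",
    "extract_measurements",
    "summarize",
    "plot_trends",
]

TIMEPOINTS = ("T1", "T2", "T3")

#: Order of series in summary tables: the coagulability triple first
#: (PT-INR, warfarin daily dose, WSI), then liver function and viral load.
SUMMARY_SERIES = ("PT-INR",) + DERIVED_SERIES + tuple(
    t for t in LAB_TESTS if t != "PT-INR"
)


class DomainError(ValueError):
    """An outcome computation was asked outside its mathematical domain."""


class PipelineContractError(RuntimeError):
    """A cohort member lacked data the selection cascade guarantees."""


def select_lab(
    records: Sequence[LabRecord],
    anchor_date: datetime.date,
    lookback_days: int,
    window: str = "retrospective",
    symmetric_days: int = 14,
) -> LabRecord | None:
    """Pick the measurement representing ``anchor_date`` from one test's records.

    Retrospective mode (primary): the record on the exact anchor date if one
    exists, else the most recent record in the closed-open window
    ``[anchor - lookback_days, anchor)``; the day-``lookback_days`` record is
    eligible.  Symmetric mode: the record closest to the anchor within
    +/- ``symmetric_days``, preferring the exact date, then the earlier side
    on a distance tie.  Same-day duplicates resolve to the last record in
    file order.  Returns None when the window is empty.
    """
    exact = [r for r in records if r.date == anchor_date]
    if exact:
        return exact[-1]
    if window == "retrospective":
        lo = anchor_date - datetime.timedelta(days=lookback_days)
        eligible = [r for r in records if lo <= r.date < anchor_date]
        if not eligible:
            return None
        best_date = max(r.date for r in eligible)
        return [r for r in eligible if r.date == best_date][-1]
    if window == "symmetric":
        eligible = [
            r for r in records if abs((r.date - anchor_date).days) <= symmetric_days
        ]
        if not eligible:
            return None
        best = min(
            (abs((r.date - anchor_date).days), (r.date - anchor_date).days > 0)
            for r in eligible
        )
        best_date = anchor_date + datetime.timedelta(
            days=best[0] if best[1] else -best[0]
        )
        return [r for r in eligible if r.date == best_date][-1]
    raise ValueError(f"unknown lab window mode {window!r}")


def daily_dose(
    prescriptions: Iterable[PrescriptionRecord], on_date: datetime.date
) -> float | None:
    """Total warfarin daily dose (mg/day) on ``on_date``.

    Sums units_per_day x unit_dosage over all warfarin records covering the
    date; concurrent warfarin products add up into one per-patient dose.
    Returns None when no warfarin record covers the date (missing, not an
    error).
    """
    covering = [
        r
        for r in prescriptions
        if r.drug_class == WARFARIN and r.covers(on_date)
    ]
    if not covering:
        return None
    return float(sum(r.daily_dose_mg for r in covering))


def compute_wsi(pt_inr: float, dose_mg_per_day: float) -> float:
    """Warfarin sensitivity index: PT-INR / daily dose (INR per mg/day)."""
    if dose_mg_per_day <= 0:
        raise DomainError(f"daily dose must be > 0, got {dose_mg_per_day!r}")
    if pt_inr <= 0:
        raise DomainError(f"PT-INR must be > 0, got {pt_inr!r}")
    return pt_inr / dose_mg_per_day


def _group_labs(
    labs: Iterable[LabRecord],
) -> dict[tuple[str, str], list[LabRecord]]:
    grouped: dict[tuple[str, str], list[LabRecord]] = {}
    for rec in labs:
        grouped.setdefault((rec.patient_id, rec.test_code), []).append(rec)
    for group in grouped.values():
        group.sort(key=lambda r: r.date)  # stable: file order kept within a day
    return grouped


def extract_measurements(
    cohort: Sequence["AnchorSet"],
    labs: Iterable[LabRecord],
    prescriptions: Iterable[PrescriptionRecord],
    config: StudyConfig,
) -> pd.DataFrame:
    """One row per cohort patient x timepoint x test.

    PT-INR rows carry the warfarin daily dose evaluated on the PT-INR
    measurement date (which may precede the anchor) and the resulting WSI;
    the cascade's lab-availability step guarantees these are present for
    every cohort member, and a violation raises
    :class:`PipelineContractError`.  Other tests are optional: a missing
    value is recorded as NaN and the patient is retained.
    """
    lab_groups = _group_labs(labs)
    rx_by_patient: dict[str, list[PrescriptionRecord]] = {}
    for rec in prescriptions:
        rx_by_patient.setdefault(rec.patient_id, []).append(rec)

    rows = []
    for anchor in cohort:
        anchors = {"T1": anchor.t1, "T2": anchor.t2, "T3": anchor.t3}
        patient_rx = rx_by_patient.get(anchor.patient_id, [])
        for timepoint, anchor_date in anchors.items():
            for test in LAB_TESTS:
                rec = select_lab(
                    lab_groups.get((anchor.patient_id, test), []),
                    anchor_date,
                    config.lookback_days,
                    window=config.lab_window,
                    symmetric_days=config.symmetric_window_days,
                )
                dose = wsi = math.nan
                if test == "PT-INR":
                    if rec is None:
                        raise PipelineContractError(
                            f"cohort patient {anchor.patient_id} has no PT-INR "
                            f"at {timepoint}; selection cascade contract breached"
                        )
                    d = daily_dose(patient_rx, rec.date)
                    if d is None or d <= 0:
                        raise PipelineContractError(
                            f"cohort patient {anchor.patient_id} has no warfarin "
                            f"dose on PT-INR date {rec.date} at {timepoint}"
                        )
                    dose = d
                    wsi = compute_wsi(rec.value, d)
                rows.append(
                    {
                        "patient_id": anchor.patient_id,
                        "timepoint": timepoint,
                        "test_code": test,
                        "measurement_date": None if rec is None else rec.date,
                        "value": math.nan if rec is None else rec.value,
                        "daily_dose_mg": dose,
                        "wsi": wsi,
                    }
                )
    columns = [
        "patient_id",
        "timepoint",
        "test_code",
        "measurement_date",
        "value",
        "daily_dose_mg",
        "wsi",
    ]
    return pd.DataFrame(rows, columns=columns)


def _series_values(measurements: pd.DataFrame, series: str) -> pd.DataFrame:
    """Patient x timepoint value matrix for one summary series."""
    if series in DERIVED_SERIES:
        sub = measurements[measurements["test_code"] == "PT-INR"]
        col = "daily_dose_mg" if series == "WARFARIN_DOSE" else "wsi"
    else:
        sub = measurements[measurements["test_code"] == series]
        col = "value"
    return sub.pivot_table(
        index="patient_id", columns="timepoint", values=col, aggfunc="last"
    )


def summarize(
    measurements: pd.DataFrame, viral_load_scale: str = "raw"
) -> pd.DataFrame:
    """Per-series, per-timepoint trend summary.

    Columns: ``n``, ``mean``, ``sd`` (sample SD, n-1 denominator; a
    single-patient group reports SD 0 with ``sd_degenerate=True``),
    ``n_prop``, ``mean_of_proportion_pct`` and ``sd_of_proportion_pct``
    (per-patient 100 x value_t / value_T1, over patients with a T1 value;
    the T1 row is 100% +/- 0 by construction).  With
    ``viral_load_scale='log10'`` the viral load is additionally summarized
    on the log10 scale as series ``HCV_RNA_LOG10``; the raw-scale summary
    remains the primary output.
    """
    if viral_load_scale not in ("raw", "log10"):
        raise ValueError(f"viral_load_scale must be 'raw' or 'log10'")
    if measurements.empty:
        return pd.DataFrame(columns=_SUMMARY_COLUMNS)

    rows = []
    series_list = list(SUMMARY_SERIES)
    if viral_load_scale == "log10":
        series_list.append("HCV_RNA_LOG10")
    for series in series_list:
        if series == "HCV_RNA_LOG10":
            wide = np.log10(_series_values(measurements, "HCV_RNA"))
        else:
            wide = _series_values(measurements, series)
        for timepoint in TIMEPOINTS:
            vals = (
                wide[timepoint].dropna()
                if timepoint in wide.columns
                else pd.Series(dtype=float)
            )
            n = int(vals.size)
            mean = float(vals.mean()) if n else math.nan
            sd, degenerate = _sample_sd(vals)
            if timepoint == "T1":
                base = wide["T1"].dropna() if "T1" in wide.columns else pd.Series(dtype=float)
                props = pd.Series(100.0, index=base.index, dtype=float)
            elif "T1" in wide.columns and timepoint in wide.columns:
                pair = wide[["T1", timepoint]].dropna()
                props = 100.0 * pair[timepoint] / pair["T1"]
            else:
                props = pd.Series(dtype=float)
            n_prop = int(props.size)
            mean_prop = float(props.mean()) if n_prop else math.nan
            sd_prop, _ = _sample_sd(props)
            rows.append(
                {
                    "test_code": series,
                    "timepoint": timepoint,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "sd_degenerate": degenerate,
                    "n_prop": n_prop,
                    "mean_of_proportion_pct": mean_prop,
                    "sd_of_proportion_pct": sd_prop,
                }
            )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


_SUMMARY_COLUMNS = [
    "test_code",
    "timepoint",
    "n",
    "mean",
    "sd",
    "sd_degenerate",
    "n_prop",
    "mean_of_proportion_pct",
    "sd_of_proportion_pct",
]


def _sample_sd(vals: pd.Series) -> tuple[float, bool]:
    n = int(vals.size)
    if n == 0:
        return math.nan, False
    if n == 1:
        return 0.0, True
    return float(vals.std(ddof=1)), False


def plot_trends(summary: pd.DataFrame, out_dir) -> list[str]:
    """Write three-point trend plots with error bars.

    One figure for the coagulability triple (mean +/- SD of PT-INR, daily
    dose, WSI) and one for the liver panel and viral load (mean of
    proportion +/- SD).  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    triple = ("PT-INR", "WARFARIN_DOSE", "WSI")
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), constrained_layout=True)
    for ax, series in zip(axes, triple):
        sub = summary[summary["test_code"] == series].set_index("timepoint")
        sub = sub.reindex(list(TIMEPOINTS))
        ax.errorbar(range(3), sub["mean"], yerr=sub["sd"], marker="o", capsize=3)
        ax.set_xticks(range(3), TIMEPOINTS)
        ax.set_title(series)
    fig.suptitle("Mean ± SD at each time point")
    path = out_dir / "trend_coagulability.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    panel = [s for s in SUMMARY_SERIES if s not in triple]
    fig, axes = plt.subplots(2, 4, figsize=(12, 6), constrained_layout=True)
    for ax, series in zip(axes.ravel(), panel):
        sub = summary[summary["test_code"] == series].set_index("timepoint")
        sub = sub.reindex(list(TIMEPOINTS))
        ax.errorbar(
            range(3),
            sub["mean_of_proportion_pct"],
            yerr=sub["sd_of_proportion_pct"],
            marker="o",
            capsize=3,
        )
        ax.set_xticks(range(3), TIMEPOINTS)
        ax.set_title(series)
        ax.axhline(100.0, lw=0.6, ls="--", color="grey")
    for ax in axes.ravel()[len(panel):]:
        ax.set_visible(False)
    fig.suptitle("Mean of proportion vs T1 (%) ± SD")
    path = out_dir / "trend_liver_panel.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))
    return written
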