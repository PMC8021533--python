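"""Time-anchored lab selection, daily dose, WSI and trend summaries."""

import math

import numpy as np
import pytest

from wsitrend import (
    DAA,
    WARFARIN,
    DomainError,
    StudyConfig,
    compute_wsi,
    daily_dose,
    extract_measurements,
    find_concurrent,
    merge_episodes,
    select_lab,
    summarize,
)

from conftest import d, lab, rx


# ---------------------------------------------------------------------------
# select_lab
# ---------------------------------------------------------------------------


def test_exact_anchor_date_preferred():
    records = [lab(day=90, value=1.8), lab(day=100, value=2.2)]
    assert select_lab(records, d(100), 30).value == 2.2


def test_most_recent_within_lookback_wins():
    records = [lab(day=90, value=1.8), lab(day=95, value=2.1)]
    assert select_lab(records, d(100), 30).date == d(95)


@pytest.mark.parametrize("day, found", [(69, False), (70, True)])
def test_lookback_window_boundary_inclusive_at_day_30(day, found):
    records = [lab(day=day)]
    assert (select_lab(records, d(100), 30) is not None) is found


def test_record_after_anchor_ignored_in_retrospective_mode():
    assert select_lab([lab(day=101)], d(100), 30) is None


def test_same_day_tie_takes_last_in_file_order():
    records = [lab(day=95, value=2.0), lab(day=95, value=2.4)]
    assert select_lab(records, d(100), 30).value == 2.4


def test_symmetric_mode_prefers_nearest_then_earlier():
    records = [lab(day=96, value=1.0), lab(day=104, value=2.0)]
    assert select_lab(records, d(100), 30, window="symmetric").value == 1.0
    records = [lab(day=97, value=1.0), lab(day=103, value=2.0)]
    # distance tie: the earlier side wins
    assert select_lab(records, d(100), 30, window="symmetric").value == 1.0
    assert select_lab([lab(day=115)], d(100), 30, window="symmetric") is None


# ---------------------------------------------------------------------------
# daily_dose / WSI
# ---------------------------------------------------------------------------


def test_daily_dose_multiplies_units_by_unit_dosage():
    assert daily_dose([rx(s=0, e=30, upd=4.0, ud=0.5)], d(10)) == 2.0


def test_concurrent_warfarin_products_sum():
    records = [
        rx(drug="WARF-1", s=0, e=30, upd=1.0, ud=1.0),
        rx(drug="WARF-2", s=0, e=30, upd=1.0, ud=0.5),
    ]
    assert daily_dose(records, d(10)) == 1.5


def test_uncovered_date_is_missing_and_daa_records_ignored():
    assert daily_dose([rx(s=0, e=9)], d(10)) is None
    assert daily_dose([rx(drug="DAA-A", cls=DAA, s=0, e=30, upd=1.0, ud=90.0)], d(10)) is None


@pytest.mark.parametrize("inr, dose, wsi", [(2.0, 2.0, 1.0), (1.8, 2.4, 0.75)])
def test_wsi_is_inr_over_dose(inr, dose, wsi):
    assert compute_wsi(inr, dose) == pytest.approx(wsi)


def test_wsi_rejects_nonpositive_dose():
    with pytest.raises(DomainError):
        compute_wsi(2.0, 0.0)


# ---------------------------------------------------------------------------
# extract_measurements
# ---------------------------------------------------------------------------


def anchor_for(warf_records, daa_records, followup=84):
    warf = merge_episodes(warf_records, 30)
    daa = merge_episodes(daa_records, 30)
    return find_concurrent(warf, daa, followup)


def full_panel_fixture():
    warf = [rx(s=0, e=365, upd=2.0, ud=1.0)]
    daa = [rx(drug="DAA-A", cls=DAA, s=30, e=113)]
    labs = []
    for day in (30, 113, 197):
        for test, value in [
            ("PT-INR", 2.0), ("AST", 60.0), ("ALT", 50.0), ("ALP", 300.0),
            ("GGT", 45.0), ("FIB4", 3.0), ("PLT", 15.0), ("HCV_RNA", 1e6),
        ]:
            labs.append(lab(test=test, day=day, value=value))
    return warf, daa, labs


def test_full_panel_yields_24_measurements(config):
    warf, daa, labs = full_panel_fixture()
    anchor = anchor_for(warf, daa)
    m = extract_measurements([anchor], labs, warf + daa, config)
    assert len(m) == 24
    ptinr = m[m.test_code == "PT-INR"]
    assert np.allclose(ptinr.daily_dose_mg, 2.0)
    assert np.allclose(ptinr.wsi, 1.0)


def test_missing_optional_test_recorded_as_nan(config):
    warf, daa, labs = full_panel_fixture()
    labs = [r for r in labs if r.test_code != "AST"]
    anchor = anchor_for(warf, daa)
    m = extract_measurements([anchor], labs, warf + daa, config)
    ast = m[m.test_code == "AST"]
    assert len(ast) == 3 and ast.value.isna().all()


def test_dose_evaluated_on_ptinr_measurement_date(config):
    # dose changes at day 105: T2 PT-INR measured at t2-12=day 101 must use
    # the dose active on day 101, not on the anchor day 113
    warf = [rx(s=0, e=104, upd=2.0, ud=1.0), rx(s=105, e=365, upd=3.0, ud=1.0)]
    daa = [rx(drug="DAA-A", cls=DAA, s=30, e=113)]
    labs = [lab(day=30), lab(day=101), lab(day=197)]
    anchor = anchor_for(warf, daa)
    m = extract_measurements([anchor], labs, warf + daa, config)
    t2 = m[(m.test_code == "PT-INR") & (m.timepoint == "T2")].iloc[0]
    assert t2.measurement_date == d(101)
    assert t2.daily_dose_mg == 2.0


def test_wsi_scale_equivariance(config):
    """Doubling every dose halves every WSI; PT-INR rescales linearly."""
    warf, daa, labs = full_panel_fixture()
    anchor = anchor_for(warf, daa)
    base = extract_measurements([anchor], labs, warf + daa, config)
    doubled_warf = [
        rx(s=0, e=365, upd=r.units_per_day * 2, ud=r.unit_dosage) for r in warf
    ]
    doubled = extract_measurements([anchor], labs, doubled_warf + daa, config)
    ptinr = base.test_code == "PT-INR"
    assert np.allclose(doubled[ptinr].wsi, base[ptinr].wsi / 2)
    scaled_labs = [
        lab(test=r.test_code, day=(r.date - d(0)).days, value=r.value * 3)
        for r in labs
    ]
    scaled = extract_measurements([anchor], scaled_labs, warf + daa, config)
    assert np.allclose(scaled[ptinr].wsi, base[ptinr].wsi * 3)


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------


def three_patient_measurements(config):
    """Three patients with hand-computable PT-INR/dose values at every anchor."""
    values = {  # patient -> (T1, T2, T3) PT-INR
        "P1": (2.0, 1.6, 2.2),
        "P2": (1.5, 1.2, 1.8),
        "P3": (2.5, 2.0, 2.5),
    }
    doses = {"P1": 2.0, "P2": 2.5, "P3": 4.0}
    labs, warf, daa = [], [], []
    for p, (v1, v2, v3) in values.items():
        warf.append(rx(p, s=0, e=365, upd=doses[p], ud=1.0))
        daa.append(rx(p, "DAA-A", DAA, s=30, e=113))
        for day, v in zip((30, 113, 197), (v1, v2, v3)):
            labs.append(lab(p, day=day, value=v))
    anchors = [
        anchor_for(
            [r for r in warf if r.patient_id == p],
            [r for r in daa if r.patient_id == p],
        )
        for p in values
    ]
    return extract_measurements(anchors, labs, warf + daa, config)


def test_summary_matches_hand_computation(config):
    m = three_patient_measurements(config)
    s = summarize(m).set_index(["test_code", "timepoint"])

    # raw means/SDs: PT-INR at T1 = {2.0, 1.5, 2.5}
    row = s.loc[("PT-INR", "T1")]
    assert row["n"] == 3
    assert row["mean"] == pytest.approx(2.0)
    assert row["sd"] == pytest.approx(0.5)  # sample SD of {2.0,1.5,2.5}

    # proportions at T2: 100*{1.6/2.0, 1.2/1.5, 2.0/2.5} = {80, 80, 80}
    row = s.loc[("PT-INR", "T2")]
    assert row["mean_of_proportion_pct"] == pytest.approx(80.0)
    assert row["sd_of_proportion_pct"] == pytest.approx(0.0)

    # T1 proportion is 100 +/- 0 by construction
    row = s.loc[("PT-INR", "T1")]
    assert row["mean_of_proportion_pct"] == pytest.approx(100.0)
    assert row["sd_of_proportion_pct"] == pytest.approx(0.0)

    # WSI at T1: {1.0, 0.6, 0.625}; mean-of-ratio differs from ratio-of-means
    row = s.loc[("WSI", "T1")]
    expected = np.array([2.0 / 2.0, 1.5 / 2.5, 2.5 / 4.0])
    assert row["mean"] == pytest.approx(expected.mean())
    assert row["sd"] == pytest.approx(expected.std(ddof=1))
    assert row["mean"] != pytest.approx(2.0 / (2.0 + 2.5 + 4.0) * 3)


def test_mean_and_sample_sd_two_values(config):
    m = three_patient_measurements(config)
    m = m[m.patient_id.isin(["P1", "P2"])]
    s = summarize(m).set_index(["test_code", "timepoint"])
    row = s.loc[("PT-INR", "T1")]  # values {2.0, 1.5}
    assert row["mean"] == pytest.approx(1.75)
    assert row["sd"] == pytest.approx(np.std([2.0, 1.5], ddof=1))


def test_single_patient_sd_degenerate(config):
    m = three_patient_measurements(config)
    s = summarize(m[m.patient_id == "P1"]).set_index(["test_code", "timepoint"])
    row = s.loc[("PT-INR", "T1")]
    assert row["n"] == 1 and row["sd"] == 0.0 and bool(row["sd_degenerate"])


def test_mean_of_ratios_differs_from_ratio_of_means(config):
    """On an asymmetric fixture mean(WSI) != mean(PT-INR)/mean(dose)."""
    m = three_patient_measurements(config)
    s = summarize(m).set_index(["test_code", "timepoint"])
    mean_wsi = s.loc[("WSI", "T1"), "mean"]
    mean_inr = s.loc[("PT-INR", "T1"), "mean"]
    mean_dose = s.loc[("WARFARIN_DOSE", "T1"), "mean"]
    assert mean_wsi == pytest.approx((1.0 + 0.6 + 0.625) / 3)
    assert mean_inr / mean_dose == pytest.approx(2.0 / (8.5 / 3))
    assert abs(mean_wsi - mean_inr / mean_dose) > 0.02


def test_summary_invariant_to_patient_order(config):
    m = three_patient_measurements(config)
    reordered = m.sort_values(["timepoint", "patient_id"], ascending=False)
    a = summarize(m)
    b = summarize(reordered)
    for col in ("n", "mean", "sd", "mean_of_proportion_pct"):
        np.testing.assert_allclose(
            a[col].to_numpy(float), b[col].to_numpy(float), equal_nan=True
        )


def test_viral_load_log_scale_option(config):
    m = three_patient_measurements(config)
    s = summarize(m, viral_load_scale="log10")
    assert "HCV_RNA_LOG10" in set(s.test_code)
    assert "HCV_RNA" in set(s.test_code)  # raw scale remains primary
    with pytest.raises(ValueError):
        summarize(m, viral_load_scale="ln")


def test_empty_measurements_give_empty_summary(config):
    import pandas as pd

    assert summarize(pd.DataFrame()).empty
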