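"""Eligibility cascade: anchors, the four exclusion rules, the ledger."""

import dataclasses
import random

import pytest

from wsitrend import (
    DAA,
    WARFARIN,
    ContractViolation,
    DrugSpec,
    GeneratorConfig,
    StudyConfig,
    check_completion,
    check_lab_availability,
    check_persistence,
    find_concurrent,
    generate_records,
    merge_episodes,
    run_cascade,
)

from conftest import d, lab, rx


def warf_episode(s, e, patient="P1"):
    (episode,) = merge_episodes([rx(patient, "WARF", WARFARIN, s, e)], 30)
    return episode


def daa_episode(s, e, patient="P1", drug="DAA-A"):
    (episode,) = merge_episodes([rx(patient, drug, DAA, s, e)], 30)
    return episode


# ---------------------------------------------------------------------------
# find_concurrent
# ---------------------------------------------------------------------------


def test_contained_daa_defines_anchor_dates():
    anchor = find_concurrent([warf_episode(0, 365)], [daa_episode(30, 113)], 84)
    assert (anchor.t1, anchor.t2, anchor.t3) == (d(30), d(113), d(197))


def test_daa_overrunning_warfarin_is_excluded():
    assert find_concurrent([warf_episode(0, 100)], [daa_episode(30, 113)], 84) is None


def test_daa_without_warfarin_is_excluded():
    assert find_concurrent([], [daa_episode(30, 113)], 84) is None


def test_earliest_contained_daa_episode_wins():
    anchors = find_concurrent(
        [warf_episode(0, 600)],
        [daa_episode(200, 283, drug="DAA-B"), daa_episode(30, 113)],
        84,
    )
    assert anchors.t1 == d(30)


def test_uncontained_early_episode_skipped_for_contained_later_one():
    anchor = find_concurrent(
        [warf_episode(100, 600)],
        [daa_episode(30, 113), daa_episode(200, 283, drug="DAA-B")],
        84,
    )
    assert anchor.t1 == d(200)


# ---------------------------------------------------------------------------
# completion / persistence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "designated, duration, expected",
    [
        (84, 69, True),   # minimum acceptable duration under the 15-day allowance
        (84, 68, False),
        (84, 84, True),
        (56, 41, True),
        (56, 40, False),
    ],
)
def test_completion_threshold(designated, duration, expected):
    spec = DrugSpec("DAA-A", "a", DAA, designated_duration_days=designated)
    episode = daa_episode(0, duration - 1)
    assert check_completion(episode, spec, 15) is expected


def test_completion_regimen_mismatch_rejected():
    spec = DrugSpec("DAA-B", "b", DAA, designated_duration_days=56)
    with pytest.raises(ContractViolation):
        check_completion(daa_episode(0, 83), spec, 15)


@pytest.mark.parametrize("warf_end, expected", [(197, True), (196, False), (397, True)])
def test_persistence_boundary_at_t3(warf_end, expected):
    anchor = find_concurrent([warf_episode(0, warf_end)], [daa_episode(30, 113)], 84)
    assert check_persistence(warf_episode(0, warf_end), anchor, 84) is expected


# ---------------------------------------------------------------------------
# lab availability
# ---------------------------------------------------------------------------


@pytest.fixture
def anchor():
    return find_concurrent([warf_episode(0, 365)], [daa_episode(30, 113)], 84)


def test_exact_date_labs_with_active_warfarin_pass(anchor, config):
    warf = [rx(s=0, e=365)]
    labs = [lab(day=n) for n in (30, 113, 197)]
    assert check_lab_availability(labs, warf, anchor, config)


def test_ptinr_31_days_before_t3_fails_lookback(anchor, config):
    warf = [rx(s=0, e=365)]
    labs = [lab(day=30), lab(day=113), lab(day=197 - 31)]
    assert not check_lab_availability(labs, warf, anchor, config)


def test_ptinr_30_days_before_t3_passes_lookback(anchor, config):
    warf = [rx(s=0, e=365)]
    labs = [lab(day=30), lab(day=113), lab(day=197 - 30)]
    assert check_lab_availability(labs, warf, anchor, config)


def test_no_warfarin_dose_on_measurement_date_fails(anchor, config):
    # warfarin prescriptions have a hole covering the T2 measurement date
    warf = [rx(s=0, e=100), rx(s=120, e=365)]
    labs = [lab(day=30), lab(day=110), lab(day=197)]
    assert not check_lab_availability(labs, warf, anchor, config)


def test_disjunctive_mode_accepts_dose_without_ptinr(anchor, config):
    warf = [rx(s=0, e=365)]
    labs = [lab(day=30), lab(day=113)]  # nothing near T3
    assert not check_lab_availability(labs, warf, anchor, config)
    relaxed = dataclasses.replace(config, require_inr_and_dose=False)
    assert check_lab_availability(labs, warf, anchor, relaxed)


def test_symmetric_window_accepts_post_anchor_ptinr(anchor, config):
    warf = [rx(s=0, e=365)]
    labs = [lab(day=30), lab(day=113), lab(day=197 + 10)]
    assert not check_lab_availability(labs, warf, anchor, config)
    symmetric = dataclasses.replace(config, lab_window="symmetric")
    assert check_lab_availability(labs, warf, anchor, symmetric)


# ---------------------------------------------------------------------------
# run_cascade
# ---------------------------------------------------------------------------


def test_empty_input_gives_empty_cohort_and_zero_ledger(config, dictionary):
    cohort, ledger = run_cascade([], [], config, dictionary)
    assert cohort == []
    assert [s.patients_remaining for s in ledger] == [0, 0, 0, 0, 0]


def test_everyone_failing_completion_shows_in_ledger(config, dictionary):
    rx_rows, labs = [], []
    for i in range(5):
        p = f"P{i}"
        rx_rows += [rx(p, "WARF", WARFARIN, 0, 400), rx(p, "DAA-A", DAA, 30, 70)]
        labs += [lab(p, day=n) for n in (30, 70, 154)]
    cohort, ledger = run_cascade(rx_rows, labs, config, dictionary)
    assert cohort == []
    remaining = [s.patients_remaining for s in ledger]
    assert remaining == [5, 5, 0, 0, 0]
    assert ledger.steps[2].patients_excluded == 5


def test_cascade_is_patient_order_invariant(config, dictionary):
    cfg = GeneratorConfig(n_patients=40, seed=11)
    rx_rows, labs, _ = generate_records(cfg)
    study, dd = cfg.study_config(), cfg.drug_dictionary()
    cohort_a, ledger_a = run_cascade(rx_rows, labs, study, dd)
    shuffled_rx, shuffled_labs = rx_rows[:], labs[:]
    random.Random(3).shuffle(shuffled_rx)
    random.Random(4).shuffle(shuffled_labs)
    # run_cascade expects labs grouped deterministically; it sorts internally
    cohort_b, ledger_b = run_cascade(shuffled_rx, shuffled_labs, study, dd)
    assert [a.patient_id for a in cohort_a] == [a.patient_id for a in cohort_b]
    assert list(ledger_a) == list(ledger_b)


def test_ledger_monotone_and_first_step_counts_dual_prescribing(config, dictionary):
    cfg = GeneratorConfig(n_patients=60, seed=5)
    rx_rows, labs, truth = generate_records(cfg)
    cohort, ledger = run_cascade(rx_rows, labs, cfg.study_config(), cfg.drug_dictionary())
    remaining = [s.patients_remaining for s in ledger]
    assert remaining == sorted(remaining, reverse=True)
    both = {r.patient_id for r in rx_rows if r.drug_class == WARFARIN} & {
        r.patient_id for r in rx_rows if r.drug_class == DAA
    }
    assert remaining[0] == len(both)
    # excluded-at-step-k bookkeeping
    for prev, nxt in zip(ledger.steps, ledger.steps[1:]):
        assert nxt.patients_excluded == prev.patients_remaining - nxt.patients_remaining


def test_relaxing_thresholds_never_shrinks_cohort():
    cfg = GeneratorConfig(n_patients=80, seed=21)
    rx_rows, labs, _ = generate_records(cfg)
    study, dd = cfg.study_config(), cfg.drug_dictionary()
    base, _ = run_cascade(rx_rows, labs, study, dd)
    base_ids = {a.patient_id for a in base}
    for relax in (
        {"gap_days": study.gap_days + 30},
        {"completion_allowance_days": study.completion_allowance_days + 30},
        {"lookback_days": study.lookback_days + 30},
    ):
        relaxed, _ = run_cascade(rx_rows, labs, dataclasses.replace(study, **relax), dd)
        assert base_ids <= {a.patient_id for a in relaxed}
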