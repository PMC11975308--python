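"""Horizon labeling, pair selection, case-control matching and nested
splits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from progrisk.cohort_prep import (
    HorizonConfig,
    PairSample,
    PairSet,
    ScanRecord,
    build_pairs,
    label_for_horizon,
    make_nested_splits,
    match_case_control,
    select_training_scans,
)


def _scan(t, event=None, follow_up=9.0, sid="S0", **kw):
    base = dict(
        subject_id=sid, scan_time_years=t, payload_ref=f"{sid}/{t}", grade=1,
        age=60, sex=0, ethnicity="A", bmi=28.0, event_time_years=event,
        follow_up_years=follow_up,
    )
    base.update(kw)
    return ScanRecord(**base)


def test_horizon_label_rules():
    scan = _scan(1.0, event=3.5)
    assert label_for_horizon(scan, 2.0) == 0  # event outside window
    assert label_for_horizon(scan, 4.0) == 1  # event inside window
    assert label_for_horizon(_scan(1.0, event=3.0), 2.0) == 1  # boundary inclusive
    censored = _scan(3.0, follow_up=4.0)
    assert label_for_horizon(censored, 4.0) is None  # insufficient follow-up
    assert label_for_horizon(censored, 1.0) == 0
    assert label_for_horizon(censored, HorizonConfig(1.0)) == 0


def test_case_followup_scan_is_latest_within_pre_event_window():
    event = 3.5
    scans = [_scan(t, event=event) for t in (0.0, 1.0, 2.0, 3.0)]
    pair = select_training_scans(scans, 2.0)
    # eligibility window: 1-4 years before the event; t=3 is too close
    assert pair.scan2.scan_time_years == 2.0
    assert (pair.y1, pair.y2) == (0, 1)
    assert pair.set_id is PairSet.SET1_PROGRESSION


def test_single_scan_subjects_yield_degenerate_pairs():
    only_baseline = [_scan(0.0, follow_up=0.0, event=0.5)]
    pair = select_training_scans(only_baseline, 1.0)
    assert pair.set_id is PairSet.SINGLE
    assert pair.scan2 is None and pair.y1 == 1
    control = [_scan(0.0, follow_up=9.0)]
    pair = select_training_scans(control, 2.0)
    assert pair.set_id is PairSet.SINGLE and pair.y1 == 0


def test_control_followup_scan_needs_defined_label():
    scans = [_scan(t, follow_up=9.0) for t in (0.0, 3.0, 5.0, 9.0)]
    pair = select_training_scans(scans, 4.0)
    # the year-9 scan has no 4-year follow-up left; year-5 has exactly 4
    assert pair.scan2.scan_time_years == 5.0
    assert pair.set_id is PairSet.SET2_STABLE_NEG


def test_subject_without_baseline_is_skipped():
    assert select_training_scans([_scan(1.0)], 2.0) is None


def test_pair_sample_rejects_label_regression():
    with pytest.raises(ValueError):
        PairSample(_scan(0.0, event=1.0), _scan(2.0, event=1.0), 1, 0, 1.0,
                   PairSet.SET1_PROGRESSION)


def _manifest(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "scan_time_years", "payload_path", "grade",
                 "age", "sex", "ethnicity", "bmi", "event_time_years"],
    )


def _subject_row(sid, age, sex, eth, bmi, event):
    return [sid, 0.0, f"{sid}/0", 1, age, sex, eth, bmi, event]


def test_matching_respects_bmi_tolerance_anchored_on_case():
    m = _manifest([
        _subject_row("case", 60, 1, "A", 30.0, 5.0),
        _subject_row("k1", 60, 1, "A", 32.9, np.nan),
        _subject_row("k2", 60, 1, "A", 34.0, np.nan),  # >10% of case BMI
    ])
    res = match_case_control(m)
    assert res.pairs == (("case", "k1"),)
    assert res.unmatched_controls == ("k2",)


def test_matching_requires_identical_age_sex_ethnicity():
    m = _manifest([
        _subject_row("case", 60, 1, "A", 30.0, 5.0),
        _subject_row("k_age", 61, 1, "A", 30.0, np.nan),
        _subject_row("k_sex", 60, 0, "A", 30.0, np.nan),
        _subject_row("k_eth", 60, 1, "B", 30.0, np.nan),
    ])
    assert match_case_control(m).pairs == ()
    # widening the age tolerance admits the one-year-off control
    assert match_case_control(m, age_tol=1).pairs == (("case", "k_age"),)


def test_matching_handles_degenerate_cohorts():
    assert match_case_control(_manifest([])).pairs == ()
    only_cases = _manifest([_subject_row("c", 60, 1, "A", 30.0, 5.0)])
    res = match_case_control(only_cases)
    assert res.pairs == () and res.unmatched_cases == ("c",)


def _brute_force_max_matching(n_case, n_ctl, compatible):
    best = 0
    if n_case <= n_ctl:
        for perm in itertools.permutations(range(n_ctl), n_case):
            best = max(best, sum(compatible(i, j) for i, j in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(n_case), n_ctl):
            best = max(best, sum(compatible(i, j) for j, i in enumerate(perm)))
    return best


def test_matching_is_maximum_cardinality_not_greedy():
    # case c1 matches both controls, c2 only k1: a greedy pass assigning
    # c1 -> k1 strands c2; the maximum matching pairs both cases
    m = _manifest([
        _subject_row("c1", 60, 1, "A", 30.0, 5.0),
        _subject_row("c2", 60, 1, "A", 27.5, 5.0),  # 10% window excludes 33.0
        _subject_row("k1", 60, 1, "A", 29.0, np.nan),
        _subject_row("k2", 60, 1, "A", 33.0, np.nan),
    ])
    res = match_case_control(m)
    assert len(res.pairs) == 2
    assert dict(res.pairs) == {"c1": "k2", "c2": "k1"}


def test_matching_cardinality_agrees_with_exhaustive_oracle():
    rng = np.random.default_rng(4)
    for trial in range(20):
        n_case, n_ctl = rng.integers(1, 5), rng.integers(1, 5)
        rows = []
        for i in range(n_case):
            rows.append(_subject_row(f"c{i}", int(rng.integers(60, 63)),
                                     int(rng.integers(0, 2)), "A",
                                     float(rng.uniform(25, 32)), 5.0))
        for j in range(n_ctl):
            rows.append(_subject_row(f"k{j}", int(rng.integers(60, 63)),
                                     int(rng.integers(0, 2)), "A",
                                     float(rng.uniform(25, 32)), np.nan))
        m = _manifest(rows)
        res = match_case_control(m)

        def compatible(i, j):
            ci = m[m.subject_id == f"c{i}"].iloc[0]
            kj = m[m.subject_id == f"k{j}"].iloc[0]
            return (ci.age == kj.age and ci.sex == kj.sex
                    and abs(ci.bmi - kj.bmi) <= 0.10 * ci.bmi)

        assert len(res.pairs) == _brute_force_max_matching(
            int(n_case), int(n_ctl), compatible
        )


def test_matched_pairs_satisfy_all_constraints_exhaustively(small_cohort):
    m = small_cohort.manifest
    res = match_case_control(m)
    baseline = m[m.scan_time_years == 0].set_index("subject_id")
    assert len(res.pairs) > 0
    used = [s for pair in res.pairs for s in pair]
    assert len(used) == len(set(used))  # one-to-one
    for case_id, ctl_id in res.pairs:
        case, ctl = baseline.loc[case_id], baseline.loc[ctl_id]
        assert not np.isnan(case.event_time_years)
        assert np.isnan(ctl.event_time_years)
        assert case.age == ctl.age and case.sex == ctl.sex
        assert case.ethnicity == ctl.ethnicity
        assert abs(case.bmi - ctl.bmi) <= 0.10 * case.bmi


def test_stable_positive_group_is_empty_at_one_year_horizon(small_cohort, matched_ids):
    pairs = build_pairs(small_cohort.manifest, [1.0], matched_ids)[1.0]
    sets = {p.set_id for p in pairs}
    assert PairSet.SET3_STABLE_POS not in sets
    assert PairSet.SET1_PROGRESSION in sets  # progression mass exists at 1y
    for p in pairs:
        if p.scan2 is not None:
            assert not (p.y1 == 1 and p.y2 == 0)


def test_nested_splits_partition_and_balance():
    ids = [f"S{i}" for i in range(42)]
    is_case = [i % 2 == 0 for i in range(42)]
    plan = make_nested_splits(ids, is_case, seed=3)
    df = plan.frame
    counts = df.groupby("outer_fold").size()
    assert (counts == 6).all()  # 42 subjects into 7 folds
    per_stratum = df.merge(
        pd.DataFrame({"subject_id": ids, "case": is_case}), on="subject_id"
    ).groupby(["outer_fold", "case"]).size()
    assert (per_stratum == 3).all()

    assignments = list(plan.assignments())
    assert len(assignments) == 42
    all_ids = set(ids)
    outer_tests = {o: set(t) for o, _, _, _, t in assignments}
    assert set().union(*outer_tests.values()) == all_ids
    for o1, o2 in itertools.combinations(outer_tests, 2):
        assert not outer_tests[o1] & outer_tests[o2]
    for _, _, train, val, test in assignments:
        train, val, test = set(train), set(val), set(test)
        assert not (train & val or train & test or val & test)
        assert train | val | test == all_ids


def test_nested_splits_deterministic_and_validated():
    ids = [f"S{i}" for i in range(30)]
    is_case = [i < 15 for i in range(30)]
    a = make_nested_splits(ids, is_case, seed=5).frame
    b = make_nested_splits(ids, is_case, seed=5).frame
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError):
        make_nested_splits(["a", "b"], [True, False], outer=7)
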