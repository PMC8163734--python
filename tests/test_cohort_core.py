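"""Cohort derivation: definitions, filters, derived variables, descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from albumin_mr.cohort_core import (
    CohortConfig,
    PhenotypeParseError,
    _derive_outcomes_vectorized,
    apply_eligibility_filter,
    classify_hypoalbuminemia,
    compute_ckd_epi_egfr,
    compute_delta_bp,
    derive_cohort,
    detect_hypertension,
    read_phenotype_table,
    summarize_baseline,
)
from conftest import make_visits


# ---------------------------------------------------------------------------
# reading

def test_roundtrip_parses_all_records(small_cohort):
    baseline, visits = read_phenotype_table(small_cohort["dir"] / "phenotype.tsv")
    n = small_cohort["config"].n_subjects
    assert len(baseline) == n
    assert len(visits) == n * len(small_cohort["config"].visit_months())


def test_duplicate_subject_rejected(tmp_path):
    df = pd.concat([make_visits([(0, 120, 80, 0)])] * 2)
    path = tmp_path / "dup.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(PhenotypeParseError, match="duplicated"):
        read_phenotype_table(path)


def test_non_numeric_bp_cites_row_and_column(tmp_path):
    df = make_visits([(0, 120, 80, 0), (24, 130, 82, 0)])
    df.loc[1, "sbp"] = "abc"
    path = tmp_path / "bad.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(PhenotypeParseError, match="'sbp' at row 1"):
        read_phenotype_table(path)


def test_out_of_range_bp_rejected(tmp_path):
    df = make_visits([(0, 120, 45, 0)])
    path = tmp_path / "low.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(PhenotypeParseError, match="dbp"):
        read_phenotype_table(path)


def test_schema_mapping(tmp_path):
    df = make_visits([(0, 120, 80, 0), (24, 125, 82, 0)]).rename(
        columns={"sbp": "SYS_BP"}
    )
    path = tmp_path / "schema.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(PhenotypeParseError):
        read_phenotype_table(path)
    baseline, visits = read_phenotype_table(path, schema={"sbp": "SYS_BP"})
    assert visits["sbp"].iloc[1] == 125


# ---------------------------------------------------------------------------
# eligibility filter

def _ten_subjects():
    base = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(10)],
            "albumin": [4.2] * 10,
            "age": [50.0] * 10,
            "sex": ["male"] * 10,
            "smoker": [0] * 10,
            "sbp": [120.0] * 10,
            "dbp": [80.0] * 10,
            "prevalent_htn": [0] * 10,
            "diabetes": [0] * 10,
            "ckd": [0] * 10,
            "cvd": [0] * 10,
            "malignancy": [0] * 10,
        }
    )
    return base


def test_filter_counts_and_log():
    base = _ten_subjects()
    base.loc[[0, 1], "prevalent_htn"] = 1
    base.loc[2, "albumin"] = np.nan
    kept, log = apply_eligibility_filter(base)
    assert len(kept) == 7 and len(log) == 3
    reasons = {e["subject_id"]: e["reason"] for e in log}
    assert reasons["s0"] == "hypertension"
    assert reasons["s2"] == "missing data"


def test_filter_first_matching_reason():
    base = _ten_subjects()
    base.loc[3, ["diabetes", "ckd"]] = 1
    _, log = apply_eligibility_filter(base)
    assert log == [{"subject_id": "s3", "reason": "diabetes mellitus"}]


def test_filter_identity_and_idempotence():
    base = _ten_subjects()
    kept, log = apply_eligibility_filter(base)
    pd.testing.assert_frame_equal(kept, base)
    assert log == []
    base.loc[0, "cvd"] = 1
    kept1, _ = apply_eligibility_filter(base)
    kept2, log2 = apply_eligibility_filter(kept1)
    pd.testing.assert_frame_equal(kept1, kept2)
    assert log2 == []


def test_filter_catches_high_baseline_bp():
    base = _ten_subjects()
    base.loc[4, "sbp"] = 142.0
    _, log = apply_eligibility_filter(base)
    assert log[0]["reason"] == "hypertension"


# ---------------------------------------------------------------------------
# definitions

def test_hypoalbuminemia_boundary():
    assert classify_hypoalbuminemia(3.9) is True
    assert classify_hypoalbuminemia(4.0) is True   # cutoff inclusive
    assert classify_hypoalbuminemia(4.01) is False
    with pytest.raises(ValueError):
        classify_hypoalbuminemia(0.0)


def test_detect_hypertension_bp_threshold():
    ev, month = detect_hypertension(
        make_visits([(0, 120, 76, 0), (24, 138, 88, 0), (48, 142, 80, 0)])
    )
    assert ev and month == 48


def test_detect_hypertension_medication_counts():
    ev, month = detect_hypertension(make_visits([(0, 118, 74, 0), (24, 120, 76, 1)]))
    assert ev and month == 24


def test_detect_hypertension_censoring_below_threshold():
    ev, month = detect_hypertension(
        make_visits([(0, 130, 82, 0), (24, 139, 89, 0), (48, 139, 89, 0)])
    )
    assert not ev and month == 48


def test_detect_hypertension_no_followup_warns():
    with pytest.warns(UserWarning):
        ev, month = detect_hypertension(make_visits([(0, 120, 80, 0)]))
    assert not ev and month == 0


def test_detect_monotone_in_medication():
    """Starting medication at an earlier visit can only move the event
    earlier, never later."""
    rows = [(0, 120, 80, 0), (24, 125, 82, 0), (48, 130, 84, 0), (72, 150, 95, 0)]
    _, base_month = detect_hypertension(make_visits(rows))
    for med_at in (1, 2):
        rows2 = [
            (m, s, d, 1 if i >= med_at else 0)
            for i, (m, s, d, _) in enumerate(rows)
        ]
        _, month = detect_hypertension(make_visits(rows2))
        assert month <= base_month


def test_delta_bp_examples():
    v = make_visits([(0, 110, 70, 0), (48, 122, 70, 0)])
    ds, dd = compute_delta_bp(v)
    assert ds == pytest.approx(0.25) and dd == pytest.approx(0.0)
    v = make_visits([(0, 120, 80, 0), (24, 114, 80, 0)])
    ds, _ = compute_delta_bp(v)
    assert ds == pytest.approx(-0.25)


def test_delta_bp_excludes_diagnosis_visit():
    v = make_visits([(0, 110, 70, 0), (24, 116, 74, 0), (48, 150, 95, 0)])
    ds, _ = compute_delta_bp(v, event_month=48)
    assert ds == pytest.approx((116 - 110) / 24)
    ds_incl, _ = compute_delta_bp(v, event_month=48, include_diagnosis_visit=True)
    assert ds_incl == pytest.approx((150 - 110) / 48)


def test_delta_bp_single_visit_undefined():
    ds, dd = compute_delta_bp(make_visits([(0, 110, 70, 0)]))
    assert np.isnan(ds) and np.isnan(dd)


@given(slope=st.floats(-0.5, 0.5), base=st.floats(90, 130))
@settings(max_examples=30, deadline=None)
def test_delta_bp_recovers_exact_linear_slope(slope, base):
    months = [0, 24, 48, 72]
    v = make_visits([(m, base + slope * m, 70 + slope * m, 0) for m in months])
    ds, dd = compute_delta_bp(v)
    assert ds == pytest.approx(slope, abs=1e-9)
    assert dd == pytest.approx(slope, abs=1e-9)


def test_ckd_epi_reference_values():
    assert compute_ckd_epi_egfr(0.7, 50, "female") == pytest.approx(101.4, abs=0.1)
    assert compute_ckd_epi_egfr(1.2, 60, "male") == pytest.approx(65.4, abs=0.1)
    with pytest.raises(ValueError):
        compute_ckd_epi_egfr(0.0, 50, "male")


@given(
    scr=st.floats(0.4, 3.0),
    age=st.floats(20, 80),
    sex=st.sampled_from(["male", "female"]),
)
@settings(max_examples=50, deadline=None)
def test_egfr_strictly_decreasing(scr, age, sex):
    base = compute_ckd_epi_egfr(scr, age, sex)
    assert compute_ckd_epi_egfr(scr + 0.1, age, sex) < base
    assert compute_ckd_epi_egfr(scr, age + 1.0, sex) < base


# ---------------------------------------------------------------------------
# derived cohort and descriptives

def test_vectorized_derivation_matches_per_subject(baseline_visits):
    baseline, visits = baseline_visits
    cfg = CohortConfig()
    fast = _derive_outcomes_vectorized(visits, cfg).set_index("subject_id")
    for sid, v in visits.groupby("subject_id"):
        ev, month = detect_hypertension(v)
        ds, dd = compute_delta_bp(v, month if ev else None)
        row = fast.loc[sid]
        assert bool(row["event"]) == ev
        assert row["event_month"] == month
        for got, want in ((row["delta_sbp"], ds), (row["delta_dbp"], dd)):
            assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)


def test_derive_cohort_adds_expected_columns(baseline_visits):
    baseline, visits = baseline_visits
    cohort = derive_cohort(baseline, visits)
    for col in ("hypoalbuminemia", "event", "event_month", "delta_sbp", "egfr"):
        assert col in cohort.columns
    ok = cohort["albumin"].notna()
    np.testing.assert_array_equal(
        cohort.loc[ok, "hypoalbuminemia"].astype(bool),
        cohort.loc[ok, "albumin"] <= 4.0,
    )


def test_summarize_baseline_exact_small_sample_tests():
    df = pd.DataFrame(
        {
            "grp": [0, 0, 0, 1, 1, 1],
            "value": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "flag": [1, 1, 1, 0, 0, 0],
        }
    )
    table = summarize_baseline(df, group="grp").set_index("variable")
    # Mann-Whitney {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 0.1
    assert table.loc["value", "statistic"] == 0
    assert table.loc["value", "p"] == pytest.approx(0.1)
    # Fisher on the 2x2 table ((3,0),(0,3)): exact two-sided p = 0.1
    assert table.loc["flag", "test"] == "fisher"
    assert table.loc["flag", "p"] == pytest.approx(0.1)


def test_summarize_baseline_identical_groups_chi2_zero():
    half = pd.DataFrame({"flag": [1] * 30 + [0] * 30, "value": list(range(60))})
    df = pd.concat(
        [half.assign(grp=0), half.assign(grp=1)], ignore_index=True
    )
    table = summarize_baseline(df, group="grp").set_index("variable")
    assert table.loc["flag", "test"] == "chi-square"
    assert table.loc["flag", "statistic"] == pytest.approx(0.0, abs=1e-12)


def test_summarize_baseline_constant_variable():
    df = pd.DataFrame({"grp": [0, 0, 1, 1], "value": [2.0, 2.0, 2.0, 2.0]})
    table = summarize_baseline(df, group="grp")
    assert np.isnan(table.loc[0, "p"])
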