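"""Phenotyping-rule tests: eGFR, DKD classification, onset, sequences."""

import math

import numpy as np
import pandas as pd
import pytest

from landboost import vocab
from landboost.events import validate_event_table
from landboost.phenotyping import (
    OutcomeSequence,
    PhenotypeConfig,
    apply_cohort_filters,
    build_outcome_sequence,
    classify_kidney_abnormal,
    compute_egfr,
    cohort_statuses,
    detect_dm_onset,
    extract_timelines,
    landmark_eligibility,
    phenotype_cohort,
)


def make_timeline(rows, age=60.0, sex="male", race="other"):
    """Hand-build a timeline from (day, domain, code, value, modifier, enc)."""
    base = [(0, vocab.DOMAIN_DEMOGRAPHICS, vocab.DEMO_AGE, age, None, "outpatient")]
    if sex == "female":
        base.append((0, vocab.DOMAIN_DEMOGRAPHICS, vocab.DEMO_SEX_FEMALE, None, None,
                     "outpatient"))
    if race == "black":
        base.append((0, vocab.DOMAIN_DEMOGRAPHICS, vocab.DEMO_RACE_BLACK, None, None,
                     "outpatient"))
    df = pd.DataFrame(
        base + rows,
        columns=["day", "domain", "feature_code", "value", "modifier",
                 "encounter_type"],
    )
    df.insert(0, "patient_id", "px")
    return extract_timelines(validate_event_table(df))[0]


def lab(day, code, value, enc="outpatient"):
    return (day, vocab.DOMAIN_LABS, code, value, None, enc)


def creatinine_for_egfr(target, age=60.0, female=False, black=False):
    base = 175.0 * age ** (-0.203) * (0.742 if female else 1.0) * (1.212 if black else 1.0)
    return (target / base) ** (-1.0 / 1.154)


# ---------------------------------------------------------------------------
# eGFR and the kidney-abnormality rule
# ---------------------------------------------------------------------------

def test_egfr_reference_values():
    # 175 * 60^-0.203 for a 60-year-old non-black male with SCr 1.0
    assert compute_egfr(1.0, 60, "male", "other") == pytest.approx(
        175.0 * 60 ** (-0.203), rel=1e-9
    )
    assert compute_egfr(1.0, 60, "male", "other") == pytest.approx(76.23, abs=0.01)
    base = 175.0 * 60 ** (-0.203)
    assert compute_egfr(1.0, 60, "female", "other") == pytest.approx(56.56, abs=0.01)
    assert compute_egfr(1.0, 60, "female", "other") == pytest.approx(
        base * 0.742, rel=1e-12
    )
    assert compute_egfr(1.0, 60, "male", "black") == pytest.approx(
        base * 1.212, rel=1e-12
    )


def test_egfr_rejects_nonpositive_and_pediatric_inputs():
    with pytest.raises(ValueError):
        compute_egfr(0.0, 60, "male", "other")
    with pytest.raises(ValueError):
        compute_egfr(1.0, 17, "male", "other")


def test_kidney_thresholds_boundary_exact():
    assert classify_kidney_abnormal(egfr=59.9) is True
    assert classify_kidney_abnormal(egfr=60.0, acr=29.9) is False
    assert classify_kidney_abnormal(acr=30.0) is True
    assert classify_kidney_abnormal(pcr=30.0) is True
    assert classify_kidney_abnormal(pcr=29.999) is False


def test_kidney_classification_monotone():
    """Worsening kidney function never flips abnormal -> normal."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        egfr = rng.uniform(20, 120)
        acr = rng.uniform(0, 100)
        flag = classify_kidney_abnormal(egfr=egfr, acr=acr)
        worse = classify_kidney_abnormal(egfr=egfr - rng.uniform(0, 30),
                                         acr=acr + rng.uniform(0, 50))
        assert not (flag and not worse)


def test_kidney_requires_some_measurement():
    with pytest.raises(ValueError):
        classify_kidney_abnormal()


# ---------------------------------------------------------------------------
# diabetes onset
# ---------------------------------------------------------------------------

def test_onset_two_hba1c_within_two_years():
    tl = make_timeline([lab(100, vocab.LAB_HBA1C, 6.6), lab(400, vocab.LAB_HBA1C, 7.0)])
    assert detect_dm_onset(tl) == 100


def test_onset_single_hba1c_insufficient():
    tl = make_timeline([lab(100, vocab.LAB_HBA1C, 6.6)])
    assert detect_dm_onset(tl) is None


def test_onset_hba1c_pair_beyond_two_years_fails():
    tl = make_timeline([lab(100, vocab.LAB_HBA1C, 6.6), lab(900, vocab.LAB_HBA1C, 7.0)])
    assert detect_dm_onset(tl) is None


def test_onset_anchors_at_earliest_qualifying_pair_member():
    tl = make_timeline(
        [lab(0, vocab.LAB_HBA1C, 6.8), lab(900, vocab.LAB_HBA1C, 6.9),
         lab(1000, vocab.LAB_HBA1C, 7.0)]
    )
    assert detect_dm_onset(tl) == 900


def test_onset_single_medication_record_qualifies():
    tl = make_timeline([(50, "medications", vocab.MED_GLUCOSE_LOWERING, None, None,
                         "outpatient")])
    assert detect_dm_onset(tl) == 50
    cfg = PhenotypeConfig(med_single_record_qualifies=False)
    assert detect_dm_onset(tl, cfg) is None


def test_onset_two_diagnoses_and_subthreshold_labs():
    tl = make_timeline(
        [(200, "diagnoses", vocab.DX_T2DM, None, None, "outpatient"),
         (300, "diagnoses", vocab.DX_T2DM, None, None, "outpatient"),
         lab(10, vocab.LAB_HBA1C, 6.4)]  # below 6.5: never counts
    )
    assert detect_dm_onset(tl) == 200


def test_onset_two_distinct_event_types():
    # a single qualifying lab day plus a single diagnosis day: criterion (4)
    tl = make_timeline(
        [lab(500, vocab.LAB_GLUCOSE_RANDOM, 220.0),
         (300, "diagnoses", vocab.DX_T2DM, None, None, "outpatient")]
    )
    assert detect_dm_onset(tl) == 300


def test_gestational_events_never_count():
    tl = make_timeline(
        [(100, vocab.DOMAIN_LABS, vocab.LAB_HBA1C, 7.0, vocab.MOD_GESTATIONAL,
          "outpatient"),
         (200, vocab.DOMAIN_LABS, vocab.LAB_HBA1C, 7.5, vocab.MOD_GESTATIONAL,
          "outpatient")]
    )
    assert detect_dm_onset(tl) is None


def test_glucose_thresholds():
    tl = make_timeline([lab(0, vocab.LAB_GLUCOSE_FASTING, 126.0),
                        lab(100, vocab.LAB_GLUCOSE_FASTING, 130.0)])
    assert detect_dm_onset(tl) == 0
    tl2 = make_timeline([lab(0, vocab.LAB_GLUCOSE_RANDOM, 199.9),
                         lab(100, vocab.LAB_GLUCOSE_RANDOM, 199.9)])
    assert detect_dm_onset(tl2) is None


# ---------------------------------------------------------------------------
# outcome sequences
# ---------------------------------------------------------------------------

def test_worked_sequence_zero_na_one():
    """Normal lab year 0, no lab year 1, abnormal lab year 2 -> (0, NA, 1)."""
    scr_norm = creatinine_for_egfr(90.0)
    scr_bad = creatinine_for_egfr(45.0, age=62.0)
    tl = make_timeline(
        [lab(0, vocab.LAB_HBA1C, 6.8), lab(90, vocab.LAB_HBA1C, 7.0),
         lab(100, vocab.LAB_CREATININE, scr_norm),
         lab(800, vocab.LAB_CREATININE, scr_bad)]
    )
    onset = detect_dm_onset(tl)
    assert onset == 0
    seq = build_outcome_sequence(tl, onset, horizon_T=3)
    assert seq.to_string() == "0,NA,1"
    assert seq.end_point_day == 800


def test_sequence_no_labs_all_na():
    tl = make_timeline([lab(0, vocab.LAB_HBA1C, 6.8), lab(90, vocab.LAB_HBA1C, 7.0)])
    seq = build_outcome_sequence(tl, 0, horizon_T=3)
    assert seq.to_string() == "NA,NA,NA"
    assert seq.end_point_day is None


def test_sequence_truncates_after_first_event():
    tl = make_timeline(
        [lab(0, vocab.LAB_HBA1C, 6.8), lab(90, vocab.LAB_HBA1C, 7.0),
         lab(50, vocab.LAB_ACR, 45.0)]
    )
    seq = build_outcome_sequence(tl, 0, horizon_T=5)
    assert seq.to_string() == "1"
    assert len(seq.statuses) == 1


def test_sequence_uses_last_lab_in_window():
    tl = make_timeline(
        [lab(10, vocab.LAB_ACR, 45.0), lab(300, vocab.LAB_ACR, 5.0)]
    )
    seq = build_outcome_sequence(tl, 0, horizon_T=1)
    assert seq.to_string() == "0"  # day-300 lab supersedes the day-10 one


def test_sequence_ignores_inpatient_labs():
    tl = make_timeline([lab(100, vocab.LAB_ACR, 45.0, enc="inpatient")])
    seq = build_outcome_sequence(tl, 0, horizon_T=1)
    assert seq.to_string() == "NA"


# ---------------------------------------------------------------------------
# landmark eligibility
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "statuses,t,expected",
    [
        ("0,NA,1", 0, True),
        ("0,NA,1", 1, False),
        ("0,NA,1", 2, True),
        ("1", 0, True),
        ("0,0", 1, True),
        ("0,1", 2, False),  # beyond sequence end
        ("NA,0", 0, False),
    ],
)
def test_landmark_eligibility_rule(statuses, t, expected):
    arr = OutcomeSequence.parse_statuses(statuses)
    assert landmark_eligibility(arr, t) is expected


def test_eligibility_rejects_negative_landmark():
    with pytest.raises(ValueError):
        landmark_eligibility(np.array([0.0]), -1)


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------

def _dm_anchor():
    return [lab(0, vocab.LAB_HBA1C, 6.8), lab(90, vocab.LAB_HBA1C, 7.0)]


def test_filter_excludes_abnormal_before_onset():
    tl = make_timeline(
        _dm_anchor() + [lab(-100, vocab.LAB_CREATININE, creatinine_for_egfr(50.0)),
                        lab(200, vocab.LAB_ACR, 5.0)]
    )
    cohort, report = apply_cohort_filters([tl])
    assert len(cohort) == 0
    r = report.set_index("criterion")["n"]
    assert r["kidney_abnormal_before_dm_onset"] == 1


def test_filter_excludes_patients_without_kidney_labs():
    tl = make_timeline(_dm_anchor())
    cohort, report = apply_cohort_filters([tl])
    assert len(cohort) == 0
    assert report.set_index("criterion")["n"]["no_valid_outpatient_kidney_lab"] == 1


def test_filter_excludes_type1_and_counts_overlap():
    rows = _dm_anchor() + [
        (10, "diagnoses", vocab.DX_T1DM, None, None, "outpatient"),
        lab(-50, vocab.LAB_ACR, 80.0),
        lab(100, vocab.LAB_ACR, 5.0),
    ]
    tl = make_timeline(rows)
    cohort, report = apply_cohort_filters([tl])
    r = report.set_index("criterion")["n"]
    # one patient, two exclusion reasons: counts exceed patients excluded
    assert r["type1_or_cf_diabetes"] == 1
    assert r["kidney_abnormal_before_dm_onset"] == 1
    assert r["total_excluded"] == 1


def test_filter_labels_cases_and_controls():
    case = make_timeline(
        _dm_anchor() + [lab(100, vocab.LAB_ACR, 5.0), lab(400, vocab.LAB_ACR, 90.0)]
    )
    control = make_timeline(
        _dm_anchor() + [lab(100, vocab.LAB_ACR, 5.0), lab(400, vocab.LAB_ACR, 6.0)]
    )
    cohort, _ = apply_cohort_filters([case, control])
    by_group = cohort.set_index("group")
    assert by_group.loc["case", "end_point_day"] == 400
    assert by_group.loc["control", "end_point_day"] == 400
    assert by_group.loc["case", "outcome_sequence"] == "0,1"
    assert by_group.loc["control", "outcome_sequence"] == "0,0,NA,NA,NA"


def test_filter_underage_excluded():
    tl = make_timeline(_dm_anchor() + [lab(100, vocab.LAB_ACR, 5.0)], age=16.0)
    cohort, report = apply_cohort_filters([tl])
    assert len(cohort) == 0
    assert report.set_index("criterion")["n"]["age_under_18_or_unknown"] == 1


# ---------------------------------------------------------------------------
# integration with the generator
# ---------------------------------------------------------------------------

def test_phenotyping_recovers_generated_ground_truth(small_cohort):
    """Statuses derived from the raw event table must equal the generator's
    realized outcomes for every included patient."""
    events, truth = small_cohort
    cohort, _ = phenotype_cohort(events, PhenotypeConfig(horizon=3))
    statuses = cohort_statuses(cohort)
    gt = truth.table
    checked = 0
    for pid, arr in statuses.items():
        sub = gt[gt["patient_id"] == pid].sort_values("landmark")
        for t in range(min(3, arr.size)):
            g = sub.iloc[t]["status"]
            mine = arr[t] if t < arr.size else math.nan
            if math.isnan(g):
                assert math.isnan(mine) or t >= arr.size
            else:
                assert mine == g
                checked += 1
    assert checked > 100


def test_timeline_demographics_extraction(small_cohort):
    events, truth = small_cohort
    tls = extract_timelines(events)
    lat = truth.latents.set_index("patient_id")
    for tl in tls[:20]:
        assert tl.age_at_day0 == pytest.approx(lat.loc[tl.patient_id, "age_at_onset"])
        assert (tl.sex == "female") == bool(lat.loc[tl.patient_id, "female"])
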