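"""Cohort phenotyping: diabetes onset, yearly DKD status, inclusion rules.

Diabetes onset is the earliest day satisfying any of: (1) a glucose-lowering
medication record; (2) HbA1c >= 6.5%, random glucose >= 200 mg/dL or fasting
glucose >= 126 mg/dL on at least two different dates within 2 years; (3) two
type-1/type-2 diabetes diagnoses on two different days within 2 years;
(4) any two distinct event types among (1)-(3); gestational-diabetes events
never count toward any criterion.

Kidney disease is operationalized as eGFR < 60 mL/min/1.73m^2 (MDRD
estimate from serum creatinine, age, sex, race) or a urine albumin- or
protein-to-creatinine ratio >= 30 mg/g.  Yearly DKD statuses are read off
the *last outpatient* kidney lab in each full-year window since onset, NA
when a year has no qualifying lab, truncated after the first event year.

All code lists and thresholds live in :class:`PhenotypeConfig` so real event
tables with their own vocabularies can be phenotyped with the same rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import vocab
from .events import validate_event_table
from .vocab import DAYS_PER_YEAR


@dataclass
class PhenotypeConfig:
    """Code lists, thresholds and rule switches for phenotyping."""

    hba1c_codes: tuple = (vocab.LAB_HBA1C,)
    random_glucose_codes: tuple = (vocab.LAB_GLUCOSE_RANDOM,)
    fasting_glucose_codes: tuple = (vocab.LAB_GLUCOSE_FASTING,)
    glucose_lowering_med_codes: tuple = (vocab.MED_GLUCOSE_LOWERING,)
    dm_dx_codes: tuple = (vocab.DX_T2DM, vocab.DX_T1DM)
    t1dm_exclusion_codes: tuple = (vocab.DX_T1DM, vocab.DX_CF_DM)
    gestational_modifier: str = vocab.MOD_GESTATIONAL
    creatinine_codes: tuple = (vocab.LAB_CREATININE,)
    acr_codes: tuple = (vocab.LAB_ACR,)
    pcr_codes: tuple = (vocab.LAB_PCR,)

    hba1c_threshold: float = 6.5        # percent
    random_glucose_threshold: float = 200.0   # mg/dL
    fasting_glucose_threshold: float = 126.0  # mg/dL
    egfr_threshold: float = 60.0        # mL/min/1.73m^2
    ratio_threshold: float = 30.0       # mg/g, ACR and PCR alike
    mdrd_coefficient: float = 175.0     # IDMS-traceable 4-variable MDRD
    two_year_window_days: int = 2 * DAYS_PER_YEAR
    med_single_record_qualifies: bool = True
    min_age: float = 18.0
    horizon: int = 5


def compute_egfr(
    serum_creatinine: float,
    age: float,
    sex: str,
    race: str,
    coefficient: float = 175.0,
) -> float:
    """MDRD eGFR (mL/min/1.73m^2) from serum creatinine (mg/dL).

    ``coefficient * SCr^-1.154 * age^-0.203 * 0.742[female] * 1.212[black]``;
    the default 175 coefficient is the IDMS-traceable recalibration.
    """
    if not serum_creatinine > 0:
        raise ValueError("serum creatinine must be positive")
    if not age >= 18:
        raise ValueError("MDRD is an adult equation (age >= 18)")
    egfr = coefficient * serum_creatinine ** (-1.154) * age ** (-0.203)
    if str(sex).lower() == "female":
        egfr *= 0.742
    if "black" in str(race).lower():
        egfr *= 1.212
    return egfr


def classify_kidney_abnormal(
    egfr: Optional[float] = None,
    acr: Optional[float] = None,
    pcr: Optional[float] = None,
    egfr_threshold: float = 60.0,
    ratio_threshold: float = 30.0,
) -> bool:
    """True iff eGFR < 60, ACR >= 30 mg/g, or PCR >= 30 mg/g.

    The eGFR bound is exclusive ("less than 60"); the ratio bounds are
    inclusive ("30 mg/g or greater").  At least one measurement is required.
    """
    if egfr is None and acr is None and pcr is None:
        raise ValueError("at least one kidney measurement required")
    if egfr is not None and egfr < egfr_threshold:
        return True
    if acr is not None and acr >= ratio_threshold:
        return True
    if pcr is not None and pcr >= ratio_threshold:
        return True
    return False


@dataclass
class OutcomeSequence:
    """Per-patient yearly DKD statuses anchored at diabetes onset.

    ``statuses[t]`` is 0.0, 1.0 or NaN for year window ``[365t, 365(t+1))``
    days since onset; at most one entry is 1 and the sequence is truncated
    after it.  ``end_point_day`` is the first-abnormal lab day for cases and
    the last-normal lab day for controls (days since onset; None if the
    patient has no qualifying lab at all).
    """

    dm_onset_day: int
    statuses: np.ndarray
    end_point_day: Optional[int]

    def to_string(self) -> str:
        out = []
        for s in self.statuses:
            out.append("NA" if math.isnan(s) else str(int(s)))
        return ",".join(out)

    @staticmethod
    def parse_statuses(text: str) -> np.ndarray:
        if text == "":
            return np.array([])
        return np.array(
            [math.nan if tok == "NA" else float(tok) for tok in text.split(",")]
        )


@dataclass
class PatientTimeline:
    """One patient's sorted events plus demographics.

    Event columns are cached as numpy arrays (``days``, ``codes``,
    ``values``, ``modifiers``, ``encounters``) because phenotyping rules are
    evaluated per patient many thousands of times.
    """

    patient_id: str
    days: np.ndarray = field(repr=False)
    codes: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    modifiers: np.ndarray = field(repr=False)
    encounters: np.ndarray = field(repr=False)
    age_at_day0: Optional[float] = None  # age (years) at the demo event day
    age_ref_day: int = 0
    sex: str = "male"
    race: str = "other"

    def age_on(self, day: float) -> Optional[float]:
        if self.age_at_day0 is None:
            return None
        return self.age_at_day0 + (day - self.age_ref_day) / DAYS_PER_YEAR

    @staticmethod
    def from_events(patient_id: str, grp: pd.DataFrame) -> "PatientTimeline":
        days = grp["day"].to_numpy()
        codes = grp["feature_code"].to_numpy()
        values = grp["value"].to_numpy(dtype=float)
        tl = PatientTimeline(
            patient_id=str(patient_id),
            days=days,
            codes=codes,
            values=values,
            modifiers=grp["modifier"].to_numpy(),
            encounters=grp["encounter_type"].to_numpy(),
        )
        age_idx = np.flatnonzero(codes == vocab.DEMO_AGE)
        if age_idx.size:
            tl.age_at_day0 = float(values[age_idx[0]])
            tl.age_ref_day = int(days[age_idx[0]])
        if (codes == vocab.DEMO_SEX_FEMALE).any():
            tl.sex = "female"
        if (codes == vocab.DEMO_RACE_BLACK).any():
            tl.race = "black"
        return tl


def extract_timelines(events: pd.DataFrame) -> list[PatientTimeline]:
    """Split a validated event table into per-patient timelines."""
    events = validate_event_table(events)
    return [
        PatientTimeline.from_events(pid, grp)
        for pid, grp in events.groupby("patient_id", sort=True)
    ]


def _earliest_pair_day(days: np.ndarray, window: int) -> Optional[int]:
    """Earliest day belonging to a pair of distinct days within ``window``."""
    days = np.unique(days)
    if days.size < 2:
        return None
    ok = np.diff(days) <= window
    if not ok.any():
        return None
    return int(days[int(np.argmax(ok))])


def detect_dm_onset(
    timeline: PatientTimeline, config: Optional[PhenotypeConfig] = None
) -> Optional[int]:
    """Earliest day qualifying as diabetes onset, or None.

    Gestational-diabetes-flagged events are discarded before any criterion
    is evaluated.  A criterion requiring two dates within 2 years anchors
    onset at the earlier day of the earliest qualifying pair.
    """
    config = config or PhenotypeConfig()
    keep = (timeline.modifiers != config.gestational_modifier).astype(bool)
    codes = timeline.codes[keep]
    days = timeline.days[keep]
    vals = timeline.values[keep]

    med_days = np.unique(days[np.isin(codes, config.glucose_lowering_med_codes)])

    with np.errstate(invalid="ignore"):
        lab_mask = (
            (np.isin(codes, config.hba1c_codes) & (vals >= config.hba1c_threshold))
            | (np.isin(codes, config.random_glucose_codes)
               & (vals >= config.random_glucose_threshold))
            | (np.isin(codes, config.fasting_glucose_codes)
               & (vals >= config.fasting_glucose_threshold))
        )
    lab_days = np.unique(days[lab_mask])

    dx_days = np.unique(days[np.isin(codes, config.dm_dx_codes)])

    candidates: list[int] = []
    if med_days.size:
        if config.med_single_record_qualifies:
            candidates.append(int(med_days[0]))
        else:
            d = _earliest_pair_day(med_days, config.two_year_window_days)
            if d is not None:
                candidates.append(d)
    d = _earliest_pair_day(lab_days, config.two_year_window_days)
    if d is not None:
        candidates.append(d)
    d = _earliest_pair_day(dx_days, config.two_year_window_days)
    if d is not None:
        candidates.append(d)

    # criterion (4): any two distinct event types among (1)-(3); no pair
    # proximity window is imposed across types
    type_days = [ds for ds in (med_days, lab_days, dx_days) if ds.size]
    if len(type_days) >= 2:
        candidates.append(int(min(ds[0] for ds in type_days)))

    return min(candidates) if candidates else None


@dataclass
class _KidneyLabDays:
    """Valid kidney labs collapsed to one entry per day (same-day mean)."""

    days: np.ndarray       # unique, sorted
    creatinine: np.ndarray  # NaN where absent that day
    acr: np.ndarray
    pcr: np.ndarray

    @property
    def empty(self) -> bool:
        return self.days.size == 0


def _kidney_labs(
    timeline: PatientTimeline,
    config: PhenotypeConfig,
    outpatient_only: bool = True,
) -> _KidneyLabDays:
    """Valid kidney labs per day: numeric, positive and (by default)
    outpatient; same-day duplicate values are averaged."""
    with np.errstate(invalid="ignore"):
        valid = timeline.values > 0
    kidney_codes = config.creatinine_codes + config.acr_codes + config.pcr_codes
    mask = np.isin(timeline.codes, kidney_codes) & valid
    if outpatient_only:
        mask &= timeline.encounters == "outpatient"
    days = timeline.days[mask]
    codes = timeline.codes[mask]
    vals = timeline.values[mask]
    if days.size == 0:
        e = np.array([])
        return _KidneyLabDays(e.astype(int), e, e, e)
    udays, inv = np.unique(days, return_inverse=True)
    out = []
    for group in (config.creatinine_codes, config.acr_codes, config.pcr_codes):
        sel = np.isin(codes, group)
        sums = np.zeros(udays.size)
        cnts = np.zeros(udays.size)
        np.add.at(sums, inv[sel], vals[sel])
        np.add.at(cnts, inv[sel], 1.0)
        with np.errstate(invalid="ignore"):
            out.append(np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan))
    return _KidneyLabDays(udays, out[0], out[1], out[2])


def _day_abnormal(
    labs: _KidneyLabDays, i: int, timeline: PatientTimeline, config: PhenotypeConfig
) -> Optional[bool]:
    """Classify lab day ``i``; None when nothing usable (e.g. no age for eGFR)."""
    egfr = None
    scr = labs.creatinine[i]
    if not math.isnan(scr):
        age = timeline.age_on(labs.days[i])
        if age is not None and age >= 18:
            egfr = compute_egfr(
                scr, age, timeline.sex, timeline.race, config.mdrd_coefficient
            )
    acr = None if math.isnan(labs.acr[i]) else float(labs.acr[i])
    pcr = None if math.isnan(labs.pcr[i]) else float(labs.pcr[i])
    if egfr is None and acr is None and pcr is None:
        return None
    return classify_kidney_abnormal(
        egfr, acr, pcr, config.egfr_threshold, config.ratio_threshold
    )


def build_outcome_sequence(
    timeline: PatientTimeline,
    dm_onset_day: int,
    horizon_T: Optional[int] = None,
    config: Optional[PhenotypeConfig] = None,
) -> OutcomeSequence:
    """Yearly DKD statuses from the last outpatient kidney lab per window.

    Window t spans ``[onset + 365t, onset + 365(t+1))``; a year without a
    qualifying lab is NA (no imputation); the sequence is truncated after
    the first 1.
    """
    config = config or PhenotypeConfig()
    T = horizon_T if horizon_T is not None else config.horizon
    labs = _kidney_labs(timeline, config)
    statuses = np.full(T, np.nan)
    first_abnormal_day = None
    last_normal_day = None
    if not labs.empty:
        rel = labs.days - dm_onset_day
        for t in range(T):
            in_win = (rel >= DAYS_PER_YEAR * t) & (rel < DAYS_PER_YEAR * (t + 1))
            if not in_win.any():
                continue
            idx = int(np.flatnonzero(in_win)[-1])  # last qualifying lab day
            flag = _day_abnormal(labs, idx, timeline, config)
            if flag is None:
                continue
            statuses[t] = 1.0 if flag else 0.0
            if flag:
                first_abnormal_day = int(rel[idx])
                statuses[t + 1:] = np.nan
                break
            last_normal_day = int(rel[idx])
    if first_abnormal_day is not None:
        end_point: Optional[int] = first_abnormal_day
        first_one = int(np.nanargmax(statuses == 1.0))
        statuses = statuses[: first_one + 1]
    else:
        end_point = last_normal_day
    return OutcomeSequence(dm_onset_day, statuses, end_point)


def landmark_eligibility(sequence: OutcomeSequence | np.ndarray, t: int) -> bool:
    """Eligible at landmark t: non-NA status at t and no earlier event.

    An NA year does not censor later windows — a patient may be NA in year 1
    and eligible again in year 2 (the (0, NA, 1) sequence).
    """
    if t < 0:
        raise ValueError("landmark index must be >= 0")
    statuses = sequence.statuses if isinstance(sequence, OutcomeSequence) else np.asarray(sequence, float)
    if t >= statuses.size or math.isnan(statuses[t]):
        return False
    return not np.any(statuses[:t] == 1.0)


EXCLUSION_CRITERIA = (
    "no_dm_onset",
    "age_under_18_or_unknown",
    "type1_or_cf_diabetes",
    "no_valid_outpatient_kidney_lab",
    "kidney_abnormal_before_dm_onset",
)


def apply_cohort_filters(
    timelines: Sequence[PatientTimeline],
    config: Optional[PhenotypeConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inclusion/exclusion rules; returns (cohort table, exclusion report).

    Kept patients are adults at onset with at least one valid outpatient
    kidney lab at/after onset, no type-1/CF-related diabetes diagnosis, and
    no kidney abnormality before onset.  Cases are labelled by their first
    abnormal lab (end point = that day); controls are always-normal (end
    point = last normal lab day).  One patient may satisfy several exclusion
    criteria, so exclusion counts can sum to more than the number excluded.
    """
    config = config or PhenotypeConfig()
    counts = {c: 0 for c in EXCLUSION_CRITERIA}
    rows = []
    n_excluded = 0
    for tl in timelines:
        onset = detect_dm_onset(tl, config)
        reasons = []
        if onset is None:
            reasons.append("no_dm_onset")
        age = tl.age_on(onset) if onset is not None else None
        if onset is not None and (age is None or age < config.min_age):
            reasons.append("age_under_18_or_unknown")
        if np.isin(tl.codes, config.t1dm_exclusion_codes).any():
            reasons.append("type1_or_cf_diabetes")
        if onset is not None:
            out_labs = _kidney_labs(tl, config, outpatient_only=True)
            if out_labs.empty or not (out_labs.days >= onset).any():
                reasons.append("no_valid_outpatient_kidney_lab")
            pre = _kidney_labs(tl, config, outpatient_only=False)
            for i in np.flatnonzero(pre.days < onset):
                if _day_abnormal(pre, int(i), tl, config):
                    reasons.append("kidney_abnormal_before_dm_onset")
                    break
        if reasons:
            n_excluded += 1
            for r in reasons:
                counts[r] += 1
            continue
        seq = build_outcome_sequence(tl, onset, config.horizon, config)
        has_event = bool(np.any(seq.statuses == 1.0))
        rows.append(
            {
                "patient_id": tl.patient_id,
                "dm_onset_day": onset,
                "age_at_onset": age,
                "sex": tl.sex,
                "race": tl.race,
                "group": "case" if has_event else "control",
                "end_point_day": seq.end_point_day,
                "outcome_sequence": seq.to_string(),
            }
        )
    cohort = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "dm_onset_day", "age_at_onset", "sex", "race",
            "group", "end_point_day", "outcome_sequence",
        ],
    )
    report = pd.DataFrame(
        {
            "criterion": list(counts) + ["total_excluded", "total_included"],
            "n": list(counts.values()) + [n_excluded, len(rows)],
        }
    )
    return cohort, report


def phenotype_cohort(
    events: pd.DataFrame, config: Optional[PhenotypeConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event table -> (cohort, exclusion report) in one call."""
    return apply_cohort_filters(extract_timelines(events), config)


def cohort_statuses(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    """Decode the outcome_sequence strings into per-patient status arrays."""
    return {
        str(r.patient_id): OutcomeSequence.parse_statuses(r.outcome_sequence)
        for r in cohort.itertuples()
    }
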