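"""Per-landmark design matrices: latest-value, stacked-window, person-period.

All designs obey the same leakage rule: a cell at landmark t may only use
events recorded *strictly before* day 365t since diabetes onset.  The
history available at landmark t is carved into t+1 windows: window 0 is the
pre-onset history (days < 0) and window w (w >= 1) is ``[365(w-1), 365w)``.

* **latest-value**: one row per eligible patient; the most recent value of
  each feature before the landmark (binary: ever observed), no timestamps.
* **stack-temporal**: one column per (feature, window) pair, so the width
  grows linearly with t+1.
* **discrete-survival**: a pooled person-period table, one row per eligible
  (patient, window) pair, predictors from the immediately preceding window
  plus a window-index column; rows are treated as independent examples.

Feature identity is the concatenation ``domain|feature_code|modifier``; a
feature is numeric if it ever carries a value, else binary (absence = 0,
numeric absence = missing).  Demographics (age at landmark, sex, race) and
engineered history counts (cumulative distinct features, increment since the
previous landmark) are appended to every design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import vocab
from .events import validate_event_table
from .phenotyping import OutcomeSequence, landmark_eligibility
from .vocab import DAYS_PER_YEAR

AGE_COL = "demo|age_at_landmark"
SEX_COL = "demo|sex_female"
RACE_COL = "demo|race_black"
HIST_CUM_COL = "hist|distinct_count"
HIST_INC_COL = "hist|distinct_increment"
WINDOW_COL = "meta|window_index"


def feature_identity(domain, code, modifier) -> str:
    mod = "" if modifier is None or (isinstance(modifier, float) and np.isnan(modifier)) else str(modifier)
    return f"{domain}|{code}|{mod}"


@dataclass
class FeatureMatrix:
    """Dense matrix with sparse semantics: binary absence 0, numeric absence NaN."""

    values: np.ndarray
    columns: list[str]
    kinds: list[str]
    row_ids: list

    def __post_init__(self) -> None:
        if len(self.columns) != len(set(self.columns)):
            raise ValueError("duplicate column descriptors")
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LandmarkDataset:
    """Eligible patients x features x labels at one landmark time."""

    t: int
    X: FeatureMatrix
    y: np.ndarray
    patient_ids: list

    @property
    def n(self) -> int:
        return len(self.patient_ids)


# ---------------------------------------------------------------------------
# event preparation
# ---------------------------------------------------------------------------

@dataclass
class EventFrame:
    """Cohort events re-anchored at onset with resolved feature identities.

    Window aggregates are memoised per (lo, hi) day range because every
    design, split and landmark reuses the same handful of windows.
    """

    df: pd.DataFrame = field(repr=False)  # patient_id, rel_day, identity, value
    dictionary: pd.DataFrame = field(repr=False)  # identity, kind, n_patients
    _agg_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def numeric_identities(self) -> set:
        d = self.dictionary
        return set(d.loc[d["kind"] == "numeric", "identity"])

    def _by_day(self) -> pd.DataFrame:
        """Same-day duplicates collapsed (numeric mean / binary presence),
        sorted by rel_day; computed once and shared by every window."""
        if "by_day" not in self._agg_cache:
            df = self.df
            is_num = df["identity"].isin(self.numeric_identities)
            num = (
                df[is_num]
                .groupby(["patient_id", "identity", "rel_day"], sort=False)["value"]
                .mean()
                .reset_index()
            )
            num["is_num"] = True
            binary = df.loc[
                ~is_num, ["patient_id", "identity", "rel_day"]
            ].drop_duplicates()
            binary["value"] = np.nan
            binary["is_num"] = False
            self._agg_cache["by_day"] = (
                pd.concat([num, binary], ignore_index=True)
                .sort_values("rel_day", kind="stable")
                .reset_index(drop=True)
            )
        return self._agg_cache["by_day"]

    def window_aggregate(self, lo: float, hi: float):
        key = (lo, hi)
        if key not in self._agg_cache:
            bd = self._by_day()
            sub = bd[(bd["rel_day"] >= lo) & (bd["rel_day"] < hi)]
            num = sub[sub["is_num"]]
            # sub is rel_day-sorted, so tail(1) is the last value in-window
            last = num.groupby(["patient_id", "identity"], sort=False).tail(1)
            pres = sub.loc[~sub["is_num"], ["patient_id", "identity"]].drop_duplicates()
            self._agg_cache[key] = (last, pres)
        return self._agg_cache[key]


def prepare_events(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    retained: Optional[set] = None,
) -> EventFrame:
    """Join events to the cohort, anchor days at onset, resolve identities.

    Demographic events are dropped here (they enter designs through the
    cohort table instead).  ``retained`` optionally restricts to a
    rare-filtered feature set.
    """
    ev = validate_event_table(events)
    ev = ev[ev["domain"] != vocab.DOMAIN_DEMOGRAPHICS].copy()
    onset = cohort.set_index("patient_id")["dm_onset_day"]
    ev = ev[ev["patient_id"].isin(onset.index)]
    ev["rel_day"] = ev["day"].to_numpy() - onset.loc[ev["patient_id"]].to_numpy()
    mods = ev["modifier"].fillna("")
    ev["identity"] = (
        ev["domain"].astype(str) + "|" + ev["feature_code"].astype(str) + "|" + mods.astype(str)
    )
    if retained is not None:
        ev = ev[ev["identity"].isin(retained)]
    dictionary = (
        ev.groupby("identity")
        .agg(
            kind=("value", lambda v: "numeric" if v.notna().any() else "binary"),
            n_patients=("patient_id", "nunique"),
        )
        .reset_index()
        .sort_values("identity")
        .reset_index(drop=True)
    )
    keep = ["patient_id", "rel_day", "identity", "value"]
    return EventFrame(df=ev[keep].reset_index(drop=True), dictionary=dictionary)


def filter_rare_features(
    events: pd.DataFrame,
    min_prevalence: float,
    patient_ids: Optional[Sequence] = None,
) -> set:
    """Identities observed in at least ``min_prevalence`` of the patients.

    Prevalence counts distinct patients ever showing the feature; pass the
    training-split ids so the filter never sees test patients.  A feature in
    exactly ``min_prevalence * n`` patients is retained.
    """
    if not (0.0 <= min_prevalence <= 1.0):
        raise ValueError("min_prevalence must be in [0, 1]")
    ev = validate_event_table(events)
    ev = ev[ev["domain"] != vocab.DOMAIN_DEMOGRAPHICS]
    if patient_ids is not None:
        ev = ev[ev["patient_id"].isin(set(patient_ids))]
        n_patients = len(set(patient_ids))
    else:
        n_patients = ev["patient_id"].nunique()
    mods = ev["modifier"].fillna("")
    identity = ev["domain"].astype(str) + "|" + ev["feature_code"].astype(str) + "|" + mods.astype(str)
    per_feature = ev.assign(identity=identity).groupby("identity")["patient_id"].nunique()
    return set(per_feature[per_feature >= min_prevalence * n_patients].index)


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

def _window_bounds(w: int) -> tuple[float, float]:
    """Window 0 = pre-onset history; window w>=1 = [365(w-1), 365w)."""
    if w == 0:
        return (-np.inf, 0.0)
    return (DAYS_PER_YEAR * (w - 1.0), DAYS_PER_YEAR * float(w))


def _aggregate(
    df: pd.DataFrame, numeric_ids: set, lo: float, hi: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Last numeric value (same-day duplicates averaged) and binary presence
    per (patient, identity) over rel_day in [lo, hi)."""
    sub = df[(df["rel_day"] >= lo) & (df["rel_day"] < hi)]
    is_num = sub["identity"].isin(numeric_ids)
    num = sub[is_num]
    if len(num):
        by_day = (
            num.groupby(["patient_id", "identity", "rel_day"], sort=True)["value"]
            .mean()
            .reset_index()
        )
        last = (
            by_day.sort_values("rel_day", kind="stable")
            .groupby(["patient_id", "identity"], sort=True)
            .tail(1)
        )
    else:
        last = pd.DataFrame(columns=["patient_id", "identity", "rel_day", "value"])
    pres = sub.loc[~is_num, ["patient_id", "identity"]].drop_duplicates()
    return last, pres


def _fill_matrix(
    mat: np.ndarray,
    row_pos: dict,
    col_pos: dict,
    last: pd.DataFrame,
    pres: pd.DataFrame,
    col_suffix: str = "",
) -> None:
    cols = {k[: len(k) - len(col_suffix)] if col_suffix else k: v
            for k, v in col_pos.items()
            if not col_suffix or k.endswith(col_suffix)}
    for frame, value in ((last, None), (pres, 1.0)):
        if not len(frame):
            continue
        r = frame["patient_id"].map(row_pos)
        c = frame["identity"].map(cols)
        keep = r.notna().to_numpy() & c.notna().to_numpy()
        if not keep.any():
            continue
        vals = (
            np.full(int(keep.sum()), value)
            if value is not None
            else frame.loc[keep, "value"].to_numpy(dtype=float)
        )
        mat[r[keep].to_numpy(dtype=int), c[keep].to_numpy(dtype=int)] = vals


# ---------------------------------------------------------------------------
# engineered history counts & demographics
# ---------------------------------------------------------------------------

def history_count_features(
    eventframe: EventFrame, patient_ids: Sequence, t: int
) -> pd.DataFrame:
    """Cumulative distinct-feature count before landmark t and its increment.

    The increment is relative to landmark t-1; at t=0 it equals the
    cumulative count.  A code observed many times counts once.
    """
    df = eventframe.df

    def cum_counts(cutoff: float) -> pd.Series:
        key = ("hist", cutoff)
        if key not in eventframe._agg_cache:
            eventframe._agg_cache[key] = (
                df[df["rel_day"] < cutoff].groupby("patient_id")["identity"].nunique()
            )
        return eventframe._agg_cache[key]

    cum = cum_counts(DAYS_PER_YEAR * float(t))
    prev = cum_counts(DAYS_PER_YEAR * float(t - 1)) if t >= 1 else pd.Series(dtype=float)
    rows = []
    for pid in patient_ids:
        c = float(cum.get(pid, 0))
        p = float(prev.get(pid, 0)) if t >= 1 else 0.0
        rows.append({"patient_id": pid, HIST_CUM_COL: c, HIST_INC_COL: c - p})
    return pd.DataFrame(rows)


def _demographic_block(cohort: pd.DataFrame, patient_ids: Sequence, t: int) -> np.ndarray:
    info = cohort.set_index("patient_id")
    out = np.zeros((len(patient_ids), 3))
    for r, pid in enumerate(patient_ids):
        row = info.loc[pid]
        age = row["age_at_onset"]
        out[r, 0] = (age + t) if pd.notna(age) else np.nan
        out[r, 1] = 1.0 if row["sex"] == "female" else 0.0
        out[r, 2] = 1.0 if row["race"] == "black" else 0.0
    return out


def _eligible_with_labels(
    cohort: pd.DataFrame, t: int, patient_ids: Optional[Sequence] = None
) -> tuple[list, np.ndarray]:
    ids, ys = [], []
    allowed = None if patient_ids is None else set(patient_ids)
    for row in cohort.itertuples():
        if allowed is not None and row.patient_id not in allowed:
            continue
        statuses = OutcomeSequence.parse_statuses(row.outcome_sequence)
        if landmark_eligibility(statuses, t):
            ids.append(row.patient_id)
            ys.append(int(statuses[t]))
    return ids, np.array(ys, dtype=int)


def _assemble(
    eventframe: EventFrame,
    cohort: pd.DataFrame,
    t: int,
    patient_ids: list,
    blocks: list[tuple[str, str]],  # (column name, kind) for event-feature cols
    fill_fn,
) -> FeatureMatrix:
    """Common scaffold: event-feature block + demographics + history counts."""
    cols = [name for name, _ in blocks] + [AGE_COL, SEX_COL, RACE_COL, HIST_CUM_COL, HIST_INC_COL]
    kinds = [k for _, k in blocks] + ["numeric", "binary", "binary", "numeric", "numeric"]
    n, p_ev = len(patient_ids), len(blocks)
    mat = np.zeros((n, len(cols)))
    for j, (_, kind) in enumerate(blocks):
        if kind == "numeric":
            mat[:, j] = np.nan
    row_pos = {pid: r for r, pid in enumerate(patient_ids)}
    col_pos = {name: j for j, (name, _) in enumerate(blocks)}
    if patient_ids:
        fill_fn(mat, row_pos, col_pos)
        mat[:, p_ev:p_ev + 3] = _demographic_block(cohort, patient_ids, t)
        hist = history_count_features(eventframe, patient_ids, t).set_index("patient_id")
        mat[:, p_ev + 3] = hist.loc[patient_ids, HIST_CUM_COL].to_numpy()
        mat[:, p_ev + 4] = hist.loc[patient_ids, HIST_INC_COL].to_numpy()
    return FeatureMatrix(values=mat, columns=cols, kinds=kinds, row_ids=list(patient_ids))


# ---------------------------------------------------------------------------
# the designs
# ---------------------------------------------------------------------------

def latest_value_design(
    eventframe: EventFrame,
    cohort: pd.DataFrame,
    t: int,
    patient_ids: Optional[Sequence] = None,
) -> LandmarkDataset:
    """Last observed value of each feature strictly before day 365t."""
    ids, y = _eligible_with_labels(cohort, t, patient_ids)
    d = eventframe.dictionary
    blocks = [(ident, kind) for ident, kind in zip(d["identity"], d["kind"])]
    numeric_ids = eventframe.numeric_identities

    def fill(mat, row_pos, col_pos):
        last, pres = eventframe.window_aggregate(-np.inf, DAYS_PER_YEAR * float(t))
        _fill_matrix(mat, row_pos, col_pos, last, pres)

    X = _assemble(eventframe, cohort, t, ids, blocks, fill)
    return LandmarkDataset(t=t, X=X, y=y, patient_ids=ids)


def stack_temporal_design(
    eventframe: EventFrame,
    cohort: pd.DataFrame,
    t: int,
    patient_ids: Optional[Sequence] = None,
) -> LandmarkDataset:
    """One column per (feature, window) over the t+1 history windows."""
    ids, y = _eligible_with_labels(cohort, t, patient_ids)
    d = eventframe.dictionary
    numeric_ids = eventframe.numeric_identities
    blocks = []
    for w in range(t + 1):
        blocks += [
            (f"{ident}@w{w}", kind) for ident, kind in zip(d["identity"], d["kind"])
        ]

    def fill(mat, row_pos, col_pos):
        for w in range(t + 1):
            last, pres = eventframe.window_aggregate(*_window_bounds(w))
            _fill_matrix(mat, row_pos, col_pos, last, pres, col_suffix=f"@w{w}")

    X = _assemble(eventframe, cohort, t, ids, blocks, fill)
    return LandmarkDataset(t=t, X=X, y=y, patient_ids=ids)


def discrete_survival_design(
    eventframe: EventFrame,
    cohort: pd.DataFrame,
    T: int,
    patient_ids: Optional[Sequence] = None,
) -> LandmarkDataset:
    """Pooled person-period table over landmarks 0..T-1.

    One row per eligible (patient, window) pair; predictors are the
    aggregates of the immediately preceding window (the pre-onset window for
    t=0) plus a window-index column; rows from the same patient are treated
    as independent examples.  Row ids are ``(patient_id, t)`` pairs.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    d = eventframe.dictionary
    numeric_ids = eventframe.numeric_identities
    blocks = [(f"{ident}@prev", kind) for ident, kind in zip(d["identity"], d["kind"])]
    cols = [name for name, _ in blocks] + [
        WINDOW_COL, AGE_COL, SEX_COL, RACE_COL, HIST_CUM_COL, HIST_INC_COL
    ]
    kinds = [k for _, k in blocks] + ["numeric"] * 2 + ["binary", "binary"] + ["numeric"] * 2
    parts, row_ids, labels = [], [], []
    for t in range(T):
        ids, y = _eligible_with_labels(cohort, t, patient_ids)
        if not ids:
            continue
        n, p_ev = len(ids), len(blocks)
        mat = np.zeros((n, len(cols)))
        for j, (_, kind) in enumerate(blocks):
            if kind == "numeric":
                mat[:, j] = np.nan
        row_pos = {pid: r for r, pid in enumerate(ids)}
        col_pos = {name: j for j, (name, _) in enumerate(blocks)}
        last, pres = eventframe.window_aggregate(*_window_bounds(t))
        _fill_matrix(mat, row_pos, col_pos, last, pres, col_suffix="@prev")
        mat[:, p_ev] = float(t)
        mat[:, p_ev + 1:p_ev + 4] = _demographic_block(cohort, ids, t)
        hist = history_count_features(eventframe, ids, t).set_index("patient_id")
        mat[:, p_ev + 4] = hist.loc[ids, HIST_CUM_COL].to_numpy()
        mat[:, p_ev + 5] = hist.loc[ids, HIST_INC_COL].to_numpy()
        parts.append(mat)
        row_ids += [(pid, t) for pid in ids]
        labels.append(y)
    values = np.vstack(parts) if parts else np.zeros((0, len(cols)))
    X = FeatureMatrix(values=values, columns=cols, kinds=kinds, row_ids=row_ids)
    return LandmarkDataset(
        t=-1, X=X, y=np.concatenate(labels) if labels else np.array([], dtype=int),
        patient_ids=row_ids,
    )


# ---------------------------------------------------------------------------
# sparse-triplet serialization (exact round-trip)
# ---------------------------------------------------------------------------

def write_design(fm: FeatureMatrix, prefix: str) -> None:
    """Write ``<prefix>.triplets.csv``, ``<prefix>.columns.csv`` and
    ``<prefix>.rows.csv``.  Binary zeros and numeric missings are implicit;
    stored values use ``repr`` so floats round-trip exactly."""
    rows, cols, vals = [], [], []
    kinds = np.array(fm.kinds)
    for j in range(fm.values.shape[1]):
        col = fm.values[:, j]
        if kinds[j] == "numeric":
            keep = np.flatnonzero(~np.isnan(col))
        else:
            keep = np.flatnonzero(col != 0)
        rows += list(keep)
        cols += [j] * len(keep)
        vals += [repr(float(v)) for v in col[keep]]
    pd.DataFrame({"row": rows, "col": cols, "value": vals}).to_csv(
        f"{prefix}.triplets.csv", index=False
    )
    pd.DataFrame(
        {"col": range(len(fm.columns)), "name": fm.columns, "kind": fm.kinds}
    ).to_csv(f"{prefix}.columns.csv", index=False)
    pd.DataFrame(
        {"row": range(len(fm.row_ids)), "row_id": [str(r) for r in fm.row_ids]}
    ).to_csv(f"{prefix}.rows.csv", index=False)


def read_design(prefix: str) -> FeatureMatrix:
    trip = pd.read_csv(f"{prefix}.triplets.csv", dtype={"value": str})
    cols = pd.read_csv(f"{prefix}.columns.csv")
    rows = pd.read_csv(f"{prefix}.rows.csv", dtype={"row_id": str})
    n, p = len(rows), len(cols)
    mat = np.zeros((n, p))
    kinds = list(cols["kind"])
    for j, kind in enumerate(kinds):
        if kind == "numeric":
            mat[:, j] = np.nan
    mat[trip["row"].to_numpy(), trip["col"].to_numpy()] = [
        float(v) for v in trip["value"]
    ]
    return FeatureMatrix(
        values=mat,
        columns=list(cols["name"]),
        kinds=kinds,
        row_ids=list(rows["row_id"]),
    )
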