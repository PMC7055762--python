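"""Long-format clinical event tables: schema, validation and CSV round-trip.

One row is one time-stamped clinical fact for one patient:
``(patient_id, day, domain, feature_code, value, modifier, encounter_type)``.
``day`` is an integer day count from a per-table origin (the simulator
anchors day 0 at diabetes onset; real exports may use any origin, phenotyping
re-anchors at the detected onset).  Lab events carry a numeric ``value``;
presence-only (binary) events leave it empty.
"""

from __future__ import annotations

import pandas as pd

from .vocab import ENCOUNTER_TYPES, EVENT_COLUMNS

SCHEMA_VERSION = "1"


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=object),
            "day": pd.Series(dtype="int64"),
            "domain": pd.Series(dtype=object),
            "feature_code": pd.Series(dtype=object),
            "value": pd.Series(dtype="float64"),
            "modifier": pd.Series(dtype=object),
            "encounter_type": pd.Series(dtype=object),
        }
    )


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check column presence/dtypes and normalize ordering.

    Returns a copy sorted by (patient_id, day) with canonical column order,
    which every downstream consumer relies on.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    out = events.loc[:, list(EVENT_COLUMNS)].copy()
    out["day"] = out["day"].astype("int64")
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    bad = ~out["encounter_type"].isin(ENCOUNTER_TYPES) & out["encounter_type"].notna()
    if bad.any():
        raise ValueError(
            f"unknown encounter_type values: {sorted(out.loc[bad, 'encounter_type'].unique())}"
        )
    out["encounter_type"] = out["encounter_type"].fillna("unknown")
    out = out.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)
    return out


def read_event_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    events = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "modifier": str})
    return validate_event_table(events)


def write_event_table(events: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    validate_event_table(events).to_csv(path, sep=sep, index=False)
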