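"""Canonical feature codes shared by the simulator and the phenotyping rules.

Feature codes are opaque strings everywhere else in the package; only the
handful of codes below carry phenotyping semantics (diabetes-defining labs
and medications, kidney-function labs, demographics).  Real event tables can
map their own vocabularies onto these roles through
:class:`landboost.phenotyping.PhenotypeConfig`.
"""

from __future__ import annotations

# --- kidney function -------------------------------------------------------
LAB_CREATININE = "lab:serum_creatinine"  # mg/dL
LAB_ACR = "lab:urine_acr"                # mg/g
LAB_PCR = "lab:urine_pcr"                # mg/g

# --- diabetes definition ---------------------------------------------------
LAB_HBA1C = "lab:hba1c"                  # percent
LAB_GLUCOSE_RANDOM = "lab:glucose_random"    # mg/dL
LAB_GLUCOSE_FASTING = "lab:glucose_fasting"  # mg/dL
MED_GLUCOSE_LOWERING = "med:glucose_lowering"
DX_T2DM = "dx:t2dm"
DX_T1DM = "dx:t1dm"
DX_CF_DM = "dx:cf_related_dm"
MOD_GESTATIONAL = "gestational"

# --- demographics ----------------------------------------------------------
DEMO_AGE = "demo:age"            # numeric value = age in years at event day
DEMO_SEX_FEMALE = "demo:sex_female"  # presence event; absence = male
DEMO_RACE_BLACK = "demo:race_black"  # presence event

DOMAIN_DEMOGRAPHICS = "demographics"
DOMAIN_LABS = "laboratory"

#: columns of the long-format event table, in canonical order
EVENT_COLUMNS = (
    "patient_id",
    "day",
    "domain",
    "feature_code",
    "value",
    "modifier",
    "encounter_type",
)

ENCOUNTER_TYPES = ("inpatient", "outpatient", "unknown")

#: days per yearly landmark window
DAYS_PER_YEAR = 365
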