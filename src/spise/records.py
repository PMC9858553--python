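"""Subject-level data model for the adolescent cohort.

One row per subject; concentrations are fasting serum values. Units are fixed
by the CSV schema and match routine clinical reporting in SI-using labs
(lipids and glucose in mmol/L, insulin in µU/mL, adipokines in ng/mL or
µg/mL). Index formulas that need conventional units (mg/dL) convert
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Optional

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: CSV column order; every loader/writer uses this schema.
COHORT_COLUMNS = [
    "id", "sex", "age", "bmi", "waist", "hip", "sbp", "dbp",
    "glucose", "total_chol", "hdl", "tg", "insulin",
    "adiponectin", "leptin", "resistin", "tnf_alpha", "crp", "apai1",
    "vit_d_25oh",
]

#: Units per column, for documentation and report headers.
UNITS = {
    "age": "years", "bmi": "kg/m^2", "waist": "cm", "hip": "cm",
    "sbp": "mmHg", "dbp": "mmHg",
    "glucose": "mmol/L", "total_chol": "mmol/L", "hdl": "mmol/L",
    "tg": "mmol/L", "insulin": "uU/mL",
    "adiponectin": "ug/mL", "leptin": "ng/mL", "resistin": "ng/mL",
    "tnf_alpha": "pg/mL", "crp": "ug/mL", "apai1": "ng/mL",
    "vit_d_25oh": "nmol/L",
}

AGE_MIN = 10.0
AGE_MAX = 17.0

NUMERIC_COLUMNS = [c for c in COHORT_COLUMNS if c not in ("id", "sex")]


@dataclass
class SubjectRecord:
    """A single adolescent's raw measurements; ``None`` marks a missing value."""

    id: str
    sex: str
    age: Optional[float] = None
    bmi: Optional[float] = None
    waist: Optional[float] = None
    hip: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    glucose: Optional[float] = None
    total_chol: Optional[float] = None
    hdl: Optional[float] = None
    tg: Optional[float] = None
    insulin: Optional[float] = None
    adiponectin: Optional[float] = None
    leptin: Optional[float] = None
    resistin: Optional[float] = None
    tnf_alpha: Optional[float] = None
    crp: Optional[float] = None
    apai1: Optional[float] = None
    vit_d_25oh: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name in NUMERIC_COLUMNS and v is not None:
                if isinstance(v, float) and math.isnan(v):
                    setattr(self, f.name, None)
                elif v <= 0:
                    raise ValueError(f"{f.name} must be positive, got {v}")

    @classmethod
    def from_row(cls, row) -> "SubjectRecord":
        """Build from a mapping (e.g. a pandas row) keyed by schema columns."""
        kwargs = {"id": str(row["id"]), "sex": row["sex"]}
        for c in NUMERIC_COLUMNS:
            v = row.get(c) if hasattr(row, "get") else row[c]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                kwargs[c] = None
            else:
                kwargs[c] = float(v)
        return cls(**kwargs)

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in COHORT_COLUMNS}
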