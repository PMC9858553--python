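"""Cohort CSV reading/writing, validation, and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mets import ThresholdConfig
from .records import AGE_MAX, AGE_MIN, COHORT_COLUMNS, NUMERIC_COLUMNS, SEXES
from .reference import NONGAUSSIAN_VARIABLES

#: soft plausibility bounds (inclusive); outside -> warning, row kept
PLAUSIBLE_RANGES = {
    "bmi": (10, 60), "waist": (40, 160), "hip": (45, 170),
    "sbp": (70, 200), "dbp": (40, 130), "glucose": (2, 30),
    "total_chol": (1, 15), "hdl": (0.2, 5), "tg": (0.1, 15),
    "insulin": (0.5, 300),
}


@dataclass
class ValidationReport:
    """Row-numbered diagnostics from loading a cohort file."""

    n_loaded: int = 0
    rejected: list = field(default_factory=list)   # (row_number, message)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.rejected


def load_cohort(path, enforce_age: bool = True) -> tuple[pd.DataFrame, ValidationReport]:
    """Load and validate a cohort CSV.

    Hard checks (row rejected with a row-numbered diagnostic): unknown sex,
    age outside the 10-17 inclusion range, non-positive measurements. Soft
    checks (warning, row kept): values outside plausibility bounds, unknown
    extra columns. Row numbers refer to the data rows of the file, 1-based.
    """
    report = ValidationReport()
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        report.warnings.append(f"ignoring unknown columns: {extra}")
        df = df[COHORT_COLUMNS]

    for c in NUMERIC_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        rownum = i + 1
        if row["sex"] not in SEXES:
            report.rejected.append((rownum, f"invalid sex {row['sex']!r}"))
            keep[i] = False
            continue
        age = row["age"]
        if enforce_age and not (pd.isna(age) or AGE_MIN <= age <= AGE_MAX):
            report.rejected.append(
                (rownum, f"age {age} outside inclusion range "
                         f"[{AGE_MIN}, {AGE_MAX}]"))
            keep[i] = False
            continue
        bad = [c for c in NUMERIC_COLUMNS
               if not pd.isna(row[c]) and row[c] <= 0]
        if bad:
            report.rejected.append(
                (rownum, f"non-positive value(s) in {bad}"))
            keep[i] = False
            continue
        for c, (lo, hi) in PLAUSIBLE_RANGES.items():
            v = row[c]
            if not pd.isna(v) and not (lo <= v <= hi):
                report.warnings.append(
                    f"row {rownum}: implausible {c}={v} (expected {lo}-{hi})")
    out = df.loc[keep].reset_index(drop=True)
    report.n_loaded = len(out)
    return out, report


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort DataFrame in the canonical column order."""
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    input_path: str = ""
    output_dir: str = "results"
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    reference_source: str = "empirical"    # or a path to a reference CSV
    nongaussian: list = field(default_factory=lambda: list(NONGAUSSIAN_VARIABLES))
    alpha: float = 0.05
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = ThresholdConfig(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path) -> None:
        data = {
            "input_path": self.input_path, "output_dir": self.output_dir,
            "reference_source": self.reference_source,
            "nongaussian": list(self.nongaussian), "alpha": self.alpha,
            "seed": self.seed, "verbosity": self.verbosity,
            "thresholds": vars(self.thresholds),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
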