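"""Pediatric metabolic-syndrome classification (NCEP definition, Cook thresholds).

A subject has MetS when at least 3 of 5 components are present:

* elevated waist circumference: >= age- and sex-specific 90th percentile
* elevated blood pressure: systolic OR diastolic >= 90th percentile
* elevated fasting glucose: >= 6.1 mmol/L
* elevated triglycerides: >= 1.24 mmol/L at age 10-15, >= 1.7 mmol/L at >= 16
* low HDL-cholesterol: <= 1.03 mmol/L

All comparisons are inclusive. The waist/BP percentile reference is derived
empirically from the cohort by default (sex x completed-age-year cells, 90th
percentile by linear interpolation between order statistics), since no
external reference table is bundled; an external table can be loaded instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import SEXES

REQUIRED_FIELDS = ["sex", "age", "waist", "sbp", "dbp", "glucose", "tg", "hdl"]
COMPONENTS = ["elevated_waist", "elevated_bp", "elevated_glucose",
              "elevated_tg", "low_hdl"]


@dataclass
class ThresholdConfig:
    """Component thresholds; defaults are the pediatric (Cook) criteria."""

    glucose_min: float = 6.1        # mmol/L
    tg_min_10_15: float = 1.24      # mmol/L, age < tg_age_break
    tg_min_16plus: float = 1.7      # mmol/L
    hdl_max: float = 1.03           # mmol/L
    waist_percentile: float = 90.0
    bp_percentile: float = 90.0
    mets_min_components: int = 3
    tg_age_break: float = 16.0      # exact age in years
    min_cell_size: int = 10         # smallest (sex, age-year) reference cell

    def __post_init__(self) -> None:
        if not (0 < self.waist_percentile < 100 and 0 < self.bp_percentile < 100):
            raise ValueError("percentiles must lie strictly between 0 and 100")
        if not (1 <= self.mets_min_components <= 5):
            raise ValueError("mets_min_components must be in 1..5")
        for name in ("glucose_min", "tg_min_10_15", "tg_min_16plus", "hdl_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def derive_percentile_reference(cohort: pd.DataFrame,
                                config: ThresholdConfig | None = None) -> pd.DataFrame:
    """Empirical waist/SBP/DBP percentiles per (sex, completed age year).

    Cells with fewer than ``config.min_cell_size`` subjects are pooled with
    adjacent age years, widening the window symmetrically one year at a time
    until the cell fills; a sex stratum too small to fill any cell raises.
    Returns a DataFrame indexed by (sex, age_year) with columns ``waist_p90``,
    ``sbp_p90``, ``dbp_p90``, ``n``, ``pool_window``.
    """
    cfg = config or ThresholdConfig()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    age_year = np.floor(cohort["age"].to_numpy(dtype=float)).astype(int)
    rows = []
    for sex in SEXES:
        sel = cohort["sex"] == sex
        if not sel.any():
            continue
        ages = np.unique(age_year[sel.to_numpy()])
        for a in ages:
            for w in range(0, int(ages.max() - ages.min()) + 1):
                cell = sel.to_numpy() & (np.abs(age_year - a) <= w)
                if cell.sum() >= cfg.min_cell_size:
                    break
            else:
                cell = sel.to_numpy()
                if cell.sum() == 0:
                    raise ValueError(f"cannot fill reference cell ({sex}, {a})")
                w = int(ages.max() - ages.min())
            sub = cohort.loc[cell]
            rows.append({
                "sex": sex, "age_year": int(a),
                "waist_p90": float(np.nanquantile(sub["waist"], cfg.waist_percentile / 100)),
                "sbp_p90": float(np.nanquantile(sub["sbp"], cfg.bp_percentile / 100)),
                "dbp_p90": float(np.nanquantile(sub["dbp"], cfg.bp_percentile / 100)),
                "n": int(cell.sum()), "pool_window": w,
            })
    ref = pd.DataFrame(rows).set_index(["sex", "age_year"]).sort_index()
    ref.attrs["provenance"] = "empirical"
    return ref


def load_reference_csv(path) -> pd.DataFrame:
    """Load an external reference table (columns sex, age_year, waist_p90, sbp_p90, dbp_p90)."""
    ref = pd.read_csv(path)
    required = {"sex", "age_year", "waist_p90", "sbp_p90", "dbp_p90"}
    missing = required - set(ref.columns)
    if missing:
        raise ValueError(f"reference table missing columns {sorted(missing)}")
    ref = ref.set_index(["sex", "age_year"]).sort_index()
    ref.attrs["provenance"] = "external-table"
    return ref


def classify_cohort(cohort: pd.DataFrame, config: ThresholdConfig | None = None,
                    ref: pd.DataFrame | None = None) -> pd.DataFrame:
    """Five component flags, component count and MetS status per subject.

    Subjects with any required field missing, or whose (sex, age-year) cell is
    absent from an externally supplied reference, are marked unclassifiable
    (``classifiable=False``, flags NA) rather than dropped or imputed.
    """
    cfg = config or ThresholdConfig()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if ref is None:
        ref = derive_percentile_reference(cohort, cfg)

    age = cohort["age"].to_numpy(dtype=float)
    age_year = np.floor(age).astype(int)
    key = pd.MultiIndex.from_arrays([cohort["sex"], age_year])
    covered = key.isin(ref.index)
    refvals = ref.reindex(key)
    waist_p90 = refvals["waist_p90"].to_numpy(dtype=float)
    sbp_p90 = refvals["sbp_p90"].to_numpy(dtype=float)
    dbp_p90 = refvals["dbp_p90"].to_numpy(dtype=float)

    complete = np.ones(len(cohort), dtype=bool)
    for f in REQUIRED_FIELDS:
        v = cohort[f]
        complete &= v.notna().to_numpy()
    classifiable = complete & covered

    waist = cohort["waist"].to_numpy(dtype=float)
    sbp = cohort["sbp"].to_numpy(dtype=float)
    dbp = cohort["dbp"].to_numpy(dtype=float)
    glu = cohort["glucose"].to_numpy(dtype=float)
    tg = cohort["tg"].to_numpy(dtype=float)
    hdl = cohort["hdl"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        flags = {
            "elevated_waist": waist >= waist_p90,
            "elevated_bp": (sbp >= sbp_p90) | (dbp >= dbp_p90),
            "elevated_glucose": glu >= cfg.glucose_min,
            "elevated_tg": np.where(age < cfg.tg_age_break,
                                    tg >= cfg.tg_min_10_15,
                                    tg >= cfg.tg_min_16plus),
            "low_hdl": hdl <= cfg.hdl_max,
        }
    out = pd.DataFrame(index=cohort.index)
    for name, arr in flags.items():
        col = pd.array(arr, dtype="boolean")
        col[~classifiable] = pd.NA
        out[name] = col
    n_comp = sum(out[c].astype("Int64") for c in COMPONENTS)
    out["n_components"] = n_comp
    out["mets"] = n_comp >= cfg.mets_min_components
    out["classifiable"] = classifiable
    return out


def prevalence_summary(cohort: pd.DataFrame, profiles: pd.DataFrame) -> dict:
    """MetS and component prevalence, overall and per sex, among classifiable subjects."""
    res: dict = {"n_unclassifiable": int((~profiles["classifiable"]).sum())}
    for label, sel in [("all", np.ones(len(cohort), dtype=bool)),
                       ("male", (cohort["sex"] == "male").to_numpy()),
                       ("female", (cohort["sex"] == "female").to_numpy())]:
        ok = sel & profiles["classifiable"].to_numpy()
        n = int(ok.sum())
        if n == 0:
            warnings.warn(f"no classifiable subjects in stratum {label!r}")
            res[label] = {"n": 0}
            continue
        block = {"n": n,
                 "mets_n": int(profiles.loc[ok, "mets"].sum()),
                 "components": {c: int(profiles.loc[ok, c].sum()) for c in COMPONENTS}}
        block["mets_pct"] = 100.0 * block["mets_n"] / n
        res[label] = block
    return res
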