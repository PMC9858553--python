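"""Unit conversions and surrogate insulin-sensitivity indices.

SPISE (Single Point Insulin Sensitivity Estimator) is a lipid/anthropometry
surrogate of clamp-measured insulin sensitivity:

    SPISE = 600 * HDL^0.185 / (TG^0.2 * BMI^1.338)

with HDL-cholesterol and triglycerides in mg/dL and BMI in kg/m^2; lower
values indicate lower insulin sensitivity. HOMA-IR is the standard fasting
insulin-resistance index, insulin [µU/mL] * glucose [mmol/L] / 22.5. Cohort
data arrive in mmol/L, so SPISE inputs are converted with the molar-mass
factors below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .records import SubjectRecord

#: mg/dL per mmol/L, standard molar-mass conversion factors.
MGDL_PER_MMOL = {
    "cholesterol": 38.67,
    "triglyceride": 88.57,
    "glucose": 18.016,
}

SPISE_COEF = 600.0
SPISE_HDL_EXP = 0.185
SPISE_TG_EXP = 0.2
SPISE_BMI_EXP = 1.338
HOMA_DENOM = 22.5


@dataclass
class IndexConfig:
    """Overridable constants for the index formulas.

    Defaults reproduce the published formulas; overriding is intended for
    sensitivity analyses only.
    """

    chol_factor: float = MGDL_PER_MMOL["cholesterol"]
    tg_factor: float = MGDL_PER_MMOL["triglyceride"]
    glucose_factor: float = MGDL_PER_MMOL["glucose"]
    spise_coef: float = SPISE_COEF
    spise_hdl_exp: float = SPISE_HDL_EXP
    spise_tg_exp: float = SPISE_TG_EXP
    spise_bmi_exp: float = SPISE_BMI_EXP


@dataclass
class IndexPanel:
    """Per-subject surrogate indices; ``None`` where inputs were missing."""

    spise: Optional[float] = None
    homa_ir: Optional[float] = None
    tg_hdl: Optional[float] = None
    adi_lep: Optional[float] = None


def _check_positive(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be finite and strictly positive")


def mmol_to_mgdl(value, analyte: str):
    """Convert mmol/L to mg/dL for cholesterol (incl. HDL), triglyceride or glucose."""
    if analyte not in MGDL_PER_MMOL:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of {sorted(MGDL_PER_MMOL)}")
    _check_positive(value, "value")
    return value * MGDL_PER_MMOL[analyte]


def mgdl_to_mmol(value, analyte: str):
    """Inverse of :func:`mmol_to_mgdl`."""
    if analyte not in MGDL_PER_MMOL:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of {sorted(MGDL_PER_MMOL)}")
    _check_positive(value, "value")
    return value / MGDL_PER_MMOL[analyte]


def compute_spise(hdl_mgdl, tg_mgdl, bmi, config: IndexConfig | None = None):
    """SPISE from HDL [mg/dL], triglycerides [mg/dL] and BMI [kg/m^2].

    Strictly increasing in HDL and decreasing in TG and BMI. Accepts scalars
    or arrays.
    """
    cfg = config or IndexConfig()
    _check_positive(hdl_mgdl, "hdl_mgdl")
    _check_positive(tg_mgdl, "tg_mgdl")
    _check_positive(bmi, "bmi")
    return (cfg.spise_coef * np.power(hdl_mgdl, cfg.spise_hdl_exp)
            / (np.power(tg_mgdl, cfg.spise_tg_exp) * np.power(bmi, cfg.spise_bmi_exp)))


def compute_homa_ir(insulin, glucose):
    """HOMA-IR from fasting insulin [µU/mL] and fasting glucose [mmol/L]."""
    _check_positive(insulin, "insulin")
    _check_positive(glucose, "glucose")
    return insulin * glucose / HOMA_DENOM


def compute_panel(subject: SubjectRecord, config: IndexConfig | None = None) -> IndexPanel:
    """All four indices for one subject; missing inputs give missing entries."""
    cfg = config or IndexConfig()
    panel = IndexPanel()
    if None not in (subject.hdl, subject.tg, subject.bmi):
        panel.spise = float(compute_spise(
            subject.hdl * cfg.chol_factor, subject.tg * cfg.tg_factor,
            subject.bmi, cfg))
    if None not in (subject.insulin, subject.glucose):
        panel.homa_ir = float(compute_homa_ir(subject.insulin, subject.glucose))
    if None not in (subject.tg, subject.hdl):
        panel.tg_hdl = subject.tg / subject.hdl     # unitless on mmol/L scale
    if None not in (subject.adiponectin, subject.leptin):
        # unit-bearing ratio, µg/mL over ng/mL, reported as-is in the field
        panel.adi_lep = subject.adiponectin / subject.leptin
    return panel


def score_cohort(cohort: pd.DataFrame, config: IndexConfig | None = None) -> pd.DataFrame:
    """Vectorized :func:`compute_panel` over a cohort DataFrame.

    Returns a DataFrame indexed like ``cohort`` with columns ``spise``,
    ``homa_ir``, ``tg_hdl`` and ``adi_lep``; NaN marks per-subject missing
    inputs (subjects are never dropped here).
    """
    cfg = config or IndexConfig()
    out = pd.DataFrame(index=cohort.index)
    hdl = cohort["hdl"].to_numpy(dtype=float)
    tg = cohort["tg"].to_numpy(dtype=float)
    bmi = cohort["bmi"].to_numpy(dtype=float)
    ok = np.isfinite(hdl) & np.isfinite(tg) & np.isfinite(bmi) \
        & (hdl > 0) & (tg > 0) & (bmi > 0)
    spise = np.full(len(cohort), np.nan)
    spise[ok] = compute_spise(hdl[ok] * cfg.chol_factor,
                              tg[ok] * cfg.tg_factor, bmi[ok], cfg)
    out["spise"] = spise

    ins = cohort["insulin"].to_numpy(dtype=float)
    glu = cohort["glucose"].to_numpy(dtype=float)
    ok = np.isfinite(ins) & np.isfinite(glu) & (ins > 0) & (glu > 0)
    homa = np.full(len(cohort), np.nan)
    homa[ok] = compute_homa_ir(ins[ok], glu[ok])
    out["homa_ir"] = homa

    with np.errstate(invalid="ignore", divide="ignore"):
        out["tg_hdl"] = np.where((tg > 0) & (hdl > 0), tg / hdl, np.nan)
        adi = cohort["adiponectin"].to_numpy(dtype=float)
        lep = cohort["leptin"].to_numpy(dtype=float)
        out["adi_lep"] = np.where((adi > 0) & (lep > 0), adi / lep, np.nan)
    return out
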