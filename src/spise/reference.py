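"""Published summary statistics from the Arab adolescent validation cohort.

These are the printed tables of the cross-sectional study of 951 Saudi
adolescents (503 boys, 448 girls, ages 10-17) that proposed sex-specific
SPISE cut-offs for pediatric metabolic syndrome. They serve two roles:

* calibration targets for the synthetic cohort generator (sex-stratified
  marginals, MetS/non-MetS contrasts, correlation signs), and
* inputs for reproducing the study's published odds ratios from the printed
  2x2 cell counts.

Gaussian-reported variables carry ``(mean, sd)``; skewed variables carry
``(median, q1, q3)``.
"""

from __future__ import annotations

N_TOTAL = 951
N_BOYS = 503
N_GIRLS = 448
N_METS_TOTAL = 82
N_METS_BOYS = 54
N_METS_GIRLS = 28

#: Overall / per-sex MetS prevalence implied by the counts above.
METS_PREVALENCE = {
    "all": N_METS_TOTAL / N_TOTAL,          # 8.6%
    "male": N_METS_BOYS / N_BOYS,           # 10.7%
    "female": N_METS_GIRLS / N_GIRLS,       # 6.3%
}

#: Published headline ROC results (percent AUC, SPISE <= cutoff rule).
PUBLISHED_ROC = {
    "male": {"auc_pct": 84.1, "cutoff": 6.14, "sens_pct": 72.2, "spec_pct": 83.9},
    "female": {"auc_pct": 90.3, "cutoff": 6.46, "sens_pct": 96.3, "spec_pct": 73.4},
}

# --- sex-stratified marginals (whole-cohort characteristics table) ---------

#: variable -> {"male": params, "female": params}; two-tuples are (mean, sd)
#: for gaussian-reported variables, three-tuples (median, q1, q3) for skewed.
SEX_MARGINALS = {
    "age": {"male": (13.9, 2.2), "female": (13.7, 2.3)},
    "bmi": {"male": (21.4, 6.2), "female": (22.8, 6.3)},
    "waist": {"male": (76.0, 17.0), "female": (74.0, 15.0)},
    "hip": {"male": (86.0, 18.0), "female": (89.0, 16.0)},
    "sbp": {"male": (107.0, 10.0), "female": (106.0, 10.0)},
    "dbp": {"male": (69.0, 8.0), "female": (69.0, 7.0)},
    "total_chol": {"male": (4.2, 0.8), "female": (4.2, 0.8)},
    "hdl": {"male": (0.99, 0.3), "female": (1.1, 0.3)},
    "glucose": {"male": (5.1, 1.0), "female": (5.1, 1.2)},
    "tg": {"male": (0.96, 0.7, 1.3), "female": (0.94, 0.7, 1.3)},
    "insulin": {"male": (10.9, 6.3, 21.3), "female": (12.5, 7.7, 21.4)},
    "adiponectin": {"male": (17.8, 11.0, 27.7), "female": (20.1, 12.8, 29.7)},
    "leptin": {"male": (6.3, 1.8, 22.2), "female": (19.5, 5.4, 38.1)},
    "resistin": {"male": (17.6, 12.1, 23.8), "female": (19.9, 14.8, 27.9)},
    "tnf_alpha": {"male": (9.1, 6.0, 13.2), "female": (7.7, 5.3, 10.6)},
    "crp": {"male": (0.99, 0.3, 3.7), "female": (1.01, 0.3, 4.1)},
    "apai1": {"male": (23.7, 12.9, 34.3), "female": (24.3, 15.3, 34.7)},
    "vit_d_25oh": {"male": (40.9, 29.5, 57.5), "female": (26.4, 17.6, 37.3)},
}

#: Published sex-level SPISE summaries (derived quantity, not simulated
#: directly): mean +/- SD overall and by MetS group.
SPISE_SUMMARY = {
    "male": {"all": (8.95, 3.3), "non_mets": (9.41, 3.2), "mets": (5.53, 2.5)},
    "female": {"all": (8.37, 3.4), "non_mets": (8.64, 3.2), "mets": (4.44, 1.4)},
}

# --- MetS vs non-MetS group contrasts --------------------------------------

#: variable -> sex -> (non_mets_location, mets_location). Locations are means
#: for gaussian-reported variables and medians for skewed ones; used to size
#: the latent-risk loadings of the generator. Variables whose group contrast
#: was reported non-significant carry equal locations (null contrast).
METS_CONTRASTS = {
    "age": {"male": (13.8, 14.7), "female": (13.6, 15.2)},
    "bmi": {"male": (20.7, 27.6), "female": (22.2, 31.9)},
    "adiponectin": {"male": (18.5, 13.1), "female": (20.3, 14.8)},
    "resistin": {"male": (17.5, 17.5), "female": (19.8, 19.8)},   # p=0.96/0.32
    "leptin": {"male": (5.2, 15.7), "female": (18.4, 38.8)},
    "tnf_alpha": {"male": (8.9, 10.9), "female": (7.6, 9.8)},
    "crp": {"male": (0.97, 2.03), "female": (0.98, 5.2)},
    "apai1": {"male": (23.8, 23.8), "female": (24.2, 24.2)},      # p=0.33/0.10
    "vit_d_25oh": {"male": (40.8, 40.8), "female": (27.2, 19.0)}, # boys p=0.35
    "insulin": {"male": (10.1, 28.5), "female": (12.1, 23.9)},
}

# --- correlation panel targets ---------------------------------------------

#: Pearson correlations of SPISE with measured variables (after natural-log
#: transform of the skewed ones), printed for all subjects / boys / girls.
CORRELATION_TARGETS = {
    "adiponectin": {"all": 0.27, "male": 0.22, "female": 0.36},
    "resistin": {"all": -0.14, "male": -0.17, "female": -0.08},
    "leptin": {"all": -0.41, "male": -0.39, "female": -0.43},
    "adi_lep": {"all": 0.49, "male": 0.45, "female": 0.51},
    "tnf_alpha": {"all": 0.06, "male": -0.03, "female": 0.14},
    "crp": {"all": -0.19, "male": -0.24, "female": -0.13},
    "apai1": {"all": -0.04, "male": -0.02, "female": -0.05},
    "vit_d_25oh": {"all": 0.22, "male": 0.13, "female": 0.27},
    "insulin": {"all": -0.40, "male": -0.42, "female": -0.37},
    "homa_ir": {"all": -0.38, "male": -0.41, "female": -0.35},
}

#: Variables the study summarized as median (Q1-Q3) and log-transformed
#: before correlation analysis.
NONGAUSSIAN_VARIABLES = [
    "tg", "insulin", "adiponectin", "leptin", "resistin", "tnf_alpha",
    "crp", "apai1", "vit_d_25oh", "homa_ir", "adi_lep",
]

# --- SPISE-stratified component table (printed 2x2 cell counts) ------------

#: Per sex, per outcome: (a, b, c, d) with a = cases in the SPISE <= cutoff
#: group, b = non-cases there, c = cases in the > cutoff group, d = non-cases
#: there, plus the printed OR and 95% CI. The boys low-HDL row's printed OR
#: (2.51) contradicts its own cell counts (cross-product 7.20) and is flagged
#: as an erratum; the counts are kept, the printed OR is not used as a check.
STRATIFIED_COUNTS = {
    "male": {
        "elevated_waist": {"cells": (52, 51, 10, 339), "or": 34.56,
                           "ci": (16.5, 72.3)},
        "elevated_bp": {"cells": (27, 76, 34, 315), "or": 3.29,
                        "ci": (1.9, 5.8)},
        "elevated_glucose": {"cells": (20, 83, 35, 314), "or": 2.16,
                             "ci": (1.2, 3.9)},
        "elevated_tg": {"cells": (45, 58, 68, 281), "or": 3.21,
                        "ci": (2.1, 5.1)},
        "low_hdl": {"cells": (91, 12, 179, 170), "or": 2.51,
                    "ci": (1.5, 3.6), "erratum": True},
        "mets": {"cells": (39, 64, 15, 334), "or": 13.56, "ci": (7.1, 26.1),
                 "rounding_note": "counts give 13.569 -> 13.57"},
    },
    "female": {
        "elevated_waist": {"cells": (44, 84, 15, 267), "or": 9.32,
                           "ci": (4.9, 17.6)},
        "elevated_bp": {"cells": (29, 99, 32, 250), "or": 2.29,
                        "ci": (1.3, 3.9)},
        "elevated_glucose": {"cells": (24, 104, 19, 263), "or": 3.19,
                             "ci": (1.7, 6.1)},
        "elevated_tg": {"cells": (50, 78, 44, 238), "or": 3.47,
                        "ci": (2.1, 5.6)},
        "low_hdl": {"cells": (83, 45, 129, 153), "or": 2.19, "ci": (1.4, 3.4)},
        "mets": {"cells": (26, 102, 0, 282), "or": None, "ci": None},
    },
}
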