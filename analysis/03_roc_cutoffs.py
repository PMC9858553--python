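#!/usr/bin/env python
"""Step 3: sex-specific SPISE ROC curves and Youden cut-offs.

Reads results/cohort.csv; writes the ROC coordinate tables and
results/cutoffs.json. The published analysis reported SPISE <= 6.14 for boys
(AUC 84.1%) and <= 6.46 for girls (AUC 90.3%).
"""

import json
from pathlib import Path

from spise.indices import score_cohort
from spise.io import load_cohort
from spise.mets import classify_cohort
from spise.roc import sex_stratified_cutoffs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort, _ = load_cohort(OUT / "cohort.csv")
    panels = score_cohort(cohort)
    profiles = classify_cohort(cohort)
    cuts = sex_stratified_cutoffs(cohort, panels, profiles)
    summary = {}
    for sex, r in cuts.items():
        c = r["cutoff"]
        r["roc"].to_frame().round(4).to_csv(
            OUT / f"roc_coordinates_{sex}.tsv", sep="\t", index=False)
        summary[sex] = {"cutoff": round(c.cutoff, 2),
                        "sensitivity_pct": round(100 * c.sensitivity, 1),
                        "specificity_pct": round(100 * c.specificity, 1),
                        "auc_pct": round(100 * c.auc, 1),
                        "youden_j": round(c.youden_j, 3)}
        print(f"{sex}: SPISE <= {c.cutoff:.2f}  sens {100*c.sensitivity:.1f}%  "
              f"spec {100*c.specificity:.1f}%  AUC {100*c.auc:.1f}%")
    (OUT / "cutoffs.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
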