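#!/usr/bin/env python
"""Step 4: SPISE-stratified odds ratios, correlation panel, component trend.

Reads results/cohort.csv and results/cutoffs.json; writes the stratified
odds-ratio table (unadjusted Woolf and age-adjusted logistic), the per-sex
correlation panel of SPISE with the measured variables, and the mean SPISE
by number of MetS components.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from spise.indices import score_cohort
from spise.io import load_cohort
from spise.mets import classify_cohort
from spise.pipeline import SUMMARY_VARIABLES, spise_by_component_count
from spise.reference import NONGAUSSIAN_VARIABLES
from spise.stats import correlation_panel, stratified_component_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort, _ = load_cohort(OUT / "cohort.csv")
    panels = score_cohort(cohort)
    profiles = classify_cohort(cohort)
    cutoffs = {s: v["cutoff"]
               for s, v in json.loads((OUT / "cutoffs.json").read_text()).items()}

    table = stratified_component_table(cohort, panels, profiles, cutoffs)
    table.round(3).to_csv(OUT / "stratified_or_table.tsv", sep="\t", index=False)
    mets_rows = table[table.outcome == "mets"]
    for _, row in mets_rows.iterrows():
        orv = "-" if not row.defined else f"{row['or']:.2f}"
        print(f"{row.sex}: MetS OR (SPISE <= {row.cutoff:.2f}) = {orv}")

    merged = pd.concat([cohort, panels], axis=1)
    rows = []
    for label, sel in [("all", np.ones(len(merged), bool)),
                       ("male", (merged.sex == "male").to_numpy()),
                       ("female", (merged.sex == "female").to_numpy())]:
        sub = merged.loc[sel]
        covs = {v: sub[v] for v in SUMMARY_VARIABLES
                if v != "spise" and v in sub.columns}
        for r in correlation_panel(sub["spise"], covs,
                                   nongaussian_set=set(NONGAUSSIAN_VARIABLES)):
            rows.append({"stratum": label, "variable": r.variable, "r": r.r,
                         "p": r.p, "n": r.n, "log": r.transformed})
    corr = pd.DataFrame(rows)
    corr.round(4).to_csv(OUT / "correlation_panel.tsv", sep="\t", index=False)
    allc = corr[corr.stratum == "all"].set_index("variable")
    for v in ("leptin", "adiponectin", "homa_ir"):
        print(f"r(SPISE, log {v}) = {allc.loc[v, 'r']:+.2f}")

    trend = spise_by_component_count(pd.concat([merged, profiles], axis=1))
    trend.round(3).to_csv(OUT / "spise_by_component_count.tsv", sep="\t",
                          index=False)
    m = trend[trend.stratum == "all"].set_index("components")["spise_mean"]
    print("mean SPISE by components:",
          "  ".join(f"{g}: {m[g]:.2f}" for g in ["0", "1", "2", ">=3"]))


if __name__ == "__main__":
    main()
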