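"""End-to-end analysis pipeline and report writers.

Runs score -> classify -> per-sex ROC/Youden -> SPISE-stratified odds-ratio
table -> correlation panel -> SPISE-by-component-count summary, and writes
TSV/JSON reports plus a plain-text log (seed, library versions, thresholds).
All display rounding lives here, in the formatting layer; computation carries
full precision.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .indices import score_cohort
from .io import RunConfig, load_cohort
from .mets import (classify_cohort, derive_percentile_reference,
                   load_reference_csv, prevalence_summary)
from .roc import sex_stratified_cutoffs
from .stats import compare_groups, correlation_panel, stratified_component_table

SUMMARY_VARIABLES = ["age", "bmi", "waist", "hip", "sbp", "dbp", "total_chol",
                     "hdl", "tg", "glucose", "insulin", "adiponectin",
                     "leptin", "resistin", "tnf_alpha", "crp", "apai1",
                     "vit_d_25oh", "adi_lep", "homa_ir", "spise"]


def _group_summary_table(merged: pd.DataFrame, group_col: str,
                         groups: tuple, nongaussian: list) -> pd.DataFrame:
    """Two-group variable summary with tests, in the style of a cohort
    characteristics table (mean +/- SD or median (Q1-Q3) plus p-value)."""
    rows = []
    for var in SUMMARY_VARIABLES:
        if var not in merged.columns:
            continue
        kind = "nongaussian" if var in nongaussian else "gaussian"
        data = {}
        for g in groups:
            vals = merged.loc[merged[group_col] == g, var].dropna()
            if kind == "nongaussian":
                vals = vals[vals > 0]
            data[str(g)] = vals.to_numpy(dtype=float)
        if any(len(v) < 2 for v in data.values()):
            continue
        res = compare_groups(data, distribution=kind)
        row = {"variable": var, "distribution": kind,
               "statistic": res.statistic, "p": res.p_value}
        for g, s in res.summary.items():
            if kind == "gaussian":
                row[f"{g}"] = f"{s['mean']:.2f} ± {s['sd']:.2f}"
            else:
                row[f"{g}"] = f"{s['median']:.2f} ({s['q1']:.2f}–{s['q3']:.2f})"
            row[f"{g}_n"] = s["n"]
        rows.append(row)
    return pd.DataFrame(rows)


def spise_by_component_count(merged: pd.DataFrame) -> pd.DataFrame:
    """Mean SPISE by number of MetS components (0, 1, 2, >=3), per sex and
    overall; decreasing SPISE across groups is the expected dose-response."""
    ok = merged["classifiable"] & merged["spise"].notna()
    sub = merged.loc[ok].copy()
    grp = np.minimum(sub["n_components"].astype(int), 3)
    sub["component_group"] = grp.map({0: "0", 1: "1", 2: "2", 3: ">=3"})
    rows = []
    for label, sel in [("all", np.ones(len(sub), dtype=bool)),
                       ("male", (sub["sex"] == "male").to_numpy()),
                       ("female", (sub["sex"] == "female").to_numpy())]:
        for g in ["0", "1", "2", ">=3"]:
            vals = sub.loc[sel & (sub["component_group"] == g).to_numpy(), "spise"]
            if len(vals) == 0:
                continue
            rows.append({"stratum": label, "components": g, "n": len(vals),
                         "spise_mean": float(vals.mean()),
                         "spise_sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the bundle as in-memory objects. Any stage failure removes the
    partially written outputs and re-raises with a stage-named message.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_tsv(df: pd.DataFrame, name: str, ndec: int = 4) -> None:
        path = outdir / name
        df.round(ndec).to_csv(path, sep="\t", index=False)
        written.append(path)

    stage = "load"
    try:
        cohort, report = load_cohort(config.input_path)
        if len(cohort) == 0:
            raise ValueError("no valid rows in cohort file")

        stage = "score"
        panels = score_cohort(cohort)

        stage = "classify"
        if config.reference_source == "empirical":
            ref = derive_percentile_reference(cohort, config.thresholds)
        else:
            ref = load_reference_csv(config.reference_source)
        profiles = classify_cohort(cohort, config.thresholds, ref)
        prevalence = prevalence_summary(cohort, profiles)
        merged = pd.concat([cohort, panels, profiles], axis=1)

        stage = "group_tables"
        nong = list(config.nongaussian)
        table_sex = _group_summary_table(merged, "sex", ("male", "female"), nong)
        ok = merged["classifiable"]
        merged_cls = merged.loc[ok].copy()
        merged_cls["mets_group"] = np.where(merged_cls["mets"].astype(bool),
                                            "mets", "non_mets")
        table_mets = _group_summary_table(merged_cls, "mets_group",
                                          ("non_mets", "mets"), nong)

        stage = "roc"
        cuts = sex_stratified_cutoffs(cohort, panels, profiles)
        skipped = [s for s in ("male", "female") if s not in cuts]

        stage = "stratified_or"
        or_table = stratified_component_table(
            cohort, panels, profiles,
            {s: r["cutoff"] for s, r in cuts.items()}, alpha=config.alpha)

        stage = "correlations"
        corr_rows = []
        for label, sel in [("all", np.ones(len(merged), dtype=bool)),
                           ("male", (merged["sex"] == "male").to_numpy()),
                           ("female", (merged["sex"] == "female").to_numpy())]:
            if sel.sum() < 3:
                continue
            sub = merged.loc[sel]
            covs = {v: sub[v] for v in SUMMARY_VARIABLES
                    if v not in ("spise",) and v in sub.columns}
            for res in correlation_panel(sub["spise"], covs,
                                         nongaussian_set=set(nong)):
                corr_rows.append({"stratum": label, "variable": res.variable,
                                  "r": res.r, "p": res.p, "n": res.n,
                                  "log_transformed": res.transformed})
        corr_table = pd.DataFrame(corr_rows)

        stage = "component_trend"
        trend = spise_by_component_count(merged)

        stage = "write"
        _write_tsv(table_sex, "table_sex_comparison.tsv")
        _write_tsv(table_mets, "table_mets_comparison.tsv")
        _write_tsv(corr_table, "table_correlations.tsv")
        _write_tsv(or_table.round(2), "table_stratified_or.tsv", ndec=2)
        _write_tsv(trend, "spise_by_component_count.tsv")
        _write_tsv(ref.reset_index(), "percentile_reference.tsv")
        for sex, r in cuts.items():
            _write_tsv(r["roc"].to_frame(), f"roc_coordinates_{sex}.tsv")
        cut_json = {
            sex: {"cutoff": round(r["cutoff"].cutoff, 2),
                  "sensitivity_pct": round(100 * r["cutoff"].sensitivity, 1),
                  "specificity_pct": round(100 * r["cutoff"].specificity, 1),
                  "auc_pct": round(100 * r["cutoff"].auc, 1),
                  "youden_j": round(r["cutoff"].youden_j, 3)}
            for sex, r in cuts.items()}
        path = outdir / "cutoffs.json"
        path.write_text(json.dumps(
            {"cutoffs": cut_json, "prevalence": prevalence,
             "skipped_strata": skipped}, indent=2))
        written.append(path)
        log = outdir / "run_log.txt"
        log.write_text(
            f"spise {__version__} | python {sys.version.split()[0]} | "
            f"numpy {np.__version__} scipy {scipy.__version__} "
            f"pandas {pd.__version__}\n"
            f"input: {config.input_path}\nseed: {config.seed}\n"
            f"alpha: {config.alpha}\nthresholds: {vars(config.thresholds)}\n"
            f"reference: {config.reference_source}\n"
            f"rows loaded: {report.n_loaded}; rejected: {len(report.rejected)}; "
            f"unclassifiable: {prevalence['n_unclassifiable']}\n"
            f"skipped strata: {skipped}\n")
        written.append(log)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {"cohort": cohort, "validation": report, "panels": panels,
            "profiles": profiles, "prevalence": prevalence, "cutoffs": cuts,
            "or_table": or_table, "correlations": corr_table,
            "table_sex": table_sex, "table_mets": table_mets,
            "component_trend": trend, "reference": ref,
            "skipped_strata": skipped}
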