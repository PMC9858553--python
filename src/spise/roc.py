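"""Direction-aware empirical ROC curves, AUC and Youden-optimal cut-offs.

Built for diagnostic markers whose *low* values indicate disease (SPISE:
candidate rules are "score <= c"), but both directions are supported. AUC is
computed as the tie-corrected Mann-Whitney statistic, which equals the
trapezoidal area under the empirical curve; the Youden cut-off maximizes
J = sensitivity + specificity - 1 over the observed thresholds with a fixed,
documented tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

LOWER_POSITIVE = "lower_positive"
HIGHER_POSITIVE = "higher_positive"


@dataclass
class RocCurve:
    """Empirical ROC coordinates.

    ``thresholds`` are the candidate cut-offs in decision order (loosening
    rule), including a sentinel giving the (sens=0, spec=1) corner; for
    ``lower_positive`` the rule at threshold c is "score <= c positive".
    """

    direction: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int
    #: oriented scores/labels kept for the rank-based AUC
    _scores: np.ndarray = field(repr=False, default=None)
    _labels: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "one_minus_specificity": 1 - self.specificity})


@dataclass
class CutoffResult:
    """Youden-optimal operating point of a ROC curve."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float
    direction: str


def empirical_roc(scores, labels, direction: str = LOWER_POSITIVE) -> RocCurve:
    """ROC curve over the unique observed score values.

    ``labels`` are truthy for positives (diseased). Ties between groups at a
    threshold are counted on the positive side (inclusive rule).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores contain missing/non-finite values")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    if direction not in (LOWER_POSITIVE, HIGHER_POSITIVE):
        raise ValueError(f"unknown direction {direction!r}")

    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    uniq = np.unique(scores)
    if direction == LOWER_POSITIVE:
        thresholds = np.concatenate([[-np.inf], uniq])
        sens = np.searchsorted(pos, thresholds, side="right") / n_pos
        spec = (n_neg - np.searchsorted(neg, thresholds, side="right")) / n_neg
    else:
        thresholds = np.concatenate([[np.inf], uniq[::-1]])
        sens = (n_pos - np.searchsorted(pos, thresholds, side="left")) / n_pos
        spec = np.searchsorted(neg, thresholds, side="left") / n_neg
    return RocCurve(direction=direction, thresholds=thresholds,
                    sensitivity=sens, specificity=spec,
                    n_pos=n_pos, n_neg=n_neg,
                    _scores=scores, _labels=labels)


def auc(roc: RocCurve) -> float:
    """Mann-Whitney AUC with 0.5 credit for between-group ties.

    Oriented by the curve's direction so an informative marker gives
    AUC > 0.5; identical (within 1e-12) to the trapezoidal area under the
    empirical curve.
    """
    s = roc._scores if roc.direction == HIGHER_POSITIVE else -roc._scores
    ranks = rankdata(s)                       # average ranks handle ties
    r_pos = ranks[roc._labels].sum()
    u = r_pos - roc.n_pos * (roc.n_pos + 1) / 2.0
    return float(u / (roc.n_pos * roc.n_neg))


def trapezoidal_auc(roc: RocCurve) -> float:
    """Area under the empirical (FPR, TPR) polygon; cross-check for :func:`auc`."""
    fpr = 1.0 - roc.specificity
    tpr = roc.sensitivity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def youden_optimal(roc: RocCurve) -> CutoffResult:
    """Maximize J = sens + spec - 1 over the curve's observed thresholds.

    Ties in J are broken by (1) higher sensitivity, then (2) the rule
    admitting more subjects as positive (larger cut-off for lower_positive,
    smaller for higher_positive). The sentinel corner is excluded so the
    reported cut-off is always an observed score value.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = None
    for i in range(1, len(roc.thresholds)):      # skip sentinel at index 0
        cand = (j[i], roc.sensitivity[i], i)     # later i == looser rule
        if best is None or cand > best:
            best = cand
    _, _, i = best
    return CutoffResult(cutoff=float(roc.thresholds[i]),
                        sensitivity=float(roc.sensitivity[i]),
                        specificity=float(roc.specificity[i]),
                        youden_j=float(j[i]), auc=auc(roc),
                        direction=roc.direction)


def sex_stratified_cutoffs(cohort: pd.DataFrame, panels: pd.DataFrame,
                           profiles: pd.DataFrame,
                           direction: str = LOWER_POSITIVE) -> dict:
    """Per-sex SPISE ROC/Youden analysis with MetS as the positive class.

    Returns ``{sex: {"cutoff": CutoffResult, "roc": RocCurve}}``; a sex whose
    classifiable subjects are single-class is skipped with a warning.
    """
    results: dict = {}
    for sex in ("male", "female"):
        sel = ((cohort["sex"] == sex).to_numpy()
               & profiles["classifiable"].to_numpy()
               & panels["spise"].notna().to_numpy())
        if sel.sum() == 0:
            warnings.warn(f"no usable subjects for sex {sex!r}; stratum skipped")
            continue
        scores = panels.loc[sel, "spise"].to_numpy(dtype=float)
        labels = profiles.loc[sel, "mets"].to_numpy(dtype=bool)
        try:
            roc = empirical_roc(scores, labels, direction)
        except ValueError as exc:
            warnings.warn(f"sex {sex!r} stratum skipped: {exc}")
            continue
        results[sex] = {"cutoff": youden_optimal(roc), "roc": roc}
    return results
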