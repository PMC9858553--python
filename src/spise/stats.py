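"""Association statistics: odds ratios, logistic fits, group tests, correlations.

The odds-ratio machinery mirrors standard epidemiological practice: the
cross-product estimate from a 2x2 table with a Woolf (log-scale Wald)
confidence interval, and a logistic regression route that reproduces the
closed form for a single binary exposure and supports age adjustment. Group
comparisons and Pearson correlations are thin wrappers over scipy.stats with
the reporting conventions (mean +/- SD vs median (Q1-Q3), log transform of
skewed variables) used in adolescent cardiometabolic studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mets import COMPONENTS


@dataclass
class TwoByTwo:
    """Contingency counts; a = exposed cases, b = exposed non-cases,
    c = unexposed cases, d = unexposed non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer")
            setattr(self, name, int(v))

    def flipped_exposure(self) -> "TwoByTwo":
        return TwoByTwo(self.b, self.a, self.d, self.c)


@dataclass
class EffectEstimate:
    or_value: float
    ci_low: float
    ci_high: float
    alpha: float
    method: str
    defined: bool = True


def odds_ratio(table: TwoByTwo, alpha: float = 0.05,
               haldane: bool = False) -> EffectEstimate:
    """Cross-product OR with Woolf CI: exp(ln OR +/- z * sqrt(sum 1/cell)).

    A zero cell makes the estimate undefined (``defined=False``) unless
    ``haldane`` adds the Haldane-Anscombe 0.5 to every cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if 0 in (a, b, c, d):
        return EffectEstimate(np.nan, np.nan, np.nan, alpha, "woolf", defined=False)
    orv = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    log_or = np.log(orv)
    return EffectEstimate(float(orv), float(np.exp(log_or - z * se)),
                          float(np.exp(log_or + z * se)), alpha, "woolf")


@dataclass
class LogisticFit:
    """IRLS maximum-likelihood logistic fit with Wald inference."""

    params: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int
    message: str = ""
    alpha: float = 0.05

    def odds_ratios(self) -> pd.DataFrame:
        z = sps.norm.ppf(1 - self.alpha / 2)
        return pd.DataFrame({
            "coef": self.params,
            "or": np.exp(self.params),
            "ci_low": np.exp(self.params - z * self.se),
            "ci_high": np.exp(self.params + z * self.se),
        })


def fit_logistic(y, X, max_iter: int = 100, tol: float = 1e-8,
                 alpha: float = 0.05) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    ``X`` must include the intercept column. Convergence requires the score
    (gradient) to fall below ``tol`` in max-norm. Perfect or quasi-perfect
    separation is reported as non-converged with a diagnostic message, never
    silently returned as a finite estimate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("y must be 1-D and X 2-D with matching rows")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("predictor matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    message = ""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        try:
            beta = beta + np.linalg.solve(X.T @ (X * w[:, None]), score)
        except np.linalg.LinAlgError:
            message = "singular information matrix (possible separation)"
            break
        if np.max(np.abs(beta)) > 30:
            message = "diverging coefficients: data are (quasi-)separated"
            break
    # saturated probabilities can zero the score at a huge finite beta;
    # that is separation, not convergence
    if converged and np.max(np.abs(beta)) > 15:
        converged = False
        message = "coefficients diverged before the score vanished: " \
                  "data are (quasi-)separated"
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(p * (1 - p), 1e-12, None)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    if not converged and not message:
        message = f"IRLS did not converge in {max_iter} iterations"
    if not converged:
        warnings.warn(f"logistic fit: {message}")
    return LogisticFit(params=beta, se=se, converged=converged,
                       n_iter=it, message=message, alpha=alpha)


def _table_from_mask(case: np.ndarray, exposed: np.ndarray) -> TwoByTwo:
    return TwoByTwo(int((case & exposed).sum()), int((~case & exposed).sum()),
                    int((case & ~exposed).sum()), int((~case & ~exposed).sum()))


def stratified_component_table(cohort: pd.DataFrame, panels: pd.DataFrame,
                               profiles: pd.DataFrame, cutoffs: dict,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Per-sex prevalence of each MetS component (and MetS itself) in the
    SPISE <= cutoff vs > cutoff strata, with unadjusted (Woolf) and
    age-adjusted (logistic) odds ratios.

    ``cutoffs`` maps sex -> cut-off value (floats or CutoffResult-like
    objects with a ``cutoff`` attribute). Undefined estimates (zero cells,
    non-converged adjusted fits) are reported as NaN with ``defined=False``.
    """
    rows = []
    for sex, cut in cutoffs.items():
        c = float(getattr(cut, "cutoff", cut))
        sel = ((cohort["sex"] == sex).to_numpy()
               & profiles["classifiable"].to_numpy()
               & panels["spise"].notna().to_numpy())
        if sel.sum() == 0:
            rows.append({"sex": sex, "outcome": "all", "defined": False})
            continue
        spise = panels.loc[sel, "spise"].to_numpy(dtype=float)
        exposed = spise <= c
        age = cohort.loc[sel, "age"].to_numpy(dtype=float)
        for outcome in COMPONENTS + ["mets"]:
            case = profiles.loc[sel, outcome].to_numpy(dtype=bool)
            tab = _table_from_mask(case, exposed)
            est = odds_ratio(tab, alpha=alpha)
            row = {
                "sex": sex, "outcome": outcome, "cutoff": c,
                "n_present": tab.a + tab.c,
                "n_low": int(exposed.sum()), "n_high": int((~exposed).sum()),
                "cases_low": tab.a, "cases_high": tab.c,
                "pct_low": 100.0 * tab.a / exposed.sum() if exposed.sum() else np.nan,
                "pct_high": 100.0 * tab.c / (~exposed).sum() if (~exposed).sum() else np.nan,
                "or": est.or_value, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "defined": est.defined,
            }
            # age-adjusted OR via logistic regression: mets ~ exposure + age
            if est.defined:
                Xm = np.column_stack([np.ones(case.size), exposed.astype(float), age])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_logistic(case.astype(float), Xm, alpha=alpha)
                if fit.converged:
                    ors = fit.odds_ratios()
                    row.update({"or_adj": ors.loc[1, "or"],
                                "ci_low_adj": ors.loc[1, "ci_low"],
                                "ci_high_adj": ors.loc[1, "ci_high"]})
                else:
                    row.update({"or_adj": np.nan, "ci_low_adj": np.nan,
                                "ci_high_adj": np.nan})
            else:
                row.update({"or_adj": np.nan, "ci_low_adj": np.nan,
                            "ci_high_adj": np.nan})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    distribution: str
    summary: dict
    statistic: float
    p_value: float


def compare_groups(groups: dict, distribution: str = "gaussian",
                   welch: bool = False) -> GroupComparison:
    """Two-group comparison in the study's reporting style.

    gaussian: mean +/- SD per group, two-sample t test (pooled variance by
    default, Welch by flag). nongaussian: median (Q1-Q3) per group, two-sided
    rank-sum (Mann-Whitney, normal approximation with tie correction).
    categorical: per-group category counts, chi-square without continuity
    correction.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (name1, x1), (name2, x2) = groups.items()
    x1 = np.asarray(x1, dtype=float if distribution != "categorical" else object)
    x2 = np.asarray(x2, dtype=float if distribution != "categorical" else object)
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("both groups must be non-empty")

    if distribution == "gaussian":
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError("need n >= 2 per group for a t test")
        stat, p = sps.ttest_ind(x1, x2, equal_var=not welch)
        summary = {name1: {"mean": float(np.mean(x1)), "sd": float(np.std(x1, ddof=1)), "n": len(x1)},
                   name2: {"mean": float(np.mean(x2)), "sd": float(np.std(x2, ddof=1)), "n": len(x2)}}
    elif distribution == "nongaussian":
        stat_res = sps.mannwhitneyu(x1, x2, alternative="two-sided",
                                    method="asymptotic")
        stat, p = stat_res.statistic, stat_res.pvalue
        def q(x):
            return {"median": float(np.median(x)),
                    "q1": float(np.quantile(x, 0.25)),
                    "q3": float(np.quantile(x, 0.75)), "n": len(x)}
        summary = {name1: q(x1), name2: q(x2)}
    elif distribution == "categorical":
        cats = sorted(set(x1) | set(x2))
        counts = np.array([[np.sum(x1 == c) for c in cats],
                           [np.sum(x2 == c) for c in cats]])
        stat, p, _, _ = sps.chi2_contingency(counts, correction=False)
        summary = {name1: dict(zip(cats, counts[0].tolist())),
                   name2: dict(zip(cats, counts[1].tolist()))}
    else:
        raise ValueError(f"unknown distribution kind {distribution!r}")
    return GroupComparison(distribution=distribution, summary=summary,
                           statistic=float(stat), p_value=float(p))


@dataclass
class CorrelationResult:
    variable: str
    r: float
    p: float
    n: int
    transformed: bool


def correlation_panel(spise, covariates: dict,
                      nongaussian_set=()) -> list[CorrelationResult]:
    """Pearson correlations of SPISE with each covariate.

    Covariates named in ``nongaussian_set`` are natural-log transformed first
    (all values must be positive). Pairwise-complete observations are used;
    p-values are two-sided from the t distribution with n - 2 df.
    """
    spise = np.asarray(spise, dtype=float)
    results = []
    for name, vals in covariates.items():
        v = np.asarray(vals, dtype=float)
        ok = np.isfinite(spise) & np.isfinite(v)
        if name in nongaussian_set:
            ok &= v > 0
        x, y = spise[ok], v[ok]
        if len(x) < 3:
            raise ValueError(f"fewer than 3 complete pairs for {name!r}")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero-variance input for {name!r}")
        if name in nongaussian_set:
            y = np.log(y)
        r, p = sps.pearsonr(x, y)
        results.append(CorrelationResult(variable=name, r=float(r),
                                         p=float(p), n=int(len(x)),
                                         transformed=name in nongaussian_set))
    return results
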