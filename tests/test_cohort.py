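"""Synthetic cohort generator: marginals, copula, latent-risk calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spise.cohort import (SyntheticConfig, VARIABLES, default_config,
                          generate_cohort, lognormal_from_quartiles,
                          nearest_positive_definite, validate_cohort)
from spise.indices import score_cohort
from spise.records import COHORT_COLUMNS
from spise.roc import LOWER_POSITIVE, auc, empirical_roc


class TestLognormalFromQuartiles:
    def test_standard_lognormal(self):
        z = sps.norm.ppf(0.75)
        mu, sigma = lognormal_from_quartiles(1.0, np.exp(-z), np.exp(z))
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(1.0, rel=1e-9)

    def test_leptin_quartiles(self):
        mu, sigma = lognormal_from_quartiles(11.4, 2.5, 31.4)
        assert sigma == pytest.approx(np.log(31.4 / 2.5) / (2 * sps.norm.ppf(0.75)),
                                      rel=1e-12)
        assert sigma == pytest.approx(1.876, abs=0.001)

    def test_ordering_violation(self):
        with pytest.raises(ValueError):
            lognormal_from_quartiles(1.0, 2.0, 3.0)

    def test_monte_carlo_round_trip(self):
        """Sampled median and quartile ratio reproduce the fitted values."""
        mu, sigma = lognormal_from_quartiles(11.4, 2.5, 31.4)
        rng = np.random.default_rng(0)
        x = rng.lognormal(mu, sigma, size=1_000_000)
        assert np.median(x) == pytest.approx(11.4, rel=0.02)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        assert q3 / q1 == pytest.approx(31.4 / 2.5, rel=0.02)
        # the fitted distribution's own theoretical quartiles round-trip
        dist = sps.lognorm(s=sigma, scale=np.exp(mu))
        assert q1 == pytest.approx(dist.ppf(0.25), rel=0.02)
        assert q3 == pytest.approx(dist.ppf(0.75), rel=0.02)


def test_same_seed_identical_cohorts():
    a = generate_cohort(default_config(seed=5, n_total=300, n_male=150))
    b = generate_cohort(default_config(seed=5, n_total=300, n_male=150))
    pd.testing.assert_frame_equal(a.data, b.data)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    c = generate_cohort(default_config(seed=6, n_total=300, n_male=150))
    assert not a.data.equals(c.data)


def test_schema_and_positivity(small_cohort):
    df = small_cohort.data
    assert list(df.columns) == COHORT_COLUMNS
    for var in VARIABLES:
        assert (df[var] > 0).all()
    assert df["age"].between(10, 17).all()
    assert set(df["sex"]) == {"male", "female"}


def test_truth_never_in_export(small_cohort):
    exported = small_cohort.export()
    assert "latent_risk" not in exported.columns
    assert "intended_mets" not in exported.columns


def test_intended_prevalence_binomial(small_cohort):
    """Intended MetS assignment is a binomial draw around the latent target."""
    gen = generate_cohort(default_config(seed=9, n_total=10_000, n_male=5290))
    p_target = (5290 * gen.config.prevalence["male"]
                + 4710 * gen.config.prevalence["female"]) / 10_000
    p_obs = gen.truth["intended_mets"].mean()
    se = np.sqrt(p_target * (1 - p_target) / 10_000)
    assert abs(p_obs - p_target) < 3 * se


def test_null_model_auc_half():
    """With all latent loadings zero the intended group is independent of
    every measurement, so SPISE carries no information about it."""
    cfg = default_config(seed=4, n_total=4000, n_male=2000)
    cfg.loadings = {v: {"male": 0.0, "female": 0.0} for v in VARIABLES}
    gen = generate_cohort(cfg)
    spise = score_cohort(gen.data)["spise"].to_numpy()
    labels = gen.truth["intended_mets"].to_numpy()
    a = auc(empirical_roc(spise, labels, LOWER_POSITIVE))
    n1, n0 = labels.sum(), (~labels).sum()
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(a - 0.5) < 3 * se


def test_copula_rank_correlation_targets():
    """Generated rank correlations track the configured residual structure."""
    gen = generate_cohort(default_config(seed=8, n_total=10_000, n_male=5290))
    df = gen.data
    boys = df[df.sex == "male"]
    for v1, v2, rho in gen.config.residual_correlations:
        lam1 = gen.config.loadings[v1]["male"]
        lam2 = gen.config.loadings[v2]["male"]
        implied = (lam1 * lam2
                   + np.sqrt((1 - lam1 ** 2) * (1 - lam2 ** 2)) * rho)
        observed = sps.spearmanr(boys[v1], boys[v2]).statistic
        # Spearman of the Gaussian copula: (6/pi) arcsin(r/2)
        expected = 6 / np.pi * np.arcsin(implied / 2)
        assert observed == pytest.approx(expected, abs=0.1)


def test_gaussian_marginal_means_within_3se(small_cohort):
    gen = generate_cohort(default_config(seed=2, n_total=10_000, n_male=5290))
    df = gen.data
    for var in ("sbp", "dbp", "total_chol", "glucose"):  # untruncated in practice
        for sex in ("male", "female"):
            mean, sd = gen.config.marginals[var][sex]
            x = df.loc[df.sex == sex, var]
            se = sd / np.sqrt(len(x))
            # 4 SE: truncation at the physiological floor shifts a little
            assert abs(x.mean() - mean) < max(4 * se, 0.02 * mean)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(n_total=100, n_male=200)
    with pytest.raises(ValueError):
        SyntheticConfig(prevalence={"male": 0.0, "female": 0.1})


def test_nearest_positive_definite_projection():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    fixed = nearest_positive_definite(bad)
    assert np.linalg.eigvalsh(fixed).min() > 0
    assert np.allclose(np.diag(fixed), 1.0)
    good = np.eye(3)
    assert np.allclose(nearest_positive_definite(good), good)


def test_validate_cohort_defaults_pass(small_cohort):
    # wider quartile tolerance: the heavy-tailed adipokines (leptin ln-SD
    # ~1.9) make the IQR-ratio estimate noisy at n=900; the n=10^4
    # calibration fidelity check lives in the acceptance suite
    report = validate_cohort(small_cohort, tolerances={"quartile_rel": 0.4})
    failed = report.loc[~report.passed]
    assert failed.empty, failed.to_string()


def test_validate_cohort_flags_miscalibration(small_cohort):
    gen = small_cohort
    broken = gen.data.copy()
    broken["bmi"] = broken["bmi"] + 10           # shift far off target
    from spise.cohort import GeneratedCohort
    rep = validate_cohort(GeneratedCohort(broken, gen.truth, gen.config))
    assert not rep.loc[rep.check == "mean:bmi", "passed"].any()
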