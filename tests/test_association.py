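"""Logistic fitting, bi-allelic Wald tests and the multi-allelic omnibus LRT."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import chi2

from hlafinemap.association import (
    bonferroni_alpha,
    fit_logistic,
    omnibus_test,
    scan,
)
from hlafinemap.association import test_biallelic as biallelic_test
from hlafinemap.dosage_io import group_multiallelic
from simhelpers import make_panel, make_pheno


def test_intercept_only_closed_form():
    y = np.array([1.0] * 60 + [0.0] * 40)
    fit = fit_logistic(y, np.ones((100, 1)))
    assert fit.converged
    assert fit.beta[0] == pytest.approx(np.log(0.6 / 0.4), abs=1e-8)


def test_fit_matches_statsmodels_oracle():
    rng = np.random.default_rng(3)
    n = 200
    X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n), rng.normal(46, 10, n)])
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 - 0.4 * X[:, 1])))).astype(float)
    fit = fit_logistic(y, X)
    oracle = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10)
    np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-7)
    assert fit.loglik == pytest.approx(oracle.llf, abs=1e-8)
    np.testing.assert_allclose(fit.cov, oracle.cov_params(), rtol=1e-5, atol=1e-9)


def test_null_effect_within_three_se():
    rng = np.random.default_rng(7)
    n = 5000
    x = rng.binomial(2, 0.3, n).astype(float)
    y = rng.binomial(1, 0.4, n).astype(float)
    fit = fit_logistic(y, np.column_stack([np.ones(n), x]))
    assert abs(fit.beta[1]) < 3 * fit.se[1]


def test_separation_flagged():
    # dosage perfectly predicts status
    y = np.array([0.0] * 20 + [1.0] * 20)
    x = y.copy()
    fit = fit_logistic(
        y, np.column_stack([np.ones(40), x, np.linspace(30, 60, 40)])
    )
    assert not fit.converged or np.max(np.abs(fit.beta)) > 15


def _biallelic_setup(seed=0, beta=np.log(0.6), n=1500, f=0.4):
    rng = np.random.default_rng(seed)
    x = rng.binomial(2, f, n).astype(float)
    age = rng.normal(46, 12, n)
    gender = rng.integers(0, 2, n).astype(float)
    eta = 0.3 + beta * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    panel = make_panel({"rs1": x, "rs1_copy": x.copy()})
    pheno = make_pheno(y, age, gender)
    return panel, pheno


def test_biallelic_wald_recovers_effect():
    panel, pheno = _biallelic_setup(seed=5)
    r = biallelic_test(panel, pheno, "rs1")
    assert r.converged and r.test == "wald" and r.df == 1
    assert r.ci95[0] <= r.or_ <= r.ci95[1]
    assert r.ci95[0] < 0.6 < r.ci95[1]
    assert 0 < r.p <= 1


def test_biallelic_no_variance_flagged():
    panel = make_panel({"rs_const": np.ones(50)})
    pheno = make_pheno(np.tile([0, 1], 25))
    r = biallelic_test(panel, pheno, "rs_const")
    assert not r.converged and r.p is None
    assert "variance" in r.note


def test_conditioning_on_perfect_copy_non_identifiable():
    panel, pheno = _biallelic_setup(seed=6)
    r = biallelic_test(panel, pheno, "rs1", conditioned_on=["rs1_copy"])
    assert not r.converged and r.p is None
    assert "collinear" in r.note


def test_allele_swap_flips_beta_and_keeps_p():
    panel, pheno = _biallelic_setup(seed=8)
    swapped = make_panel(
        {"rs1": 2.0 - panel.get_dosage("rs1"), "rs1_copy": panel.get_dosage("rs1_copy")}
    )
    r1 = biallelic_test(panel, pheno, "rs1")
    r2 = biallelic_test(swapped, pheno, "rs1")
    assert r2.beta == pytest.approx(-r1.beta, abs=1e-8)
    assert r2.p == pytest.approx(r1.p, rel=1e-6)


def test_wald_and_lrt_asymptotically_agree():
    panel, pheno = _biallelic_setup(seed=9, beta=-0.1, n=2000)
    r = biallelic_test(panel, pheno, "rs1")
    # LRT by two explicit fits on the same rows
    y = pheno["status"].to_numpy(float)
    x = panel.get_dosage("rs1")
    cov = pheno[["age", "gender"]].to_numpy(float)
    full = fit_logistic(y, np.column_stack([np.ones(len(y)), x, cov]))
    null = fit_logistic(y, np.column_stack([np.ones(len(y)), cov]))
    p_lrt = chi2.sf(2 * (full.loglik - null.loglik), 1)
    assert r.p == pytest.approx(p_lrt, rel=0.2)


def _multiallelic_setup(seed=1, n=600, betas=(0.0, 0.0)):
    """Three-residue position; returns panel, pheno, group."""
    rng = np.random.default_rng(seed)
    freqs = np.array([0.5, 0.3, 0.2])
    h1 = rng.choice(3, size=n, p=freqs)
    h2 = rng.choice(3, size=n, p=freqs)
    dos = np.zeros((3, n))
    for h in (h1, h2):
        np.add.at(dos, (h, np.arange(n)), 1.0)
    eta = betas[0] * dos[1] + betas[1] * dos[2]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    panel = make_panel(
        {
            "AA_A_62_30019970_L": dos[0],
            "AA_A_62_30019970_Q": dos[1],
            "AA_A_62_30019970_R": dos[2],
        }
    )
    pheno = make_pheno(y, rng.normal(46, 12, n), rng.integers(0, 2, n).astype(float))
    group = group_multiallelic(panel)[0]
    return panel, pheno, group


def test_omnibus_d_statistic_matches_independent_fits():
    panel, pheno, group = _multiallelic_setup(seed=2, n=20, betas=(0.5, -0.5))
    r = omnibus_test(panel, pheno, group)
    # independent route: statsmodels fits of the full and null models
    y = pheno["status"].to_numpy(float)
    cov = pheno[["age", "gender"]].to_numpy(float)
    # reference residue = most frequent (L at freq 0.5): drop its dosage
    dq = panel.get_dosage("AA_A_62_30019970_Q")
    dr = panel.get_dosage("AA_A_62_30019970_R")
    Xf = np.column_stack([np.ones(20), dq, dr, cov])
    Xn = np.column_stack([np.ones(20), cov])
    llf = sm.Logit(y, Xf).fit(disp=0, method="newton", tol=1e-12).llf
    lln = sm.Logit(y, Xn).fit(disp=0, method="newton", tol=1e-12).llf
    assert r.chi2_stat == pytest.approx(2 * (llf - lln), abs=1e-6)
    assert r.df == 2
    assert r.p == pytest.approx(chi2.sf(2 * (llf - lln), 2), rel=1e-6)


def test_omnibus_reference_choice_does_not_change_p():
    panel, pheno, group = _multiallelic_setup(seed=4, n=400, betas=(0.3, -0.2))
    r = omnibus_test(panel, pheno, group)
    # refit dropping a different member: same LRT because the m dosages sum to 2
    y = pheno["status"].to_numpy(float)
    cov = pheno[["age", "gender"]].to_numpy(float)
    dl = panel.get_dosage("AA_A_62_30019970_L")
    dq = panel.get_dosage("AA_A_62_30019970_Q")
    full = fit_logistic(y, np.column_stack([np.ones(400), dl, dq, cov]))
    null = fit_logistic(y, np.column_stack([np.ones(400), cov]))
    assert r.chi2_stat == pytest.approx(2 * (full.loglik - null.loglik), abs=1e-6)


def test_omnibus_nonnegative_statistic():
    panel, pheno, group = _multiallelic_setup(seed=5)
    r = omnibus_test(panel, pheno, group)
    assert r.chi2_stat >= 0.0


def test_omnibus_degenerate_group_errors():
    n = 50
    panel = make_panel(
        {
            "AA_A_62_30019970_L": np.full(n, 2.0),
            "AA_A_62_30019970_Q": np.zeros(n),
            "AA_A_62_30019970_R": np.zeros(n),
        }
    )
    pheno = make_pheno(np.tile([0, 1], 25))
    group = group_multiallelic(panel)[0]
    with pytest.raises(ValueError, match="degenerate"):
        omnibus_test(panel, pheno, group)


def test_bonferroni_threshold_small_m():
    assert bonferroni_alpha(10) == pytest.approx(5e-3)
    with pytest.raises(ValueError):
        bonferroni_alpha(0)


def test_scan_counts_groups_once(default_cohort):
    _, _, panel, pheno, _ = default_cohort
    sc = scan(panel, pheno)
    n_groups = len(group_multiallelic(panel))
    assert sc.m_tests == panel.n_variants + n_groups
    assert sc.alpha == pytest.approx(0.05 / sc.m_tests)
    df = sc.to_frame()
    assert set(df["test"]) == {"wald", "lrt_omnibus"}


def test_scan_null_panel_rarely_significant():
    # Bonferroni controls family-wise error: significant hits are rare
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        n = 300
        rows = {f"rs{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(25)}
        panel = make_panel(rows)
        pheno = make_pheno(
            rng.binomial(1, 0.5, n), rng.normal(46, 12, n), rng.integers(0, 2, n)
        )
        hits += len(scan(panel, pheno).significant())
    assert hits <= 3  # expected ~0.05 per scan over 20 scans
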