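"""Per-variant association engine for dosage data.

Bi-allelic variants (SNPs, classical alleles, residue presence/absence) are
tested with an additive logistic regression of case-control status on allele
dosage, adjusted for age and gender and for any conditioned-on variants; the
effect is reported as an odds ratio per dosage unit with a Wald 95% CI.

A multi-allelic amino-acid position with m residues is tested jointly with a
likelihood-ratio omnibus test: the full model carries the dosages of m-1
residues (the most frequent residue is the reference and is dropped), the
null model carries covariates only, and

    D = -2 ln(L0 / L1)  ~  chi2 with m-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .dosage_io import DosagePanel, MultiAllelicGroup, group_multiallelic

logger = logging.getLogger(__name__)

Z975 = 1.959964  # normal 97.5% quantile used for all Wald CIs

__all__ = [
    "LogisticFit",
    "AssocResult",
    "ScanResult",
    "fit_logistic",
    "test_biallelic",
    "omnibus_test",
    "scan",
    "bonferroni_alpha",
]


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray  # inverse observed information at the optimum
    loglik: float
    converged: bool
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    loglik_rtol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton iteration (IRLS).

    Converges when the largest score component is below ``score_tol`` or the
    relative log-likelihood change is below ``loglik_rtol``; capped at
    ``max_iter`` iterations.  Diverging coefficients (|beta| > 15 without
    convergence) are the signature of perfect separation and are reported as
    ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    beta = np.zeros(p)
    ll = _loglik(y, X @ beta)
    converged = False
    H = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        score = X.T @ (y - mu)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        H = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving safeguards the monotone likelihood ascent
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break
        beta = cand
        if abs(ll_new - ll) <= loglik_rtol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    else:
        it = max_iter
    if not converged and np.max(np.abs(beta)) > 15.0:
        logger.debug("fit_logistic: divergence suggests perfect separation")
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogisticFit(beta=beta, cov=cov, loglik=ll, converged=converged, n_iter=it)


@dataclass
class AssocResult:
    """One association test result (Wald bi-allelic or omnibus LRT)."""

    marker_id: str
    test: str  # "wald" | "lrt_omnibus"
    beta: float | None
    or_: float | None
    ci95: tuple[float, float] | None
    p: float | None
    df: int
    n_used: int
    converged: bool
    conditioned_on: tuple[str, ...] = ()
    chi2_stat: float | None = None
    eaf_cases: float | None = None
    eaf_controls: float | None = None
    note: str = ""


def _design(
    pheno: pd.DataFrame,
    dosage_cols: Sequence[np.ndarray],
    covars: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-case design matrix: intercept, dosage col(s), covariates."""
    cols = [np.asarray(c, dtype=float) for c in dosage_cols]
    cov = [pheno[c].to_numpy(dtype=float) for c in covars]
    stack = np.column_stack([np.ones(len(pheno))] + cols + cov)
    y = pheno["status"].to_numpy(dtype=float)
    mask = ~np.isnan(stack).any(axis=1)
    return y[mask], stack[mask], mask


def _eaf_by_status(dosage: np.ndarray, status: np.ndarray) -> tuple[float, float]:
    d = np.asarray(dosage, dtype=float)
    ok = ~np.isnan(d)
    cases = ok & (status == 1)
    ctrls = ok & (status == 0)
    f_cases = float(d[cases].mean() / 2.0) if cases.any() else float("nan")
    f_ctrls = float(d[ctrls].mean() / 2.0) if ctrls.any() else float("nan")
    return f_cases, f_ctrls


def test_biallelic(
    panel: DosagePanel,
    pheno: pd.DataFrame,
    marker_id: str,
    conditioned_on: Sequence[str] = (),
    covars: Sequence[str] = ("age", "gender"),
) -> AssocResult:
    """Additive dosage logistic test of one bi-allelic variant.

    Model: status ~ dosage + age + gender + dosages of ``conditioned_on``.
    Wald p from beta/SE; OR and 95% CI as exp(beta -/+ 1.96*SE).  Zero-variance
    dosages and designs made rank-deficient by conditioning are flagged
    (converged=False, p absent) rather than fitted.
    """
    d = panel.get_dosage(marker_id)
    status = pheno["status"].to_numpy()
    eaf_ca, eaf_co = _eaf_by_status(d, status)
    cond_cols = [panel.get_dosage(m) for m in conditioned_on]
    y, X, mask = _design(pheno, [d] + cond_cols, covars)
    base = dict(
        marker_id=marker_id,
        test="wald",
        df=1,
        n_used=int(mask.sum()),
        conditioned_on=tuple(conditioned_on),
        eaf_cases=eaf_ca,
        eaf_controls=eaf_co,
    )
    if np.nanstd(X[:, 1]) < 1e-12:
        return AssocResult(
            beta=None, or_=None, ci95=None, p=None, converged=False,
            note="no dosage variance", **base,
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return AssocResult(
            beta=None, or_=None, ci95=None, p=None, converged=False,
            note="collinear design (non-identifiable)", **base,
        )
    fit = fit_logistic(y, X)
    if not fit.converged:
        return AssocResult(
            beta=float(fit.beta[1]), or_=None, ci95=None, p=None,
            converged=False, note="non-converged fit", **base,
        )
    b, se = fit.beta[1], fit.se[1]
    z2 = (b / se) ** 2 if se > 0 else np.inf
    return AssocResult(
        beta=float(b),
        or_=float(np.exp(b)),
        ci95=(float(np.exp(b - Z975 * se)), float(np.exp(b + Z975 * se))),
        p=float(chi2.sf(z2, 1)),
        converged=True,
        chi2_stat=float(z2),
        **base,
    )


def omnibus_test(
    panel: DosagePanel,
    pheno: pd.DataFrame,
    group: MultiAllelicGroup,
    conditioned_on: Sequence[str] = (),
    covars: Sequence[str] = ("age", "gender"),
) -> AssocResult:
    """Likelihood-ratio omnibus test of a multi-allelic amino-acid position.

    The reference residue (highest mean dosage) is dropped; remaining members
    that leave the design rank-deficient are dropped too, with the degrees of
    freedom reduced accordingly and a note recorded.
    """
    if group.m < 3:
        raise ValueError("omnibus test requires m >= 3 residues")
    member_ids = [v.marker_id for v in group.members]
    dosages = {m: panel.get_dosage(m) for m in member_ids}
    freqs = {m: np.nanmean(dosages[m]) for m in member_ids}
    ref = max(member_ids, key=lambda m: (freqs[m], m))
    candidates = [m for m in member_ids if m != ref]

    cond_cols = [panel.get_dosage(m) for m in conditioned_on]
    # incremental rank screen over member columns
    kept: list[str] = []
    note = ""
    covar_arr = [pheno[c].to_numpy(dtype=float) for c in covars]
    base_cols = [np.ones(len(pheno))] + cond_cols + covar_arr
    for m in candidates:
        trial = np.column_stack(base_cols + [dosages[k] for k in kept] + [dosages[m]])
        ok = ~np.isnan(trial).any(axis=1)
        if np.linalg.matrix_rank(trial[ok]) == trial.shape[1]:
            kept.append(m)
        else:
            note = "rank-deficient member(s) dropped"
            logger.info("omnibus %s: dropped collinear member %s", group.group_id, m)
    if not kept:
        raise ValueError(
            f"degenerate multi-allelic group {group.group_id}: no testable residue"
        )
    y, X_full, mask = _design(pheno, [dosages[m] for m in kept] + cond_cols, covars)
    y0, X_null, _ = _design(pheno, cond_cols, covars)
    # the null fit must use the same complete-case rows as the full fit
    if len(y0) != len(y):
        stack_mask = mask
        cov = np.column_stack(
            [np.ones(len(pheno))] + cond_cols + covar_arr
        )[stack_mask]
        X_null, y0 = cov, y
    fit1 = fit_logistic(y, X_full)
    fit0 = fit_logistic(y0, X_null)
    D = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    df = len(kept)
    return AssocResult(
        marker_id=group.group_id,
        test="lrt_omnibus",
        beta=None,
        or_=None,
        ci95=None,
        p=float(chi2.sf(D, df)),
        df=df,
        n_used=int(len(y)),
        converged=fit1.converged and fit0.converged,
        conditioned_on=tuple(conditioned_on),
        chi2_stat=float(D),
        note=note,
    )


def bonferroni_alpha(m_tests: int, family_alpha: float = 0.05) -> float:
    """Bonferroni-corrected per-test significance threshold 0.05/M."""
    if m_tests < 1:
        raise ValueError("need at least one test")
    return family_alpha / m_tests


@dataclass
class ScanResult:
    """All association results of one conditioned scan of a panel."""

    results: list[AssocResult]
    m_tests: int
    alpha: float
    conditioned_on: tuple[str, ...]

    def biallelic(self) -> list[AssocResult]:
        return [r for r in self.results if r.test == "wald"]

    def significant(self) -> list[AssocResult]:
        return [r for r in self.results if r.p is not None and r.p < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "marker_id": r.marker_id,
                    "test": r.test,
                    "eaf_cases": r.eaf_cases,
                    "eaf_controls": r.eaf_controls,
                    "beta": r.beta,
                    "or": r.or_,
                    "ci_low": r.ci95[0] if r.ci95 else np.nan,
                    "ci_high": r.ci95[1] if r.ci95 else np.nan,
                    "p": r.p,
                    "df": r.df,
                    "chi2": r.chi2_stat,
                    "n_used": r.n_used,
                    "converged": r.converged,
                    "significant": r.p is not None and r.p < self.alpha,
                    "note": r.note,
                }
            )
        return pd.DataFrame(rows)


def scan(
    panel: DosagePanel,
    pheno: pd.DataFrame,
    conditioned_on: Sequence[str] = (),
    covars: Sequence[str] = ("age", "gender"),
    family_alpha: float = 0.05,
) -> ScanResult:
    """Test every variant of a QC-passed panel, conditioned on prior signals.

    Every bi-allelic marker — SNPs, classical alleles, and each residue of a
    multi-allelic position coded Present/Absent — gets a Wald dosage test;
    each multi-allelic position additionally gets one omnibus LRT.  The
    Bonferroni threshold uses M = (bi-allelic markers tested) + (omnibus
    groups), each group counted once.
    """
    cond = set(conditioned_on)
    groups = group_multiallelic(panel)
    results: list[AssocResult] = []
    n_bi = 0
    for meta in panel.variants:
        if meta.marker_id in cond:
            continue
        results.append(
            test_biallelic(panel, pheno, meta.marker_id, conditioned_on, covars)
        )
        n_bi += 1
    n_groups = 0
    for g in groups:
        if any(v.marker_id in cond for v in g.members):
            continue
        try:
            results.append(omnibus_test(panel, pheno, g, conditioned_on, covars))
            n_groups += 1
        except ValueError as exc:
            logger.warning("omnibus skipped for %s: %s", g.group_id, exc)
    m_tests = n_bi + n_groups
    alpha = bonferroni_alpha(m_tests, family_alpha) if m_tests else family_alpha
    return ScanResult(
        results=results,
        m_tests=m_tests,
        alpha=alpha,
        conditioned_on=tuple(conditioned_on),
    )
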