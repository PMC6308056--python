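"""Stepwise forward conditional selection and permutation confirmation.

Selection iterates full conditioned scans of the panel: the most significant
bi-allelic term (residue presence, SNP, or classical allele) below the
significance threshold is added to the covariate set, and scanning repeats
until no remaining variant reaches the threshold.  Multi-allelic omnibus
results are reported in every step's scan table but selection operates on
single dosage terms, which is what conditioning in subsequent models uses.

Permutation testing resamples case-control labels against intact
(dosage, covariate) rows; the permutation p-value is (r + 1) / (n_perm + 1)
where r counts permuted Wald chi-square statistics at least as extreme as
the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssocResult, ScanResult, fit_logistic, scan
from .dosage_io import DosagePanel

logger = logging.getLogger(__name__)

__all__ = ["StepResult", "PermResult", "stepwise_select", "permutation_test"]


@dataclass
class StepResult:
    step_index: int  # 1-based
    selected: str
    p_at_selection: float
    conditioned_on: tuple[str, ...]  # selections made before this step
    scan: ScanResult


@dataclass
class PermResult:
    marker_id: str
    observed_stat: float
    n_perm: int
    n_as_extreme: int

    @property
    def perm_p(self) -> float:
        return (self.n_as_extreme + 1) / (self.n_perm + 1)


def _candidate_key(r: AssocResult) -> tuple[float, float, str]:
    # smaller p wins; ties broken by larger statistic, then lexical id
    return (r.p, -(r.chi2_stat or 0.0), r.marker_id)


def stepwise_select(
    panel: DosagePanel,
    pheno: pd.DataFrame,
    threshold: float | None = None,
    covars: tuple[str, ...] = ("age", "gender"),
    max_steps: int = 25,
) -> list[StepResult]:
    """Forward stepwise conditional selection at a fixed p threshold.

    ``threshold=None`` uses the scan's own Bonferroni level 0.05/M.
    Candidates whose fit is flagged (collinear with prior selections,
    no variance, non-converged) are skipped for that step.
    """
    selected: list[str] = []
    steps: list[StepResult] = []
    for step in range(1, max_steps + 1):
        sc = scan(panel, pheno, conditioned_on=tuple(selected), covars=covars)
        thr = threshold if threshold is not None else sc.alpha
        candidates = [
            r for r in sc.biallelic() if r.converged and r.p is not None
        ]
        n_skipped = sum(1 for r in sc.biallelic() if not r.converged)
        if n_skipped:
            logger.info("step %d: %d candidate(s) skipped as unfittable", step, n_skipped)
        if not candidates:
            break
        best = min(candidates, key=_candidate_key)
        if best.p >= thr:
            break
        steps.append(
            StepResult(
                step_index=step,
                selected=best.marker_id,
                p_at_selection=best.p,
                conditioned_on=tuple(selected),
                scan=sc,
            )
        )
        selected.append(best.marker_id)
    return steps


def permutation_test(
    panel: DosagePanel,
    pheno: pd.DataFrame,
    marker_id: str,
    conditioned_on: tuple[str, ...] = (),
    n_perm: int = 10_000,
    seed: int = 0,
    covars: tuple[str, ...] = ("age", "gender"),
) -> PermResult:
    """Label-permutation test of one variant's Wald chi-square.

    Only the status vector is permuted; dosages and covariates stay attached
    to their rows, so the permutation null preserves the covariate structure
    while breaking the variant-status association.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = panel.get_dosage(marker_id)
    cond = [panel.get_dosage(m) for m in conditioned_on]
    cov = [pheno[c].to_numpy(dtype=float) for c in covars]
    X = np.column_stack([np.ones(len(pheno)), d] + cond + cov)
    y = pheno["status"].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    X, y = X[ok], y[ok]

    def wald_chi2(yv: np.ndarray) -> float:
        if np.std(X[:, 1]) < 1e-12:
            return 0.0
        fit = fit_logistic(yv, X)
        se = fit.se[1]
        if not fit.converged or se <= 0:
            return 0.0
        return float((fit.beta[1] / se) ** 2)

    observed = wald_chi2(y)
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        n_extreme += wald_chi2(rng.permutation(y)) >= observed
    return PermResult(
        marker_id=marker_id,
        observed_stat=observed,
        n_perm=n_perm,
        n_as_extreme=int(n_extreme),
    )
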