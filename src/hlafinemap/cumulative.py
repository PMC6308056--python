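"""Cumulative protective-variant analysis.

Samples are binned by the number of selected protective variants they carry
(carrier = dosage >= 0.5 at a locus, so categories run 0..K over K loci).
Each category is compared with the zero-carrier reference by a crude 2x2
odds ratio with a Woolf confidence interval, and the dose-response across
categories is tested with the Cochran-Armitage trend test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .association import Z975
from .dosage_io import DosagePanel

logger = logging.getLogger(__name__)

__all__ = ["CumulativeTable", "carrier_count", "category_or", "trend_test", "cumulative_analysis"]


@dataclass
class CategoryRow:
    category: int
    n_cases: int
    n_controls: int
    or_: float | None  # None for the reference category
    ci95: tuple[float, float] | None
    p: float | None


@dataclass
class CumulativeTable:
    rows: list[CategoryRow]
    trend_stat: float
    trend_p: float

    def to_frame(self) -> pd.DataFrame:
        n_ca = sum(r.n_cases for r in self.rows)
        n_co = sum(r.n_controls for r in self.rows)
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "n_effective_variants": r.category,
                    "cases": r.n_cases,
                    "cases_pct": 100.0 * r.n_cases / n_ca if n_ca else np.nan,
                    "controls": r.n_controls,
                    "controls_pct": 100.0 * r.n_controls / n_co if n_co else np.nan,
                    "or": r.or_,
                    "ci_low": r.ci95[0] if r.ci95 else np.nan,
                    "ci_high": r.ci95[1] if r.ci95 else np.nan,
                    "p": r.p,
                }
            )
        df = pd.DataFrame(recs)
        df.attrs["trend_stat"] = self.trend_stat
        df.attrs["trend_p"] = self.trend_p
        return df


def carrier_count(
    panel: DosagePanel, selected: list[str], threshold: float = 0.5
) -> pd.Series:
    """Per-sample count of carried protective loci (0..K).

    Carrier at a locus means dosage >= ``threshold`` (expected at least one
    copy after rounding toward carriage).  Samples missing a dosage at any
    selected locus are excluded with a log entry.
    """
    mat = np.vstack([panel.get_dosage(m) for m in selected])
    missing = np.isnan(mat).any(axis=0)
    counts = (mat >= threshold).sum(axis=0)
    s = pd.Series(counts, index=pd.Index(panel.sample_ids, name="sample_id"), dtype=int)
    if missing.any():
        logger.warning(
            "carrier_count: excluded %d sample(s) with missing dosage", int(missing.sum())
        )
        s = s[~missing]
    return s


def category_or(
    cases: np.ndarray, controls: np.ndarray
) -> list[CategoryRow]:
    """Crude per-category odds ratios against the zero-carrier reference.

    OR = (a*d)/(b*c) on the 2x2 (category k vs category 0) table, Woolf CI
    exp(ln OR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d)), two-sided Wald p on
    ln OR.  Any zero cell triggers the Haldane-Anscombe +0.5 correction.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.shape != controls.shape or cases.ndim != 1:
        raise ValueError("cases and controls must be matching 1-d count vectors")
    if cases[0] <= 0 or controls[0] <= 0:
        raise ValueError("reference (zero-carrier) category has no cases or controls")
    ref_ca, ref_co = cases[0], controls[0]
    rows = [
        CategoryRow(
            category=0, n_cases=int(ref_ca), n_controls=int(ref_co),
            or_=None, ci95=None, p=None,
        )
    ]
    for k in range(1, len(cases)):
        a, b, c, d = cases[k], controls[k], ref_ca, ref_co
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = np.log((a * d) / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z2 = (log_or / se) ** 2
        rows.append(
            CategoryRow(
                category=k,
                n_cases=int(cases[k]),
                n_controls=int(controls[k]),
                or_=float(np.exp(log_or)),
                ci95=(
                    float(np.exp(log_or - Z975 * se)),
                    float(np.exp(log_or + Z975 * se)),
                ),
                p=float(chi2.sf(z2, 1)),
            )
        )
    return rows


def trend_test(
    cases: np.ndarray, controls: np.ndarray, scores: np.ndarray | None = None
) -> tuple[float, float]:
    """Cochran-Armitage trend test on a 2 x (K+1) table.

    Returns the signed z statistic and the two-sided p from the chi-square
    tail with one degree of freedom.  Default scores are the integer
    category labels 0..K.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    n_i = cases + controls
    if (n_i > 0).sum() < 2:
        raise ValueError("trend test needs >= 2 nonempty categories")
    s = np.arange(len(cases), dtype=float) if scores is None else np.asarray(scores, float)
    A = cases.sum()
    N = n_i.sum()
    T = float(np.sum(s * (cases * N - n_i * A))) / N
    var = A * (N - A) / N * (np.sum(s**2 * n_i) - np.sum(s * n_i) ** 2 / N) / N
    if var <= 0:
        raise ValueError("degenerate trend table (zero score variance)")
    z = T / np.sqrt(var)
    return float(z), float(chi2.sf(z * z, 1))


def cumulative_analysis(
    panel: DosagePanel,
    pheno: pd.DataFrame,
    selected: list[str],
    threshold: float = 0.5,
) -> CumulativeTable:
    """Full cumulative table: counts, per-category crude ORs, trend test."""
    counts = carrier_count(panel, selected, threshold)
    status = pheno["status"].reindex(counts.index)
    K = len(selected)
    cases = np.array([((counts == k) & (status == 1)).sum() for k in range(K + 1)])
    controls = np.array([((counts == k) & (status == 0)).sum() for k in range(K + 1)])
    rows = category_or(cases, controls)
    stat, p = trend_test(cases, controls)
    return CumulativeTable(rows=rows, trend_stat=stat, trend_p=p)
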