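"""Variant-level quality control for genotype and imputed-dosage data.

Two layers mirror a typical HLA-imputation workflow:

* pre-imputation genotype QC — call rate >= 95%, MAF >= 3%, and
  Hardy-Weinberg exact test in controls at p >= 1e-6;
* post-imputation dosage QC — imputation INFO >= 0.5 and MAF >= 0.01,
  where INFO is the ratio of the observed dosage variance to the variance
  2*f*(1-f) expected under Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosage_io import DosagePanel

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "info_score",
    "dosage_maf",
    "post_imputation_filter",
    "hwe_exact_test",
    "genotype_qc",
]


@dataclass
class QCReport:
    """Per-variant QC metrics with pass/fail and failure reasons."""

    table: pd.DataFrame  # index marker_id; maf, info, call_rate, hwe_p, pass, reasons

    def passed(self) -> pd.Index:
        return self.table.index[self.table["pass"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def info_score(dosages: np.ndarray) -> float:
    """Imputation INFO: observed dosage variance over 2*p*(1-p) under HWE.

    ``p`` is the dosage-based allele frequency mean(d)/2.  The observed
    variance uses the population (divide-by-n) convention; the n vs n-1
    choice shifts INFO by O(1/n) so it is fixed here and documented.
    Monomorphic input (p in {0, 1}) returns 0.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("info_score needs >= 2 non-missing dosages")
    if np.ptp(d) == 0.0:  # constant dosage: zero variance exactly
        return 0.0
    p = d.mean() / 2.0
    expected = 2.0 * p * (1.0 - p)
    if expected <= 0.0:
        return 0.0
    return float(d.var() / expected)  # ddof=0: population variance


def dosage_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency from mean dosage (folded to [0, 0.5])."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no non-missing dosages")
    p = d.mean() / 2.0
    return float(min(p, 1.0 - p))


def post_imputation_filter(
    panel: DosagePanel, info_min: float = 0.5, maf_min: float = 0.01
) -> tuple[DosagePanel, QCReport]:
    """Drop variants with INFO < ``info_min`` or MAF < ``maf_min``."""
    records = []
    keep = np.zeros(panel.n_variants, dtype=bool)
    for i, meta in enumerate(panel.variants):
        row = panel.dosage[i]
        maf = dosage_maf(row)
        info = info_score(row)
        reasons = []
        if info < info_min:
            reasons.append(f"INFO<{info_min}")
        if maf < maf_min:
            reasons.append(f"MAF<{maf_min}")
        keep[i] = not reasons
        records.append(
            {
                "marker_id": meta.marker_id,
                "maf": maf,
                "info": info,
                "call_rate": np.nan,
                "hwe_p": np.nan,
                "pass": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    table = pd.DataFrame.from_records(records).set_index("marker_id")
    return panel.subset_variants(keep), QCReport(table)


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the observed
    configuration (the standard exact-test convention for SNP data).
    """
    n_het = int(n_het)
    n_hom_minor = int(n_hom_minor)
    n_hom_major = int(n_hom_major)
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("no genotypes")
    rare = 2 * min(n_hom_minor, n_hom_major) + n_het  # minor allele copies
    # log-probability of each possible het count, conditional on allele counts
    het_values = list(range(rare % 2, rare + 1, 2))
    logs = []
    for h in het_values:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        lp = (
            h * math.log(2)
            + _lfact(n)
            - _lfact(hom_r)
            - _lfact(h)
            - _lfact(hom_c)
            + _lfact(rare)
            + _lfact(2 * n - rare)
            - _lfact(2 * n)
        )
        logs.append(lp)
    logs = np.array(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs_h = n_het
    p_obs = probs[het_values.index(obs_h)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _lfact(k: int) -> float:
    return math.lgamma(k + 1)


def genotype_qc(
    genotypes: np.ndarray,
    status: np.ndarray,
    marker_ids: list[str] | None = None,
    call_rate_min: float = 0.95,
    maf_min: float = 0.03,
    hwe_p_min: float = 1e-6,
) -> QCReport:
    """Pre-imputation SNP QC on hard genotypes (0/1/2; NaN = missing).

    HWE is tested in controls only; if the cohort has no controls the HWE
    filter is skipped with a warning.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    if genotypes.ndim == 1:
        genotypes = genotypes[None, :]
    status = np.asarray(status)
    is_control = status == 0
    if not is_control.any():
        logger.warning("genotype_qc: no controls present; HWE filter skipped")
    if marker_ids is None:
        marker_ids = [f"m{i}" for i in range(genotypes.shape[0])]
    records = []
    for mid, row in zip(marker_ids, genotypes):
        obs = ~np.isnan(row)
        call_rate = obs.mean()
        g = row[obs]
        maf = min(g.mean() / 2.0, 1.0 - g.mean() / 2.0) if g.size else 0.0
        reasons = []
        if call_rate < call_rate_min:
            reasons.append(f"call_rate<{call_rate_min}")
        if maf < maf_min:
            reasons.append(f"MAF<{maf_min}")
        hwe_p = np.nan
        if is_control.any():
            gc = row[obs & is_control]
            if gc.size:
                counts = np.round(gc).astype(int)
                n2 = int((counts == 2).sum())
                n1 = int((counts == 1).sum())
                n0 = int((counts == 0).sum())
                # orient so the first argument is the minor homozygote
                hwe_p = hwe_exact_test(min(n0, n2), n1, max(n0, n2))
                if hwe_p < hwe_p_min:
                    reasons.append(f"HWE_p<{hwe_p_min}")
        records.append(
            {
                "marker_id": mid,
                "maf": maf,
                "info": np.nan,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "pass": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return QCReport(pd.DataFrame.from_records(records).set_index("marker_id"))
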