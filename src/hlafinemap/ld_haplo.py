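"""Pairwise linkage disequilibrium and EM haplotype-frequency estimation.

Haplotype frequencies over L (possibly multi-allelic) loci are estimated from
unphased hard genotypes by the classical EM over phase configurations: the
E-step weights each individual's compatible haplotype pairs by products of
current frequencies, the M-step re-counts.  The log-likelihood ascends
monotonically; frequencies below a pruning floor are removed at convergence.

Pairwise D' and r-squared for bi-allelic markers are computed from the
two-locus EM haplotype frequencies of the hard-called dosages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .association import Z975, fit_logistic
from .dosage_io import DosagePanel, VariantKind

logger = logging.getLogger(__name__)

__all__ = [
    "HaploFreqSet",
    "LDResult",
    "HaploAssocResult",
    "em_haplotypes",
    "pairwise_ld",
    "haplotype_assoc",
    "hard_call",
    "classical_genotypes",
]

Genotype = tuple[tuple[object, object], ...]  # per-locus unordered allele pair


def _phase_pairs(genotype: Genotype) -> list[tuple[tuple, tuple]]:
    """All distinct unordered haplotype pairs compatible with a genotype.

    The first heterozygous locus is pinned to one orientation, which
    enumerates each unordered pair exactly once (2^(h-1) configurations for
    h heterozygous loci).
    """
    het = [i for i, (a, b) in enumerate(genotype) if a != b]
    if not het:
        hap = tuple(a for a, _ in genotype)
        return [(hap, hap)]
    free = het[1:]
    pairs = []
    for flips in itertools.product((0, 1), repeat=len(free)):
        flip_at = {loc: fl for loc, fl in zip(free, flips)}
        h1, h2 = [], []
        for i, (a, b) in enumerate(genotype):
            if i not in het:
                h1.append(a)
                h2.append(a)
            elif i == het[0] or not flip_at.get(i, 0):
                h1.append(a)
                h2.append(b)
            else:
                h1.append(b)
                h2.append(a)
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


@dataclass
class HaploFreqSet:
    """EM-estimated multi-locus haplotype frequencies."""

    loci: list[str]
    haplotypes: list[tuple[tuple, float]]  # (allele tuple, frequency), freq desc
    loglik: float
    n_em_iters: int
    converged: bool
    included: np.ndarray = field(repr=False)  # indices of individuals used
    loglik_trace: list[float] = field(default_factory=list, repr=False)
    _phase_lists: list[list[tuple[tuple, tuple]]] = field(default_factory=list, repr=False)
    _freqs: dict[tuple, float] = field(default_factory=dict, repr=False)

    def frequency(self, haplotype: tuple) -> float:
        return self._freqs.get(tuple(haplotype), 0.0)

    def expected_copies(self, haplotype: tuple) -> np.ndarray:
        """Posterior expected copy count (0..2) of a haplotype per individual."""
        target = tuple(haplotype)
        out = np.zeros(len(self._phase_lists))
        for k, pairs in enumerate(self._phase_lists):
            weights = np.array(
                [
                    (1.0 if h1 == h2 else 2.0) * self._freqs.get(h1, 0.0) * self._freqs.get(h2, 0.0)
                    for h1, h2 in pairs
                ]
            )
            tot = weights.sum()
            if tot <= 0:
                continue
            copies = np.array(
                [(h1 == target) + (h2 == target) for h1, h2 in pairs], dtype=float
            )
            out[k] = float(weights @ copies / tot)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"haplotype": "-".join(str(a) for a in hap), "frequency": f}
                for hap, f in self.haplotypes
            ]
        )


def em_haplotypes(
    genotypes: list[Genotype | None],
    loci: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    prune: float = 1e-6,
) -> HaploFreqSet:
    """EM haplotype-frequency estimation from unphased genotypes.

    ``genotypes[k]`` is a tuple of per-locus allele pairs, or None (missing
    at any locus) to exclude individual k.  Initialization is the linkage-
    equilibrium product of observed allele frequencies; the run is
    deterministic (no restarts), so for L >= 3 a local optimum is possible.
    """
    if loci is None and genotypes:
        first = next((g for g in genotypes if g is not None), None)
        loci = [f"L{i}" for i in range(len(first) if first else 0)]
    if loci is not None and len(loci) < 2:
        raise ValueError("need >= 2 loci")
    included = np.array([k for k, g in enumerate(genotypes) if g is not None], dtype=int)
    n_missing = len(genotypes) - len(included)
    if n_missing:
        logger.info("em_haplotypes: excluded %d individual(s) with missing genotypes", n_missing)
    used = [genotypes[k] for k in included]
    if not used:
        raise ValueError("no complete genotypes")
    if len({len(g) for g in used}) != 1:
        raise ValueError("inconsistent locus count across genotypes")

    phase_lists = [_phase_pairs(g) for g in used]
    # linkage-equilibrium initialization from observed allele frequencies
    L = len(used[0])
    allele_freq: list[dict] = [{} for _ in range(L)]
    for g in used:
        for i, (a, b) in enumerate(g):
            allele_freq[i][a] = allele_freq[i].get(a, 0.0) + 1.0
            allele_freq[i][b] = allele_freq[i].get(b, 0.0) + 1.0
    for d in allele_freq:
        tot = sum(d.values())
        for a in d:
            d[a] /= tot
    haps = sorted({h for pairs in phase_lists for pair in pairs for h in pair})
    freqs = {
        h: float(np.prod([allele_freq[i][a] for i, a in enumerate(h)])) for h in haps
    }
    z = sum(freqs.values())
    freqs = {h: f / z for h, f in freqs.items()}

    if len(loci) >= 3:
        logger.warning("em_haplotypes: L>=3 without restarts may reach a local optimum")

    n2 = 2.0 * len(used)
    ll_old = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = {h: 0.0 for h in haps}
        ll = 0.0
        for pairs in phase_lists:
            w = np.array(
                [
                    (1.0 if h1 == h2 else 2.0) * freqs[h1] * freqs[h2]
                    for h1, h2 in pairs
                ]
            )
            tot = w.sum()
            ll += np.log(max(tot, 1e-300))
            if tot <= 0:
                continue
            w /= tot
            for (h1, h2), wk in zip(pairs, w):
                counts[h1] += wk
                counts[h2] += wk
        freqs = {h: c / n2 for h, c in counts.items()}
        trace.append(float(ll))
        if ll - ll_old < tol and it > 1:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    kept = {h: f for h, f in freqs.items() if f >= prune}
    z = sum(kept.values())
    kept = {h: f / z for h, f in kept.items()}
    ordered = sorted(kept.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return HaploFreqSet(
        loci=list(loci),
        haplotypes=[(h, float(f)) for h, f in ordered],
        loglik=float(ll_old),
        n_em_iters=it,
        converged=converged,
        included=included,
        loglik_trace=trace,
        _phase_lists=phase_lists,
        _freqs=kept,
    )


def hard_call(
    dosages: np.ndarray, uncertainty: float = 0.1
) -> np.ndarray:
    """Round dosages to 0/1/2 at thresholds 0.5/1.5.

    Values within ``uncertainty`` of a threshold boundary are set missing
    (NaN) rather than forced to a genotype.
    """
    d = np.asarray(dosages, dtype=float)
    g = np.where(d >= 1.5, 2.0, np.where(d >= 0.5, 1.0, 0.0))
    near = (np.abs(d - 0.5) < uncertainty) | (np.abs(d - 1.5) < uncertainty)
    g = np.where(near | np.isnan(d), np.nan, g)
    return g


@dataclass
class LDResult:
    marker_a: str
    marker_b: str
    d_prime: float
    r2: float
    hap_freqs: dict[tuple, float]
    em_loglik: float


def pairwise_ld(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    marker_a: str = "a",
    marker_b: str = "b",
    uncertainty: float = 0.1,
) -> LDResult:
    """D' and r-squared between two bi-allelic markers from hard calls.

    Two-locus haplotype frequencies come from the EM; D = p_AB - p_A p_B,
    D' = |D| / D_max with the sign-dependent bound, r2 = D^2 / (p_A p_a p_B p_b).
    """
    ga = hard_call(dosage_a, uncertainty)
    gb = hard_call(dosage_b, uncertainty)
    genotypes: list[Genotype | None] = []
    for xa, xb in zip(ga, gb):
        if np.isnan(xa) or np.isnan(xb):
            genotypes.append(None)
        else:
            pa = ("A", "A") if xa == 2 else ("A", "a") if xa == 1 else ("a", "a")
            pb = ("B", "B") if xb == 2 else ("B", "b") if xb == 1 else ("b", "b")
            genotypes.append((pa, pb))
    usable = [g for g in genotypes if g is not None]
    if not usable:
        raise ValueError("no usable genotype pairs")
    for i, labels in ((0, {"A", "a"}), (1, {"B", "b"})):
        seen = {a for g in usable for a in g[i]}
        if len(seen) < 2:
            raise ValueError(f"marker {(marker_a, marker_b)[i]!r} is monomorphic")
    hs = em_haplotypes(genotypes, loci=[marker_a, marker_b])
    f = {h: hs.frequency(h) for h in [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]}
    pA = f[("A", "B")] + f[("A", "b")]
    pB = f[("A", "B")] + f[("a", "B")]
    D = f[("A", "B")] - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom if denom > 0 else 0.0
    return LDResult(
        marker_a=marker_a,
        marker_b=marker_b,
        d_prime=float(min(d_prime, 1.0)),
        r2=float(min(r2, 1.0)),
        hap_freqs=f,
        em_loglik=hs.loglik,
    )


@dataclass
class HaploAssocResult:
    haplotype: tuple
    frequency: float
    trend_or: float
    trend_ci95: tuple[float, float]
    trend_p: float
    carrier_or: float
    carrier_ci95: tuple[float, float]
    carrier_p: float
    n_used: int


def haplotype_assoc(
    haploset: HaploFreqSet,
    pheno: pd.DataFrame,
    target: tuple,
    covars: tuple[str, ...] = ("age", "gender"),
) -> HaploAssocResult:
    """Association of one haplotype with case-control status.

    Per-individual expected copies (0..2) of the target haplotype come from
    the EM phase posteriors.  The trend OR is per expected copy (logistic,
    adjusted for age and gender); the carrier OR dichotomizes at expected
    copies >= 0.5.
    """
    target = tuple(target)
    freq = haploset.frequency(target)
    if freq <= 0.0:
        raise ValueError(f"haplotype {target} has zero estimated frequency")
    copies = haploset.expected_copies(target)
    sub = pheno.iloc[haploset.included]
    y = sub["status"].to_numpy(dtype=float)
    cov = [sub[c].to_numpy(dtype=float) for c in covars]

    def _wald(x: np.ndarray) -> tuple[float, tuple[float, float], float]:
        X = np.column_stack([np.ones(len(y)), x] + cov)
        fit = fit_logistic(y, X)
        b, se = fit.beta[1], fit.se[1]
        z2 = (b / se) ** 2 if se > 0 else np.inf
        return (
            float(np.exp(b)),
            (float(np.exp(b - Z975 * se)), float(np.exp(b + Z975 * se))),
            float(chi2.sf(z2, 1)),
        )

    trend_or, trend_ci, trend_p = _wald(copies)
    carrier_or, carrier_ci, carrier_p = _wald((copies >= 0.5).astype(float))
    return HaploAssocResult(
        haplotype=target,
        frequency=freq,
        trend_or=trend_or,
        trend_ci95=trend_ci,
        trend_p=trend_p,
        carrier_or=carrier_or,
        carrier_ci95=carrier_ci,
        carrier_p=carrier_p,
        n_used=len(y),
    )


def classical_genotypes(
    panel: DosagePanel, loci: list[str]
) -> list[Genotype | None]:
    """Per-sample unphased classical-allele pairs across the given loci.

    Four-digit allele dosages are hard-called to integer copies; a sample is
    usable only when its copies sum to exactly 2 at every requested locus.
    """
    per_locus: list[list[tuple[object, object] | None]] = []
    for locus in loci:
        markers = [
            v
            for v in panel.variants
            if v.kind is VariantKind.HLA_ALLELE
            and v.locus == locus
            and v.allele_digits == "four"
        ]
        if not markers:
            raise ValueError(f"no four-digit classical alleles at locus {locus!r}")
        calls = np.vstack([np.round(panel.get_dosage(v.marker_id)) for v in markers])
        pairs: list[tuple[object, object] | None] = []
        for k in range(panel.n_samples):
            col = calls[:, k]
            if np.isnan(col).any() or col.sum() != 2:
                pairs.append(None)
                continue
            pair: list[object] = []
            for v, c in zip(markers, col):
                pair.extend([v.allele_name] * int(c))
            pairs.append((pair[0], pair[1]))
        per_locus.append(pairs)
    out: list[Genotype | None] = []
    for k in range(panel.n_samples):
        cols = [pl[k] for pl in per_locus]
        out.append(None if any(c is None for c in cols) else tuple(cols))
    return out
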