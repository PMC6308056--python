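"""Variance in disease liability explained by a set of variants.

Two routes are provided, because published liability-scale figures for
case-control HLA studies mix them:

* ``h2_observed`` + ``to_liability`` — the observed-scale R^2 of the fitted
  fixed genetic effects, transformed to the liability scale with the
  ascertainment-corrected factor of Lee et al. at a stated population
  prevalence K and sample case fraction P;
* ``threshold_model_h2`` — a direct liability-threshold computation from
  per-variant (frequency, odds ratio) pairs, summing genotype-mean liability
  variances under HWE and linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .association import LogisticFit

__all__ = ["H2Estimate", "h2_observed", "to_liability", "threshold_model_h2"]


@dataclass
class H2Estimate:
    variant_set: str
    h2_observed: float
    h2_liability: float
    prevalence_K: float
    case_fraction_P: float
    method: str  # "lee_transform" | "threshold_model"


def h2_observed(
    fit: LogisticFit, X: np.ndarray, genetic_cols: list[int], y: np.ndarray
) -> float:
    """Observed-scale variance explained by the fitted genetic effects.

    The genetic score is X[:, genetic_cols] @ beta[genetic_cols] (covariates
    excluded); h2_obs is its squared Pearson correlation with the 0/1
    outcome.
    """
    if not fit.converged:
        raise ValueError("h2_observed requires a converged model fit")
    if not genetic_cols:
        raise ValueError("no genetic columns given")
    score = np.asarray(X, dtype=float)[:, genetic_cols] @ fit.beta[genetic_cols]
    if np.std(score) < 1e-15:
        return 0.0
    r = np.corrcoef(score, np.asarray(y, dtype=float))[0, 1]
    return float(r * r)


def to_liability(h2_obs: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale transformation under ascertainment.

    h2_liab = h2_obs * [K(1-K)/z^2] * [K(1-K)/(P(1-P))], where z is the
    standard-normal density at the liability threshold t with upper-tail
    mass K.  Linear in h2_obs.
    """
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise ValueError("K and P must lie in (0, 1)")
    t = norm.isf(K)
    z = norm.pdf(t)
    return float(h2_obs * (K * (1 - K) / z**2) * (K * (1 - K) / (P * (1 - P))))


def threshold_model_h2(variants: list[tuple[float, float]], K: float) -> float:
    """Liability variance explained by independent variants under a
    liability-threshold model.

    Each variant is (effect-allele frequency f, per-copy odds ratio).  HWE
    genotype frequencies are combined with genotype risks satisfying
    odds_g = odds_0 * OR^g, with the baseline odds solved (Brent root find)
    so the marginal prevalence is K.  Each genotype's mean liability is
    T - t_g with t_g the genotype-specific threshold and T the population
    threshold; the variance of these means, summed across variants, is the
    liability-scale h2 (linkage equilibrium assumed).
    """
    if not (0.0 < K < 1.0):
        raise ValueError("K must lie in (0, 1)")
    total = 0.0
    T = norm.isf(K)
    for f, or_ in variants:
        if not (0.0 < f < 1.0):
            raise ValueError(f"frequency {f} outside (0, 1)")
        if or_ <= 0.0:
            raise ValueError(f"odds ratio {or_} must be positive")
        w = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        orv = np.array([1.0, or_, or_**2])

        def marginal(log_odds0: float) -> float:
            odds = np.exp(log_odds0) * orv
            return float(w @ (odds / (1 + odds))) - K

        lo, hi = np.log(K / (1 - K)) - 20, np.log(K / (1 - K)) + 20
        log_odds0 = brentq(marginal, lo, hi, xtol=1e-13)
        odds = np.exp(log_odds0) * orv
        risks = odds / (1 + odds)
        t_g = norm.isf(risks)
        mu = T - t_g  # genotype mean liability relative to population
        mean_mu = float(w @ mu)
        total += float(w @ (mu - mean_mu) ** 2)
    return total
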