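"""EM haplotype estimation, pairwise LD, haplotype association."""

import itertools

import numpy as np
import pytest

from hlafinemap.ld_haplo import (
    em_haplotypes,
    haplotype_assoc,
    hard_call,
    pairwise_ld,
)
from simhelpers import make_pheno


def _draw_genotypes(hap_freqs: dict[tuple, float], n: int, rng) -> list:
    haps = list(hap_freqs)
    p = np.array([hap_freqs[h] for h in haps])
    idx = rng.choice(len(haps), size=(n, 2), p=p)
    out = []
    for i1, i2 in idx:
        h1, h2 = haps[i1], haps[i2]
        out.append(tuple((a, b) for a, b in zip(h1, h2)))
    return out


def test_phase_known_equals_direct_counting():
    # doubly homozygous individuals: phase is known, EM = counting
    genotypes = (
        [((("A"), ("A")), (("B"), ("B")))] * 6
        + [((("a"), ("a")), (("b"), ("b")))] * 4
    )
    hs = em_haplotypes(genotypes)
    assert hs.frequency(("A", "B")) == pytest.approx(0.6, abs=1e-9)
    assert hs.frequency(("a", "b")) == pytest.approx(0.4, abs=1e-9)


def test_em_recovers_known_two_locus_frequencies():
    truth = {
        ("A", "B"): 0.4,
        ("A", "b"): 0.3,
        ("a", "B"): 0.2,
        ("a", "b"): 0.1,
    }
    rng = np.random.default_rng(12)
    genotypes = _draw_genotypes(truth, 200, rng)
    hs = em_haplotypes(genotypes)
    for hap, f in truth.items():
        assert hs.frequency(hap) == pytest.approx(f, abs=0.05)


def test_em_loglik_monotone():
    truth = {("A", "B"): 0.35, ("A", "b"): 0.15, ("a", "B"): 0.15, ("a", "b"): 0.35}
    genotypes = _draw_genotypes(truth, 100, np.random.default_rng(5))
    hs = em_haplotypes(genotypes)
    trace = np.array(hs.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-12)
    assert hs.converged
    assert sum(f for _, f in hs.haplotypes) == pytest.approx(1.0, abs=1e-8)


def test_em_matches_simplex_grid_search():
    """Two-locus EM agrees with brute-force ML over the haplotype simplex."""
    rng = np.random.default_rng(8)
    truth = {("A", "B"): 0.45, ("A", "b"): 0.1, ("a", "B"): 0.15, ("a", "b"): 0.3}
    genotypes = _draw_genotypes(truth, 30, rng)
    hs = em_haplotypes(genotypes, tol=1e-12)

    # genotype class counts: (nA, nB) copies of A and B alleles per individual
    classes: dict[tuple[int, int], int] = {}
    for g in genotypes:
        na = sum(1 for a in g[0] if a == "A")
        nb = sum(1 for b in g[1] if b == "B")
        classes[(na, nb)] = classes.get((na, nb), 0) + 1

    def loglik(p):  # p = (pAB, pAb, paB, pab) arrays, shape (m, 4)
        pAB, pAb, paB, pab = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
        probs = {
            (2, 2): pAB**2,
            (2, 1): 2 * pAB * pAb,
            (2, 0): pAb**2,
            (1, 2): 2 * pAB * paB,
            (1, 1): 2 * pAB * pab + 2 * pAb * paB,
            (1, 0): 2 * pAb * pab,
            (0, 2): paB**2,
            (0, 1): 2 * paB * pab,
            (0, 0): pab**2,
        }
        ll = np.zeros(len(p))
        for cls, cnt in classes.items():
            ll += cnt * np.log(np.maximum(probs[cls], 1e-300))
        return ll

    def grid(center, width, step):
        axes = [np.arange(max(0.0, c - width), min(1.0, c + width) + step / 2, step) for c in center[:3]]
        pts = np.array(
            [
                (a, b, c, 1 - a - b - c)
                for a, b, c in itertools.product(*axes)
                if a + b + c <= 1.0 + 1e-12
            ]
        )
        pts[:, 3] = np.clip(pts[:, 3], 0.0, 1.0)
        return pts[np.argmax(loglik(pts))]

    coarse = grid((0.5, 0.5, 0.5), 0.5, 0.01)
    best = grid(coarse, 0.012, 0.0005)
    em = np.array(
        [hs.frequency(h) for h in [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]]
    )
    np.testing.assert_allclose(em, best, atol=1e-3)
    assert hs.loglik >= loglik(best[None, :])[0] - 1e-6


def test_missing_genotypes_excluded():
    genotypes = [
        (("A", "a"), ("B", "b")),
        None,
        (("A", "A"), ("B", "B")),
    ]
    hs = em_haplotypes(genotypes)
    assert list(hs.included) == [0, 2]


def test_hard_call_uncertain_zone():
    d = np.array([0.0, 0.45, 0.55, 1.0, 1.44, 1.56, 2.0])
    g = hard_call(d)
    assert np.isnan(g[1]) and np.isnan(g[2]) and np.isnan(g[4]) and np.isnan(g[5])
    assert g[0] == 0 and g[3] == 1 and g[6] == 2


def test_complete_ld_pair():
    # only AB and ab haplotypes, equal frequency
    a = np.array([2.0, 2.0, 0.0, 0.0, 1.0, 1.0] * 20)
    b = a.copy()
    ld = pairwise_ld(a, b)
    assert ld.d_prime == pytest.approx(1.0, abs=1e-6)
    assert ld.r2 == pytest.approx(1.0, abs=1e-6)


def test_independent_loci_low_r2():
    rng = np.random.default_rng(3)
    a = rng.binomial(2, 0.4, 5000).astype(float)
    b = rng.binomial(2, 0.3, 5000).astype(float)
    ld = pairwise_ld(a, b)
    assert ld.r2 < 0.01


def test_missing_haplotype_gives_dprime_one_r2_below():
    # three haplotypes present (Ab absent), unequal allele frequencies
    truth = {("A", "B"): 0.3, ("a", "B"): 0.3, ("a", "b"): 0.4}
    genotypes = _draw_genotypes(truth, 2000, np.random.default_rng(9))
    a = np.array([sum(1.0 for x in g[0] if x == "A") for g in genotypes])
    b = np.array([sum(1.0 for x in g[1] if x == "B") for g in genotypes])
    ld = pairwise_ld(a, b)
    assert ld.d_prime == pytest.approx(1.0, abs=0.05)
    assert ld.r2 < 0.9


def test_ld_invariant_to_label_swap():
    rng = np.random.default_rng(4)
    truth = {("A", "B"): 0.4, ("A", "b"): 0.2, ("a", "B"): 0.1, ("a", "b"): 0.3}
    genotypes = _draw_genotypes(truth, 1000, rng)
    a = np.array([sum(1.0 for x in g[0] if x == "A") for g in genotypes])
    b = np.array([sum(1.0 for x in g[1] if x == "B") for g in genotypes])
    ld1 = pairwise_ld(a, b)
    ld2 = pairwise_ld(2.0 - a, b)
    assert ld2.d_prime == pytest.approx(ld1.d_prime, abs=1e-6)
    assert ld2.r2 == pytest.approx(ld1.r2, abs=1e-6)


def test_monomorphic_ld_errors():
    with pytest.raises(ValueError, match="monomorphic"):
        pairwise_ld(np.zeros(100), np.tile([0.0, 1.0], 50))


def _three_locus_assoc(beta: float, target, seed=0, n=2500):
    rng = np.random.default_rng(seed)
    freqs = {
        ("A*11:01", "B*13:01", "DQB1*03:01"): 0.15,
        ("A*02:01", "B*46:01", "DQB1*05:02"): 0.35,
        ("A*24:02", "B*40:01", "DQB1*03:03"): 0.30,
        ("A*33:03", "B*58:01", "DQB1*02:01"): 0.20,
    }
    genotypes = _draw_genotypes(freqs, n, rng)
    # _draw_genotypes keeps the drawn haplotype order, so zipping the
    # per-locus pairs reconstructs the true phased haplotypes
    copies = np.array(
        [
            sum(
                1
                for hap in zip(*[g[i] for i in range(3)])
                if hap == target
            )
            for g in genotypes
        ],
        dtype=float,
    )
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + beta * copies)))).astype(int)
    pheno = make_pheno(y, rng.normal(46, 12, n), rng.integers(0, 2, n))
    hs = em_haplotypes(genotypes, loci=["A", "B", "DQB1"])
    return hs, pheno


def test_haplotype_assoc_recovers_planted_or():
    target = ("A*11:01", "B*13:01", "DQB1*03:01")
    hs, pheno = _three_locus_assoc(np.log(0.5), target, seed=6)
    r = haplotype_assoc(hs, pheno, target)
    assert 0.4 < r.trend_or < 0.62
    assert r.trend_p < 1e-6


def test_haplotype_assoc_null_haplotype_near_one():
    target = ("A*11:01", "B*13:01", "DQB1*03:01")
    null_hap = ("A*24:02", "B*40:01", "DQB1*03:03")
    hs, pheno = _three_locus_assoc(np.log(0.5), target, seed=7)
    r = haplotype_assoc(hs, pheno, null_hap)
    assert r.trend_ci95[0] < 1.1 and r.trend_ci95[1] > 0.9


def test_haplotype_assoc_absent_haplotype_errors():
    target = ("A*11:01", "B*13:01", "DQB1*03:01")
    hs, pheno = _three_locus_assoc(0.0, target, seed=8, n=300)
    with pytest.raises(ValueError, match="zero"):
        haplotype_assoc(hs, pheno, ("A*99:99", "B*13:01", "DQB1*03:01"))
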