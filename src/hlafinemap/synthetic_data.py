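"""Generator of imputed-HLA case-control cohorts with known truth.

Individuals are built from two multi-locus haplotypes of classical 4-digit
HLA alleles.  A deterministic allele dictionary translates each classical
allele into its amino-acid residues and tag-SNP alleles, so residue,
classical-allele and SNP dosages are exact functions of the phased alleles —
this reproduces the tight LD between a classical allele and the residues it
carries that fine-mapping has to disentangle.  Disease status follows an
additive logistic model on true allele counts plus age and gender; cases and
controls are collected by rejection sampling until the ascertainment quotas
are met.  Optional imputation noise shrinks dosages toward 2f and jitters
them so that the realized INFO score matches a target.

Default cohort conditions: 1583 cases / 972 controls and four planted
protective presence effects with per-copy odds ratios 0.57, 0.52, 0.64 and
0.64 at population frequencies ~0.40, 0.18, 0.38 and 0.19 — one per locus
(A, C-region SNP, DRB1, B), so the planted signals are statistically
independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dosage_io import (
    CohortPheno,
    DosagePanel,
    PRESENCE_ALLELES,
    VariantMeta,
    parse_marker_id,
)
from .qc import info_score

__all__ = [
    "LocusModel",
    "AlleleDictionary",
    "PopulationModel",
    "DiseaseModel",
    "TruthRecord",
    "default_panel",
    "table1_disease_model",
    "aa_marker_id",
    "simulate_cohort",
    "add_imputation_noise",
]


@dataclass(frozen=True)
class LocusModel:
    """One HLA locus: its 4-digit alleles and their residue/SNP content."""

    locus: str
    alleles: tuple[str, ...]  # 4-digit names, e.g. "A*11:01"
    residues: dict[int, dict[str, str]]  # aa position -> allele -> residue
    snps: dict[str, dict[str, str]]  # snp id -> allele -> base
    genomic_base: int

    def two_digit_group(self, allele: str) -> str:
        return allele.split(":")[0]


@dataclass(frozen=True)
class AlleleDictionary:
    """Per-locus translation tables from classical alleles to markers."""

    loci: dict[str, LocusModel]

    def locus_names(self) -> list[str]:
        return sorted(self.loci)


@dataclass
class PopulationModel:
    """Per-locus classical-allele frequencies plus inter-locus coupling.

    ``coupled_haplotypes`` lists multi-locus haplotypes (total over loci) with
    their frequencies; the residual probability mass is distributed at linkage
    equilibrium using the residual per-locus frequencies, so per-locus
    marginals equal ``locus_freqs`` exactly.
    """

    locus_freqs: dict[str, dict[str, float]]
    coupled_haplotypes: list[tuple[dict[str, str], float]] = field(default_factory=list)
    n_background_snps: int = 40
    background_maf_range: tuple[float, float] = (0.05, 0.5)

    def validate(self) -> None:
        for locus, freqs in self.locus_freqs.items():
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{locus}: allele frequencies sum to {total}, not 1")
            if any(f < 0 or f > 1 for f in freqs.values()):
                raise ValueError(f"{locus}: frequency outside [0,1]")
        mass = sum(f for _, f in self.coupled_haplotypes)
        if mass > 1.0 + 1e-12:
            raise ValueError("coupled haplotype frequencies exceed 1")
        for locus, freqs in self.locus_freqs.items():
            for allele in freqs:
                if self._residual(locus, allele) < -1e-12:
                    raise ValueError(
                        f"coupling exceeds marginal frequency of {allele} at {locus}"
                    )

    def _residual(self, locus: str, allele: str) -> float:
        used = sum(
            f for hap, f in self.coupled_haplotypes if hap.get(locus) == allele
        )
        return self.locus_freqs[locus][allele] - used


@dataclass
class DiseaseModel:
    """Additive log-odds disease model with ascertainment quotas.

    ``effects`` plant per-copy log-odds on markers (by marker id); the
    intercept is chosen for a workable marginal case rate under case-control
    sampling (odds ratios are invariant to outcome-dependent ascertainment,
    which is what the pipeline estimates).
    """

    effects: list[tuple[str, float]] = field(default_factory=list)
    beta_age: float = 0.0
    beta_gender: float = 0.0
    intercept: float = 0.0
    n_cases: int = 1583
    n_controls: int = 972

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("ascertainment quotas must be positive")
        for marker, beta in self.effects:
            if not math.isfinite(beta):
                raise ValueError(f"non-finite effect for {marker}")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort."""

    sample_ids: list[str]
    loci: list[str]
    haplotypes: np.ndarray  # (n_samples, n_loci, 2) of classical allele names
    true_dosage: np.ndarray  # integer truth, aligned with the emitted panel
    marker_ids: list[str]
    prob_case: np.ndarray


# ---------------------------------------------------------------------------
# default translation panel


def aa_marker_id(adict: AlleleDictionary, locus: str, pos: int, residue: str) -> str:
    lm = adict.loci[locus]
    return f"AA_{locus}_{pos}_{lm.genomic_base + 3 * pos}_{residue}"


def default_panel() -> tuple[AlleleDictionary, PopulationModel]:
    """Default 4-locus HLA panel (A, B, C, DRB1).

    Each locus carries 4 classical alleles, 6-7 modeled amino-acid positions
    (at least one with >= 3 residues) and a tag SNP.  The designated residues
    Gln-62 (A), Glu-45 (B), Phe-67 (DRB1) and the rs2894207 G allele are each
    carried by exactly one 4-digit allele, at frequencies bracketing the
    effect-allele frequencies seen in south-Chinese case-control data.
    """

    def locus(name, alleles, base, residues, snps):
        return LocusModel(
            locus=name,
            alleles=tuple(alleles),
            residues={
                pos: dict(zip(alleles, pattern)) for pos, pattern in residues.items()
            },
            snps={
                sid: dict(zip(alleles, pattern)) for sid, pattern in snps.items()
            },
            genomic_base=base,
        )

    a = locus(
        "A",
        ["A*11:01", "A*02:01", "A*24:02", "A*33:03"],
        30018310,
        {
            -16: "GGSS",
            9: "YFFS",
            44: "RRKK",
            62: "QRRE",
            77: "DNND",
            95: "LIIL",
            156: "QRWL",
        },
        {"rs2860580": "TCCC"},
    )
    b = locus(
        "B",
        ["B*13:01", "B*46:01", "B*40:01", "B*58:01"],
        31429628,
        {
            -16: "LVVL",
            9: "YHHY",
            45: "ETTK",
            67: "CYYM",
            97: "RSSW",
            116: "LSSF",
        },
        {"rs3869062": "TCCC"},
    )
    c = locus(
        "C",
        ["C*01:02", "C*03:04", "C*07:02", "C*08:01"],
        31344505,
        {
            -21: "MMVV",
            9: "YFFS",
            66: "NKKN",
            99: "CSSY",
            116: "FLLS",
            156: "WRRR",
        },
        {"rs2894207": "GAAA"},
    )
    drb1 = locus(
        "DRB1",
        ["DRB1*11:01", "DRB1*09:01", "DRB1*12:02", "DRB1*15:01"],
        32654525,
        {
            11: "SDDP",
            13: "SFFR",
            26: "FLLY",
            67: "FIIL",
            71: "RKKA",
            74: "AEEQ",
        },
        {"rs28421666": "AGGG"},
    )
    adict = AlleleDictionary(loci={m.locus: m for m in (a, b, c, drb1)})
    pop = PopulationModel(
        locus_freqs={
            "A": dict(zip(a.alleles, [0.40, 0.25, 0.20, 0.15])),
            "B": dict(zip(b.alleles, [0.19, 0.30, 0.26, 0.25])),
            "C": dict(zip(c.alleles, [0.18, 0.35, 0.27, 0.20])),
            "DRB1": dict(zip(drb1.alleles, [0.38, 0.25, 0.20, 0.17])),
        },
        coupled_haplotypes=[
            (
                {"A": "A*11:01", "B": "B*13:01", "C": "C*01:02", "DRB1": "DRB1*11:01"},
                0.03,
            )
        ],
    )
    pop.validate()
    return adict, pop


def table1_disease_model(
    adict: AlleleDictionary, n_cases: int = 1583, n_controls: int = 972
) -> DiseaseModel:
    """Four planted protective effects of fine-mapping magnitude.

    Per-copy odds ratios 0.57 (A Gln-62), 0.52 (rs2894207 G), 0.64
    (DRB1 Phe-67) and 0.64 (B Glu-45), one per locus.
    """
    return DiseaseModel(
        effects=[
            (aa_marker_id(adict, "A", 62, "Q"), math.log(0.57)),
            ("rs2894207", math.log(0.52)),
            (aa_marker_id(adict, "DRB1", 67, "F"), math.log(0.64)),
            (aa_marker_id(adict, "B", 45, "E"), math.log(0.64)),
        ],
        n_cases=n_cases,
        n_controls=n_controls,
    )


# ---------------------------------------------------------------------------
# marker emission / translation


def _locus_markers(lm: LocusModel) -> tuple[list[VariantMeta], list[tuple[str, str]], np.ndarray]:
    """Markers emitted for one locus plus the translation matrix.

    The translation matrix C has one row per marker and one column per
    classical allele; marker dosage = C @ allele copy counts.  Positions with
    exactly two residues emit a single presence marker (the alphabetically
    first residue); positions with >= 3 residues emit one presence marker per
    residue, so member dosages sum to 2 per sample.
    """
    n_all = len(lm.alleles)
    metas: list[VariantMeta] = []
    alleles: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []

    for pos in sorted(lm.residues):
        table = lm.residues[pos]
        observed = sorted(set(table.values()))
        if len(observed) < 2:
            continue
        emit = observed if len(observed) >= 3 else observed[:1]
        for res in emit:
            metas.append(parse_marker_id(aa_marker_id_from(lm, pos, res)))
            alleles.append(PRESENCE_ALLELES)
            rows.append(
                np.array([1.0 if table[a] == res else 0.0 for a in lm.alleles])
            )
    for i, allele in enumerate(lm.alleles):
        digits = allele.split("*")[1].replace(":", "")
        metas.append(parse_marker_id(f"HLA_{lm.locus}_{digits}"))
        alleles.append(PRESENCE_ALLELES)
        rows.append(np.eye(n_all)[i])
    groups = sorted({lm.two_digit_group(a) for a in lm.alleles})
    for grp in groups:
        digits = grp.split("*")[1]
        metas.append(parse_marker_id(f"HLA_{lm.locus}_{digits}"))
        alleles.append(PRESENCE_ALLELES)
        rows.append(
            np.array(
                [1.0 if lm.two_digit_group(a) == grp else 0.0 for a in lm.alleles]
            )
        )
    for sid in sorted(lm.snps):
        table = lm.snps[sid]
        bases = sorted(set(table.values()))
        if len(bases) < 2:
            continue
        effect = table[lm.alleles[0]]
        other = next(b for b in bases if b != effect)
        metas.append(parse_marker_id(sid))
        alleles.append((effect, other))
        rows.append(
            np.array([1.0 if table[a] == effect else 0.0 for a in lm.alleles])
        )
    return metas, alleles, np.vstack(rows)


def aa_marker_id_from(lm: LocusModel, pos: int, residue: str) -> str:
    return f"AA_{lm.locus}_{pos}_{lm.genomic_base + 3 * pos}_{residue}"


# ---------------------------------------------------------------------------
# cohort simulation


def _sample_haplotypes(
    pop: PopulationModel, loci: list[str], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n haplotypes; returns (n, n_loci) array of allele-index ints."""
    allele_order = {l: sorted(pop.locus_freqs[l]) for l in loci}
    out = np.empty((n, len(loci)), dtype=np.int64)
    coupled = pop.coupled_haplotypes
    mass = np.array([f for _, f in coupled] + [0.0])
    mass[-1] = 1.0 - mass[:-1].sum()
    choice = rng.choice(len(mass), size=n, p=mass)
    residual_idx = len(mass) - 1
    for j, locus in enumerate(loci):
        order = allele_order[locus]
        res_freqs = np.array([pop._residual(locus, a) for a in order])
        res_freqs = np.clip(res_freqs, 0.0, None)
        res_freqs /= res_freqs.sum()
        # residual-mass rows keep their linkage-equilibrium draw
        out[:, j] = rng.choice(len(order), size=n, p=res_freqs)
        for ci, (hap, _) in enumerate(coupled):
            out[choice == ci, j] = order.index(hap[locus])
    del residual_idx
    return out


def simulate_cohort(
    adict: AlleleDictionary,
    pop: PopulationModel,
    disease: DiseaseModel,
    seed: int,
    max_draw_factor: int = 500,
) -> tuple[DosagePanel, list[CohortPheno], TruthRecord]:
    """Simulate a case-control cohort of truth (noise-free) dosages.

    Two haplotypes per individual are drawn from the population model; age is
    N(46, 12) truncated at 18, gender Bernoulli(0.5); status follows the
    additive logistic model; rejection sampling runs until both quotas are
    filled.  Fully reproducible by seed.
    """
    pop.validate()
    disease.validate()
    rng = np.random.default_rng(seed)
    loci = adict.locus_names()
    allele_order = {l: sorted(pop.locus_freqs[l]) for l in loci}

    metas: list[VariantMeta] = []
    alleles: list[tuple[str, str]] = []
    trans: list[tuple[int, slice, np.ndarray]] = []  # (locus idx, marker rows, C)
    for j, locus in enumerate(loci):
        lm = adict.loci[locus]
        # translation matrix columns follow the sorted allele order used below
        m, al, C = _locus_markers(lm)
        perm = [lm.alleles.index(a) for a in allele_order[locus]]
        rows = slice(len(metas), len(metas) + len(m))
        metas.extend(m)
        alleles.extend(al)
        trans.append((j, rows, C[:, perm]))

    n_bg = pop.n_background_snps
    lo, hi = pop.background_maf_range
    bg_freqs = rng.uniform(lo, hi, size=n_bg)
    bg_ids = [f"rs9{100000 + i}" for i in range(n_bg)]

    effect_ids = [m for m, _ in disease.effects]
    marker_index = {meta.marker_id: i for i, meta in enumerate(metas)}
    for m in effect_ids:
        if m not in marker_index and m not in bg_ids:
            raise KeyError(f"planted effect marker {m!r} not produced by the panel")

    need = {1: disease.n_cases, 0: disease.n_controls}
    got: dict[int, list[tuple[np.ndarray, np.ndarray, float, int, float]]] = {0: [], 1: []}
    total_target = disease.n_cases + disease.n_controls
    max_draws = max_draw_factor * total_target
    drawn = 0
    batch = max(512, total_target // 2)
    while (len(got[1]) < need[1] or len(got[0]) < need[0]) and drawn < max_draws:
        b = batch
        drawn += b
        h1 = _sample_haplotypes(pop, loci, b, rng)
        h2 = _sample_haplotypes(pop, loci, b, rng)
        age = rng.normal(46.0, 12.0, size=b)
        while (age < 18.0).any():  # truncate by redraw
            bad = age < 18.0
            age[bad] = rng.normal(46.0, 12.0, size=int(bad.sum()))
        gender = rng.integers(0, 2, size=b)
        # translate to dosages
        dosage = np.empty((len(metas), b))
        for j, rows, C in trans:
            counts = np.zeros((C.shape[1], b))
            for hap in (h1, h2):
                np.add.at(counts, (hap[:, j], np.arange(b)), 1.0)
            dosage[rows, :] = C @ counts
        bg = rng.binomial(2, bg_freqs[:, None], size=(n_bg, b)).astype(float)
        eta = np.full(b, disease.intercept)
        for m, beta in disease.effects:
            if m in marker_index:
                eta += beta * dosage[marker_index[m]]
            else:
                eta += beta * bg[bg_ids.index(m)]
        eta += disease.beta_age * age + disease.beta_gender * gender
        prob = 1.0 / (1.0 + np.exp(-eta))
        status = rng.random(b) < prob
        for s in (1, 0):
            room = need[s] - len(got[s])
            if room <= 0:
                continue
            take = np.flatnonzero(status == bool(s))[:room]
            for k in take:
                got[s].append(
                    (
                        np.stack([h1[k], h2[k]], axis=1),  # (n_loci, 2)
                        np.concatenate([dosage[:, k], bg[:, k]]),
                        float(age[k]),
                        int(gender[k]),
                        float(prob[k]),
                    )
                )
    if len(got[1]) < need[1] or len(got[0]) < need[0]:
        raise RuntimeError(
            "ascertainment quota unreachable within draw budget; "
            "adjust the disease-model intercept toward a workable case rate"
        )

    records = got[1] + got[0]
    statuses = [1] * need[1] + [0] * need[0]
    n = len(records)
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    all_metas = metas + [parse_marker_id(s) for s in bg_ids]
    all_alleles = alleles + [("A", "B")] * n_bg
    dosage_mat = np.column_stack([r[1] for r in records])
    haplos = np.stack([r[0] for r in records])  # (n, n_loci, 2)
    hap_names = np.empty(haplos.shape, dtype=object)
    for j, locus in enumerate(loci):
        order = allele_order[locus]
        for a_idx, name in enumerate(order):
            hap_names[..., j, :][haplos[:, j, :] == a_idx] = name

    panel = DosagePanel(
        sample_ids=sample_ids,
        variants=all_metas,
        dosage=dosage_mat,
        alleles=all_alleles,
    )
    pheno = [
        CohortPheno(sample_id=sid, status=st, age=r[2], gender=r[3])
        for sid, st, r in zip(sample_ids, statuses, records)
    ]
    truth = TruthRecord(
        sample_ids=sample_ids,
        loci=loci,
        haplotypes=hap_names,
        true_dosage=dosage_mat.copy(),
        marker_ids=[m.marker_id for m in all_metas],
        prob_case=np.array([r[4] for r in records]),
    )
    return panel, pheno, truth


# ---------------------------------------------------------------------------
# imputation noise


def add_imputation_noise(
    panel: DosagePanel, target_info: float, seed: int
) -> DosagePanel:
    """Degrade truth dosages so the realized INFO score matches a target.

    Per variant: dosage = lambda * truth + (1 - lambda) * 2f + sigma * eps
    with eps ~ N(0, 1), sigma = 0.2 * (1 - lambda), clipped into [0, 2];
    lambda is tuned by bisection against the realized (recomputed) INFO.
    The construction shrinks toward the mean dosage 2f, so per-variant allele
    frequencies are preserved up to clipping effects.  ``target_info=1``
    returns the panel unchanged.
    """
    if target_info <= 0.0 or target_info > 1.0:
        raise ValueError("target_info must be in (0, 1]")
    out = DosagePanel(
        sample_ids=list(panel.sample_ids),
        variants=list(panel.variants),
        dosage=panel.dosage.copy(),
        alleles=list(panel.alleles),
    )
    if target_info == 1.0:
        return out
    rng = np.random.default_rng(seed)
    for i in range(panel.n_variants):
        truth = panel.dosage[i]
        ok = ~np.isnan(truth)
        t = truth[ok]
        if t.size < 2 or np.ptp(t) == 0:
            continue
        f = t.mean() / 2.0
        eps = rng.standard_normal(t.size)

        def realized(lam: float) -> float:
            sigma = 0.2 * (1.0 - lam)
            d = np.clip(lam * t + (1.0 - lam) * 2.0 * f + sigma * eps, 0.0, 2.0)
            return info_score(d)

        lo_l, hi_l = 0.0, 1.0
        if realized(1.0) <= target_info:
            lam = 1.0
        else:
            for _ in range(50):
                mid = 0.5 * (lo_l + hi_l)
                if realized(mid) < target_info:
                    lo_l = mid
                else:
                    hi_l = mid
            lam = 0.5 * (lo_l + hi_l)
        sigma = 0.2 * (1.0 - lam)
        noisy = np.clip(lam * t + (1.0 - lam) * 2.0 * f + sigma * eps, 0.0, 2.0)
        row = out.dosage[i]
        row[ok] = noisy
    return out
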