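"""Shared builders for test cohorts and small fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from hlafinemap.dosage_io import DosagePanel, parse_marker_id
from hlafinemap.synthetic_data import (
    AlleleDictionary,
    DiseaseModel,
    LocusModel,
    PopulationModel,
)


def make_panel(rows: dict[str, np.ndarray], sample_ids: list[str] | None = None) -> DosagePanel:
    """Panel from a marker_id -> dosage-vector mapping."""
    ids = list(rows)
    if ids:
        mat = np.vstack([np.asarray(rows[m], dtype=float) for m in ids])
    else:
        mat = np.empty((0, 0))
    n = mat.shape[1]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return DosagePanel(
        sample_ids=sample_ids,
        variants=[parse_marker_id(m) for m in ids],
        dosage=mat,
    )


def make_pheno(
    status: np.ndarray, age: np.ndarray | None = None, gender: np.ndarray | None = None
) -> pd.DataFrame:
    n = len(status)
    if age is None:
        age = np.full(n, 46.0)
    if gender is None:
        gender = np.zeros(n)
    return pd.DataFrame(
        {"status": np.asarray(status), "age": age, "gender": gender},
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )


def single_locus_panel() -> tuple[AlleleDictionary, PopulationModel]:
    """Trimmed one-locus model (HLA-A analog) for fast replicate studies."""
    lm = LocusModel(
        locus="A",
        alleles=("A*11:01", "A*02:01", "A*24:02", "A*33:03"),
        residues={
            62: dict(zip(("A*11:01", "A*02:01", "A*24:02", "A*33:03"), "QRRE")),
            9: dict(zip(("A*11:01", "A*02:01", "A*24:02", "A*33:03"), "YFFS")),
        },
        snps={},
        genomic_base=30018310,
    )
    pop = PopulationModel(
        locus_freqs={"A": dict(zip(lm.alleles, [0.40, 0.25, 0.20, 0.15]))},
        coupled_haplotypes=[],
        n_background_snps=0,
    )
    return AlleleDictionary(loci={"A": lm}), pop


def gln62_effect_model(
    beta: float, n_cases: int = 1583, n_controls: int = 972
) -> DiseaseModel:
    return DiseaseModel(
        effects=[("AA_A_62_30018496_Q", beta)],
        n_cases=n_cases,
        n_controls=n_controls,
    )


def dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    ok = ~(np.isnan(a) | np.isnan(b))
    if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return 0.0
    return float(np.corrcoef(a[ok], b[ok])[0, 1] ** 2)
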