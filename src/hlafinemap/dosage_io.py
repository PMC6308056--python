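"""Reading, writing and parsing of SNP2HLA/Beagle-dialect dosage data.

The dosage dialect is one marker per row::

    <marker_id> <alleleA> <alleleB> <dosage per sample ...>

with dosages in [0, 2] counting copies of alleleA (the first allele column),
``NA`` marking a missing value, and a companion sample file holding one sample
id per line (optionally ``FID IID``; the last token is used).

Marker ids encode three kinds of variant:

* ``AA_<locus>_<pos>_<genomic>[_<residue>]`` — an amino-acid polymorphism,
  e.g. ``AA_A_62_30019970_Q`` (presence of Gln at HLA-A position 62).
  Positions may be negative (leader peptide).  The residue suffix is absent in
  the bi-allelic form of the dialect, where the two residues sit in the allele
  columns instead.
* ``HLA_<locus>_<digits>`` — a classical allele at 2-digit (allele group) or
  4-digit (protein) resolution, e.g. ``HLA_DQB1_0301`` = DQB1*03:01.
* ``SNP_<locus>_<genomic>``, ``rs...`` or anything else — a bi-allelic SNP.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PRESENCE_ALLELES = ("P", "A")  # Present / Absent coding for AA and HLA markers

__all__ = [
    "VariantKind",
    "VariantMeta",
    "DosagePanel",
    "CohortPheno",
    "MultiAllelicGroup",
    "MarkerParseError",
    "DosageFormatError",
    "parse_marker_id",
    "format_marker_id",
    "read_dosage",
    "write_dosage",
    "read_pheno",
    "align",
    "group_multiallelic",
]


class MarkerParseError(ValueError):
    """A marker id does not follow the SNP2HLA dialect."""


class DosageFormatError(ValueError):
    """A dosage/sample/phenotype file violates the format contract."""


class VariantKind(str, Enum):
    SNP = "SNP"
    AA = "AA"
    HLA_ALLELE = "HLA_ALLELE"


@dataclass(frozen=True)
class VariantMeta:
    """Typed identity of one marker, parsed from its id.

    ``aa_position`` may be negative (positions in the leader peptide, e.g.
    -16 in HLA-B).  Genomic positions are 1-based.
    """

    marker_id: str
    kind: VariantKind
    locus: str = "intergenic"
    aa_position: int | None = None
    genomic_position: int | None = None
    residue: str | None = None
    allele_digits: str | None = None  # "two" | "four"
    allele_name: str | None = None

    def __post_init__(self) -> None:
        if self.kind is VariantKind.AA and self.aa_position is None:
            raise MarkerParseError(f"AA marker without position: {self.marker_id}")
        if self.kind is VariantKind.HLA_ALLELE and (
            self.allele_digits is None or self.allele_name is None
        ):
            raise MarkerParseError(f"HLA marker without allele: {self.marker_id}")


_AA_RE = re.compile(r"^AA_([A-Z0-9]+)_(-?\d+)_(\d+)(?:_([A-Za-z]+|x))?$")
_HLA_RE = re.compile(r"^HLA_([A-Z0-9]+)_(\d+)$")
_SNP_RE = re.compile(r"^SNP_([A-Z0-9]+)_(\d+)$")


def parse_marker_id(marker_id: str) -> VariantMeta:
    """Classify a marker id into a :class:`VariantMeta`.

    Round-trips: ``format_marker_id(parse_marker_id(m)) == m`` for every
    well-formed id of any kind.
    """
    if not marker_id:
        raise MarkerParseError("empty marker id")
    if marker_id.startswith("AA_"):
        m = _AA_RE.match(marker_id)
        if m is None:
            raise MarkerParseError(f"malformed amino-acid marker id: {marker_id!r}")
        locus, pos, gpos, residue = m.groups()
        return VariantMeta(
            marker_id=marker_id,
            kind=VariantKind.AA,
            locus=locus,
            aa_position=int(pos),
            genomic_position=int(gpos),
            residue=residue,
        )
    if marker_id.startswith("HLA_"):
        m = _HLA_RE.match(marker_id)
        if m is None:
            raise MarkerParseError(f"malformed classical-allele marker id: {marker_id!r}")
        locus, digits = m.groups()
        if len(digits) == 2:
            return VariantMeta(
                marker_id=marker_id,
                kind=VariantKind.HLA_ALLELE,
                locus=locus,
                allele_digits="two",
                allele_name=f"{locus}*{digits}",
            )
        if len(digits) == 4:
            return VariantMeta(
                marker_id=marker_id,
                kind=VariantKind.HLA_ALLELE,
                locus=locus,
                allele_digits="four",
                allele_name=f"{locus}*{digits[:2]}:{digits[2:]}",
            )
        raise MarkerParseError(
            f"classical-allele id must carry 2 or 4 digits: {marker_id!r}"
        )
    m = _SNP_RE.match(marker_id)
    if m is not None:
        locus, gpos = m.groups()
        return VariantMeta(
            marker_id=marker_id,
            kind=VariantKind.SNP,
            locus=locus,
            genomic_position=int(gpos),
        )
    # rs ids and any other token are intergenic SNPs
    return VariantMeta(marker_id=marker_id, kind=VariantKind.SNP, locus="intergenic")


def format_marker_id(meta: VariantMeta) -> str:
    """Inverse of :func:`parse_marker_id` (reconstructed from fields)."""
    if meta.kind is VariantKind.AA:
        base = f"AA_{meta.locus}_{meta.aa_position}_{meta.genomic_position}"
        return base if meta.residue is None else f"{base}_{meta.residue}"
    if meta.kind is VariantKind.HLA_ALLELE:
        assert meta.allele_name is not None
        locus, fields = meta.allele_name.split("*")
        return f"HLA_{locus}_{fields.replace(':', '')}"
    if meta.marker_id.startswith("SNP_"):
        return f"SNP_{meta.locus}_{meta.genomic_position}"
    return meta.marker_id


@dataclass
class DosagePanel:
    """Marker-by-sample dosage matrix with parsed marker metadata.

    ``dosage[i, k]`` is the expected copy count (0..2) of ``alleles[i][0]``
    carried by sample ``k``; missing values are NaN.
    """

    sample_ids: list[str]
    variants: list[VariantMeta]
    dosage: np.ndarray  # (n_variants, n_samples), float, NaN = missing
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.variants)} variants x {len(self.sample_ids)} samples"
            )
        if not self.alleles:
            self.alleles = [_default_alleles(v) for v in self.variants]
        ids = [v.marker_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise DosageFormatError("duplicate marker ids in panel")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DosageFormatError("duplicate sample ids in panel")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0.0) < -1e-6 or np.nanmax(
                self.dosage, initial=0.0
            ) > 2 + 1e-6:
                raise DosageFormatError("dosage values outside [0, 2]")
        np.clip(self.dosage, 0.0, 2.0, out=self.dosage)
        self._index = {m: i for i, m in enumerate(ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def marker_ids(self) -> list[str]:
        return [v.marker_id for v in self.variants]

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    def get_dosage(self, marker_id: str) -> np.ndarray:
        return self.dosage[self.index_of(marker_id)]

    def subset_variants(self, keep: Sequence[str] | np.ndarray) -> "DosagePanel":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = np.array([self.index_of(m) for m in keep], dtype=int)
        return DosagePanel(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            dosage=self.dosage[idx].copy(),
            alleles=[self.alleles[i] for i in idx],
        )

    def subset_samples(self, keep_ids: Sequence[str]) -> "DosagePanel":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in keep_ids], dtype=int)
        return DosagePanel(
            sample_ids=list(keep_ids),
            variants=list(self.variants),
            dosage=self.dosage[:, idx].copy(),
            alleles=list(self.alleles),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.marker_ids, columns=self.sample_ids)


def _default_alleles(meta: VariantMeta) -> tuple[str, str]:
    if meta.kind in (VariantKind.AA, VariantKind.HLA_ALLELE):
        return PRESENCE_ALLELES
    return ("A", "B")


@dataclass(frozen=True)
class CohortPheno:
    """One sample's phenotype record: case-control status plus covariates."""

    sample_id: str
    status: int  # 1 = case, 0 = control
    age: float
    gender: int


@dataclass(frozen=True)
class MultiAllelicGroup:
    """All residue-presence markers at one amino-acid position with >= 3 residues."""

    locus: str
    aa_position: int
    members: tuple[VariantMeta, ...]

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def group_id(self) -> str:
        return f"AA_{self.locus}_{self.aa_position}"


def read_samples(sample_path: str | Path) -> list[str]:
    """One sample per line; 'FID IID' rows use the IID (last token)."""
    samples: list[str] = []
    for line in Path(sample_path).read_text().splitlines():
        tokens = line.split()
        if tokens:
            samples.append(tokens[-1])
    if len(set(samples)) != len(samples):
        raise DosageFormatError("duplicate sample ids in sample file")
    return samples


def read_dosage(dosage_path: str | Path, sample_path: str | Path) -> DosagePanel:
    """Read a Beagle-style dosage file plus its companion sample file."""
    sample_ids = read_samples(sample_path)
    n = len(sample_ids)
    variants: list[VariantMeta] = []
    alleles: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(dosage_path).read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 3 + n:
            raise DosageFormatError(
                f"line {lineno}: expected {3 + n} fields, got {len(tokens)}"
            )
        marker_id, a1, a2 = tokens[:3]
        if marker_id in seen:
            raise DosageFormatError(f"line {lineno}: duplicate marker id {marker_id!r}")
        seen.add(marker_id)
        vals = np.array(
            [np.nan if t == "NA" else float(t) for t in tokens[3:]], dtype=float
        )
        with np.errstate(invalid="ignore"):
            bad = (vals < -1e-6) | (vals > 2 + 1e-6)
        if np.any(bad):
            raise DosageFormatError(
                f"line {lineno}: dosage outside [0, 2] for marker {marker_id!r}"
            )
        variants.append(parse_marker_id(marker_id))
        alleles.append((a1, a2))
        rows.append(np.clip(vals, 0.0, 2.0))
    dosage = (
        np.vstack(rows) if rows else np.empty((0, n), dtype=float)
    )
    return DosagePanel(sample_ids=sample_ids, variants=variants, dosage=dosage, alleles=alleles)


def write_dosage(
    panel: DosagePanel,
    dosage_path: str | Path,
    sample_path: str | Path,
    decimals: int = 3,
) -> None:
    """Write a panel in the Beagle-style dosage dialect (deterministic order).

    Values written at fixed decimal precision round-trip bit-exactly through
    :func:`read_dosage`.
    """
    with open(dosage_path, "w") as fh:
        for meta, (a1, a2), row in zip(panel.variants, panel.alleles, panel.dosage):
            vals = " ".join(
                "NA" if np.isnan(d) else f"{d:.{decimals}f}" for d in row
            )
            fh.write(f"{meta.marker_id} {a1} {a2} {vals}\n")
    Path(sample_path).write_text("".join(f"{s}\n" for s in panel.sample_ids))


def read_pheno(path: str | Path) -> list[CohortPheno]:
    """Read a TSV with header ``sample_id  status  age  gender``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "status", "age", "gender"}
    missing = required - set(df.columns)
    if missing:
        raise DosageFormatError(f"phenotype file missing columns: {sorted(missing)}")
    if not df["status"].isin([0, 1]).all():
        bad = df.loc[~df["status"].isin([0, 1]), "status"].iloc[0]
        raise DosageFormatError(f"non-binary case-control status: {bad!r}")
    return [
        CohortPheno(
            sample_id=r.sample_id,
            status=int(r.status),
            age=float(r.age),
            gender=int(r.gender),
        )
        for r in df.itertuples()
    ]


def write_pheno(pheno: Iterable[CohortPheno], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.sample_id, p.status, p.age, p.gender) for p in pheno],
        columns=["sample_id", "status", "age", "gender"],
    )
    df.to_csv(path, sep="\t", index=False)


def align(
    panel: DosagePanel, pheno: Sequence[CohortPheno]
) -> tuple[DosagePanel, pd.DataFrame]:
    """Inner-join panel and phenotype on sample id.

    Returns the panel restricted and reordered to the shared samples, plus a
    DataFrame (index = sample id, columns status/age/gender) in the same
    order.  Drops on either side are logged with counts.
    """
    pheno_ids = [p.sample_id for p in pheno]
    if len(set(pheno_ids)) != len(pheno_ids):
        raise DosageFormatError("duplicate sample ids in phenotype table")
    pheno_id_set = set(pheno_ids)
    shared = [s for s in panel.sample_ids if s in pheno_id_set]
    n_drop_panel = panel.n_samples - len(shared)
    n_drop_pheno = len(pheno_ids) - len(shared)
    if n_drop_panel or n_drop_pheno:
        logger.warning(
            "align: dropped %d panel sample(s) and %d phenotype row(s) without a match",
            n_drop_panel,
            n_drop_pheno,
        )
    by_id = {p.sample_id: p for p in pheno}
    df = pd.DataFrame(
        {
            "status": [by_id[s].status for s in shared],
            "age": [by_id[s].age for s in shared],
            "gender": [by_id[s].gender for s in shared],
        },
        index=pd.Index(shared, name="sample_id"),
    )
    return panel.subset_samples(shared), df


def group_multiallelic(panel: DosagePanel) -> list[MultiAllelicGroup]:
    """Group residue-presence markers into multi-allelic amino-acid positions.

    Positions with >= 3 distinct residues form one group (tested jointly via
    the omnibus test); positions with exactly 2 residues stay bi-allelic.
    Ordering is deterministic: by locus, then position; members by residue.
    """
    buckets: dict[tuple[str, int], list[VariantMeta]] = {}
    for meta in panel.variants:
        if meta.kind is VariantKind.AA and meta.residue is not None:
            buckets.setdefault((meta.locus, meta.aa_position), []).append(meta)
    groups = []
    for (locus, pos) in sorted(buckets):
        members = sorted(buckets[(locus, pos)], key=lambda v: v.residue or "")
        if len(members) >= 3:
            groups.append(
                MultiAllelicGroup(locus=locus, aa_position=pos, members=tuple(members))
            )
    return groups
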