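"""Config-driven end-to-end pipeline.

Stages run in order: input (files or simulator) -> post-imputation QC ->
association scan -> stepwise conditional selection -> permutation
confirmation -> cumulative carrier analysis -> classical-allele haplotype
estimation -> liability-scale variance explained.  Every table is written
with a header comment recording the package version, seed and config hash;
a machine-readable ``summary.json`` collects the headline results.  Outputs
are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import bonferroni_alpha, fit_logistic, scan
from .conditional import permutation_test, stepwise_select
from .cumulative import cumulative_analysis
from .dosage_io import (
    CohortPheno,
    DosagePanel,
    align,
    read_dosage,
    read_pheno,
    write_dosage,
    write_pheno,
)
from .heritability import H2Estimate, h2_observed, to_liability
from .ld_haplo import classical_genotypes, em_haplotypes, haplotype_assoc
from .qc import post_imputation_filter
from .synthetic_data import (
    add_imputation_noise,
    default_panel,
    simulate_cohort,
    table1_disease_model,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "load_inputs"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run (see docs/methods.md for rationale)."""

    seed: int = 0
    # input files (ignored when simulate=True)
    dosage_path: str | None = None
    sample_path: str | None = None
    pheno_path: str | None = None
    # simulator
    simulate: bool = True
    n_cases: int = 1583
    n_controls: int = 972
    target_info: float = 1.0
    n_background_snps: int = 40
    # QC
    info_min: float = 0.5
    maf_min: float = 0.01
    # association / selection
    family_alpha: float = 0.05
    threshold: float | None = None  # None = Bonferroni 0.05/M per scan
    # permutation
    n_perm: int = 10_000
    # cumulative
    carrier_threshold: float = 0.5
    # haplotypes
    haplo_loci: list[str] = field(default_factory=lambda: ["A", "B", "DRB1"])
    min_haplo_freq: float = 0.02
    # heritability
    prevalence: float = 0.000078

    def validate(self) -> None:
        if not (0.0 <= self.info_min <= 1.0):
            raise ValueError(f"info_min outside [0, 1]: {self.info_min}")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError(f"maf_min outside [0, 0.5]: {self.maf_min}")
        if not (0.0 < self.family_alpha < 1.0):
            raise ValueError("family_alpha outside (0, 1)")
        if not (0.0 < self.target_info <= 1.0):
            raise ValueError("target_info outside (0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence outside (0, 1)")
        if not (0.0 <= self.carrier_threshold <= 2.0):
            raise ValueError("carrier_threshold outside [0, 2]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not self.simulate and not (
            self.dosage_path and self.sample_path and self.pheno_path
        ):
            raise ValueError("file-based run needs dosage, sample and pheno paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (
        f"# hlafinemap {__version__} | seed={config.seed} "
        f"| config={config.config_hash()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def load_inputs(
    config: RunConfig, out: Path | None = None
) -> tuple[DosagePanel, list[CohortPheno]]:
    """Simulate (writing the files) or read the input cohort."""
    if config.simulate:
        adict, pop = default_panel()
        pop.n_background_snps = config.n_background_snps
        disease = table1_disease_model(adict, config.n_cases, config.n_controls)
        panel, pheno, truth = simulate_cohort(adict, pop, disease, seed=config.seed)
        if config.target_info < 1.0:
            panel = add_imputation_noise(panel, config.target_info, seed=config.seed + 1)
        if out is not None:
            write_dosage(panel, out / "simulated.dosage", out / "simulated.sample")
            write_pheno(pheno, out / "simulated.pheno.tsv")
            tdf = pd.DataFrame(
                truth.true_dosage.T, columns=truth.marker_ids,
            )
            tdf.insert(0, "sample_id", truth.sample_ids)
            _write_tsv(tdf, out / "truth.tsv", config)
        return panel, pheno
    panel = read_dosage(config.dosage_path, config.sample_path)
    pheno = read_pheno(config.pheno_path)
    return panel, pheno


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the summary dict (also written)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    panel, pheno_list = _stage("input", load_inputs, config, out)
    panel, pheno = align(panel, pheno_list)
    summary["n_samples"] = panel.n_samples
    summary["n_cases"] = int(pheno["status"].sum())
    summary["n_variants_input"] = panel.n_variants

    def qc_stage():
        filtered, report = post_imputation_filter(panel, config.info_min, config.maf_min)
        _write_tsv(report.table, out / "qc_report.tsv", config, index=True)
        return filtered

    panel2 = _stage("qc", qc_stage)
    summary["n_variants_pass_qc"] = panel2.n_variants

    def scan_stage():
        sc = scan(panel2, pheno, family_alpha=config.family_alpha)
        _write_tsv(sc.to_frame(), out / "scan_unconditioned.tsv", config)
        return sc

    sc0 = _stage("scan", scan_stage)
    summary["m_tests"] = sc0.m_tests
    summary["bonferroni_alpha"] = sc0.alpha
    summary["n_significant_unconditioned"] = len(sc0.significant())

    def stepwise_stage():
        steps = stepwise_select(
            panel2, pheno, threshold=config.threshold
        )
        for st in steps:
            _write_tsv(
                st.scan.to_frame(), out / f"scan_step{st.step_index}.tsv", config
            )
        sel_df = pd.DataFrame(
            [
                {
                    "step": st.step_index,
                    "marker_id": st.selected,
                    "p_at_selection": st.p_at_selection,
                    "conditioned_on": ",".join(st.conditioned_on),
                }
                for st in steps
            ]
        )
        _write_tsv(sel_df, out / "stepwise_selection.tsv", config)
        return steps

    steps = _stage("stepwise", stepwise_stage)
    selected = [st.selected for st in steps]
    summary["selected"] = selected

    # final joint multivariable model: all selected terms + age + gender
    joint: list[dict] = []
    fit = None
    X = y = None
    genetic_cols: list[int] = []
    if selected:
        def joint_stage():
            from .association import Z975
            from scipy.stats import chi2 as _chi2

            cols = [panel2.get_dosage(m) for m in selected]
            Xm = np.column_stack(
                [np.ones(panel2.n_samples)]
                + cols
                + [pheno["age"].to_numpy(float), pheno["gender"].to_numpy(float)]
            )
            yv = pheno["status"].to_numpy(float)
            ok = ~np.isnan(Xm).any(axis=1)
            Xm, yv = Xm[ok], yv[ok]
            f = fit_logistic(yv, Xm)
            rows = []
            for i, m in enumerate(selected, start=1):
                b, se = f.beta[i], f.se[i]
                rows.append(
                    {
                        "marker_id": m,
                        "or": float(np.exp(b)),
                        "ci_low": float(np.exp(b - Z975 * se)),
                        "ci_high": float(np.exp(b + Z975 * se)),
                        "p": float(_chi2.sf((b / se) ** 2, 1)),
                    }
                )
            _write_tsv(pd.DataFrame(rows), out / "joint_model.tsv", config)
            return rows, f, Xm, yv

        joint, fit, X, y = _stage("joint_model", joint_stage)
        genetic_cols = list(range(1, 1 + len(selected)))
        summary["joint_model"] = joint

    if selected:
        def perm_stage():
            rows = []
            for k, m in enumerate(selected):
                others = tuple(s for s in selected if s != m)
                pr = permutation_test(
                    panel2, pheno, m, conditioned_on=others,
                    n_perm=config.n_perm, seed=config.seed + 100 + k,
                )
                rows.append(
                    {
                        "marker_id": m,
                        "observed_chi2": pr.observed_stat,
                        "n_perm": pr.n_perm,
                        "n_as_extreme": pr.n_as_extreme,
                        "perm_p": pr.perm_p,
                    }
                )
            _write_tsv(pd.DataFrame(rows), out / "permutation.tsv", config)
            return rows

        summary["permutation"] = _stage("permutation", perm_stage)

        def cumulative_stage():
            tab = cumulative_analysis(
                panel2, pheno, selected, threshold=config.carrier_threshold
            )
            df = tab.to_frame()
            df["trend_stat"] = tab.trend_stat
            df["trend_p"] = tab.trend_p
            _write_tsv(df, out / "cumulative.tsv", config)
            return {
                "categories": df.drop(columns=["trend_stat", "trend_p"]).to_dict("records"),
                "trend_stat": tab.trend_stat,
                "trend_p": tab.trend_p,
            }

        summary["cumulative"] = _stage("cumulative", cumulative_stage)

    def haplo_stage():
        loci = [l for l in config.haplo_loci if any(
            v.locus == l and v.allele_digits == "four" for v in panel2.variants
        )]
        if len(loci) < 2:
            logger.warning("haplotype stage skipped: fewer than 2 usable loci")
            return None
        geno = classical_genotypes(panel2, loci)
        hs = em_haplotypes(geno, loci=loci)
        _write_tsv(hs.to_frame(), out / "haplotype_freqs.tsv", config)
        rows = []
        for hap, f in hs.haplotypes:
            if f < config.min_haplo_freq:
                continue
            r = haplotype_assoc(hs, pheno, hap)
            rows.append(
                {
                    "haplotype": "-".join(str(a) for a in hap),
                    "frequency": f,
                    "trend_or": r.trend_or,
                    "trend_p": r.trend_p,
                    "carrier_or": r.carrier_or,
                    "carrier_p": r.carrier_p,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "haplotype_assoc.tsv", config)
        return rows

    summary["haplotypes"] = _stage("haplotype", haplo_stage)

    if selected and fit is not None and fit.converged:
        def h2_stage():
            obs = h2_observed(fit, X, genetic_cols, y)
            P = float(np.mean(y))
            liab = to_liability(obs, config.prevalence, P)
            est = H2Estimate(
                variant_set="selected",
                h2_observed=obs,
                h2_liability=liab,
                prevalence_K=config.prevalence,
                case_fraction_P=P,
                method="lee_transform",
            )
            _write_tsv(pd.DataFrame([dataclasses.asdict(est)]), out / "h2.tsv", config)
            return dataclasses.asdict(est)

        summary["h2"] = _stage("h2", h2_stage)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage(name: str, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
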