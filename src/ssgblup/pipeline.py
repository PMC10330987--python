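"""End-to-end orchestration: simulate/load → QC → matrices → fits → CV.

Stages run in study order.  Genotype-dependent stages (marker QC, G, H⁻¹,
GBLUP and ssGBLUP fits) are skipped automatically when the method list
needs none of them or no genotypes are available.  Every report the run
writes is tab-separated text, and a structured YAML log records each
filter count, stage size and derived seed, so a rerun with the same
configuration reproduces the outputs byte for byte.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .animal_model import (
    McmcConfig,
    ModelSpec,
    PosteriorFit,
    build_design,
    fit_animal_model,
    heritability,
    variance_shares,
)
from .errors import ConfigError, SsgblupError
from .genotype_qc import GenotypeMatrix, run_genotype_qc
from .pedigree import PedigreeTable
from .phenotype_qc import QcReport, run_phenotype_qc
from .relmat import (
    RelationshipMatrix,
    assemble_h_inverse,
    a_inverse,
    blend_ga,
    extract_agg,
    genomic_relationship,
    h_from_h_inverse,
    matrix_summary,
    solve_blend,
    tabular_a,
)
from .simulate import (
    gene_drop_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    split_panels,
)
from .utils import derive_seed
from .validation import MethodSetup, run_cross_validation, summarize_cv

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """Raw inputs after the simulate-or-load stage."""

    pedigree: PedigreeTable
    records: pd.DataFrame
    panels: tuple[GenotypeMatrix, GenotypeMatrix] | None
    genotypes: GenotypeMatrix | None  # single pre-merged matrix, if given
    genotyped_ids: np.ndarray


@dataclass
class PipelineResult:
    """Everything a run computed, plus where the reports were written."""

    inputs: PipelineInputs
    qc_records: pd.DataFrame
    phenotype_report: QcReport
    genotype_report: object | None
    matrices: dict[str, RelationshipMatrix]
    blend: object | None
    matrix_summaries: pd.DataFrame
    fits: dict[str, PosteriorFit]
    variance_report: pd.DataFrame
    cv_report: pd.DataFrame | None
    log: dict = field(default_factory=dict)


# ---------------------------------------------------------------------- #
# stages
# ---------------------------------------------------------------------- #
def load_inputs(config: sio.RunConfig) -> PipelineInputs:
    """Simulate synthetic inputs or read them from the configured paths."""
    if config.simulate is not None:
        sim = config.simulate
        ped = simulate_pedigree(sim)
        drop = gene_drop_genotypes(ped, sim)
        records = simulate_phenotypes(ped, sim, drop.true_values)
        panels = split_panels(drop)
        return PipelineInputs(
            pedigree=ped,
            records=records,
            panels=panels,
            genotypes=None,
            genotyped_ids=drop.genotyped_ids,
        )
    ped = sio.read_pedigree(config.pedigree_path)
    records = sio.read_phenotypes(config.phenotype_path)
    genotypes = None
    genotyped_ids = np.array([], dtype=np.int64)
    if config.genotype_path is not None:
        genotypes = sio.read_genotypes(
            config.genotype_path, config.genotype_sidecar_path
        )
        genotyped_ids = np.asarray(genotypes.ids, dtype=np.int64)
    return PipelineInputs(
        pedigree=ped,
        records=records,
        panels=None,
        genotypes=genotypes,
        genotyped_ids=genotyped_ids,
    )


def build_matrices(
    inputs: PipelineInputs,
    qc_genotypes: GenotypeMatrix | None,
    methods: tuple[str, ...],
) -> tuple[dict[str, RelationshipMatrix], object | None, pd.DataFrame]:
    """Construct every relationship matrix the chosen methods need."""
    matrices: dict[str, RelationshipMatrix] = {}
    blend = None
    need_genomic = bool({"GBLUP", "ssGBLUP"} & set(methods))
    a = tabular_a(inputs.pedigree)
    matrices["A"] = a
    if need_genomic:
        if qc_genotypes is None:
            raise ConfigError(f"methods {methods} need genotypes, none available")
        g = genomic_relationship(qc_genotypes)
        matrices["G"] = g
        if "ssGBLUP" in methods:
            agg = extract_agg(a, g.ids)
            blend = solve_blend(g, agg)
            g_a = blend_ga(g, blend)
            a_inv = a_inverse(inputs.pedigree)
            h_inv = assemble_h_inverse(a_inv, agg, g_a, g.ids)
            matrices.update(A_gg=agg, G_a=g_a, A_inv=a_inv, H_inv=h_inv)
            matrices["H"] = h_from_h_inverse(h_inv)
    summaries = pd.DataFrame(
        [{"matrix": name, **matrix_summary(m)} for name, m in matrices.items()]
    )
    return matrices, blend, summaries


def _method_setups(
    config: sio.RunConfig,
    matrices: dict[str, RelationshipMatrix],
) -> dict[str, MethodSetup]:
    deltas = {"BLUP": "A", "GBLUP": "G", "ssGBLUP": "H"}
    setups = {}
    for method in config.methods:
        kind = deltas[method]
        if kind not in matrices:
            raise ConfigError(f"{method} needs matrix {kind}, not built")
        setups[method] = MethodSetup(
            spec=ModelSpec(trait=config.trait, method=method),
            delta=matrices[kind],
        )
    return setups


def headline_fits(
    config: sio.RunConfig,
    records: pd.DataFrame,
    setups: dict[str, MethodSetup],
) -> tuple[dict[str, PosteriorFit], pd.DataFrame]:
    """Full-length variance-component fits, one per method, plus the
    report table (value, posterior SD as SE, percentage share, h²)."""
    fits: dict[str, PosteriorFit] = {}
    rows = []
    for method, setup in setups.items():
        sub = records
        if method == "GBLUP":
            keep = records["animal"].isin(np.asarray(setup.delta.ids)).to_numpy()
            sub = records.loc[keep].reset_index(drop=True)
        mcmc = McmcConfig(
            n_iterations=config.mcmc.n_iterations,
            burn_in=config.mcmc.burn_in,
            thin=config.mcmc.thin,
            seed=derive_seed(config.seed, f"fit:{method}"),
        )
        design = build_design(sub, setup.spec, setup.delta.ids)
        fit = fit_animal_model(design, setup.delta, setup.spec, mcmc)
        fits[method] = fit
        mean, sd = fit.var_mean, fit.var_sd
        shares = variance_shares(fit)
        for comp in ("sigma_a", "sigma_cg", "sigma_e"):
            rows.append(
                {
                    "trait": config.trait,
                    "method": method,
                    "component": comp,
                    "value": mean[comp],
                    "se": sd[comp],
                    "pct": shares[comp],
                }
            )
        rows.append(
            {
                "trait": config.trait,
                "method": method,
                "component": "h2",
                "value": heritability(fit),
                "se": np.nan,
                "pct": np.nan,
            }
        )
    return fits, pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# full run
# ---------------------------------------------------------------------- #
def run_pipeline(config: sio.RunConfig, write: bool = True) -> PipelineResult:
    """Execute the whole study pipeline and (optionally) write reports."""
    log: dict = {"seed": config.seed, "trait": config.trait, "stages": []}

    def _stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except SsgblupError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        log["stages"].append(name)
        return out

    inputs = _stage("load", load_inputs, config)
    log["n_pedigree"] = len(inputs.pedigree)
    log["n_records_raw"] = len(inputs.records)
    log["n_genotyped"] = len(inputs.genotyped_ids)

    qc_records, pheno_report = _stage(
        "phenotype_qc",
        run_phenotype_qc,
        inputs.records,
        inputs.pedigree,
        inputs.genotyped_ids,
        sd_multiplier=config.sd_multiplier,
    )
    log["phenotype_qc"] = dict(pheno_report.steps)
    log["n_records_qc"] = len(qc_records)

    need_genomic = bool({"GBLUP", "ssGBLUP"} & set(config.methods))
    qc_geno = geno_report = call_stats = None
    if need_genomic:
        if inputs.panels is not None:
            qc_geno, geno_report, call_stats = _stage(
                "genotype_qc",
                run_genotype_qc,
                inputs.panels[0],
                inputs.panels[1],
                call_rate_threshold=config.call_rate_threshold,
                maf_threshold=config.maf_threshold,
            )
        elif inputs.genotypes is not None:
            qc_geno, geno_report, call_stats = _stage(
                "genotype_qc",
                run_genotype_qc,
                inputs.genotypes,
                None,
                call_rate_threshold=config.call_rate_threshold,
                maf_threshold=config.maf_threshold,
            )
        else:
            raise ConfigError(f"methods {config.methods} need genotypes")
        log["genotype_qc"] = dict(geno_report.steps)
        log["individual_missing_mean"] = float(call_stats.individual_missing_mean)

    matrices, blend, summaries = _stage(
        "matrices", build_matrices, inputs, qc_geno, config.methods
    )
    if blend is not None:
        log["blend_alpha"] = float(blend.alpha)
        log["blend_beta"] = float(blend.beta)

    setups = _method_setups(config, matrices)
    fits, variance_report = _stage("fits", headline_fits, config, qc_records, setups)

    cv_report = None
    if config.cv.n_partitions > 0 and len(inputs.genotyped_ids):
        cv_mcmc = McmcConfig(
            n_iterations=config.cv.mcmc.n_iterations,
            burn_in=config.cv.mcmc.burn_in,
            thin=config.cv.mcmc.thin,
            seed=derive_seed(config.seed, "cv"),
        )
        results, _ = _stage(
            "validation",
            run_cross_validation,
            qc_records,
            setups,
            inputs.genotyped_ids,
            n_partitions=config.cv.n_partitions,
            test_fraction=config.cv.test_fraction,
            mcmc=cv_mcmc,
            seed=derive_seed(config.seed, "cv"),
        )
        cv_report = summarize_cv(results)
        cv_report.insert(0, "trait", config.trait)

    result = PipelineResult(
        inputs=inputs,
        qc_records=qc_records,
        phenotype_report=pheno_report,
        genotype_report=geno_report,
        matrices=matrices,
        blend=blend,
        matrix_summaries=summaries,
        fits=fits,
        variance_report=variance_report,
        cv_report=cv_report,
        log=log,
    )
    if write:
        write_reports(result, config)
    return result


def write_reports(result: PipelineResult, config: sio.RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.phenotype_report.to_frame().to_csv(
        outdir / "qc_phenotypes.tsv", sep="\t", index=False
    )
    if result.genotype_report is not None:
        pd.DataFrame(
            result.genotype_report.steps, columns=["rule", "count"]
        ).to_csv(outdir / "qc_genotypes.tsv", sep="\t", index=False)
    result.matrix_summaries.to_csv(
        outdir / "matrix_summaries.tsv", sep="\t", index=False
    )
    result.variance_report.to_csv(
        outdir / "variance_components.tsv", sep="\t", index=False
    )
    if result.cv_report is not None:
        result.cv_report.to_csv(outdir / "cv_correlations.tsv", sep="\t", index=False)
        # bar-chart export: one bar per method with its standard error
        result.cv_report[["trait", "method", "cor", "se"]].to_csv(
            outdir / "figure_correlations.tsv", sep="\t", index=False
        )
    if config.simulate is not None:
        sio.write_pedigree(result.inputs.pedigree, outdir / "pedigree.tsv")
        sio.write_phenotypes(result.inputs.records, outdir / "phenotypes.tsv")
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(_plain(result.log), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
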