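"""End-to-end driver: QC -> annotate -> associate -> enrich -> report.

The pipeline is a pure function of its configuration (including all seeds):
rerunning with the same config reproduces every artifact. Configuration is
a nested mapping (usually loaded from YAML) with per-stage sections::

    simulate:            # either this ...
      n_subjects: 263
      n_sites: 20000
      seed: 7
    inputs:              # ... or this
      coverage_dir: path/
      samples: samples.tsv
      gene_model: genes.bed
      gene_set: gene_set.tsv
    qc:        {min_coverage: 10, min_subject_fraction: 0.5}
    association: {covariates: [age, race, sex, batch]}
    enrichment: {alpha_site: 0.05, permutations: 10000, seed: 42, unit: site}
    report:    {n_top: 15, alpha_family: 0.05}
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    GeneModel,
    annotate_sites,
    flag_obesity_sites,
    load_gene_set,
    load_obesity_gene_set,
    write_annotations,
)
from .association import fit_all, genomic_inflation, write_results
from .coverage import assemble_matrix, filter_sites, write_matrix
from .enrichment import enrich, format_report
from .report import ThresholdSet, manhattan_table, top_sites_report
from .simulate import SimulationConfig, simulate_cohort, write_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Execute all stages; returns a name -> path map of the artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: list[str] = [f"methewas {__version__}"]

    def stage(name):
        log.append(f"stage: {name}")

    try:
        stage("inputs")
        matrix_raw, samples, gene_model, gene_set = _load_inputs(config, out, artifacts, log)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inputs", exc) from exc

    try:
        stage("qc")
        qc_cfg = config.get("qc", {})
        matrix, qc_report = filter_sites(
            matrix_raw,
            min_coverage=int(qc_cfg.get("min_coverage", 10)),
            min_subject_fraction=float(qc_cfg.get("min_subject_fraction", 0.5)),
        )
        artifacts["qc_report"] = out / "qc_report.json"
        artifacts["qc_report"].write_text(json.dumps(qc_report.to_dict(), indent=2))
        artifacts["matrix"] = out / "matrix.tsv"
        write_matrix(matrix, artifacts["matrix"])
        log.append(
            f"  {qc_report.n_sites_retained} of {qc_report.n_sites_input} sites retained"
        )
    except Exception as exc:
        raise PipelineError("qc", exc) from exc

    try:
        stage("annotate")
        annotations = annotate_sites(matrix.sites, gene_model)
        annotations = flag_obesity_sites(annotations, gene_set)
        artifacts["annotations"] = out / "annotations.tsv"
        write_annotations(annotations, artifacts["annotations"])
        log.append(
            f"  {int(annotations['intragenic'].sum())} intragenic, "
            f"{int(annotations['obesity_flag'].sum())} on obesity genes"
        )
    except Exception as exc:
        raise PipelineError("annotate", exc) from exc

    try:
        stage("associate")
        assoc_cfg = config.get("association", {})
        covariates = tuple(assoc_cfg.get("covariates", ["age", "race", "sex", "batch"]))
        results = fit_all(matrix, samples, covariates=covariates)
        artifacts["association"] = out / "association.tsv"
        write_results(results, artifacts["association"])
        inflation = genomic_inflation(results.loc[results["converged"], "p_value"])
        artifacts["inflation"] = out / "inflation.json"
        artifacts["inflation"].write_text(
            json.dumps(dataclasses.asdict(inflation), indent=2)
        )
        log.append(
            f"  {int(results['converged'].sum())} of {len(results)} sites converged; "
            f"lambda = {inflation.lambda_gc:.3f}"
        )
    except Exception as exc:
        raise PipelineError("associate", exc) from exc

    try:
        stage("enrich")
        enr_cfg = config.get("enrichment", {})
        result = enrich(
            results,
            annotations,
            alpha_site=float(enr_cfg.get("alpha_site", 0.05)),
            B=int(enr_cfg.get("permutations", 10_000)),
            seed=int(enr_cfg.get("seed", 42)),
            unit=str(enr_cfg.get("unit", "site")),
        )
        artifacts["enrichment"] = out / "enrichment.json"
        artifacts["enrichment"].write_text(json.dumps(result.to_dict(), indent=2))
        artifacts["enrichment_txt"] = out / "enrichment.txt"
        artifacts["enrichment_txt"].write_text(format_report(result) + "\n")
        log.append(
            f"  hypergeometric p = {result.p_hypergeometric:.4g}, "
            f"permutation p = {result.p_permutation:.4g}"
        )
    except Exception as exc:
        raise PipelineError("enrich", exc) from exc

    try:
        stage("report")
        rep_cfg = config.get("report", {})
        alpha_family = float(rep_cfg.get("alpha_family", 0.05))
        thresholds = ThresholdSet(
            alpha_family=alpha_family,
            m_genomewide=result.table.n_total_intragenic,
            m_set=result.table.n_obesity_sites,
        )
        artifacts["thresholds"] = out / "thresholds.json"
        artifacts["thresholds"].write_text(json.dumps(thresholds.to_dict(), indent=2))
        top = top_sites_report(
            results,
            annotations,
            n_top=int(rep_cfg.get("n_top", 15)),
            alpha_family=alpha_family,
        )
        artifacts["top_sites"] = out / "top_sites.tsv"
        top.to_csv(artifacts["top_sites"], sep="\t", index=False, float_format="%.6g")
        manhattan = manhattan_table(results, annotations)
        artifacts["manhattan"] = out / "manhattan.tsv"
        manhattan.to_csv(artifacts["manhattan"], sep="\t", index=False, float_format="%.6g")
    except Exception as exc:
        raise PipelineError("report", exc) from exc

    artifacts["run_log"] = out / "run_log.txt"
    artifacts["run_log"].write_text("\n".join(log) + "\n")
    return artifacts


def _load_inputs(config: dict, out: Path, artifacts: dict, log: list):
    """Either simulate a cohort or load user-supplied files."""
    if "simulate" in config:
        sim_cfg = SimulationConfig(**_coerce_sim(config["simulate"]))
        cohort = simulate_cohort(sim_cfg)
        cohort_dir = out / "cohort"
        write_cohort(cohort, cohort_dir)
        artifacts["cohort_dir"] = cohort_dir
        log.append(f"  simulated cohort, seed {sim_cfg.seed}")
        samples = cohort.sample_table
        # round-trip through the written files so the pipeline exercises
        # the same readers a real dataset would
        cov_files = {
            str(s): cohort_dir / f"{s}.cov.tsv"
            for s in samples["subject_id"].astype(str)
        }
        matrix = assemble_matrix(cov_files, samples)
        gene_model = cohort.gene_model
        gene_set = load_obesity_gene_set()
        return matrix, samples, gene_model, gene_set
    inputs = config["inputs"]
    samples = pd.read_csv(inputs["samples"], sep="\t")
    cov_dir = Path(inputs["coverage_dir"])
    cov_files = sorted(cov_dir.glob("*.cov.tsv")) or sorted(cov_dir.glob("*.tsv"))
    matrix = assemble_matrix(cov_files, samples)
    gene_model = GeneModel.from_bed(inputs["gene_model"])
    if "gene_set" in inputs:
        gene_set = load_gene_set(
            inputs["gene_set"], threshold=float(inputs.get("score_threshold", 0.20))
        )
    else:
        gene_set = load_obesity_gene_set()
    return matrix, samples, gene_model, gene_set


def _coerce_sim(section: dict) -> dict:
    out = dict(section)
    if "effect_sites" in out:
        out["effect_sites"] = tuple(
            (str(g), float(e)) for g, e in out["effect_sites"]
        )
    return out
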