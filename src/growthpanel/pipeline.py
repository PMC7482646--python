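"""End-to-end pipeline: simulate/ingest -> filter -> classify -> QC ->
burden -> association -> overlaps, with TSV outputs and a run log.

The configuration is a plain mapping (typically loaded from YAML): either
a ``simulate`` block (cohort generator settings) or an ``inputs`` block
(paths to VCF + sidecar + phenotype/panel/known/prediction tables), plus
optional ``qc``, ``burden`` and ``association`` blocks overriding
defaults. Every stage error is re-raised tagged with its stage name. A
fixed seed makes the whole run byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from .acmg import classifications_to_frame, classify_cohort
from .association import association_scan, association_to_frame
from .burden import burden_scan, burden_to_frame
from .filtering import qualifying_to_frame, select_qualifying_variants
from .overlap import OverlapReport, build_report, diagnostic_yield
from .qc import pca_covariates, run_qc
from .records import GenotypeMatrix, PanelDefinition, PhenotypeTable
from .simulate import (
    CohortSimConfig,
    DiagnosticSpike,
    PhenotypeEffect,
    known_table_from_truth,
    simulate_cohort,
)

STAGES = ("ingest", "filter", "classify", "qc", "burden", "assoc", "overlap", "write")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage:{stage}] {message}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc

        return wrapped

    return deco


@dataclass
class PipelineResult:
    report: OverlapReport
    outputs: Dict[str, Path]
    summary: Dict[str, object]


def _sim_config_from_block(block: dict, panel: PanelDefinition, seed: int) -> CohortSimConfig:
    spikes = [DiagnosticSpike(**s) for s in block.get("spikes", [])]
    effects = [PhenotypeEffect(**e) for e in block.get("effects", [])]
    kwargs = {
        k: v
        for k, v in block.items()
        if k not in ("spikes", "effects", "panel", "seed")
    }
    if "rare_only_genes" in kwargs:
        kwargs["rare_only_genes"] = frozenset(kwargs["rare_only_genes"])
    return CohortSimConfig(panel=panel, spikes=spikes, effects=effects, seed=seed, **kwargs)


@_stage("ingest")
def _ingest(config: dict, seed: int):
    if "panel" in config.get("inputs", {}):
        panel = gio.read_panel(config["inputs"]["panel"])
    else:
        panel = gio.default_panel()
    if "simulate" in config:
        sim = _sim_config_from_block(config["simulate"], panel, seed)
        cohort = simulate_cohort(sim)
        known = known_table_from_truth(cohort.truth)
        if known.empty:
            known = gio.default_known_mutations()
        return cohort.genotypes, cohort.variants, cohort.phenotypes, panel, known
    inputs = config.get("inputs")
    if not inputs:
        raise ValueError("config needs either a 'simulate' or an 'inputs' block")
    for key in ("vcf", "samples", "phenotypes"):
        if key not in inputs:
            raise ValueError(f"inputs block missing {key!r}")
        if not os.path.exists(inputs[key]):
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    matrix, variants = gio.read_genotypes_vcf(inputs["vcf"], inputs["samples"])
    phenotypes = gio.read_phenotype_table(inputs["phenotypes"])
    if "predictions" in inputs:
        preds = gio.read_predictions(inputs["predictions"])
        for v in variants:
            if v.variant_id in preds:
                v.predictions = preds[v.variant_id]
    known = (
        gio.read_known_mutations(inputs["known_mutations"])
        if "known_mutations" in inputs
        else gio.default_known_mutations()
    )
    return matrix, variants, phenotypes, panel, known


@_stage("filter")
def _filter(variants, matrix, panel, known):
    return select_qualifying_variants(variants, matrix, panel, known)


@_stage("classify")
def _classify(qualifying, panel, n_cases):
    results, counts = classify_cohort(qualifying, panel)
    calls = [
        (sid, cls.value) for qv, cls in results for sid in qv.carrier_ids
    ]
    yield_pct = diagnostic_yield(calls, n_cases)
    return results, counts, yield_pct


@_stage("qc")
def _qc(matrix, variants, qc_cfg: dict):
    qc_matrix, report = run_qc(matrix, variants, **qc_cfg)
    n_pcs = 4
    analysis = qc_matrix.subset_variants(report.kept_variants) if report.kept_variants else None
    pcs = None
    if analysis is not None and analysis.n_variants >= n_pcs:
        scores = pca_covariates(analysis, k=n_pcs)
        pcs = pd.DataFrame(
            scores,
            index=list(qc_matrix.sample_ids),
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        )
    return qc_matrix, report, pcs


@_stage("burden")
def _burden(matrix, variants, panel, burden_cfg: dict):
    alpha = burden_cfg.get("alpha", 0.05)
    method_all = burden_cfg.get("method_all", "bonferroni")
    method_rare = burden_cfg.get("method_rare", "benjamini_hochberg")
    method_indel = burden_cfg.get("method_indel", "bonferroni")
    return (
        burden_scan(matrix, variants, panel, "all", method_all, alpha),
        burden_scan(matrix, variants, panel, "rare", method_rare, alpha),
        burden_scan(matrix, variants, panel, "indel", method_indel, alpha),
    )


@_stage("assoc")
def _assoc(qc_matrix, report, pcs, phenotypes, variants, assoc_cfg: dict):
    cov = pd.DataFrame(index=list(qc_matrix.sample_ids))
    cov["sex"] = [1.0 if s == "male" else 0.0 for s in qc_matrix.sex]
    if "age_years" in phenotypes.frame.columns:
        cov["age_years"] = phenotypes.frame["age_years"].reindex(cov.index)
    if pcs is not None:
        for c in pcs.columns:
            cov[c] = pcs[c]
    return association_scan(
        qc_matrix,
        phenotypes,
        variants,
        covariates=cov,
        variant_subset=report.kept_variants,
        m_effective=report.m_effective,
        alpha=assoc_cfg.get("alpha", 0.05),
        lenient=assoc_cfg.get("lenient", 0.001),
    )


def run_full_pipeline(config: dict, out_dir) -> PipelineResult:
    """Execute every stage and write all outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    matrix, variants, phenotypes, panel, known = _ingest(config, seed)
    qualifying = _filter(variants, matrix, panel, known)
    class_results, class_counts, yield_pct = _classify(
        qualifying, panel, matrix.n_cases
    )
    qc_matrix, qc_report, pcs = _qc(matrix, variants, config.get("qc", {}))
    b_all, b_rare, b_indel = _burden(
        matrix, variants, panel, config.get("burden", {})
    )
    assoc_results, plan = _assoc(
        qc_matrix, qc_report, pcs, phenotypes, variants, config.get("association", {})
    )
    report = build_report(b_all, b_rare, assoc_results, yield_pct)

    outputs: Dict[str, Path] = {}
    try:
        outputs["qualifying"] = out / "qualifying_variants.tsv"
        qualifying_to_frame(qualifying).to_csv(outputs["qualifying"], sep="\t", index=False)
        outputs["classifications"] = out / "classifications.tsv"
        classifications_to_frame(class_results).to_csv(
            outputs["classifications"], sep="\t", index=False
        )
        outputs["qc"] = out / "qc_report.tsv"
        pd.DataFrame(
            qc_report.summary_rows(), columns=["item", "kind", "action", "reason"]
        ).to_csv(outputs["qc"], sep="\t", index=False)
        for name, res in (("burden_all", b_all), ("burden_rare", b_rare), ("burden_indel", b_indel)):
            outputs[name] = out / f"{name}.tsv"
            burden_to_frame(res, panel).to_csv(outputs[name], sep="\t", index=False)
        outputs["associations"] = out / "associations.tsv"
        association_to_frame(assoc_results).to_csv(
            outputs["associations"], sep="\t", index=False
        )
        outputs["overlap"] = out / "overlap.tsv"
        pd.DataFrame(
            [
                {"set": "genes_all", "genes": ",".join(sorted(report.genes_all))},
                {"set": "genes_rare", "genes": ",".join(sorted(report.genes_rare))},
                {"set": "genes_assoc", "genes": ",".join(sorted(report.genes_assoc))},
                {"set": "overlap_A", "genes": ",".join(sorted(report.overlap_a))},
                {"set": "overlap_B", "genes": ",".join(sorted(report.overlap_b))},
                {"set": "triple", "genes": ",".join(sorted(report.triple))},
            ]
        ).to_csv(outputs["overlap"], sep="\t", index=False)
        outputs["log"] = out / "run_log.txt"
        with open(outputs["log"], "w") as fh:
            fh.write(f"growthpanel {__version__}\n")
            fh.write(f"seed: {seed}\n")
            fh.write(f"samples: {matrix.n_samples} (cases {matrix.n_cases})\n")
            fh.write(f"variants: {matrix.n_variants}\n")
            fh.write(f"qualifying: {len(qualifying)}\n")
            fh.write(f"classification counts: {dict(class_counts)}\n")
            fh.write(f"diagnostic yield: {round(yield_pct)}% ({yield_pct:.4f})\n")
            fh.write(f"qc thresholds: {qc_report.thresholds}\n")
            fh.write(f"m_effective: {qc_report.m_effective}\n")
            fh.write(f"strict threshold: {plan.strict:.3g}\n")
            fh.write(f"lenient threshold: {plan.lenient}\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("write", str(exc)) from exc

    summary = {
        "n_qualifying": len(qualifying),
        "classification_counts": dict(class_counts),
        "diagnostic_yield_percent": yield_pct,
        "m_effective": qc_report.m_effective,
        "strict_threshold": plan.strict,
        "genes_all": sorted(report.genes_all),
        "genes_rare": sorted(report.genes_rare),
        "genes_assoc": sorted(report.genes_assoc),
        "overlap_A": sorted(report.overlap_a),
        "overlap_B": sorted(report.overlap_b),
        "triple": sorted(report.triple),
    }
    return PipelineResult(report=report, outputs=outputs, summary=summary)
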