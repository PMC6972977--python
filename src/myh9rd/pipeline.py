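"""Orchestration of the classification and summary stages.

``run_classify`` produces one report row per patient-variant pair; when the
variant table carries an ``evidence`` column (codes adjudicated by an expert
review, as in the packaged cohort) those codes are combined directly,
otherwise the engine derives them from annotations, rarity, hotspots,
pedigree cosegregation and the registry.  ``run_summarize`` aggregates a
classified cohort into spectrum counts, domain-stratified phenotype
proportions and the diagnostic yield.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Dict, List, Optional

import pandas as pd

from .acmg import (
    EnginePolicy,
    KnownVariantRegistry,
    apply_policy,
    assign_evidence,
    combine_evidence,
    contribution_assignment,
    format_evidence_code,
    parse_evidence_string,
)
from .cohort import (
    CLASS_RANK,
    CohortSummary,
    domain_phenotype_table,
    new_diagnosis_count,
    spectrum_summary,
)
from .domains import DomainArchitecture, domain_of_exon
from .io import (
    RunConfig,
    informative_meioses_by_family,
    patients_from_table,
    read_af_table,
    read_patient_table,
    read_ped,
    read_variant_table,
    variants_from_table,
)
from .popfilter import RarityThresholds

logger = logging.getLogger(__name__)

__all__ = ["run_classify", "run_summarize", "load_registry", "best_class_by_patient"]

_REPORT_COLUMNS = [
    "patient_id", "variant_id", "hgvs_c", "hgvs_p", "exon", "domain",
    "codes", "strict_class", "final_class", "policy", "contribution", "audit",
]


def load_registry(path) -> KnownVariantRegistry:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return KnownVariantRegistry(
        (row.hgvs_p, int(row.residue), row.classification) for row in df.itertuples()
    )


def _load_inputs(config: RunConfig):
    config.validate_paths()
    variants_df = read_variant_table(config.variants)
    af = read_af_table(config.af_table) if config.af_table else None
    records = variants_from_table(variants_df, af)
    patients_df = read_patient_table(config.patients)
    patients = patients_from_table(patients_df)
    meioses = (
        informative_meioses_by_family(read_ped(config.pedigree))
        if config.pedigree
        else {}
    )
    registry = load_registry(config.registry) if config.registry else None
    arch = (
        DomainArchitecture.from_yaml(config.architecture)
        if config.architecture
        else DomainArchitecture()
    )
    return variants_df, records, patients_df, patients, meioses, registry, arch


def run_classify(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Classify every patient-variant pair; returns (and writes) the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    variants_df, records, _, patients, meioses, registry, arch = _load_inputs(config)

    evidence_by_variant = None
    if "evidence" in variants_df.columns:
        ids = (
            variants_df["variant_id"]
            if "variant_id" in variants_df.columns
            else [f"VAR{i + 1:04d}" for i in range(len(variants_df))]
        )
        evidence_by_variant = {
            str(vid): parse_evidence_string(ev)
            for vid, ev in zip(ids, variants_df["evidence"])
        }

    policy = EnginePolicy(conservative_novel_cap=config.conservative_novel_cap)
    thresholds = RarityThresholds(
        pm2_af_max=config.pm2_af_max, rare_af_max=config.rare_af_max
    )

    rows: List[dict] = []
    for patient in patients:
        for vid in patient.variant_ids:
            variant = records[vid]
            if evidence_by_variant is not None:
                codes = evidence_by_variant[vid]
            else:
                codes = assign_evidence(
                    variant,
                    patient=patient,
                    informative_meioses=meioses.get(patient.family_id),
                    registry=registry,
                    arch=arch,
                    thresholds=thresholds,
                )
            strict = combine_evidence(codes)
            result = apply_policy(strict, codes, variant.novel_flag, policy)
            contribution_assignment(result, patient)
            if result.policy_applied:
                logger.info(
                    "policy %s overrode %s -> %s for %s/%s",
                    result.policy_applied, strict, result.klass,
                    patient.patient_id, vid,
                )
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "variant_id": vid,
                    "hgvs_c": variant.hgvs_c,
                    "hgvs_p": variant.hgvs_p,
                    "exon": variant.exon,
                    "domain": domain_of_exon(variant.exon, arch),
                    "codes": ", ".join(format_evidence_code(c) for c in codes),
                    "strict_class": strict,
                    "final_class": result.klass,
                    "policy": result.policy_applied or "",
                    "contribution": result.contribution,
                    "audit": "; ".join(f"{rule}: {detail}" for rule, detail in result.audit),
                }
            )
    report = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    if report.empty:
        logger.warning("empty variant table: writing empty report")
    if write:
        os.makedirs(config.out_dir, exist_ok=True)
        report.to_csv(os.path.join(config.out_dir, "classification_report.tsv"),
                      sep="\t", index=False)
        with open(os.path.join(config.out_dir, "classification_report.json"), "w") as fh:
            json.dump(report.to_dict(orient="records"), fh, indent=1, sort_keys=True)
    return report


def best_class_by_patient(report: pd.DataFrame) -> Dict[str, str]:
    """Highest final class per patient (for diagnostic-yield counting)."""
    best: Dict[str, str] = {}
    for row in report.itertuples():
        pid = str(row.patient_id)
        if pid not in best or CLASS_RANK[row.final_class] > CLASS_RANK[best[pid]]:
            best[pid] = row.final_class
    return best


def run_summarize(
    config: RunConfig,
    report: Optional[pd.DataFrame] = None,
    write: bool = True,
) -> CohortSummary:
    """Aggregate a classified cohort into the study-style summary."""
    variants_df, records, patients_df, patients, _, registry, arch = _load_inputs(config)
    if report is None:
        report = run_classify(config, write=write)

    long_rows = []
    for patient in patients:
        for vid in patient.variant_ids:
            v = records[vid]
            long_rows.append(
                {
                    "patient_id": patient.patient_id,
                    "family_id": patient.family_id,
                    "hgvs_c": v.hgvs_c,
                    "hgvs_p": v.hgvs_p,
                    "exon": v.exon,
                    "novel": v.novel_flag,
                }
            )
    long_df = pd.DataFrame(long_rows)
    spectrum = spectrum_summary(
        long_df,
        known_hgvs_p=registry.known_hgvs_p() if registry else None,
        arch=arch,
    )

    final_by_pair = {
        (str(r.patient_id), str(r.variant_id)): r.final_class for r in report.itertuples()
    }
    final_by_variant: Dict[str, str] = {}
    for (_, vid), klass in final_by_pair.items():
        if vid not in final_by_variant or CLASS_RANK[klass] > CLASS_RANK[final_by_variant[vid]]:
            final_by_variant[vid] = klass

    variant_domains = {vid: domain_of_exon(v.exon, arch) for vid, v in records.items()}
    variant_residues = {
        vid: v.protein_change.residue_start for vid, v in records.items()
    }
    pheno_table, severity_table = domain_phenotype_table(
        patients, variant_domains, variant_residues, final_by_variant,
        severity_cutoff=config.severity_cutoff,
    )

    best = best_class_by_patient(report)
    yield_count = new_diagnosis_count(patients, best)

    enrollment = {}
    for p in patients:
        enrollment[p.enrollment_status] = enrollment.get(p.enrollment_status, 0) + 1

    summary = CohortSummary(
        n_patients=len(patients),
        n_index_cases=len({p.family_id for p in patients}),
        n_variants=spectrum["n_unique_variants"],
        n_novel=spectrum["n_novel"],
        consequence_counts=spectrum["consequence_counts"],
        domain_counts=spectrum["domain_counts"],
        distinct_exons=spectrum["distinct_exons"],
        enrollment_counts=enrollment,
        phenotype_by_domain=pheno_table,
        severity_by_domain=severity_table,
        new_diagnoses=yield_count,
    )
    if write:
        os.makedirs(config.out_dir, exist_ok=True)
        with open(os.path.join(config.out_dir, "cohort_summary.json"), "w") as fh:
            json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
        flat = []
        for pheno, doms in summary.phenotype_by_domain.items():
            for dom, (num, den) in doms.items():
                flat.append({"table": "phenotype", "stratum": pheno, "domain": dom,
                             "numerator": num, "denominator": den})
        for grp, doms in summary.severity_by_domain.items():
            for dom, (num, den) in doms.items():
                flat.append({"table": "severity", "stratum": grp, "domain": dom,
                             "numerator": num, "denominator": den})
        pd.DataFrame(flat).to_csv(
            os.path.join(config.out_dir, "cohort_summary.tsv"), sep="\t", index=False
        )
    return summary
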