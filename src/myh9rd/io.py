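"""Readers and writers for the pipeline's tabular dialects.

Variant and cohort tables are TSV; pedigrees are whitespace-delimited PED;
allele-frequency references are TSV keyed by the coding-DNA string; protein
alignments are aligned FASTA; run configuration is YAML.  A minimal VCF
reader maps INFO-encoded notation strings into the variant-table dialect for
interoperability with annotation pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml
from Bio import AlignIO

from .cohort import PatientRecord
from .hgvs import (
    PopulationFrequency,
    VariantAnnotations,
    VariantRecord,
    parse_hgvs_c,
    parse_hgvs_p,
)

__all__ = [
    "read_variant_table", "variants_from_table",
    "read_patient_table", "patients_from_table",
    "read_ped", "informative_meioses_by_family",
    "read_af_table", "read_alignment", "read_vcf_minimal",
    "RunConfig",
]


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _opt_float(value) -> Optional[float]:
    return None if _missing(value) else float(value)


def _opt_str(value) -> Optional[str]:
    return None if _missing(value) else str(value)


def _tri(value) -> Optional[bool]:
    if _missing(value):
        return None
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("true", "yes"):
            return True
        if low in ("false", "no"):
            return False
        return bool(int(low))
    return bool(int(value))


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"hgvs_c", "hgvs_p", "exon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: variant table missing columns {sorted(missing)}")
    return df


def variants_from_table(
    df: pd.DataFrame,
    af_table: Optional[Dict[str, Tuple[Optional[float], Optional[float]]]] = None,
) -> Dict[str, VariantRecord]:
    """Build :class:`VariantRecord` objects from a variant table.

    Annotation columns are optional; absent columns leave the corresponding
    annotation missing (tri-state None).  When an allele-frequency reference
    is supplied it overrides the table's own af columns.
    """
    records: Dict[str, VariantRecord] = {}
    for idx, row in df.iterrows():
        vid = str(row["variant_id"]) if "variant_id" in df.columns else f"VAR{idx + 1:04d}"
        get = lambda col: row[col] if col in df.columns else None  # noqa: E731
        annotations = VariantAnnotations(
            cadd_score=_opt_float(get("cadd_score")),
            sift_call=_opt_str(get("sift_call")),
            polyphen_call=_opt_str(get("polyphen_call")),
            mutation_taster_call=_opt_str(get("mutation_taster_call")),
            gvgd_class=_opt_str(get("gvgd_class")),
            nucleotide_conserved=_tri(get("nucleotide_conserved")),
            aminoacid_conserved=_tri(get("aminoacid_conserved")),
            protein_effect_predicted=_tri(get("protein_effect_predicted")),
            functional_evidence=bool(_tri(get("functional_evidence")) or False),
            de_novo_status=_opt_str(get("de_novo_status")) or "none",
            prevalence_evidence=_opt_str(get("prevalence_evidence")),
        )
        hgvs_c = str(row["hgvs_c"])
        af_exac, af_gnomad = _opt_float(get("af_exac")), _opt_float(get("af_gnomad"))
        if af_table and hgvs_c in af_table:
            af_exac, af_gnomad = af_table[hgvs_c]
        freq = PopulationFrequency(af_exac=af_exac, af_gnomad=af_gnomad)
        records[vid] = VariantRecord(
            id=vid,
            coding_change=parse_hgvs_c(hgvs_c),
            protein_change=parse_hgvs_p(str(row["hgvs_p"])),
            exon=int(row["exon"]),
            gene_region_position=_opt_str(get("gene_region_position")) or "",
            novel_flag=bool(_tri(get("novel")) or False),
            annotations=annotations,
            frequencies=freq,
        )
    return records


def read_patient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "family_id", "variant_ids", "enrollment_status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: patient table missing columns {sorted(missing)}")
    return df


def patients_from_table(df: pd.DataFrame) -> List[PatientRecord]:
    records = []
    for _, row in df.iterrows():
        get = lambda col: row[col] if col in df.columns else None  # noqa: E731
        hpo = _opt_str(get("hpo_terms"))
        bs = _opt_float(get("bleeding_score"))
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                family_id=str(row["family_id"]),
                variant_ids=str(row["variant_ids"]).split(";"),
                enrollment_status=str(row["enrollment_status"]),
                sex=_opt_str(get("sex")),
                age_at_diagnosis=_opt_float(get("age_at_diagnosis")),
                hpo_terms=set(hpo.split(";")) if hpo else set(),
                platelet_count=_opt_float(get("platelet_count")),
                mpv=_opt_float(get("mpv")),
                bleeding_score=int(bs) if bs is not None else None,
                macrothrombocytes=_tri(get("macrothrombocytes")),
                thrombocytopenia=_tri(get("thrombocytopenia")),
                dohle_bodies=_opt_str(get("dohle_bodies")) or "unknown",
                dohle_method=_opt_str(get("dohle_method")),
                hearing_impairment=_tri(get("hearing_impairment")),
                nephropathy=_tri(get("nephropathy")),
                liver_enzyme_elevation=_tri(get("liver_enzyme_elevation")),
                cataract=_tri(get("cataract")),
                menorrhagia=_tri(get("menorrhagia")),
                family_history_myh9rd=_tri(get("family_history_myh9rd")),
                phenotype_specific=_tri(get("phenotype_specific")),
            )
        )
    return records


def read_ped(path) -> pd.DataFrame:
    """Read a 6-column PED file (family, individual, father, mother, sex, phenotype)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str,
    )
    return df


def informative_meioses_by_family(ped: pd.DataFrame) -> Dict[str, int]:
    """Affected members minus the index case, per family.

    A crude cosegregation count: each additional affected family member
    contributes one informative meiosis.
    """
    counts: Dict[str, int] = {}
    for fam, group in ped.groupby("family_id"):
        affected = (group["phenotype"].astype(str) == "2").sum()
        counts[str(fam)] = max(0, int(affected) - 1)
    return counts


def read_af_table(path) -> Dict[str, Tuple[Optional[float], Optional[float]]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "hgvs_c" not in df.columns:
        raise ValueError(f"{path}: allele-frequency table missing column 'hgvs_c'")
    table = {}
    for _, row in df.iterrows():
        table[str(row["hgvs_c"])] = (
            _opt_float(row.get("af_exac")),
            _opt_float(row.get("af_gnomad")),
        )
    return table


def read_alignment(path):
    return AlignIO.read(str(path), "fasta")


def read_vcf_minimal(path) -> pd.DataFrame:
    """Map a minimal VCF into the variant-table dialect.

    Passes CHROM/POS/REF/ALT through and pulls HGVSC, HGVSP and EXON from
    INFO.  Records lacking the notation keys are skipped.
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        hgvs_c = rec.INFO.get("HGVSC")
        hgvs_p = rec.INFO.get("HGVSP")
        exon = rec.INFO.get("EXON")
        if not (hgvs_c and hgvs_p and exon is not None):
            continue
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "gene_region_position": f"{rec.CHROM}:{rec.POS}{rec.REF}>{rec.ALT[0]}"
                if rec.ALT
                else f"{rec.CHROM}:{rec.POS}",
                "hgvs_c": str(hgvs_c),
                "hgvs_p": str(hgvs_p),
                "exon": int(exon),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Paths, thresholds and policy toggles for a pipeline run."""

    variants: str
    patients: str
    out_dir: str = "results"
    pedigree: Optional[str] = None
    af_table: Optional[str] = None
    alignment: Optional[str] = None
    registry: Optional[str] = None
    architecture: Optional[str] = None  # YAML domain/hotspot overrides
    pm2_af_max: float = 1e-4
    rare_af_max: float = 1e-3
    conservative_novel_cap: bool = True
    conservation_threshold: float = 0.9
    severity_cutoff: float = 50.0
    log_level: str = "INFO"
    extra: Dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"}
        data.update(self.extra)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate_paths(self) -> None:
        for name in ("variants", "patients", "pedigree", "af_table", "alignment",
                     "registry", "architecture"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")
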