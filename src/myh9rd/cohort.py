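"""Patient records and cohort-level genotype-phenotype summaries.

Severity stratification splits patients at a platelet count of 50e9/L
(<=50 severe/moderate, >50 mild); thrombocytopenia is a count strictly below
150e9/L.  Both cutoffs are configurable.  Patients carrying two variants are
counted once in domain stratification, attributed to the variant with the
higher final classification (ties resolved toward the higher residue, which
prefers tail-domain over head-domain positions); the attribution is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .domains import DomainArchitecture, domain_of_exon
from .hgvs import classify_consequence, parse_hgvs_p

logger = logging.getLogger(__name__)

__all__ = [
    "ENROLLMENT_STATUSES",
    "PatientRecord",
    "CohortSummary",
    "severity_group",
    "thrombocytopenia_flag",
    "attribute_domain",
    "domain_phenotype_table",
    "new_diagnosis_count",
    "spectrum_summary",
]

ENROLLMENT_STATUSES = (
    "unclassified_platelet_disorder",
    "suspected_MYH9RD",
    "known_MYH9RD_unconfirmed",
)

#: ordinal ranking of classification verdicts (used for tie-breaks and
#: monotonicity checks)
CLASS_ORDER = ["benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic"]
CLASS_RANK = {name: i for i, name in enumerate(CLASS_ORDER)}

#: MCMDM-1 VWD bleeding score instrument range
BLEEDING_SCORE_RANGE = (-3, 45)


@dataclass
class PatientRecord:
    """Phenotype bundle for one enrolled patient.

    Tri-state clinical flags use ``True``/``False``/``None`` (unknown);
    unknown never counts toward a numerator and is dropped from denominators.
    """

    patient_id: str
    family_id: str
    variant_ids: List[str]
    enrollment_status: str
    sex: Optional[str] = None
    age_at_diagnosis: Optional[float] = None
    hpo_terms: Set[str] = field(default_factory=set)
    platelet_count: Optional[float] = None  # 1e9/L, automated
    platelet_count_microscopy: Optional[float] = None
    mpv: Optional[float] = None
    bleeding_score: Optional[int] = None
    macrothrombocytes: Optional[bool] = None
    thrombocytopenia: Optional[bool] = None
    dohle_bodies: str = "unknown"  # reported | absent | unknown
    dohle_method: Optional[str] = None  # MGG | immunofluorescence
    hearing_impairment: Optional[bool] = None
    nephropathy: Optional[bool] = None
    liver_enzyme_elevation: Optional[bool] = None
    cataract: Optional[bool] = None
    menorrhagia: Optional[bool] = None
    family_history_myh9rd: Optional[bool] = None
    phenotype_specific: Optional[bool] = None  # reviewer's PP4 flag

    def __post_init__(self) -> None:
        if not self.variant_ids:
            raise ValueError(f"patient {self.patient_id} carries no variant")
        if self.enrollment_status not in ENROLLMENT_STATUSES:
            raise ValueError(
                f"unknown enrollment status {self.enrollment_status!r} "
                f"for patient {self.patient_id}"
            )
        for name in ("platelet_count", "platelet_count_microscopy"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bleeding_score is not None:
            lo, hi = BLEEDING_SCORE_RANGE
            if not lo <= self.bleeding_score <= hi:
                raise ValueError(f"bleeding score {self.bleeding_score} outside {lo}..{hi}")
        if self.dohle_bodies not in ("reported", "absent", "unknown"):
            raise ValueError(f"invalid dohle_bodies state {self.dohle_bodies!r}")
        if self.thrombocytopenia is None and self.platelet_count is not None:
            self.thrombocytopenia = thrombocytopenia_flag(self.platelet_count)

    def has_extra_hematologic_feature(self) -> bool:
        """At least one main syndromic feature beyond macrothrombocytes.

        The features are Dohle-like inclusion bodies, hearing impairment,
        nephropathy and liver-enzyme alteration (the basis of the disease-
        specific descriptive evidence code A).
        """
        return bool(
            self.dohle_bodies == "reported"
            or self.hearing_impairment
            or self.nephropathy
            or self.liver_enzyme_elevation
        )

    def phenotype_observed(self) -> bool:
        return (
            self.macrothrombocytes is not None
            or self.platelet_count is not None
            or self.thrombocytopenia is not None
            or self.has_extra_hematologic_feature()
        )


def severity_group(platelet_count: Optional[float], cutoff: float = 50.0) -> Optional[str]:
    """Severity stratum by platelet count: <=cutoff severe/moderate, else mild."""
    if platelet_count is None or pd.isna(platelet_count):
        logger.info("platelet count missing; patient excluded from stratification")
        return None
    return "severe_moderate" if platelet_count <= cutoff else "mild"


def thrombocytopenia_flag(
    platelet_count: Optional[float], threshold: float = 150.0
) -> Optional[bool]:
    """True when the platelet count is strictly below the threshold."""
    if platelet_count is None or pd.isna(platelet_count):
        logger.info("platelet count missing; thrombocytopenia not evaluable")
        return None
    return platelet_count < threshold


def attribute_domain(
    patient: PatientRecord,
    variant_domains: Mapping[str, str],
    variant_residues: Mapping[str, int],
    final_classes: Mapping[str, str],
) -> Tuple[str, str]:
    """Pick the single (variant, domain) a multi-variant patient is counted under.

    The variant with the higher final classification wins; ties go to the
    higher residue position.  Returns (variant_id, domain).
    """
    def key(vid: str):
        return (CLASS_RANK.get(final_classes.get(vid, "VUS"), 2), variant_residues[vid])

    best = max(patient.variant_ids, key=key)
    if len(patient.variant_ids) > 1:
        logger.info(
            "patient %s carries %d variants; attributed to %s (%s)",
            patient.patient_id, len(patient.variant_ids), best, variant_domains[best],
        )
    return best, variant_domains[best]


@dataclass
class CohortSummary:
    """Aggregate counts with explicit denominators for every proportion."""

    n_patients: int
    n_index_cases: int
    n_variants: int
    n_novel: int
    consequence_counts: Dict[str, int]
    domain_counts: Dict[str, int]
    distinct_exons: int
    enrollment_counts: Dict[str, int] = field(default_factory=dict)
    phenotype_by_domain: Dict[str, Dict[str, Tuple[int, int]]] = field(default_factory=dict)
    severity_by_domain: Dict[str, Dict[str, Tuple[int, int]]] = field(default_factory=dict)
    new_diagnoses: Optional[int] = None

    def to_dict(self) -> dict:
        def frac(table):
            return {
                pheno: {
                    dom: {
                        "numerator": num,
                        "denominator": den,
                        "fraction": (num / den) if den else None,
                        "percent": round(100.0 * num / den, 1) if den else None,
                    }
                    for dom, (num, den) in doms.items()
                }
                for pheno, doms in table.items()
            }

        return {
            "n_patients": self.n_patients,
            "n_index_cases": self.n_index_cases,
            "n_variants": self.n_variants,
            "n_novel": self.n_novel,
            "consequence_counts": dict(self.consequence_counts),
            "domain_counts": dict(self.domain_counts),
            "distinct_exons": self.distinct_exons,
            "enrollment_counts": dict(self.enrollment_counts),
            "phenotype_by_domain": frac(self.phenotype_by_domain),
            "severity_by_domain": frac(self.severity_by_domain),
            "new_diagnoses": self.new_diagnoses,
        }


def spectrum_summary(
    variant_table: pd.DataFrame,
    known_hgvs_p: Optional[Iterable[str]] = None,
    arch: Optional[DomainArchitecture] = None,
) -> Dict[str, object]:
    """Summarise a (patient x variant) long table into spectrum counts.

    Variants are deduplicated on (hgvs_c, hgvs_p).  Novelty is judged against
    a supplied registry of known protein changes when given, otherwise a
    ``novel`` column is used.  Duplicate patient-variant rows collapse with a
    warning; the result is invariant under row order and repeated application.
    """
    required = {"hgvs_c", "hgvs_p", "exon"}
    missing = required - set(variant_table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    df = variant_table.copy()
    if "patient_id" in df.columns:
        before = len(df)
        df = df.drop_duplicates(subset=["patient_id", "hgvs_c", "hgvs_p"])
        if len(df) < before:
            logger.warning("collapsed %d duplicate patient-variant rows", before - len(df))

    unique = df.drop_duplicates(subset=["hgvs_c", "hgvs_p"]).copy()
    changes = [parse_hgvs_p(p) for p in unique["hgvs_p"]]
    unique["consequence"] = [classify_consequence(c).value for c in changes]
    unique["domain"] = [domain_of_exon(int(e), arch) for e in unique["exon"]]

    if known_hgvs_p is not None:
        known = set(known_hgvs_p)
        unique["is_novel"] = [p not in known for p in unique["hgvs_p"]]
    elif "novel" in unique.columns:
        unique["is_novel"] = unique["novel"].astype(bool)
    else:
        raise ValueError("need a known-variant registry or a 'novel' column")

    return {
        "n_unique_variants": int(len(unique)),
        "n_novel": int(unique["is_novel"].sum()),
        "consequence_counts": unique["consequence"].value_counts().to_dict(),
        "domain_counts": unique["domain"].value_counts().to_dict(),
        "novel_domain_counts": unique.loc[unique["is_novel"], "domain"]
        .value_counts()
        .to_dict(),
        "distinct_exons": int(unique["exon"].nunique()),
        "distinct_families": (
            int(df["family_id"].nunique()) if "family_id" in df.columns else None
        ),
        "n_patients": (
            int(df["patient_id"].nunique()) if "patient_id" in df.columns else None
        ),
    }


def new_diagnosis_count(
    patients: Sequence[PatientRecord],
    final_class_by_patient: Mapping[str, str],
) -> int:
    """Patients newly diagnosed by sequencing.

    A new molecular diagnosis requires an enrollment status of unclassified
    platelet disorder or suspected-but-unconfirmed disease, plus a carried
    variant whose final class is likely pathogenic or pathogenic.  Patients
    with a missing status or class are skipped with a log record.
    """
    eligible = {"unclassified_platelet_disorder", "suspected_MYH9RD"}
    count = 0
    for p in patients:
        klass = final_class_by_patient.get(p.patient_id)
        if klass is None:
            logger.info("patient %s has no final class; skipped", p.patient_id)
            continue
        if p.enrollment_status in eligible and klass in ("likely_pathogenic", "pathogenic"):
            count += 1
    return count


_PHENOTYPE_FIELDS = (
    "thrombocytopenia",
    "hearing_impairment",
    "nephropathy",
    "liver_enzyme_elevation",
    "bleeding",  # derived: bleeding_score > 0
)


def domain_phenotype_table(
    patients: Sequence[PatientRecord],
    variant_domains: Mapping[str, str],
    variant_residues: Mapping[str, int],
    final_classes: Mapping[str, str],
    severity_cutoff: float = 50.0,
) -> Tuple[Dict[str, Dict[str, Tuple[int, int]]], Dict[str, Dict[str, Tuple[int, int]]]]:
    """Domain-stratified phenotype proportions and severity split.

    Returns (phenotype_by_domain, severity_by_domain); each cell is a
    (numerator, denominator) pair.  For phenotypes the denominator is the
    number of patients attributed to the domain whose flag is known; for
    severity the denominator is the number of patients in the severity group
    with a known platelet count (so the by-domain fractions within a group
    sum to 1).
    """
    attributed: List[Tuple[PatientRecord, str]] = []
    for p in patients:
        _, dom = attribute_domain(p, variant_domains, variant_residues, final_classes)
        attributed.append((p, dom))

    domains = sorted({dom for _, dom in attributed})
    pheno_table: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for pheno in _PHENOTYPE_FIELDS:
        row: Dict[str, Tuple[int, int]] = {}
        for dom in domains:
            num = den = 0
            for p, d in attributed:
                if d != dom:
                    continue
                if pheno == "bleeding":
                    flag = None if p.bleeding_score is None else p.bleeding_score > 0
                else:
                    flag = getattr(p, pheno)
                if flag is None:
                    continue
                den += 1
                num += bool(flag)
            row[dom] = (num, den)
        pheno_table[pheno] = row

    groups: Dict[str, List[str]] = {}
    for p, dom in attributed:
        grp = severity_group(p.platelet_count, cutoff=severity_cutoff)
        if grp is None:
            continue
        groups.setdefault(grp, []).append(dom)
    severity_table: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for grp, doms in groups.items():
        den = len(doms)
        severity_table[grp] = {dom: (doms.count(dom), den) for dom in sorted(set(doms))}
    return pheno_table, severity_table
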