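"""Packaged study cohort: 28 unique MYH9 variants carried by 50 patients.

The tables transcribe the published report of this cohort (variant notation,
exon and domain placement, CADD scores, population allele frequencies,
evidence-code strings, classifications, contribution labels, enrollment
statuses and family structure).  One patient (39) carries two variants, so
the 50 patients correspond to 51 patient-variant pairs; 44 patients are
index cases of distinct pedigrees.

File checksums guard against silent edits: the spectrum counts asserted by
the test-suite are only meaningful for this exact transcription.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List

import pandas as pd

from .acmg import EvidenceCode, KnownVariantRegistry, parse_evidence_string
from .cohort import PatientRecord
from .hgvs import (
    PopulationFrequency,
    VariantAnnotations,
    VariantRecord,
    parse_hgvs_c,
    parse_hgvs_p,
)

__all__ = ["FixtureCohort", "load_fixture", "EXCEPTION_LEDGER", "CLASS_TOKENS"]

_CHECKSUMS = {
    "table1_variants.tsv": "c4610f112e5dc636ec0cf85f52793fe27a758c834cd35f235415c74d76ec051b",
    "table1_patients.tsv": "fa9b14b1d0e6ab7775d2a9bf5a3aef1e32762202f54d6df8455742eae9652735",
    "known_registry.tsv": "ad151fbf919285e25c7ccf9373dc769ecd3f91aa21b614228f4f57fd189d1973",
}

CLASS_TOKENS = {
    "Pathogenic": "pathogenic",
    "Likely pathogenic": "likely_pathogenic",
    "VUS": "VUS",
}

#: Variants whose published classification differs from strict rule combining
#: (plus the conservative-novel policy).  The published report does not
#: explain these adjudications; they are recorded verbatim rather than
#: absorbed into the rules.  Values are (engine_class, printed_class).
EXCEPTION_LEDGER: Dict[str, tuple] = {
    # Lys74Glu: PS4_supporting+PM2+PP4+PP3 combines to VUS, printed LP
    "V13": ("VUS", "likely_pathogenic"),
    # Arg1933*: PS4+PM2+PM1+PP4 combines to LP, printed pathogenic
    "V27": ("likely_pathogenic", "pathogenic"),
    # Met1934Trpfs*14: PS4+#PM4+PM2+PM1+PP4 combines to pathogenic, printed LP
    "V28": ("pathogenic", "likely_pathogenic"),
}


class FixtureChecksumError(RuntimeError):
    """Packaged fixture content does not match its recorded checksum."""


@dataclass
class FixtureCohort:
    variants: pd.DataFrame
    patients: pd.DataFrame
    variant_records: Dict[str, VariantRecord]
    patient_records: List[PatientRecord]
    evidence: Dict[str, List[EvidenceCode]]
    classification_printed: Dict[str, str]
    contribution_printed: Dict[str, str]
    registry: KnownVariantRegistry

    @property
    def n_patients(self) -> int:
        return len(self.patient_records)

    @property
    def n_variants(self) -> int:
        return len(self.variant_records)


def _read_packaged(name: str) -> bytes:
    data = resources.files("myh9rd.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _CHECKSUMS[name]
    if digest != expected:
        raise FixtureChecksumError(
            f"{name}: checksum {digest} != expected {expected}; "
            "the packaged fixture has been modified"
        )
    return data


def _tri(value) -> object:
    if pd.isna(value) or value == "":
        return None
    return bool(int(value))


def _opt_float(value):
    if pd.isna(value) or value == "":
        return None
    return float(value)


def load_fixture() -> FixtureCohort:
    """Load and validate the packaged cohort tables."""
    import io as _io

    variants = pd.read_csv(
        _io.BytesIO(_read_packaged("table1_variants.tsv")), sep="\t", dtype=str
    )
    patients = pd.read_csv(
        _io.BytesIO(_read_packaged("table1_patients.tsv")), sep="\t", dtype=str
    )
    registry_df = pd.read_csv(
        _io.BytesIO(_read_packaged("known_registry.tsv")), sep="\t", dtype=str
    )

    registry = KnownVariantRegistry(
        (row.hgvs_p, int(row.residue), row.classification)
        for row in registry_df.itertuples()
    )

    variant_records: Dict[str, VariantRecord] = {}
    evidence: Dict[str, List[EvidenceCode]] = {}
    classification_printed: Dict[str, str] = {}
    for row in variants.itertuples():
        annotations = VariantAnnotations(cadd_score=_opt_float(row.cadd_score))
        freq = PopulationFrequency(
            af_exac=_opt_float(row.af_exac), af_gnomad=_opt_float(row.af_gnomad)
        )
        variant_records[row.variant_id] = VariantRecord(
            id=row.variant_id,
            coding_change=parse_hgvs_c(row.hgvs_c),
            protein_change=parse_hgvs_p(row.hgvs_p),
            exon=int(row.exon),
            gene_region_position=row.gene_region_position,
            novel_flag=bool(int(row.novel)),
            annotations=annotations,
            frequencies=freq,
        )
        evidence[row.variant_id] = parse_evidence_string(row.evidence)
        classification_printed[row.variant_id] = CLASS_TOKENS[row.classification_printed]

    patient_records: List[PatientRecord] = []
    contribution_printed: Dict[str, str] = {}
    for row in patients.itertuples():
        rec = PatientRecord(
            patient_id=str(row.patient_id),
            family_id=row.family_id,
            variant_ids=row.variant_ids.split(";"),
            enrollment_status=row.enrollment_status,
            platelet_count=_opt_float(row.platelet_count),
            thrombocytopenia=_tri(row.thrombocytopenia),
            macrothrombocytes=_tri(row.macrothrombocytes),
            dohle_bodies=(row.dohle_bodies if isinstance(row.dohle_bodies, str) else "unknown"),
            dohle_method=(row.dohle_method if isinstance(row.dohle_method, str) else None),
            hearing_impairment=_tri(row.hearing_impairment),
            nephropathy=_tri(row.nephropathy),
            liver_enzyme_elevation=_tri(row.liver_enzyme_elevation),
            family_history_myh9rd=_tri(row.family_history_myh9rd),
            phenotype_specific=_tri(row.phenotype_specific),
        )
        for vid in rec.variant_ids:
            if vid not in variant_records:
                raise ValueError(f"patient {rec.patient_id} references unknown {vid}")
        patient_records.append(rec)
        contribution_printed[rec.patient_id] = row.contribution_printed.lower()

    return FixtureCohort(
        variants=variants,
        patients=patients,
        variant_records=variant_records,
        patient_records=patient_records,
        evidence=evidence,
        classification_printed=classification_printed,
        contribution_printed=contribution_printed,
        registry=registry,
    )
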