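"""Synthetic cohort generator with planted, recoverable ground truth.

Emulates the statistical structure the analysis assumes: families each
segregating one rare heterozygous MYH9 variant, domain-dependent platelet
counts (head-domain variants trend more severe), domain-dependent penetrance
of the extra-hematological features, a rare allele-frequency spectrum with
mass at "absent from databases", pedigrees providing cosegregation counts,
and a protein alignment in which mutated residues are fully conserved.

Defaults mirror the study cohort: 44 families (most of size one), domain mix
0.34/0.54/0.12 (HD/TD/NHTD), consequence mix 21:3:2:1:1, enrollment mix
19:11:20, and a planted pathogenic fraction of 16/28.  Every sampled truth
(variant class, exclusion flags, penetrance draws) is emitted alongside the
tables so recovery tests can compare against the plant exactly.

The generator does not emulate: sequencing error, genotype calling,
ascertainment through referral networks, age-dependent penetrance, or
locus/allelic heterogeneity beyond a single variant per family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import PatientRecord
from .constants import PROTEIN_LENGTH
from .domains import HD, NHTD, TD, DomainArchitecture
from .hgvs import (
    PopulationFrequency,
    VariantAnnotations,
    VariantRecord,
    parse_hgvs_c,
    parse_hgvs_p,
)
from .popfilter import CandidateContext

__all__ = ["SimulationConfig", "SimulatedCohort", "generate_cohort", "write_outputs"]

_FEATURES = ("hearing_impairment", "nephropathy", "liver_enzyme_elevation", "dohle")

_AA_POOL = ["Ala", "Arg", "Asn", "Asp", "Gln", "Glu", "Gly", "Leu", "Lys",
            "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val"]
_AA1 = "ARNDQEGLKMFPSTWYV"


def _check_probs(name: str, probs: Dict) -> None:
    vals = list(probs.values())
    if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
        raise ValueError(f"{name} is not a probability vector: {probs}")


@dataclass
class SimulationConfig:
    """Knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    n_families: int = 44
    family_size_probs: Dict[int, float] = field(
        default_factory=lambda: {1: 0.88, 2: 0.08, 3: 0.03, 4: 0.01}
    )
    domain_weights: Dict[str, float] = field(
        default_factory=lambda: {HD: 0.34, TD: 0.54, NHTD: 0.12}
    )
    consequence_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.75,
            "frameshift": 0.107,
            "stop_gain": 0.071,
            "inframe_deletion": 0.036,
            "inframe_insertion": 0.036,
        }
    )
    #: probability a rare variant is absent from population databases
    af_absent_prob: float = 0.8
    #: log10-AF range of the observed rare tail
    af_log10_range: Tuple[float, float] = (-6.0, -4.0)
    #: per-domain lognormal (mu, sigma) of platelet counts, 1e9/L
    platelet_lognormal: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {HD: (3.69, 0.50), TD: (4.09, 0.50), NHTD: (3.56, 0.60)}
    )
    #: P(feature | domain) for the extra-hematological features and inclusions
    penetrance: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "hearing_impairment": {HD: 0.24, TD: 0.18, NHTD: 0.30},
            "nephropathy": {HD: 0.12, TD: 0.02, NHTD: 0.02},
            "liver_enzyme_elevation": {HD: 0.05, TD: 0.03, NHTD: 0.05},
            "dohle": {HD: 1.0, TD: 1.0, NHTD: 1.0},
        }
    )
    enrollment_status_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "unclassified_platelet_disorder": 0.38,
            "suspected_MYH9RD": 0.22,
            "known_MYH9RD_unconfirmed": 0.40,
        }
    )
    planted_pathogenic_fraction: float = 16 / 28
    #: fraction of candidate families planted with an exclusion reason
    exclusion_plant_rate: float = 24 / 74
    #: rate at which planted annotations contradict the true class
    inconsistency_rate: float = 0.0
    alignment_depth: int = 10
    #: fraction of non-variant alignment columns left free to vary
    alignment_variable_fraction: float = 0.3

    def __post_init__(self) -> None:
        _check_probs("family_size_probs", self.family_size_probs)
        _check_probs("domain_weights", self.domain_weights)
        _check_probs("consequence_weights", self.consequence_weights)
        _check_probs("enrollment_status_weights", self.enrollment_status_weights)
        for feat, table in self.penetrance.items():
            for dom, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"penetrance[{feat}][{dom}]={p} outside [0,1]")
        for rate in (self.af_absent_prob, self.planted_pathogenic_fraction,
                     self.exclusion_plant_rate, self.inconsistency_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0,1]")


_DOMAIN_RESIDUES = {HD: (5, 833), TD: (834, 1926), NHTD: (1927, 1950)}
_DOMAIN_EXONS = {HD: (2, 19), TD: (21, 40), NHTD: (41, 41)}


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    variants: pd.DataFrame
    patients: pd.DataFrame
    pedigree: pd.DataFrame
    af_table: pd.DataFrame
    alignment: MultipleSeqAlignment
    variant_records: Dict[str, VariantRecord]
    patient_records: List[PatientRecord]
    contexts: Dict[str, CandidateContext]
    truth: Dict[str, object]


def _sample_variant(rng: np.random.Generator, domain: str, consequence: str,
                    used: set) -> Tuple[str, str, int, int]:
    """Sample a variant with a notation key not yet used in this cohort.

    Residues may recur across families (recurrent variants are a feature of
    real cohorts) but the (coding, protein) notation pair is kept unique so
    deduplicated spectrum counts equal the number of planted variants.
    """
    lo, hi = _DOMAIN_RESIDUES[domain]
    e_lo, e_hi = _DOMAIN_EXONS[domain]
    for _ in range(10000):
        r = int(rng.integers(lo, hi + 1))
        c0 = 3 * r - 2
        offset_in_codon = int(rng.integers(0, 3))
        pos = c0 + offset_in_codon
        ref_b, alt_b = rng.choice(list("ACGT"), size=2, replace=False)
        ref3, alt3 = rng.choice(_AA_POOL, size=2, replace=False)
        if consequence == "missense":
            hgvs_c = f"c.{pos}{ref_b}>{alt_b}"
            hgvs_p = f"p.({ref3}{r}{alt3})"
        elif consequence == "stop_gain":
            hgvs_c = f"c.{pos}{ref_b}>{alt_b}"
            hgvs_p = f"p.({ref3}{r}*)"
        elif consequence == "frameshift":
            max_off = min(20, PROTEIN_LENGTH - r + 1)
            off = int(rng.integers(2, max(3, max_off + 1)))
            hgvs_c = f"c.{pos}del{ref_b}"
            hgvs_p = f"p.({ref3}{r}{alt3}fs*{off})"
        elif consequence == "inframe_deletion":
            hgvs_c = f"c.{c0}_{c0 + 8}delGCAGCAGCA"
            hgvs_p = f"p.({ref3}{r}_{alt3}{r + 2}del)"
        else:  # inframe_insertion, rendered as a duplication
            hgvs_c = f"c.{c0}_{c0 + 8}dupGCAGCAGCA"
            hgvs_p = f"p.({ref3}{r}_{alt3}{r + 2}dup)"
        key = (hgvs_c, hgvs_p)
        if key not in used:
            used.add(key)
            exon = int(rng.integers(e_lo, e_hi + 1))
            return hgvs_c, hgvs_p, exon, r
    raise RuntimeError("variant notation space exhausted")  # pragma: no cover


def generate_cohort(config: Optional[SimulationConfig] = None) -> SimulatedCohort:
    """Sample a full synthetic cohort; reproducible for a fixed config."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    arch = DomainArchitecture()

    sizes = list(config.family_size_probs)
    size_p = [config.family_size_probs[s] for s in sizes]
    domains = list(config.domain_weights)
    dom_p = [config.domain_weights[d] for d in domains]
    consequences = list(config.consequence_weights)
    cons_p = [config.consequence_weights[c] for c in consequences]
    statuses = list(config.enrollment_status_weights)
    status_p = [config.enrollment_status_weights[s] for s in statuses]

    used_keys: set = set()
    variant_residue_set: set = set()
    variant_rows, patient_rows, ped_rows = [], [], []
    variant_records: Dict[str, VariantRecord] = {}
    patient_records: List[PatientRecord] = []
    contexts: Dict[str, CandidateContext] = {}
    truth_class: Dict[str, str] = {}
    truth_domain_patient: Dict[str, str] = {}
    truth_features: Dict[str, Dict[str, bool]] = {}
    truth_excluded: Dict[str, Optional[str]] = {}
    meioses_by_family: Dict[str, int] = {}

    pid = 0
    for fam_idx in range(config.n_families):
        fam = f"SF{fam_idx + 1:04d}"
        vid = f"SV{fam_idx + 1:04d}"
        domain = str(rng.choice(domains, p=dom_p))
        consequence = str(rng.choice(consequences, p=cons_p))
        hgvs_c, hgvs_p, exon, residue = _sample_variant(
            rng, domain, consequence, used_keys
        )
        variant_residue_set.add(residue)
        pathogenic = bool(rng.random() < config.planted_pathogenic_fraction)
        consistent = not (rng.random() < config.inconsistency_rate)
        supportive = pathogenic if consistent else not pathogenic

        absent = bool(rng.random() < config.af_absent_prob)
        if absent:
            af_exac = af_gnomad = None
        else:
            lo10, hi10 = config.af_log10_range
            af_exac = float(10 ** rng.uniform(lo10, hi10))
            af_gnomad = float(10 ** rng.uniform(lo10, hi10))

        annotations = VariantAnnotations(
            cadd_score=float(np.round(rng.uniform(22, 36), 1)) if supportive else
            float(np.round(rng.uniform(5, 15), 1)),
            sift_call="deleterious" if supportive else "benign",
            polyphen_call="deleterious" if supportive else "benign",
            mutation_taster_call="deleterious" if supportive else "benign",
            gvgd_class="C65" if supportive else "C0",
            nucleotide_conserved=supportive,
            aminoacid_conserved=supportive,
            protein_effect_predicted=supportive,
            functional_evidence=bool(supportive and rng.random() < 0.3),
            prevalence_evidence="strong" if (supportive and rng.random() < 0.5) else None,
        )
        freq = PopulationFrequency(af_exac=af_exac, af_gnomad=af_gnomad)
        record = VariantRecord(
            id=vid,
            coding_change=parse_hgvs_c(hgvs_c),
            protein_change=parse_hgvs_p(hgvs_p),
            exon=exon,
            novel_flag=bool(rng.random() < 12 / 28),
            annotations=annotations,
            frequencies=freq,
        )
        variant_records[vid] = record
        truth_class[vid] = "pathogenic" if pathogenic else "uncertain"
        variant_rows.append(
            {
                "variant_id": vid,
                "family_id": fam,
                "hgvs_c": hgvs_c,
                "hgvs_p": hgvs_p,
                "exon": exon,
                "domain": domain,
                "consequence": consequence,
                "residue": residue,
                "af_exac": af_exac,
                "af_gnomad": af_gnomad,
                "novel": int(record.novel_flag),
                "cadd_score": annotations.cadd_score,
                "sift_call": annotations.sift_call,
                "polyphen_call": annotations.polyphen_call,
                "mutation_taster_call": annotations.mutation_taster_call,
                "gvgd_class": annotations.gvgd_class,
                "nucleotide_conserved": int(bool(annotations.nucleotide_conserved)),
                "aminoacid_conserved": int(bool(annotations.aminoacid_conserved)),
                "protein_effect_predicted": int(bool(annotations.protein_effect_predicted)),
                "functional_evidence": int(annotations.functional_evidence),
                "de_novo_status": annotations.de_novo_status,
                "prevalence_evidence": annotations.prevalence_evidence or "",
                "true_class": truth_class[vid],
            }
        )

        size = int(rng.choice(sizes, p=size_p))
        meioses_by_family[fam] = max(0, size - 1)

        excluded_reason = None
        if rng.random() < config.exclusion_plant_rate:
            excluded_reason = str(rng.choice(["a", "b", "c", "d"]))

        mu, sigma = config.platelet_lognormal[domain]
        for member in range(size):
            pid += 1
            pat = f"SP{pid:05d}"
            count = float(np.round(min(400.0, max(1.0, rng.lognormal(mu, sigma))), 0))
            features = {
                feat: bool(rng.random() < config.penetrance[feat][domain])
                for feat in _FEATURES
            }
            status = str(rng.choice(statuses, p=status_p))
            bleeding = int(rng.poisson(3))
            rec = PatientRecord(
                patient_id=pat,
                family_id=fam,
                variant_ids=[vid],
                enrollment_status=status,
                sex=str(rng.choice(["F", "M"])),
                platelet_count=count,
                macrothrombocytes=True,
                dohle_bodies="reported" if features["dohle"] else "absent",
                dohle_method="immunofluorescence",
                hearing_impairment=features["hearing_impairment"],
                nephropathy=features["nephropathy"],
                liver_enzyme_elevation=features["liver_enzyme_elevation"],
                bleeding_score=min(bleeding, 45),
                family_history_myh9rd=size > 1,
                phenotype_specific=True,
            )
            patient_records.append(rec)
            truth_domain_patient[pat] = domain
            truth_features[pat] = features
            truth_excluded[pat] = excluded_reason
            contexts[pat] = CandidateContext(
                non_bpd_carrier_count=1 if excluded_reason == "a" else 0,
                phenotype_compatible=excluded_reason != "b",
                alternate_gene_diagnosis=excluded_reason == "c",
                present_in_unaffected_relative=excluded_reason == "d",
            )
            patient_rows.append(
                {
                    "patient_id": pat,
                    "family_id": fam,
                    "variant_ids": vid,
                    "enrollment_status": status,
                    "sex": rec.sex,
                    "platelet_count": count,
                    "bleeding_score": rec.bleeding_score,
                    "macrothrombocytes": 1,
                    "dohle_bodies": rec.dohle_bodies,
                    "hearing_impairment": int(features["hearing_impairment"]),
                    "nephropathy": int(features["nephropathy"]),
                    "liver_enzyme_elevation": int(features["liver_enzyme_elevation"]),
                    "family_history_myh9rd": int(size > 1),
                    "phenotype_specific": 1,
                    "excluded_reason": excluded_reason or "",
                }
            )
            # nuclear pedigree: affected members are carriers, founders added once
            father, mother = f"{fam}_FA", f"{fam}_MO"
            ped_rows.append([fam, pat, father if size > 1 else "0",
                             mother if size > 1 else "0",
                             1 if rec.sex == "M" else 2, 2])
        if size > 1:
            ped_rows.append([fam, f"{fam}_FA", "0", "0", 1, 1])
            ped_rows.append([fam, f"{fam}_MO", "0", "0", 2, 2])

    variants = pd.DataFrame(variant_rows)
    patients = pd.DataFrame(patient_rows)
    pedigree = pd.DataFrame(
        ped_rows, columns=["family_id", "individual_id", "father_id", "mother_id",
                           "sex", "phenotype"]
    )
    af_table = variants[["hgvs_c", "af_exac", "af_gnomad"]].copy()

    alignment = _build_alignment(rng, config, sorted(variant_residue_set))

    truth = {
        "penetrance": config.penetrance,
        "planted_pathogenic_fraction": config.planted_pathogenic_fraction,
        "true_class": truth_class,
        "patient_domain": truth_domain_patient,
        "patient_features": truth_features,
        "excluded_reason": truth_excluded,
        "n_excluded_patients": sum(1 for r in truth_excluded.values() if r),
        "meioses_by_family": meioses_by_family,
    }
    return SimulatedCohort(
        config=config,
        variants=variants,
        patients=patients,
        pedigree=pedigree,
        af_table=af_table,
        alignment=alignment,
        variant_records=variant_records,
        patient_records=patient_records,
        contexts=contexts,
        truth=truth,
    )


def _build_alignment(rng: np.random.Generator, config: SimulationConfig,
                     variant_residues: List[int]) -> MultipleSeqAlignment:
    """Protein MSA whose mutated columns are fully conserved by construction."""
    ref = rng.choice(list(_AA1), size=PROTEIN_LENGTH)
    depth = config.alignment_depth
    rows = [ref.copy() for _ in range(depth)]
    variant_set = set(variant_residues)
    variable = rng.random(PROTEIN_LENGTH) < config.alignment_variable_fraction
    for col in range(PROTEIN_LENGTH):
        if (col + 1) in variant_set or not variable[col]:
            continue
        for row in rows[1:]:
            if rng.random() < 0.5:
                row[col] = rng.choice(list(_AA1))
    records = [
        SeqRecord(Seq("".join(row)), id=("reference" if i == 0 else f"ortholog_{i}"),
                  description="")
        for i, row in enumerate(rows)
    ]
    return MultipleSeqAlignment(records)


def write_outputs(cohort: SimulatedCohort, outdir) -> Dict[str, str]:
    """Write the generated tables in the dialects the pipeline reads."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in (
        ("variants.tsv", cohort.variants),
        ("patients.tsv", cohort.patients),
        ("af_table.tsv", cohort.af_table),
    ):
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    ped_path = os.path.join(outdir, "pedigree.ped")
    cohort.pedigree.to_csv(ped_path, sep="\t", index=False, header=False)
    paths["pedigree.ped"] = ped_path
    fasta_path = os.path.join(outdir, "alignment.fasta")
    with open(fasta_path, "w") as fh:
        for rec in cohort.alignment:
            fh.write(f">{rec.id}\n{str(rec.seq)}\n")
    paths["alignment.fasta"] = fasta_path
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    paths["truth.json"] = truth_path
    return paths
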