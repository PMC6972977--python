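"""ACMG/AMP evidence assignment and combining, with the disease-specific scheme.

Evidence codes carry a strength level (very strong / strong / moderate /
supporting) that may be modulated away from the prefix default, rendered with
the conventional suffix tokens (``PS4_supporting``, ``PP1_strong``).  Two
extensions are specific to MYH9-related disorder practice:

* ``#PM4`` replaces PVS1 when a truncation terminates within the protein's
  last 50 residues; it counts at moderate strength and records the
  substitution.
* Codes ``A`` (at least one main syndromic feature beyond macrothrombocytes)
  and ``B`` (family history of the disorder) are descriptive context: they
  justify phenotype-level judgments but are excluded from numeric combining.
  Rows such as "PM2, A, B" classifying as VUS are only consistent with this
  reading.

Combining follows the Richards et al. 2015 rule table applied to the counts
of effective levels, extended by one monotone-closure clause (two very-strong
codes classify as pathogenic).  Benign-side codes are supported analogously;
simultaneous pathogenic- and benign-side hits resolve to VUS.

A named, toggleable policy reproduces the conservative handling of novel
variants: a novel variant is capped at VUS unless some independent
corroboration backs it (functional data PS3, a known pathogenic change at
the same residue PM5, a mutational hotspot PM1, or any strong-level code).
Predicted impact alone - even PVS1 - does not lift the cap.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .cohort import PatientRecord
from .constants import LAST50_BOUNDARY
from .domains import DomainArchitecture, in_hotspot
from .hgvs import ProteinKind, VariantRecord, termination_position
from .popfilter import RarityThresholds, rarity_assess

logger = logging.getLogger(__name__)

__all__ = [
    "VERY_STRONG", "STRONG", "MODERATE", "SUPPORTING", "DESCRIPTIVE",
    "EvidenceCode", "parse_evidence_token", "parse_evidence_string",
    "format_evidence_code",
    "classify_pathogenic_counts", "classify_benign_counts", "combine_evidence",
    "Classification", "EnginePolicy", "apply_policy",
    "contribution_assignment", "assign_evidence",
    "KnownVariantRegistry",
]

VERY_STRONG = "very_strong"
STRONG = "strong"
MODERATE = "moderate"
SUPPORTING = "supporting"
DESCRIPTIVE = "descriptive"
STAND_ALONE = "stand_alone"

DEFAULT_LEVELS: Dict[str, str] = {
    "PVS1": VERY_STRONG,
    **{f"PS{i}": STRONG for i in range(1, 5)},
    **{f"PM{i}": MODERATE for i in range(1, 7)},
    **{f"PP{i}": SUPPORTING for i in range(1, 6)},
    "A": DESCRIPTIVE,
    "B": DESCRIPTIVE,
    # benign side (exercised in tests; combining handles them analogously)
    "BA1": STAND_ALONE,
    **{f"BS{i}": STRONG for i in range(1, 5)},
    **{f"BP{i}": SUPPORTING for i in range(1, 8)},
}

_LEVEL_SUFFIX = {
    "very_strong": VERY_STRONG,
    "strong": STRONG,
    "moderate": MODERATE,
    "supporting": SUPPORTING,
}


@dataclass(frozen=True)
class EvidenceCode:
    """One evidence code with its effective strength level."""

    base: str
    level: str
    modulated: bool = False
    substituted_for: Optional[str] = None

    def __post_init__(self) -> None:
        if self.base not in DEFAULT_LEVELS:
            raise ValueError(f"unknown evidence code {self.base!r}")
        if DEFAULT_LEVELS[self.base] is DESCRIPTIVE and self.level != DESCRIPTIVE:
            raise ValueError(f"code {self.base} is descriptive-only")

    @property
    def side(self) -> str:
        if self.level is DESCRIPTIVE or self.level == DESCRIPTIVE:
            return "descriptive"
        return "benign" if self.base.startswith("B") else "pathogenic"


def _code(base: str, level: Optional[str] = None, substituted_for: Optional[str] = None
          ) -> EvidenceCode:
    default = DEFAULT_LEVELS[base]
    lvl = level or default
    return EvidenceCode(
        base=base, level=lvl, modulated=(lvl != default), substituted_for=substituted_for
    )


_TOKEN = re.compile(r"^(?P<hash>#?)(?P<base>[A-Z]+\d*)(?:_(?P<suffix>[a-z_]+))?$")


def parse_evidence_token(token: str) -> EvidenceCode:
    """Parse one printed evidence token, e.g. ``PS4_supporting`` or ``#PM4``."""
    m = _TOKEN.match(token.strip())
    if not m:
        raise ValueError(f"malformed evidence token {token!r}")
    base = m.group("base")
    if base not in DEFAULT_LEVELS:
        raise ValueError(f"unknown evidence code {base!r} in token {token!r}")
    level = None
    if m.group("suffix"):
        if m.group("suffix") not in _LEVEL_SUFFIX:
            raise ValueError(f"unknown strength suffix in token {token!r}")
        level = _LEVEL_SUFFIX[m.group("suffix")]
    substituted = "PVS1" if m.group("hash") else None
    if substituted and base != "PM4":
        raise ValueError(f"'#' substitution marker only applies to PM4: {token!r}")
    return _code(base, level, substituted_for=substituted)


def parse_evidence_string(text: str) -> List[EvidenceCode]:
    """Parse a comma-separated printed evidence list."""
    tokens = [t for t in (tok.strip() for tok in text.split(",")) if t]
    return [parse_evidence_token(t) for t in tokens]


def format_evidence_code(code: EvidenceCode) -> str:
    prefix = "#" if code.substituted_for else ""
    suffix = f"_{code.level}" if code.modulated else ""
    return f"{prefix}{code.base}{suffix}"


# ---------------------------------------------------------------------------
# combining rules


def classify_pathogenic_counts(nvs: int, ns: int, nm: int, np_: int) -> str:
    """Richards 2015 pathogenic/likely-pathogenic table over level counts.

    One clause beyond the published list: two or more very-strong codes
    classify as pathogenic (monotone closure; the published table only
    anticipates a single PVS1).
    """
    pathogenic = (
        (nvs >= 1 and (ns >= 1 or nm >= 2 or (nm >= 1 and np_ >= 1) or np_ >= 2))
        or nvs >= 2
        or ns >= 2
        or (ns >= 1 and (nm >= 3 or (nm >= 2 and np_ >= 2) or (nm >= 1 and np_ >= 4)))
    )
    if pathogenic:
        return "pathogenic"
    likely = (
        (nvs >= 1 and nm >= 1)
        or (ns >= 1 and nm >= 1)
        or (ns >= 1 and np_ >= 2)
        or nm >= 3
        or (nm >= 2 and np_ >= 2)
        or (nm >= 1 and np_ >= 4)
    )
    return "likely_pathogenic" if likely else "VUS"


def classify_benign_counts(nba: int, nbs: int, nbp: int) -> str:
    """Benign-side combining: stand-alone or >=2 strong -> benign;
    1 strong + 1 supporting or >=2 supporting -> likely benign."""
    if nba >= 1 or nbs >= 2:
        return "benign"
    if (nbs >= 1 and nbp >= 1) or nbp >= 2:
        return "likely_benign"
    return "VUS"


def _effective_counts(codes: Iterable[EvidenceCode]) -> Tuple[int, int, int, int, int, int, int]:
    nvs = ns = nm = np_ = nba = nbs = nbp = 0
    for c in codes:
        if c.side == "descriptive":
            continue
        if c.side == "benign":
            if c.level == STAND_ALONE:
                nba += 1
            elif c.level == STRONG:
                nbs += 1
            else:
                nbp += 1
        else:
            if c.level == VERY_STRONG:
                nvs += 1
            elif c.level == STRONG:
                ns += 1
            elif c.level == MODERATE:
                nm += 1
            elif c.level == SUPPORTING:
                np_ += 1
    return nvs, ns, nm, np_, nba, nbs, nbp


def combine_evidence(codes: Iterable[EvidenceCode]) -> str:
    """Strict classification from an evidence code set.

    Descriptive codes (A, B) are ignored; modulated levels replace defaults;
    conflicting pathogenic- and benign-side outcomes resolve to VUS.  The
    result depends only on the multiset of effective levels.
    """
    nvs, ns, nm, np_, nba, nbs, nbp = _effective_counts(codes)
    path = classify_pathogenic_counts(nvs, ns, nm, np_)
    ben = classify_benign_counts(nba, nbs, nbp)
    if path != "VUS" and ben != "VUS":
        logger.warning("conflicting pathogenic and benign evidence; resolving to VUS")
        return "VUS"
    return path if path != "VUS" else ben


# ---------------------------------------------------------------------------
# policy and contribution


@dataclass(frozen=True)
class EnginePolicy:
    """Toggleable classification policies."""

    conservative_novel_cap: bool = True


@dataclass
class Classification:
    """Final verdict plus contribution-to-phenotype and audit trail."""

    klass: str
    contribution: Optional[str] = None
    policy_applied: Optional[str] = None
    audit: List[Tuple[str, str]] = field(default_factory=list)


def _cap_exempt(codes: Sequence[EvidenceCode]) -> Optional[str]:
    """Corroborating evidence that lifts the conservative-novel cap, if any."""
    for c in codes:
        if c.base in ("PS3", "PM5", "PM1"):
            return c.base
        if c.side == "pathogenic" and c.level == STRONG:
            return format_evidence_code(c)
    return None


def apply_policy(
    strict: str,
    codes: Sequence[EvidenceCode],
    novel: bool,
    policy: Optional[EnginePolicy] = None,
) -> Classification:
    """Apply named post-combining policies to a strict classification.

    The conservative-novel cap limits a novel variant to VUS when nothing
    beyond predicted impact supports it: no functional evidence, no
    same-residue pathogenic precedent, no hotspot, and no strong-level code.
    Every override is recorded in the audit with the policy name.
    """
    policy = policy or EnginePolicy()
    result = Classification(klass=strict)
    result.audit.append(("strict_combining", strict))
    if (
        policy.conservative_novel_cap
        and novel
        and strict in ("likely_pathogenic", "pathogenic")
    ):
        exempt = _cap_exempt(codes)
        if exempt is None:
            result.klass = "VUS"
            result.policy_applied = "conservative_novel_cap"
            result.audit.append(("conservative_novel_cap", f"{strict} -> VUS"))
        else:
            result.audit.append(("conservative_novel_cap", f"exempt via {exempt}"))
    return result


def contribution_assignment(
    classification: Classification, patient: Optional[PatientRecord]
) -> str:
    """Contribution-to-phenotype label: full / uncertain.

    Full requires macrothrombocytes together with either thrombocytopenia or
    a corroboration outside the hematologic core: hearing impairment,
    nephropathy, liver-enzyme alteration, or a family history of the
    disorder.  Inclusion bodies alone do not complete the picture - a patient
    with macrothrombocytes, inclusions and a normal platelet count remains
    uncertain, as does a patient with no phenotype data at all.
    """
    if patient is None or not patient.phenotype_observed():
        logger.warning("no phenotype data; contribution uncertain")
        classification.contribution = "uncertain"
        return "uncertain"
    corroborated = bool(
        patient.hearing_impairment
        or patient.nephropathy
        or patient.liver_enzyme_elevation
        or patient.family_history_myh9rd
    )
    if patient.macrothrombocytes and (patient.thrombocytopenia or corroborated):
        classification.contribution = "full"
    else:
        classification.contribution = "uncertain"
    return classification.contribution


# ---------------------------------------------------------------------------
# evidence assignment


class KnownVariantRegistry:
    """Registry of previously reported (known pathogenic) protein changes."""

    def __init__(self, entries: Iterable[Tuple[str, int, str]] = ()):
        # entries: (hgvs_p, residue, classification)
        self._by_hgvs: Dict[str, str] = {}
        self._residues: Dict[int, Set[str]] = {}
        for hgvs_p, residue, klass in entries:
            self.add(hgvs_p, residue, klass)

    def add(self, hgvs_p: str, residue: int, klass: str = "pathogenic") -> None:
        self._by_hgvs[hgvs_p] = klass
        self._residues.setdefault(residue, set()).add(hgvs_p)

    def contains(self, hgvs_p: str) -> bool:
        return hgvs_p in self._by_hgvs

    def known_hgvs_p(self) -> Set[str]:
        return set(self._by_hgvs)

    def pathogenic_missense_at(self, residue: int, other_than: str) -> bool:
        """A different pathogenic change recorded at the same residue (PM5)."""
        return any(
            h != other_than and self._by_hgvs[h] in ("pathogenic", "likely_pathogenic")
            for h in self._residues.get(residue, ())
        )


#: informative-meioses tiers for cosegregation strength (package convention)
PP1_TIERS = ((7, STRONG), (4, MODERATE), (2, SUPPORTING))


def _pp1_level(informative_meioses: Optional[int]) -> Optional[str]:
    if informative_meioses is None:
        return None
    for cutoff, level in PP1_TIERS:
        if informative_meioses >= cutoff:
            return level
    return None


def assign_evidence(
    variant: VariantRecord,
    patient: Optional[PatientRecord] = None,
    informative_meioses: Optional[int] = None,
    registry: Optional[KnownVariantRegistry] = None,
    arch: Optional[DomainArchitecture] = None,
    thresholds: Optional[RarityThresholds] = None,
    lof_mechanism: bool = True,
) -> List[EvidenceCode]:
    """Derive the evidence code set for one patient-variant pair.

    Implements: PVS1 / #PM4 for truncations split at the last-50-residue
    boundary; PM4 for in-frame length changes; PM2 from rarity; PM1 from
    hotspots; PM5 from the registry; PS2/PM6 from de novo status; PP1 tiers
    from cosegregation; the conjunctive PP3 (all conservation and predictor
    lines must agree); PP4 from the phenotype-specificity flag; PS3 from
    functional evidence; PS4 from the prevalence input; and descriptive A/B.
    Missing annotations withhold the dependent code, never grant it.
    """
    arch = arch or DomainArchitecture()
    ann = variant.annotations
    codes: List[EvidenceCode] = []
    withheld: List[str] = []

    tp = termination_position(variant.protein_change)
    if tp is not None:
        if tp <= LAST50_BOUNDARY:
            if lof_mechanism:
                codes.append(_code("PVS1"))
        else:
            codes.append(_code("PM4", substituted_for="PVS1"))
    elif variant.protein_change.kind in (
        ProteinKind.INFRAME_DELETION,
        ProteinKind.INFRAME_DUPLICATION,
    ):
        codes.append(_code("PM4"))

    if rarity_assess(variant.frequencies, thresholds).pm2_eligible:
        codes.append(_code("PM2"))

    if in_hotspot(variant.protein_change, arch):
        codes.append(_code("PM1"))

    if variant.protein_change.kind is ProteinKind.MISSENSE and registry is not None:
        if registry.pathogenic_missense_at(
            variant.protein_change.residue_start, other_than=variant.hgvs_p
        ):
            codes.append(_code("PM5"))

    if ann.de_novo_status == "confirmed":
        codes.append(_code("PS2"))
    elif ann.de_novo_status == "assumed":
        codes.append(_code("PM6"))

    pp1 = _pp1_level(informative_meioses)
    if pp1 is not None:
        codes.append(_code("PP1", pp1))

    pp3_lines = (
        ann.nucleotide_conserved,
        ann.aminoacid_conserved,
        ann.protein_effect_predicted,
        (ann.gvgd_class == "C65") if ann.gvgd_class is not None else None,
        (ann.sift_call == "deleterious") if ann.sift_call is not None else None,
        (ann.mutation_taster_call == "deleterious")
        if ann.mutation_taster_call is not None
        else None,
        (ann.polyphen_call == "deleterious") if ann.polyphen_call is not None else None,
    )
    if all(line is True for line in pp3_lines):
        codes.append(_code("PP3"))
    elif any(line is None for line in pp3_lines) and not any(
        line is False for line in pp3_lines
    ):
        withheld.append("PP3")

    if patient is not None and patient.phenotype_specific:
        codes.append(_code("PP4"))

    if ann.functional_evidence:
        codes.append(_code("PS3"))

    if ann.prevalence_evidence == "strong":
        codes.append(_code("PS4"))
    elif ann.prevalence_evidence == "supporting":
        codes.append(_code("PS4", SUPPORTING))

    if patient is not None:
        if patient.has_extra_hematologic_feature():
            codes.append(_code("A"))
        if patient.family_history_myh9rd:
            codes.append(_code("B"))

    if withheld:
        logger.info(
            "evidence withheld on missing annotations for %s: %s",
            variant.id, ", ".join(withheld),
        )
    return codes
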