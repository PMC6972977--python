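"""Allele-frequency rarity assessment and cohort exclusion criteria.

Rarity is judged against ExAC/gnomAD extracts and an internal control cohort
of non-bleeding/platelet-disorder participants (>13,000 in the study design).
The default PM2 eligibility threshold is an allele frequency of 1e-4 with no
internal control carriers; no published numeric cutoff exists for this
disorder, so both thresholds are configuration.

Candidate carriers are removed from a cohort for any of four reasons:
(a) the variant also occurs in non-BPD participants, (b) the phenotype is
incompatible with the disorder (e.g. thrombocytosis), (c) a causal variant
in another gene explains the phenotype, (d) the variant occurs in an
unaffected family member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Optional, Set

from .hgvs import PopulationFrequency

logger = logging.getLogger(__name__)

__all__ = [
    "RarityVerdict",
    "RarityAssessment",
    "RarityThresholds",
    "rarity_assess",
    "CandidateContext",
    "ExclusionAssessment",
    "apply_exclusion_criteria",
    "EXCLUSION_REASONS",
]


class RarityVerdict(str, Enum):
    RARE_PM2_ELIGIBLE = "rare_pm2_eligible"
    RARE = "rare"
    COMMON = "common"


@dataclass(frozen=True)
class RarityThresholds:
    """Configurable frequency cutoffs for PM2 eligibility and rarity."""

    pm2_af_max: float = 1e-4
    rare_af_max: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 <= self.pm2_af_max <= self.rare_af_max:
            raise ValueError("require 0 <= pm2_af_max <= rare_af_max")


@dataclass(frozen=True)
class RarityAssessment:
    verdict: RarityVerdict
    max_af: float
    unobserved: bool  # absent from every population database

    @property
    def pm2_eligible(self) -> bool:
        return self.verdict is RarityVerdict.RARE_PM2_ELIGIBLE


def rarity_assess(
    freq: PopulationFrequency,
    thresholds: Optional[RarityThresholds] = None,
) -> RarityAssessment:
    """Classify a variant as PM2-eligible, merely rare, or common.

    Absent frequencies are treated as zero but flagged ``unobserved`` so
    absence-from-database remains distinguishable from an observed AF of 0.
    PM2 additionally requires zero carriers among internal controls.
    """
    thresholds = thresholds or RarityThresholds()
    max_af = freq.max_known_af
    if max_af > thresholds.rare_af_max:
        verdict = RarityVerdict.COMMON
    elif max_af <= thresholds.pm2_af_max and freq.internal_control_carriers == 0:
        verdict = RarityVerdict.RARE_PM2_ELIGIBLE
    else:
        verdict = RarityVerdict.RARE
    return RarityAssessment(verdict=verdict, max_af=max_af, unobserved=freq.unobserved)


EXCLUSION_REASONS = {
    "a": "variant present in non-BPD participants",
    "b": "phenotype incompatible with the disorder",
    "c": "phenotype explained by causal variant in another gene",
    "d": "variant present in an unaffected family member",
}


@dataclass(frozen=True)
class CandidateContext:
    """Review flags attached to one candidate patient-variant pair.

    ``None`` means the flag could not be evaluated; the corresponding
    criterion is then logged as not applicable rather than assumed false.
    """

    non_bpd_carrier_count: Optional[int] = None
    phenotype_compatible: Optional[bool] = None
    alternate_gene_diagnosis: Optional[bool] = None
    present_in_unaffected_relative: Optional[bool] = None


@dataclass(frozen=True)
class ExclusionAssessment:
    reason_codes: FrozenSet[str]
    not_evaluated: FrozenSet[str] = field(default_factory=frozenset)

    @property
    def retained(self) -> bool:
        return not self.reason_codes


def apply_exclusion_criteria(context: CandidateContext) -> ExclusionAssessment:
    """Evaluate the four exclusion criteria against a candidate's context."""
    reasons: Set[str] = set()
    not_evaluated: Set[str] = set()

    if context.non_bpd_carrier_count is None:
        not_evaluated.add("a")
    elif context.non_bpd_carrier_count > 0:
        reasons.add("a")

    if context.phenotype_compatible is None:
        not_evaluated.add("b")
    elif not context.phenotype_compatible:
        reasons.add("b")

    if context.alternate_gene_diagnosis is None:
        not_evaluated.add("c")
    elif context.alternate_gene_diagnosis:
        reasons.add("c")

    if context.present_in_unaffected_relative is None:
        not_evaluated.add("d")
    elif context.present_in_unaffected_relative:
        reasons.add("d")

    if not_evaluated:
        logger.debug(
            "exclusion criteria not evaluable: %s", ", ".join(sorted(not_evaluated))
        )
    return ExclusionAssessment(
        reason_codes=frozenset(reasons), not_evaluated=frozenset(not_evaluated)
    )
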