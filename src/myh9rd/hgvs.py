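"""Parsing, formatting and truncation arithmetic for MYH9 variant notation.

Covers the coding (``c.``) and protein (``p.``) notation forms that occur in
MYH9-related-disorder reports: substitutions, deletions, duplications,
missense, nonsense (with or without a retained substituted residue),
frameshifts with a ``fs*N`` stop offset, and in-frame deletions/duplications.
It is deliberately not a general HGVS implementation: intronic, UTR and
complex delins forms are out of scope.

Protein-level notation is authoritative for consequence typing.  Truncation
arithmetic follows the convention that ``p.(X###Y*)`` retains the substituted
residue with termination immediately after it, so ``p.(Gln890Arg*)`` on the
1,960-residue NMMHC-IIA yields an 890-residue product with 1,070 residues
removed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .constants import FIRST_CODING_EXON, LAST_EXON, PROTEIN_LENGTH

logger = logging.getLogger(__name__)

__all__ = [
    "HgvsParseError",
    "CodingKind",
    "ProteinKind",
    "Consequence",
    "CodingChange",
    "ProteinChange",
    "VariantAnnotations",
    "PopulationFrequency",
    "VariantRecord",
    "parse_hgvs_c",
    "parse_hgvs_p",
    "format_hgvs_c",
    "format_hgvs_p",
    "classify_consequence",
    "truncated_length",
    "residues_removed",
    "termination_position",
]


class HgvsParseError(ValueError):
    """Raised when a variant description cannot be parsed; names the token."""


class CodingKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"


class ProteinKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE_AFTER_SUBSTITUTION = "nonsense_after_substitution"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_DUPLICATION = "inframe_duplication"


class Consequence(str, Enum):
    """Consequence classes as tallied in variant-spectrum summaries."""

    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"


AA3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "Sec", "Ter",
}

_NT = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class CodingChange:
    """A change on the coding DNA sequence (1-based, both ends inclusive)."""

    position_start: int
    position_end: int
    ref_bases: str
    alt_bases: str
    kind: CodingKind

    def __post_init__(self) -> None:
        if self.position_start < 1 or self.position_end < self.position_start:
            raise HgvsParseError(
                f"invalid coding coordinates {self.position_start}_{self.position_end}"
            )
        if self.kind is CodingKind.SUBSTITUTION and (
            len(self.ref_bases) != 1 or len(self.alt_bases) != 1
        ):
            raise HgvsParseError("substitution requires single ref and alt bases")


@dataclass(frozen=True)
class ProteinChange:
    """A change on the protein sequence (1-based residue coordinates)."""

    residue_start: int
    residue_end: int
    ref_aa: str
    alt_aa: str
    kind: ProteinKind
    stop_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.residue_start < 1 or self.residue_end < self.residue_start:
            raise HgvsParseError(
                f"invalid residue interval {self.residue_start}_{self.residue_end}"
            )
        if self.residue_end > PROTEIN_LENGTH:
            raise HgvsParseError(
                f"residue {self.residue_end} beyond protein length {PROTEIN_LENGTH}"
            )
        if self.kind is ProteinKind.FRAMESHIFT and self.stop_offset is not None:
            if self.stop_offset < 1:
                raise HgvsParseError("frameshift stop offset must be >= 1")


_C_SUB = re.compile(r"^(\d+)([ACGT])>([ACGT])$")
_C_RANGE = re.compile(r"^(\d+)(?:_(\d+))?(del|dup|ins|delins)([ACGT]*)$")


def parse_hgvs_c(text: str) -> CodingChange:
    """Parse a coding-DNA variant description such as ``c.97T>G``.

    Raises :class:`HgvsParseError` on malformed input, naming the offending
    token.  Whitespace inside the description (as sometimes printed) is
    tolerated.
    """
    raw = text
    text = re.sub(r"\s+", "", text)
    if not text.startswith("c."):
        raise HgvsParseError(f"missing 'c.' prefix in {raw!r}")
    body = text[2:]
    m = _C_SUB.match(body)
    if m:
        pos = int(m.group(1))
        return CodingChange(pos, pos, m.group(2), m.group(3), CodingKind.SUBSTITUTION)
    m = _C_RANGE.match(body)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        op = m.group(3)
        bases = m.group(4)
        if bases and not _NT.match(bases):
            raise HgvsParseError(f"invalid nucleotides {bases!r} in {raw!r}")
        span = end - start + 1
        if bases and op in ("del", "dup") and len(bases) != span:
            raise HgvsParseError(
                f"{op} of {span} nt but {len(bases)} bases given in {raw!r}"
            )
        if op == "del":
            return CodingChange(start, end, bases, "", CodingKind.DELETION)
        if op == "dup":
            return CodingChange(start, end, bases, bases * 2, CodingKind.DUPLICATION)
        if op == "ins":
            if not bases:
                raise HgvsParseError(f"insertion without bases in {raw!r}")
            return CodingChange(start, end, "", bases, CodingKind.INSERTION)
        return CodingChange(start, end, "", bases, CodingKind.DELINS)
    raise HgvsParseError(f"unrecognised coding description {body!r} in {raw!r}")


def format_hgvs_c(change: CodingChange) -> str:
    """Render a :class:`CodingChange` back to its normalized string form."""
    s, e = change.position_start, change.position_end
    span = f"{s}" if s == e else f"{s}_{e}"
    if change.kind is CodingKind.SUBSTITUTION:
        return f"c.{s}{change.ref_bases}>{change.alt_bases}"
    if change.kind is CodingKind.DELETION:
        return f"c.{span}del{change.ref_bases}"
    if change.kind is CodingKind.DUPLICATION:
        return f"c.{span}dup{change.ref_bases}"
    if change.kind is CodingKind.INSERTION:
        return f"c.{span}ins{change.alt_bases}"
    return f"c.{span}delins{change.alt_bases}"


_P_BODY = re.compile(r"^p\.(\((?P<inner1>.+)\)|(?P<inner2>.+))$")
_P_SINGLE = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)"
    r"(?P<rest>\*|[A-Z][a-z]{2}\*?|[A-Z][a-z]{2}fs\*(?:\d+|\?))$"
)
_P_RANGE = re.compile(
    r"^(?P<ref1>[A-Z][a-z]{2})(?P<pos1>\d+)_(?P<ref2>[A-Z][a-z]{2})(?P<pos2>\d+)"
    r"(?P<op>del|dup)$"
)


def _check_aa(code: str, raw: str) -> str:
    if code not in AA3:
        raise HgvsParseError(f"unknown amino-acid code {code!r} in {raw!r}")
    return code


def parse_hgvs_p(text: str) -> ProteinChange:
    """Parse a protein variant description such as ``p.(Gly1938Alafs*10)``.

    Both the predicted ``p.(...)`` and bare ``p....`` renderings are accepted;
    the formatter always emits the parenthesised predicted form.
    """
    raw = text
    text = re.sub(r"\s+", "", text)
    m = _P_BODY.match(text)
    if not m:
        raise HgvsParseError(f"missing 'p.' prefix in {raw!r}")
    body = m.group("inner1") or m.group("inner2")

    m = _P_RANGE.match(body)
    if m:
        ref1 = _check_aa(m.group("ref1"), raw)
        ref2 = _check_aa(m.group("ref2"), raw)
        start, end = int(m.group("pos1")), int(m.group("pos2"))
        kind = (
            ProteinKind.INFRAME_DELETION
            if m.group("op") == "del"
            else ProteinKind.INFRAME_DUPLICATION
        )
        return ProteinChange(start, end, f"{ref1}_{ref2}", "", kind)

    m = _P_SINGLE.match(body)
    if not m:
        raise HgvsParseError(f"unrecognised protein description {body!r} in {raw!r}")
    ref = _check_aa(m.group("ref"), raw)
    pos = int(m.group("pos"))
    rest = m.group("rest")
    if rest == "*":
        return ProteinChange(pos, pos, ref, "Ter", ProteinKind.STOP_GAIN)
    if rest.endswith("*") and "fs" not in rest:
        alt = _check_aa(rest[:-1], raw)
        return ProteinChange(pos, pos, ref, alt, ProteinKind.NONSENSE_AFTER_SUBSTITUTION)
    if "fs*" in rest:
        alt = _check_aa(rest[:3], raw)
        offset_tok = rest.split("fs*")[1]
        offset = None if offset_tok == "?" else int(offset_tok)
        return ProteinChange(pos, pos, ref, alt, ProteinKind.FRAMESHIFT, stop_offset=offset)
    alt = _check_aa(rest, raw)
    return ProteinChange(pos, pos, ref, alt, ProteinKind.MISSENSE)


def format_hgvs_p(change: ProteinChange) -> str:
    """Render a :class:`ProteinChange` in predicted ``p.(...)`` form."""
    if change.kind in (ProteinKind.INFRAME_DELETION, ProteinKind.INFRAME_DUPLICATION):
        ref1, ref2 = change.ref_aa.split("_")
        op = "del" if change.kind is ProteinKind.INFRAME_DELETION else "dup"
        return f"p.({ref1}{change.residue_start}_{ref2}{change.residue_end}{op})"
    base = f"{change.ref_aa}{change.residue_start}"
    if change.kind is ProteinKind.STOP_GAIN:
        return f"p.({base}*)"
    if change.kind is ProteinKind.NONSENSE_AFTER_SUBSTITUTION:
        return f"p.({base}{change.alt_aa}*)"
    if change.kind is ProteinKind.FRAMESHIFT:
        off = "?" if change.stop_offset is None else str(change.stop_offset)
        return f"p.({base}{change.alt_aa}fs*{off})"
    return f"p.({base}{change.alt_aa})"


def classify_consequence(change: ProteinChange) -> Consequence:
    """Map a protein change to its consequence class.

    Duplications count as in-frame insertions; a substitution immediately
    followed by a stop counts as a stop gain.
    """
    if change.kind is ProteinKind.MISSENSE:
        return Consequence.MISSENSE
    if change.kind in (ProteinKind.STOP_GAIN, ProteinKind.NONSENSE_AFTER_SUBSTITUTION):
        return Consequence.STOP_GAIN
    if change.kind is ProteinKind.FRAMESHIFT:
        return Consequence.FRAMESHIFT
    if change.kind is ProteinKind.INFRAME_DELETION:
        return Consequence.INFRAME_DELETION
    return Consequence.INFRAME_INSERTION


def truncated_length(change: ProteinChange, ref_len: int = PROTEIN_LENGTH) -> int:
    """Number of residues in the (possibly truncated) protein product.

    A bare nonsense at residue *r* retains residues 1..r-1; a substituted
    residue followed by a stop retains *r*; a frameshift at *r* with stop
    offset *N* retains r+N-2 residues (r-1 native plus N-1 from the shifted
    frame).  Non-truncating changes retain the full reference length.
    """
    if ref_len <= 0:
        raise ValueError("reference protein length must be positive")
    if change.kind is ProteinKind.STOP_GAIN:
        return change.residue_start - 1
    if change.kind is ProteinKind.NONSENSE_AFTER_SUBSTITUTION:
        return change.residue_start
    if change.kind is ProteinKind.FRAMESHIFT:
        if change.stop_offset is None:
            logger.warning("frameshift %s has unknown stop offset", format_hgvs_p(change))
            return ref_len
        return change.residue_start + change.stop_offset - 2
    return ref_len


def residues_removed(change: ProteinChange, ref_len: int = PROTEIN_LENGTH) -> int:
    """Residues lost relative to the reference; 0 for non-truncating changes."""
    return ref_len - truncated_length(change, ref_len)


def termination_position(change: ProteinChange) -> Optional[int]:
    """Residue position of the premature stop codon, or None.

    A bare nonsense stops at its own residue; a substitution-then-stop one
    residue later; a frameshift ``fs*N`` at r+N-1.  Used to decide whether a
    truncation falls within the last 50 residues (PM4 in place of PVS1).
    """
    if change.kind is ProteinKind.STOP_GAIN:
        return change.residue_start
    if change.kind is ProteinKind.NONSENSE_AFTER_SUBSTITUTION:
        return change.residue_start + 1
    if change.kind is ProteinKind.FRAMESHIFT:
        if change.stop_offset is None:
            logger.warning(
                "cannot place termination for %s: unknown stop offset",
                format_hgvs_p(change),
            )
            return None
        return change.residue_start + change.stop_offset - 1
    return None


@dataclass
class VariantAnnotations:
    """Tri-state evidence annotations consumed by the classification engine.

    ``None`` means missing; missing never grants evidence.  Predictor calls
    are the strings ``"deleterious"`` / ``"benign"`` or ``None``.
    """

    cadd_score: Optional[float] = None
    sift_call: Optional[str] = None
    polyphen_call: Optional[str] = None
    mutation_taster_call: Optional[str] = None
    gvgd_class: Optional[str] = None
    nucleotide_conserved: Optional[bool] = None
    aminoacid_conserved: Optional[bool] = None
    protein_effect_predicted: Optional[bool] = None
    known_pathogenic_same_residue: bool = False
    functional_evidence: bool = False
    de_novo_status: str = "none"  # confirmed | assumed | none
    prevalence_evidence: Optional[str] = None  # strong | supporting | None (PS4 input)

    def __post_init__(self) -> None:
        for name in ("sift_call", "polyphen_call", "mutation_taster_call"):
            v = getattr(self, name)
            if v not in (None, "deleterious", "benign"):
                raise ValueError(f"{name} must be deleterious/benign/None, got {v!r}")
        if self.de_novo_status not in ("confirmed", "assumed", "none"):
            raise ValueError(f"invalid de_novo_status {self.de_novo_status!r}")
        if self.prevalence_evidence not in (None, "strong", "supporting"):
            raise ValueError(f"invalid prevalence_evidence {self.prevalence_evidence!r}")


@dataclass
class PopulationFrequency:
    """Observed allele frequencies in reference populations and internal controls.

    ``None`` distinguishes absent-from-database from an observed frequency of
    zero; both satisfy the rarity requirement by default.
    """

    af_exac: Optional[float] = None
    af_gnomad: Optional[float] = None
    internal_control_carriers: int = 0
    internal_cohort_size: int = 13000

    def __post_init__(self) -> None:
        for name in ("af_exac", "af_gnomad"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.internal_control_carriers < 0:
            raise ValueError("carrier count must be >= 0")

    @property
    def max_known_af(self) -> float:
        return max((v for v in (self.af_exac, self.af_gnomad) if v is not None), default=0.0)

    @property
    def unobserved(self) -> bool:
        return self.af_exac is None and self.af_gnomad is None


@dataclass
class VariantRecord:
    """One MYH9 variant with notation, exon placement and annotations."""

    id: str
    coding_change: CodingChange
    protein_change: ProteinChange
    exon: int
    gene_region_position: str = ""
    novel_flag: bool = False
    annotations: VariantAnnotations = field(default_factory=VariantAnnotations)
    frequencies: PopulationFrequency = field(default_factory=PopulationFrequency)

    def __post_init__(self) -> None:
        if not FIRST_CODING_EXON <= self.exon <= LAST_EXON:
            raise ValueError(f"exon {self.exon} outside coding range "
                             f"{FIRST_CODING_EXON}-{LAST_EXON}")

    @property
    def consequence(self) -> Consequence:
        return classify_consequence(self.protein_change)

    @property
    def hgvs_c(self) -> str:
        return format_hgvs_c(self.coding_change)

    @property
    def hgvs_p(self) -> str:
        return format_hgvs_p(self.protein_change)
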