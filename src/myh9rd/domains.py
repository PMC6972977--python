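"""NMMHC-IIA domain architecture, hotspot regions and alignment conservation.

The 41-exon gene maps onto the protein as: exons 2-19 encode the globular
head domain (HD), exon 20 the neck, exons 21-40 the coiled-coil tail domain
(TD) and exon 41 the final 34 residues forming the nonhelical tail domain
(NHTD, residues 1927-1960).

Hotspot intervals drive PM1 eligibility.  The defaults are the NHTD
truncation window (the last-50-residue region, >=1911) and the exon-2 head
cluster at residues 93-96; both are configurable because published reports
describe the hotspots qualitatively rather than as coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import yaml

from .constants import (
    FIRST_CODING_EXON,
    LAST_EXON,
    NHTD_START_RESIDUE,
    PROTEIN_LENGTH,
)
from .hgvs import ProteinChange

__all__ = [
    "HD", "NECK", "TD", "NHTD",
    "DomainArchitecture",
    "ConservationProfile",
    "domain_of_exon",
    "domain_of_residue",
    "in_hotspot",
    "conservation_fraction",
    "conservation_profile",
]

HD = "HD"
NECK = "neck"
TD = "TD"
NHTD = "NHTD"

DEFAULT_HOTSPOTS: Dict[str, Tuple[int, int]] = {
    # truncations clustering in the last-50-residue window of the NHTD
    "nhtd_truncation": (PROTEIN_LENGTH - 50 + 1, PROTEIN_LENGTH),
    # recurrent missense cluster in the exon-2 part of the head domain
    "exon2_head_cluster": (93, 96),
}


@dataclass
class DomainArchitecture:
    """Exon->domain and residue->domain mapping for the 1,960-residue protein."""

    protein_length: int = PROTEIN_LENGTH
    nhtd_start_residue: int = NHTD_START_RESIDUE
    #: residue-level fallback boundaries used only when no exon is available
    hd_residue_end: int = 833
    td_residue_end: int = 1926
    #: descriptive SH3/motor-domain interface (exon-2 residues); not evidence
    interface_region: Tuple[int, int] = (26, 60)
    hotspots: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HOTSPOTS)
    )

    def __post_init__(self) -> None:
        if self.nhtd_start_residue != self.protein_length - 34 + 1:
            raise ValueError("NHTD must span the final 34 residues")
        for name, (lo, hi) in self.hotspots.items():
            if not (1 <= lo <= hi <= self.protein_length):
                raise ValueError(f"hotspot {name!r} interval out of range: {(lo, hi)}")

    @property
    def exon_to_domain(self) -> Dict[int, str]:
        table = {}
        for exon in range(FIRST_CODING_EXON, LAST_EXON + 1):
            if exon <= 19:
                table[exon] = HD
            elif exon == 20:
                table[exon] = NECK
            elif exon <= 40:
                table[exon] = TD
            else:
                table[exon] = NHTD
        return table

    @classmethod
    def from_yaml(cls, path) -> "DomainArchitecture":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("protein_length", "nhtd_start_residue", "hd_residue_end",
                    "td_residue_end"):
            if key in data:
                kwargs[key] = int(data[key])
        if "interface_region" in data:
            kwargs["interface_region"] = tuple(data["interface_region"])
        if "hotspots" in data:
            kwargs["hotspots"] = {
                name: (int(iv[0]), int(iv[1])) for name, iv in data["hotspots"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = {
            "protein_length": self.protein_length,
            "nhtd_start_residue": self.nhtd_start_residue,
            "hd_residue_end": self.hd_residue_end,
            "td_residue_end": self.td_residue_end,
            "interface_region": list(self.interface_region),
            "hotspots": {k: list(v) for k, v in self.hotspots.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def domain_of_exon(exon: int, arch: Optional[DomainArchitecture] = None) -> str:
    """Domain encoded by a coding exon (2-41)."""
    arch = arch or DomainArchitecture()
    if not FIRST_CODING_EXON <= exon <= LAST_EXON:
        raise ValueError(f"exon {exon} outside coding range 2-{LAST_EXON}")
    return arch.exon_to_domain[exon]


def domain_of_residue(
    residue: int,
    arch: Optional[DomainArchitecture] = None,
    exon: Optional[int] = None,
) -> str:
    """Domain containing a protein residue.

    Residues at or beyond the NHTD start (1927) are always NHTD.  Below that,
    the variant's exon resolves the domain when known; otherwise the
    configured residue boundaries are used.
    """
    arch = arch or DomainArchitecture()
    if not 1 <= residue <= arch.protein_length:
        raise ValueError(f"residue {residue} outside 1-{arch.protein_length}")
    if residue >= arch.nhtd_start_residue:
        return NHTD
    if exon is not None:
        dom = domain_of_exon(exon, arch)
        # an exon-41 variant before residue 1927 is still attributed NHTD
        return dom
    if residue <= arch.hd_residue_end:
        return HD
    return TD


def in_hotspot(change: ProteinChange, arch: Optional[DomainArchitecture] = None) -> bool:
    """Whether the affected residue interval intersects a configured hotspot.

    The interval is the variant's own footprint (start..end residues as
    written), not the downstream region a truncation abolishes.
    """
    arch = arch or DomainArchitecture()
    for lo, hi in arch.hotspots.values():
        if change.residue_start <= hi and change.residue_end >= lo:
            return True
    return False


def _reference_row(alignment, reference_id: Optional[str]):
    if reference_id is None:
        return alignment[0]
    for rec in alignment:
        if rec.id == reference_id:
            return rec
    raise ValueError(f"reference sequence {reference_id!r} not in alignment")


def _column_for_residue(ref_seq: str, residue: int) -> int:
    seen = 0
    for col, ch in enumerate(ref_seq):
        if ch != "-":
            seen += 1
            if seen == residue:
                return col
    raise ValueError(f"residue {residue} beyond reference alignment width")


def conservation_fraction(alignment, residue: int, reference_id: Optional[str] = None) -> float:
    """Fraction of aligned sequences matching the reference residue.

    ``residue`` indexes the ungapped reference sequence.  Gap characters never
    count as matches but every row counts toward the depth, so a half-gapped
    column can score at most 0.5.  An all-gap column raises ``ValueError``.
    """
    ref = _reference_row(alignment, reference_id)
    col = _column_for_residue(str(ref.seq), residue)
    column = [str(rec.seq)[col] for rec in alignment]
    if all(ch == "-" for ch in column):
        raise ValueError(f"alignment column {col} is all gaps")
    ref_char = str(ref.seq)[col]
    matches = sum(1 for ch in column if ch == ref_char and ch != "-")
    return matches / len(column)


@dataclass
class ConservationProfile:
    """Per-residue conservation fractions over the reference sequence."""

    fractions: Sequence[float]
    depth: int

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("conservation fractions must lie in [0,1]")

    def is_highly_conserved(self, residue: int, threshold: float = 0.9) -> bool:
        return self.fractions[residue - 1] >= threshold


def conservation_profile(alignment, reference_id: Optional[str] = None) -> ConservationProfile:
    """Compute the conservation fraction at every reference residue."""
    ref = _reference_row(alignment, reference_id)
    n_res = sum(1 for ch in str(ref.seq) if ch != "-")
    fractions = [
        conservation_fraction(alignment, r, reference_id) for r in range(1, n_res + 1)
    ]
    return ConservationProfile(fractions=fractions, depth=len(alignment))
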