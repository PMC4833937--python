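"""Glyoxalase activity and metal-dependency classifiers.

GLYI: enzymes carry a conserved H/Q-E-H/Q-E metal-binding quartet in the
(N-terminal) glyoxalase domain; activity is predicted Present only when
all four sites are intact.  Among active enzymes, metal dependency tracks
domain length — Ni-type domains run ~120 aa, Zn-type ~142 aa and longer —
so length thresholds (Ni <= 130, Zn >= 140, in between ambiguous) decide
the call unless an explicit Zn signature is supplied.

GLYII: activity requires both the metal-binding motif (default THXHXDH,
the THHHXDH variant selectable) and the active-site motif [CG]HT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .family_catalog import (
    FamilyMember,
    GLYI_DOMAIN,
    GLYII_DOMAIN,
    HAGHC_DOMAIN,
)

__all__ = [
    "GlyIDomainRecord",
    "GlyIClassification",
    "GlyIIMotifRecord",
    "SiteReference",
    "detect_glyI_sites",
    "classify_glyI",
    "classify_glyII",
    "domain_architecture",
    "find_protein_motif",
    "NI_MAX_LENGTH",
    "ZN_MIN_LENGTH",
    "GLYII_METAL_MOTIF",
    "GLYII_METAL_MOTIF_ALT",
    "GLYII_ACTIVE_SITE",
]

NI_MAX_LENGTH = 130
ZN_MIN_LENGTH = 140
# Allowed residue classes at the four conserved metal-binding columns.
SITE_CLASSES = ("HQ", "E", "HQ", "E")

GLYII_METAL_MOTIF = "THXHXDH"
GLYII_METAL_MOTIF_ALT = "THHHXDH"
GLYII_ACTIVE_SITE = "[CG]HT"


@dataclass
class GlyIDomainRecord:
    protein_id: str
    domain_length: int
    site_flags: tuple[bool, bool, bool, bool]
    zn_signature_present: bool = False
    domain_seq: str = ""

    def __post_init__(self) -> None:
        if self.domain_seq and len(self.domain_seq) != self.domain_length:
            raise ValueError(
                f"{self.protein_id}: domain_length != len(domain_seq)"
            )


@dataclass
class GlyIClassification:
    activity: str  # Present | Absent
    metal: str  # Ni | Zn | ambiguous | none


@dataclass
class GlyIIMotifRecord:
    protein_id: str
    metal_motif_present: bool
    active_site_present: bool
    activity: str  # Yes | No
    metal_positions: list[int] = field(default_factory=list)
    active_positions: list[int] = field(default_factory=list)


@dataclass
class SiteReference:
    """Reference glyoxalase-domain sequence with its four annotated
    metal-binding columns (0-based positions in the reference)."""

    sequence: str
    site_columns: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for c in self.site_columns:
            if not 0 <= c < len(self.sequence):
                raise ValueError(f"site column {c} outside reference")


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def detect_glyI_sites(
    domain_seq: str, reference: SiteReference
) -> tuple[bool, bool, bool, bool]:
    """Flag which of the four conserved metal-binding sites are intact.

    The query domain is globally aligned to the reference; the residue
    mapped to each annotated reference column is checked against its
    allowed class (H/Q for sites 1 and 3, E for sites 2 and 4).  A query
    under 30 aa is an error; a query aligning at under 20% identity gets
    all-False flags with a warning.
    """
    import warnings

    if len(domain_seq) < 30:
        raise ValueError("query domain shorter than 30 aa")
    aligner = _global_aligner()
    aln = aligner.align(reference.sequence, domain_seq)[0]
    ref_idx, query_idx = aln.indices  # -1 marks gaps
    matched = sum(
        1
        for r, q in zip(ref_idx, query_idx)
        if r >= 0 and q >= 0 and reference.sequence[r] == domain_seq[q]
    )
    ncols = len(ref_idx)
    if ncols and matched / ncols < 0.20:
        warnings.warn("query unalignable to site reference (<20% identity)",
                      stacklevel=2)
        return (False, False, False, False)
    col_to_query = {
        r: q for r, q in zip(ref_idx, query_idx) if r >= 0
    }
    flags = []
    for col, allowed in zip(reference.site_columns, SITE_CLASSES):
        q = col_to_query.get(col, -1)
        flags.append(q >= 0 and domain_seq[q] in allowed)
    return tuple(flags)


def classify_glyI(record: GlyIDomainRecord) -> GlyIClassification:
    """Activity from the site quartet; metal dependency from domain length
    (and optional Zn signature) for active enzymes."""
    if not all(record.site_flags):
        return GlyIClassification("Absent", "none")
    if record.zn_signature_present or record.domain_length >= ZN_MIN_LENGTH:
        metal = "Zn"
    elif record.domain_length <= NI_MAX_LENGTH:
        metal = "Ni"
    else:
        metal = "ambiguous"
    return GlyIClassification("Present", metal)


def _pattern_to_set(pattern: str) -> list[str]:
    """Expand an IUPAC-style residue pattern ('X' any, '[AB]' classes)."""
    out: list[str] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            out.append(pattern[i + 1 : j].replace("/", ""))
            i = j + 1
        elif ch == "X":
            out.append("")  # empty = any residue
            i += 1
        else:
            out.append(ch)
            i += 1
    return out


def find_protein_motif(protein: str, pattern: str) -> list[int]:
    """All 0-based match positions of an X-wildcard residue pattern."""
    cols = _pattern_to_set(pattern)
    m = len(cols)
    protein = protein.upper()
    hits = []
    for i in range(len(protein) - m + 1):
        if all(
            not allowed or protein[i + k] in allowed
            for k, allowed in enumerate(cols)
        ):
            hits.append(i)
    return hits


def classify_glyII(
    protein: str,
    protein_id: str = "",
    metal_motif_pattern: str = GLYII_METAL_MOTIF,
    active_site_pattern: str = GLYII_ACTIVE_SITE,
) -> GlyIIMotifRecord:
    """Activity Yes iff both the metal-binding and active-site motifs occur."""
    if not protein:
        raise ValueError("empty protein sequence")
    metal_pos = find_protein_motif(protein, metal_motif_pattern)
    active_pos = find_protein_motif(protein, active_site_pattern)
    return GlyIIMotifRecord(
        protein_id=protein_id,
        metal_motif_present=bool(metal_pos),
        active_site_present=bool(active_pos),
        activity="Yes" if metal_pos and active_pos else "No",
        metal_positions=metal_pos,
        active_positions=active_pos,
    )


def domain_architecture(member: FamilyMember) -> str:
    """Architecture class from the member's domain-hit list.

    GLYI: 'single' or 'double' glyoxalase domain; GLYII: 'lactamase_only'
    or 'lactamase_plus_HAGHC'.
    """
    accs = [d.domain_accession for d in member.domains]
    if member.family == "GLYI":
        n = accs.count(GLYI_DOMAIN)
        if n == 0:
            raise ValueError(f"{member.name}: no {GLYI_DOMAIN} hit")
        return "double" if n >= 2 else "single"
    if member.family == "GLYII":
        if GLYII_DOMAIN not in accs:
            raise ValueError(f"{member.name}: no {GLYII_DOMAIN} hit")
        return (
            "lactamase_plus_HAGHC" if HAGHC_DOMAIN in accs else "lactamase_only"
        )
    raise ValueError(f"{member.name}: unknown family {member.family!r}")
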