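"""Cis-regulatory element scanning over upstream promoter regions.

Elements are named IUPAC consensus strings (e.g. ABRE ACGTG core, W-box
TTGACC, HSE AGAANNTTCT) matched exactly at every offset on both strands
of a 1-kb upstream window; no PWM scoring.  An N in the genomic sequence
never matches any pattern symbol.  Positions use the -1000..-1
convention: -1 is the base immediately 5' of the transcription start.
Overlapping and palindromic matches are all reported.

The shipped catalog is a set of PlantCARE-style default consensi and is
fully overridable from a TSV (columns: name, pattern).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CisElement",
    "CisElementMatch",
    "default_catalog",
    "load_catalog",
    "scan_promoter",
    "element_census",
    "iupac_sites",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class CisElement:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC symbols {sorted(bad)!r}")


@dataclass(frozen=True)
class CisElementMatch:
    gene_id: str
    element: str
    strand: str
    position: int  # offset of the match's leftmost base, -L..-1
    matched_seq: str


def revcomp_pattern(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def load_catalog(path: str | Path) -> list[CisElement]:
    df = pd.read_csv(path, sep="\t")
    return [CisElement(r["name"], r["pattern"].upper()) for _, r in df.iterrows()]


def default_catalog() -> list[CisElement]:
    ref = resources.files("glyfam.data").joinpath("cis_elements.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path)


@lru_cache(maxsize=512)
def _compiled(pattern: str) -> "re.Pattern[str]":
    # overlapping matches via lookahead; classes spell out concrete bases
    # so an N in the sequence never matches anything
    body = "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern.upper()
    )
    return re.compile(f"(?=({body}))")


def iupac_sites(seq: str, pattern: str) -> list[int]:
    """All 0-based start offsets where the IUPAC pattern matches.

    N in the *sequence* matches nothing (unknown base), while N in the
    pattern matches any concrete base.  Overlapping occurrences are all
    reported.
    """
    return [m.start() for m in _compiled(pattern).finditer(seq.upper())]


def scan_promoter(
    upstream_seq: str,
    catalog: list[CisElement],
    gene_id: str = "",
) -> list[CisElementMatch]:
    """Exhaustive both-strand scan of one upstream sequence.

    The sequence is the gene's upstream window read 5'->3' on the gene's
    strand; its last base sits at position -1.  A minus-strand match is a
    forward occurrence of the reverse-complemented pattern; its position
    is still the leftmost base of the occupied window.
    """
    L = len(upstream_seq)
    out: list[CisElementMatch] = []
    for elem in catalog:
        for strand, pat in (("+", elem.pattern),
                            ("-", revcomp_pattern(elem.pattern))):
            for i in iupac_sites(upstream_seq, pat):
                out.append(
                    CisElementMatch(
                        gene_id=gene_id,
                        element=elem.name,
                        strand=strand,
                        position=i - L,
                        matched_seq=upstream_seq[i : i + len(pat)],
                    )
                )
    out.sort(key=lambda m: (m.position, m.element, m.strand))
    return out


def matches_to_bed6(
    matches: list[CisElementMatch],
    genes: dict[str, tuple[str, int, int, str]],
    window: int = 1000,
):
    """Convert promoter matches to BED6 rows in genome coordinates.

    ``genes`` maps gene_id -> (chrom, start, end, strand).  The match
    position is an offset in the strand-oriented upstream window; a
    reported '-' strand flips relative to the gene's own strand.
    """
    rows = []
    for m in matches:
        chrom, start, end, gstrand = genes[m.gene_id]
        width = len(m.matched_seq)
        if gstrand == "+":
            s = start + m.position  # position is negative
        else:
            s = end - m.position - width
        abs_strand = m.strand if gstrand == "+" else (
            "-" if m.strand == "+" else "+"
        )
        rows.append(
            (chrom, s, s + width, f"{m.gene_id}:{m.element}", 0, abs_strand)
        )
    return rows


def element_census(matches: list[CisElementMatch]) -> pd.DataFrame:
    """Per-gene x element instance counts (genes as rows)."""
    if not matches:
        return pd.DataFrame()
    df = pd.DataFrame(
        [(m.gene_id, m.element) for m in matches], columns=["gene", "element"]
    )
    return (
        df.groupby(["gene", "element"]).size().unstack(fill_value=0).sort_index()
    )
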