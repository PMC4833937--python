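"""Family catalog construction: domain-based membership, positional
nomenclature, and per-family summary statistics.

Membership follows the Pfam-domain rule used for plant glyoxalase surveys:
a protein is GLYI iff it carries a lactoylglutathione lyase domain
(PF00903) and GLYII iff it carries a metallo-beta-lactamase domain
(PF00753), optionally accompanied by a HAGH-C domain (PF16123).
Candidates with neither required domain are discarded (with a logged
reason).  Gene names are assigned serially per family along chromosomes,
splice variants as .1, .2, ...
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import GeneModel, TranscriptModel

logger = logging.getLogger(__name__)

GLYI_DOMAIN = "PF00903"
GLYII_DOMAIN = "PF00753"
HAGHC_DOMAIN = "PF16123"

__all__ = [
    "DomainHit",
    "FamilyMember",
    "FamilyCatalog",
    "read_domain_hits",
    "assign_family",
    "assign_nomenclature",
    "summarize_family",
    "gene_structure_stats",
    "GLYI_DOMAIN",
    "GLYII_DOMAIN",
    "HAGHC_DOMAIN",
]


@dataclass
class DomainHit:
    protein_id: str
    domain_accession: str
    start: int  # 1-based inclusive, domain-table convention
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: domain start > end ({self.start}>{self.end})"
            )


@dataclass
class FamilyMember:
    name: str
    gene_id: str
    transcript_id: str
    family: str
    protein: str = ""
    domains: list[DomainHit] = field(default_factory=list)
    cds_length: int = 0
    pp_length: int = 0
    mw: float = 0.0
    pi: float = 0.0


@dataclass
class FamilyCatalog:
    members: list[FamilyMember] = field(default_factory=list)
    prefix: str = "Gm"

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m.gene_id)
        return list(seen)

    def family(self, family: str) -> list[FamilyMember]:
        return [m for m in self.members if m.family == family]


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a domain-hit table.

    Accepts either a headered TSV (protein_id, domain_accession, start, end,
    score) or the whitespace-delimited HMMER ``--domtblout`` dialect, in
    which case target name, accession, ali-from, ali-to and score columns
    are used.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("protein_id"):
            for line in fh:
                if not line.strip():
                    continue
                pid, acc, s, e, score = line.rstrip("\n").split("\t")[:5]
                hits.append(DomainHit(pid, acc, int(s), int(e), float(score)))
        else:
            fh.seek(0)
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.split()
                if len(f) < 23:
                    raise ValueError("unrecognized domain-table line: " + line)
                # domtblout: 0 target, 4 query accession, 13 dom score,
                # 17-18 ali coords
                acc = f[4].split(".")[0]
                hits.append(
                    DomainHit(f[0], acc, int(f[17]), int(f[18]), float(f[13]))
                )
    return hits


def assign_family(protein_id: str, domain_hits: list[DomainHit]) -> str:
    """Return 'GLYI', 'GLYII' or 'none' for a protein's domain hits.

    A protein hitting both family-defining domains is a conflict and
    raises; this pattern does not occur in curated glyoxalase sets.
    """
    accs = {
        h.domain_accession for h in domain_hits if h.protein_id == protein_id
    }
    is_glyi = GLYI_DOMAIN in accs
    is_glyii = GLYII_DOMAIN in accs
    if is_glyi and is_glyii:
        raise ValueError(
            f"{protein_id}: conflicting family domains {GLYI_DOMAIN}+{GLYII_DOMAIN}"
        )
    if is_glyi:
        return "GLYI"
    if is_glyii:
        return "GLYII"
    logger.info("discarding %s: no family-defining domain", protein_id)
    return "none"


def _chrom_key(chrom: str):
    digits = "".join(ch for ch in chrom if ch.isdigit())
    return (0, int(digits), chrom) if digits else (1, 0, chrom)


def _tx_suffix_key(transcript_id: str, index: int):
    m = re.search(r"\.(\d+)$", transcript_id)
    return (0, int(m.group(1))) if m else (1, index)


def assign_nomenclature(
    catalog: FamilyCatalog, coords: dict[str, tuple[str, int]]
) -> FamilyCatalog:
    """Name members <prefix><family>-<k>.<j> by chromosomal position.

    ``coords`` maps gene_id -> (chromosome label, start coordinate).  Genes
    are numbered per family in (chromosome, start) order; splice variants
    by their transcript-ID suffix (falling back to input order).  The
    result is independent of the input ordering of ``members``.
    """
    for m in catalog.members:
        if m.gene_id not in coords:
            raise ValueError(f"{m.gene_id}: no coordinates for nomenclature")
    for fam in ("GLYI", "GLYII"):
        members = catalog.family(fam)
        if not members:
            continue
        gene_ids = sorted(
            {m.gene_id for m in members},
            key=lambda g: (_chrom_key(coords[g][0]), coords[g][1], g),
        )
        gene_number = {g: k for k, g in enumerate(gene_ids, start=1)}
        by_gene: dict[str, list[FamilyMember]] = {}
        for m in members:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gid, ms in by_gene.items():
            ms.sort(
                key=lambda m: _tx_suffix_key(
                    m.transcript_id, catalog.members.index(m)
                )
            )
            for j, m in enumerate(ms, start=1):
                m.name = f"{catalog.prefix}{fam}-{gene_number[gid]}.{j}"
    return catalog


def summarize_family(catalog: FamilyCatalog, family: str) -> dict:
    """Isoform-level summary statistics for one family."""
    members = catalog.family(family)
    if not members:
        raise ValueError(f"no members in family {family!r}")
    cds = [m.cds_length for m in members]
    return {
        "n_genes": len({m.gene_id for m in members}),
        "n_proteins": len(members),
        "cds_min": min(cds),
        "cds_max": max(cds),
        "cds_mean": sum(cds) / len(cds),
        "pp_max": max(m.pp_length for m in members),
        "pi_min": min(m.pi for m in members),
        "pi_max": max(m.pi for m in members),
        "genes_with_multiple_isoforms": sum(
            1
            for g in {m.gene_id for m in members}
            if sum(1 for m in members if m.gene_id == g) > 1
        ),
    }


def _gap_count(intervals: list[tuple[int, int]]) -> int:
    return max(0, len(intervals) - 1)


def gene_structure_stats(gene: GeneModel) -> dict[str, dict[str, int]]:
    """Intron counts per transcript: within the ORF and within each UTR.

    An ORF intron is a gap between consecutive CDS segments; UTR introns
    are counted analogously within the 5' and 3' UTR intervals.
    """
    out = {}
    for tx in gene.transcripts:
        out[tx.transcript_id] = {
            "orf_introns": _gap_count(tx.cds),
            "utr5_introns": _gap_count(tx.utr5),
            "utr3_introns": _gap_count(tx.utr3),
        }
    return out
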