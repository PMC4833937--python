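"""Seeded synthetic-genome and expression generators with recorded
ground truth.

The generator emulates the inputs of a gene-family survey on a small
scale: multi-chromosome genomes with stranded multi-exon gene models
(5'/3' UTRs, introns), planted glyoxalase-family members whose proteins
embed a synthetic GLYI domain (with the conserved H/Q-E-H/Q-E
metal-binding quartet intact or broken) or GLYII motif blocks, duplicated
gene pairs evolved to a target synonymous divergence (tandem or
segmental placement), promoters scrubbed of accidental catalog matches
and re-planted with known cis-elements, and tissue/stress expression
matrices with planted profile classes.  Every planted fact is recorded
in a GroundTruth object so recovery tests never re-derive expectations
from the generator's own outputs.

One integer seed drives everything; independent substreams are derived
with fixed offsets so adding a generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .duplication import (
    CODON_TABLE,
    CodonAlignment,
    STOP_CODONS,
    ng86,
)
from .genome_io import (
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
    write_fasta,
    write_gff3,
)
from .family_catalog import GLYI_DOMAIN, GLYII_DOMAIN, HAGHC_DOMAIN
from .promoter import CisElement, IUPAC, default_catalog, iupac_sites, revcomp_pattern

__all__ = [
    "SimConfig",
    "DuplicationSpec",
    "PromoterPlanting",
    "ExpressionSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate_genome",
    "evolve_duplicate",
    "generate_expression",
    "GLYI_SITE_REFERENCE",
]

# Synthetic reference GLYI domain (122 aa) used both for planting domains
# and as the site-detection reference profile in tests.  The four
# conserved metal-binding columns hold H, E, H, E (0-based positions
# below); the rest of the sequence is arbitrary but fixed.
_REF_BODY = (
    "MKVLSAFGDR" "TPAWVNKTGH" "LEFAVPRDSM"  # 0-29; site1 H at 19
    "GKYNLAFEEG" "AVRTDLPSWK" "MVEDNTAGRL"  # 30-59; site2 E at 37
    "FPAGVSKDNI" "WTRHELMGAD" "SVKPFYQERT"  # 60-89; site3 H at 73
    "ANLGDWSMKV" "PRTCEGALDN" "YFHQIKSAVE"  # 90-119; site4 E at 104
    "GW"
)
GLYI_SITE_COLUMNS = (19, 37, 73, 104)
assert [_REF_BODY[c] for c in GLYI_SITE_COLUMNS] == ["H", "E", "H", "E"]
GLYI_SITE_REFERENCE = _REF_BODY

# Extra segment inserted near the C-terminus for Zn-type (long) domains.
_ZN_INSERT = "DRSKAQLPNMTWEGVYHFSCADI"  # 23 aa -> 145-aa domain

GLYII_METAL_BLOCK = "THSHNDH"  # instance of THXHXDH
GLYII_ACTIVE_BLOCK = "GHT"
_HAGHC_BLOCK = "WNPKSLDEGARTFVYQCMIHWSERAKGDNLPVT"

TISSUES = {
    "root": "underground", "nodule": "underground",
    "young_leaf": "aerial", "flower": "aerial", "pod_1cm": "aerial",
    "pod_shell_10d": "aerial", "pod_shell_14d": "aerial",
    "seed_10d": "seed", "seed_14d": "seed", "seed_21d": "seed",
    "seed_25d": "seed", "seed_28d": "seed", "seed_35d": "seed",
    "seed_42d": "seed",
}


@dataclass
class DuplicationSpec:
    pair_type: str  # tandem | segmental
    target_ks: float
    family: str = "GLYI"

    def __post_init__(self) -> None:
        if not 0 <= self.target_ks < 0.7:
            raise ValueError("target_ks must be in [0, 0.7)")
        if self.pair_type not in ("tandem", "segmental"):
            raise ValueError(f"unknown pair type {self.pair_type!r}")


@dataclass
class PromoterPlanting:
    element: str
    offset: int  # -1000..-1 position of the element's leftmost base
    strand: str = "+"


@dataclass
class ExpressionSpec:
    profile: str  # constitutive | seed_specific | non_seed | silent
    stress_fc: float = 1.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic survey.

    Defaults mirror the surveyed system at desk scale: about half the
    family members carry a broken conserved-site quartet, duplicate
    pairs sit in the purifying regime (synonymous divergence 0.05-0.45,
    one tandem pair among segmental ones), and expression classes cover
    constitutive, seed-specific and silent profiles.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 90_000
    n_glyi_genes: int = 6
    n_glyii_genes: int = 3
    fraction_inactive: float = 0.5
    zn_fraction: float = 0.2
    # planted pairs must themselves satisfy the >90%-identity definition
    # of a duplicate: at the purifying evolution regime protein identity
    # falls through 90% near Ks ~ 0.15, so default targets sit well below
    duplications: list[DuplicationSpec] = field(
        default_factory=lambda: [
            DuplicationSpec("segmental", 0.05),
            DuplicationSpec("segmental", 0.08),
            DuplicationSpec("tandem", 0.08),
        ]
    )
    promoter_plantings: dict[int, list[PromoterPlanting]] = field(
        default_factory=dict
    )
    expression: dict[str, ExpressionSpec] = field(default_factory=dict)
    expression_sigma: float = 0.1
    promoter_length: int = 1000
    domain_cds_codons: int = 160  # protein length incl. flanks
    # duplicate-pair genes get longer proteins so identity concentrates
    # tightly around its expectation at the target Ks
    dup_cds_codons: int = 300

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        dups = [DuplicationSpec(**d) for d in raw.pop("duplications", [])]
        plantings = {
            int(k): [PromoterPlanting(**p) for p in v]
            for k, v in raw.pop("promoter_plantings", {}).items()
        }
        expr = {
            k: ExpressionSpec(**v) for k, v in raw.pop("expression", {}).items()
        }
        cfg = cls(**raw)
        if dups:
            cfg.duplications = dups
        if plantings:
            cfg.promoter_plantings = plantings
        if expr:
            cfg.expression = expr
        return cfg


@dataclass
class GeneTruth:
    gene_id: str
    family: str  # GLYI | GLYII | none
    strand: str
    site_flags: tuple[bool, bool, bool, bool] | None = None
    length_class: str | None = None  # Ni | Zn (GLYI only)
    has_haghc: bool = False
    glyii_motifs_present: bool = True


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str, str, float]] = field(
        default_factory=list
    )  # (gene_a, gene_b, type, target_ks)
    cis_plantings: list[tuple[str, str, str, int]] = field(
        default_factory=list
    )  # (gene_id, element, strand, offset)
    expression_classes: dict[str, str] = field(default_factory=dict)
    expression_fc: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    genome: list[GenomeSequence]
    genes: list[GeneModel]
    proteins: dict[str, str]  # transcript_id -> protein
    cds: dict[str, str]  # transcript_id -> CDS (5'->3')
    domain_hits: list[tuple[str, str, int, int, float]]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        write_gff3(self.genes, outdir / "genes.gff3")
        with open(outdir / "proteins.fasta", "w") as fh:
            for tid, prot in self.proteins.items():
                fh.write(f">{tid}\n{prot}\n")
        with open(outdir / "cds.fasta", "w") as fh:
            for tid, c in self.cds.items():
                fh.write(f">{tid}\n{c}\n")
        with open(outdir / "domain_hits.tsv", "w") as fh:
            fh.write("protein_id\tdomain_accession\tstart\tend\tscore\n")
            for pid, acc, s, e, score in self.domain_hits:
                fh.write(f"{pid}\t{acc}\t{s}\t{e}\t{score}\n")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _v in _CODONS_BY_AA.values():
    _v.sort()


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
        for aa in protein
    ]
    return "".join(codons) + "TAA"


def _glyi_protein(
    rng: np.random.Generator,
    broken_sites: tuple[bool, ...],
    zn_type: bool,
    total_len: int,
) -> tuple[str, tuple[int, int], tuple[bool, bool, bool, bool]]:
    """Protein with an embedded GLYI domain; returns (protein,
    (domain_start, domain_end) 1-based inclusive, site_flags)."""
    domain = list(GLYI_SITE_REFERENCE)
    flags = []
    for k, col in enumerate(GLYI_SITE_COLUMNS):
        if broken_sites[k]:
            domain[col] = "A"  # knock out the conserved residue
            flags.append(False)
        else:
            flags.append(True)
    domain_seq = "".join(domain)
    if zn_type:
        domain_seq = domain_seq[:110] + _ZN_INSERT + domain_seq[110:]
    aas = "ACDEFGHIKLMNPQRSTVWY"
    n_flank = max(1, (total_len - len(domain_seq)) // 2)
    c_flank = max(1, total_len - len(domain_seq) - n_flank)
    prot = (
        "M"
        + "".join(rng.choice(list(aas), size=n_flank - 1))
        + domain_seq
        + "".join(rng.choice(list(aas), size=c_flank))
    )
    start = n_flank + 1  # 1-based
    end = n_flank + len(domain_seq)
    return prot, (start, end), tuple(flags)


def _glyii_protein(
    rng: np.random.Generator, with_haghc: bool, motifs_present: bool,
    total_len: int,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Protein with a lactamase block (metal + active-site motifs inside)
    and optionally a HAGH-C block; returns (protein, domain spans)."""
    aas = "ACDEFGIKLMNPQRSVWY"  # avoid stray H/T runs forming motifs
    core = list(rng.choice(list(aas), size=90))
    lact = "".join(core)
    metal = GLYII_METAL_BLOCK if motifs_present else "AAAAAAA"
    lact = lact[:20] + metal + lact[27:60] + GLYII_ACTIVE_BLOCK + lact[63:]
    blocks = [("lact", lact)]
    if with_haghc:
        blocks.append(("haghc", _HAGHC_BLOCK))
    n_flank = 12
    prot = "M" + "".join(rng.choice(list(aas), size=n_flank - 1))
    spans = []
    for kind, seq in blocks:
        start = len(prot) + 1
        prot += seq
        spans.append((kind, start, len(prot)))
        prot += "".join(rng.choice(list(aas), size=8))
    pad = max(0, total_len - len(prot))
    prot += "".join(rng.choice(list(aas), size=pad))
    return prot, spans


def _build_transcript(
    tid: str,
    gene_start: int,
    cds: str,
    rng: np.random.Generator,
) -> tuple[TranscriptModel, int, str]:
    """Lay out one transcript from gene_start: 5'UTR, CDS split over
    exons with introns, 3'UTR.  Returns (model, end coordinate, spliced
    genomic sequence to install) in plus-strand layout coordinates."""
    utr5_len = int(rng.integers(40, 120))
    utr3_len = int(rng.integers(40, 120))
    n_exons = int(rng.integers(2, 5))
    # split CDS into n_exons chunks of >= 30 bp
    cuts = sorted(rng.choice(
        range(30, len(cds) - 30), size=n_exons - 1, replace=False
    )) if n_exons > 1 and len(cds) > 90 else []
    chunks = []
    prev = 0
    for c in cuts:
        chunks.append(cds[prev:c])
        prev = c
    chunks.append(cds[prev:])

    pos = gene_start
    exons, cds_ivs, utr5, utr3 = [], [], [], []
    pieces: list[tuple[int, str]] = []

    utr5_seq = _random_dna(rng, utr5_len)
    utr5.append((pos, pos + utr5_len))
    first_exon_start = pos
    pieces.append((pos, utr5_seq))
    pos += utr5_len
    for k, chunk in enumerate(chunks):
        if k > 0:
            intron_len = int(rng.integers(80, 250))
            exons.append((first_exon_start, pos))
            pieces.append((pos, "GT" + _random_dna(rng, intron_len - 4) + "AG"))
            pos += intron_len
            first_exon_start = pos
        cds_ivs.append((pos, pos + len(chunk)))
        pieces.append((pos, chunk))
        pos += len(chunk)
    utr3.append((pos, pos + utr3_len))
    pieces.append((pos, _random_dna(rng, utr3_len)))
    pos += utr3_len
    exons.append((first_exon_start, pos))

    tx = TranscriptModel(tid, exons=exons, cds=cds_ivs, utr5=utr5, utr3=utr3)
    layout = "".join(p for _, p in sorted(pieces))
    return tx, pos, layout


def evolve_duplicate(
    cds: str, target_ks: float, seed: int, ka_ks: float = 0.3
) -> str:
    """Mutate a copy of ``cds`` until its NG86 Ks against the original
    first reaches ``target_ks``.

    Proposed single-nucleotide changes that create a stop codon are
    rejected; synonymous proposals are always accepted and nonsynonymous
    ones with probability ``ka_ks`` (the purifying regime of surveyed
    duplicate pairs).
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    if cds[-3:] in STOP_CODONS:
        body = cds[:-3]
        stop = cds[-3:]
    else:
        body, stop = cds, ""
    if len(body) < 300:
        raise ValueError(
            "CDS too short to evolve to a target Ks; provide >= 100 codons"
        )
    if target_ks == 0:
        return cds
    rng = np.random.default_rng(seed)
    seq = list(body)
    n_codons = len(body) // 3
    orig_codons = [body[3 * i : 3 * i + 3] for i in range(n_codons)]

    def measured_ks() -> float:
        copy_codons = [
            "".join(seq[3 * i : 3 * i + 3]) for i in range(n_codons)
        ]
        aln = CodonAlignment(orig_codons, copy_codons)
        try:
            _, _, ks = ng86(aln)
        except ValueError:  # saturated
            return float("inf")
        return ks

    check_every = max(5, n_codons // 100)
    applied = 0
    for _ in range(200 * n_codons):
        pos = int(rng.integers(len(seq)))
        new_base = "ACGT"[rng.integers(4)]
        if new_base == seq[pos]:
            continue
        ci = pos // 3
        old_codon = "".join(seq[3 * ci : 3 * ci + 3])
        new_codon = (
            old_codon[: pos % 3] + new_base + old_codon[pos % 3 + 1 :]
        )
        if new_codon in STOP_CODONS:
            continue
        synonymous = CODON_TABLE[old_codon] == CODON_TABLE[new_codon]
        if not synonymous and rng.random() > ka_ks:
            continue
        seq[pos] = new_base
        applied += 1
        if applied % check_every == 0 and measured_ks() >= target_ks:
            break
    return "".join(seq) + stop


def _scrub_and_plant(
    window: str,
    plantings: list[PromoterPlanting],
    catalog: list[CisElement],
    rng: np.random.Generator,
) -> str:
    """Remove accidental catalog matches from a promoter window, then
    install the requested elements (concrete IUPAC realizations)."""
    L = len(window)
    seq = list(window)
    planted_spans: list[tuple[int, int]] = []

    def occupied(i: int, m: int) -> bool:
        return any(i < e and i + m > s for s, e in planted_spans)

    def plant(p: PromoterPlanting) -> None:
        elem = next(c for c in catalog if c.name == p.element)
        pat = elem.pattern if p.strand == "+" else revcomp_pattern(elem.pattern)
        concrete = "".join(
            IUPAC[sym][rng.integers(len(IUPAC[sym]))] for sym in pat
        )
        i = p.offset + L
        if not 0 <= i <= L - len(concrete):
            raise ValueError(f"planting offset {p.offset} outside window")
        seq[i : i + len(concrete)] = list(concrete)
        planted_spans.append((i, i + len(concrete)))

    for p in plantings:
        plant(p)
    # scrub everything not deliberately planted, on both strands; flipping
    # can create new matches, so iterate to a fixed point
    for _ in range(200):
        dirty = False
        s = "".join(seq)
        for elem in catalog:
            for pat in (elem.pattern, revcomp_pattern(elem.pattern)):
                for i in iupac_sites(s, pat):
                    if occupied(i, len(pat)):
                        continue
                    # flip one unoccupied base inside the match
                    for j in range(i, i + len(pat)):
                        if not occupied(j, 1):
                            cur = seq[j]
                            seq[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
                            dirty = True
                            break
        if not dirty:
            break
    return "".join(seq)


def generate_genome(config: SimConfig) -> SyntheticDataset:
    """Generate genome FASTA / GFF3 / protein & CDS sets / domain-hit
    table with full ground truth.  Deterministic given config.seed."""
    rng_layout = _rng(config.seed, 1)
    rng_seq = _rng(config.seed, 2)
    rng_prom = _rng(config.seed, 3)
    catalog = default_catalog()

    chrom_seqs = [
        list(_random_dna(rng_seq, config.chromosome_length))
        for _ in range(config.n_chromosomes)
    ]
    truth = GroundTruth()
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    domain_hits: list[tuple[str, str, int, int, float]] = []
    # slot padding keeps every gene's 1-kb promoter window (upstream for
    # +, downstream for -) clear of neighbouring genes and windows
    pad = 2 * config.promoter_length + 200
    cursor = [pad] * config.n_chromosomes

    def install(
        chrom: int,
        gene_id: str,
        protein: str,
        cds_body: str,
        strand: str,
        spans: list[tuple[str, int, int]],
        tandem_after: str | None = None,
    ) -> GeneModel:
        tid = f"{gene_id}.1"
        tx, end_plus, layout = _build_transcript(
            tid, 0, cds_body, rng_seq
        )
        span_len = end_plus
        if tandem_after is None:
            start = cursor[chrom] + int(rng_layout.integers(0, 400))
        else:
            # adjacent but beyond the copy's own promoter window
            prev = next(g for g in genes if g.gene_id == tandem_after)
            start = prev.end + int(
                rng_layout.integers(config.promoter_length + 100, 2500)
            )
        end = start + span_len
        if end + pad > config.chromosome_length:
            raise ValueError(
                f"gene {gene_id} does not fit chromosome {chrom + 1}"
            )
        cursor[chrom] = max(cursor[chrom], end + pad)

        if strand == "+":
            offset = start
            installed = layout
            shift = lambda iv: (iv[0] + offset, iv[1] + offset)
        else:
            installed = reverse_complement(layout)
            shift = lambda iv: (end - iv[1], end - iv[0])
        tx.exons = sorted(shift(iv) for iv in tx.exons)
        tx.cds = sorted(shift(iv) for iv in tx.cds)
        tx.utr5 = sorted(shift(iv) for iv in tx.utr5)
        tx.utr3 = sorted(shift(iv) for iv in tx.utr3)
        chrom_seqs[chrom][start:end] = list(installed)
        gene = GeneModel(
            gene_id, f"chr{chrom + 1}", strand, start, end, [tx]
        )
        genes.append(gene)
        proteins[tid] = protein
        cds_map[tid] = cds_body
        for kind, s, e in spans:
            acc = {
                "glyi": GLYI_DOMAIN,
                "lact": GLYII_DOMAIN,
                "haghc": HAGHC_DOMAIN,
            }[kind]
            domain_hits.append((tid, acc, s, e, 100.0))
        return gene

    gene_counter = 0

    def next_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"SYNG{gene_counter:03d}"

    # --- plain family genes -------------------------------------------------
    n_inactive = round(config.fraction_inactive * config.n_glyi_genes)
    glyi_parents: list[str] = []
    for k in range(config.n_glyi_genes):
        inactive = k < n_inactive
        zn_type = (not inactive) and (
            rng_layout.random() < config.zn_fraction
        )
        broken = (False, False, False, False)
        if inactive:
            which = int(rng_layout.integers(4))
            broken = tuple(i == which for i in range(4))
        prot, (ds, de), flags = _glyi_protein(
            rng_seq, broken, zn_type, config.domain_cds_codons
        )
        cds_body = _reverse_translate(prot, rng_seq)
        gid = next_id()
        chrom = int(rng_layout.integers(config.n_chromosomes))
        strand = "+" if rng_layout.random() < 0.5 else "-"
        install(chrom, gid, prot, cds_body, strand, [("glyi", ds, de)])
        truth.genes[gid] = GeneTruth(
            gid, "GLYI", strand, site_flags=flags,
            length_class="Zn" if zn_type else "Ni",
        )
        if not inactive:
            glyi_parents.append(gid)

    for _ in range(config.n_glyii_genes):
        prot, spans = _glyii_protein(
            rng_seq,
            with_haghc=rng_layout.random() < 0.5,
            motifs_present=True,
            total_len=config.domain_cds_codons,
        )
        cds_body = _reverse_translate(prot, rng_seq)
        gid = next_id()
        chrom = int(rng_layout.integers(config.n_chromosomes))
        strand = "+" if rng_layout.random() < 0.5 else "-"
        install(chrom, gid, prot, cds_body, strand, spans)
        truth.genes[gid] = GeneTruth(
            gid, "GLYII", strand,
            has_haghc=any(k == "haghc" for k, _, _ in spans),
        )

    # --- duplicated pairs ---------------------------------------------------
    for di, spec in enumerate(config.duplications):
        prot, (ds, de), flags = _glyi_protein(
            rng_seq, (False, False, False, False), False,
            config.dup_cds_codons,
        )
        cds_body = _reverse_translate(prot, rng_seq)
        gid_a = next_id()
        chrom_a = int(rng_layout.integers(config.n_chromosomes))
        install(chrom_a, gid_a, prot, cds_body, "+", [("glyi", ds, de)])
        truth.genes[gid_a] = GeneTruth(
            gid_a, "GLYI", "+", site_flags=flags, length_class="Ni"
        )

        copy_seed = int(
            np.random.SeedSequence([config.seed, 40 + di]).generate_state(1)[0]
            % (2**31)
        )
        cds_copy = evolve_duplicate(cds_body, spec.target_ks, copy_seed)
        from .genome_io import translate

        prot_copy, _ = translate(cds_copy)
        gid_b = next_id()
        if spec.pair_type == "tandem":
            chrom_b, after = chrom_a, gid_a
        else:
            chrom_b = (chrom_a + 1) % config.n_chromosomes
            after = None
        install(
            chrom_b, gid_b, prot_copy, cds_copy, "+",
            [("glyi", ds, de)], tandem_after=after,
        )
        truth.genes[gid_b] = GeneTruth(
            gid_b, "GLYI", "+", site_flags=flags, length_class="Ni"
        )
        truth.duplicate_pairs.append(
            (gid_a, gid_b, spec.pair_type, spec.target_ks)
        )

    # --- promoters ----------------------------------------------------------
    elem_names = [c.name for c in catalog]
    for gi, gene in enumerate(genes):
        plantings = config.promoter_plantings.get(gi)
        if plantings is None:
            k = int(rng_prom.integers(1, 4))
            plantings = []
            used: list[tuple[int, int]] = []
            for _ in range(k):
                name = elem_names[rng_prom.integers(len(elem_names))]
                m = len(next(c for c in catalog if c.name == name).pattern)
                for _attempt in range(50):
                    off = -int(
                        rng_prom.integers(m, config.promoter_length - 1)
                    )
                    if all(
                        off + m <= s or off >= e for s, e in used
                    ):
                        used.append((off, off + m))
                        break
                else:
                    continue
                strand = "+" if rng_prom.random() < 0.5 else "-"
                plantings.append(PromoterPlanting(name, off, strand))
        chrom = int(gene.chrom_id[3:]) - 1
        L = config.promoter_length
        if gene.strand == "+":
            ws, we = gene.start - L, gene.start
            window = "".join(chrom_seqs[chrom][ws:we])
        else:
            ws, we = gene.end, gene.end + L
            window = reverse_complement("".join(chrom_seqs[chrom][ws:we]))
        window = _scrub_and_plant(window, plantings, catalog, rng_prom)
        if gene.strand == "+":
            chrom_seqs[chrom][ws:we] = list(window)
        else:
            chrom_seqs[chrom][ws:we] = list(reverse_complement(window))
        for p in plantings:
            truth.cis_plantings.append(
                (gene.gene_id, p.element, p.strand, p.offset)
            )

    genome = [
        GenomeSequence(f"chr{i + 1}", "".join(s))
        for i, s in enumerate(chrom_seqs)
    ]
    genes_sorted = sorted(genes, key=lambda g: (g.chrom_id, g.start))
    return SyntheticDataset(
        genome, genes_sorted, proteins, cds_map, domain_hits, truth
    )


_PROFILE_MEANS = {
    # per tissue-class mean on the normalized scale (tau = 1.0)
    "constitutive": {"underground": 8.0, "aerial": 8.0, "seed": 8.0},
    "seed_specific": {"underground": 0.05, "aerial": 0.05, "seed": 5.0},
    "non_seed": {"underground": 5.0, "aerial": 5.0, "seed": 0.05},
    "silent": {"underground": 0.05, "aerial": 0.05, "seed": 0.05},
}


def generate_expression(config: SimConfig):
    """Tissue and stress matrices with planted profiles.

    Returns (tissue DataFrame, tissue classes, stress DataFrame with
    'mock'/'stress' columns, GroundTruth-style dicts updated into a fresh
    GroundTruth).
    """
    import pandas as pd

    rng = _rng(config.seed, 7)
    specs = config.expression
    if not specs:
        profiles = ["constitutive", "seed_specific", "non_seed", "silent"]
        fcs = [2.5, 1.0, 0.3, 1.0]
        specs = {
            f"SYNG{k + 1:03d}": ExpressionSpec(
                profiles[k % 4], stress_fc=fcs[k % 4]
            )
            for k in range(8)
        }
    truth = GroundTruth()
    rows = {}
    stress_rows = {}
    sigma = config.expression_sigma
    for gid, spec in specs.items():
        means = _PROFILE_MEANS[spec.profile]
        vals = []
        for tissue, tclass in TISSUES.items():
            mu = means[tclass]
            noise = float(np.exp(sigma * rng.standard_normal())) if sigma else 1.0
            vals.append(mu * noise)
        rows[gid] = vals
        mock = 2.0
        noise_m = float(np.exp(sigma * rng.standard_normal())) if sigma else 1.0
        noise_s = float(np.exp(sigma * rng.standard_normal())) if sigma else 1.0
        stress_rows[gid] = [mock * noise_m, mock * spec.stress_fc * noise_s]
        truth.expression_classes[gid] = spec.profile
        truth.expression_fc[gid] = spec.stress_fc
    tissue_df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(TISSUES)
    )
    stress_df = pd.DataFrame.from_dict(
        stress_rows, orient="index", columns=["mock", "stress"]
    )
    return tissue_df, dict(TISSUES), stress_df, truth
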