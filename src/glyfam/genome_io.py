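"""Genome and gene-model data layer.

All coordinates are held internally as 0-based half-open intervals; the
GFF3 reader/writer converts from/to the 1-based inclusive convention at
the boundary.  Sequences are plain uppercase strings over {A,C,G,T,N}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "GeneModel",
    "GenomeIOError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_bed6",
    "extract_cds",
    "translate",
    "extract_upstream",
    "reverse_complement",
]


class GenomeIOError(ValueError):
    """Raised for malformed sequence or annotation input."""


@dataclass
class GenomeSequence:
    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise GenomeIOError(
                f"{self.chrom_id}: non-DNA symbols {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise GenomeIOError(
                        f"{self.transcript_id}: overlapping {name} intervals"
                    )
            setattr(self, name, ivs)
        cds_len = sum(e - s for s, e in self.cds)
        if self.cds and cds_len % 3 != 0:
            warnings.warn(
                f"{self.transcript_id}: CDS length {cds_len} not divisible by 3",
                stacklevel=2,
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        ivs = self.exons or self.cds
        return (min(s for s, _ in ivs), max(e for _, e in ivs))


@dataclass
class GeneModel:
    gene_id: str
    chrom_id: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"{self.gene_id}: strand must be + or -")
        if self.start >= self.end:
            raise GenomeIOError(f"{self.gene_id}: start >= end")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate."""
        return self.start if self.strand == "+" else self.end


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence records (file order)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise GenomeIOError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.chrom_id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _gff3_attrs(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse the gene/mRNA/exon/CDS/UTR subset of GFF3 into gene models.

    GFF3 columns 4-5 are 1-based inclusive; internal intervals are 0-based
    half-open.  Models are returned sorted by (chromosome, start).
    """
    genes: dict[str, GeneModel] = {}
    mrna_parent: dict[str, str] = {}
    mrna_parts: dict[str, dict[str, list[tuple[int, int]]]] = {}
    mrna_meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}:{ln}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            s, e = int(start) - 1, int(end)
            if e <= s:
                raise GenomeIOError(f"{path}:{ln}: end < start")
            a = _gff3_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise GenomeIOError(f"{path}:{ln}: gene without ID")
                genes[gid] = GeneModel(gid, chrom, strand, s, e)
            elif ftype == "mRNA":
                tid, parent = a.get("ID"), a.get("Parent")
                if tid is None or parent is None:
                    raise GenomeIOError(f"{path}:{ln}: mRNA needs ID and Parent")
                mrna_parent[tid] = parent
                mrna_meta[tid] = (chrom, strand)
                mrna_parts[tid] = {"exon": [], "CDS": [], "utr5": [], "utr3": []}
                order.append(tid)
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = a.get("Parent")
                if parent is None or parent not in mrna_parts:
                    raise GenomeIOError(
                        f"{path}:{ln}: {ftype} without known parent mRNA"
                    )
                key = {
                    "exon": "exon",
                    "CDS": "CDS",
                    "five_prime_UTR": "utr5",
                    "three_prime_UTR": "utr3",
                }[ftype]
                mrna_parts[parent][key].append((s, e))

    for tid in order:
        parent = mrna_parent[tid]
        if parent not in genes:
            raise GenomeIOError(f"mRNA {tid} references missing gene {parent}")
        parts = mrna_parts[tid]
        tx = TranscriptModel(
            tid,
            exons=parts["exon"],
            cds=parts["CDS"],
            utr5=parts["utr5"],
            utr3=parts["utr3"],
        )
        genes[parent].transcripts.append(tx)

    def chrom_key(c: str):
        digits = "".join(ch for ch in c if ch.isdigit())
        return (0, int(digits), c) if digits else (1, 0, c)

    return sorted(genes.values(), key=lambda g: (chrom_key(g.chrom_id), g.start))


def write_gff3(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom_id}\tglyfam\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for tx in g.transcripts:
                s, e = tx.span
                fh.write(
                    f"{g.chrom_id}\tglyfam\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}"
                    f"\t.\tID={tx.transcript_id};Parent={g.gene_id}\n"
                )
                for ftype, ivs in (
                    ("exon", tx.exons),
                    ("CDS", tx.cds),
                    ("five_prime_UTR", tx.utr5),
                    ("three_prime_UTR", tx.utr3),
                ):
                    for s, e in ivs:
                        fh.write(
                            f"{g.chrom_id}\tglyfam\t{ftype}\t{s + 1}\t{e}\t.\t"
                            f"{g.strand}\t.\tParent={tx.transcript_id}\n"
                        )


def write_bed6(intervals, path: str | Path) -> None:
    """intervals: iterable of (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")


def extract_cds(genome: GenomeSequence, transcript: TranscriptModel,
                strand: str = "+") -> str:
    """Concatenate CDS segments 5'->3' (reverse-complemented on minus)."""
    for s, e in transcript.cds:
        if s < 0 or e > genome.length:
            raise GenomeIOError(
                f"{transcript.transcript_id}: CDS [{s},{e}) outside "
                f"{genome.chrom_id} (length {genome.length})"
            )
    seq = "".join(genome.sequence[s:e] for s, e in transcript.cds)
    return reverse_complement(seq) if strand == "-" else seq


def translate(cds: str) -> tuple[str, bool]:
    """Translate with the universal code.

    Returns (protein, internal_stop_flag).  The terminal stop is stripped;
    a trailing partial codon is truncated with a warning.
    """
    if not cds:
        raise GenomeIOError("empty CDS")
    cds = cds.upper()
    bad = set(cds) - set("ACGTN")
    if bad:
        raise GenomeIOError(f"non-DNA symbols in CDS: {sorted(bad)!r}")
    if len(cds) % 3:
        warnings.warn("CDS length not divisible by 3; truncating", stacklevel=2)
        cds = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    internal_stop = "*" in prot
    if internal_stop:
        prot = prot.split("*", 1)[0]
    return prot, internal_stop


def extract_upstream(genome: GenomeSequence, gene: GeneModel,
                     n: int = 1000) -> tuple[str, bool]:
    """The n bases immediately 5' of the gene's transcription start.

    Returns (sequence, truncated_flag); the sequence reads 5'->3' on the
    gene's own strand.  Truncated at chromosome edges rather than failing.
    """
    if n <= 0:
        raise GenomeIOError("n must be positive")
    if gene.strand == "+":
        s, e = max(0, gene.start - n), gene.start
        seq = genome.sequence[s:e]
    else:
        s, e = gene.end, min(genome.length, gene.end + n)
        seq = reverse_complement(genome.sequence[s:e])
    return seq, len(seq) < n
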