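"""Duplicate-pair detection, NG86 Ka/Ks estimation and divergence dating.

The Nei-Gojobori (1986) counting method is implemented from first
principles:

* Site counts.  For each codon and each of its three positions, the
  fraction of possible single-nucleotide changes that are synonymous is
  computed, with changes that create a stop codon excluded from the
  denominator; the codon's synonymous site count S is the sum of the
  three fractions and N = 3 - S.  S and N are averaged over the two
  sequences, so S + N = 3 x n_codons exactly.

* Difference counts.  Codon pairs differing at k positions are resolved
  by averaging the synonymous/nonsynonymous step counts over all k!
  single-change pathways, skipping pathways that pass through a stop
  codon (if every pathway is blocked, the codon is dropped with a
  warning).

* Distances.  pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected,
  d = -(3/4) ln(1 - 4p/3), giving Ks and Ka; p >= 3/4 is saturation and
  raises.

Duplication typing follows the operational rules used in plant
gene-family surveys: pairs over 90% protein identity are duplicates;
a pair on one chromosome separated by at most five intervening genes
within 100 kb is tandem, anything else segmental.  Divergence time is
T = Ks / (2 lambda), with lambda the synonymous substitution rate per
site per year (6.1e-9 for soybean).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import log

from Bio import Align
from Bio.Data.CodonTable import standard_dna_table

from .genome_io import translate

__all__ = [
    "DuplicatePair",
    "CodonAlignment",
    "NgCounts",
    "pairwise_identity",
    "classify_duplication",
    "codon_align",
    "ng86",
    "ng86_counts",
    "jukes_cantor",
    "SENSE_CODONS",
    "divergence_time",
    "selection_class",
    "DEFAULT_RATE",
    "codon_site_fractions",
    "codon_pair_differences",
]

DEFAULT_RATE = 6.1e-9  # synonymous substitutions / site / year (soybean)
IDENTITY_THRESHOLD = 90.0
TANDEM_MAX_INTERVENING = 5
TANDEM_MAX_GAP = 100_000

_BASES = "TCAG"
CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TABLE)


@dataclass
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity_pct: float
    dup_type: str  # segmental | tandem | none
    ka: float = float("nan")
    ks: float = float("nan")
    ratio: float = float("nan")
    time_mya: float = float("nan")


@dataclass
class CodonAlignment:
    codons_a: list[str]
    codons_b: list[str]
    dropped_columns: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class NgCounts:
    S: float
    N: float
    Sd: float
    Nd: float

    @property
    def pS(self) -> float:
        return self.Sd / self.S

    @property
    def pN(self) -> float:
        return self.Nd / self.N


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over a global protein alignment.

    The denominator includes internal gap columns but excludes terminal
    overhangs (columns before the first or after the last aligned pair).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _aligner().align(seq_a, seq_b)[0]
    ia, ib = aln.indices
    aligned_cols = [
        k for k in range(len(ia)) if ia[k] >= 0 and ib[k] >= 0
    ]
    if not aligned_cols:
        return 0.0
    first, last = aligned_cols[0], aligned_cols[-1]
    ncols = last - first + 1
    matches = sum(
        1
        for k in aligned_cols
        if seq_a[ia[k]] == seq_b[ib[k]]
    )
    return 100.0 * matches / ncols


def classify_duplication(
    same_chromosome: bool,
    identity_pct: float,
    intervening_genes: int,
    genomic_gap: int,
) -> str:
    """'none' below the identity threshold; else tandem when the pair sits
    within 5 intervening genes and 100 kb on one chromosome, otherwise
    segmental."""
    if identity_pct <= IDENTITY_THRESHOLD:
        return "none"
    if (
        same_chromosome
        and intervening_genes <= TANDEM_MAX_INTERVENING
        and genomic_gap <= TANDEM_MAX_GAP
    ):
        return "tandem"
    return "segmental"


def codon_align(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided codon alignment (PAL2NAL-style back-threading).

    Translations are globally aligned; each aligned residue column is
    projected back onto its codon triplet.  Columns containing a gap, an
    ambiguous base, or a stop codon are dropped and counted.
    """

    def prep(cds: str) -> str:
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        # trim a trailing stop so it does not enter the alignment
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        return cds

    cds_a, cds_b = prep(cds_a), prep(cds_b)
    prot_a, _ = translate(cds_a + "TAA")
    prot_b, _ = translate(cds_b + "TAA")
    aln = _aligner().align(prot_a, prot_b)[0]
    ia, ib = aln.indices
    cods_a, cods_b, dropped = [], [], 0
    for k in range(len(ia)):
        ra, rb = ia[k], ib[k]
        if ra < 0 or rb < 0:
            dropped += 1
            continue
        ca = cds_a[3 * ra : 3 * ra + 3]
        cb = cds_b[3 * rb : 3 * rb + 3]
        if (
            set(ca + cb) - set("ACGT")
            or ca in STOP_CODONS
            or cb in STOP_CODONS
        ):
            dropped += 1
            continue
        cods_a.append(ca)
        cods_b.append(cb)
    return CodonAlignment(cods_a, cods_b, dropped)


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str) -> float:
    """Synonymous site count of a sense codon.

    Each position contributes (synonymous changes) / (changes not creating
    a stop); summed over the three positions.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            denom += 1
            if CODON_TABLE[alt] == aa:
                syn += 1
        if denom:
            s += syn / denom
    return s


@lru_cache(maxsize=None)
def codon_pair_differences(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two sense codons; pathways through stop codons are skipped.

    Returns (nan, nan) when every pathway is blocked.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return (0.0, 0.0)
    syn_tot = nonsyn_tot = 0.0
    n_ok = 0
    for order in itertools.permutations(diff_pos):
        cur = ca
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if not blocked:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_ok += 1
    if n_ok == 0:
        return (float("nan"), float("nan"))
    return (syn_tot / n_ok, nonsyn_tot / n_ok)


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"substitution proportion {p:.4f} saturated (>= 0.75)")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_counts(alignment: CodonAlignment) -> NgCounts:
    """NG86 site and difference counts for a codon alignment."""
    if alignment.n_codons < 1:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        sa, sb = codon_site_fractions(ca), codon_site_fractions(cb)
        sd, nd = codon_pair_differences(ca, cb)
        if sd != sd:  # NaN: all pathways blocked by stops
            warnings.warn(
                f"codon pair {ca}/{cb}: all pathways pass through stops; "
                "dropped",
                stacklevel=2,
            )
            continue
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        Sd += sd
        Nd += nd
    return NgCounts(S=S, N=N, Sd=Sd, Nd=Nd)


def ng86(alignment: CodonAlignment) -> tuple[NgCounts, float, float]:
    """NG86 counts and Jukes-Cantor-corrected (Ka, Ks) for an alignment."""
    counts = ng86_counts(alignment)
    ks = jukes_cantor(counts.pS) if counts.S > 0 else 0.0
    ka = jukes_cantor(counts.pN) if counts.N > 0 else 0.0
    return counts, ka, ks


def divergence_time(ks: float, rate: float = DEFAULT_RATE) -> float:
    """T = Ks / (2 * rate), reported in Mya."""
    if ks < 0:
        raise ValueError("negative Ks")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return ks / (2.0 * rate) * 1e-6


def selection_class(ka: float, ks: float, tol: float = 1e-9) -> str:
    """Purifying / neutral / positive from the Ka/Ks ratio (threshold 1)."""
    if ks == 0:
        if ka > 0:
            warnings.warn("Ks = 0 with Ka > 0: infinite ratio", stacklevel=2)
            return "positive"
        return "neutral"
    ratio = ka / ks
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"
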