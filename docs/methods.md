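# Methods

`glyfam` re-implements, as a reusable and tested library, the standard
workflow of a plant gene-family survey, using the soybean glyoxalase
system (GLYI/GLYII) as its concrete subject.  This note documents the
models and procedures, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Family identification and nomenclature

Membership is decided purely by Pfam-style domain content: a protein is
GLYI iff it carries at least one lactoylglutathione lyase domain
(PF00903) and GLYII iff it carries a metallo-β-lactamase domain
(PF00753), optionally with a C-terminal HAGH-C substrate-binding domain
(PF16123).  Candidates with neither domain are discarded with a logged
reason.  The homology search that produces the candidate set is out of
scope: the library consumes a complete domain-hit table (headered TSV or
HMMER `--domtblout`).

Names follow the community convention `<prefix><family>-<k>.<j>`: genes
are numbered serially per family along chromosomes (natural numeric sort
of the chromosome label, then start coordinate ascending), splice
variants by transcript-ID suffix.  Nomenclature is a pure function of
coordinates — permuting the input order changes nothing.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and BED (0-based half-open) convert at the I/O boundary.  "Gene start"
for promoter extraction is the strand-aware transcription start of the
gene feature, not the CDS start.

## Protein properties

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water, the ProtParam convention; `X` contributes the mean
residue mass and is flagged.  The isoelectric point solves
net-charge(pH) = 0, where the charge is a Henderson–Hasselbalch sum over
D, E, C, Y side chains (negative), H, K, R side chains (positive) and
the two termini.  The charge is strictly decreasing in pH, so bisection
on [0, 14] (tolerance 1e-3) finds the unique root; a dense-grid scan is
used as the independent oracle in tests.  The pKa set defaults to the
Bjellqvist/ExPASy values and is injectable (YAML), e.g. to swap in EMBOSS
values.  Because the underlying full-length protein sequences of the
surveyed family are not part of the packaged fixtures, printed pI/MW
values are carried as data, not recomputed from sequence.

## Activity and metal-dependency classifiers

GLYI activity requires an intact conserved metal-binding quartet
H/Q–E–H/Q–E in the (N-terminal) glyoxalase domain.  Site detection
globally aligns the query domain (BLOSUM62, gap open 10 / extend 0.5) to
a reference domain whose four site columns are annotated; the residue
mapped to each column is checked against its allowed class.  Queries
under 30 aa are rejected; queries aligning below 20% identity get
all-false flags with a warning.  The packaged reference is a synthetic
domain (the surveyed reference sequences are not published with the
tables); any reference profile can be supplied.

Metal dependency of active enzymes tracks domain length: Ni-type domains
run ≈120 aa, Zn-type ≈142 aa and longer.  Thresholds are Ni ≤ 130 aa and
Zn ≥ 140 aa, with 131–139 aa called `ambiguous`; observed survey values
(117–126 vs 145–169) sit well clear of the dead zone.  A configurable
Zn-signature pattern can override length; it defaults to unset, making
length the deciding criterion, because the Zn-specific conserved regions
are not sequence-specified in the literature the thresholds come from.

GLYII activity requires both a metal-binding motif — default `THXHXDH`,
with the stricter `THHHXDH` variant selectable, since both forms are in
circulation — and the active-site motif `[C/G]HT`.  Matching is exact
over X-wildcard residue patterns; all match positions are recorded.

## Duplication, Ka/Ks and divergence dating

Pairs over 90% protein identity are duplicates.  Identity is computed
over a global alignment (BLOSUM62, affine gaps 10/0.5); the denominator
includes internal gap columns and excludes terminal overhangs — the
definition is stated because "similarity" has no unique convention.  A
duplicate pair on one chromosome separated by ≤ 5 intervening genes
(counted over the full annotation, not just family members) within
100 kb is tandem; anything else is segmental.

Ka/Ks uses the Nei–Gojobori (1986) counting method on a protein-guided
codon alignment (translations aligned globally, residue columns threaded
back to codons; columns with gaps, ambiguous bases or stops dropped and
counted).  Site counts: each codon position contributes
(synonymous changes)/(changes not creating a stop); S is the sum over
positions, N = 3 − S, averaged over the two sequences so S + N = 3 ×
codons exactly.  Differences: codons differing at k positions are
averaged over all k! single-step pathways, skipping pathways through
stop codons; if every pathway is blocked the codon is dropped with a
warning.  pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 is saturation and raises.  A
brute-force pathway-enumeration oracle (recursive, independent of the
table-driven implementation) verifies every sense-codon pair in tests.

Divergence time is T = Ks/(2λ) in Mya with λ the synonymous substitution
rate per site per year, default 6.1×10⁻⁹ (soybean); the rate is
configurable.  Selection classes threshold Ka/Ks at 1 (tolerance 1e-9);
Ks = 0 with Ka > 0 reports positive with an infinite-ratio flag.

## Phylogeny

Distances are protein p-distances with pairwise gap deletion (a column
is skipped for a pair only when either member has a gap), the common
default of distance-based phylogeny tools; complete deletion is not
implemented.  Trees are built by Saitou–Nei neighbor joining with a
deterministic tie-break (lowest label-index pair).  NJ is exact on
additive matrices; property tests regenerate random additive trees
(4–12 leaves) and require exact topology and ≤1e-9 branch-length error.
Negative branch estimates (possible on non-additive input) are clamped
to zero with the deficit moved to the sibling edge and counted.
Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate, and reports the percentage of replicates
containing each internal bipartition of the full-data tree.  Multiple
sequence alignment itself is consumed as input from any aligner.

## Promoter scanning

1-kb upstream windows (strand-aware, truncated with a flag at
chromosome edges) are scanned exhaustively on both strands against a
named catalog of IUPAC consensus elements.  An N in the genome matches
nothing.  Positions use the −1000…−1 convention, giving the leftmost
base of the occupied window; a minus-strand match is a forward
occurrence of the reverse-complemented pattern.  Overlapping and
palindromic matches are all reported; there is no PWM scoring — the
scanner, not the catalog, is the contract.  The shipped catalog holds
PlantCARE-style default consensi (ABRE ACGTG core, W-box TTGACC, HSE
AGAANNTTCT, the TGACG/CGTCA pair, …) and is fully overridable via TSV.

## Expression

Matrices are genes × conditions of nonnegative normalized values with a
condition → class map (underground/aerial/seed, or mock/stress).  Fold
change is max(stress, floor)/max(mock, floor) with floor 0.1; regulation
calls default to up ≥ 2× and down ≤ 0.5× — declared defaults, since
heatmap-based judgments in the surveyed literature state no cutoff.
Hierarchical clustering uses 1 − Pearson r distance with average
linkage (MeV-style defaults; Euclidean and other linkages available);
zero-variance rows sit at distance 1 to everything with a warning.  A
brute-force average-linkage agglomerator is the test oracle.
Specificity classes use an expressed-threshold τ = 1.0 on the
normalized scale: constitutive (≥ 90% of conditions expressed),
seed-specific, non-seed, silent, otherwise restricted.

## Synthetic data

The generator emulates the survey's inputs at desk scale: 3 chromosomes
of 90 kb, 6 GLYI and 3 GLYII genes plus 3 duplicate pairs, stranded
multi-exon gene models with UTRs and GT…AG introns, i.i.d. uniform
background DNA.  Half the GLYI members carry one knocked-out conserved
site (mirroring the surveyed family, where about half the isoforms are
inactive); a fifth of active members are long-domain Zn-type.  Promoter
windows are scrubbed to a fixed point of zero accidental catalog matches
before elements are planted as concrete IUPAC realizations, so
planted-element recovery is exact by construction.  Duplicate pairs copy
a parent CDS and accept random single-base mutations — synonymous
always, nonsynonymous with probability 0.3, the purifying regime of the
surveyed pairs — until the NG86-measured Ks first reaches its target.
Planted pairs must themselves satisfy the > 90%-identity duplicate
definition: identity at this regime falls through 90% near Ks ≈ 0.15,
so default targets are 0.05–0.08 and duplicate-pair genes use 300-codon
proteins to keep identity tightly concentrated.  Expression profiles are
class templates (constitutive 8.0, seed-only 5.0, silent 0.05 on a
τ = 1 scale) with multiplicative lognormal noise (σ = 0.1 by default)
and planted stress fold changes.

One integer seed drives everything; submodule streams are derived with
fixed offsets (`SeedSequence([seed, k])`) so adding a generator never
perturbs existing output.  Ground truth records every planted fact, and
end-to-end tests assert against recorded truth only.

What the generator does not emulate: codon-usage and isochore bias,
realistic intron length distributions, overlapping or nested genes,
alternative splicing (one transcript per synthetic gene — the fixture
tables carry the multi-isoform cases), probe-to-gene mapping noise, and
read-level sequencing artifacts.  Passing recovery tests therefore
demonstrate correctness of the algorithms under clean planted truth,
not robustness to annotation error in real genomes.

## Fixture tables

The catalog, duplicate-pair, site-flag and motif tables packaged under
`glyfam/data/` transcribe published survey values verbatim and are used
to check every derivable column: Ka/Ks ratios and divergence times from
printed Ka and Ks (15/15 rows at 4 decimal places), GLYI activity and
metal calls from printed site flags and domain lengths (41/41), GLYII
activity from printed motif flags (23/23), and family summary statistics
(24 genes/41 proteins, CDS 333–1101 bp, max protein 366 aa, minimum pI
4.86 for GLYI; 12/23 and 527 aa for GLYII).  Two recorded
inconsistencies inside the source tables are carried as printed, not
reconciled: the stated 740-bp mean CDS differs from the mean of the
printed lengths (743.2), and the stated GLYII minimum CDS (432 bp)
exceeds the shortest printed GLYII CDS (258 bp).

## Problem sizes in tests

The default suite runs the generator at the desk-scale configuration
above, NG86 oracle equivalence over all 61×61 sense-codon pairs, Ks
recovery on 3000-codon sequences (20 seeds × 3 targets), 100 random
additive NJ trials, and 5-seed expression recovery — about 20 s in
total.
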