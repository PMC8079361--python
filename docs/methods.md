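# Methods

This note records the models, parameter choices and numerical conventions
behind `slrtx`, and what the simulation-based tests do and do not
demonstrate.

## Library model and simulator

The simulator emulates a UMI-based synthetic long-read transcriptome
library: each sampled cDNA molecule is tagged with a 16 nt UMI (drawn
uniformly from the 4^16 space; collisions are allowed and recorded in the
truth table rather than prevented, so the collision pathway stays
testable), flanked by fixed 22 nt synthetic 5′/3′ adapters (package
constants, configurable — the real adapter sequences are proprietary), and
sheared into short reads whose headers carry
`BX:<sample>:<UMI> MI:<molecule>`.

Three wet-lab artefacts are modelled explicitly, each with a truth label:

- **Premature reverse-transcription termination** (default probability
  0.13): a 5′ segment of the transcript, uniform over [100, L/2] nt, is
  lost before the terminal adapter attaches. The molecule therefore still
  classifies as full length while its start site sits >100 nt downstream
  of the annotated one — the "false full-length" phenomenon. The 100 nt
  floor matches the observation that essentially all non-canonical start
  sites are shifted by more than 100 nt; the 0.13 default is a free
  parameter chosen near the observed fraction of downstream-shifted
  contigs, since the underlying molecular fraction is not published.
- **3′ poly-T mis-priming** (default probability 0.156): the termination
  site moves by an offset drawn from a discrete normal (SD 2 nt) truncated
  to [−5, +5]; negative offsets trim the 3′ end, positive offsets extend
  into the poly-A tail (realised as appended A's). An offset of 0 is a
  possible draw and lands in the "exact" bucket.
- **Inter-molecular PCR chimeras** (default rate 0.018): a Bernoulli
  fraction of molecules is replaced by the 5′ part of the molecule joined
  to the 3′ part of a partner from a different isoform, with the junction
  uniform in the middle half of the insert — chimeras are presumed to form
  once, near the middle.

Fragmentation draws read starts uniformly over [−(R−1), L−1] with clipping
at the molecule ends (fragments shorter than 25 nt are dropped), which
keeps per-position coverage approximately uniform including the termini —
the property the consensus error model relies on. The read count per
molecule is chosen so the mean per-position depth matches the configured
coverage. Substitutions, insertions and deletions are injected
independently per base (defaults 4×10⁻³ / 4×10⁻⁴ / 5×10⁻⁴, matching
short-read RNA sequencing error scales). The simulator does **not** model
cycle-dependent Illumina error spectra, PCR duplication beyond chimeras,
or poly-A tail length; conclusions about those aspects of real data cannot
be drawn from these tests. All outputs are byte-deterministic in the seed;
each operation derives a stage-local generator from (seed, stage index).

Toy annotations place genes with exon/intron sizes of 150–400 nt by
default; multi-isoform genes use exon skipping so isoforms share sequence,
which exercises the ambiguity handling in assignment and end-mapping. With
fusion scenarios enabled the layout guarantees one cis pair separated by
>40 kb with a gene wholly in between, one cis pair under 40 kb, and one
trans pair, plus a designed-fusion table with 50+50 nt junction flanks.

## Assembly and the quality model

Bins are single molecules, so a general assembler is unnecessary. We count
k-mers (k = 25) over both read orientations, drop k-mers below multiplicity
2 (this removes most error k-mers and short tips), and extend greedily from
the most-supported k-mer, choosing at each branch the successor with the
higher count and breaking ties alphabetically — the same rule that
collapses error bubbles deterministically. The draft is oriented by the 5′
adapter and polished up to twice by re-aligning all member reads (edlib,
both orientations) and taking a per-column plurality vote over
{A, C, G, T, deletion}; ties prefer a base over a gap, then alphabetical
order. Uncovered flank columns are trimmed; interior zero-depth columns
violate the contract and raise.

Per-base quality integrates depth, read qualities and consensus as

    p_err = (d − c + 1) / (d + 2)

with `d` the column depth and `c` the plurality count (a Laplace-smoothed
dissent probability), floored at the depth-weighted mean per-read error
probability of the column, and `Q = round(−10·log10 p_err)` capped at Q60.
This closed form is a declared stand-in: it is deliberately conservative —
at unanimous depth 30 it yields Q15, not the cap — because treating reads
as independent would overstate confidence under systematic (e.g.
RT-induced) errors. No downstream analysis depends on its exact values.
Minimum reads per bin is 3; below that a consensus is statistically
meaningless.

Adapters are located by best semi-global match within a terminal window of
1.5× adapter length at edit distance ≤ 2; the completeness class follows
from the two flags, and `full_length` requires both.

## Alignment and QC conventions

Contig-to-reference alignment uses edlib (unit-cost semi-global, extended
CIGAR), keeping the operation runs as the alignment record. Affine gap
scoring would not change any reported quantity on near-identical
contig/reference pairs, which is the regime all QC operates in.

Error rates share one denominator — total aligned assembled bases
(matches + mismatches + insertions) — and the match rate is defined as
1 − (substitution + insertion + deletion), so the four rates always sum
to 1. Positional bias is the per-position rate of an error type divided by
its overall rate; homopolymer runs ≥ 4 nt are flagged because indel
hotspots concentrate in runs of four to seven identical bases.

Terminus offsets are signed, positive downstream. The start-site offset is
where the alignment enters the reference minus any unaligned 5′ overhang;
the termination-site offset is where it leaves relative to the reference
end plus any 3′ overhang (so appended poly-A reads as a positive offset).
Buckets: exact (0), within ±5 (non-zero), and >100 downstream; fractions
are over full-length contigs only.

Chimera detection maps the two terminal 100 nt windows independently
against the reference set. Different best references → inter-molecular;
one reference but inconsistent strand/order/separation (beyond 1.5× contig
length) → intra-molecular; an unmappable window (best edit distance above
25% of the window) → unmapped-end; all three count as flagged. When a
window ties across several references — unavoidable when isoforms share
exons — the contig is clean if the two ends' tie sets intersect
consistently; on ERCC-style references (distinct sequences) the tie set is
a singleton and this rule is inert.

Abundance comparison is Pearson r of log2(expected) vs log2(observed+0.5),
with and without the ≥700 bp length filter, observed counts over
full-length contigs only; r is reported as undefined for fewer than three
references or a constant axis.

## Isoform assignment

The contig's closest spliced transcript (minimum edit distance over both
strands) fixes the gene; the alignment to that transcript is projected
through its exon map. Deletion runs ≥ 20 transcript nt become replacement
junctions (exon skipping), insertion runs that long mark the contig novel
(sequence not placeable on the gene), and shorter indels adjacent to a
junction shift its effective coordinate. The resulting genomic junction
chain must match a contiguous block of an annotated isoform's chain with
every junction end within ±5 nt (the tolerance mirrors the ±5 nt
granularity used at transcript termini); among consistent isoforms the one
with fewest unmatched junctions wins, then the lexicographically smallest
id. Mono-exonic contigs are assigned by exon containment with the same
tie-break. The 20 nt intron threshold separates splice gaps from indel
errors at these scales.

## Differential expression

Counts are normalised by median-of-ratios size factors. Dispersion is
estimated per feature by method of moments and floored at 0.01 **and** at
the pooled median across features: at 3-vs-3 replication the per-feature
estimate is so noisy that a plain Wald test is anticonservative (measured
type-I ≈ 0.10 at nominal 0.05). The test statistic compares the group
means against the null variance at the pooled mean (a score-type
denominator) with a standard-normal reference, which measures ≈ 0.047
type-I error under a negative-binomial null while retaining power for
large effects. Selection is BH-adjusted p ≤ 0.05 and fold change > 2;
all-zero features get p = 1 and are excluded from the BH denominator.
This engine is intentionally minimal — it implements the selection rule,
not any particular published implementation.

## SNV screens

The chi-squared "uneven distribution" screen needs a null for how ALT
contigs should spread across isoforms; we use each isoform's share of the
variant's total (WT+ALT) contigs, i.e. allele placement is tested against
overall isoform usage rather than uniformity. Variants on a single isoform
or with fewer than 5 contigs are excluded before testing; zero-expected
cells are pooled into the neighbour with the closest total. The 2×k Fisher
test is exact by full enumeration over fixed-margin tables up to total
200, Monte-Carlo (10⁵ draws, fixed seed 20210427) beyond. The switching
rule resolves the overlapping published thresholds (≥0.5 high, ≤0.5 low)
as high ≥ 0.5, low < 0.5, strict on the low side; pairs with an undefined
rate in any sample are excluded with a reason.

## Fusion detection

Known-junction search is exact substring matching of the 30-mer centred on
the 100 nt flank (characters 36–65), in both orientations — reverse
complement included because contig strandness is not guaranteed after
assembly. Verification splits the contig at the hit and requires each arm
to align to its expected partner at ≥90% identity over ≥50 nt, with the
breakpoint refined to the split of minimum combined edit distance (±10 nt
scan). Novel candidates are contigs whose terminal windows map to two
distinct genes; their breakpoint is the minimum-cost split against the two
partners' transcripts (coarse 25 nt grid, then fine scan), projected to
genomic coordinates. Filters: pass ⇔ trans, or cis with gene-span
separation > 40 kb and ≥1 wholly intervening gene, and both breakpoints
within ±2 nt of an annotated exon edge, and verified. Separation is
measured between gene boundaries (the published criterion does not specify
junction-to-junction vs gene-to-gene; this choice is configurable), and
the ±2 nt exon-edge tolerance absorbs alignment jitter.

## Problem sizes and determinism

The shipped test and acceptance runs use 400–500 molecules of 0.5–1.5 kb
at depth 25, 20 references, 1,000-variant null screens and 50-table Fisher
oracle sweeps — sizes chosen so every stochastic check has enough events
for 3-standard-error comparisons while the full suite completes in a few
minutes. All simulations are seeded; the acceptance script derives every
generator from its `--seed` argument.

## Known limitations

- The assembler is specialised to single-molecule bins; repeats longer
  than k within one molecule can truncate the greedy walk.
- The quality model is a conservative stand-in (see above); calibrated
  per-base error probabilities would require a trained model.
- UMI errors are not corrected: each distinct UMI is a distinct bin, as in
  the underlying protocol analysis.
- Insertion consensus during polishing ignores read-insertion votes;
  systematic insertions shared by most reads of a bin would be missed
  (they do not arise in the simulator's error model).
- The DE engine is a two-group test only; designs with covariates are out
  of scope.
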