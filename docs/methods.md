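# Methods

This note records the models, conventions and design choices behind
`retrodup`, in the order the pipeline runs them.

## Coordinates and conventions

All coordinates are 0-based, half-open (BED convention), in every module,
file format and API. Sequence identity is always matches / (matches +
mismatches); gap columns never enter the denominator. Interval merging
follows BEDTools-merge semantics (overlapping *and* book-ended intervals
join).

## Synthetic genomes (`synthgen`)

The simulator is first-class code, not a fixture: it defines the
conditions under which every downstream claim is tested.

**Background sequence.** Chromosomes are built from 10 kb blocks whose GC
content is drawn from Normal(gc, 0.08), clipped to [0.2, 0.8]. This
isochore-like regional structure exists so that depth tracks show a
realistic GC spread — with i.i.d. bases every 1 kb window has virtually
identical GC and a GC-bias correction would be untestable. The repeat
mask is a set of random 200–2000 bp intervals accumulated until the
target masked fraction is reached (trimmed to land within the stated
±20% tolerance); masked sequence is ordinary random sequence that is
merely *flagged*, which is all the seeding rules consume.

**Genes** are written in place (overwriting background) as n exons of an
intact ORF (ATG, non-stop codons, stop) separated by GT…AG introns.
Single-exon genes are refused: a retrocopy call must cross a junction,
so they cannot act as parents.

**Retrocopies** follow the target-site-duplication model of L1
integration: the TSD duplicates the sequence already present at the
insertion site, so the inserted block is `[TSD][body][poly(A)]` (in the
appropriate orientation) and the pre-existing target sequence becomes the
downstream copy. The pre-integration ("empty") allele therefore retains
exactly one TSD copy — required for the filled/empty comparator to see
the repeat exactly at the insertion boundary, as it does in real data.
The body is the spliced cDNA, optionally 5'-truncated by a fraction of
its length and point-mutated at a per-base substitution probability.
When the canonical cleavage motif is requested (and the TSD is >= 5 bp),
the seven bases of minus-strand context (`TTTTAA` + one free base) are
written into the target site before duplication. Private retrocopies
planted during divergence never force a motif: the motif belongs to the
site, which the sister's empty allele must share.

**Divergence.** A sister assembly receives Binomial(eligible sites,
2·μ·g) substitutions — two lineages each accumulating μ·g — placed only
at unmasked positions outside planted events, then its own private
retrocopy insertions. A registry propagates the coordinate shifts every
insertion causes, so recorded truth intervals always extract exactly
from the emitted FASTA (this round-trip is asserted in tests).

**Site sampling.** Insertion sites are rejection-sampled (bounded at 100
tries, then a deterministic placement error) away from the mask, prior
events (150 bp margin) and chromosome ends (800 bp margin — flanks up to
500 bp must be extractable, as they always are on a full-size
chromosome). Cohort simulations additionally pass an `avoid` list so
that independent insertions in different sisters stay mutually distant:
on a 2.4 Gb genome two independent insertions within flank distance are
vanishingly rare, but on a 150 kb toy genome they would be common — an
artifact of scaling down, not a property of the process under study.

**Depth.** Window raw depth is Poisson with mean
`mean_depth × (local copy number / 2) × (1 + 2·gc_bias·(gc − 0.5))`,
aggregated over the window's unmasked bases; a base inside a planted
duplication family of f total copies has diploid copy number 2f. Windows
hold exactly `window_unmasked` unmasked bases except the last per
chromosome.

**What the generator does not emulate:** read-level sequencing error,
indels and rearrangements other than the planted insertions, transposon
sequence families inside the mask, UTR annotation error, assembly
collapse/expansion artifacts. Passing tests therefore demonstrate the
*logic* of each stage under substitution-only divergence, not robustness
to assembler misrepresentation of duplications — which on real data is
exactly where self-alignment and read-depth calls disagree.

## Duplication discovery and post-processing (`dupalign`)

The pairwise finder is a k-mer seed-and-extend engine honouring the
output contract of a segmental-duplication caller: maximal gapless local
alignments >= 1 kb at >= 90% identity, seeds (k = 21) barred from
initiating inside the repeat mask, mitochondrial pairs removed, pairs
stored with A lexicographically <= B. Because the synthetic substrate
carries substitutions but no indels, alignments live on single
diagonals; seeds sharing a diagonal merge into runs (gap <= 600 bp) and
are X-drop extended (+1/−3, drop 15). The forward strand only is
searched — planted duplications are direct copies, and the pair type
carries no strand. Tandem arrays legitimately produce overlapping-
paralog alignments (e.g. source+copy1 vs copy1+copy2), which is why
recovery is asserted as coverage of each planted family member rather
than one-to-one pair identity.

High-recurrence segments: duplications < 2.5 kb have both projected
endpoints rounded to the nearest hundred (half away from zero, so
…50 rounds up), rounded intervals merge into segments, and each segment
counts *distinct* pairwise records overlapping it — a pair with both
ends in one segment counts once. Segments with >= 4 records are kept.

Edge enrichment re-places each interval uniformly within its own
chromosome (lengths preserved, chromosomes shorter than twice the edge
skipped with a warning); fold = observed fraction / permutation mean.

The read-depth comparison filters both sets to assembled chromosomes,
>= 15 kb, >= 95% identity (self-alignment side) and outside the first
megabase, then reports union/intersection bp and support: a
self-alignment interval is supported when the median copy number of its
intersecting windows is >= 2.5; a read-depth region when it overlaps any
self-alignment interval.

## Read-depth copy number (`depthcn`)

Depth is corrected against diploid control windows (windows fully inside
caller-supplied control intervals; >= 50 required). Controls are grouped
into GC bins of width 0.05; the correction curve is the binned control
depth means *linearly interpolated* between knots placed at each bin's
mean control GC, evaluated at the window's GC. Interpolation (rather
than a per-bin constant) removes the sawtooth residual that a constant
leaves and corrects a linear bias exactly; knots at bin-mean GC (rather
than bin centers) avoid a systematic tilt when GC is not uniform within
bins. Windows in bins with no controls take the interpolated/edge value,
with a warning. Corrected depth is scaled so control windows average
copy number 2, making the estimate invariant to global depth scaling.

Duplicated regions are maximal runs of consecutive windows
(adjacent rows of one chromosome's sorted window list, regardless of the
masked gap between them) with CN > 2.5, kept when the run holds >= 4
windows *and* spans >= 10 kb of genome (first window start to last
window end). Region and gene copy numbers are medians (even counts
average the two central values). A gene must fully encompass >= 3
windows to be reported; duplicated means median > 2.5.

## Retrocopy calling (`retrofind`)

One transcript represents each gene: maximal spliced length, ties broken
to fewest exons, then rejection if any intron < 50 bp or fewer than two
exons. The cDNA is aligned to both genome strands with the k-mer engine
at k = 11; k-mers occurring more than 32 times are skipped at seeding
(the over-represented-seed filter of a cDNA mapper — this is also what
keeps poly(A) seeds out). Alignments survive when >= 100 bp, outside the
parent gene's full genomic footprint, >= 90% identity, and crossing at
least one exon–exon junction with >= 10 aligned bases on each side (the
margin prevents 1 bp-overhang artifacts). Survivors of one transcript
within 100 bp merge into a single locus with a recorded segment count
(multi-segment loci are excluded from hallmark detection later). When
transcripts of different genes align equally to one locus the call keeps
the union of candidate parents.

Full-ORF: the call's aligned query ranges must cover the parental CDS
contiguously; the corresponding genomic sequence is extracted through
the block mapping (reverse-complemented for minus-strand calls) and
translated — original ATG, no internal stop, terminal stop.

## Hallmarks (`hallmarks`)

**Locus preparation.** Loci within 100 bp of an N-run or a chromosome
end, and multi-segment loci, are excluded; symmetric flanks (default
60 bp, chosen to keep TSD and poly(A) detections concordant while
minimising flank size) are extracted.

**TSD.** Up- vs down-flank local alignment under +2/−6, N pairs −1000,
affine gaps costing 10 to open plus 10 per column (a length-g gap costs
10 + 10g). The Gotoh DP is written here; Biopython's PairwiseAligner
under the same matrix serves as the independent oracle in tests, never
as the implementation. Among co-optimal alignments the one with the
smallest up-flank start, then smallest down-flank start, wins
(deterministic tie-break; the tool being emulated reports "the highest
scoring alignment only" without stating one). Alignments containing N
and alignments shorter than 5 bp yield no TSD. If the optimum starts
within 5 bp of the up-flank start or ends within 5 bp of the down-flank
end, the flanks are re-extracted 5 bp wider and detection repeats, at
most 10 times (+50 bp per side); at the bound the current result stands.
Note the null is not empty: two random 60-mers share a clean 5-mer about
90% of the time, so short spurious TSDs are expected and real — the
recovery guarantees are stated for planted repeats on flanks verified
(by a restricted oracle) to contain no chance alignment that ties or
beats them.

**Poly(A).** The search region is the flank beyond the transcript 3'
end (the downstream flank for '+' loci, upstream for '−'), scanned from
its left (reference 5') end; the homopolymer base is A ('+') or T ('−').
A run survives a non-homopolymeric base when >= 4 of the next 5 bases
are homopolymeric; runs are trimmed until they start and end with 3
homopolymeric bases, never extend into the detected TSD footprint, and
must reach 5 bp. Among candidates the one nearest the TSD (by bases
between footprints; nearest the retrocopy when no TSD) is reported.

**Classification.** Lenient categories need >= 5 bp per hallmark.
Strict needs >= 10 bp, and a strict "both" requires fewer than 5 bases
between the TSD and poly(A) footprints; a >= 10 bp pair that is present
but separated is labelled by its TSD (`tsd_only`) — the strict pass is
about confident insertions, and the TSD is the anchoring evidence.
Concordance = both present with separation < 5.

**Cleavage.** The reported 7-mer is the two bases 5' of the TSD plus its
first five bases, read in retrocopy orientation and always reported on
the minus strand: for a '+' locus the upstream copy's forward context is
reverse-complemented; for a '−' locus the downstream copy is read on the
minus strand. The canonical motif appears as `TTTTAA·`.

**Filled vs empty sites.** The two alleles (locus ± 5 kb flanks from two
assemblies) are compared by anchor scanning: small extraction offsets
(<= 50 bp) are absorbed first, then matching prefixes/suffixes are
walked with SNP tolerance (a boundary is declared at the first mismatch
of the first window with >= 3 mismatches in 10 bases). The insertion is
the length difference localised at the left anchor. Rejections follow
the stated rules: insertion < 80 bp; anchor span disagreeing with the
length difference by > 50 bp (structural variation at the site); best
local match of the insertion to the parent cDNA covering <= 75% of the
insertion (Biopython local alignment). The confirmed TSD is the maximal
exact repeat at the insertion boundary, tested at both boundaries
because a target-site repeat makes the placement rotationally ambiguous;
>= 5 bp counts. A chance match of the single base adjacent to the repeat
legitimately lengthens the maximal exact repeat by one — truth
comparisons in tests construct non-extending boundaries where exact
equality is asserted.

## Sharing and rates (`rates`)

**Flank presence.** A flank "maps" when it has a unique best placement
at >= 90% identity over >= 80% of its length (a second placement within
80% of the best score elsewhere makes it ambiguous). Both flanks must
map to one chromosome in consistent orientation with spacing at most
twice the donor span. The target gap between the mapped flanks decides
the state: essentially no gap (<= max(10 bp, 10% of the insert)) is
*absent*; a gap >= 50% of the insert that aligns to the donor insert at
>= 75% identity (edlib global) is *shared*; anything else is
*unresolved*.

**Matrix.** Loci are unified across assemblies by flank anchors into the
top-priority assembly's coordinates (anchors within 100 bp cluster), not
by lifted coordinates; each unified locus is re-sourced from its
highest-priority carrier and tested everywhere; any unresolved cell
discounts the locus from pattern counts. Pairwise unique counts consider
a locus when it is resolved in both assemblies of the comparison,
regardless of its state elsewhere.

**Arithmetic.** generations = ½ · SNPs / (size · μ), rounded to integer
for reporting; rate = mean(unique_a, unique_b) / generations, rounded to
3 significant figures by default (exposed as a parameter — published
tables mix 2 and 3 s.f.); births = round(1 / rounded rate); bounds
re-derive generations at each μ bound (generations fall as μ rises, so
the low-μ bound gives the low rate). Callable size subtracts the
exclusion sets (read-depth duplications, self-alignment duplications,
tandem repeats) from the called regions before SNPs are counted.

**Outgroups.** Both 1 kb flanks must map to one outgroup contig; the
intervening sequence must be >= 75% of the retrocopy length and must map
back over the original donor locus to count as present; flanks mapping
with a short gap give absent; everything else is unresolved.

## Problem sizes

The test suite and the acceptance script run on synthetic genomes of
0.15–2 Mb with 2–10 planted events per class, 500-locus hallmark
panels, 1,000-pair aligner-oracle comparisons, and a 20-replicate
six-assembly cohort — sizes chosen so the full suite completes in well
under a minute per module while every stochastic assertion retains a
>= 3σ margin.

## Known limitations

* The duplication finder is substitution-aware only (no indel chaining);
  it is a stand-in honouring an output contract, not a re-implementation
  of any published caller.
* Hallmark detection inherits the 60 bp flank ceiling: TSD + poly(A)
  combinations longer than the flank, or hallmarks displaced by
  unannotated UTR sequence, are missed.
* Presence assessment assumes collinear flanks; inversions or
  translocations at a locus yield `unresolved`, never a wrong state.
* The insertion-rate estimate inherits the assumptions of the
  calibration: no selection on new insertions, a uniform insertion rate,
  and the external SNV mutation-rate estimate, which dominates the
  quoted uncertainty.
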