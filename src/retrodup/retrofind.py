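"""Retrocopy discovery: representative cDNAs, genome alignment, filter
cascade, and full-ORF classification.

A single transcript represents each gene (longest isoform, then fewest
exons; genes with any intron < 50 bp or a single exon are rejected).  Its
spliced cDNA is aligned to both strands of the assembly with the k-mer
engine (over-represented 11-mers skipped at seeding, the "ooc" analog), and
alignments survive the cascade only when >= 100 bp long, outside the parent
gene's genomic footprint, >= 90% identical (matches / (matches +
mismatches)), and crossing at least one exon-exon junction with aligned
sequence on both sides.  Filtered alignments of one transcript within
100 bp merge into a single (possibly multi-segment) locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome import GeneModel, GenomeAssembly, revcomp
from .kalign import Block, KmerIndex, map_query

JUNCTION_MARGIN = 10  # aligned bases required on each side of a junction


@dataclass
class Transcript:
    """Representative spliced transcript of a gene."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[list[int]]
    spliced: str
    junctions: list[int]
    cds_start: int
    cds_end: int

    @classmethod
    def from_gene(cls, gene: GeneModel, asm: GenomeAssembly) -> "Transcript":
        return cls(
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            exons=[list(e) for e in gene.exons],
            spliced=gene.spliced_sequence(asm),
            junctions=gene.junction_offsets(),
            cds_start=gene.cds_start,
            cds_end=gene.cds_end,
        )

    def footprint(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def intron_lengths(self) -> list[int]:
        return [s2 - e1 for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


def select_transcript(isoforms: list[Transcript]) -> Transcript | None:
    """Pick a gene's representative isoform, or reject the gene.

    Longest spliced sequence wins; ties break toward fewest exons.  The
    chosen isoform is then rejected (None) if it has fewer than two exons or
    any intron shorter than 50 bp.
    """
    if not isoforms:
        return None
    best = sorted(isoforms, key=lambda t: (-len(t.spliced), len(t.exons)))[0]
    if len(best.exons) < 2:
        return None
    if any(ln < 50 for ln in best.intron_lengths()):
        return None
    return best


def align_cdna(
    transcript: Transcript | str,
    index: KmerIndex,
    max_hits: int = 32,
    min_block: int = 30,
) -> list[Block]:
    """Local alignments of a spliced cDNA against both strands of an
    indexed assembly."""
    query = transcript if isinstance(transcript, str) else transcript.spliced
    return map_query(query, index, max_hits=max_hits, min_block=min_block)


def compute_identity(matches, mismatches=None) -> float:
    """Sequence identity = matches / (matches + mismatches); gaps are not
    part of the denominator."""
    if mismatches is None:  # an alignment-like object
        matches, mismatches = matches.matches, matches.mismatches
    denom = matches + mismatches
    if denom <= 0:
        raise ValueError("matches + mismatches must be positive")
    return matches / denom


@dataclass
class RetrocopyCall:
    """A retrocopy locus with its parent transcript annotation."""

    chrom: str
    start: int
    end: int
    strand: str
    parents: tuple[str, ...]
    aligned_length: int
    matches: int
    mismatches: int
    junctions_crossed: int
    segments: int
    blocks: list[Block] = field(default_factory=list, repr=False)
    full_orf: bool | None = None

    @property
    def identity(self) -> float:
        return compute_identity(self.matches, self.mismatches)

    @property
    def parent(self) -> str:
        return self.parents[0]


def _junctions_crossed(block: Block, junctions: list[int]) -> set[int]:
    return {
        j
        for j in junctions
        if block.qstart + JUNCTION_MARGIN <= j <= block.qend - JUNCTION_MARGIN
    }


def call_retrocopies(
    alignments: list[Block],
    transcript: Transcript,
    parent_locus: tuple[str, int, int] | None = None,
    min_len: int = 100,
    min_identity: float = 0.90,
    merge_dist: int = 100,
) -> list[RetrocopyCall]:
    """Apply the retrocopy filter cascade and merge survivors into loci."""
    if parent_locus is None:
        parent_locus = (transcript.chrom, *transcript.footprint())
    pc, ps, pe = parent_locus
    kept = []
    for b in alignments:
        if b.length < min_len:
            continue
        if b.chrom == pc and b.gstart < pe and ps < b.gend:
            continue
        if b.identity < min_identity:
            continue
        if not _junctions_crossed(b, transcript.junctions):
            continue
        kept.append(b)
    kept.sort(key=lambda b: (b.chrom, b.gstart))
    calls: list[RetrocopyCall] = []
    group: list[Block] = []

    def emit(group):
        if not group:
            return
        juncs = set()
        for b in group:
            juncs |= _junctions_crossed(b, transcript.junctions)
        call = RetrocopyCall(
            chrom=group[0].chrom,
            start=min(b.gstart for b in group),
            end=max(b.gend for b in group),
            strand=group[0].strand,
            parents=(transcript.gene_id,),
            aligned_length=sum(b.length for b in group),
            matches=sum(b.matches for b in group),
            mismatches=sum(b.mismatches for b in group),
            junctions_crossed=len(juncs),
            segments=len(group),
            blocks=list(group),
        )
        # hard invariant: a retrocopy call never overlaps its parent locus
        assert not (call.chrom == pc and call.start < pe and ps < call.end)
        calls.append(call)

    for b in kept:
        if group and b.chrom == group[-1].chrom and b.gstart - group[-1].gend <= merge_dist:
            group.append(b)
        else:
            emit(group)
            group = [b]
    emit(group)
    return calls


def check_full_orf(
    call: RetrocopyCall, transcript: Transcript, asm: GenomeAssembly
) -> bool:
    """True iff the locus carries the parental coding region end-to-end with
    the original start codon, no premature stop, and the original stop."""
    cs, ce = transcript.cds_start, transcript.cds_end
    if ce - cs < 6 or (ce - cs) % 3 != 0:
        return False
    covered = sorted((b.qstart, b.qend) for b in call.blocks)
    # the CDS must be contiguously covered by the aligned query ranges
    pos = cs
    for qs, qe in covered:
        if qs <= pos < qe:
            pos = qe
        if pos >= ce:
            break
    if pos < ce:
        return False
    pieces = []
    g = asm.sequences[call.chrom]
    for b in sorted(call.blocks, key=lambda b: b.qstart):
        lo, hi = max(b.qstart, cs), min(b.qend, ce)
        if lo >= hi:
            continue
        if b.strand == "+":
            gs = b.gstart + (lo - b.qstart)
            pieces.append((lo, g[gs:gs + (hi - lo)]))
        else:
            ge = b.gend - (lo - b.qstart)
            pieces.append((lo, revcomp(g[ge - (hi - lo):ge])))
    pieces.sort()
    cds_seq = ""
    end_at = cs
    for lo, seq in pieces:
        if lo < end_at:  # overlapping block; drop the duplicated prefix
            seq = seq[end_at - lo:]
            lo = end_at
        cds_seq += seq
        end_at = lo + len(seq)
    if len(cds_seq) != ce - cs or not cds_seq.startswith("ATG"):
        return False
    prot = str(Seq(cds_seq).translate())
    return "*" not in prot[:-1] and prot.endswith("*")


def find_retrocopies(
    asm: GenomeAssembly,
    genes: list[GeneModel],
    k: int = 11,
    min_len: int = 100,
    min_identity: float = 0.90,
    annotate_orf: bool = True,
) -> list[RetrocopyCall]:
    """End-to-end retrocopy discovery for a gene set on one assembly."""
    index = KmerIndex(asm, k=k)
    calls: list[RetrocopyCall] = []
    for gene in genes:
        tr = select_transcript([Transcript.from_gene(gene, asm)])
        if tr is None:
            continue
        blocks = align_cdna(tr, index)
        found = call_retrocopies(
            blocks, tr, min_len=min_len, min_identity=min_identity
        )
        if annotate_orf:
            for c in found:
                c.full_orf = check_full_orf(c, tr, asm)
        calls.extend(found)
    return mark_unresolved_parents(calls)


def mark_unresolved_parents(calls: list[RetrocopyCall]) -> list[RetrocopyCall]:
    """Merge parent sets of calls from different genes at one locus.

    When paralogous transcripts align equally well to the same locus the
    parent cannot be resolved; such calls keep the union of candidate
    parents, best-identity call retained.
    """
    calls = sorted(calls, key=lambda c: (c.chrom, c.start))
    out: list[RetrocopyCall] = []
    for c in calls:
        if out and c.chrom == out[-1].chrom and c.start < out[-1].end:
            prev = c if c.identity > out[-1].identity else out[-1]
            if abs(c.identity - out[-1].identity) < 1e-9:
                prev.parents = tuple(sorted(set(out[-1].parents) | set(c.parents)))
            out[-1] = prev
        else:
            out.append(c)
    return out
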