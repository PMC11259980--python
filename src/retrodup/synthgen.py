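"""Synthetic genome simulator with planted events and full ground truth.

The simulator builds random assemblies and plants the features the rest of
the pipeline detects: multi-exon protein-coding genes, retrocopy insertions
(target-site duplications, poly(A) tails, LINE-1 endonuclease cleavage
motifs, optional 5' truncation and divergence from the parent cDNA), tandem
and dispersed segmental duplications, sister assemblies diverged by a known
per-generation SNV rate, and read-depth tracks whose expectation scales
with planted copy number.

Coordinates are 0-based half-open throughout.  Retrocopies and duplications
are genuine *insertions*: an :class:`EventRegistry` tracks every planted
feature and shifts masks, gene models and earlier truth records when new
sequence is inserted upstream of them, so recorded truth coordinates always
map exactly onto the emitted FASTA.
"""

from __future__ import annotations

import copy as _copy
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAssembly, PlacementError, revcomp, gc_fraction

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
CANONICAL_CLEAVAGE = "TTTT/AA"


def _resolve_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute each base independently with probability ``divergence``."""
    if divergence <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < divergence)[0]
    lut = {b: [o for o in b"ACGT" if o != b] for b in b"ACGT"}
    for i in hit:
        choices = lut.get(arr[i])
        if choices:
            arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


@dataclass
class TruthRecord:
    """Ground truth for one planted event (retrocopy, duplication or SNP)."""

    kind: str
    chrom: str
    start: int
    end: int
    # retrocopy fields
    parent_gene: str | None = None
    orientation: str | None = None
    tsd_len: int = 0
    tsd_seq: str = ""
    polya_len: int = 0
    truncation: float = 0.0
    divergence: float = 0.0
    cleavage: str | None = None
    body_start: int | None = None
    body_end: int | None = None
    inserted_seq: str = ""
    # duplication fields
    source: list | None = None  # [chrom, start, end]
    copies: list = field(default_factory=list)  # list of [chrom, start, end]
    # snp fields
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self):
        if self.tsd_len < 0 or self.polya_len < 0:
            raise ValueError("tsd_len and polya_len must be >= 0")
        if not (0 <= self.truncation <= 1 and 0 <= self.divergence <= 1):
            raise ValueError("truncation and divergence must be fractions")


class EventRegistry:
    """Tracks planted features on one assembly and propagates coordinate
    shifts caused by insertions."""

    def __init__(self, asm: GenomeAssembly):
        self.asm = asm
        self.occupied: dict[str, list[list[int]]] = defaultdict(list)
        self.genes: list[GeneModel] = []
        self.truths: list[TruthRecord] = []

    # -- placement ---------------------------------------------------------
    def collides(self, chrom: str, start: int, end: int, margin: int = 0) -> bool:
        for s, e in self.occupied.get(chrom, []):
            if start - margin < e and s < end + margin:
                return True
        return False

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append([start, end])

    def in_mask(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.asm.mask.get(chrom, []):
            if start < e and s < end:
                return True
        return False

    def sample_site(
        self,
        rng: np.random.Generator,
        length: int,
        chrom: str | None = None,
        margin: int = 150,
        edge_margin: int = 800,
        max_tries: int = 100,
    ) -> tuple[str, int]:
        """Rejection-sample an insertion/overwrite site clear of prior
        events, the repeat mask and chromosome ends (``edge_margin`` keeps
        room for flank extraction); deterministic failure after
        ``max_tries``."""
        chroms = [chrom] if chrom else self.asm.chroms()
        sizes = np.array([len(self.asm.sequences[c]) for c in chroms], dtype=float)
        lo = max(margin, edge_margin)
        for _ in range(max_tries):
            c = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
            hi = len(self.asm.sequences[c]) - length - lo
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if self.collides(c, pos, pos + length, margin=margin):
                continue
            if self.in_mask(c, pos - margin, pos + length + margin):
                continue
            return c, pos
        raise PlacementError(
            f"no free site of {length} bp found after {max_tries} tries"
        )

    # -- coordinate shifting ----------------------------------------------
    def shift(self, chrom: str, pos: int, length: int) -> None:
        """Shift every registered feature at/after ``pos`` by ``length``."""

        def sh(iv):
            if iv[0] >= pos:
                iv[0] += length
                iv[1] += length

        for iv in self.occupied.get(chrom, []):
            sh(iv)
        for g in self.genes:
            if g.chrom == chrom:
                for ex in g.exons:
                    sh(ex)
        for t in self.truths:
            if t.chrom == chrom:
                if t.start >= pos:
                    t.start += length
                    t.end += length
                    if t.body_start is not None:
                        t.body_start += length
                        t.body_end += length
            if t.source is not None and t.source[0] == chrom and t.source[1] >= pos:
                t.source[1] += length
                t.source[2] += length
            for cp in t.copies:
                if cp[0] == chrom and cp[1] >= pos:
                    cp[1] += length
                    cp[2] += length
        # mask: shift intervals beyond pos; split intervals spanning it
        new_mask = []
        for s, e in self.asm.mask.get(chrom, []):
            if s >= pos:
                new_mask.append((s + length, e + length))
            elif e > pos:
                new_mask.append((s, pos))
                new_mask.append((pos + length, e + length))
            else:
                new_mask.append((s, e))
        if chrom in self.asm.mask:
            self.asm.mask[chrom] = new_mask

    def insert(self, chrom: str, pos: int, seq: str) -> None:
        s = self.asm.sequences[chrom]
        self.asm.sequences[chrom] = s[:pos] + seq + s[pos:]
        self.shift(chrom, pos, len(seq))

    def clone(self) -> "EventRegistry":
        new = EventRegistry(self.asm.copy())
        new.occupied = _copy.deepcopy(self.occupied)
        new.genes = _copy.deepcopy(self.genes)
        new.truths = _copy.deepcopy(self.truths)
        return new


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_genome(
    n_chroms: int,
    chrom_length: int,
    repeat_fraction: float,
    gc: float = 0.5,
    gc_sd: float = 0.08,
    block: int = 10_000,
    seed=None,
    rng=None,
    chrom_prefix: str = "chr",
) -> GenomeAssembly:
    """Random assembly with a planted repeat mask.

    Base composition varies regionally (isochore-like): the genome is built
    in ``block``-bp blocks whose GC is drawn from Normal(``gc``, ``gc_sd``),
    so depth tracks show a realistic GC spread for bias correction to work
    against.  The masked fraction of each chromosome lands within +/-20% of
    ``repeat_fraction`` (exact when 0); output is deterministic per seed.
    """
    if n_chroms < 1 or chrom_length < 10_000:
        raise ValueError("need n_chroms >= 1 and chrom_length >= 10000")
    if not (0 <= repeat_fraction < 1):
        raise ValueError("repeat_fraction must be in [0, 1)")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = _resolve_rng(seed, rng)
    sequences, mask = {}, {}
    for i in range(n_chroms):
        name = f"{chrom_prefix}{i + 1}"
        pieces = []
        done = 0
        while done < chrom_length:
            ln = min(block, chrom_length - done)
            bgc = float(np.clip(rng.normal(gc, gc_sd), 0.2, 0.8)) if gc_sd else gc
            pieces.append(_random_seq(rng, ln, bgc))
            done += ln
        sequences[name] = "".join(pieces)
        target = int(repeat_fraction * chrom_length)
        ivs: list[tuple[int, int]] = []
        covered = 0
        tries = 0
        while covered < target and tries < 10_000:
            tries += 1
            ln = min(int(rng.integers(200, 2001)), target - covered)
            start = int(rng.integers(0, chrom_length - ln))
            if any(start < e and s < start + ln for s, e in ivs):
                continue
            ivs.append((start, start + ln))
            covered += ln
        if ivs:
            mask[name] = sorted(ivs)
    return GenomeAssembly(sequences, mask)


def _orf_sequence(rng: np.random.Generator, length: int) -> tuple[str, int]:
    """Spliced transcript of ``length`` bp whose frame-0 prefix is an intact
    ORF (ATG ... stop, no internal stop).  Returns (sequence, orf_length)."""
    orf_len = 3 * (length // 3)
    n_codons = orf_len // 3
    if n_codons < 3:
        raise ValueError("spliced length too short for an ORF")
    codons = ["ATG"]
    non_stop = [
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in _STOPS
    ]
    for _ in range(n_codons - 2):
        codons.append(non_stop[rng.integers(len(non_stop))])
    codons.append(_STOPS[rng.integers(3)])
    seq = "".join(codons) + _random_seq(rng, length - orf_len)
    return seq, orf_len


def plant_gene(
    asm: GenomeAssembly,
    registry: EventRegistry,
    n_exons: int,
    exon_len: int,
    intron_len: int,
    site: int | None = None,
    chrom: str | None = None,
    strand: str = "+",
    gene_id: str | None = None,
    seed=None,
    rng=None,
) -> GeneModel:
    """Write a multi-exon gene with an intact ORF into the assembly.

    The gene overwrites random background sequence in place (no coordinate
    shifts).  Single-exon genes are rejected: they cannot act as retrocopy
    parents because a retrocopy call must cross an exon-exon junction.
    """
    if n_exons < 2:
        raise ValueError("n_exons must be >= 2 (single-exon parents excluded)")
    if exon_len < 30 or intron_len < 1:
        raise ValueError("exon_len must be >= 30 and intron_len >= 1")
    rng = _resolve_rng(seed, rng)
    span = n_exons * exon_len + (n_exons - 1) * intron_len
    if site is None:
        chrom, site = registry.sample_site(rng, span, chrom=chrom)
    else:
        chrom = chrom or asm.chroms()[0]
        if site + span > len(asm.sequences[chrom]):
            raise PlacementError("gene footprint runs off the chromosome")
        if registry.collides(chrom, site, site + span):
            raise PlacementError("gene footprint collides with a planted event")

    spliced, orf_len = _orf_sequence(rng, n_exons * exon_len)
    exon_seqs = [spliced[i * exon_len:(i + 1) * exon_len] for i in range(n_exons)]
    pieces = []
    for i, ex in enumerate(exon_seqs):
        pieces.append(ex)
        if i < n_exons - 1:
            intron = "GT" + _random_seq(rng, max(0, intron_len - 4)) + "AG"
            pieces.append(intron[:intron_len])
    layout = "".join(pieces)  # transcript orientation
    genomic = layout if strand == "+" else revcomp(layout)
    s = asm.sequences[chrom]
    asm.sequences[chrom] = s[:site] + genomic + s[site + span:]

    # genomic exon intervals, sorted by coordinate
    exons = []
    off = 0
    for i in range(n_exons):
        exons.append([site + off, site + off + exon_len])
        off += exon_len + intron_len
    if strand == "-":
        exons = [[site + span - (e - site), site + span - (s0 - site)]
                 for s0, e in reversed(exons)]
    gene = GeneModel(
        gene_id=gene_id or f"gene{len(registry.genes) + 1}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=0,
        cds_end=orf_len,
    )
    registry.reserve(chrom, site, site + span)
    registry.genes.append(gene)
    return gene


def plant_retrocopy(
    asm: GenomeAssembly,
    registry: EventRegistry,
    gene: GeneModel,
    site: int | None = None,
    chrom: str | None = None,
    orientation: str = "+",
    tsd_len: int = 12,
    polya_len: int = 14,
    truncation: float = 0.0,
    divergence: float = 0.0,
    cleavage: str | None = CANONICAL_CLEAVAGE,
    seed=None,
    rng=None,
) -> TruthRecord:
    """Insert a retrocopy of ``gene`` and record full ground truth.

    Inserted sequence is ``[TSD] + body + [poly(A)] + [TSD]`` where body is
    the (possibly 5'-truncated, point-mutated) spliced cDNA in the requested
    orientation and the poly(A) run follows the transcript 3' end.  When a
    cleavage motif is requested (and tsd_len >= 5) the two bases preceding
    the insertion point plus the first five TSD bases, read per the
    minus-strand reporting convention, spell the canonical LINE-1
    endonuclease site TTTT/AA.
    """
    if tsd_len != 0 and not (5 <= tsd_len <= 50):
        raise ValueError("tsd_len must be 0 or in [5, 50]")
    if polya_len != 0 and not (5 <= polya_len <= 50):
        raise ValueError("polya_len must be 0 or in [5, 50]")
    if orientation not in "+-":
        raise ValueError("orientation must be '+' or '-'")
    rng = _resolve_rng(seed, rng)

    cdna = gene.spliced_sequence(asm)
    trunc_n = int(round(truncation * len(cdna)))
    body_t = _mutate(rng, cdna[trunc_n:], divergence)

    total_len_estimate = 2 * tsd_len + polya_len + len(body_t)
    if site is None:
        chrom, site = registry.sample_site(rng, total_len_estimate)
    else:
        chrom = chrom or gene.chrom
        if registry.collides(chrom, site, site + total_len_estimate, margin=100):
            raise PlacementError("retrocopy site collides with a planted event")

    # Target-site duplication model: the TSD duplicates the sequence already
    # present at the insertion site, so the pre-integration (empty) allele
    # keeps exactly one copy.  The inserted block is [TSD][middle]; the
    # pre-existing target sequence becomes the downstream TSD copy.
    seven = None
    if cleavage and tsd_len >= 5:
        if cleavage != CANONICAL_CLEAVAGE:
            raise ValueError(f"unknown cleavage motif {cleavage!r}")
        extra = _BASES[rng.integers(4)]
        seven = "TTTTAA" + extra
        fwd = revcomp(seven)  # 7 bp of forward-strand context
        s = asm.sequences[chrom]
        if orientation == "+":
            # context = [2 bp before the upstream TSD][its first 5 bases];
            # the upstream copy duplicates the target site, so write the
            # motif into the target site itself
            asm.sequences[chrom] = s[:site - 2] + fwd[:2] + fwd[2:7] + s[site + 5:]
        else:
            # context = [last 5 bases of the downstream TSD][2 bp after]
            e = site + tsd_len
            asm.sequences[chrom] = s[:e - 5] + fwd + s[e + 2:]
    tsd = asm.sequences[chrom][site:site + tsd_len]

    if orientation == "+":
        block = tsd + body_t + "A" * polya_len
        body_rel = (tsd_len, tsd_len + len(body_t))
    else:
        block = tsd + "T" * polya_len + revcomp(body_t)
        body_rel = (tsd_len + polya_len, tsd_len + polya_len + len(body_t))
    total = len(block) + tsd_len  # TSD ... TSD footprint on the genome

    record = TruthRecord(
        kind="retrocopy",
        chrom=chrom,
        start=site,
        end=site + total,
        parent_gene=gene.gene_id,
        orientation=orientation,
        tsd_len=tsd_len,
        tsd_seq=tsd,
        polya_len=polya_len,
        truncation=truncation,
        divergence=divergence,
        cleavage=seven,
        body_start=site + body_rel[0],
        body_end=site + body_rel[1],
        inserted_seq=block + tsd,
    )
    registry.insert(chrom, site, block)
    registry.truths.append(record)
    registry.reserve(chrom, site, site + total)
    return record


def plant_duplication(
    asm: GenomeAssembly,
    registry: EventRegistry,
    source: tuple[str, int, int],
    n_copies: int,
    divergence: float = 0.0,
    placement: str = "dispersed",
    seed=None,
    rng=None,
) -> TruthRecord:
    """Insert ``n_copies`` of a source segment, tandem or dispersed.

    Each copy carries an independent per-base substitution probability of
    ``divergence``.  The truth record lists the (shift-corrected) source and
    every copy interval.
    """
    chrom, start, end = source
    if end - start < 1000:
        raise ValueError("source must be >= 1000 bp (duplication definition floor)")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if placement not in ("tandem", "dispersed"):
        raise ValueError("placement must be 'tandem' or 'dispersed'")
    rng = _resolve_rng(seed, rng)
    record = TruthRecord(
        kind="duplication",
        chrom=chrom,
        start=start,
        end=end,
        divergence=divergence,
        source=[chrom, start, end],
    )
    registry.truths.append(record)
    registry.reserve(chrom, start, end)
    length = end - start
    for _ in range(n_copies):
        src_c, src_s, src_e = record.source
        seq = _mutate(rng, asm.sequences[src_c][src_s:src_e], divergence)
        if placement == "tandem":
            cp_chrom, pos = src_c, src_e
        else:
            cp_chrom, pos = registry.sample_site(rng, length)
        registry.insert(cp_chrom, pos, seq)
        record.copies.append([cp_chrom, pos, pos + length])
        registry.reserve(cp_chrom, pos, pos + length)
    record.start, record.end = record.source[1], record.source[2]
    return record


def diverge_assembly(
    asm: GenomeAssembly,
    registry: EventRegistry,
    generations: int,
    mu: float,
    private_retros: int = 0,
    avoid: list[tuple[str, int, int]] | None = None,
    seed=None,
    rng=None,
) -> tuple[GenomeAssembly, EventRegistry, list[TruthRecord]]:
    """Create a sister assembly separated by ``generations`` generations.

    Two lineages diverging accumulate substitutions at ``2 * mu *
    generations`` per site; SNPs are placed only at unmasked positions
    outside planted events.  ``private_retros`` retrocopy insertions (absent
    from the input assembly) are then planted in the sister.  ``avoid``
    lists additional intervals (input-assembly frame) that private
    insertions must keep clear of — used by cohort simulations so that
    independent insertions in different sisters stay mutually distant, as
    they would on a full-size genome.  Returns the sister assembly, its
    registry, and the list of new truth records (SNPs followed by private
    retrocopies).
    """
    if generations < 0 or mu < 0:
        raise ValueError("generations and mu must be non-negative")
    rng = _resolve_rng(seed, rng)
    sister_reg = registry.clone()
    sister = sister_reg.asm
    for c, s, e in avoid or []:
        sister_reg.reserve(c, s, e)
    new_truths: list[TruthRecord] = []

    p = 2.0 * mu * generations
    if p > 0:
        for chrom in sister.chroms():
            eligible = ~sister.mask_array(chrom)
            for s, e in sister_reg.occupied.get(chrom, []):
                eligible[s:e] = False
            idx = np.nonzero(eligible)[0]
            n = rng.binomial(len(idx), min(p, 1.0))
            if n == 0:
                continue
            picks = rng.choice(idx, size=n, replace=False)
            seq = np.frombuffer(sister.sequences[chrom].encode(), np.uint8).copy()
            for pos in sorted(int(x) for x in picks):
                ref = chr(seq[pos])
                if ref not in _BASES:
                    continue
                alt = _BASES[rng.integers(4)]
                while alt == ref:
                    alt = _BASES[rng.integers(4)]
                seq[pos] = ord(alt)
                rec = TruthRecord(
                    kind="snp", chrom=chrom, start=pos, end=pos + 1,
                    ref=ref, alt=alt,
                )
                sister_reg.truths.append(rec)
                new_truths.append(rec)
            sister.sequences[chrom] = seq.tobytes().decode()

    for _ in range(private_retros):
        gene = sister_reg.genes[rng.integers(len(sister_reg.genes))]
        rec = plant_retrocopy(
            sister,
            sister_reg,
            gene,
            orientation="+-"[rng.integers(2)],
            tsd_len=int(rng.integers(8, 21)),
            polya_len=int(rng.integers(8, 26)),
            truncation=0.0,
            divergence=0.0,
            # no motif forcing: a cleavage site belongs to the target site,
            # which the donor's (empty) allele must share
            cleavage=None,
            rng=rng,
        )
        new_truths.append(rec)
    return sister, sister_reg, new_truths


def simulate_depth(
    asm: GenomeAssembly,
    dups: list[TruthRecord],
    mean_depth: float,
    window_unmasked: int = 1000,
    gc_bias: float = 0.0,
    seed=None,
    rng=None,
) -> pd.DataFrame:
    """Simulate a per-window sequencing depth track.

    Windows each contain ``window_unmasked`` unmasked bases (the last window
    of a chromosome may hold fewer).  The raw depth of a window is Poisson
    with expectation ``mean_depth * (local copy number / 2) * gc
    modulation``; the local (diploid) copy number of a base inside a planted
    duplication family of f total assembly copies is ``2 f``.  Columns:
    chrom, start, end, unmasked, gc, depth.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = _resolve_rng(seed, rng)
    rows = []
    for chrom in asm.chroms():
        seq = asm.sequences[chrom]
        masked = asm.mask_array(chrom)
        mult = np.ones(len(seq))
        for rec in dups:
            if rec.kind != "duplication":
                continue
            fam = [rec.source] + list(rec.copies)
            f = len(fam)
            for c, s, e in fam:
                if c == chrom:
                    mult[s:e] = np.maximum(mult[s:e], f)
        unmasked_idx = np.nonzero(~masked)[0]
        gcarr = np.frombuffer(seq.encode(), np.uint8)
        is_gc = (gcarr == ord("G")) | (gcarr == ord("C"))
        for w0 in range(0, len(unmasked_idx), window_unmasked):
            chunk = unmasked_idx[w0:w0 + window_unmasked]
            if len(chunk) == 0:
                continue
            start, end = int(chunk[0]), int(chunk[-1]) + 1
            gc = float(is_gc[chunk].mean())
            f_local = float(mult[chunk].mean())
            mod = max(0.1, 1.0 + 2.0 * gc_bias * (gc - 0.5))
            lam = mean_depth * f_local * mod
            depth = rng.poisson(lam * len(chunk)) / len(chunk)
            rows.append((chrom, start, end, len(chunk), gc, depth))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "unmasked", "gc", "depth"]
    )
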