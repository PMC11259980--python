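"""Retrotransposition hallmark annotation of retrocopy loci.

Detects the two sequence signatures left by LINE-1 mediated insertion —
target-site duplications (TSDs) and poly(A) tails — plus the endonuclease
cleavage-site context, on symmetric flanks extracted around each locus.

TSDs come from a bespoke local alignment of the upstream versus downstream
flank: +2 per match, -6 per mismatch, -1000 for any column involving N,
and a gap costing 10 to open plus 10 per column.  Alignments shorter than
5 bp are discarded; when the optimum abuts the outer flank edge the flanks
are re-extended by 5 bp (bounded) and detection repeats.  Poly(A) runs are
read from the flank beyond the transcript 3' end (A or T depending on
orientation), extended through isolated interruptions when at least 4 of
the next 5 bases are homopolymeric, trimmed to start and end with 3
consecutive homopolymeric bases, and never extended into the TSD.
Cleavage sites are reported as minus-strand 7-mers: two bases upstream of
the TSD plus its first five bases, in retrocopy orientation (canonically
TTTT/AA).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .genome import GenomeAssembly, revcomp
from .retrofind import RetrocopyCall

MATCH = 2
MISMATCH = -6
N_PENALTY = -1000
GAP_OPEN = 10   # charged once per gap
GAP_EXTEND = 10  # charged per gap column
MIN_HALLMARK = 5
STRICT_MIN = 10
MAX_SEPARATION = 5  # "both" requires separation strictly below this


# ---------------------------------------------------------------------------
# TSD detection
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    score: int
    u_start: int
    u_end: int
    d_start: int
    d_end: int
    u_seq: str
    d_seq: str

    @property
    def length(self) -> int:
        return max(self.u_end - self.u_start, self.d_end - self.d_start)


def _pair_score(a: str, b: str) -> int:
    if a == "N" or b == "N":
        return N_PENALTY
    return MATCH if a == b else MISMATCH


def sw_align(up: str, down: str) -> Alignment | None:
    """Best local alignment of ``up`` vs ``down`` under the TSD matrix.

    Affine gaps: a gap of length g costs GAP_OPEN + g * GAP_EXTEND.  Among
    equal-scoring optima the alignment with the smallest ``up`` start, then
    the smallest ``down`` start, is returned.
    """
    n, m = len(up), len(down)
    if n == 0 or m == 0:
        return None
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap consuming up
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap consuming down
    for i in range(1, n + 1):
        a = up[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - GAP_OPEN - GAP_EXTEND,
                          E[i - 1, j] - GAP_EXTEND)
            F[i, j] = max(H[i, j - 1] - GAP_OPEN - GAP_EXTEND,
                          F[i, j - 1] - GAP_EXTEND)
            diag = H[i - 1, j - 1] + _pair_score(a, down[j - 1])
            H[i, j] = max(0, diag, E[i, j], F[i, j])
    best = int(H.max())
    if best <= 0:
        return None
    ends = np.argwhere(H == best)
    candidates = []
    for i_end, j_end in ends[np.lexsort((ends[:, 1], ends[:, 0]))]:
        i, j = int(i_end), int(j_end)
        state = "H"
        while True:
            if state == "H":
                if H[i, j] == 0:
                    break
                diag = H[i - 1, j - 1] + _pair_score(up[i - 1], down[j - 1])
                if H[i, j] == diag:
                    i, j = i - 1, j - 1
                elif H[i, j] == E[i, j]:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":
                if E[i, j] == H[i - 1, j] - GAP_OPEN - GAP_EXTEND:
                    i, state = i - 1, "H"
                else:
                    i = i - 1
            else:
                if F[i, j] == H[i, j - 1] - GAP_OPEN - GAP_EXTEND:
                    j, state = j - 1, "H"
                else:
                    j = j - 1
        candidates.append((i, j, int(i_end), int(j_end)))
    u_s, d_s, u_e, d_e = min(candidates)
    return Alignment(
        score=best,
        u_start=u_s, u_end=u_e, d_start=d_s, d_end=d_e,
        u_seq=up[u_s:u_e], d_seq=down[d_s:d_e],
    )


@dataclass
class TSD:
    length: int
    seq: str
    u_start: int  # within the up flank used
    u_end: int
    d_start: int  # within the down flank used
    d_end: int
    flank_used: int


def detect_tsd(
    up: str,
    down: str,
    min_len: int = MIN_HALLMARK,
    extend=None,
    max_extensions: int = 10,
) -> TSD | None:
    """Detect a target-site duplication between two flank sequences.

    ``extend(flank_bp)``, when given, must return freshly extracted
    ``(up, down)`` flanks of the requested size; it is invoked when the
    best alignment starts within 5 bp of the up-flank start or ends within
    5 bp of the down-flank end (at most ``max_extensions`` times, +5 bp
    each).  Alignments containing N, or shorter than ``min_len``, yield
    None.
    """
    base = len(up)
    for it in range(max_extensions + 1):
        aln = sw_align(up, down)
        if aln is None:
            return None
        at_edge = aln.u_start < 5 or aln.d_end > len(down) - 5
        if at_edge and extend is not None and it < max_extensions:
            up, down = extend(base + 5 * (it + 1))
            continue
        if "N" in aln.u_seq or "N" in aln.d_seq:
            return None
        if aln.length < min_len:
            return None
        return TSD(
            length=aln.length,
            seq=aln.u_seq,
            u_start=aln.u_start, u_end=aln.u_end,
            d_start=aln.d_start, d_end=aln.d_end,
            flank_used=len(up),
        )
    return None


# ---------------------------------------------------------------------------
# poly(A) detection
# ---------------------------------------------------------------------------

@dataclass
class PolyA:
    length: int
    start: int  # within the searched region
    end: int


def _polya_runs(region: str, base: str) -> list[tuple[int, int]]:
    """All candidate homopolymer runs under the termination/trim rules."""
    runs = []
    i = 0
    n = len(region)
    while i < n:
        if region[i] != base:
            i += 1
            continue
        j = i
        while j < n:
            if region[j] == base:
                j += 1
                continue
            # non-homopolymeric base: continue only if >= 4 of next 5 match
            nxt = region[j + 1:j + 6]
            if len(nxt) == 5 and sum(c == base for c in nxt) >= 4:
                j += 1
                continue
            break
        s, e = i, j
        # trim to start and end with 3 homopolymeric bases in a row
        while e - s >= 3 and region[s:s + 3] != base * 3:
            s += 1
        while e - s >= 3 and region[e - 3:e] != base * 3:
            e -= 1
        if e - s >= 3:
            runs.append((s, e))
        i = j + 1
    return runs


def detect_polya(
    region: str,
    orientation: str,
    tsd_span: tuple[int, int] | None = None,
    min_len: int = MIN_HALLMARK,
    retro_side: str = "left",
) -> PolyA | None:
    """Detect a poly(A) tail in the flank beyond the retrocopy 3' end.

    The scan reads the reference region left to right regardless of
    orientation; the homopolymer base is A for '+' retrocopies and T for
    '-'.  ``tsd_span`` is the TSD footprint within the region (runs are
    clipped so they never extend into it) and candidate selection prefers
    the run closest to the TSD, falling back to the run closest to the
    retrocopy (``retro_side``: which edge of the region abuts it).
    """
    base = "A" if orientation == "+" else "T"
    candidates = []
    for s, e in _polya_runs(region, base):
        if tsd_span is not None:
            ts, te = tsd_span
            if s < te and ts < e:  # clip out of the TSD footprint
                if s < ts:
                    e = min(e, ts)
                else:
                    s = max(s, te)
            if e - s < 3:
                continue
            # re-trim after clipping
            while e - s >= 3 and region[s:s + 3] != base * 3:
                s += 1
            while e - s >= 3 and region[e - 3:e] != base * 3:
                e -= 1
        if e - s >= min_len:
            candidates.append((s, e))
    if not candidates:
        return None
    if tsd_span is not None:
        ts, te = tsd_span

        def dist(run):
            s, e = run
            if e <= ts:
                return ts - e
            if s >= te:
                return s - te
            return 0
    else:
        def dist(run):
            s, e = run
            return s if retro_side == "left" else len(region) - e

    s, e = min(candidates, key=dist)
    return PolyA(length=e - s, start=s, end=e)


# ---------------------------------------------------------------------------
# locus preparation and annotation
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    locus_id: str
    chrom: str
    start: int
    end: int
    orientation: str
    up: str
    down: str
    flank: int
    call: RetrocopyCall | None = None


def prepare_loci(
    calls: list[RetrocopyCall],
    asm: GenomeAssembly,
    flank: int = 60,
    gap_margin: int = 100,
) -> list[Locus]:
    """Extract symmetric flanks for hallmark detection.

    Loci within 100 bp of an N-gap or a chromosome end, and loci composed
    of multiple alignment segments, are excluded.
    """
    loci = []
    for i, c in enumerate(calls):
        seq = asm.sequences[c.chrom]
        if c.segments > 1:
            continue
        if c.start < gap_margin or c.end > len(seq) - gap_margin:
            continue
        if "N" in seq[c.start - gap_margin:c.end + gap_margin]:
            continue
        loci.append(
            Locus(
                locus_id=f"{c.chrom}:{c.start}-{c.end}",
                chrom=c.chrom,
                start=c.start,
                end=c.end,
                orientation=c.strand,
                up=seq[c.start - flank:c.start],
                down=seq[c.end:c.end + flank],
                flank=flank,
                call=c,
            )
        )
    return loci


def classify(
    tsd_len: int,
    polya_len: int,
    separation: int | None,
    strict_min: int = STRICT_MIN,
) -> tuple[str, str, bool]:
    """(category, strict category, concordant flag) from hallmark lengths.

    Lenient categories need >= 5 bp.  Strict hallmarks need >= 10 bp and a
    strict "both" additionally requires TSD and poly(A) separated by fewer
    than 5 bases; a strict pair that is present but separated is labelled
    by its TSD.  Concordance = both present and separation < 5.
    """
    has_tsd = tsd_len >= MIN_HALLMARK
    has_pa = polya_len >= MIN_HALLMARK

    def cat(t, p, need_adjacent):
        if t and p:
            if need_adjacent and (separation is None or separation >= MAX_SEPARATION):
                return "tsd_only"
            return "both"
        if t:
            return "tsd_only"
        if p:
            return "polya_only"
        return "neither"

    category = cat(has_tsd, has_pa, need_adjacent=False)
    strict = cat(tsd_len >= strict_min, polya_len >= strict_min, need_adjacent=True)
    concordant = bool(
        has_tsd and has_pa and separation is not None
        and separation < MAX_SEPARATION
    )
    return category, strict, concordant


@dataclass
class HallmarkAnnotation:
    locus_id: str
    chrom: str
    start: int
    end: int
    orientation: str
    tsd_len: int
    tsd_seq: str
    tsd_up: tuple[int, int] | None   # genomic footprint of the upstream copy
    tsd_down: tuple[int, int] | None
    polya_len: int
    polya_span: tuple[int, int] | None  # genomic footprint
    separation: int | None
    category: str
    strict_category: str
    concordant: bool
    cleavage: str | None


def cleavage_site(
    asm: GenomeAssembly,
    chrom: str,
    orientation: str,
    tsd_up: tuple[int, int] | None,
    tsd_down: tuple[int, int] | None,
) -> str:
    """Minus-strand 7-mer around the endonuclease nick: two bases before
    the TSD plus its first five bases, in retrocopy orientation."""
    seq = asm.sequences[chrom]
    if orientation == "+":
        if tsd_up is None:
            raise ValueError("cleavage site requires a detected TSD")
        s = tsd_up[0]
        return revcomp(seq[s - 2:s + 5])
    if tsd_down is None:
        raise ValueError("cleavage site requires a detected TSD")
    e = tsd_down[1]
    return revcomp(seq[e - 5:e + 2])


def annotate_locus(locus: Locus, asm: GenomeAssembly) -> HallmarkAnnotation:
    """Run TSD, poly(A), cleavage and classification on one prepared locus."""
    seq = asm.sequences[locus.chrom]

    def extend(fl):
        return (
            seq[max(0, locus.start - fl):locus.start],
            seq[locus.end:locus.end + fl],
        )

    tsd = detect_tsd(locus.up, locus.down, extend=extend)
    tsd_up = tsd_down = None
    if tsd is not None:
        up_off = locus.start - tsd.flank_used
        tsd_up = (up_off + tsd.u_start, up_off + tsd.u_end)
        tsd_down = (locus.end + tsd.d_start, locus.end + tsd.d_end)

    if locus.orientation == "+":
        region_start = locus.end
        region = seq[region_start:region_start + locus.flank]
        tsd_span = (
            (tsd_down[0] - region_start, tsd_down[1] - region_start)
            if tsd_down else None
        )
        retro_side = "left"
    else:
        region_start = max(0, locus.start - locus.flank)
        region = seq[region_start:locus.start]
        tsd_span = (
            (tsd_up[0] - region_start, tsd_up[1] - region_start)
            if tsd_up else None
        )
        retro_side = "right"
    pa = detect_polya(region, locus.orientation, tsd_span, retro_side=retro_side)
    polya_span = (region_start + pa.start, region_start + pa.end) if pa else None

    separation = None
    if tsd is not None and pa is not None:
        anchor = tsd_down if locus.orientation == "+" else tsd_up
        if polya_span[1] <= anchor[0]:
            separation = anchor[0] - polya_span[1]
        elif polya_span[0] >= anchor[1]:
            separation = polya_span[0] - anchor[1]
        else:
            separation = 0

    category, strict, concordant = classify(
        tsd.length if tsd else 0, pa.length if pa else 0, separation
    )
    cleav = None
    if tsd is not None:
        cleav = cleavage_site(
            asm, locus.chrom, locus.orientation, tsd_up, tsd_down
        )
    return HallmarkAnnotation(
        locus_id=locus.locus_id,
        chrom=locus.chrom,
        start=locus.start,
        end=locus.end,
        orientation=locus.orientation,
        tsd_len=tsd.length if tsd else 0,
        tsd_seq=tsd.seq if tsd else "",
        tsd_up=tsd_up,
        tsd_down=tsd_down,
        polya_len=pa.length if pa else 0,
        polya_span=polya_span,
        separation=separation,
        category=category,
        strict_category=strict,
        concordant=concordant,
        cleavage=cleav,
    )


def annotate_retrocopies(
    calls: list[RetrocopyCall], asm: GenomeAssembly, flank: int = 60
) -> list[HallmarkAnnotation]:
    return [annotate_locus(l, asm) for l in prepare_loci(calls, asm, flank=flank)]


def annotations_to_frame(anns: list[HallmarkAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": a.locus_id,
            "chrom": a.chrom,
            "start": a.start,
            "end": a.end,
            "orientation": a.orientation,
            "tsd_len": a.tsd_len,
            "tsd_seq": a.tsd_seq,
            "polya_len": a.polya_len,
            "separation": a.separation,
            "category": a.category,
            "strict_category": a.strict_category,
            "concordant": a.concordant,
            "cleavage_7mer": a.cleavage,
        }
        for a in anns
    )


# ---------------------------------------------------------------------------
# cleavage profile
# ---------------------------------------------------------------------------

def cleavage_profile(sites: list[str]) -> dict[str, pd.DataFrame]:
    """Position frequency matrix over equal-length cleavage k-mers.

    Returns ``{"counts": DataFrame, "freqs": DataFrame}`` with positions as
    rows and A/C/G/T as columns; frequencies sum to 1 per position.
    """
    if not sites:
        raise ValueError("no cleavage sites given")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("cleavage sites must all have the same length")
    counts = pd.DataFrame(0, index=range(L), columns=list("ACGT"))
    for s in sites:
        for i, b in enumerate(s):
            if b in "ACGT":
                counts.loc[i, b] += 1
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.replace(0, 1), axis=0)
    return {"counts": counts, "freqs": freqs}


# ---------------------------------------------------------------------------
# filled vs empty site confirmation
# ---------------------------------------------------------------------------

@dataclass
class EmptySiteResult:
    status: str  # confirmed | rejected | unresolved
    reason: str | None = None
    insertion: tuple[int, int] | None = None  # within the filled sequence
    tsd_len: int = 0
    tsd_seq: str = ""
    cleavage: str | None = None


def _anchor_boundary(a: str, b: str, window: int = 10, dense: int = 3) -> int:
    """Length of the matching prefix of ``a`` vs ``b``, tolerating sparse
    substitutions (SNPs): the prefix ends at the first mismatch of the
    first window holding >= ``dense`` mismatches in ``window`` bases."""
    n = min(len(a), len(b))
    mm = [i for i in range(n) if a[i] != b[i]]
    for ix in range(len(mm) - dense + 1):
        if mm[ix + dense - 1] - mm[ix] < window:
            return mm[ix]
    return n


def _best_offset(a: str, b: str, span: int = 300, max_off: int = 50) -> int:
    """Small relative offset o minimizing mismatches of a[...] vs b[o + ...];
    lets the comparator tolerate imprecise flank extraction."""
    best_o, best_mm = 0, float("inf")
    for o in range(-max_off, max_off + 1):
        a0, b0 = max(0, -o), max(0, o)
        s = min(span, len(a) - a0, len(b) - b0)
        if s < 50:
            continue
        mm = sum(a[a0 + i] != b[b0 + i] for i in range(s))
        if mm < best_mm:
            best_mm, best_o = mm, o
    return best_o


def confirm_at_empty_site(
    filled: str,
    empty: str,
    cdna: str,
    orientation: str = "+",
    min_insertion: int = 80,
    min_cdna_cover: float = 0.75,
    max_other_sv: int = 50,
    max_tsd: int = 60,
    min_anchor: int = 50,
) -> EmptySiteResult:
    """Confirm a retrocopy TSD by comparing filled and empty alleles.

    The filled and empty sequences (the same locus extracted with flanks
    from two assemblies, one lacking the insertion) are anchored from both
    ends to localize the insertion.  Rejected when the insertion is shorter
    than ``min_insertion``, when its best local match to the parent cDNA
    covers <= ``min_cdna_cover`` of its length, or when the two anchors
    disagree with the length difference by more than ``max_other_sv``
    (structural variation on both sides of the site).  The confirmed TSD is
    the maximal exact repeat at the insertion boundary (>= 5 bp to count),
    reported with its minus-strand cleavage 7-mer.
    """
    # tolerate imprecise extraction: trim small leading/trailing offsets
    o_pre = _best_offset(filled, empty)
    f0, e0 = max(0, -o_pre), max(0, o_pre)
    o_suf = _best_offset(filled[::-1], empty[::-1])
    f1 = len(filled) - max(0, -o_suf)
    e1 = len(empty) - max(0, o_suf)
    filled_t, empty_t = filled[f0:f1], empty[e0:e1]
    delta = len(filled_t) - len(empty_t)
    left = _anchor_boundary(filled_t, empty_t)
    right = _anchor_boundary(filled_t[::-1], empty_t[::-1])
    if left < min_anchor or right < min_anchor:
        return EmptySiteResult("unresolved", "flanks fail to anchor")
    if delta < min_insertion:
        return EmptySiteResult("rejected", "insertion below size floor")
    span = (len(filled_t) - right) - left
    if abs(span - delta) > max_other_sv:
        return EmptySiteResult("rejected", "structural variation at the site")
    ins_s, ins_e = f0 + left, f0 + left + delta
    insertion = filled[ins_s:ins_e]
    if _local_cover(insertion, cdna) <= min_cdna_cover:
        return EmptySiteResult("rejected", "insertion does not match cDNA")
    # maximal exact repeat at the insertion boundary; a target-site repeat
    # makes the placement rotationally ambiguous, so test both boundaries
    left_k = 0
    while (
        left_k < max_tsd
        and ins_s - left_k - 1 >= 0
        and filled[ins_s - left_k - 1] == filled[ins_e - left_k - 1]
    ):
        left_k += 1
    right_k = 0
    while (
        right_k < max_tsd
        and ins_e + right_k < len(filled)
        and filled[ins_s + right_k] == filled[ins_e + right_k]
    ):
        right_k += 1
    if max(left_k, right_k) < MIN_HALLMARK:
        return EmptySiteResult(
            "confirmed", "no boundary TSD", (ins_s, ins_e), 0, ""
        )
    if right_k >= left_k:
        k = right_k
        tsd_up = (ins_s, ins_s + k)
        tsd_down = (ins_e, ins_e + k)
    else:
        k = left_k
        tsd_up = (ins_s - k, ins_s)
        tsd_down = (ins_e - k, ins_e)
    if orientation == "+":
        s = tsd_up[0]
        seven = revcomp(filled[s - 2:s + 5])
    else:
        e = tsd_down[1]
        seven = revcomp(filled[e - 5:e + 2])
    return EmptySiteResult(
        "confirmed", None, (ins_s, ins_e), k, filled[tsd_up[0]:tsd_up[1]], seven
    )


def _local_cover(insertion: str, cdna: str) -> float:
    """Fraction of the insertion covered by its best local match to the
    cDNA (either orientation)."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-3,
        extend_gap_score=-1,
    )
    best = 0
    for target in (cdna, revcomp(cdna)):
        alns = aligner.align(insertion, target)
        if len(alns) == 0:
            continue
        aln = alns[0]
        qspan = aln.aligned[0]
        if len(qspan):
            best = max(best, int(qspan[-1][1] - qspan[0][0]))
    return best / len(insertion)
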