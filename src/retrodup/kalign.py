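"""Internal k-mer seed-and-extend alignment engine.

This is the package's stand-in for the external aligners a production
pipeline would call (a self-alignment duplication finder, a cDNA-to-genome
mapper, a flank mapper).  It honors their output contracts — maximal
gapless local alignments with match/mismatch accounting — rather than
reproducing any particular tool's internals.  Because the synthetic
substrate carries substitutions but no indels, alignments live on single
diagonals: seeds are exact k-mer matches grouped by diagonal, merged into
runs, and extended with an X-drop scan.

The genome is indexed once per assembly (:class:`KmerIndex`); queries are
then mapped against both strands.  Over-represented k-mers (the 11-mer
"ooc" analog) are skipped at seeding time.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .genome import GenomeAssembly, revcomp

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[ord(chr(_b).lower())] = _i


def _codes(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(values, valid) for every k-mer start; valid is False where the
    window contains a non-ACGT base."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        vals |= codes[j:j + n].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
    bad = (codes == 255).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return vals, valid


@dataclass
class Block:
    """One gapless local alignment block.

    For strand '-', ``genome[gstart:gend]`` matches
    ``revcomp(query[qstart:qend])``; query coordinates are always in the
    original query orientation.
    """

    chrom: str
    strand: str
    gstart: int
    gend: int
    qstart: int
    qend: int
    matches: int
    mismatches: int

    @property
    def length(self) -> int:
        return self.qend - self.qstart

    @property
    def identity(self) -> float:
        return self.matches / (self.matches + self.mismatches)


class KmerIndex:
    """Sorted k-mer table over every chromosome of an assembly."""

    def __init__(self, asm: GenomeAssembly, k: int = 13, respect_mask: bool = False):
        if not asm.sequences or all(len(s) == 0 for s in asm.sequences.values()):
            raise ValueError("cannot index an empty assembly")
        self.asm = asm
        self.k = k
        self.chrom_names = list(asm.sequences)
        vals_all, chrom_all, pos_all = [], [], []
        for ci, chrom in enumerate(self.chrom_names):
            seq = asm.sequences[chrom]
            codes = _codes(seq)
            vals, valid = _kmer_values(codes, k)
            if respect_mask and chrom in asm.mask and len(valid):
                m = asm.mask_array(chrom).astype(np.int32)
                cs = np.concatenate([[0], np.cumsum(m)])
                valid &= (cs[k:] - cs[:-k]) == 0
            idx = np.nonzero(valid)[0]
            vals_all.append(vals[idx])
            chrom_all.append(np.full(len(idx), ci, dtype=np.int32))
            pos_all.append(idx.astype(np.int64))
        vals = np.concatenate(vals_all)
        order = np.argsort(vals, kind="stable")
        self.vals = vals[order]
        self.chrom_idx = np.concatenate(chrom_all)[order]
        self.pos = np.concatenate(pos_all)[order]

    def lookup(self, value: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.vals, value, side="left")
        hi = np.searchsorted(self.vals, value, side="right")
        return self.chrom_idx[lo:hi], self.pos[lo:hi]


def _group_runs(sorted_vals: list[int], max_gap: int) -> list[tuple[int, int]]:
    runs = []
    start = prev = sorted_vals[0]
    for v in sorted_vals[1:]:
        if v - prev > max_gap:
            runs.append((start, prev))
            start = v
        prev = v
    runs.append((start, prev))
    return runs


def _extend_xdrop(q: str, g: str, qs: int, qe: int, gs: int, ge: int,
                  xdrop: int = 12) -> tuple[int, int, int, int]:
    """Extend a diagonal interval in both directions (match +1, mismatch -3),
    keeping the best-scoring endpoints."""
    # right
    score = best = 0
    best_off = 0
    off = 0
    while qe + off < len(q) and ge + off < len(g):
        score += 1 if q[qe + off] == g[ge + off] else -3
        off += 1
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    qe += best_off
    ge += best_off
    # left
    score = best = 0
    best_off = 0
    off = 0
    while qs - off > 0 and gs - off > 0:
        off += 1
        score += 1 if q[qs - off] == g[gs - off] else -3
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    qs -= best_off
    gs -= best_off
    return qs, qe, gs, ge


def _count_matches(q: str, g: str, qs: int, qe: int, gs: int) -> tuple[int, int]:
    qa = np.frombuffer(q[qs:qe].encode(), np.uint8)
    ga = np.frombuffer(g[gs:gs + (qe - qs)].encode(), np.uint8)
    m = int((qa == ga).sum())
    return m, len(qa) - m


def map_query(
    query: str,
    index: KmerIndex,
    max_hits: int = 32,
    max_gap: int = 120,
    min_block: int = 30,
    xdrop: int = 12,
    both_strands: bool = True,
) -> list[Block]:
    """Map a query against an indexed assembly; returns gapless blocks on
    both strands, each with match/mismatch counts."""
    k = index.k
    blocks: list[Block] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        codes = _codes(q)
        vals, valid = _kmer_values(codes, k)
        buckets: dict[tuple[int, int], list[int]] = defaultdict(list)
        for qp in np.nonzero(valid)[0]:
            cis, gps = index.lookup(vals[qp])
            if len(gps) == 0 or len(gps) > max_hits:
                continue
            for ci, gp in zip(cis, gps):
                buckets[(int(ci), int(gp) - int(qp))].append(int(qp))
        for (ci, diag), qps in buckets.items():
            chrom = index.chrom_names[ci]
            g = index.asm.sequences[chrom]
            for r0, r1 in _group_runs(sorted(set(qps)), max_gap):
                qs, qe = r0, r1 + k
                qs, qe, gs, ge = _extend_xdrop(q, g, qs, qe, qs + diag, qe + diag, xdrop)
                if qe - qs < min_block:
                    continue
                m, mm = _count_matches(q, g, qs, qe, gs)
                if strand == "+":
                    blocks.append(Block(chrom, "+", gs, ge, qs, qe, m, mm))
                else:
                    L = len(query)
                    blocks.append(
                        Block(chrom, "-", gs, ge, L - qe, L - qs, m, mm)
                    )
    return _dedup_blocks(blocks)


def _dedup_blocks(blocks: list[Block]) -> list[Block]:
    seen = set()
    out = []
    for b in sorted(blocks, key=lambda b: (b.chrom, b.gstart, b.gend, b.strand)):
        key = (b.chrom, b.strand, b.gstart, b.gend, b.qstart, b.qend)
        if key not in seen:
            seen.add(key)
            out.append(b)
    return out


def self_pairs(
    asm: GenomeAssembly,
    k: int = 21,
    max_family: int = 64,
    max_gap: int = 600,
    xdrop: int = 15,
    min_len: int = 1000,
) -> list[tuple[str, int, int, str, int, int, int, int]]:
    """Forward-strand self-alignment of an assembly.

    Seeds are exact k-mers occurring 2..``max_family`` times outside the
    repeat mask; hit pairs are grouped per (chromA, chromB, diagonal),
    merged into runs, X-drop extended, and returned as
    ``(chromA, startA, endA, chromB, startB, endB, matches, mismatches)``
    with A lexicographically <= B.  Pure self-hits (zero diagonal) are
    dropped.
    """
    index = KmerIndex(asm, k=k, respect_mask=True)
    vals = index.vals
    # group boundaries of equal k-mer values in the sorted table
    if len(vals) == 0:
        return []
    starts = np.nonzero(np.concatenate([[True], vals[1:] != vals[:-1]]))[0]
    ends = np.concatenate([starts[1:], [len(vals)]])
    counts = ends - starts
    keep = np.nonzero((counts >= 2) & (counts <= max_family))[0]
    buckets: dict[tuple[int, int, int], list[int]] = defaultdict(list)
    for gi in keep:
        s, e = int(starts[gi]), int(ends[gi])
        cis = index.chrom_idx[s:e]
        gps = index.pos[s:e]
        order = np.lexsort((gps, cis))
        cis, gps = cis[order], gps[order]
        for i in range(len(gps)):
            for j in range(i + 1, len(gps)):
                ca, pa = int(cis[i]), int(gps[i])
                cb, pb = int(cis[j]), int(gps[j])
                if ca == cb and pa == pb:
                    continue
                buckets[(ca, cb, pb - pa)].append(pa)
    raw = []
    for (ca, cb, diag), pas in buckets.items():
        ga = index.asm.sequences[index.chrom_names[ca]]
        gb = index.asm.sequences[index.chrom_names[cb]]
        for r0, r1 in _group_runs(sorted(set(pas)), max_gap):
            a_s, a_e = r0, r1 + index.k
            a_s, a_e, b_s, b_e = _extend_xdrop(
                ga, gb, a_s, a_e, a_s + diag, a_e + diag, xdrop
            )
            if a_e - a_s < min_len:
                continue
            m, mm = _count_matches(ga, gb, a_s, a_e, b_s)
            raw.append(
                (index.chrom_names[ca], a_s, a_e,
                 index.chrom_names[cb], b_s, b_e, m, mm)
            )
    return raw
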