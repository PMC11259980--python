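"""Self-alignment duplication discovery and post-processing.

Discovers pairwise segmental duplications in a single assembly (>= 1 kb,
>= 90% identity, seeds barred from the repeat mask, mitochondrial pairs
removed), merges the pair projections into a nonredundant interval set,
detects short high-recurrence segments (>= 4 sub-2.5 kb duplications after
rounding endpoints to the nearest hundred), tests enrichment at chromosome
edges by permutation, and compares self-alignment calls against read-depth
duplicated regions.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .genome import GenomeAssembly
from .kalign import self_pairs


@dataclass(frozen=True)
class PairwiseDuplication:
    """Two genomic intervals with percent identity; A lexicographically <= B."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    identity: float
    length: int

    def __post_init__(self):
        if (self.chrom_a, self.start_a, self.end_a) > (
            self.chrom_b, self.start_b, self.end_b
        ):
            raise ValueError("pair must be stored with A <= B")

    @classmethod
    def make(cls, ca, sa, ea, cb, sb, eb, identity):
        a, b = (ca, sa, ea), (cb, sb, eb)
        if b < a:
            a, b = b, a
        return cls(*a, *b, identity=identity, length=max(ea - sa, eb - sb))

    def projections(self):
        yield (self.chrom_a, self.start_a, self.end_a)
        yield (self.chrom_b, self.start_b, self.end_b)


def find_pairwise_duplications(
    asm: GenomeAssembly,
    min_len: int = 1000,
    min_identity: float = 0.90,
    k: int = 21,
    mito: str = "chrM",
) -> list[PairwiseDuplication]:
    """Self-align an assembly and report pairwise duplications.

    Identity is matches / aligned columns (gapless alignments, so gaps never
    enter the denominator).  Pairs touching the mitochondrial sequence are
    removed; seeds never initiate inside the repeat mask.
    """
    raw = self_pairs(asm, k=k, min_len=min_len)
    # merge overlapping runs on the same diagonal (sub-runs whose extensions
    # bridged) before filtering
    by_diag: dict[tuple, list] = defaultdict(list)
    for ca, sa, ea, cb, sb, eb, m, mm in raw:
        by_diag[(ca, cb, sb - sa)].append((sa, ea, m, mm))
    pairs = []
    seen = set()
    for (ca, cb, diag), entries in by_diag.items():
        if mito in (ca, cb):
            continue
        entries.sort()
        merged = [list(entries[0])]
        for sa, ea, m, mm in entries[1:]:
            if sa <= merged[-1][1]:
                if ea > merged[-1][1]:
                    frac = (ea - merged[-1][1]) / (ea - sa)
                    merged[-1][2] += int(m * frac)
                    merged[-1][3] += int(mm * frac)
                    merged[-1][1] = ea
            else:
                merged.append([sa, ea, m, mm])
        for sa, ea, m, mm in merged:
            length = ea - sa
            if length < min_len or m + mm == 0:
                continue
            identity = m / (m + mm)
            if identity < min_identity:
                continue
            pair = PairwiseDuplication.make(
                ca, sa, ea, cb, sa + diag, ea + diag, identity
            )
            key = (pair.chrom_a, pair.start_a, pair.end_a,
                   pair.chrom_b, pair.start_b, pair.end_b)
            if key not in seen:
                seen.add(key)
                pairs.append(pair)
    return sorted(
        pairs, key=lambda p: (p.chrom_a, p.start_a, p.chrom_b, p.start_b)
    )


def default_partition(chrom: str) -> str:
    """Assembled-vs-unplaced classifier: unplaced names carry 'Un', 'scaffold'
    or 'contig'; everything else counts as assembled."""
    low = chrom.lower()
    if "un" in low.removeprefix("chr") or "scaffold" in low or "contig" in low:
        return "unplaced"
    return "assembled"


def merge_duplicated_intervals(
    dups: list[PairwiseDuplication],
    chrom_partition=default_partition,
) -> dict[str, dict]:
    """Project every pair end and merge into a nonredundant interval set.

    Returns, per partition, ``{"intervals": {chrom: [(s, e), ...]},
    "total_bp": int}``.  Overlapping and book-ended intervals merge
    (BEDTools-merge semantics).
    """
    by_part: dict[str, dict] = defaultdict(lambda: defaultdict(list))
    for p in dups:
        for chrom, s, e in p.projections():
            by_part[chrom_partition(chrom)][chrom].append((s, e))
    out = {}
    for part, by_chrom in by_part.items():
        merged = iv.merge_dict(by_chrom)
        out[part] = {"intervals": merged, "total_bp": iv.total_bp_dict(merged)}
    return out


def round_to_hundred(x: int) -> int:
    """Nearest-hundred rounding, half away from zero (2,349->2,300;
    3,175->3,200)."""
    return int((x + 50) // 100) * 100


@dataclass
class HighRecurrenceSegment:
    chrom: str
    start: int
    end: int
    count: int


def detect_high_recurrence(
    dups: list[PairwiseDuplication],
    max_len: int = 2500,
    min_count: int = 4,
) -> list[HighRecurrenceSegment]:
    """Short segments hit by many distinct duplication alignments.

    Duplications >= ``max_len`` are discarded; projected intervals have both
    endpoints rounded to the nearest hundred, are merged into segments, and
    each segment counts the distinct pairwise records whose rounded
    projection overlaps it (a pair with both ends in one segment counts
    once).  Only segments with count >= ``min_count`` are returned.
    """
    rounded = []  # (chrom, start, end, pair_index)
    for i, p in enumerate(dups):
        if p.length >= max_len:
            continue
        for chrom, s, e in p.projections():
            rs, re = round_to_hundred(s), round_to_hundred(e)
            if re <= rs:
                re = rs + 100
            rounded.append((chrom, rs, re, i))
    by_chrom: dict[str, list] = defaultdict(list)
    for chrom, s, e, i in rounded:
        by_chrom[chrom].append((s, e, i))
    segments = []
    for chrom, entries in by_chrom.items():
        merged = iv.merge([(s, e) for s, e, _ in entries])
        for ms, me in merged:
            members = {i for s, e, i in entries if s < me and ms < e}
            if len(members) >= min_count:
                segments.append(HighRecurrenceSegment(chrom, ms, me, len(members)))
    return sorted(segments, key=lambda s: (s.chrom, s.start))


def edge_enrichment(
    intervals_by_chrom: dict,
    chrom_sizes: dict,
    edge: int = 1_000_000,
    n_perm: int = 1000,
    seed=None,
) -> dict:
    """Fold enrichment of intervals in the first/last ``edge`` bp of each
    chromosome versus uniform within-chromosome permutations.

    Permutations re-place each interval uniformly within its own chromosome,
    preserving lengths; ``fold = observed fraction / permutation mean``.
    """
    rng = np.random.default_rng(seed)
    usable = {}
    for chrom, size in chrom_sizes.items():
        if size < 2 * edge:
            warnings.warn(f"{chrom} shorter than 2x edge; skipped")
            continue
        usable[chrom] = size
    items = [
        (chrom, s, e)
        for chrom, ivs in intervals_by_chrom.items()
        if chrom in usable
        for s, e in ivs
    ]
    n = len(items)
    if n == 0:
        raise ValueError("no intervals on usable chromosomes")

    def frac(pos_list):
        first = sum(
            1 for chrom, s, e in pos_list if s < edge
        )
        last = sum(
            1 for chrom, s, e in pos_list if e > usable[chrom] - edge
        )
        return first / n, last / n

    obs_first, obs_last = frac(items)
    perm_first = np.empty(n_perm)
    perm_last = np.empty(n_perm)
    for i in range(n_perm):
        placed = []
        for chrom, s, e in items:
            ln = e - s
            hi = usable[chrom] - ln
            ns = int(rng.integers(0, max(1, hi)))
            placed.append((chrom, ns, ns + ln))
        perm_first[i], perm_last[i] = frac(placed)

    def report(obs, perm):
        mean = float(perm.mean())
        return {
            "observed": obs,
            "perm_mean": mean,
            "perm_max": float(perm.max()),
            "fold": obs / mean if mean > 0 else float("inf"),
        }

    return {
        "n_intervals": n,
        "first_mb": report(obs_first, perm_first),
        "last_mb": report(obs_last, perm_last),
    }


def compare_with_readdepth(
    selfalign: list[PairwiseDuplication],
    rd_regions: pd.DataFrame,
    windows: pd.DataFrame,
    chrom_sizes: dict,
    min_len: int = 15000,
    min_identity: float = 0.95,
    exclude_first_mb: bool = True,
    chrom_partition=default_partition,
) -> dict:
    """Compare filtered self-alignment and read-depth duplication sets.

    Both sets are restricted to assembled chromosomes, length >= ``min_len``
    (pair identity >= ``min_identity`` for self-alignment) and, optionally,
    outside the first megabase.  Reports union/intersection/unique bp, plus
    support calls: a self-alignment interval is supported when its
    intersecting windows have median copy number >= 2.5; a read-depth region
    is supported when it overlaps any self-alignment interval.
    """
    sa_chroms = {c for p in selfalign for c, _, _ in p.projections()}
    rd_chroms = set(rd_regions["chrom"]) | set(windows["chrom"])
    if sa_chroms and rd_chroms and not (sa_chroms & rd_chroms):
        raise ValueError("self-alignment and read-depth chromosome names disjoint")

    def keep_interval(chrom, s, e):
        if chrom_partition(chrom) != "assembled":
            return False
        if e - s < min_len:
            return False
        if exclude_first_mb and s < 1_000_000:
            return False
        return True

    sa: dict[str, list] = defaultdict(list)
    for p in selfalign:
        if p.identity < min_identity:
            continue
        for chrom, s, e in p.projections():
            if keep_interval(chrom, s, e):
                sa[chrom].append((s, e))
    sa = iv.merge_dict(sa)
    rd: dict[str, list] = defaultdict(list)
    for row in rd_regions.itertuples():
        if keep_interval(row.chrom, row.start, row.end):
            rd[row.chrom].append((row.start, row.end))
    rd = iv.merge_dict(rd)

    both = iv.intersect_bp_dict(sa, rd)
    sa_bp = iv.total_bp_dict(sa)
    rd_bp = iv.total_bp_dict(rd)

    sa_supported = 0
    sa_total = 0
    for chrom, ivs in sa.items():
        w = windows[windows["chrom"] == chrom]
        for s, e in ivs:
            sa_total += 1
            hit = w[(w["end"] > s) & (w["start"] < e)]
            if len(hit) and float(hit["cn"].median()) >= 2.5:
                sa_supported += 1
    rd_supported = 0
    rd_total = 0
    for chrom, ivs in rd.items():
        for s, e in ivs:
            rd_total += 1
            if any(s < e2 and s2 < e for s2, e2 in sa.get(chrom, [])):
                rd_supported += 1

    return {
        "selfalign_bp": sa_bp,
        "readdepth_bp": rd_bp,
        "union_bp": sa_bp + rd_bp - both,
        "both_bp": both,
        "selfalign_only_bp": sa_bp - both,
        "readdepth_only_bp": rd_bp - both,
        "selfalign_supported": sa_supported,
        "selfalign_total": sa_total,
        "readdepth_supported": rd_supported,
        "readdepth_total": rd_total,
    }
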