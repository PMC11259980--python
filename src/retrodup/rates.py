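"""Cross-assembly retrocopy sharing and the insertion-rate estimate.

Presence of a retrocopy in another assembly is assessed by mapping its two
flanks: if both flanks place uniquely and consistently and the intervening
target sequence matches the insertion, the locus is shared; if the flanks
join with (essentially) no intervening sequence it is absent; anything
else is unresolved.  Counting filtered SNP divergence between assemblies
and calibrating with a pedigree-derived SNV mutation rate mu gives the
generations since divergence,

    generations = (SNPs / 2) / (callable bp * mu),

and the per-generation retrocopy insertion rate is the mean number of
lineage-private retrocopies divided by those generations, with bounds from
the published mutation-rate range.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from . import intervals as iv
from .genome import GenomeAssembly
from .kalign import KmerIndex, map_query

FLANK_MIN_IDENTITY = 0.90
FLANK_MIN_COVER = 0.80


# ---------------------------------------------------------------------------
# flank-based presence assessment
# ---------------------------------------------------------------------------

def _map_flank(flank_seq: str, index: KmerIndex):
    """Unique best placement of a flank: >= 90% identity over >= 80% of the
    flank; None when absent or ambiguous."""
    blocks = map_query(flank_seq, index, min_block=30)
    good = [
        b for b in blocks
        if b.length >= FLANK_MIN_COVER * len(flank_seq)
        and b.identity >= FLANK_MIN_IDENTITY
    ]
    if not good:
        return None
    good.sort(key=lambda b: b.matches, reverse=True)
    if len(good) > 1 and good[1].matches >= 0.8 * good[0].matches:
        # second placement nearly as good: ambiguous
        if not (
            good[1].chrom == good[0].chrom
            and abs(good[1].gstart - good[0].gstart) < 50
        ):
            return None
    return good[0]


def assess_presence(
    locus: tuple[str, int, int],
    donor: GenomeAssembly,
    target: GenomeAssembly,
    flank: int = 500,
    target_index: KmerIndex | None = None,
) -> str:
    """Classify a donor retrocopy locus in a target assembly.

    Returns ``"shared"``, ``"absent"`` or ``"unresolved"``.
    """
    chrom, start, end = locus
    seq = donor.sequences[chrom]
    if start - flank < 0 or end + flank > len(seq):
        return "unresolved"
    up = seq[start - flank:start]
    down = seq[end:end + flank]
    insert = seq[start:end]
    if target_index is None:
        target_index = KmerIndex(target, k=15)
    bu = _map_flank(up, target_index)
    bd = _map_flank(down, target_index)
    if bu is None or bd is None:
        return "unresolved"
    if bu.chrom != bd.chrom or bu.strand != bd.strand:
        return "unresolved"
    donor_span = end - start + 2 * flank
    if bu.strand == "+":
        gap_s, gap_e = bu.gend, bd.gstart
    else:
        gap_s, gap_e = bd.gend, bu.gstart
    if gap_s > gap_e or (gap_e - gap_s) + 2 * flank > 2 * donor_span:
        return "unresolved"
    gap_seq = target.sequences[bu.chrom][gap_s:gap_e]
    ins_len = len(insert)
    if len(gap_seq) <= max(10, 0.1 * ins_len):
        return "absent"
    if len(gap_seq) >= 0.5 * ins_len:
        res = edlib.align(insert, gap_seq, mode="NW", task="distance")
        if res["editDistance"] >= 0:
            identity = 1 - res["editDistance"] / max(ins_len, len(gap_seq))
            if identity >= 0.75:
                return "shared"
    return "unresolved"


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    table: pd.DataFrame          # rows: locus ids; columns: assembly names
    pattern_counts: pd.Series    # counts per shared/absent pattern
    discounted: list[str]        # loci dropped for unresolved cells


def build_presence_matrix(
    call_sets: dict[str, list[tuple[str, int, int]]],
    assemblies: dict[str, GenomeAssembly],
    priority: list[str],
    flank: int = 500,
    cluster_dist: int = 100,
) -> PresenceMatrix:
    """Unify retrocopy loci across assemblies and tabulate sharing.

    Loci are anchored by flank mapping into the highest-priority assembly
    (anchors within ``cluster_dist`` bp collapse to one locus); each
    unified locus is then re-sourced from its highest-priority carrier and
    tested in every assembly.  Loci with any unresolved cell are discounted
    from pattern counts.
    """
    indexes = {name: KmerIndex(asm, k=15) for name, asm in assemblies.items()}
    anchor_name = priority[0]
    anchor_index = indexes[anchor_name]

    # anchor every locus into the top-priority assembly's coordinates
    entries = []  # (anchor_chrom, anchor_pos, name, locus)
    for name in priority:
        for locus in call_sets.get(name, []):
            chrom, start, end = locus
            if name == anchor_name:
                entries.append((chrom, start, name, locus))
                continue
            seq = assemblies[name].sequences[chrom]
            up = seq[max(0, start - flank):start]
            b = _map_flank(up, anchor_index)
            if b is not None:
                pos = b.gend if b.strand == "+" else b.gstart
                entries.append((b.chrom, pos, name, locus))
            else:
                entries.append((f"{name}!{chrom}", start, name, locus))
    entries.sort(key=lambda t: (t[0], t[1]))
    clusters: list[dict] = []
    for chrom, pos, name, locus in entries:
        if (
            clusters
            and clusters[-1]["chrom"] == chrom
            and pos - clusters[-1]["pos"] <= cluster_dist
        ):
            clusters[-1]["pos"] = pos
            clusters[-1]["sources"].setdefault(name, locus)
        else:
            clusters.append({"chrom": chrom, "pos": pos, "sources": {name: locus}})

    names = list(assemblies)
    rows = {}
    discounted = []
    for info in clusters:
        donor_name = next(n for n in priority if n in info["sources"])
        locus = info["sources"][donor_name]
        locus_id = f"{donor_name}:{locus[0]}:{locus[1]}-{locus[2]}"
        cells = {}
        for name in names:
            if name == donor_name or name in info["sources"]:
                cells[name] = "shared"
            else:
                cells[name] = assess_presence(
                    locus,
                    assemblies[donor_name],
                    assemblies[name],
                    flank=flank,
                    target_index=indexes[name],
                )
        rows[locus_id] = cells
        if any(v == "unresolved" for v in cells.values()):
            discounted.append(locus_id)

    table = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    counted = table.drop(index=discounted)
    patterns = counted.apply(
        lambda r: "+".join(n for n in names if r[n] == "shared"), axis=1
    )
    pattern_counts = patterns.value_counts()
    return PresenceMatrix(table, pattern_counts, discounted)


# ---------------------------------------------------------------------------
# divergence counting and rate arithmetic
# ---------------------------------------------------------------------------

def count_divergence(
    snps: dict[str, list[int]],
    exclusions: list[dict],
    called_regions: dict,
) -> tuple[int, int]:
    """Filtered SNP count and callable size.

    ``snps`` maps chromosome to SNP positions; ``exclusions`` is a list of
    per-chromosome interval dicts (read-depth duplications, self-alignment
    duplications, tandem repeats); ``called_regions`` the per-chromosome
    callable intervals.  Callable size is the called bp minus exclusions;
    the SNP count is over surviving bases.
    """
    filtered = dict(called_regions)
    for ex in exclusions:
        filtered = iv.subtract_dict(filtered, ex)
    size = iv.total_bp_dict(filtered)
    count = 0
    for chrom, positions in snps.items():
        ivs = filtered.get(chrom, [])
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        pos = np.asarray(sorted(positions))
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        count += int(ok.sum())
    return count, size


def estimate_generations(snps: int, size: int, mu: float) -> int:
    """Generations since divergence: (SNPs / 2) / (size * mu), rounded."""
    if size <= 0 or mu <= 0:
        raise ValueError("size and mu must be positive")
    if snps < 0:
        raise ValueError("snps must be non-negative")
    return int(round(0.5 * snps / (size * mu)))


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


@dataclass
class RateEstimate:
    snps: int | None
    size: int | None
    mu: float
    mu_bounds: tuple[float, float] | None
    generations: int
    generations_range: tuple[int, int] | None
    unique_a: int
    unique_b: int
    rate: float
    rate_range: tuple[float, float] | None
    births: int
    births_range: tuple[int, int] | None


def estimate_rate(
    unique_a: int,
    unique_b: int,
    generations: int,
    mu: float = 4.5e-9,
    mu_bounds: tuple[float, float] | None = None,
    snps: int | None = None,
    size: int | None = None,
    sig_figs: int = 3,
) -> RateEstimate:
    """Per-generation retrocopy insertion rate with mutation-rate bounds.

    rate = mean(unique_a, unique_b) / generations, rounded to ``sig_figs``
    significant figures; births = round(1 / rounded rate).  When
    ``mu_bounds`` plus the SNP count and callable size are given, the
    range re-derives generations at each bound (a larger mu means fewer
    generations and a higher rate).
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    mean_unique = (unique_a + unique_b) / 2
    rate = _round_sig(mean_unique / generations, sig_figs)
    births = int(round(1 / rate)) if rate > 0 else 0
    gen_range = rate_range = births_range = None
    if mu_bounds is not None:
        if snps is None or size is None:
            raise ValueError("mu bounds require snps and size")
        mu_lo, mu_hi = mu_bounds
        g_hi = estimate_generations(snps, size, mu_lo)  # low mu, many generations
        g_lo = estimate_generations(snps, size, mu_hi)
        gen_range = (g_lo, g_hi)
        r_lo = _round_sig(mean_unique / g_hi, sig_figs)
        r_hi = _round_sig(mean_unique / g_lo, sig_figs)
        rate_range = (r_lo, r_hi)
        births_range = (
            int(round(1 / r_hi)) if r_hi > 0 else 0,
            int(round(1 / r_lo)) if r_lo > 0 else 0,
        )
    return RateEstimate(
        snps=snps,
        size=size,
        mu=mu,
        mu_bounds=mu_bounds,
        generations=generations,
        generations_range=gen_range,
        unique_a=unique_a,
        unique_b=unique_b,
        rate=rate,
        rate_range=rate_range,
        births=births,
        births_range=births_range,
    )


# ---------------------------------------------------------------------------
# ancestral (outgroup) presence
# ---------------------------------------------------------------------------

def ancestral_presence(
    locus: tuple[str, int, int],
    donor: GenomeAssembly,
    outgroup: GenomeAssembly,
    flank: int = 1000,
    min_size_fraction: float = 0.75,
    outgroup_index: KmerIndex | None = None,
    donor_index: KmerIndex | None = None,
) -> str:
    """Presence of a retrocopy in an outgroup assembly.

    Both 1 kb flanks must map to a single outgroup contig; the intervening
    outgroup sequence must be >= 75% of the retrocopy length and must map
    back over the original donor locus.  Returns ``"present"``,
    ``"absent"`` or ``"unresolved"``.
    """
    chrom, start, end = locus
    seq = donor.sequences[chrom]
    if start - flank < 0 or end + flank > len(seq):
        return "unresolved"
    if outgroup_index is None:
        outgroup_index = KmerIndex(outgroup, k=15)
    bu = _map_flank(seq[start - flank:start], outgroup_index)
    bd = _map_flank(seq[end:end + flank], outgroup_index)
    if bu is None or bd is None or bu.chrom != bd.chrom or bu.strand != bd.strand:
        return "unresolved"
    if bu.strand == "+":
        gap_s, gap_e = bu.gend, bd.gstart
    else:
        gap_s, gap_e = bd.gend, bu.gstart
    if gap_s > gap_e:
        return "unresolved"
    candidate = outgroup.sequences[bu.chrom][gap_s:gap_e]
    if len(candidate) < min_size_fraction * (end - start):
        return "absent"
    if donor_index is None:
        donor_index = KmerIndex(donor, k=15)
    back = map_query(candidate, donor_index, min_block=50)
    for b in back:
        if b.chrom == chrom and b.gstart < end and start < b.gend:
            return "present"
    return "unresolved"


def unique_counts_vs_reference(
    table: pd.DataFrame, assembly: str, reference: str
) -> tuple[int, int, int]:
    """(total resolvable, unique to assembly, unique to reference) for one
    pairwise comparison; a locus enters when resolved in both columns,
    regardless of its state elsewhere."""
    sub = table[[assembly, reference]]
    ok = (sub != "unresolved").all(axis=1)
    sub = sub[ok]
    both_or_either = (sub == "shared").any(axis=1)
    total = int(both_or_either.sum())
    uniq_a = int(((sub[assembly] == "shared") & (sub[reference] == "absent")).sum())
    uniq_r = int(((sub[reference] == "shared") & (sub[assembly] == "absent")).sum())
    return total, uniq_a, uniq_r
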