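"""Half-open interval arithmetic on (start, end) tuples.

All coordinates throughout the package are 0-based, half-open (BED
convention).  These helpers operate on plain ``(start, end)`` tuples or on
per-chromosome dicts ``{chrom: [(start, end), ...]}``.
"""

from __future__ import annotations


def merge(intervals, book_ended: bool = True):
    """Merge overlapping (and, by default, book-ended) intervals.

    Returns a sorted list of disjoint ``(start, end)`` tuples, BEDTools-merge
    style.
    """
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        last = out[-1]
        joined = s <= last[1] if book_ended else s < last[1]
        if joined:
            last[1] = max(last[1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def total_bp(intervals) -> int:
    return sum(e - s for s, e in merge(intervals))


def overlaps(a, b) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def intersect_bp(a_list, b_list) -> int:
    """Base pairs in the intersection of two interval lists."""
    a = merge(a_list)
    b = merge(b_list)
    i = j = 0
    bp = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            bp += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return bp


def subtract(a_list, b_list):
    """Intervals of ``a_list`` with every base covered by ``b_list`` removed."""
    a = merge(a_list)
    b = merge(b_list)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def merge_dict(by_chrom: dict, book_ended: bool = True) -> dict:
    return {c: merge(ivs, book_ended) for c, ivs in by_chrom.items() if ivs}


def total_bp_dict(by_chrom: dict) -> int:
    return sum(total_bp(ivs) for ivs in by_chrom.values())


def intersect_bp_dict(a: dict, b: dict) -> int:
    return sum(
        intersect_bp(a[c], b[c]) for c in set(a) & set(b)
    )


def subtract_dict(a: dict, b: dict) -> dict:
    return {c: subtract(ivs, b.get(c, [])) for c, ivs in a.items()}
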