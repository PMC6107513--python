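"""Independent brute-force oracles for the interval algebra and signal math.

Everything here is deliberately naive (O(n^2) scans, per-base sums,
transitive closure) and shares no code with the implementation it checks.
"""

from __future__ import annotations

from sekit.intervals import GenomicInterval


def ov_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return min(a.end, b.end) - max(a.start, b.start)


def bf_window_join(A, B, w):
    pairs = []
    for a in A:
        pa = GenomicInterval(a.chrom, max(0, a.start - w), a.end + w)
        for b in B:
            if ov_len(pa, b) >= 1:
                pairs.append((a, b))
    return pairs


def bf_stitch(A, d):
    """Transitive closure over pairwise gaps <= d (union-find)."""
    ivs = sorted(A, key=lambda x: (x.chrom, x.start, x.end))
    parent = list(range(len(ivs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(ivs):
        for j, b in enumerate(ivs):
            if i < j and a.chrom == b.chrom:
                gap = max(a.start, b.start) - min(a.end, b.end)
                if gap <= d:
                    parent[find(i)] = find(j)
    groups: dict[int, list[GenomicInterval]] = {}
    for i, iv in enumerate(ivs):
        groups.setdefault(find(i), []).append(iv)
    out = []
    for members in groups.values():
        region = GenomicInterval(
            members[0].chrom,
            min(m.start for m in members),
            max(m.end for m in members),
        )
        out.append((region, tuple(sorted(members, key=lambda m: (m.start, m.end)))))
    out.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    return out


def bf_exclude(A, B, pad):
    kept = []
    for a in A:
        hit = any(
            ov_len(a, GenomicInterval(b.chrom, max(0, b.start - pad), b.end + pad)) >= 1
            for b in B
        )
        if not hit:
            kept.append(a)
    return kept


def bf_closest(a, B):
    """(upstream (feature, signed dist) | None, downstream | None, overlapping)."""
    over, up, down = [], None, None
    for b in B:
        if b.chrom != a.chrom:
            continue
        if ov_len(a, b) >= 1:
            over.append(b)
        elif b.end <= a.start:
            gap = a.start - b.end
            if up is None or gap < up[1] or (gap == up[1] and (b.start, b.end) < (up[0].start, up[0].end)):
                up = (b, gap)
        else:
            gap = b.start - a.end
            if down is None or gap < down[1] or (gap == down[1] and (b.start, b.end) < (down[0].start, down[0].end)):
                down = (b, gap)
    over.sort(key=lambda b: (b.start, b.end))
    return (
        (up[0], -up[1]) if up else None,
        (down[0], down[1]) if down else None,
        over,
    )


def bf_compare_sets(S1, S2):
    common = [p for p in S1 if any(ov_len(p, q) >= 1 for q in S2)]
    spec1 = [p for p in S1 if not any(ov_len(p, q) >= 1 for q in S2)]
    spec2 = [q for q in S2 if not any(ov_len(p, q) >= 1 for p in S1)]
    return common, spec1, spec2


def bf_region_area(steps, region):
    """Per-base sum of a step list [(start, end, value)] over a region."""
    total = 0.0
    for s, e, v in steps:
        for pos in range(max(s, region.start), min(e, region.end)):
            total += v
    return total


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=400):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return out
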