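"""Independent brute-force oracles used to check the implementation.

These deliberately use naive enumeration (tuple grouping, linear scans)
rather than the package's algorithms.
"""

from __future__ import annotations

import numpy as np


def ehh_by_prefix_grouping(H: np.ndarray, core: int, flank: int) -> float:
    """EHH at flanking SNP `flank` by enumerating identical prefixes.

    Groups the n haplotypes by the tuple of alleles over every SNP between
    core and flank inclusive and counts ordered identical pairs.
    """
    lo, hi = min(core, flank), max(core, flank)
    groups: dict[tuple, int] = {}
    for row in H:
        key = tuple(row[lo : hi + 1])
        groups[key] = groups.get(key, 0) + 1
    n = H.shape[0]
    return sum(c * (c - 1) for c in groups.values()) / (n * (n - 1))


def ihh_trapezoid(dists, ehhs, cutoff: float) -> float:
    """One-arm iHH by explicit trapezoid summation with truncation."""
    total = 0.0
    prev_d, prev_e = 0.0, 1.0
    for d, e in zip(dists, ehhs):
        total += (prev_e + e) * (d - prev_d) / 2.0
        if e < cutoff:
            return total
        prev_d, prev_e = d, e
    return total


def call_peaks_linear_scan(values, t_high: float, t_low: float):
    """Hysteresis peak calling by an explicit linear scan.

    Returns (first_index, last_index) inclusive for each maximal run of
    values >= t_low containing at least one value > t_high.
    """
    out = []
    start = None
    seeded = False
    for i, v in enumerate(values):
        if v >= t_low:
            if start is None:
                start, seeded = i, False
            if v > t_high:
                seeded = True
        else:
            if start is not None and seeded:
                out.append((start, i - 1))
            start = None
    if start is not None and seeded:
        out.append((start, len(values) - 1))
    return out


def merge_intervals_naive(intervals):
    """Transitive >= 1 bp merge of (chrom, start, end) tuples."""
    by_chrom: dict[str, list] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    out = []
    for c in by_chrom:
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((c, cur_s, cur_e))
    return sorted(out)
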