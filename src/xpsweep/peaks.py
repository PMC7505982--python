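"""Dual-threshold (hysteresis) peak calling, merging and gene annotation.

A peak is a maximal run of consecutive loci whose (optionally absolute) score
stays at or above a low threshold and that contains at least one locus whose
score strictly exceeds a high threshold — e.g. |XP-EHH| > 3.5 seeded peaks
whose boundaries extend to where the score falls back below 1.5, or XP-CLR
window scores > 4.5 bounded at 2.5.  Two seed excursions inside one
low-threshold corridor form a single peak.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomeLayout, Peak, PeakSet, ScoreTrack, ValidationError, WindowTrack
from .ehh import sliding_mean

logger = logging.getLogger(__name__)


def smooth_flanking_windows(track: WindowTrack, flank: int) -> WindowTrack:
    """Average each window's score with its ``flank`` neighbours either side.

    The study smoothed XP-CLR 50-kb window scores across the three flanking
    windows either side to suppress single-window outliers.  Truncated at
    chromosome ends; chromosomes never mixed.
    """
    if flank < 0:
        raise ValidationError(f"flank must be >= 0, got {flank}")
    if flank == 0:
        return track
    parts = []
    for _, grp in track.per_chromosome():
        out = grp.copy()
        out["score"] = sliding_mean(grp["score"].to_numpy(dtype=float), 2 * flank + 1)
        parts.append(out)
    return WindowTrack(pd.concat(parts, ignore_index=True), pair=track.pair,
                       statistic=track.statistic)


def _peak_runs(values: np.ndarray, t_high: float, t_low: float):
    """Indices (first, last) of maximal >= t_low runs containing a > t_high locus."""
    above = values >= t_low
    runs = []
    i, n = 0, values.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if np.any(values[i : j + 1] > t_high):
            runs.append((i, j))
        i = j + 1
    return runs


def call_peaks(track: ScoreTrack | WindowTrack, t_high: float, t_low: float,
               layout: GenomeLayout, use_absolute: bool = False,
               statistic: str | None = None,
               comparison: str | None = None) -> PeakSet:
    """Call hysteresis peaks from a smoothed score track.

    Seed condition is strictly ``> t_high``; extension keeps loci ``>= t_low``.
    For point tracks the peak spans the outermost qualifying SNP positions
    (0-based half-open, a SNP at 1-based ``pos`` occupying ``[pos-1, pos)``);
    for window tracks it spans the union of the qualifying windows.
    """
    if not (t_high > t_low > 0):
        raise ValidationError(f"need t_high > t_low > 0, got {t_high}, {t_low}")
    stat = statistic or track.statistic
    comp = comparison or ("{}_vs_{}".format(*track.pair) if track.pair else "")
    peaks: list[Peak] = []
    for chrom, grp in track.per_chromosome():
        scores = grp["score"].to_numpy(dtype=float)
        values = np.abs(scores) if use_absolute else scores
        for i, j in _peak_runs(values, t_high, t_low):
            if track.is_point:
                pos = grp["pos"].to_numpy()
                start, end = int(pos[i]) - 1, int(pos[j])
            else:
                start = int(grp["start"].to_numpy()[i])
                end = int(grp["end"].to_numpy()[j])
            peaks.append(
                Peak(chrom, start, end, statistic=stat,
                     comparisons=frozenset([comp]) if comp else frozenset(),
                     max_score=float(np.max(np.abs(scores[i : j + 1]))))
            )
    return PeakSet(peaks, layout).sorted()


def merge_peaks(sets: list[PeakSet], layout: GenomeLayout | None = None) -> PeakSet:
    """Union of peak sets, transitively merging intervals that share >= 1 bp.

    Book-ended intervals (0 bp shared) do not merge.  Contributing comparisons
    are unioned and the largest |score| is propagated.  Mirrors the study's
    merge of overlapping peaks across breed comparisons.
    """
    if not sets:
        if layout is None:
            raise ValidationError("empty input requires an explicit layout")
        return PeakSet([], layout)
    layout = layout or sets[0].layout
    for s in sets:
        if s.layout != layout:
            raise ValidationError("peak sets use mismatched genome layouts")
    all_peaks = [p for s in sets for p in s.peaks]
    if not all_peaks:
        return PeakSet([], layout)
    order = {name: i for i, name in enumerate(layout.names)}
    all_peaks.sort(key=lambda p: (order[p.chrom], p.start, p.end))
    merged: list[Peak] = []
    cur = all_peaks[0]
    for p in all_peaks[1:]:
        if p.chrom == cur.chrom and p.start < cur.end:
            cur = Peak(
                cur.chrom, cur.start, max(cur.end, p.end),
                statistic=cur.statistic if cur.statistic == p.statistic
                else "+".join(sorted({cur.statistic, p.statistic} - {""})),
                comparisons=cur.comparisons | p.comparisons,
                max_score=max((v for v in (cur.max_score, p.max_score)
                               if not np.isnan(v)), default=float("nan")),
            )
        else:
            merged.append(cur)
            cur = p
    merged.append(cur)
    return PeakSet(merged, layout)


def annotate_peaks(peaks: PeakSet, genes: pd.DataFrame) -> list[list[str]]:
    """Genes sharing >= 1 bp with each peak.

    ``genes`` columns: chrom, start, end (0-based half-open), gene_id.
    Malformed records (end <= start) are skipped with a logged warning.
    Book-ended genes are not reported (half-open convention).
    """
    trees: dict[str, IntervalTree] = {}
    n_bad = 0
    for row in genes.itertuples(index=False):
        if row.end <= row.start:
            n_bad += 1
            continue
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene_id)
    if n_bad:
        logger.warning("skipped %d malformed gene records", n_bad)
    out = []
    for p in peaks:
        tree = trees.get(p.chrom)
        hits = sorted({iv.data for iv in tree.overlap(p.start, p.end)}) if tree else []
        out.append(hits)
    return out


def total_coverage(peaks: PeakSet) -> int:
    """Total bp covered by the peak set after merging overlaps."""
    return sum(p.size for p in merge_peaks([peaks], peaks.layout))
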