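"""Random-placement permutation nulls for genomic interval overlap.

The shared null model of every enrichment analysis in the pipeline: region
sets of fixed number and size are placed uniformly at random on the genome
(chromosome chosen with probability proportional to the number of valid start
positions, start uniform), the overlap statistic is recomputed per placement,
and the observed value is summarized as a Z score with a two-sided
normal-tail p and an ecdf-based empirical p.  The resampled set is always the
query (the peaks); the reference intervals or variant points stay fixed, so
their number and genomic distribution are preserved under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (GenomeLayout, Peak, PeakSet, PermutationResult, ScoreTrack,
                   ValidationError, WindowTrack, derive_seed)
from .peaks import call_peaks, merge_peaks

logger = logging.getLogger(__name__)

DEFAULT_NPERM_OVERLAP = 100   # cross-species / cross-metric overlap tests
DEFAULT_NPERM_GWAS = 1000     # GWAS-variant enrichment
DEFAULT_MIN_GWAS_POINTS = 300


def empirical_p(null_values: np.ndarray, observed: float) -> float:
    """Two-tailed ecdf p: double the minority tail, floored at 1/n.

    F is the empirical cdf of the permutation values (fraction <= observed,
    as R's ``ecdf``); p = max(2 * min(F, 1 - F), 1 / n).
    """
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    if n < 1:
        raise ValidationError("empirical p needs >= 1 permutation value")
    f = np.mean(null_values <= observed)
    return max(2.0 * min(f, 1.0 - f), 1.0 / n)


def normal_p(z: float) -> float:
    """Two-sided normal-tail probability of a Z score."""
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Random region placement
# ---------------------------------------------------------------------------


class _Genome:
    """Array view of a layout for fast vectorized placement."""

    def __init__(self, layout: GenomeLayout):
        self.layout = layout
        self.names = layout.names
        self.lengths = np.array([layout.length(c) for c in self.names], dtype=np.int64)


def _sample_starts(genome: _Genome, sizes: np.ndarray, rng: np.random.Generator):
    """Place each region independently; returns (chrom_idx, starts).

    Chromosome chosen with probability proportional to (length - size + 1)
    among chromosomes that fit; start uniform on [0, length - size].
    """
    caps = genome.lengths[None, :] - sizes[:, None] + 1  # valid starts per chrom
    caps = np.maximum(caps, 0)
    totals = caps.sum(axis=1)
    if np.any(totals == 0):
        bad = int(sizes[totals == 0][0])
        raise ValidationError(f"region size {bad} exceeds every chromosome length")
    cum = np.cumsum(caps, axis=1)
    u = rng.random(sizes.size) * totals
    chrom_idx = (u[:, None] < cum).argmax(axis=1)
    starts = rng.integers(0, caps[np.arange(sizes.size), chrom_idx])
    return chrom_idx, starts


def sample_random_regions(layout: GenomeLayout, sizes, rng: np.random.Generator) -> PeakSet:
    """Uniform random placement of regions of the given sizes on the genome.

    Sizes are preserved exactly; sampled regions may overlap one another.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if sizes.size == 0:
        return PeakSet([], layout)
    if np.any(sizes <= 0):
        raise ValidationError("region sizes must be positive")
    genome = _Genome(layout)
    chrom_idx, starts = _sample_starts(genome, sizes, rng)
    peaks = [
        Peak(genome.names[c], int(s), int(s + sz), statistic="random")
        for c, s, sz in zip(chrom_idx, starts, sizes)
    ]
    return PeakSet(peaks, layout)


# ---------------------------------------------------------------------------
# Overlap counting
# ---------------------------------------------------------------------------


class _MergedIntervals:
    """Merged, sorted reference intervals per chromosome for O(log n) queries."""

    def __init__(self, peaks: PeakSet):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        merged = merge_peaks([peaks], peaks.layout)
        for chrom in peaks.layout.names:
            ivs = [(p.start, p.end) for p in merged if p.chrom == chrom]
            if ivs:
                arr = np.asarray(ivs, dtype=np.int64)
                self.by_chrom[chrom] = (arr[:, 0], arr[:, 1])

    def hits(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean: does each query interval share >= 1 bp with a reference?"""
        if chrom not in self.by_chrom:
            return np.zeros(starts.size, dtype=bool)
        ref_s, ref_e = self.by_chrom[chrom]
        idx = np.searchsorted(ref_s, ends, side="left")
        ok = idx > 0
        ok[ok] = ref_e[idx[ok] - 1] > starts[ok]
        return ok


def count_overlapping(query: PeakSet, reference: PeakSet) -> int:
    """Number of query intervals sharing >= 1 bp with >= 1 reference interval."""
    if query.layout != reference.layout:
        raise ValidationError("query and reference use different genome layouts")
    ref = _MergedIntervals(reference)
    total = 0
    for chrom in query.layout.names:
        ivs = [(p.start, p.end) for p in query if p.chrom == chrom]
        if not ivs:
            continue
        arr = np.asarray(ivs, dtype=np.int64)
        total += int(ref.hits(chrom, arr[:, 0], arr[:, 1]).sum())
    return total


def _count_sampled(genome: _Genome, ref: _MergedIntervals, sizes: np.ndarray,
                   rng: np.random.Generator) -> int:
    chrom_idx, starts = _sample_starts(genome, sizes, rng)
    total = 0
    for c in np.unique(chrom_idx):
        mask = chrom_idx == c
        s = starts[mask]
        total += int(ref.hits(genome.names[c], s, s + sizes[mask]).sum())
    return total


def _summarize(observed: float, null_counts: np.ndarray, seed: int,
               label: str = "") -> PermutationResult:
    mean = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1)) if null_counts.size > 1 else 0.0
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (observed - mean) / sd
    return PermutationResult(
        observed=float(observed),
        perm_mean=mean,
        perm_sd=sd,
        z=z,
        p_normal=float("nan") if degenerate else normal_p(z),
        p_empirical=empirical_p(null_counts, observed),
        n_permutations=int(null_counts.size),
        seed=seed,
        degenerate=degenerate,
        label=label,
    )


def permute_overlap_test(query: PeakSet, reference: PeakSet, n_perm: int,
                         seed: int, label: str = "") -> PermutationResult:
    """Overlap of query peaks with a fixed reference vs random placement.

    Per permutation the query set is resampled (same number and sizes,
    uniform placement); the reference never moves.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = count_overlapping(query, reference)
    genome = _Genome(query.layout)
    ref = _MergedIntervals(reference)
    sizes = np.asarray(query.sizes(), dtype=np.int64)
    rng = np.random.default_rng(seed)
    if sizes.size == 0:
        null_counts = np.zeros(n_perm)
    else:
        null_counts = np.array(
            [_count_sampled(genome, ref, sizes, rng) for _ in range(n_perm)], dtype=float
        )
    return _summarize(observed, null_counts, seed, label)


# ---------------------------------------------------------------------------
# GWAS-variant enrichment
# ---------------------------------------------------------------------------


def _count_peaks_with_points(peaks_by_chrom, pos_by_chrom) -> int:
    total = 0
    for chrom, (starts, ends) in peaks_by_chrom.items():
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        total += int((hi > lo).sum())
    return total


def gwas_overlap_test(peaks: PeakSet, points: pd.DataFrame,
                      min_points: int = DEFAULT_MIN_GWAS_POINTS,
                      n_perm: int = DEFAULT_NPERM_GWAS,
                      seed: int = 0) -> dict[str, PermutationResult]:
    """Per-trait enrichment of peaks overlapping trait-associated variants.

    ``points`` columns: chrom, pos (0-based bp), trait.  Traits with fewer
    than ``min_points`` variants are skipped (the study required >= 300).
    Observed statistic: number of peaks containing >= 1 variant of the trait.
    Null: the peaks are resampled; the variants stay fixed, preserving their
    number and genomic distribution.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    counts = points.groupby("trait").size()
    traits = [t for t in counts.index if counts[t] >= min_points]
    if not traits:
        logger.warning("no trait has >= %d variants; empty result", min_points)
        return {}

    pos_by_trait = {
        t: {
            chrom: np.sort(grp["pos"].to_numpy(dtype=np.int64))
            for chrom, grp in points[points["trait"] == t].groupby("chrom")
        }
        for t in traits
    }
    obs_by_chrom = {}
    for chrom in peaks.layout.names:
        ivs = [(p.start, p.end) for p in peaks if p.chrom == chrom]
        if ivs:
            arr = np.asarray(ivs, dtype=np.int64)
            obs_by_chrom[chrom] = (arr[:, 0], arr[:, 1])
    observed = {t: _count_peaks_with_points(obs_by_chrom, pos_by_trait[t]) for t in traits}

    genome = _Genome(peaks.layout)
    sizes = np.asarray(peaks.sizes(), dtype=np.int64)
    rng = np.random.default_rng(seed)
    nulls = {t: np.empty(n_perm) for t in traits}
    for k in range(n_perm):
        chrom_idx, starts = _sample_starts(genome, sizes, rng)
        perm_by_chrom = {}
        for c in np.unique(chrom_idx):
            mask = chrom_idx == c
            perm_by_chrom[genome.names[c]] = (starts[mask], starts[mask] + sizes[mask])
        for t in traits:
            nulls[t][k] = _count_peaks_with_points(perm_by_chrom, pos_by_trait[t])
    return {t: _summarize(observed[t], nulls[t], seed, label=t) for t in traits}


# ---------------------------------------------------------------------------
# Threshold grids
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentGrid:
    """Cross-family overlap results across peak-calling threshold pairs.

    Rows index query-family thresholds, columns reference-family thresholds;
    each cell holds the PermutationResult of the merged-peak overlap test at
    that threshold combination plus the peak counts.
    """

    thresholds_query: list[tuple[float, float]]
    thresholds_reference: list[tuple[float, float]]
    results: list[list[PermutationResult]]
    n_peaks_query: list[int]
    n_peaks_reference: list[int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ta in enumerate(self.thresholds_query):
            for j, tb in enumerate(self.thresholds_reference):
                r = self.results[i][j]
                rows.append(
                    {
                        "query_t_high": ta[0], "query_t_low": ta[1],
                        "ref_t_high": tb[0], "ref_t_low": tb[1],
                        "n_peaks_query": self.n_peaks_query[i],
                        "n_peaks_reference": self.n_peaks_reference[j],
                        **r.as_dict(),
                    }
                )
        return pd.DataFrame(rows)


def _call_family(tracks, t_high, t_low, layout, use_absolute, statistic):
    sets = [
        call_peaks(tr, t_high, t_low, layout, use_absolute=use_absolute, statistic=statistic)
        for tr in tracks
    ]
    return merge_peaks(sets, layout)


def grid_scan(tracks_query, tracks_reference, thresholds_query, thresholds_reference,
              layout: GenomeLayout, n_perm: int = DEFAULT_NPERM_OVERLAP, seed: int = 0,
              use_absolute_query: bool = True, use_absolute_reference: bool = False,
              statistic_query: str = "query", statistic_reference: str = "reference",
              ) -> EnrichmentGrid:
    """Overlap tests across a grid of peak-calling threshold pairs.

    For each combination, peaks are called per comparison track, merged across
    comparisons within each family, and the query family is tested against the
    reference family with a random-placement permutation null.  The cell seed
    is derived deterministically from (seed, row, column), so any cell can be
    reproduced by a single run.
    """
    for t_high, t_low in list(thresholds_query) + list(thresholds_reference):
        if not (t_high > t_low > 0):
            raise ValidationError(f"invalid threshold pair ({t_high}, {t_low})")
    q_sets = [
        _call_family(tracks_query, th, tl, layout, use_absolute_query, statistic_query)
        for th, tl in thresholds_query
    ]
    r_sets = [
        _call_family(tracks_reference, th, tl, layout, use_absolute_reference,
                     statistic_reference)
        for th, tl in thresholds_reference
    ]
    results = []
    for i, q in enumerate(q_sets):
        row = []
        for j, r in enumerate(r_sets):
            cell_seed = derive_seed(seed, "grid", i, j)
            row.append(permute_overlap_test(q, r, n_perm, cell_seed,
                                            label=f"q{i}_r{j}"))
        results.append(row)
    return EnrichmentGrid(
        thresholds_query=list(thresholds_query),
        thresholds_reference=list(thresholds_reference),
        results=results,
        n_peaks_query=[len(s) for s in q_sets],
        n_peaks_reference=[len(s) for s in r_sets],
    )


def select_thresholds(grid: EnrichmentGrid):
    """Threshold pair minimizing the expected number of chance overlaps.

    The expected false-positive count is the permutation mean; ties are broken
    by larger Z, then by larger observed count.  Degenerate cells (zero
    permutation sd) are not eligible; if every cell is degenerate this errors.
    """
    best = None
    best_key = None
    for i, row in enumerate(grid.results):
        for j, r in enumerate(row):
            if r.degenerate:
                continue
            key = (r.perm_mean, -r.z, -r.observed)
            if best_key is None or key < best_key:
                best_key = key
                best = (grid.thresholds_query[i], grid.thresholds_reference[j])
    if best is None:
        raise ValidationError("every grid cell is degenerate; cannot select thresholds")
    return best
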