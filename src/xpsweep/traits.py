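"""Correlation of per-locus selection scores with pairwise breed-trait
differences.

For each sweep locus and each trait, the median XP-EHH score of every breed
comparison across the locus is correlated (Pearson) with the difference in
mean breed value between the same ordered breed pairs.  Significance comes
from a random-placement permutation null: per permutation a random region of
the same size is drawn, its median scores recomputed, and the correlation
recalculated; the two-tailed empirical p doubles the minority ecdf tail with
a floor of 1/n_permutations, and a Bonferroni correction multiplies by the
number of loci tested for the trait.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import (GenomeLayout, Peak, PeakSet, ScoreTrack, ValidationError,
                   derive_seed)
from .permutation import _Genome, _sample_starts, empirical_p

logger = logging.getLogger(__name__)

DEFAULT_NPERM_TRAITS = 5000  # the study's trait-correlation permutation count


def median_score_per_locus(track: ScoreTrack, chrom: str, start: int, end: int):
    """Median score at SNPs inside the 0-based half-open locus, or None.

    A SNP at 1-based ``pos`` lies inside iff ``start <= pos - 1 < end``.
    Loci containing no SNPs are flagged by returning None.
    """
    d = track.data
    sel = d[(d["chrom"] == chrom) & (d["pos"] - 1 >= start) & (d["pos"] - 1 < end)]
    if sel.empty:
        return None
    return float(np.median(sel["score"].to_numpy(dtype=float)))


def trait_diff_matrix(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pairwise differences of breed means, oriented as the score pairs.

    ``table`` is indexed by population with one column per trait.  The
    difference for pair (A, B) is mean_A - mean_B, the same orientation as the
    XP-EHH score for (A, B).  Missing values propagate as NaN and the pair is
    dropped for that trait downstream.
    """
    for a, b in pairs:
        for breed in (a, b):
            if breed not in table.index:
                raise ValidationError(f"breed {breed!r} missing from trait table")
    rows = {f"{a}_vs_{b}": table.loc[a] - table.loc[b] for a, b in pairs}
    out = pd.DataFrame(rows).T
    out.index.name = "pair"
    return out


def correlate_locus_trait(median_scores, trait_diffs):
    """Pearson correlation over breed pairs; NaN pairs dropped, needs >= 3.

    Returns NaN (flagged undefined) when either vector has zero variance.
    """
    x = np.asarray(median_scores, dtype=float)
    y = np.asarray(trait_diffs, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError(f"Pearson correlation needs >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


class _FastTrack:
    """Per-chromosome sorted position/score arrays for median queries."""

    def __init__(self, track: ScoreTrack):
        self.by_chrom = {}
        for chrom, grp in track.per_chromosome():
            self.by_chrom[chrom] = (
                grp["pos"].to_numpy(dtype=np.int64) - 1,  # 0-based
                grp["score"].to_numpy(dtype=float),
            )

    def median(self, chrom: str, start: int, end: int):
        if chrom not in self.by_chrom:
            return None
        pos, score = self.by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        if hi == lo:
            return None
        return float(np.median(score[lo:hi]))


def permuted_trait_pvalues(loci: PeakSet, tracks: dict[tuple[str, str], ScoreTrack],
                           table: pd.DataFrame, n_perm: int = DEFAULT_NPERM_TRAITS,
                           seed: int = 0, max_retries: int = 100) -> pd.DataFrame:
    """Trait-sweep correlations with permutation p-values for every locus.

    For each locus, the observed Pearson r between per-pair median scores and
    per-pair trait differences is compared with the correlations of random
    same-size regions (one region per permutation, shared across traits within
    that permutation so per-trait nulls are comparable).  Regions landing on
    no SNPs for some pair are redrawn up to ``max_retries`` times.  Returns a
    long DataFrame: locus coordinates, trait, r, p_uncorrected, p_bonferroni,
    n_pairs, n_permutations, seed.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    pairs = list(tracks)
    if len(pairs) < 3:
        raise ValidationError("trait correlation needs >= 3 breed pairs")
    diffs = trait_diff_matrix(table, pairs)
    traits = list(diffs.columns)
    fast = {p: _FastTrack(tracks[p]) for p in pairs}
    genome = _Genome(loci.layout)

    records = []
    usable_loci = []
    for locus in loci:
        obs = [fast[p].median(locus.chrom, locus.start, locus.end) for p in pairs]
        if any(v is None for v in obs):
            logger.warning("locus %s:%d-%d has no SNPs for some pair; excluded",
                           locus.chrom, locus.start, locus.end)
            continue
        usable_loci.append((locus, np.asarray(obs, dtype=float)))

    n_loci = len(usable_loci)
    for li, (locus, obs_scores) in enumerate(usable_loci):
        rng = np.random.default_rng(derive_seed(seed, "traitperm", li))
        size = np.asarray([locus.size], dtype=np.int64)
        null_r = {t: np.empty(n_perm) for t in traits}
        r_obs = {t: correlate_locus_trait(obs_scores, diffs[t].to_numpy()) for t in traits}
        for k in range(n_perm):
            scores = None
            for _ in range(max_retries):
                chrom_idx, starts = _sample_starts(genome, size, rng)
                chrom = genome.names[chrom_idx[0]]
                s = int(starts[0])
                cand = [fast[p].median(chrom, s, s + locus.size) for p in pairs]
                if all(v is not None for v in cand):
                    scores = np.asarray(cand, dtype=float)
                    break
            if scores is None:
                raise ValidationError(
                    f"could not place a SNP-bearing null region of size {locus.size} "
                    f"after {max_retries} retries"
                )
            for t in traits:
                null_r[t][k] = correlate_locus_trait(scores, diffs[t].to_numpy())
        for t in traits:
            nulls = null_r[t][np.isfinite(null_r[t])]
            if not np.isfinite(r_obs[t]) or nulls.size == 0:
                p_unc = float("nan")
            else:
                p_unc = empirical_p(nulls, r_obs[t])
            records.append(
                {
                    "chrom": locus.chrom, "start": locus.start, "end": locus.end,
                    "trait": t, "r": r_obs[t], "p_uncorrected": p_unc,
                    "n_pairs": len(pairs), "n_permutations": n_perm, "seed": seed,
                }
            )
    out = pd.DataFrame(records)
    if not out.empty:
        # Bonferroni over the number of loci tested per trait (cross-trait
        # correction deliberately not applied; both factors are recoverable)
        out["p_bonferroni"] = np.minimum(1.0, out["p_uncorrected"] * n_loci)
    return out
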