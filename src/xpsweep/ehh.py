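"""Extended haplotype homozygosity (EHH), iHH, and XP-EHH.

EHH at a flanking SNP *s* is the probability that two haplotypes drawn
without replacement from the sample are identical over every SNP from the
core to *s* inclusive:

    EHH(s) = sum_g c_g (c_g - 1) / (n (n - 1))

where the groups *g* partition the *n* haplotypes by identity of the
core-to-*s* prefix.  EHH at zero distance is defined as 1.  iHH is the
trapezoidal integral of EHH over genetic distance, both arms summed, each arm
truncated at (and including the trapezoid reaching) the first SNP where EHH
drops below a cutoff, or at the chromosome end.  XP-EHH for an ordered
population pair (A, B) at a SNP is ln(iHH_A / iHH_B), computed from
whole-population EHH (no split by core allele), then standardized to mean 0
and sample sd 1 over all valid SNPs genome-wide for that pair.  Extreme
positive scores indicate unusually long haplotype homozygosity in A relative
to B, the signature of a recent hard sweep in A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .core import HaplotypeSet, ScoreTrack, ValidationError

DEFAULT_EHH_CUTOFF = 0.05  # hapbin's default truncation threshold
DEFAULT_RECOMB_RATE = 1.0  # cM per Mbp, the study's flat genetic map


def bp_to_cm(positions, rate: float = DEFAULT_RECOMB_RATE) -> np.ndarray:
    """Convert physical bp positions to genetic positions under a flat map.

    ``rate`` is in cM per Mbp, so 1 Mb corresponds to ``rate`` cM.
    """
    if rate < 0:
        raise ValidationError(f"negative recombination rate {rate}")
    positions = np.asarray(positions, dtype=np.float64)
    if positions.size > 1 and np.any(np.diff(positions) < 0):
        raise ValidationError("positions must be sorted")
    return positions * rate / 1e6


# ---------------------------------------------------------------------------
# EHH curves (reference implementation, vectorized NumPy)
# ---------------------------------------------------------------------------


@dataclass
class EhhCurve:
    """EHH of one population around a core SNP.

    ``left``/``right`` hold (genetic distance from core in cM, EHH) per
    flanking SNP, ordered by increasing distance; the core point (0, 1) is
    implicit.
    """

    core: int
    left: tuple[np.ndarray, np.ndarray]
    right: tuple[np.ndarray, np.ndarray]


def compute_ehh(haplotypes: np.ndarray, core: int, direction: str, genetic_pos=None):
    """EHH along one arm, at every flanking SNP out to the chromosome end.

    Returns (distances_cM, ehh_values) ordered by increasing distance from the
    core.  ``genetic_pos`` defaults to SNP index (unit spacing), which is only
    appropriate for toy matrices.
    """
    H = np.ascontiguousarray(haplotypes, dtype=np.uint8)
    n, m = H.shape
    if n < 2:
        raise ValidationError("EHH requires >= 2 haplotypes")
    if not (0 <= core < m):
        raise ValidationError(f"core index {core} out of range for {m} SNPs")
    if direction not in ("left", "right"):
        raise ValidationError(f"direction must be 'left' or 'right', got {direction!r}")
    if genetic_pos is None:
        genetic_pos = np.arange(m, dtype=np.float64)
    genetic_pos = np.asarray(genetic_pos, dtype=np.float64)

    step = -1 if direction == "left" else 1
    cols = range(core + step, -1 if step < 0 else m, step)
    # group ids start from the core allele: the prefix includes the core SNP
    groups = H[:, core].astype(np.int64)
    dists, ehhs = [], []
    denom = n * (n - 1)
    for j in cols:
        # refine the identity partition by the allele at j
        keys = groups * 2 + H[:, j]
        _, groups, counts = np.unique(keys, return_inverse=True, return_counts=True)
        ehhs.append(float(np.sum(counts * (counts - 1)) / denom))
        dists.append(abs(genetic_pos[j] - genetic_pos[core]))
    return np.asarray(dists), np.asarray(ehhs)


def ehh_curve(haplotypes: np.ndarray, core: int, genetic_pos=None) -> EhhCurve:
    """Both arms of the EHH curve around ``core``."""
    return EhhCurve(
        core=core,
        left=compute_ehh(haplotypes, core, "left", genetic_pos),
        right=compute_ehh(haplotypes, core, "right", genetic_pos),
    )


def _arm_integral(dists: np.ndarray, ehhs: np.ndarray, cutoff: float) -> float:
    total = 0.0
    d_prev, e_prev = 0.0, 1.0
    for d, e in zip(dists, ehhs):
        total += 0.5 * (e_prev + e) * (d - d_prev)
        if e < cutoff:
            break
        d_prev, e_prev = d, e
    return total


def compute_ihh(curve: EhhCurve, cutoff: float = DEFAULT_EHH_CUTOFF) -> float:
    """Trapezoidal integral of an EHH curve over genetic distance (cM).

    Each arm is truncated at — and includes the trapezoid reaching — the first
    SNP whose EHH falls below ``cutoff``, or runs to the chromosome end.
    """
    if not (0 < cutoff < 1):
        raise ValidationError(f"EHH cutoff must lie in (0, 1), got {cutoff}")
    return _arm_integral(*curve.left, cutoff) + _arm_integral(*curve.right, cutoff)


# ---------------------------------------------------------------------------
# Fast iHH kernels (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ihh_one_arm(H, core, step, gpos, cutoff):  # pragma: no cover - numba
    n, m = H.shape
    g = np.empty(n, np.int64)
    for i in range(n):
        g[i] = H[i, core]
    remap = np.empty(2 * n + 4, np.int64)
    counts = np.empty(n + 2, np.int64)
    denom = n * (n - 1)
    total = 0.0
    e_prev = 1.0
    d_prev = gpos[core]
    j = core + step
    while 0 <= j < m:
        for k in range(2 * n + 4):
            remap[k] = -1
        nxt = 0
        for i in range(n):
            key = g[i] * 2 + H[i, j]
            if remap[key] < 0:
                remap[key] = nxt
                nxt += 1
            g[i] = remap[key]
        for k in range(nxt):
            counts[k] = 0
        for i in range(n):
            counts[g[i]] += 1
        s = 0
        for k in range(nxt):
            s += counts[k] * (counts[k] - 1)
        e = s / denom
        d = gpos[j]
        total += 0.5 * (e_prev + e) * abs(d - d_prev)
        if e < cutoff:
            break
        if e == 0.0:
            break
        e_prev = e
        d_prev = d
        j += step
    return total


@njit(cache=True)
def _ihh_all_cores(H, gpos, cutoff):  # pragma: no cover - numba
    m = H.shape[1]
    out = np.empty(m, np.float64)
    for c in range(m):
        out[c] = _ihh_one_arm(H, c, -1, gpos, cutoff) + _ihh_one_arm(H, c, 1, gpos, cutoff)
    return out


def ihh_track(haplotypes: np.ndarray, genetic_pos: np.ndarray,
              cutoff: float = DEFAULT_EHH_CUTOFF) -> np.ndarray:
    """iHH at every SNP of one population's haplotype matrix."""
    if not (0 < cutoff < 1):
        raise ValidationError(f"EHH cutoff must lie in (0, 1), got {cutoff}")
    H = np.ascontiguousarray(haplotypes, dtype=np.uint8)
    if H.shape[0] < 2:
        raise ValidationError("iHH requires >= 2 haplotypes")
    return _ihh_all_cores(H, np.asarray(genetic_pos, dtype=np.float64), cutoff)


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------


def standardize_scores(values) -> np.ndarray:
    """Center to mean 0 and scale to sample sd 1 (n-1 denominator)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2 or not np.all(np.isfinite(values)):
        raise ValidationError("standardization needs >= 2 finite values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize values with zero spread")
    return (values - values.mean()) / sd


@dataclass
class XpehhResult:
    """Per-SNP XP-EHH for one ordered population pair.

    ``data`` columns: chrom, pos (1-based), ihh_a, ihh_b, raw, std, valid.
    Raw scores are finite iff both iHH values are positive; standardized
    scores over the valid SNPs have mean 0 and sample sd 1 genome-wide.
    """

    pair: tuple[str, str]
    data: pd.DataFrame
    cutoff: float

    def track(self, column: str = "std") -> ScoreTrack:
        """Point score track over the valid SNPs (invalid SNPs are dropped)."""
        d = self.data[self.data["valid"]]
        out = pd.DataFrame({"chrom": d["chrom"], "pos": d["pos"], "score": d[column]})
        return ScoreTrack(out.reset_index(drop=True), pair=self.pair, statistic="xpehh")


def compute_xpehh(haps: HaplotypeSet, pair: tuple[str, str],
                  cutoff: float = DEFAULT_EHH_CUTOFF) -> XpehhResult:
    """XP-EHH at every SNP for the ordered pair (A, B).

    Whole-population EHH is used on each side (all haplotypes of the
    population, no split by core allele).  SNPs where either iHH is zero are
    flagged invalid and excluded from standardization.
    """
    pop_a, pop_b = pair
    idx_a = haps.population_indices(pop_a)
    idx_b = haps.population_indices(pop_b)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValidationError("each population needs >= 2 haplotypes")

    frames = []
    for chrom, ch in haps.chromosomes.items():
        if ch.n_snps == 0:
            continue
        ihh_a = ihh_track(ch.haplotypes[idx_a], ch.genetic_pos, cutoff)
        ihh_b = ihh_track(ch.haplotypes[idx_b], ch.genetic_pos, cutoff)
        valid = (ihh_a > 0) & (ihh_b > 0)
        raw = np.full(ch.n_snps, np.nan)
        raw[valid] = np.log(ihh_a[valid] / ihh_b[valid])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": ch.positions,
                    "ihh_a": ihh_a,
                    "ihh_b": ihh_b,
                    "raw": raw,
                    "valid": valid,
                }
            )
        )
    if not frames:
        raise ValidationError("haplotype set has no SNPs")
    data = pd.concat(frames, ignore_index=True)
    std = np.full(len(data), np.nan)
    valid = data["valid"].values
    raw_valid = data.loc[valid, "raw"].values
    if raw_valid.size >= 2 and raw_valid.std(ddof=1) > 0:
        std[valid] = standardize_scores(raw_valid)
    else:
        logging.getLogger(__name__).warning(
            "raw XP-EHH has zero spread for pair %s; standardized scores undefined",
            (pop_a, pop_b),
        )
    data["std"] = std
    return XpehhResult(pair=(pop_a, pop_b), data=data, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean over ``window`` points, truncated at the ends."""
    s = pd.Series(np.asarray(values, dtype=np.float64))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def block_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Each point replaced by the mean of its non-overlapping block."""
    values = np.asarray(values, dtype=np.float64)
    out = np.empty_like(values)
    for i in range(0, values.size, window):
        out[i : i + window] = values[i : i + window].mean()
    return out


def smooth_snp_window(track: ScoreTrack, window: int, mode: str = "sliding",
                      absolute: bool = False) -> ScoreTrack:
    """Smooth a per-SNP score track by averaging across SNP windows.

    The default is a centered sliding window (the study averaged XP-EHH over
    1000-SNP windows; at desk scale a smaller window with the same SNP spacing
    fraction is appropriate).  ``mode='block'`` emulates non-overlapping
    windows.  Chromosomes are never mixed.  With ``absolute=True`` the
    magnitude is smoothed instead of the signed score.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if mode == "sliding" and window % 2 == 0:
        raise ValidationError("sliding window must be odd so it is centered")
    if mode not in ("sliding", "block"):
        raise ValidationError(f"unknown smoothing mode {mode!r}")
    fn = sliding_mean if mode == "sliding" else block_mean
    parts = []
    for _, grp in track.per_chromosome():
        vals = grp["score"].to_numpy(dtype=np.float64)
        if absolute:
            vals = np.abs(vals)
        out = grp.copy()
        out["score"] = fn(vals, window)
        parts.append(out)
    return ScoreTrack(pd.concat(parts, ignore_index=True), pair=track.pair,
                      statistic=track.statistic)
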