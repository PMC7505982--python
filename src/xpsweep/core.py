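"""Shared domain types for the sweep-comparison pipeline.

All genomic intervals are 0-based, half-open ``[start, end)`` internally and
in BED output; VCF and score-track positions are 1-based and converted at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


def derive_seed(seed: int, *keys) -> int:
    """Derive a reproducible child seed (< 2**31) from a root seed and keys.

    Strings are folded in via CRC32 so substreams for named stages
    ("xpehh", "permutation", ...) are stable across runs and platforms.
    """
    import zlib

    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(ints))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered, named chromosomes with lengths: the coordinate universe for
    every interval operation and for random region placement."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: int(length) for name, length in self.chromosomes}

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeHaplotypes:
    """Phased haplotypes for one chromosome.

    ``haplotypes`` is a (n_haplotypes, n_snps) 0/1 matrix; ``positions`` are
    1-based bp (strictly increasing) and ``genetic_pos`` is in cM
    (non-decreasing).
    """

    positions: np.ndarray
    genetic_pos: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=np.float64)
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValidationError("haplotype matrix must be 2-D")
        n_snp = self.haplotypes.shape[1]
        if self.positions.shape != (n_snp,) or self.genetic_pos.shape != (n_snp,):
            raise ValidationError("positions must match haplotype matrix width")
        if n_snp > 1:
            if not np.all(np.diff(self.positions) > 0):
                raise ValidationError("physical positions must be strictly increasing")
            if not np.all(np.diff(self.genetic_pos) >= 0):
                raise ValidationError("genetic positions must be non-decreasing")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValidationError("haplotype entries must be 0/1")

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes over a genome, with population labels.

    Haplotype row order is shared across chromosomes; ``populations[i]`` is the
    population label of row ``i``.
    """

    layout: GenomeLayout
    populations: np.ndarray
    chromosomes: dict[str, ChromosomeHaplotypes]
    sample_names: list[str] | None = None

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=object)
        n_hap = len(self.populations)
        for chrom, ch in self.chromosomes.items():
            if chrom not in self.layout:
                raise ValidationError(f"chromosome {chrom!r} not in layout")
            if ch.n_haplotypes != n_hap:
                raise ValidationError(
                    f"chromosome {chrom!r} has {ch.n_haplotypes} haplotypes, expected {n_hap}"
                )
            if ch.n_snps and int(ch.positions[-1]) > self.layout.length(chrom):
                raise ValidationError(f"SNP position beyond end of {chrom!r}")

    @property
    def n_haplotypes(self) -> int:
        return len(self.populations)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == label)
        if idx.size == 0:
            raise ValidationError(f"unknown population {label!r}")
        return idx

    def copy(self) -> "HaplotypeSet":
        return HaplotypeSet(
            layout=self.layout,
            populations=self.populations.copy(),
            chromosomes={
                c: ChromosomeHaplotypes(
                    ch.positions.copy(), ch.genetic_pos.copy(), ch.haplotypes.copy()
                )
                for c, ch in self.chromosomes.items()
            },
            sample_names=list(self.sample_names) if self.sample_names else None,
        )


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------

_POINT_COLS = ["chrom", "pos", "score"]
_WINDOW_COLS = ["chrom", "start", "end", "score"]


@dataclass
class ScoreTrack:
    """Per-SNP point scores for one ordered population pair.

    ``data`` columns: chrom, pos (1-based, as in VCF), score; sorted by
    (chromosome appearance order, position).
    """

    data: pd.DataFrame
    pair: tuple[str, str] | None = None
    statistic: str = "score"

    def __post_init__(self):
        missing = [c for c in _POINT_COLS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"point track missing columns {missing}")
        self.data = self.data.reset_index(drop=True)
        for chrom, grp in self.data.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValidationError(f"positions not sorted on {chrom!r}")

    @property
    def is_point(self) -> bool:
        return True

    def per_chromosome(self):
        return self.data.groupby("chrom", sort=False)


@dataclass
class WindowTrack:
    """Per-window interval scores (e.g. ingested XP-CLR 50-kb windows).

    ``data`` columns: chrom, start, end (0-based half-open, non-overlapping,
    sorted per chromosome), score.
    """

    data: pd.DataFrame
    pair: tuple[str, str] | None = None
    statistic: str = "score"

    def __post_init__(self):
        missing = [c for c in _WINDOW_COLS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"window track missing columns {missing}")
        self.data = self.data.reset_index(drop=True)
        if (self.data["end"] <= self.data["start"]).any():
            raise ValidationError("window end must exceed start")
        for chrom, grp in self.data.groupby("chrom", sort=False):
            if not grp["start"].is_monotonic_increasing:
                raise ValidationError(f"windows not sorted on {chrom!r}")
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValidationError(f"overlapping windows on {chrom!r}")

    @property
    def is_point(self) -> bool:
        return False

    def per_chromosome(self):
        return self.data.groupby("chrom", sort=False)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """One putative selective-sweep interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    statistic: str = ""
    comparisons: frozenset = frozenset()
    max_score: float = float("nan")

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValidationError(f"invalid interval [{self.start}, {self.end})")

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Peak") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class PeakSet:
    """A collection of peak intervals over one genome layout."""

    peaks: list[Peak]
    layout: GenomeLayout

    def __post_init__(self):
        for p in self.peaks:
            if p.chrom not in self.layout:
                raise ValidationError(f"peak on unknown chromosome {p.chrom!r}")
            if p.end > self.layout.length(p.chrom):
                raise ValidationError(f"peak beyond end of {p.chrom!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def sizes(self) -> list[int]:
        return [p.size for p in self.peaks]

    def sorted(self) -> "PeakSet":
        order = {name: i for i, name in enumerate(self.layout.names)}
        peaks = sorted(self.peaks, key=lambda p: (order[p.chrom], p.start, p.end))
        return PeakSet(peaks, self.layout)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "statistic": [p.statistic for p in self.peaks],
                "comparisons": [",".join(sorted(p.comparisons)) for p in self.peaks],
                "max_score": [p.max_score for p in self.peaks],
            }
        )


# ---------------------------------------------------------------------------
# Permutation results
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed statistic vs its random-placement null.

    ``z = (observed - perm_mean) / perm_sd`` when the permutation spread is
    nonzero; ``p_normal`` is the two-sided normal-tail probability of ``z`` and
    ``p_empirical`` the ecdf-based two-tailed probability floored at
    ``1 / n_permutations``. ``degenerate`` flags a zero permutation sd, in
    which case ``z`` and ``p_normal`` are NaN.
    """

    observed: float
    perm_mean: float
    perm_sd: float
    z: float
    p_normal: float
    p_empirical: float
    n_permutations: int
    seed: int
    degenerate: bool = False
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "observed": self.observed,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
            "z": self.z,
            "p_normal": self.p_normal,
            "p_empirical": self.p_empirical,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }
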