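"""Synthetic genomes, haplotype panels with implanted sweeps, trait tables
and GWAS point sets.

The neutral model draws every sample haplotype as a mosaic of a shared pool
of ancestral founder haplotypes, with copying-template switches occurring at
a rate of one per ``mosaic_segment_mean`` bp (geometric segment lengths).
All populations copy from the same pool, so between-population differences
are pure sampling noise and linkage disequilibrium decays with physical
distance — the two properties cross-population haplotype statistics need
from a null.  A hard sweep is implanted by star-like founder replacement:
within a region, each haplotype of the target population is independently
replaced by one randomly chosen founder haplotype with probability
``founder_frequency``, producing the elevated haplotype homozygosity in one
population that XP-EHH detects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (ChromosomeHaplotypes, GenomeLayout, HaplotypeSet, PeakSet,
                   ValidationError, derive_seed)
from .ehh import bp_to_cm

DEFAULT_N_FOUNDERS = 24          # ancestral pool size; ~dozens of founder lineages
DEFAULT_MOSAIC_SEGMENT_MEAN = 100_000  # bp; LD decays on the 0.1-Mb scale
DEFAULT_MAF_FLOOR = 0.05         # matches the study's MAF >= 5% input filter


@dataclass(frozen=True)
class SweepSpec:
    """One hard sweep: a founder haplotype driven to high frequency in one
    population over a genomic region."""

    chromosome: str
    start: int
    end: int
    target_population: str
    founder_frequency: float

    def __post_init__(self):
        if not (0 <= self.founder_frequency <= 1):
            raise ValidationError(
                f"founder_frequency must be in [0, 1], got {self.founder_frequency}"
            )
        if self.end <= self.start or self.start < 0:
            raise ValidationError(f"invalid sweep region [{self.start}, {self.end})")


def make_genome_layout(n_chrom: int, lengths, names=None) -> GenomeLayout:
    """Build a genome layout from chromosome lengths (bp)."""
    lengths = list(lengths)
    if len(lengths) != n_chrom:
        raise ValidationError(f"expected {n_chrom} lengths, got {len(lengths)}")
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chrom)]
    return GenomeLayout(tuple((n, int(l)) for n, l in zip(names, lengths)))


def _mosaic_paths(n_hap: int, positions: np.ndarray, n_founders: int,
                  segment_mean: float, rng: np.random.Generator) -> np.ndarray:
    """Founder index per (haplotype, SNP) under geometric-segment copying."""
    n_snp = positions.size
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-gaps / segment_mean)
    switch = rng.random((n_hap, n_snp - 1)) < p_switch[None, :]
    # candidate founder at every SNP; the value at each segment start is the
    # founder copied until the next switch
    cand = rng.integers(0, n_founders, size=(n_hap, n_snp))
    new_seg = np.concatenate([np.ones((n_hap, 1), bool), switch], axis=1)
    idx = np.where(new_seg, np.arange(n_snp)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    return np.take_along_axis(cand, idx, axis=1)


def simulate_neutral_haplotypes(layout: GenomeLayout, populations, n_snps_per_chrom: int,
                                maf_floor: float = DEFAULT_MAF_FLOOR,
                                mosaic_segment_mean: float = DEFAULT_MOSAIC_SEGMENT_MEAN,
                                seed: int = 0, n_founders: int = DEFAULT_N_FOUNDERS,
                                recomb_rate: float = 1.0) -> HaplotypeSet:
    """Phased haplotype panel with a shared neutral background.

    ``populations`` is a list of (label, n_haplotypes).  SNP positions are
    uniform random, deduplicated and sorted; sites whose pooled minor-allele
    fraction falls below ``maf_floor`` are dropped, so the returned SNP count
    per chromosome may be slightly below ``n_snps_per_chrom``.  Genetic
    positions use a flat ``recomb_rate`` cM/Mbp map.
    """
    if n_snps_per_chrom < 2:
        raise ValidationError("need >= 2 SNPs per chromosome")
    if not (0 <= maf_floor <= 0.5):
        raise ValidationError(f"maf_floor must be in [0, 0.5], got {maf_floor}")
    labels = [p[0] for p in populations]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate population labels")
    for label, n in populations:
        if n < 2:
            raise ValidationError(f"population {label!r} needs >= 2 haplotypes")
    pop_arr = np.concatenate([[label] * n for label, n in populations]).astype(object)
    n_hap = pop_arr.size

    chroms: dict[str, ChromosomeHaplotypes] = {}
    for ci, (chrom, length) in enumerate(layout.chromosomes):
        rng = np.random.default_rng(derive_seed(seed, "neutral", ci))
        if length < n_snps_per_chrom:
            raise ValidationError(f"chromosome {chrom!r} too short for {n_snps_per_chrom} SNPs")
        pos = np.array([], dtype=np.int64)
        while pos.size < n_snps_per_chrom:
            extra = rng.integers(1, length + 1, size=2 * n_snps_per_chrom)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=n_snps_per_chrom, replace=False))

        # founder pool: per-SNP allele frequencies away from the boundaries so
        # most sites survive the MAF floor
        freqs = rng.uniform(0.1, 0.9, size=n_snps_per_chrom)
        pool = (rng.random((n_founders, n_snps_per_chrom)) < freqs[None, :]).astype(np.uint8)
        paths = _mosaic_paths(n_hap, pos, n_founders, mosaic_segment_mean, rng)
        H = pool[paths, np.arange(n_snps_per_chrom)[None, :]]
        pooled = H.mean(axis=0)
        keep = np.minimum(pooled, 1 - pooled) >= maf_floor
        if keep.sum() < 2:
            raise ValidationError(
                f"maf_floor {maf_floor} leaves < 2 SNPs on {chrom!r}; lower it"
            )
        pos, H = pos[keep], np.ascontiguousarray(H[:, keep])
        chroms[chrom] = ChromosomeHaplotypes(pos, bp_to_cm(pos, recomb_rate), H)
    return HaplotypeSet(layout=layout, populations=pop_arr, chromosomes=chroms)


def implant_sweep(haps: HaplotypeSet, spec: SweepSpec, seed: int = 0) -> HaplotypeSet:
    """Implant a star-like hard sweep; returns a new HaplotypeSet.

    Within the region, one randomly chosen haplotype of the target population
    becomes the founder; every target-population haplotype is independently
    replaced by the founder with probability ``founder_frequency``.  Other
    populations and all flanking sequence are untouched.
    """
    target = haps.population_indices(spec.target_population)
    if spec.chromosome not in haps.chromosomes:
        raise ValidationError(f"chromosome {spec.chromosome!r} not in haplotype set")
    if spec.end > haps.layout.length(spec.chromosome):
        raise ValidationError("sweep region beyond chromosome end")
    ch = haps.chromosomes[spec.chromosome]
    in_region = (ch.positions - 1 >= spec.start) & (ch.positions - 1 < spec.end)
    if in_region.sum() < 10:
        raise ValidationError(
            f"sweep region contains {int(in_region.sum())} SNPs; needs >= 10"
        )
    rng = np.random.default_rng(derive_seed(seed, "sweep"))
    founder_row = int(rng.choice(target))
    replace = rng.random(target.size) < spec.founder_frequency

    out = haps.copy()
    H = out.chromosomes[spec.chromosome].haplotypes
    founder_alleles = H[founder_row, in_region].copy()
    for row in target[replace]:
        H[row, in_region] = founder_alleles
    return out


def make_trait_table(populations, traits, linked_locus_scores: dict[str, float],
                     effect_size: float, noise_sd: float, seed: int = 0,
                     linked_trait: str | None = None) -> pd.DataFrame:
    """Breed-level trait means with one trait linked to a locus score.

    The designated trait (default: the first) equals ``effect_size`` times
    the per-population locus score plus Gaussian noise; the remaining traits
    are independent noise.  Needs >= 3 populations so pairwise-difference
    correlations downstream are defined.
    """
    populations = list(populations)
    traits = list(traits)
    if len(populations) < 3:
        raise ValidationError("trait table needs >= 3 populations")
    missing = [p for p in populations if p not in linked_locus_scores]
    if missing:
        raise ValidationError(f"no locus score for populations {missing}")
    if linked_trait is None:
        linked_trait = traits[0]
    if linked_trait not in traits:
        raise ValidationError(f"linked trait {linked_trait!r} not among traits")
    rng = np.random.default_rng(derive_seed(seed, "traits"))
    table = pd.DataFrame(index=pd.Index(populations, name="breed"), columns=traits,
                         dtype=float)
    for t in traits:
        noise = rng.normal(0.0, noise_sd, size=len(populations))
        if t == linked_trait:
            base = effect_size * np.array([linked_locus_scores[p] for p in populations])
        else:
            base = np.zeros(len(populations))
        table[t] = base + noise
    return table


def make_gwas_points(layout: GenomeLayout, traits, n_points_per_trait: int,
                     enriched_regions: PeakSet | None = None,
                     enrichment_fraction: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Trait-labelled variant positions, optionally clustered inside regions.

    For each trait, ``enrichment_fraction`` of the points are placed uniformly
    inside ``enriched_regions`` (region chosen proportional to its length) and
    the rest uniformly on the genome.  Returns a BED-like DataFrame with
    columns chrom, pos (0-based), trait.
    """
    if n_points_per_trait < 1:
        raise ValidationError("n_points_per_trait must be >= 1")
    if not (0 <= enrichment_fraction <= 1):
        raise ValidationError(
            f"enrichment_fraction must be in [0, 1], got {enrichment_fraction}"
        )
    if enrichment_fraction > 0 and (enriched_regions is None or len(enriched_regions) == 0):
        raise ValidationError("enrichment requested but no enriched regions given")
    rng = np.random.default_rng(derive_seed(seed, "gwas"))
    names = layout.names
    lengths = np.array([layout.length(c) for c in names], dtype=np.int64)
    records = []
    for t in traits:
        n_enr = int(round(enrichment_fraction * n_points_per_trait))
        n_bg = n_points_per_trait - n_enr
        if n_enr:
            regions = list(enriched_regions)
            sizes = np.array([r.size for r in regions], dtype=float)
            ridx = rng.choice(len(regions), size=n_enr, p=sizes / sizes.sum())
            for k in ridx:
                r = regions[k]
                records.append((r.chrom, int(rng.integers(r.start, r.end)), t))
        if n_bg:
            cidx = rng.choice(len(names), size=n_bg, p=lengths / lengths.sum())
            for c in cidx:
                records.append((names[c], int(rng.integers(0, lengths[c])), t))
    return pd.DataFrame(records, columns=["chrom", "pos", "trait"])
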