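"""Readers and writers for the standard formats the pipeline touches.

VCF and score-track positions are 1-based on disk; BED, GTF-derived gene
intervals and all internal intervals are 0-based half-open.  Conversion
happens only here, at the I/O boundary.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .core import (ChromosomeHaplotypes, GenomeLayout, HaplotypeSet, Peak,
                   PeakSet, ScoreTrack, ValidationError, WindowTrack)
from .ehh import bp_to_cm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Population map / chromosome lengths / trait tables
# ---------------------------------------------------------------------------


def read_population_map(path) -> dict[str, str]:
    """Two-column whitespace text: sample <tab> population."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"bad population-map line: {line!r}")
            out[parts[0]] = parts[1]
    return out


def write_population_map(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in mapping.items():
            fh.write(f"{sample}\t{pop}\n")


def read_chrom_lengths(path) -> GenomeLayout:
    """Two-column text: chromosome <tab> length (bp)."""
    chroms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            chroms.append((name, int(length)))
    return GenomeLayout(tuple(chroms))


def write_chrom_lengths(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_trait_table(path) -> pd.DataFrame:
    """TSV with a `breed` column and one column per trait."""
    table = pd.read_csv(path, sep="\t")
    if "breed" not in table.columns:
        raise ValidationError("trait table must have a 'breed' column")
    table = table.set_index("breed")
    if table.index.duplicated().any():
        raise ValidationError("duplicate breeds in trait table")
    return table.astype(float)


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="breed")


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------


def read_phased_vcf(path, population_map: dict[str, str],
                    layout: GenomeLayout | None = None,
                    recomb_rate: float = 1.0) -> HaplotypeSet:
    """Load a phased, biallelic, fully genotyped VCF into a haplotype matrix.

    Every sample must appear in ``population_map``; unphased or missing
    genotypes abort with the offending record named; multi-allelic records
    are skipped with a logged count.  The layout defaults to the VCF header
    contigs (falling back to the last position seen per chromosome).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in population_map]
    if missing:
        raise ValidationError(f"samples without a population label: {missing}")
    populations = np.array(
        [population_map[s] for s in samples for _ in range(2)], dtype=object
    )

    per_chrom: dict[str, list] = {}
    n_multi = 0
    last_pos: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        chrom, pos = v.CHROM, v.POS
        if last_pos.get(chrom, 0) >= pos:
            raise ValidationError(f"positions out of order at {chrom}:{pos}")
        last_pos[chrom] = pos
        row = np.empty(2 * len(samples), dtype=np.uint8)
        for si, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[2]
            if a < 0 or b < 0:
                raise ValidationError(f"missing genotype at {chrom}:{pos} sample {samples[si]}")
            if not phased:
                raise ValidationError(f"unphased genotype at {chrom}:{pos} sample {samples[si]}")
            row[2 * si], row[2 * si + 1] = a, b
        per_chrom.setdefault(chrom, []).append((pos, row))
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    if not per_chrom:
        raise ValidationError("VCF contains no usable biallelic records")

    if layout is None:
        header_sizes = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
        chroms = []
        for chrom in per_chrom:
            size = header_sizes.get(chrom) or last_pos[chrom]
            chroms.append((chrom, int(size)))
        layout = GenomeLayout(tuple(chroms))

    chrom_data = {}
    for chrom, rows in per_chrom.items():
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        H = np.vstack([r[1] for r in rows]).T  # (haplotypes, snps)
        chrom_data[chrom] = ChromosomeHaplotypes(pos, bp_to_cm(pos, recomb_rate), H)
    return HaplotypeSet(layout=layout, populations=populations,
                        chromosomes=chrom_data, sample_names=samples)


def write_phased_vcf(haps: HaplotypeSet, path) -> None:
    """Write the haplotype set as a minimal phased VCF (GT with '|').

    Consecutive haplotype rows (2i, 2i+1) form one diploid sample; both rows
    of a sample must carry the same population label.
    """
    n_hap = haps.n_haplotypes
    if n_hap % 2 != 0:
        raise ValidationError("VCF output needs an even haplotype count (diploids)")
    counters: dict[str, int] = {}
    samples = []
    for i in range(0, n_hap, 2):
        if haps.populations[i] != haps.populations[i + 1]:
            raise ValidationError("haplotype pair spans two populations")
        pop = haps.populations[i]
        counters[pop] = counters.get(pop, 0) + 1
        samples.append(f"{pop}_{counters[pop]}")
    if haps.sample_names:
        samples = haps.sample_names
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in haps.layout.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, ch in haps.chromosomes.items():
            H = ch.haplotypes
            for j in range(ch.n_snps):
                gts = "\t".join(
                    f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(n_hap // 2)
                )
                fh.write(f"{chrom}\t{ch.positions[j]}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def filter_variants(haps: HaplotypeSet, maf_min: float = 0.05,
                    call_rate_min: float = 0.8) -> HaplotypeSet:
    """Drop SNPs below a pooled MAF or per-site call-rate threshold.

    Mirrors the study's input filter (MAF >= 5%, genotyping rate >= 80%).
    Matrices loaded here are complete, so the call-rate filter only bites on
    matrices carrying an explicit missing sentinel; it is applied for
    contract completeness.
    """
    if not (0 <= maf_min <= 1) or not (0 <= call_rate_min <= 1):
        raise ValidationError("thresholds must lie in [0, 1]")
    out_chroms = {}
    n_removed = 0
    for chrom, ch in haps.chromosomes.items():
        H = ch.haplotypes
        called = H <= 1
        call_rate = called.mean(axis=0)
        with np.errstate(invalid="ignore"):
            alt = np.where(called, H, 0).sum(axis=0) / np.maximum(called.sum(axis=0), 1)
        maf = np.minimum(alt, 1 - alt)
        keep = (maf >= maf_min) & (call_rate >= call_rate_min)
        n_removed += int((~keep).sum())
        out_chroms[chrom] = ChromosomeHaplotypes(
            ch.positions[keep], ch.genetic_pos[keep],
            np.ascontiguousarray(H[:, keep]),
        )
    if all(ch.n_snps == 0 for ch in out_chroms.values()):
        raise ValidationError("variant filter removed every SNP")
    logger.info("variant filter removed %d SNPs", n_removed)
    return HaplotypeSet(layout=haps.layout, populations=haps.populations.copy(),
                        chromosomes=out_chroms, sample_names=haps.sample_names)


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------


def read_score_track(path):
    """Read a TSV score track; dispatches on column count.

    Point form: chrom, pos, score (pos 1-based).  Window form: chrom, start,
    end, score (0-based half-open).  Unsorted rows are sorted with a notice.
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if set(cols) >= {"chrom", "pos", "score"} and "start" not in cols:
        df = df[["chrom", "pos", "score"]]
        if not df.groupby("chrom", sort=False)["pos"].apply(
                lambda s: s.is_monotonic_increasing).all():
            logger.info("sorting unsorted point track %s", path)
            df = df.sort_values(["chrom", "pos"], kind="stable")
        return ScoreTrack(df.reset_index(drop=True))
    if set(cols) >= {"chrom", "start", "end", "score"} and "pos" not in cols:
        df = df[["chrom", "start", "end", "score"]]
        if not df.groupby("chrom", sort=False)["start"].apply(
                lambda s: s.is_monotonic_increasing).all():
            logger.info("sorting unsorted window track %s", path)
            df = df.sort_values(["chrom", "start"], kind="stable")
        return WindowTrack(df.reset_index(drop=True))
    raise ValidationError(
        f"cannot interpret track columns {cols}; need chrom/pos/score or "
        "chrom/start/end/score (not both pos and start)"
    )


def write_score_track(track, path) -> None:
    track.data.to_csv(path, sep="\t", index=False)


def write_xpehh_table(result, path) -> None:
    """Full per-SNP XP-EHH table (chrom, pos, ihh_a, ihh_b, raw, std, valid)."""
    result.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed_peaks(path, layout: GenomeLayout) -> PeakSet:
    """BED3+ file into a PeakSet (name column kept as the comparison label)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            comps = frozenset(name.split(",")) - {""} if name else frozenset()
            peaks.append(Peak(chrom, start, end, comparisons=comps))
    return PeakSet(peaks, layout).sorted()


def write_bed_peaks(peaks: PeakSet, path, sidecar: bool = True) -> None:
    """BED with integer scores (|score| x 100, truncated) plus an exact TSV.

    BED's score column is integer-valued; the exact maximum |score| is
    preserved in a ``.scores.tsv`` sidecar next to the BED file.
    """
    with open(path, "w") as fh:
        for p in peaks:
            name = ",".join(sorted(p.comparisons)) or p.statistic or "."
            score = 0 if np.isnan(p.max_score) else min(1000, int(p.max_score * 100))
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\n")
    if sidecar:
        peaks.to_frame().to_csv(str(path) + ".scores.tsv", sep="\t", index=False)


def read_gwas_points(path) -> pd.DataFrame:
    """4-column BED-like points: chrom, start, end, trait -> chrom, pos, trait."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "trait"])
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"], "trait": df["trait"]})


def write_gwas_points(points: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in points.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.trait}\n")


# ---------------------------------------------------------------------------
# GTF genes
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gtf_genes(path) -> pd.DataFrame:
    """Gene features from a GTF: chrom, start (0-based), end, gene_id.

    Only ``gene`` feature rows are used; malformed records are skipped with a
    logged warning.  GTF is 1-based inclusive; converted to half-open here.
    """
    records = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                n_bad += 1
                continue
            if parts[2] != "gene":
                continue
            m = _GENE_ID_RE.search(parts[8])
            if m is None:
                n_bad += 1
                continue
            try:
                start, end = int(parts[3]) - 1, int(parts[4])
            except ValueError:
                n_bad += 1
                continue
            records.append((parts[0], start, end, m.group(1)))
    if n_bad:
        logger.warning("skipped %d malformed GTF records", n_bad)
    return pd.DataFrame(records, columns=["chrom", "start", "end", "gene_id"])


def write_permutation_results(results, path) -> None:
    """One row per PermutationResult (mapping label -> result, or a list)."""
    if isinstance(results, dict):
        rows = [r.as_dict() for r in results.values()]
    else:
        rows = [r.as_dict() for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
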