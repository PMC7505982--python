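# Methods

## Model and procedure

The pipeline detects and compares between-population selective sweeps from
phased haplotypes. EHH around a core SNP is the probability that two
haplotypes sampled without replacement are identical over the interval from
the core to a flanking SNP, computed by refining the haplotype identity
partition SNP by SNP; the core SNP itself is part of the prefix, and EHH at
zero distance is defined as 1. iHH is the trapezoidal integral of EHH over
genetic distance with both arms summed; each arm is truncated at — and
includes the trapezoid reaching — the first SNP whose EHH falls below the
cutoff, or runs to the chromosome end. Truncation includes that final
trapezoid so iHH is continuous as the cutoff goes to zero; stopping before
it would make iHH jump when a SNP crosses the cutoff.

XP-EHH uses whole-population EHH on each side (no split by core allele):
the statistic contrasts populations, not alleles, so each population's full
haplotype sample enters its iHH. Raw scores ln(iHH_A/iHH_B) are
standardized to mean 0 and sample sd 1 (n−1 denominator) pooled over all
SNPs genome-wide per pair; per-chromosome standardization was rejected
because it would decouple chromosomes that share one demographic history.
SNPs where either iHH is zero are flagged invalid, excluded from
standardization, and dropped from downstream tracks.

Genetic positions default to a flat 1 cM/Mbp map, the standard assumption
when no species recombination map is trusted; the rate is a parameter of
`bp_to_cm` and of the VCF reader.

## Smoothing and peak calling

Per-SNP scores are smoothed with a centered sliding mean over a SNP-count
window, truncated at chromosome ends and never mixing chromosomes. Sliding
was chosen over non-overlapping blocks because it preserves per-SNP
resolution for peak boundary placement; a block mode is exposed
(`mode="block"`) for emulating block-wise averaging, and the magnitude can
be smoothed instead of the signed score (`absolute=True`). Window-interval
tracks (e.g. ingested XP-CLR 50-kb windows) are smoothed by averaging each
window with its `flank` neighbours either side (default workflows use 3).

Peak calling is hysteresis thresholding: seeds require a locus strictly
above t_high, extension keeps loci at or above t_low, so the boundary locus
is the last one ≥ t_low. Two seed excursions inside one corridor form one
peak. For point tracks the peak spans the outermost qualifying SNP
positions (a SNP at 1-based pos occupies [pos−1, pos)); midpoint-to-
neighbour boundaries were rejected as less defensible without a model of
inter-SNP score behaviour. Defaults follow the established practice for
these metrics: 3.5/1.5 on smoothed |XP-EHH|, 4.5/2.5 on smoothed XP-CLR
windows. Merging across comparisons is transitive with ≥ 1 shared bp;
book-ended intervals do not merge. All intervals are 0-based half-open
internally and in BED output.

## Permutation nulls

All enrichment statistics share one null: regions of identical number and
size are placed independently and uniformly on the genome — chromosome
chosen with probability proportional to (length − size + 1) among
chromosomes that fit, start uniform. The resampled set is always the query
(the peak set under test); reference intervals or variant points stay
fixed, preserving their number and genomic distribution. Sampled regions
may overlap each other and are not excluded from any mask (a mask hook
would be the natural extension; none is applied by default because the
modelled genomes have no assembly gaps).

Two p-values are reported for every test: the two-sided normal-tail
probability of Z = (observed − mean)/sd (sample sd over permutations), and
the ecdf-based two-tailed empirical p = max(2·min(F(obs), 1−F(obs)),
1/n_perm), with F the fraction of permuted values ≤ observed. The floor
keeps empirical p-values nonzero at finite permutation counts. Zero
permutation spread is flagged degenerate: Z and the normal p are NaN, the
empirical p is still defined. Default permutation counts are 100 for
cross-set overlap tests, 1000 for GWAS enrichment, and 5000 for trait
correlations — the scales at which these tests are conventionally run.

The threshold grid scan calls and merges peaks per threshold pair for both
families and tests every combination; cell seeds derive deterministically
from (seed, row, column) so any cell reproduces as a single run.
Threshold selection minimizes the expected number of chance overlaps (the
permutation mean), tie-broken by larger Z, then larger observed count.

GWAS enrichment counts peaks containing ≥ 1 variant of a trait; traits with
fewer than 300 variants are skipped, the conventional floor below which the
variant set is too sparse for a stable overlap count.

## Trait association

For each locus, the median standardized XP-EHH per ordered breed pair
(median of SNP scores inside the locus; even counts average the central
pair) is correlated with the pairwise difference of breed trait means,
oriented identically (A,B) ↔ mean_A − mean_B. Raw standardized scores,
not smoothed ones, feed the median by default; smoothing is a display and
peak-calling device, configurable here. The null draws one same-size
random region per permutation, shared across traits within that permutation
so per-trait nulls are comparable; regions landing on no SNPs for some pair
are redrawn (bounded retries). Bonferroni multiplies by the number of loci
tested per trait; no cross-trait correction is applied, and the trait count
is recoverable from the output for readers who want the stricter factor.

## Liftover

UCSC chain files are parsed with full arithmetic validation (block and gap
sums must equal the header spans, named by chain id on failure). An
interval maps through the single highest-scoring overlapping chain — no
split mappings, mirroring default liftOver behaviour — and is rejected when
the aligned fraction of its bases falls below `min_match` (default 0.95; a
chain-building identity setting is a different knob and deliberately not
conflated with this one). Minus-strand query coordinates are converted to
plus-strand on output. Plus/plus chains can be inverted exactly, which the
tests use for round-trip identity checks.

## Synthetic data

The generator produces the statistical structure the analysis assumes, not
a demographic model. Neutral haplotypes are mosaics of a shared pool of
founder haplotypes (default 24): copying templates switch at rate
1/`mosaic_segment_mean` per bp (default 100 kb, geometric segment lengths),
giving haplotype identity that decays with distance — the one property
EHH-based statistics need from a null — while both populations draw from
the same pool so no between-population signal exists. SNP positions are
uniform, deduplicated, sorted; founder allele frequencies are uniform on
(0.1, 0.9), and sites whose pooled minor-allele fraction falls below the
floor (default 0.05, matching the conventional MAF ≥ 5% input filter) are
dropped, so realized SNP counts sit slightly below the request. A full
coalescent simulator was rejected as unnecessary for these statistics and
much slower at the scales used.

Sweeps are star-like founder replacements: within the region, each
target-population haplotype is independently replaced by one randomly
chosen founder haplotype with probability `founder_frequency`. This
produces exactly the haplotype-homozygosity contrast XP-EHH targets with a
single interpretable parameter; there is no frequency trajectory, no soft
sweep, no partial recombination onto the swept background. Trait tables
set one designated trait to effect_size × per-population locus score plus
Gaussian noise, other traits pure noise; GWAS point sets place a chosen
fraction of each trait's points uniformly inside given regions (region
chosen proportional to length) and the rest uniformly on the genome.

What passing tests therefore show: the statistics are computed correctly,
the permutation machinery is calibrated (uniform null p-values), and hard
sweeps of the implanted kind are recovered. What they do not show:
robustness to soft or incomplete sweeps, realistic recombination-map
heterogeneity, genotyping error, phasing error, or ascertainment — real
data properties outside the generator's scope.

## Numerical choices and problem sizes

- EHH cutoff 0.05 (the common default for iHH truncation); configurable.
- All generators and tests are pure functions of (parameters, seed);
  substreams derive from a root seed with named keys, so adding a stage
  never perturbs another stage's stream.
- Degenerate inputs fail fast with `ValidationError` (constant scores in
  standardization, t_high ≤ t_low, regions larger than every chromosome,
  < 3 breed pairs for correlations), except where a defined fallback exists
  (identical populations give raw ≡ 0 with undefined standardized scores,
  flagged by warning).
- The test suite runs the sweep-recovery study at 50 haplotypes per
  population, one 10-Mb chromosome, ~20k SNPs, a 0.5-Mb sweep at founder
  frequency 0.9, and a 101-SNP smoothing window — the same fraction of the
  SNP count as a 1000-SNP window is of a multi-million-SNP panel.
  Calibration checks use 500 replicates at 200 permutations each, with the
  overlap design sized (300 query regions against a ~25%-coverage
  reference) so the discrete overlap count is well resolved and the
  empirical p can approach uniformity.
- `scripts/acceptance.py` uses a two-chromosome 20-Mb genome, four breeds
  of 30 haplotypes, four implanted sweeps, 100 overlap permutations, 1000
  GWAS permutations, and 5000 trait permutations.

## Known limitations

- Whole-genome pooled standardization assumes sweeps occupy a small
  fraction of SNPs; at desk scale a heavily swept genome inflates the sd
  and shrinks standardized peaks (visible when many sweeps share one pair).
- The GWAS peak-count statistic saturates when peaks are large relative to
  the genome and variants dense; it is informative at realistic
  peak-to-genome ratios.
- Liftover maps each interval through one chain; peaks genuinely split
  across chains are reported unmapped rather than fragmented.
- The window-track ingestion path assumes non-overlapping, sorted windows
  per chromosome, as produced by standard window-based scans.
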