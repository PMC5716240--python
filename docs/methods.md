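# Methods

## Model and procedure

`poolfst` estimates inter-group differentiation per SNP from pooled read
counts. For collections *i* and *j* the variant-allele frequency of a group
is its variant coverage divided by its total nucleotide (A+C+G+T) coverage;
indel counts are carried through the tables but excluded from all frequency
arithmetic, since they constitute neither reference nor variant nucleotide
coverage. The combined frequency `p̂` is coverage-weighted — the coverage of
the variant in both collections over the total coverage in both — not the
unweighted mean of the two group frequencies. From the group frequencies the
per-site decomposition is

    α_g  = 2 p̂_g (1 − p̂_g)
    b_s  = (n_i α_i + n_j α_j) / (n_i + n_j − 1)
    a_s  = [4 n_i (p̂_i − p̂)² + 4 n_j (p̂_j − p̂)² − b_s] / (2 · 2 n_i n_j/(n_i + n_j))

with `F_ST(s) = a_s/(a_s + b_s)` and, for a gene with m SNPs, the
ratio-of-sums aggregate `F_ST(g) = Σ a_s / Σ (a_s + b_s)`. The ratio of sums
is not interchangeable with the mean of per-site ratios: two SNPs with
components (0.1, 0.1) and (0.1, 0.7) give 0.2 by ratio-of-sums and 0.3125 by
mean-of-ratios. `α` doubles as the Hardy–Weinberg expected heterozygosity
reported per sex. `b_s ≥ 0` and `a_s + b_s ≥ 0` hold for all legal inputs;
`a_s` itself may be negative under sampling noise and is reported as
computed — clamping negative components would bias every gene sum upward.

`n_i`/`n_j` are mosquitoes sampled per collection, not read counts. The
default is 24 per sex: 12 mosquitoes per pool × 2 biological replicates
whose counts are summed before estimation. Both are configurable; with
females fixed and males at 0.5 the true-frequency site F_ST is 0.4783 at
n = 12 and 0.4894 at n = 24, so the choice moves fully-sex-linked sites by
about 0.01.

## Filtering

Sites pass, in order:

1. **Coverage** — every replicate of both sexes carries ≥ 15 nucleotide
   reads (the readcount producer's minimum-coverage convention; the value is
   `min_coverage` in the configuration).
2. **Replicate concordance** — at least one sex shows a shared
   non-reference base with ≥ 1 read in each of its replicates. The rule is
   deliberately *any-group*: at a fully sex-linked site females are fixed
   for the reference and carry no variant reads at all, so demanding a
   shared variant of both sexes would discard precisely the sites the scan
   exists to find. `concordance_mode="coverage"` relaxes the rule to
   coverage only.
3. **Monomorphic removal** — sites where both sexes place 100% of their
   coverage on one identical base (equal to the reference or not) carry no
   differentiation signal and are dropped, with their count reported.

Multi-allelic sites are retained and collapse to reference vs the major
non-reference base (summed over both groups; ties break A<C<G<T) for the
estimator; full per-base counts stay in the pooled output. Base quality is
assumed enforced upstream by the readcount producer, and PCR duplicates are
not modelled. A filter summary (category → site count) is always written,
and the retained/dropped categories partition the input exactly.

## Coordinates and formats

All internal coordinates are 1-based closed, matching the readcount position
column; BED input (0-based half-open) is converted on parsing, and BED and
GFF3 encodings of the same span produce identical internal intervals. A SNP
maps to every gene whose span (UTRs and introns included, boundaries
inclusive) contains it — overlapping genes each receive the site. Interval
lookup uses an interval tree per chromosome. Output tables are TSV with
`#` comment headers recording the tool version and full parameter set;
floats print with 6 significant digits and row order is deterministic, so
identical runs are byte-identical.

## Inference layer

* **Classification**: genes with defined `F_ST(g) ≥ 0.100` (inclusive) are
  flagged; undefined values (degenerate denominators, tolerance 1e-12) are
  never flagged and are tallied separately.
* **Male heterozygosity excess**: one-sided test of mean gene-wise male
  H_exp exceeding female H_exp within a region. Default is Welch's unpaired
  t-test; a paired-by-gene variant exists because the two values of a gene
  are naturally paired. Gene-wise H_exp is the arithmetic mean over the
  gene's retained SNPs, and region membership is by gene midpoint.
* **Regions**: defaults are the whole of chromosome 1 and its central third.
  The central third also serves as the default proxy for the
  M-locus-proximal region, which has no published coordinates; any interval
  can be configured.
* **Chromosome enrichment**: per chromosome, a one-sided Fisher's exact test
  of the 2×2 table (this chromosome vs others) × (flagged vs not), i.e. an
  exact hypergeometric tail.
* **Category over-representation**: upper-tail hypergeometric p-value per
  functional category, with the gene→category map supplied by the user
  (orthology/annotation assignment is out of scope).
* Raw p-values are reported by default; Benjamini–Hochberg adjustment is
  optional for the per-chromosome and per-category batteries.
* **Between-population F_ST** reuses the same estimator with the two groups
  being the same sex of two populations (female–female, male–male), after
  intersecting sites and re-applying the cross-population monomorphic rule.
* **Beta diagnostics**: gene-wise F_ST values, clamped into (ε, 1−ε) with
  ε = 1e-6, are fit by method of moments
  (`α̂ = m(m(1−m)/v − 1)`, `β̂ = α̂(1−m)/m`); a Kolmogorov–Smirnov distance
  against the fitted density is reported as a diagnostic only, not a test.

Exact tests and t-tests are computed by `scipy.stats`; the test suite checks
them against independent exact-fraction enumeration oracles.

## Synthetic data generator

The generator emulates pooled exome sequencing of one population: two sexes,
12 mosquitoes per pool, two biological replicates per sex (each replicate an
independent pool), three chromosomes of 100 non-overlapping 2 kb genes
spaced 1 kb apart, 5 SNPs per gene.

* **Background SNP**: one population frequency `p ~ Beta(0.3, 5)` shared by
  the sexes, giving mean `H_exp ≈ 0.09` — the order observed in real pooled
  mosquito exomes. Each replicate pool draws `2 × 12` allele copies
  binomially at `p` (finite-pool noise), then reads at the realised pool
  frequency.
* **Sex-linked SNP** (inside the configured region, with probability
  `d = 0.8`, when recombination is suppressed): X and Y haplotypes carry
  divergent frequencies, by default a fixed difference (`p_X = 0`,
  `p_Y = 1`). Males are modelled as obligate Mm heterozygotes: a male pool
  draws 12 X copies at `p_X` plus 12 Y copies at `p_Y`, so at a fixed
  difference the male pool frequency is exactly 0.5 with no finite-pool
  variance, while females draw 24 X copies. Partial divergence is available
  through a frequency offset.
* **Reads**: depth per site and replicate is negative-binomial with mean 180
  (`aaa_like`) or 261 (`senaae_like`) and dispersion 3, giving the
  right-skewed, median-below-mean coverage profile of exome capture; each
  read miscalls with probability 1e-3, redistributed uniformly over the
  other three bases (consistent with Q30-filtered input). Equal DNA
  contribution per mosquito is assumed.

Presets: `aaa_like` places the sex-linked region on the central third of
chromosome 1 (a clustered, M-locus-proximal architecture); `senaae_like`
spans 90% of chromosome 1 with background diversity scaled ×1.3 in both
sexes (chromosome-wide X–Y differentiation); `null` has no sex-linked sites.
One root seed drives deterministically spawned child streams per stage, so
identical seeds give byte-identical tables.

What the generator does **not** model: linkage disequilibrium beyond the
single region flag, recombination and pedigree structure, exome-capture
bias, mapping artefacts, allele-specific error, or indel variation.
Passing recovery tests therefore demonstrate the estimator and inference
chain behave correctly under idealised pool-seq noise — not that every
property holds for real libraries with capture and alignment artefacts.

## Problem sizes and numerical choices

Recovery and specificity checks use 100 seeded runs of the 300-gene,
1500-SNP genome at 150× mean depth — about 1.5 × 10⁵ simulated sites per
battery, enough to pin the flagged-gene rate and the mean sex-linked site
F_ST to well under the tolerances asserted, while keeping the whole suite
interactive. Undefined F_ST (denominator ≤ 1e-12) is encoded as NaN in
memory and `NA` on disk, and degenerate (0, 0) sites contribute harmlessly
to gene sums. Exhaustive exact-test validation enumerates all 2×2 tables
with total n ≤ 30 against fraction-arithmetic oracles.

## Known limitations

* The estimator is biallelic in form; multi-allelic collapse discards minor
  non-reference alleles from the frequency (not from the output counts).
* Replicate summation assumes replicates are exchangeable draws of the same
  population; systematic between-replicate batch effects would be absorbed
  into within-group heterozygosity.
* The unpaired region test treats genes as independent; physically linked
  genes inside a non-recombining region violate this, so regional p-values
  are descriptive rather than strictly calibrated.
* Sliding-window statistics and likelihood-based allele-frequency models
  are out of scope.
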