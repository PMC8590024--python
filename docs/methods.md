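# Methods

This note documents the statistical models implemented in `estuarscan`, the
conventions and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the design decisions taken where the
underlying procedures are commonly left underspecified.

## Coordinates, genotypes and filters

All in-memory coordinates are 0-based half-open; VCF (1-based) is converted
at the file boundary and BED is emitted natively. Genotypes are diploid codes
0/1/2 (hom-ref / het / hom-alt) with −1 for uncalled; multi-allelic VCF
records are skipped by default because every downstream statistic is defined
on biallelic SNPs (an opt-in `multiallelic="split"` emits one row per
alternate allele, treating genotypes carrying a *different* alternate as
missing; note split rows share a position, so the strictly-increasing
position invariant only holds for the default mode).

Variant filtering follows GATK-style hard filters — a SNP is removed iff
QD < 2.0 or FS > 60.0 or MQ < 40.0 (indels: QD/FS only); all comparisons are
strict, and variants with missing annotations fail closed by default.
Site-level filtering retains SNPs with pooled minor-allele frequency
strictly > 0.05 and genotype call rate strictly > 0.8. The call-rate
threshold is interpreted as per-variant genotype completeness ("integrity");
this is an assumption, as the corresponding plink-style parameter name is
ambiguous.

## Windowed statistics

Windows are 100 kb sliding with a 10-kb step (defaults; any size ≥ step is
accepted), starting at 0 per chromosome; by default only full windows are
kept, with an option to truncate trailing windows.

- π per site uses the unbiased pairwise estimator 2x(n_s−x)/(n_s(n_s−1)) with
  per-site called-allele counts n_s; windows report the sum divided by window
  length L (per-bp). Sites with fewer than 2 called alleles are skipped.
- θ_w = (S/a₁)/L. The window-level allele count n used for a₁ and the D
  constants is 2 × (number of samples with within-window call rate ≥ 0.9),
  with sites restricted to those samples — simpler and more stable than
  per-site n. With complete data this reduces to 2 × sample size, which is
  the fast vectorized path; with missing data the per-window rule is applied
  exactly.
- Tajima's D uses the 1989 constants computed from n and the *window sums*
  (π̂ as summed per-site mean pairwise differences, not per-bp). D is
  undefined (NaN, never an exception) when S = 0 or n < 4.
- FST is the Hudson estimator in the Bhatia ratio-of-sums form, with the
  finite-sample correction p(1−p)/(n−1) per population. Sites monomorphic in
  both populations (or with < 2 called alleles in either) are excluded;
  windows with ΣD_i = 0 are NaN. Negative values are reported as computed —
  clamping window estimates at 0 would bias genome-wide averages upward.
  The estimator choice matters: absolute window values are not comparable
  across different FST estimators, so scans should use a single estimator
  throughout.
- LD r² is the squared Pearson correlation of genotype dosages (0/1/2)
  across individuals — the Rogers–Huff composite measure, appropriate for
  unphased data and deterministic (no EM haplotyping). Pairs are formed
  within a chromosome up to 500 kb (default), complete-case per pair; pairs
  monomorphic in the complete-case subset are skipped. The decay curve bins
  distances (100-bp bins by default) and the half-decay distance is the
  midpoint of the first bin whose mean r² falls to half the maximum bin
  mean — so the resolution of the half-decay estimate is one bin width.

## Composite sweep scan

Candidate windows must (1) have FST at or above the top-1% empirical
threshold in *both* of two population-pair comparisons, and (2) sit at or
below the 5% genome-wide quantile of that window's Tajima's D in at least
one of the populations ("valley"). Both quantiles are exposed
(`q`, `valley_q`). Numerical conventions:

- The outlier threshold takes exactly m = max(⌊n(1−q)⌋, 1) windows: the
  threshold is the (n−m)-th ascending value and everything ≥ it is an
  outlier, so "top 1%" is an exact count and ties at the threshold are all
  included. With q = 0 every window is an outlier.
- "Valley" has no canonical numeric definition; a genome-wide per-population
  lower quantile (default 5%) is used. Lowering `valley_q` can only shrink
  the retained set (monotone).
- Outlier overlap across the two pairs is identity intersection on the shared
  window grid; mixed grids are rejected.
- Surviving windows overlapping or within one step (`max_gap`, default
  10 kb) are merged into maximal regions; genes overlapping a region by
  ≥ 1 bp are attached (no promoter extension at this stage).

The scan detects sweeps differentiating the shared population of the two
pairs (e.g. a southern population against both middle and northern); a sweep
private to a non-shared population elevates only one pair and is by design
not reported.

## Heterozygosity classification and non-synonymous gene ratios

A SNP is highly heterozygous in a population when strictly more than half of
its genotyped individuals are heterozygous; "A-only" means highly
heterozygous in A and **not** in B (B's het fraction ≤ 0.5, not "zero hets" —
the symmetric complement of the > 0.5 rule). The fold ratio is the ratio of
the two exclusive totals, reported to two decimals. Per individual, the
non-synonymous gene ratio is (genes carrying ≥ 1 non-synonymous non-reference
genotype) / (genes carrying ≥ 1 non-reference genotype) × 100; the
denominator choice (genes with any variant in that individual) is a
documented convention, as the quantity is usually reported without one.
Individuals with an empty denominator are excluded from population
mean ± SEM summaries.

Group comparisons use two-sided Wilcoxon tests: rank-sum (Mann–Whitney,
normal approximation with tie correction; exact available) for unpaired
designs and signed-rank for paired designs. Degenerate all-tied inputs
return p = 1. The unpaired rank-sum is the default for population
comparisons since the compared groups are independent samples.

## Differential expression and HP/LP classification

DE testing is a light-weight negative-binomial Wald test rather than a wrap
of a published package, keeping the pipeline self-contained; externally
computed DE tables can be substituted. Per contrast:

- size factors are DESeq-style median-of-ratios (genes containing a zero are
  excluded from the geometric reference). This carries the usual assumption
  that most genes are not differentially expressed; a strongly asymmetric DE
  fraction biases size factors and shrinks estimated fold changes.
- dispersion is a pooled per-gene method-of-moments estimate
  α = (v − m)/m² from the two groups (weights n_g − 1), floored at 1e-8.
- the Wald statistic compares log normalized group means with delta-method
  variance (1/m + α)/n per group and a t reference with Welch–Satterthwaite
  degrees of freedom; the t reference keeps null p-values close to uniform
  at n = 5 per group (verified by simulation, KS distance ≈ 0.02).
  A pseudo-mean of 0.5 keeps logs finite when one group is all zero; genes
  with zero counts in both groups are excluded (NaN).
- multiple testing uses Benjamini–Hochberg step-up (via statsmodels), NaNs
  passed through.

Genes enter the analysis when they have ≥ 10 reads in strictly more than 90%
of samples. A gene is **HP** iff its BH-adjusted p is < α (default 0.01) in
the habitat contrast of *both* populations of origin; all other tested genes
are LP, and genes testable in only one contrast are LP with a flag
(conservative). The plasticity score is the mean |log2FC| across the two
contrasts — a simple magnitude summary, since "transcriptional plasticity" is
not usually given a formula.

Gene regions are strand-aware: upstream = 5′ flank, downstream = 3′ flank
(default flank 5 kb, configurable — flank length is a free parameter of this
analysis and results should be reported alongside it), genic = gene body,
truncated at chromosome bounds. Mean per-site Hudson FST is computed per
gene per region from single-site FST values; empty regions are NaN and drop
out of the tests. HP-vs-LP comparisons use the unpaired rank-sum test per
region class (plus the classes combined), and the genome-wide
genic-vs-intergenic comparison is a per-gene paired signed-rank of genic FST
against the mean of the two flanks.

## k-mer genome size

k is the smallest odd integer with 4ᵏ/G > 200 for a genome-size prior G.
Peak detection smooths the histogram with a centered moving average of width
3 (deterministic), takes the first local minimum as the error cutoff and the
two largest local maxima above it as the heterozygous and homozygous peaks
(ties broken toward lower depth; the deeper peak is homozygous). K_num sums
depth × count strictly above the error cutoff — error k-mers are excluded by
construction, a rule that is usually left implicit — and
G = K_num / homozygous-peak depth; the homozygous peak is used as the
divisor. C-value scaling is simple proportionality, reported to 0.1 Mb.
T = Ks/(2μ) converts synonymous divergence to time given a per-year mutation
rate.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) with independent RNG
streams per component, so adding one block never shifts another's draws.

- **Genotypes**: Balding–Nichols — ancestral frequency p ~ U(0.05, 0.95) per
  SNP, population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (E[FST] = F),
  genotypes Binomial(2, p_pop) per individual. SNP positions are uniform
  without replacement; sites are independent (no linkage). Sweep injection
  is phenomenological: inside the interval the target population has a
  fraction of sites fixed for the alternate allele (frequency differential +
  diversity reduction; default 0.7) and a fraction converted to singleton
  heterozygotes (site-frequency skew; default 0.3). This exercises the
  scan's decision rules with an analytic FST target; it is not a selection
  simulation and carries no hitchhiking/LD structure.
- **Coalescent**: standard neutral constant-size coalescent via msprime
  (n haploid lineages, Ne = 1, ploidy 1, infinite-sites binary mutations at
  rate θ/2 per unit coalescent time), giving the closed-form calibration
  targets E[S] = θa₁ and E[π̂] = θ used to validate the estimators.
- **Expression**: per-gene baselines log-normal (default median 200 counts,
  log-sd 1), NB counts with gene dispersion (default 0.1), sample size
  factors U(0.7, 1.3). HP genes (default 30%) get a habitat effect of
  |log2FC| = 2 with a common random sign in both populations; LP genes get
  the effect in one population (half of them) or none. Real data differ in
  having gene-specific dispersions, correlated genes and batch structure.
- **k-mer spectra**: negative-binomial-shaped heterozygous and homozygous
  peaks with the NB mode pinned at the nominal depth (and depth/2), an error
  spike at depths 1–5, total non-error mass exactly G × depth, Poisson
  sampling noise per depth bin. Repeat-rich genomes (multi-copy peaks) are
  not emulated.

Because the generators omit linkage, selection dynamics and annotation
errors, passing tests demonstrate correctness of the estimators and decision
rules under the stated models — not robustness to the full complexity of
real resequencing data.

## Validation experiments and problem sizes

The `experiments` module (used by both the test suite and
`scripts/acceptance.py`) runs at desk scale, chosen so the full suite
completes in well under a minute per experiment while keeping Monte-Carlo
error small relative to each acceptance band:

- FST recovery: 2 × 50 diploids, 5,000 SNPs, F = 0.15 (band ±0.03).
- Coalescent calibration: n = 10, θ = 5, 2,000 replicates (S and π̂ within
  5%, mean D within ±0.1 — E[D] is slightly negative at finite n, which the
  band accommodates).
- Sweep recovery: 20 replicate genomes of 5 × 8 Mb chromosomes
  (~3,950 windows), one 50-kb sweep per chromosome targeting the southern
  population, 16,000 SNPs per chromosome, 3 × 30 diploids. The genome is
  sized so the top-1% window count comfortably covers the windows each sweep
  elevates; on a much smaller genome the 1% tail is narrower than a single
  sweep's footprint and recovery necessarily drops.
- HP/LP recovery and DE null calibration: 2,000 genes, 5 replicates per
  design cell.
- Upstream-divergence pattern: 400 genes (flank 2 kb), per-SNP baseline FST
  Beta(1.5, 8.5) (mean 0.15), upstream shift +0.05 for HP genes; 40
  replicates for power, 300 no-shift replicates for the genic null rate.
- k-mer recovery: 20 spectra at G = 5 Mb, 60× depth.

## Known limitations

- Window FST values depend on the estimator; comparisons with scans that
  used a different estimator should be made on ranks, not values.
- The LD machinery enumerates pairs in Python and is intended for
  moderate-size inputs; genome-scale LD scans should subsample loci.
- The DE test is a two-group Wald test; it has no shrinkage, no covariates
  and no outlier handling, and at very small counts it is conservative.
- The valley rule uses a marginal per-population quantile; it does not model
  spatial autocorrelation of D along the chromosome.
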