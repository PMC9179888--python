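# Methods

`selsig` detects selection signatures in diploid SNP-array genotypes of two
kinds: **within-population** signatures from runs of homozygosity (ROH
islands) and **between-population** signatures from variance in linkage
disequilibrium (varLD).  A forward-time simulator supplies panels with known
ground truth so every stage is testable end to end.

## Data model and coordinates

Genotypes live in a `GenotypePanel`: an `int8` sample × SNP matrix of
A1-allele dosages (0/1/2, `MISSING = -1`) with a marker map sorted by
(chromosome, bp position) and per-sample population labels.  Coordinates are
1-based inclusive bp internally; BED output converts to 0-based half-open.
Every statistic computed here (homozygosity, Pearson correlation) is
invariant to allele relabeling, so no strand or allele-flip handling is
attempted — a documented limitation for users who mix filesets from
different calling pipelines.  Interval lengths are measured span-style
(`end − start`), including the overlap lengths reported by the annotator.

## Quality control

Thresholds follow standard array practice: samples with > 10% missing calls,
then — recomputed on the kept samples — SNPs with > 10% missingness, minor
allele frequency below 1% (LD profile only) and Hardy–Weinberg exact-test
p < 1e-7 are removed, in that order, each SNP recorded with its first
triggering reason.  Two profiles exist because low-MAF SNPs carry real
homozygosity information: the **ROH profile** skips the MAF filter, the
**LD profile** applies it.  The HWE test is the two-sided conditional exact
test (the probability mass of all heterozygote counts no more probable than
the observed one, given the allele counts), computed by the standard
mid-out multiplicative recurrence and cached per (rare-allele count, n).
HWE is evaluated within each population separately; monomorphic SNPs return
p = 1.  `apply_qc` is idempotent, and the two-population varLD arm runs on
the intersection of the per-population LD-profile marker sets.

## Runs of homozygosity

A ROH length class is a constraint set: minimum span in bp, an allowance of
missing and heterozygous calls, at least 15 SNPs, and no inter-SNP gap above
1 Mb.  The five default classes are

| min length | allowed missing | allowed het |
|-----------:|----------------:|------------:|
| 1 Mb       | 0               | 0           |
| 2 Mb       | 0               | 0           |
| 4 Mb       | 1               | 0           |
| 8 Mb       | 2               | 0           |
| 16 Mb      | 4               | 1           |

so that genotyping artifacts do not fragment long runs while short runs stay
strict.  The reported segment set is defined exactly as the
*containment-maximal valid windows*: a window is valid when all constraints
hold and both endpoints are called homozygous (an uncalled endpoint would
inflate length); a valid window is reported unless another valid window
contains it.  This is equivalent to "maximal windows whose one-step
extension violates a constraint, minus contained windows": any one-step
extension of a valid window that is itself valid contains it, and the
budget/gap constraints are monotone under extension, so the two definitions
select the same set.  The detector exploits that the farthest feasible end
index is non-decreasing in the start index, giving a vectorized O(n) scan
per chromosome; the test suite proves exact set equality against an O(n²)
exhaustive enumeration on hundreds of random chromosomes.

**F_ROH** for a sample is the union length of its ROH divided by the
SNP-covered autosomal genome length L (sum over chromosomes of last-minus-
first SNP position).  The per-class table reports, for minimum length c, the
union of segments over *all* classes with minimum length ≥ c: a 16 Mb run
rescued by its error allowances is still a run ≥ 1 Mb.  Without this, the
strict 2 Mb class can lose coverage around a missing call that the relaxed
4 Mb class absorbs, and the expected ordering
F_ROH(16) ≤ … ≤ F_ROH(1 Mb) — the classes probe common ancestors roughly 3,
6, 12, 25 and 50 generations back — would not be guaranteed.  With the
cumulative union it holds by construction.

**ROH islands** use the 1 Mb class only (the shortest runs retain the oldest
signals): the incidence track counts, per SNP, the samples covered by at
least one run; the island threshold is the empirical top-1% order statistic
of those counts (ties included — counts are small integers, interpolation
would be fictitious), and runs of flagged SNPs merge into regions
(`merge_gap_snps = 0` by default: only adjacent flagged SNPs merge; the peak
is the leftmost maximal SNP).  Islands are computed per population on that
population's own QC'd marker set.

## Linkage disequilibrium

Pairwise LD is the squared Pearson correlation of dosages (composite
genotype LD — the data are unphased) over pairwise-complete samples, for all
same-chromosome pairs within 1000 kb.  Pairs with fewer than three complete
samples or zero variance are undefined and excluded (counted in the log).
The decay summary sorts pairs by distance and averages r² in consecutive
non-overlapping blocks of five pairs ("sliding" and "non-overlapping" are
contradictory; non-overlapping blocks are implemented).  For comparing two
populations' curves, or for plotting, `binned_decay` aggregates into
equal-width distance bins, since single 5-pair blocks are far too noisy for
a block-by-block comparison.

## varLD

For every window of 50 consecutive SNPs (step 1, never crossing a
chromosome break, anchored at the middle SNP) the two populations' windowed
LD matrices — signed pairwise-complete Pearson correlations, diagonal 1,
undefined entries 0 — are compared through their ordered eigenvalue
spectra: `raw = Σ_i |λ_A,(i) − λ_B,(i)|`.  Raw scores are standardized
genome-wide (mean 0, SD 1) and regions above the empirical top 1%, 0.1% and
0.01% thresholds are reported, adjacent flagged anchors merged, single
anchors kept as single-SNP regions; the region sets nest across thresholds
by quantile monotonicity.  Window size, LD measure (`signed_r`/`r2`) and a
direct matrix-difference comparison (`Σ|r_A − r_B|`, non-default) are
configurable, and every run logs them; the defaults are this package's
choices, fixed for reproducibility rather than inherited from any published
parameterization.

Two numerical conventions matter: identical panels give a zero-variance raw
track, which standardizes to all-zero with a degeneracy warning rather than
0/0; and chromosomes shorter than the window are skipped with a warning.

**Known limitation — heteroscedastic null.**  The sampling variance of a
windowed eigenvalue spectrum grows with the strength of LD in the window.
If both populations share a region of extreme LD (e.g. a fixed haplotype
present in both), random-split comparisons concentrate noise there: the
score is a contrast detector calibrated by genome-wide empirical
percentiles, not a pointwise-calibrated test statistic.  Validation
therefore tests the false-positive behavior on a split of a population
whose truth interval has ordinary LD, and power on two matched histories
differing only by an injected sweep.

## Synthetic data generator

The generator emulates the study design the analyses assume:

* **Founders.**  Per-SNP allele frequencies ~ Beta(0.8, 0.8) truncated to
  [0.05, 0.95] (a U-shaped, array-like spectrum without monomorphic sites),
  independent across sites; donor pools for admixture draw Balding–Nichols
  frequencies at FST = 0.10 from the base pool, typical of between-breed
  differentiation on a shared array.
* **Genome.**  26 autosomes × 1500 SNPs at random positions on 100 Mb
  chromosomes ≈ 39K markers over ~2.6 Gb — a 50K-array layout after QC.
* **Transmission.**  Discrete generations; parent pairs drawn with
  replacement (no selfing); crossovers Poisson on a uniform 1 cM/Mb map,
  realized as origin-parity switches at the SNP loci with a fresh random
  phase per chromosome.
* **Histories.**  Default "isolated" population: Ne = 100 for 50
  generations, 96 sampled — a small, long-closed mountain breed; its
  expected F after 50 generations, 1 − (1 − 1/2Ne)^50 ≈ 0.22, is what the
  1 Mb-class F_ROH recovers.  Default "admixed" population: Ne = 400 with a
  50% two-donor pulse 15 generations before sampling, 68 sampled — a larger
  managed population created by crossbreeding a few decades ago.
* **Sweeps.**  `fix_haplotype` replaces each final-generation gamete over
  the interval, independently with probability 0.9, by one fixed pool
  haplotype: the hard-sweep endpoint, which leaves genotypes in
  Hardy–Weinberg proportions.  (Copying into both gametes of a fraction of
  individuals would plant a heterozygote deficit so strong that the HWE QC
  filter deletes the swept region.)  `differ_LD` applies the same to exactly
  one population, creating a between-population LD contrast with known
  coordinates.
* **Missingness** is i.i.d. at 0.002 per genotype.
* **Ground truth.**  Pedigree inbreeding is computed exactly by the kinship
  recursion over the realized pedigree; the full-sib design (sib pairs bred
  from unrelated founders, offspring of within-pair matings) gives pedigree
  F = 1/4 exactly, against which mean F_ROH is validated to ±0.05.

What the generator does **not** emulate: ascertainment LD between array
SNPs in the founders (LD arises only from drift and admixture), a realistic
recombination map, mutation, selection during the pedigree, genotype-calling
error beyond i.i.d. missingness, and real sheep demography.  Passing tests
therefore demonstrate correctness of the *algorithms* under a controlled
generative model, not calibration of the statistics on real ovine data.

## Validation problem sizes

The validation suite (and `scripts/acceptance.py`) uses the full 26 × 1500
genome where the design requires it (full-sib F_ROH recovery, the
isolated-vs-admixed contrast over 10 seeds) and a 6-chromosome genome at the
same 15 SNP/Mb density for the 20-seed varLD power/null and 10-seed LD-decay
experiments — enough windows (~5100) for stable top-0.1% thresholds while
keeping the whole suite in the minutes range.  The injected differ_LD truth
interval spans 20 Mb so that, after ~50% QC attrition in swept regions
(drifted frequencies pushed under the MAF cut-off), whole 50-SNP scan
windows still fit inside the sweep.

## Numerical choices and degenerate inputs

* Threshold quantiles are order statistics (smallest of the top ⌈n·f⌉
  values), ties included; constant tracks flag everything with a warning
  (islands) or yield no regions (varLD, where "all equal" means "no
  contrast").
* Pairwise-complete correlation everywhere; no imputation.
* A chromosome with one SNP contributes zero covered length (logged).
* Unsorted marker maps are sorted on read, never rejected; duplicate SNP
  ids are an error.
* Text ped/map filesets carry allele symbols only, so `write_plink` appends
  the two allele columns to the `.map` (read back when present, inferred
  from first occurrence otherwise) to keep round-trips exact.
* All simulation randomness flows from one integer seed through
  `numpy.random.default_rng`; identical seed + config ⇒ bit-identical
  panels.
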