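# Methods

This note documents the statistical models implemented in `sweepscan`, the
conventions chosen where the methods literature leaves latitude, and what the
synthetic-data generators do and do not emulate.

## Scan statistics

### Weir–Cockerham FST

Per-site FST between two populations uses the Weir & Cockerham (1984)
variance-component estimator: among-population (`a`), among-individual-within-
population (`b`) and within-individual (`c`) components computed from the two
populations' diploid sample sizes, allele frequencies and observed
heterozygote frequencies, with the per-site estimate `a / (a + b + c)`.

Conventions:

* **Missing data.** `a`, `b`, `c` are computed from genotypes whose two
  alleles are both called (the ANOVA derivation assumes complete genotypes).
  The DAF/MAF used elsewhere (binning, filters) use called-allele counting:
  every called haplotype allele counts, half-missing genotypes included.
* **Clamping.** Negative per-site estimates are sampling noise around
  FST = 0 and are clamped to 0; estimates above 1 are clamped to 1.
* **No allelic variation.** When both populations are monomorphic for the
  same allele the estimator is 0/0. The package defines FST = 0 there (zero
  divergence). This matters: an allele private to the focal population makes
  the sister–outgroup comparison exactly this case, and dropping such sites
  would blind the scan to private-allele sweeps — the most interesting
  signal. "Undefined" is reserved for insufficient sample size (fewer than
  two complete genotypes in either population).
* **Per-site vs combined.** Scan outputs are per-site ratios. The mean of
  per-site ratios is downward-biased for the model divergence parameter
  (Jensen's inequality applied to a ratio estimator); under a
  Balding–Nichols F = 0.1 design with 100 diploids per population it sits
  near 0.082 while the multi-locus combined ratio `sum(a) / sum(a+b+c)` —
  the summary Weir & Cockerham recommend across loci — recovers 0.10.
  `popgen.combined_fst` exposes the combined summary for calibration; it is
  not used in any per-site scan output.

### Population branch statistic

PBS for a focal population A against sister B and outgroup C:

    T_xy  = -ln(1 - FST_xy)
    PBS_A = (T_AB + T_AC - T_BC) / 2

FST is capped at `1 - 1e-12` before the log so T stays finite; a site
undefined in any pairwise comparison has undefined PBS. Empirical
significance thresholds use the upper-tail convention: the smallest observed
value such that the fraction of values strictly above it is at most alpha.

### nSL and XP-nSL

For a pair of haplotypes, `SL_ij` at a focal site is the number of sites in
the maximal contiguous run of identical alleles containing the focal site.
Conventions: the run extends left and right to the first mismatch or the
matrix edge (no edge-exclusion zone — edge truncation is visible in the
output and can be masked downstream); the focal site is counted, so
`SL_ij >= 1` when the pair agrees there; sites where either compared
haplotype is missing are treated as matching inside a run, but pairs missing
at the focal site are excluded from that site's mean.

* `nSL = ln(SL_anc / SL_der)` with means over pairs of ancestral-allele and
  derived-allele carriers; computed only where the within-population MAF
  exceeds 0.05 and both carrier classes have at least two members. A swept
  derived allele rides on long shared haplotypes, making nSL strongly
  negative under this sign convention; the composite test uses the absolute
  normalized score, so the sign convention does not affect significance.
* `XP-nSL = ln(SL_pop1 / SL_pop2)` with means over all within-population
  pairs; positive values mean longer haplotypes (candidate selection) in
  pop1.

Raw scores are standardized to mean 0, sd 1 (population sd, ddof = 0) within
derived-allele-frequency bins (2%-wide by default; configurable) for nSL, and
genome-wide (a single bin) for XP-nSL. Bins with fewer than two defined
scores or zero variance yield undefined normalized scores.

Scans should be run on segregating sites only. A variant file contains only
variants; if a fixed site grid (e.g. from the simulator) is scanned,
invariant columns inflate every pair's runs and compress the nSL ratio. The
validation harness filters to segregating sites before scanning.

## Composite test

Stages, in order, on per-site (DAF, PBS, normalized nSL) triples for the
focal population:

1. **Intermediate-DAF window.** Sites with DAF outside the closed interval
   [0.15, 0.50] are removed. The window targets beneficial alleles still at
   intermediate frequency.
2. **DAF bins.** 4%-wide bins anchored at 0.15 (left-closed/right-open;
   the final truncated bin 0.47–0.50 is closed and kept as its own bin).
   Bin edges are computed with a 1e-9 relative tolerance so printed decimal
   boundaries (0.19, 0.23, ...) land in the intended bin.
3. **Empirical p-values.** Within each bin, `p_i = #{s_j >= s_i} / N_bin`
   (self included; ties share the larger p), applied to raw PBS and to
   |normalized nSL|. Both are one-sided upper tails. A singleton bin gives
   p = 1.
4. **Removal rule.** The harmonic-mean p-value is only reliable when its
   components are below 0.5, so a site with either p > 0.5 is removed
   entirely (the merge needs both components).
5. **HMP merge.** `hmp = (w1 + w2) / (w1/p1 + w2/p2)` with equal weights by
   default; with equal weights this is `2 p1 p2 / (p1 + p2)` and always lies
   between the two inputs. No asymptotically-exact (Landau) correction is
   applied: significance is the empirical top fraction, not an absolute
   HMP cutoff.
6. **Flagging.** The smallest `ceil(0.05 * N)` merged values among retained
   sites are flagged; ties at the cutoff are all included (logged).

The nSL score is standardized once (frequency bins in the scan stage) and
its absolute value ranked here; re-standardizing within the 4% bins
("double standardization") is not done by default.

Because each site is ranked against its bin, the reference distribution
should be genome-scale. At desk scale the validation harness emulates this
with a pool of independently simulated neutral regions: the scanned region's
sites join the pooled bins exactly as a candidate locus joins the genome-wide
empirical distribution.

## Association model

Single-variant ordinary least squares:

    y = b0 + beta * g + b_sex * sex + sum_k gamma_k * PC_k + e

* Genotypes are coded for the cohort's minor allele: additive = copy count
  (0/1/2), dominant = carrier indicator (0/1).
* Right-skewed positive phenotypes (FeNO-like) are natural-log transformed
  before fitting.
* Population-structure covariates are the top principal components of the
  LD-pruned (greedy windowed pruning at r² > 0.8, window 50 sites, step 5),
  genotype matrix, standardized per site by `2p` and `sqrt(2p(1-p))` with
  mean imputation of missing dosages; component signs are fixed by making
  the largest-magnitude site loading positive.
* Complete-case analysis: any sample missing a genotype, phenotype or
  covariate is dropped.
* The 95% CI uses the t quantile at the residual degrees of freedom (not a
  fixed 1.96); at n = 290 the difference is negligible but the convention is
  stated. The p-value is the two-sided Wald t test on the dosage
  coefficient; R² is the full-model R². A zero-variance phenotype is
  reported as R² = 0.

## Synthetic data

### Balding–Nichols generator

Per site, an ancestral frequency `p0 ~ Uniform(0.05, 0.95)`; each
population's frequency `p_k ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`; diploid
genotypes multinomial under Hardy–Weinberg. Expected FST equals F, giving a
closed-form calibration target. `F = 0` degenerates to `p_k = p0`.

### Wright–Fisher forward simulator

Discrete generations, three demes on a fixed grid of L sites. Each
generation: parents drawn with replacement proportional to fitness (1,
1 + hs, 1 + 2s by focal-site genotype; uniform when s = 0); each gamete is a
crossover mosaic of the parent's two haplotypes (crossover count
Poisson(rho·(L-1)), positions uniform on adjacent-site boundaries); mutation
flips alleles site-wise with probability mu (finite sites, re-mutation
allowed, so the site grid stays aligned across demes). The final generation
is sampled without replacement to the requested diploid sample sizes.
Output matrices are phased and polarized by construction (ancestral =
initial state).

Default parameters and rationale (all configurable through `SimParams`):

| parameter | default | rationale |
| --- | --- | --- |
| N (diploids/deme) | 500 | forward-simulation scale; ~20x smaller than a human effective size |
| L (sites) | 400 | 1 kb spacing; region comfortably wider than sweep haplotype runs |
| mu (per site/gen) | 5e-5 | per-kb mutation rate rescaled for the 20x-reduced N |
| rho (per boundary/gen) | 2e-4 | 1 kb human recombination (~1e-5) rescaled for the reduced N |
| burn-in | 150 gen | builds LD from the linkage-equilibrium start |
| outgroup split | 200 gen ago | pairwise FST to the outgroup ~0.15 |
| A/B split | 100 gen ago | focal-sister FST ~0.08-0.1, continental-pair scale |
| sample sizes | 46/112/48 | focal cohort vs two reference panels |
| h | 1.0 | additive allele effects under the 1/1+hs/1+2s parametrization |

The founder spectrum is a 50/50 mixture of a rare-heavy log-uniform
spectrum and Uniform(0.05, 0.95): segregating-site panels are enriched for
common variants relative to the neutral site-frequency spectrum, and a
purely rare-heavy spectrum leaves so little per-site heterozygosity that all
haplotype pairs share long runs, compressing the nSL ratio.

Under selection the beneficial allele is injected at the A/B split (the
sweep onset) as a young mutation private to deme A: at the
monomorphic-ancestral site nearest the region center, 10 haplotypes — all
copies of one randomly chosen founder background — receive the derived
allele. This models a hard sweep from a single recent origin, the regime
that produces the private-allele, extended-haplotype signature the scans
target; seeding from multi-origin standing variation at the same frequency
produces soft sweeps with little shared-haplotype signal. Replicates where
the allele is lost, or (when conditioning is requested) where the final
sampled focal DAF misses the target window, are re-drawn with a logged
attempt count (rejection conditioning; no trajectory conditioning).

What the simulator does **not** emulate: migration and admixture,
background selection, gene conversion, variable recombination/mutation
maps, genotyping error, and equilibrium diversity (the burn-in is short of
4N generations; the founder spectrum, not mutation-drift balance, sets
standing diversity). Passing calibration and power checks on these
simulations therefore demonstrates internal statistical correctness and
sensitivity to hard sweeps under idealized three-deme histories, not
performance on real cohort data.

### Phenotype generator

`log y = intercept + beta_g * dosage + beta_sex * sex + sum gamma_k PC_k + e`,
`e ~ N(0, sigma^2)`, sex ~ Bernoulli(0.5), PC covariates standard normal.
The raw phenotype is `exp(log y)` so the pipeline's log transform is
exercised end to end. Defaults (`beta_g = 0.20`, `beta_sex = 0.37`,
`sigma = 0.7`, intercept 2.0) place the phenotype on the scale of exhaled
nitric oxide in ppb: cohort mean log-FeNO near 2.2, a male-female gap near
0.37 on the log scale, and a minor-allele frequency of 9% is used in the
validation cohorts.

## Problem sizes used in validation

The test suite and acceptance script run: oracle comparisons on 200 random
matrices (up to 12 haplotypes x 60 sites); Balding–Nichols calibration at
5000 sites x 100 diploids; a neutral background pool of 10 regions plus 50
conditioned sweep replicates at the defaults above; and association recovery
with 200 effect cohorts plus 2000 null cohorts at n = 290. These sizes were
chosen so every property is measured with useful precision while the whole
suite stays desk-scale.

## Known limitations

* Empirical p-values are granular at desk scale (floor 1/N_bin); genome-scale
  inputs are needed for p-values below ~1e-2 per bin.
* The top-5% rule is rank-based; with heavy ties at the cutoff the flagged
  count exceeds the nominal count (logged).
* The sweep-power estimate varies a few percentage points between background
  pools (the 5% cutoff is estimated from the pool); the calibration
  (flagged fraction = 5%) is exact by rank arithmetic regardless.
* `ld_prune` is O(window² ) per window and intended for the array-scale
  inputs of the association stage, not genome-wide pruning.
* The Wright–Fisher kernel is dense int8 per deme (memory ~ 2NL bytes); it is
  sized for calibration studies, not population-scale inference.
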