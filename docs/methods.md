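# Methods

## Analysis model

`pathperm` tests whether a gene pathway carries more nominal case-control
association signal than random, architecture-matched gene sets. The chain
is: per-study SNP association → fixed-effect meta-analysis → LD feature
decomposition → permutation test, reported across gender × outcome strata.

**Per-SNP association.** The primary model is additive logistic
regression: for subject $i$ with dosage $g_{ij} \in \{0,1,2\}$ at SNP $j$,

$$\operatorname{logit} P(Y_i = 1) = \beta_0 + \beta_j g_{ij} + \gamma^\top z_i,$$

with covariates $z_i$ (standardized age, study-site indicators and, in
mixed strata, sex; constant columns are dropped automatically inside
single-gender strata). Wald two-sided p-values are reported, matching the
common single-variant GWAS output. Monomorphic SNPs and fits showing
separation or non-convergence are flagged (`note` field), logged and
excluded from feature construction. Two vectorized covariate-free screens
back the simulation studies: the Cochran–Armitage trend test (weights
0/1/2, no continuity correction) and an allelic 2×2 log odds ratio with
the Haldane–Anscombe 0.5 correction applied only when a cell is empty.
The allelic screen assumes Hardy–Weinberg dosages — exactly true of the
generator — and, unlike the trend screen, yields an effect and standard
error, so it feeds the meta-analysis. The large simulation suites use it
because several hundred full-genome replicates of per-SNP maximum
likelihood fits would dominate their run time without changing what they
measure; the logistic model is exercised by its own targeted tests.

**Meta-analysis.** Default inverse-variance fixed effect: weights
$w_i = 1/\mathrm{se}_i^2$, combined $\hat\beta = \sum w_i \beta_i / \sum w_i$,
$\mathrm{se} = (\sum w_i)^{-1/2}$, normal p. The combined set uses
intersection semantics (a SNP must be usable in every study), mirroring
an overlapping-SNP combined analysis; union semantics are an option.
Sample-size-weighted z ($z = \sum \sqrt{n_i} z_i / \sqrt{\sum n_i}$) is
available where only p-values and directions are trusted. Allele
harmonization accepts matches and strand complements, flips the sign for
swapped labels, drops irreconcilable SNPs with a log message, and routes
intrinsically strand-ambiguous A/T and C/G pairs through a warning hook
(the generator never produces genuinely flipped strands, so ambiguity is
surfaced rather than resolved).

**Features.** SNPs map to a gene iff their position lies in the closed
interval [start − flank, end + flank] (flank default 50,000 bases;
coordinates 1-based inclusive throughout). A pathway's SNP set is the
deduplicated union over its genes; for gene-level tests a shared SNP
counts in every capturing gene. LD blocks are estimated from a reference
panel by greedy contiguous agglomeration: walking each chromosome in
position order, a SNP joins the current block while its squared dosage
correlation with at least one member reaches the threshold (default 0.8);
blocks need ≥ 2 members. The intersection of a block with the mapped SNP
set forms a complex feature when ≥ 2 SNPs survive; a lone surviving SNP
is demoted to a simple feature. Features partition the mapped SNPs — an
invariant enforced by the data structures.

**Permutation test.** A simple feature is significant iff its SNP has
p < α (default 0.05); a complex feature iff any member does. The observed
count is compared with counts from `n_perm` (default 1,000) random
feature sets drawn genome-wide with the same architecture — the simple
count and the exact multiset of complex sizes. Within one draw, sampling
is uniform without replacement; if a size class is exhausted, the nearest
size within ±1 then ±2 substitutes (logged); strict mode raises instead.
The empirical p is the plug-in strict-exceedance estimate
`#{null > observed} / n_perm`, reproducing the printed arithmetic in
which 6 exceedances in 1,000 is exactly 0.006; `(k+1)/(N+1)` is available
as `estimator="corrected"`. A zero numerator is stored as 0.0 and
rendered `<0.001` at 1,000 permutations; values above 0.99 render
`>0.99`. Ties with the observed count are, by the strict convention, not
exceedances. Gene-level drill-down reuses the same pool, giving each gene
an independent substream derived from the seed and the gene symbol (CRC32)
so any gene can be reproduced in isolation.

**The null pool contains the tested set.** The genome-wide feature pool
keeps the tested pathway's features by default. Under the global null the
pathway is then exactly exchangeable with every class-matched random
draw, so the empirical p-value is calibrated regardless of how large a
fraction of the genome the pathway occupies. Excluding the pathway
(`exclude_self=True`) forces null draws into the complement; with a small
genome that couples the 1,000 null counts through the realized complement
and overdisperses the empirical p (we measured a 13% type-I rate at the
5% threshold on a ~5,000-SNP genome whose pathway held ~20% of the
features, against 5.0% with inclusion). On a realistic genome — hundreds
of thousands of SNPs against a ~900-SNP pathway — the two choices are
indistinguishable.

**Strata and reporting.** Outcomes partition cases by IOP at diagnosis:
HPG keeps IOP ≥ 22 mmHg, NPG keeps IOP < 22; cases without a recorded IOP
enter only the overall outcome; controls are shared. X-linked SNPs are
analysed only in female-only strata; male-only and combined strata drop
them from data, features and pool alike. The per-SNP multiple-testing
threshold is α / (n_SNPs × n_strata) with the stratification multiplier
defaulting to 3 (gender × IOP read as three effective strata, which
reproduces 1.85 × 10⁻⁵ from 903 SNPs at α = 0.05; the multiplier is
configurable because the intended accounting is ambiguous). Tables carry
three significant figures; machine-readable output keeps full precision.

## Synthetic data

The generator produces what the analysis assumes and nothing more.

*Reference panel.* Chromosomes carry a mix of LD blocks and singleton
SNPs at evenly spaced positions. Within a block, each haplotype draws one
latent allele $Z \sim \mathrm{Bernoulli}(f)$ and every member SNP copies
$Z$ with flip probability $\varepsilon$; the pairwise correlation is

$$r = \frac{(1-2\varepsilon)^2 f(1-f)}{(1-2\varepsilon)^2 f(1-f) + \varepsilon(1-\varepsilon)},$$

and $\varepsilon$ is solved (Brent) so $r^2$ hits the configured target.
This closed form is what the generator's own tests check. Latent
frequencies are uniform on `maf_range` (default 0.05–0.5; the real
cohorts' frequency spectrum is not public, so the defaults are
conventional, not calibrated). Blocks are mutually independent —
realistic recombination maps, population structure and imputation are
deliberately out of scope.

*Cohorts.* Disease follows a logistic model on causal-SNP dosages
(optionally restricted to one gender), a standardized age covariate
(coefficient 0.3), site effects and a baseline logit of −0.5. Subjects
are accepted conditional on status until the configured case and control
counts are met exactly (fixed-margin cohorts); an acceptance probability
near zero raises after 20 stalled batches. Cases receive an
IOP-at-diagnosis of N(24, 4²) mmHg, missing with probability 0.24 —
matching a study in which roughly a quarter of cases lack an IOP
classification and appear only in the overall stratum. Male X genotypes
are hemizygous, coded 0/2; one consistent convention, stated rather than
inherited, since dosage coding on X for males has no single standard.
Default female fraction 0.55, near the case mix of the motivating study.

*Annotations.* Genes are anchored on disjoint runs of consecutive SNPs,
so every pathway gene window contains at least one genotyped SNP by
construction. The default pathway shape is 23 genes across 15 autosomes
plus two X-linked members, named with the canonical estrogen-metabolism
symbols (COMT, ESR1, STS, ARSD, …) when that exact shape is requested.

What passing tests on this generator do *not* show: robustness to
population stratification, genotyping artefacts, strand flips,
non-uniform MAF spectra, or LD that decays smoothly with distance — real
data have all of these and the generator has none.

## Simulation study sizes

The acceptance suite fixes two worlds, chosen once:

* **Calibration** — 16 chromosomes (one X), 36 blocks per chromosome with
  2–12 SNPs each, 15% singletons, within-block r² = 0.9, 1,000
  haplotypes: ~4,700 SNPs. The 23-gene pathway captures ~1,000 SNPs
  (~130 simple and ~140 complex features), mirroring the 123/122 shape of
  the motivating pathway. 200 replicates of the full pipeline — two
  cohorts of 750 cases / 750 controls, allelic scan, inverse-variance
  meta-analysis, 1,000 permutations — under zero genetic effects; the
  rejection rate at the 0.05 permuted threshold must sit within the
  binomial 95% band around 0.05. Measured: 0.050.
* **Dimorphism** — same shape at 25 kb SNP spacing, pathway ~350 SNPs, ten
  causal SNPs with per-allele odds ratio 1.3 acting only in women, spread
  over ten autosomes among the pathway's simple features with latent MAF
  ≥ 0.15. Cohort sizes (2 × 1,250/1,250) are set so the analysed female
  stratum holds roughly 1,500 cases against 1,500-odd controls, the
  stratum in which the effects live. Over 50 replicates the female
  pathway p must fall below 0.05 in ≥ 80% and the male p must exceed 0.05
  in ≥ 90%. Measured: 94% and 96%.

Both suites derive per-replicate seeds from fixed bases, so reruns are
bit-reproducible.

## Numerical choices and edge cases

* p-values are floored at 10⁻³⁰⁰ to keep them in (0, 1].
* Logistic fits use Newton's method (statsmodels), 100 iterations;
  standard errors that are non-finite, non-positive or above 50 are
  treated as separation.
* Monomorphic columns get r² = 0 (including the diagonal) with a logged
  count, so they can never join a block.
* Features whose members all lack p-values are dropped from counting
  (logged); partially scored complex features use the available members.
* The greedy block builder is deterministic given a position-sorted
  input; input order cannot affect output beyond the sort.
* Association tables serialize with six significant digits and
  round-trip losslessly at that precision.

## Known limitations

* Block estimation is a single-threshold greedy rule, not a
  confidence-interval (Gabriel-style) method; the per-gene feature counts
  of any particular external analysis are therefore not exactly
  reproducible by construction, only the counting and permutation
  conventions downstream of the blocks.
* The strict-exceedance plug-in estimator is mildly anti-conservative on
  very coarse count distributions (few features); the corrected estimator
  is the remedy when that matters.
* No heterogeneity statistics or random-effects meta-analysis; no
  gene-set methods beyond the architecture-matched permutation; no
  genomic-control correction.
* The covariate-free screens must not be combined across studies with
  confounded covariate structures; use the logistic model there.
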