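# Methods

## The synthetic cohort

The generator produces the smallest object on which every stage of a
control-selection comparison is testable: a sample table with case
status and the 13 standard covariates, an integer dosage matrix with
local LD and population structure, per-variant imputation INFO scores,
and the usual sample-QC artifacts.

**Genotypes.** Each variant has a base allele frequency drawn uniformly
from a configured range (default 0.05–0.5). With S subpopulations and
differentiation F, per-subpopulation frequencies follow the
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) around the base frequency;
F = 0 collapses to no differentiation. Within a block of consecutive
variants, each haplotype is a latent AR(1) Gaussian (correlation ρ,
default 0.85–0.9) thresholded at the frequency quantile; dosage is the
sum of two independent haplotypes. This gives tunable block LD at
negligible cost; it makes no attempt to mimic human recombination maps
— blocks have a hard edge and inter-block r² is exactly zero in
expectation. Missing dosages are inserted completely at random; the
study this emulates specifies no informative-missingness mechanism.

**Principal components.** PCs are the top 10 components of the
standardized, mean-imputed dosage matrix (randomized SVD on a
subsampled variant panel, `pca_max_variants`). Computing them from the
genotypes — rather than simulating them — is essential: it makes PC
quality an explicit function of panel size, which is the lever behind
the confounding experiments below. A fallback flag
(`use_true_subpop_pcs`) substitutes noisy subpopulation contrasts for
the leading PCs, emulating the regime where ancestry is essentially
perfectly measured (as with PCs computed from hundreds of thousands of
variants in a real biobank).

**Phenotype.** Case status follows a logistic liability: intercept
(≈ logit of the target prevalence) plus planted per-allele effects,
covariate effects (default: age, 0.6 log-odds per SD — cancer risk is
strongly age-graded), and `confounding_strength` × a standardized
subpopulation score. Every liability contribution is mean-centered so
the intercept pins the prevalence regardless of planted effects.
Genetic females are never cases (male-only phenotype) and are marked
ineligible.

**Artifacts.** Configured proportions of samples get a reported/genetic
sex mismatch, a sex-chromosome aneuploidy flag, an inflated missingness
metric, or a heterozygosity value pushed ≥ 8 SD from the bulk; INFO
scores are Beta draws (default Beta(20, 1.5), putting ~3% of variants
below the 0.7 threshold).

## QC

Sample filters run in a fixed precedence (sex mismatch → aneuploidy →
missingness → heterozygosity → female/ineligible) and each removed
sample is attributed to the first rule it fails, so report counts
reconcile exactly with set differences. The heterozygosity rule is
|HET − mean| > 3 SD; the source study cites its biobank's released
outlier list without a formula, so a conventional SD rule stands in.
Variant filters (INFO < 0.7 → MAF < 1% → MAC < 5) run per analysis
cohort: MAF is recomputed within each design's cases + selected
controls, so the three strategies legitimately test slightly different
variant sets — mirroring the differing SNP totals the published tables
show. A config switch (`shared_variant_qc`) applies one shared filter
instead; the per-design default reproduces the observed behaviour.

## Matching

The propensity model is a case-vs-pool logistic regression on the 13
covariates (categoricals as indicator contrasts against the most
frequent level), fitted by IRLS to tolerance 1e-8. Matching is greedy
nearest-neighbour without replacement on the probability scale, cases
in descending-score order (hardest to match first); each case takes its
k controls in one pass. The tool the study names documents neither its
case ordering nor whether 1:k runs as one k-nearest pass or k 1:1
rounds, so both are implemented (`case_order`, `passes`) with the
defaults above. Ties break on the smaller pool index, which makes the
algorithm exactly reproducible and lets a five-line restatement of the
rule serve as its test oracle. The implementation keeps the sorted pool
in a doubly linked list with union-find-style path compression over
removed entries, so paper-scale matching (15,250 cases against a
208,128 pool) takes under a second.

No caliper is applied by default; distance is on the probability scale.
Both choices are switchable and neither changes any conclusion at the
preset scales.

## Association scan

Each variant is tested by maximum-likelihood logistic regression (IRLS,
tolerance 1e-8, warm-started from the covariate-only null fit) with a
1-df Wald chi-square on the dosage coefficient. Variants with MAC < 5,
zero dosage variance, or a non-convergent fit are excluded and tallied.
p-values are computed in log space via sf(χ²) = 2Φ(−√χ²), so
−log₁₀P stays finite far beyond 300. The two-step whole-genome ridge
machinery of biobank GWAS tools is deliberately not reproduced: the
synthetic cohorts are unrelated individuals, where the leave-one-
chromosome-out polygenic adjustment is unnecessary, and the plain
covariate-adjusted scan is the transparent engine the comparisons need.
Degenerate designs (constant covariate columns) are handled by dropping
the constant columns; perfect separation marks the variant untested
rather than aborting the scan.

## Power

The analytic engine is the normal approximation to the allelic 2×2
log-OR test (formulas in the README). The study used an online
calculator backed by an R power package whose exact model variant is
not printed; rather than guessing it, the Monte-Carlo simulator is the
acceptance surface: `empirical_power` draws case genotypes from the
exact retrospective logistic model (P(g | case) ∝ HWE(p₀)·ORᵍ) and runs
the same aggregated Wald test the scan uses. Across a 3×3 MAF × OR grid
at 2,000/8,000 with 2,000 replicates the analytic and empirical values
agree within ~1.5 percentage points. Power is monotone in sample sizes
and |ln OR| everywhere, and in MAF while case and control allele
frequencies stay below ~0.5; immediately below MAF 0.5 with large OR
the case-arm frequency crosses the binomial variance optimum and power
can dip marginally — the monotonicity property is therefore asserted
away from that edge. Frequencies above 0.5 are accepted and parametrize
a major risk allele (equivalent to the minor allele with OR → 1/OR).

## Clumping and comparison

Clumping is single-linkage chaining: the transitive closure of
"within ±500 kb on the same chromosome", with the gap comparison
inclusive (exactly 500 kb groups together) and significance strictly
greater than −log₁₀(5×10⁻⁸). Chained loci can span more than 1 Mb; a
`lead_window` mode (fixed window around the running top SNP, the way
PLINK-style clumping behaves) is available for contrast. The suggestive
tier (P < 1×10⁻⁵) is reporting-only and never feeds clumping.

Locus identity across runs is lead-to-lead distance ≤ window with
greedy nearest-first pairing (the source compares loci across designs
without stating its rule; this one is declared, not inferred, and is
checked against brute-force optimal pairing on small instances). The
three-way Venn composes the pairwise matchings transitively;
intransitive components are counted by the set of runs present and
flagged. LD rescue computes lead-to-lead r² on the all-controls panel
(the largest shared reference) and the published-style percentage to
two decimals; an empty denominator reports "not applicable", never 0%.
Effect concordance regresses study betas on benchmark betas after
harmonizing to the benchmark effect allele, with adjusted
R² = 1 − (1−R²)(n−1)/(n−2). The real 269-SNP benchmark table cannot be
redistributed, so a synthetic stand-in with a configurable population
R² (default 0.82) exercises the code path; it is labelled synthetic
everywhere it appears.

## Study presets and what they show

All presets are frozen study conditions, sized so the full suite runs
on one CPU in minutes; the methods scale linearly if larger cohorts are
wanted.

* **paper-scale covariates** — exactly 15,250 cases and a 208,128-male
  pool, covariates only (no genotypes). Supports the count-exact
  checks: all-controls 223,378; random 1:4 with seed 42 → 61,000
  controls; matched 1:4 → 76,250-person cohort.
* **null calibration** — 3,000 samples, 8,000 independent variants, no
  effects, one subpopulation. The scan's type-I rate at p < 0.05 and λ
  (expected within [0.95, 1.05]).
* **confounded** — 8,000 samples, 2 × 900 variants in 5-variant LD
  blocks, two subpopulations at Fst 0.05, confounding strength 0.7,
  PCs from a 200-variant panel, three planted ~OR 2 causals. The
  deliberately small PC panel leaves the linear PC adjustment an
  imperfect proxy for subpopulation, so residual stratification
  inflates the scans.
* **planted recovery** — one chromosome, three OR 2.0 causals at MAF
  0.3, sized so analytic power ≈ 1; recovery of each planted position
  within ±500 kb is checked over 20 seeded runs.
* **ratio sweep** — six graded causals (OR 1.45–1.65) with ~650 cases,
  sized so detection power climbs steeply to ratio 1:6 and flattens
  after, producing the count-versus-ratio plateau.

### Why matched beats random on λ, and by how much

With the same covariates in the matching model and the regression,
matching cannot remove confounding that the covariates do not measure:
subpopulation variation orthogonal to the PCs inflates matched and
random designs alike. What matching does add is robustness to
*misspecification*: it balances the whole covariate distribution, while
the scan adjusts only linearly, so the nonlinear part of the
PC-confounding (bimodal PC1 with overlap) is removed by balance but not
by adjustment. On the confounded preset this yields mean null-variant
λ ≈ 1.14 for matched versus ≈ 1.18 for random and all (10 seeds), with
the ordering holding in 8/10 individual seeds — the comparison is
therefore asserted on seed means. The companion claim that a matched
design is fully calibrated is true exactly when the covariates measure
the structure well: with the truth-derived PC flag (noise 0.1) the
matched λ averages 1.00 ± 0.05, and that is the setting where the
calibration check runs. λ on the confounded preset is always computed
on null variants (excluding ±500 kb around planted causals), since
planted signal would shift the chi-square median and masquerade as
inflation.

## Numerical choices

IRLS steps are damped to max-norm 10; runaway coefficients (>100) mark
separation. The Wald covariance is the inverse observed information at
convergence, with a 1e-8 ridge fallback for near-singular solves.
Lead-SNP ties break by smaller position then lexicographic id; matching
ties by smaller pool index; random selection and every simulation stage
derive from a single `numpy` Generator seeded from the config, so
identical configs give byte-identical cohort files (floats are written
with shortest-exact repr).

## Limitations

The LD model has no recombination-map realism, so clumping behaviour at
block edges does not emulate fine-scale human LD; lead swapping between
designs is rarer here than in real data (at the preset effect sizes the
three designs usually agree on lead SNPs, and the lead-concordance
comparison frequently resolves as a tie). Artifacts are planted, not
mechanistic — the missingness/heterozygosity outliers exist to exercise
the filters, not to model assay chemistry. The X chromosome,
relatedness, rare-variant tests and imputation modelling are out of
scope. Passing tests demonstrate the pipeline's statistical behaviour
under these generating assumptions, not calibration to any real
biobank's LD or PC geometry.
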