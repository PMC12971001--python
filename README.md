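# ctrlgwas — control-selection strategies for biobank case-control GWAS

In biobank-scale case-control GWAS, far more potential controls are
available than a study needs: once ~15,000 prostate-cancer cases are
defined in a cohort of half a million, essentially every other male
participant is an eligible control. Using *all* of them maximizes power
but multiplies compute (and, for sequencing studies, the cost of
sequencing controls). This package implements and evaluates the three
standard alternatives on synthetic cohorts with known truth:

* **all** — every eligible non-case is a control;
* **random 1:k** — a seeded uniform subsample of k controls per case;
* **matched 1:k** — nearest-neighbour propensity-score matching without
  replacement on the 13 standard covariates (recruitment age, assessment
  centre, genotyping chip, 10 genetic principal components).

Around those designs it provides the full evaluation pipeline: a
synthetic-cohort generator (Balding–Nichols subpopulation
differentiation, latent-AR(1) LD blocks, logistic liability with planted
causal variants and a subpopulation-to-risk confounding term, QC
artifacts), sample/variant QC (INFO ≥ 0.7, cohort-recomputed MAF ≥ 1%,
MAC ≥ 5), a covariate-adjusted per-variant logistic Wald scan with
REGENIE-style output, ±500 kb distance clumping with lead-SNP
extraction, analytic/Monte-Carlo power for the additive allelic test,
and cross-strategy concordance diagnostics (locus Venn, lead identity,
LD rescue at r² > 0.8, effect-size regression against a benchmark SNP
set).

## The statistics at the core

**Association.** For each variant with dosage g ∈ [0, 2], case status y
is modelled as logit P(y=1) = β₀ + β_g·g + γᵀx with x the 13 covariates;
fitting is by IRLS and the test is the 1-df Wald chi-square
(β_g/SE)², with p-values kept in log space (−log₁₀P > 300 stays
finite). Genomic control is λ = median(χ²)/0.4549364.

**Matching.** A case-vs-pool logistic model on the covariates gives each
sample a propensity score e(x); cases are processed hardest-first
(descending score) and each claims its k nearest still-available pool
members by |Δe|, ties to the smaller pool index — fully deterministic
given the scores.

**Clumping.** Genome-wide significant variants (−log₁₀P > 7.30103,
i.e. P < 5×10⁻⁸) are grouped per chromosome by single-linkage chaining
of the |Δpos| ≤ 500 kb relation; the member with the highest −log₁₀P
leads the locus.

**Power.** With control risk-allele frequency p₀ (odds q₀ = p₀/(1−p₀))
and per-allele odds ratio OR, the case frequency is
p₁ = OR·q₀/(1+OR·q₀), the log-OR variance is
V = 1/(2n₁p₁(1−p₁)) + 1/(2n₀p₀(1−p₀)), and two-sided power at level α is
Φ(|ln OR|/√V − z₁₋α/₂) + Φ(−|ln OR|/√V − z₁₋α/₂).

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale
(an 8,000-sample, 1,800-variant confounded cohort; each step reads the
previous step's files under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_build_designs.py
python analysis/03_run_gwas.py
python analysis/04_loci_concordance.py
python analysis/05_power_cost.py
python analysis/06_stability_ratio.py
```

Output of steps 02–03 (seed 1):

```
eligible: 929 cases, 7051 pool
all      n=  7980 mean|SMD| before=0.094 after=0.094
random   n=  4645 mean|SMD| before=0.094 after=0.099
matched  n=  4645 mean|SMD| before=0.094 after=0.028

all      tested= 1794 max -log10P= 37.10 significant=  5 (2.8e-03) suggestive=  7 lambda=1.295
random   tested= 1794 max -log10P= 31.14 significant=  4 (2.2e-03) suggestive=  7 lambda=1.262
matched  tested= 1795 max -log10P= 36.16 significant=  5 (2.8e-03) suggestive=  6 lambda=1.148
```

Reading this: matching shrinks the mean absolute standardized mean
difference of the covariates from 0.094 to 0.028 while a random 1:4
subsample leaves the imbalance untouched; consequently the matched
scan's null-variant inflation factor λ (1.148) sits well below the
random design's (1.262) — residual population stratification that the
linear PC adjustment misses is absorbed by the balanced design. All
three designs still recover the three planted causal loci (step 04
reports a triple-intersection Venn of 3 and lead-SNP agreement), and the
effect-size regression against a synthetic 269-SNP benchmark returns
slope 0.998 with adjusted R² 0.80. Step 05 prints the analytic-power
anchors — 100.0% power at MAF 0.03, OR 1.5 for a 15,250-case 1:4
design; 80% power reached by MAF ≈ 0.008 at OR 1.5 — and the cost
arithmetic: subsetting 200,000 → 60,000 samples saves 70% of linear-time
compute and 91% for O(N²) algorithms. Step 06 shows the ratio sweep
plateau: mean locus yield rises quickly to 1:6 (per-step gain 0.25) and
flattens beyond it (0.10).

## Layout

```
src/ctrlgwas/        synthdata, io, cohort_qc, control_select, assoc,
                     power, loci, compare, runner
analysis/            numbered drivers for the six study stages
tests/               unit, property (hypothesis) and acceptance suites
docs/methods.md      model assumptions, parameter choices, limitations
```
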