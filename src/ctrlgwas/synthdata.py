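"""Synthetic biobank cohort generator with known truth.

Emulates the ingredients a control-selection GWAS study needs: a sample
table with case status and 13 covariates (recruitment age, assessment
centre, genotyping chip, 10 principal components), integer allele dosages
with block LD structure and subpopulation differentiation, per-variant
imputation INFO scores, planted causal variants, and the usual sample-QC
artifacts (sex mismatch, aneuploidy, missingness/heterozygosity outliers).

The genotype model is deliberately simple and cheap: per-subpopulation
allele frequencies follow a Balding-Nichols beta around a shared base
frequency (differentiation parameter ``fst``), and haplotypes within a
block of consecutive variants are derived by thresholding a latent AR(1)
Gaussian at the frequency quantile, giving tunable local LD without a
coalescent simulation. Case status follows a logistic liability with
planted per-allele effects, covariate effects, and a direct
subpopulation-to-risk coupling (``confounding_strength``) so that
population stratification confounds naive association scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "assign_phenotypes",
    "inject_artifacts",
    "compute_pcs",
    "simulate_cohort",
    "published_scale_covariates",
    "synthetic_benchmark",
    "desk_preset",
    "null_calibration_preset",
    "confounded_preset",
    "planted_recovery_preset",
    "ratio_sweep_preset",
]

CENTRES = [
    "C01", "C02", "C03", "C04", "C05", "C06", "C07", "C08",
]
CHIPS = ["array1", "array2"]
NUCLEOTIDES = np.array(list("ACGT"))
MISSING = -1  # sentinel in the int8 dosage matrix


@dataclass
class SimulationConfig:
    """Everything that determines a synthetic cohort.

    ``seed`` fully determines the output: two calls with the same config
    produce identical cohorts, field for field.
    """

    n_samples: int = 25_000
    n_chromosomes: int = 4
    variants_per_chromosome: int = 5_000
    chromosome_length_bp: int = 50_000_000
    block_size: int = 20
    within_block_rho: float = 0.9
    n_subpops: int = 1
    fst: float = 0.0
    base_maf_range: tuple[float, float] = (0.05, 0.5)
    prevalence_intercept: float = float(logit(0.07))
    # (chromosome label, variant rank on that chromosome, per-allele log-odds)
    causal_effects: list[tuple[int, int, float]] = field(default_factory=list)
    # base allele frequency forced at causal variants (None -> drawn like the rest)
    causal_base_maf: float | None = None
    covariate_effect_sizes: dict[str, float] = field(default_factory=lambda: {"age": 0.6})
    confounding_strength: float = 0.0
    female_fraction: float = 0.0
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {
            "sex_mismatch": 0.0,
            "aneuploidy": 0.0,
            "missingness_outlier": 0.0,
            "het_outlier": 0.0,
        }
    )
    info_beta_params: tuple[float, float] = (20.0, 1.5)
    missing_rate: float = 0.002
    pca_max_variants: int = 2_000
    n_pcs: int = 10
    use_true_subpop_pcs: bool = False
    true_pc_noise: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.within_block_rho < 1):
            raise ValueError(f"within_block_rho must be in [0,1), got {self.within_block_rho}")
        if self.block_size < 1 or self.variants_per_chromosome < self.block_size:
            raise ValueError("need variants_per_chromosome >= block_size >= 1")
        if not (0 <= self.fst < 1):
            raise ValueError(f"fst must be in [0,1), got {self.fst}")
        lo, hi = self.base_maf_range
        if not (0.001 <= lo <= hi <= 0.5):
            raise ValueError(f"base_maf_range must lie within [0.001, 0.5], got {self.base_maf_range}")
        for name, rate in {**self.artifact_rates, "missing_rate": self.missing_rate,
                           "female_fraction": self.female_fraction}.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be a proportion in [0,1], got {rate}")
        ranks = [(c, r) for c, r, _ in self.causal_effects]
        if len(set(ranks)) != len(ranks):
            raise ValueError("causal variant positions must be unique")
        for c, r, _ in self.causal_effects:
            if not (1 <= c <= self.n_chromosomes) or not (0 <= r < self.variants_per_chromosome):
                raise ValueError(f"causal position ({c},{r}) outside the simulated grid")


@dataclass
class SyntheticCohort:
    """In-memory cohort: sample table, variant table, dosage matrix, truth."""

    samples: pd.DataFrame  # SAMPLE_ID, REPORTED_SEX, GENETIC_SEX, STATUS, AGE, CENTRE, CHIP, PC1..PC10, MISS_RATE, HET, ANEUPLOIDY
    variants: pd.DataFrame  # CHROM, POS, ID, ALLELE0, ALLELE1, INFO
    dosages: np.ndarray  # int8, shape (n_variants, n_samples); -1 = missing
    truth: dict  # {"subpop": array, "causal": DataFrame, "config": dict}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage_row(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["ID"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in cohort")
        return self.dosages[idx[0]]


def _balding_nichols(rng: np.random.Generator, base_p: np.ndarray,
                     fst: float, n_subpops: int) -> np.ndarray:
    """Per-subpopulation allele frequencies around shared base frequencies.

    Returns shape (n_subpops, n_variants). fst == 0 collapses to the base
    frequency in every subpopulation.
    """
    if fst == 0.0 or n_subpops == 1:
        return np.tile(base_p, (n_subpops, 1))
    a = base_p * (1.0 - fst) / fst
    b = (1.0 - base_p) * (1.0 - fst) / fst
    freqs = rng.beta(a, b, size=(n_subpops, base_p.size))
    # keep thresholds well-defined
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def _ar1_latent(rng: np.random.Generator, n: int, block: int, rho: float) -> np.ndarray:
    """n haplotype draws of a latent AR(1) Gaussian of length ``block``."""
    z = np.empty((n, block))
    z[:, 0] = rng.standard_normal(n)
    if block > 1:
        innov = rng.standard_normal((n, block - 1)) * math.sqrt(1.0 - rho * rho)
        for j in range(1, block):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return z


def simulate_genotypes(config: SimulationConfig, subpops: np.ndarray,
                       rng: np.random.Generator | None = None) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Draw the dosage matrix and variant table.

    Returns ``(dosages, variants, base_freqs)`` with dosages int8 of shape
    (n_variants, n_samples); missing entries are ``-1``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(subpops)
    m_per = config.variants_per_chromosome
    m = config.n_chromosomes * m_per

    base_p = rng.uniform(*config.base_maf_range, size=m)
    if config.causal_base_maf is not None:
        for chrom, rank, _ in config.causal_effects:
            base_p[(chrom - 1) * m_per + rank] = config.causal_base_maf
    sub_freq = _balding_nichols(rng, base_p, config.fst, config.n_subpops)

    # variant table: sorted unique positions per chromosome
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), m_per)
    positions = np.empty(m, dtype=np.int64)
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.choice(config.chromosome_length_bp, size=m_per, replace=False)) + 1
        positions[c * m_per:(c + 1) * m_per] = pos
    a0_idx = rng.integers(0, 4, size=m)
    a1_idx = (a0_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "CHROM": chroms,
            "POS": positions,
            "ID": [f"{c}:{p}" for c, p in zip(chroms, positions)],
            "ALLELE0": NUCLEOTIDES[a0_idx],
            "ALLELE1": NUCLEOTIDES[a1_idx],
            "INFO": np.ones(m),
        }
    )

    dosages = np.empty((m, n), dtype=np.int8)
    sub_index = [np.flatnonzero(subpops == s) for s in range(config.n_subpops)]
    b = config.block_size
    for c in range(config.n_chromosomes):
        start = c * m_per
        for blk_start in range(0, m_per, b):
            width = min(b, m_per - blk_start)
            lo = start + blk_start
            cols = slice(lo, lo + width)
            for s, idx in enumerate(sub_index):
                if idx.size == 0:
                    continue
                thresh = norm.ppf(sub_freq[s, cols])
                h1 = _ar1_latent(rng, idx.size, width, config.within_block_rho) < thresh
                h2 = _ar1_latent(rng, idx.size, width, config.within_block_rho) < thresh
                dosages[cols.start:cols.stop, idx] = \
                    (h1.astype(np.int8) + h2.astype(np.int8)).T
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING
    return dosages, variants, base_p


def compute_pcs(dosages: np.ndarray, rng: np.random.Generator,
                max_variants: int = 2_000, n_pcs: int = 10) -> np.ndarray:
    """Top principal components of the centered dosage matrix.

    Missing entries are mean-imputed per variant before the decomposition;
    components are standardized to unit variance and sign-fixed so that
    regeneration is deterministic.
    """
    from sklearn.utils.extmath import randomized_svd

    m = dosages.shape[0]
    if m > max_variants:
        keep = np.sort(rng.choice(m, size=max_variants, replace=False))
    else:
        keep = np.arange(m)
    g = dosages[keep].astype(np.float32).T  # samples x variants
    miss = g < 0
    if miss.any():
        col_mean = np.where(miss, np.nan, g).astype(np.float64)
        col_mean = np.nanmean(col_mean, axis=0)
        g[miss] = col_mean[np.nonzero(miss)[1]].astype(np.float32)
    g -= g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    g /= sd
    u, s, vt = randomized_svd(g, n_components=n_pcs, random_state=12345)
    pcs = (u * s).astype(np.float64)
    pcs = pcs / pcs.std(axis=0)
    # deterministic sign: largest-magnitude coordinate positive
    flip = np.sign(pcs[np.abs(pcs).argmax(axis=0), np.arange(pcs.shape[1])])
    flip[flip == 0] = 1.0
    return pcs * flip


def _true_subpop_pcs(rng: np.random.Generator, subpops: np.ndarray,
                     n_subpops: int, n_pcs: int, noise: float) -> np.ndarray:
    """PCs taken directly from the truth: contrasts of subpopulation plus noise."""
    n = subpops.size
    pcs = rng.standard_normal((n, n_pcs))
    for k in range(min(n_subpops - 1, n_pcs)):
        ind = (subpops == k + 1).astype(float)
        ind = (ind - ind.mean()) / (ind.std() if ind.std() > 0 else 1.0)
        pcs[:, k] = ind + noise * rng.standard_normal(n)
        pcs[:, k] /= pcs[:, k].std()
    return pcs


def _centre_probs(n_subpops: int) -> np.ndarray:
    """Per-subpopulation assessment-centre distributions, mildly tilted."""
    base = np.array([0.16, 0.15, 0.14, 0.13, 0.12, 0.11, 0.10, 0.09])
    probs = np.empty((n_subpops, base.size))
    for s in range(n_subpops):
        tilt = np.roll(np.linspace(1.25, 0.8, base.size), s * 2)
        p = base * tilt
        probs[s] = p / p.sum()
    return probs


def assign_phenotypes(samples: pd.DataFrame, dosages: np.ndarray,
                      variants: pd.DataFrame, subpops: np.ndarray,
                      config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Fill STATUS from the logistic liability.

    P(case) = expit(intercept + sum causal-effect * dosage
                    + sum covariate effects + confounding * subpop score);
    genetic females are never cases (STATUS = "ineligible"). Every
    liability contribution is mean-centered, so the intercept pins the
    approximate population prevalence regardless of planted effects.
    """
    n = len(samples)
    eta = np.full(n, config.prevalence_intercept)
    m_per = config.variants_per_chromosome
    for chrom, rank, beta in config.causal_effects:
        row = dosages[(chrom - 1) * m_per + rank].astype(float)
        freq = row[row >= 0].mean() / 2.0 if (row >= 0).any() else 0.0
        row[row < 0] = 2.0 * freq  # mean-impute missing for the liability
        eta += beta * (row - 2.0 * freq)
    for cov, beta in config.covariate_effect_sizes.items():
        if beta == 0:
            continue
        if cov == "age":
            age = samples["AGE"].to_numpy(float)
            eta += beta * (age - age.mean()) / age.std()
        elif cov == "chip":
            chip = (samples["CHIP"] == "array1").to_numpy(float)
            eta += beta * (chip - chip.mean())
        else:
            raise ValueError(f"unsupported covariate effect {cov!r}")
    if config.confounding_strength != 0 and config.n_subpops > 1:
        score = subpops.astype(float)
        score = (score - score.mean()) / score.std()
        eta += config.confounding_strength * score
    p = expit(eta)
    is_female = (samples["GENETIC_SEX"] == "F").to_numpy()
    case = (rng.random(n) < p) & ~is_female
    status = np.where(is_female, "ineligible", np.where(case, "case", "control"))
    out = samples.copy()
    out["STATUS"] = status
    return out


def inject_artifacts(samples: pd.DataFrame, variants: pd.DataFrame,
                     dosages: np.ndarray, config: SimulationConfig,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant QC artifacts and draw per-variant INFO scores.

    Sample-level MISS_RATE/HET baselines are the empirical per-sample
    metrics from the dosage matrix; flagged outliers are pushed far outside
    the bulk so that any reasonable mean +/- k*sd rule catches them.
    """
    n = len(samples)
    out = samples.copy()
    miss = (dosages == MISSING)
    out["MISS_RATE"] = miss.mean(axis=0)
    nonmiss = (~miss).sum(axis=0).astype(float)
    nonmiss[nonmiss == 0] = 1.0
    out["HET"] = (dosages == 1).sum(axis=0) / nonmiss
    out["ANEUPLOIDY"] = False

    rates = config.artifact_rates

    def pick(rate: float) -> np.ndarray:
        k = int(round(rate * n))
        k = min(k, n)
        return rng.choice(n, size=k, replace=False) if k else np.empty(0, dtype=int)

    idx = pick(rates.get("sex_mismatch", 0.0))
    if idx.size:
        rep = out["REPORTED_SEX"].to_numpy().copy()
        rep[idx] = np.where(rep[idx] == "M", "F", "M")
        out["REPORTED_SEX"] = rep
    idx = pick(rates.get("aneuploidy", 0.0))
    if idx.size:
        flags = out["ANEUPLOIDY"].to_numpy().copy()
        flags[idx] = True
        out["ANEUPLOIDY"] = flags
    idx = pick(rates.get("missingness_outlier", 0.0))
    if idx.size:
        mr = out["MISS_RATE"].to_numpy().copy()
        mr[idx] = mr[idx] + rng.uniform(0.08, 0.20, size=idx.size)
        out["MISS_RATE"] = np.clip(mr, 0, 1)
    idx = pick(rates.get("het_outlier", 0.0))
    if idx.size:
        het = out["HET"].to_numpy().copy()
        sd = het.std() if het.std() > 0 else 0.01
        shift = (8.0 + rng.uniform(0, 4, size=idx.size)) * sd
        sign = rng.choice([-1.0, 1.0], size=idx.size)
        het[idx] = het[idx] + sign * shift
        out["HET"] = np.clip(het, 0, 1)

    var_out = variants.copy()
    a, b = config.info_beta_params
    var_out["INFO"] = rng.beta(a, b, size=len(variants))
    return out, var_out


def _base_sample_table(config: SimulationConfig, subpops: np.ndarray,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    genetic_sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    age = np.round(rng.uniform(40, 70, size=n), 1)
    centre_probs = _centre_probs(config.n_subpops)
    centres = np.empty(n, dtype=object)
    for s in range(config.n_subpops):
        idx = np.flatnonzero(subpops == s)
        centres[idx] = rng.choice(CENTRES, size=idx.size, p=centre_probs[s])
    chip = np.where(rng.random(n) < 0.112, "array1", "array2")
    return pd.DataFrame(
        {
            "SAMPLE_ID": [f"S{i:06d}" for i in range(n)],
            "REPORTED_SEX": genetic_sex.copy(),
            "GENETIC_SEX": genetic_sex,
            "STATUS": "control",
            "AGE": age,
            "CENTRE": centres,
            "CHIP": chip,
        }
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run the full generator: genotypes, covariates, PCs, phenotypes, artifacts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subpops = rng.integers(0, config.n_subpops, size=config.n_samples)
    dosages, variants, base_p = simulate_genotypes(config, subpops, rng)
    samples = _base_sample_table(config, subpops, rng)
    if config.use_true_subpop_pcs:
        pcs = _true_subpop_pcs(rng, subpops, config.n_subpops, config.n_pcs,
                               config.true_pc_noise)
    else:
        pcs = compute_pcs(dosages, rng, config.pca_max_variants, config.n_pcs)
    for k in range(config.n_pcs):
        samples[f"PC{k + 1}"] = np.round(pcs[:, k], 6)
    samples = assign_phenotypes(samples, dosages, variants, subpops, config, rng)
    samples, variants = inject_artifacts(samples, variants, dosages, config, rng)

    m_per = config.variants_per_chromosome
    causal = pd.DataFrame(
        [
            {
                "ID": variants["ID"].iloc[(c - 1) * m_per + r],
                "CHROM": c,
                "POS": int(variants["POS"].iloc[(c - 1) * m_per + r]),
                "BETA": beta,
            }
            for c, r, beta in config.causal_effects
        ],
        columns=["ID", "CHROM", "POS", "BETA"],
    )
    truth = {"subpop": subpops, "causal": causal, "config": asdict(config)}
    return SyntheticCohort(samples=samples, variants=variants, dosages=dosages, truth=truth)


def published_scale_covariates(n_cases: int = 15_250, n_pool: int = 208_128,
                           seed: int = 0) -> pd.DataFrame:
    """Covariates-only sample table at published biobank scale.

    Exact case and eligible-pool counts by construction (no genotypes, PCs
    drawn as independent standard normals); used for design-size and
    matching-count checks where only the covariate table matters.
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_pool
    status = np.array(["case"] * n_cases + ["control"] * n_pool)
    # cases skew older, echoing the age gradient of prostate cancer
    age = np.where(status == "case",
                   np.clip(rng.normal(64, 5, n), 40, 73),
                   np.clip(rng.normal(57, 8, n), 40, 73)).round(1)
    centre = rng.choice(CENTRES, size=n)
    chip = np.where(rng.random(n) < 0.112, "array1", "array2")
    df = pd.DataFrame(
        {
            "SAMPLE_ID": [f"B{i:06d}" for i in range(n)],
            "REPORTED_SEX": "M",
            "GENETIC_SEX": "M",
            "STATUS": status,
            "AGE": age,
            "CENTRE": centre,
            "CHIP": chip,
        }
    )
    pcs = rng.standard_normal((n, 10))
    for k in range(10):
        df[f"PC{k + 1}"] = np.round(pcs[:, k], 6)
    df["MISS_RATE"] = 0.0
    df["HET"] = 0.2
    df["ANEUPLOIDY"] = False
    # shuffle so cases are not a contiguous block
    order = rng.permutation(n)
    return df.iloc[order].reset_index(drop=True)


def synthetic_benchmark(n_snps: int = 269, slope: float = 1.0,
                        target_r2: float = 0.82, seed: int = 0,
                        flip_fraction: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic stand-in for a published benchmark SNP set.

    Returns ``(benchmark, stats)``: a benchmark table of per-SNP effect
    sizes, and a matching summary-statistics frame whose betas equal
    ``slope * benchmark_beta`` plus Gaussian noise sized so the population
    R-squared of the regression is ``target_r2``. ``flip_fraction`` of the
    stats rows have their alleles swapped and betas negated, exercising
    harmonization.
    """
    rng = np.random.default_rng(seed)
    beta_sd = 0.12
    bench_beta = rng.normal(0.0, beta_sd, size=n_snps)
    noise_sd = abs(slope) * beta_sd * math.sqrt((1.0 - target_r2) / target_r2)
    study_beta = slope * bench_beta + rng.normal(0.0, noise_sd, size=n_snps)
    chrom = rng.integers(1, 23, size=n_snps)
    pos = rng.integers(1, 50_000_000, size=n_snps)
    a0 = NUCLEOTIDES[rng.integers(0, 4, size=n_snps)]
    shift = rng.integers(1, 4, size=n_snps)
    a1 = NUCLEOTIDES[(np.searchsorted(NUCLEOTIDES, a0) + shift) % 4]
    ids = [f"rs{900000 + i}" for i in range(n_snps)]
    benchmark = pd.DataFrame(
        {"ID": ids, "CHROM": chrom, "POS": pos, "EFFECT_ALLELE": a1,
         "OTHER_ALLELE": a0, "BETA": bench_beta}
    )
    flip = rng.random(n_snps) < flip_fraction
    stats = pd.DataFrame(
        {
            "CHROM": chrom,
            "GENPOS": pos,
            "ID": ids,
            "ALLELE0": np.where(flip, a1, a0),
            "ALLELE1": np.where(flip, a0, a1),
            "A1FREQ": rng.uniform(0.05, 0.95, size=n_snps),
            "N": 76_250,
            "BETA": np.where(flip, -study_beta, study_beta),
            "SE": 0.02,
            "CHISQ": 30.0,
            "LOG10P": 8.0,
        }
    )
    return benchmark, stats


# ---------------------------------------------------------------------------
# presets — the fixed study conditions used by the analysis scripts and tests


def desk_preset(seed: int = 0) -> SimulationConfig:
    """Default desk-scale cohort: 4 chromosomes x 5,000 variants, 25,000 men."""
    return SimulationConfig(
        n_samples=25_000,
        n_chromosomes=4,
        variants_per_chromosome=5_000,
        n_subpops=2,
        fst=0.02,
        confounding_strength=0.25,
        causal_effects=[(1, 1200, math.log(1.6)), (2, 2500, math.log(1.5)),
                        (3, 900, math.log(1.7)), (4, 4000, math.log(1.45))],
        causal_base_maf=0.3,
        artifact_rates={"sex_mismatch": 0.002, "aneuploidy": 0.001,
                        "missingness_outlier": 0.002, "het_outlier": 0.002},
        female_fraction=0.05,
        seed=seed,
    )


def null_calibration_preset(seed: int = 0, n_samples: int = 3_000,
                            n_variants: int = 8_000) -> SimulationConfig:
    """No effects, no stratification, independent variants: type-I / lambda checks."""
    return SimulationConfig(
        n_samples=n_samples,
        n_chromosomes=2,
        variants_per_chromosome=n_variants // 2,
        block_size=1,
        within_block_rho=0.0,
        n_subpops=1,
        fst=0.0,
        prevalence_intercept=float(logit(0.10)),
        covariate_effect_sizes={},
        confounding_strength=0.0,
        missing_rate=0.0,
        seed=seed,
    )


def confounded_preset(seed: int = 0) -> SimulationConfig:
    """Two-subpopulation cohort with deliberate case-rate and allele-frequency
    coupling, sized for repeated end-to-end runs.

    PCs are computed from a limited variant panel, so they track the true
    subpopulation imperfectly; a linear PC adjustment then under-corrects
    the stratification, which is exactly the regime where covariate
    matching has something to add over random subsetting.
    """
    return SimulationConfig(
        n_samples=8_000,
        n_chromosomes=2,
        variants_per_chromosome=900,
        block_size=5,
        within_block_rho=0.85,
        n_subpops=2,
        fst=0.05,
        prevalence_intercept=float(logit(0.07)),
        causal_effects=[(1, 200, math.log(2.0)), (1, 650, math.log(1.9)),
                        (2, 450, math.log(2.0))],
        causal_base_maf=0.3,
        confounding_strength=0.7,
        pca_max_variants=200,
        missing_rate=0.0,
        seed=seed,
    )


def planted_recovery_preset(seed: int = 0) -> SimulationConfig:
    """Strong planted effects (analytic power ~ 1) for locus-recovery checks."""
    return SimulationConfig(
        n_samples=5_000,
        n_chromosomes=1,
        variants_per_chromosome=500,
        block_size=10,
        within_block_rho=0.85,
        n_subpops=1,
        fst=0.0,
        prevalence_intercept=float(logit(0.15)),
        causal_effects=[(1, 100, math.log(2.0)), (1, 250, math.log(2.0)),
                        (1, 400, math.log(2.0))],
        causal_base_maf=0.3,
        missing_rate=0.0,
        seed=seed,
    )


def ratio_sweep_preset(seed: int = 0) -> SimulationConfig:
    """Graded planted effects so locus yield climbs, then plateaus, with ratio."""
    effects = [(1, 40, math.log(1.45)), (1, 110, math.log(1.5)),
               (1, 180, math.log(1.55)), (1, 250, math.log(1.6)),
               (1, 320, math.log(1.5)), (1, 390, math.log(1.65))]
    return SimulationConfig(
        n_samples=9_000,
        n_chromosomes=1,
        variants_per_chromosome=450,
        block_size=10,
        within_block_rho=0.85,
        n_subpops=1,
        fst=0.0,
        prevalence_intercept=float(logit(0.055)),
        causal_effects=effects,
        causal_base_maf=0.25,
        missing_rate=0.0,
        seed=seed,
    )
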