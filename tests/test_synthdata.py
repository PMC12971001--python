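"""Generator checks: allele-frequency model, LD structure, phenotype model,
artifact injection, and lossless serialization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import beta as beta_dist, chi2_contingency

from ctrlgwas import io, synthdata
from ctrlgwas.synthdata import MISSING, SimulationConfig


def hudson_fst(freq_a: np.ndarray, freq_b: np.ndarray, n_a: int, n_b: int) -> float:
    """Independent Hudson-estimator oracle, averaged over variants.

    FST = mean numerator / mean denominator with
    num = (pA-pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1), den = pA(1-pB) + pB(1-pA).
    """
    num = (freq_a - freq_b) ** 2 \
        - freq_a * (1 - freq_a) / (n_a - 1) - freq_b * (1 - freq_b) / (n_b - 1)
    den = freq_a * (1 - freq_b) + freq_b * (1 - freq_a)
    return float(num.mean() / den.mean())


def _dosage_freqs(dosages, subpops, missing=MISSING):
    out = []
    for s in np.unique(subpops):
        sub = dosages[:, subpops == s]
        valid = sub != missing
        out.append(np.where(valid, sub, 0).sum(axis=1) / (2 * valid.sum(axis=1)))
    return out


class TestGenotypeModel:
    def test_no_differentiation_recovers_base_frequency(self):
        cfg = SimulationConfig(n_samples=4000, n_chromosomes=1,
                               variants_per_chromosome=200, block_size=1,
                               within_block_rho=0.0, n_subpops=1, fst=0.0,
                               missing_rate=0.0, seed=3)
        subpops = np.zeros(cfg.n_samples, dtype=int)
        dos, _, base_p = synthdata.simulate_genotypes(cfg, subpops)
        emp = dos.mean(axis=1) / 2.0
        se = np.sqrt(base_p * (1 - base_p) / (2 * cfg.n_samples))
        assert np.all(np.abs(emp - base_p) < 5 * se)

    def test_empirical_fst_recovers_config_value(self):
        cfg = SimulationConfig(n_samples=1000, n_chromosomes=1,
                               variants_per_chromosome=2000, block_size=1,
                               within_block_rho=0.0, n_subpops=2, fst=0.05,
                               base_maf_range=(0.1, 0.5), missing_rate=0.0, seed=9)
        rng = np.random.default_rng(cfg.seed)
        subpops = rng.integers(0, 2, size=cfg.n_samples)
        dos, _, _ = synthdata.simulate_genotypes(cfg, subpops, rng)
        fa, fb = _dosage_freqs(dos, subpops)
        n_a = 2 * int((subpops == 0).sum())
        n_b = 2 * int((subpops == 1).sum())
        est = hudson_fst(fa, fb, n_a, n_b)
        assert est == pytest.approx(0.05, abs=0.01)

    def test_unlinked_variants_have_no_dosage_correlation(self):
        cfg = SimulationConfig(n_samples=8000, n_chromosomes=1,
                               variants_per_chromosome=40, block_size=1,
                               within_block_rho=0.0, n_subpops=1, fst=0.0,
                               missing_rate=0.0, seed=21)
        dos, _, _ = synthdata.simulate_genotypes(cfg, np.zeros(8000, dtype=int))
        r = [np.corrcoef(dos[i], dos[i + 1])[0, 1] for i in range(39)]
        assert np.max(np.abs(r)) < 0.05

    def test_adjacent_ld_monotone_in_rho(self):
        mean_r = []
        for rho in (0.0, 0.5, 0.9):
            cfg = SimulationConfig(n_samples=3000, n_chromosomes=1,
                                   variants_per_chromosome=100, block_size=5,
                                   within_block_rho=rho, n_subpops=1, fst=0.0,
                                   missing_rate=0.0, seed=4)
            dos, _, _ = synthdata.simulate_genotypes(cfg, np.zeros(3000, dtype=int))
            rs = []
            for b in range(0, 100, 5):
                for j in range(b, b + 4):
                    rs.append(np.corrcoef(dos[j], dos[j + 1])[0, 1])
            mean_r.append(np.mean(rs))
        assert mean_r[0] < mean_r[1] < mean_r[2]

    def test_rho_one_rejected(self):
        cfg = SimulationConfig(within_block_rho=1.0)
        with pytest.raises(ValueError, match="within_block_rho"):
            cfg.validate()

    def test_determinism_field_for_field(self):
        cfg = SimulationConfig(n_samples=80, n_chromosomes=1,
                               variants_per_chromosome=40, block_size=4,
                               n_subpops=2, fst=0.03, female_fraction=0.3,
                               pca_max_variants=40, missing_rate=0.01, seed=17)
        a = synthdata.simulate_cohort(cfg)
        b = synthdata.simulate_cohort(dataclasses.replace(cfg))
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.truth["subpop"], b.truth["subpop"])


class TestPhenotypeModel:
    def test_intercept_only_prevalence(self):
        cfg = SimulationConfig(n_samples=20000, n_chromosomes=1,
                               variants_per_chromosome=10, block_size=1,
                               prevalence_intercept=float(logit(0.07)),
                               covariate_effect_sizes={}, missing_rate=0.0,
                               pca_max_variants=10, seed=5)
        c = synthdata.simulate_cohort(cfg)
        frac = (c.samples["STATUS"] == "case").mean()
        assert frac == pytest.approx(0.07, abs=3 * np.sqrt(0.07 * 0.93 / 20000))

    def test_planted_effect_detected_by_single_variant_fit(self):
        cfg = SimulationConfig(n_samples=6000, n_chromosomes=1,
                               variants_per_chromosome=50, block_size=1,
                               prevalence_intercept=float(logit(0.15)),
                               causal_effects=[(1, 25, float(np.log(1.5)))],
                               causal_base_maf=0.3, covariate_effect_sizes={},
                               missing_rate=0.0, pca_max_variants=20, seed=6)
        c = synthdata.simulate_cohort(cfg)
        from ctrlgwas.assoc import fit_logistic
        y = (c.samples["STATUS"] == "case").to_numpy(float)
        g = c.dosages[25].astype(float)
        X = np.column_stack([np.ones(len(y)), g])
        fit = fit_logistic(y, X)
        z = fit.beta[1] / fit.se[1]
        assert z > 5  # far beyond null quantiles
        assert fit.beta[1] == pytest.approx(np.log(1.5), abs=0.15)

    def test_confounding_shifts_case_rate_across_subpops(self, small_confounded):
        c = small_confounded
        male = c.samples["GENETIC_SEX"] == "M"
        table = pd.crosstab(c.truth["subpop"][male.to_numpy()],
                            c.samples.loc[male, "STATUS"] == "case")
        chi2, p, _, _ = chi2_contingency(table)
        assert p < 1e-6

    def test_females_never_cases(self, tiny_cohort):
        fem = tiny_cohort.samples["GENETIC_SEX"] == "F"
        assert (tiny_cohort.samples.loc[fem, "STATUS"] == "ineligible").all()


class TestArtifacts:
    def test_zero_rates_flag_nothing(self):
        cfg = SimulationConfig(n_samples=500, n_chromosomes=1,
                               variants_per_chromosome=30, block_size=3,
                               missing_rate=0.0, pca_max_variants=30, seed=8)
        c = synthdata.simulate_cohort(cfg)
        assert (c.samples["REPORTED_SEX"] == c.samples["GENETIC_SEX"]).all()
        assert not c.samples["ANEUPLOIDY"].any()

    def test_sex_mismatch_count_binomial(self):
        cfg = SimulationConfig(n_samples=10000, n_chromosomes=1,
                               variants_per_chromosome=20, block_size=1,
                               artifact_rates={"sex_mismatch": 0.01},
                               missing_rate=0.0, pca_max_variants=20, seed=12)
        c = synthdata.simulate_cohort(cfg)
        n_flag = (c.samples["REPORTED_SEX"] != c.samples["GENETIC_SEX"]).sum()
        assert n_flag == 100  # the generator plants round(rate * n) exactly

    def test_info_fraction_matches_beta_cdf(self):
        a, b = 20.0, 1.5
        cfg = SimulationConfig(n_samples=50, n_chromosomes=2,
                               variants_per_chromosome=2000, block_size=1,
                               info_beta_params=(a, b), missing_rate=0.0,
                               pca_max_variants=50, seed=13)
        c = synthdata.simulate_cohort(cfg)
        frac = (c.variants["INFO"] < 0.7).mean()
        expected = beta_dist.cdf(0.7, a, b)
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert frac == pytest.approx(expected, abs=4 * se)


class TestCohortIO:
    def test_round_trip_identity(self, tiny_cohort, tmp_path):
        io.write_cohort(tiny_cohort, tmp_path / "c")
        back = io.read_cohort(tmp_path / "c")
        pd.testing.assert_frame_equal(
            tiny_cohort.samples[io.SAMPLE_COLUMNS].reset_index(drop=True),
            back.samples, check_dtype=False)
        pd.testing.assert_frame_equal(
            tiny_cohort.variants[io.VARIANT_COLUMNS].reset_index(drop=True),
            back.variants, check_dtype=False)
        assert np.array_equal(tiny_cohort.dosages, back.dosages)
        assert np.array_equal(tiny_cohort.truth["subpop"], back.truth["subpop"])
        pd.testing.assert_frame_equal(tiny_cohort.truth["causal"], back.truth["causal"],
                                      check_dtype=False)
        assert back.truth["config"] == tiny_cohort.truth["config"]

    def test_missing_dosages_survive_round_trip(self, tiny_cohort, tmp_path):
        assert (tiny_cohort.dosages == MISSING).any()
        io.write_cohort(tiny_cohort, tmp_path / "c")
        text = (tmp_path / "c" / "dosages.tsv").read_text()
        assert "\tNA" in text
        back = io.read_cohort(tmp_path / "c")
        assert np.array_equal(back.dosages == MISSING, tiny_cohort.dosages == MISSING)

    def test_write_is_byte_deterministic(self, tiny_cohort, tmp_path):
        io.write_cohort(tiny_cohort, tmp_path / "a")
        io.write_cohort(tiny_cohort, tmp_path / "b")
        for name in ("samples.tsv", "variants.tsv", "dosages.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_truncated_matrix_reports_line(self, tiny_cohort, tmp_path):
        io.write_cohort(tiny_cohort, tmp_path / "c")
        f = tmp_path / "c" / "dosages.tsv"
        lines = f.read_text().splitlines()
        f.write_text("\n".join(lines[:-5]) + "\n")
        with pytest.raises(io.CohortFormatError, match="variant rows"):
            io.read_cohort(tmp_path / "c")

    def test_ragged_row_reports_line_number(self, tiny_cohort, tmp_path):
        io.write_cohort(tiny_cohort, tmp_path / "c")
        f = tmp_path / "c" / "dosages.tsv"
        lines = f.read_text().splitlines()
        lines[3] = "\t".join(lines[3].split("\t")[:-2])
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(io.CohortFormatError, match="line 4"):
            io.read_cohort(tmp_path / "c")


def test_paper_scale_covariate_table_counts():
    df = synthdata.published_scale_covariates(n_cases=1525, n_pool=20812, seed=2)
    assert (df["STATUS"] == "case").sum() == 1525
    assert (df["STATUS"] == "control").sum() == 20812
    assert list(df.columns[:7]) == ["SAMPLE_ID", "REPORTED_SEX", "GENETIC_SEX",
                                    "STATUS", "AGE", "CENTRE", "CHIP"]


def test_synthetic_benchmark_targets_population_r2(rng):
    bench, stats = synthdata.synthetic_benchmark(n_snps=4000, target_r2=0.82, seed=3)
    r = np.corrcoef(bench["BETA"], stats["BETA"])[0, 1]
    assert r ** 2 == pytest.approx(0.82, abs=0.03)
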