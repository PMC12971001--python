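import numpy as np
import pytest

from ctrlgwas import synthdata


@pytest.fixture(scope="session")
def tiny_cohort():
    """50-sample, 2-chromosome cohort with artifacts, for IO/QC tests."""
    cfg = synthdata.SimulationConfig(
        n_samples=50,
        n_chromosomes=2,
        variants_per_chromosome=30,
        block_size=5,
        within_block_rho=0.7,
        n_subpops=2,
        fst=0.05,
        female_fraction=0.2,
        artifact_rates={"sex_mismatch": 0.04, "aneuploidy": 0.02,
                        "missingness_outlier": 0.04, "het_outlier": 0.04},
        missing_rate=0.02,
        pca_max_variants=60,
        seed=11,
    )
    return synthdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_confounded():
    """Small two-subpopulation cohort with planted effects and confounding."""
    cfg = synthdata.confounded_preset(seed=5)
    cfg.n_samples = 4000
    cfg.variants_per_chromosome = 300
    cfg.causal_effects = [(1, 80, float(np.log(2.0))), (1, 220, float(np.log(1.9))),
                          (2, 150, float(np.log(2.0)))]
    return synthdata.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
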