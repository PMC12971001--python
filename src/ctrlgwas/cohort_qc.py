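"""Sample- and variant-level quality control.

Sample filters: reported-vs-genetic sex mismatch, sex-chromosome
aneuploidy, missingness/heterozygosity outliers, and genetic females for
a male-only phenotype. Variant filters, applied to the assembled
analysis cohort of a given design: imputation INFO < 0.7, minor allele
frequency < 1% (recomputed within that cohort), and minor allele count
< 5 on integer dosages. Each removed item is attributed to the first
rule that fails it, in a fixed precedence order, so the report counts
reconcile exactly with the set differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import MISSING


@dataclass
class QCConfig:
    info_min: float = 0.7
    maf_min: float = 0.01
    mac_min: int = 5
    miss_max: float = 0.05
    het_sd: float = 3.0
    exclude_sex_mismatch: bool = True
    exclude_aneuploidy: bool = True
    male_only: bool = True


@dataclass
class QCReport:
    samples_removed: dict[str, int] = field(default_factory=dict)
    variants_removed: dict[str, int] = field(default_factory=dict)
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_variants_in: int = 0
    n_variants_out: int = 0
    n_cases: int = 0
    n_control_pool: int = 0

    def to_dict(self) -> dict:
        return {
            "samples_removed": dict(self.samples_removed),
            "variants_removed": dict(self.variants_removed),
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_variants_in": self.n_variants_in,
            "n_variants_out": self.n_variants_out,
            "n_cases": self.n_cases,
            "n_control_pool": self.n_control_pool,
        }


class NoEligibleSamplesError(ValueError):
    pass


def filter_samples(samples: pd.DataFrame, config: QCConfig | None = None,
                   report: QCReport | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Apply sample QC; returns (eligible samples in input order, report).

    Precedence: sex mismatch -> aneuploidy -> missingness outlier ->
    heterozygosity outlier -> genetic female / ineligible status. The
    het rule is |HET - mean| > het_sd * sd over the input samples.
    """
    config = config or QCConfig()
    report = report or QCReport()
    report.n_samples_in = len(samples)

    removed = np.zeros(len(samples), dtype=bool)
    counts: dict[str, int] = {}

    def apply(name: str, mask: np.ndarray) -> None:
        new = mask & ~removed
        counts[name] = int(new.sum())
        removed[new] = True

    if config.exclude_sex_mismatch:
        apply("sex_mismatch",
              (samples["REPORTED_SEX"] != samples["GENETIC_SEX"]).to_numpy())
    if config.exclude_aneuploidy:
        apply("aneuploidy", samples["ANEUPLOIDY"].to_numpy().astype(bool))
    apply("missingness", (samples["MISS_RATE"] > config.miss_max).to_numpy())
    het = samples["HET"].to_numpy(float)
    apply("heterozygosity", np.abs(het - het.mean()) > config.het_sd * het.std())
    if config.male_only:
        apply("female_or_ineligible",
              ((samples["GENETIC_SEX"] == "F")
               | (samples["STATUS"] == "ineligible")).to_numpy())

    eligible = samples.loc[~removed]
    report.samples_removed = counts
    report.n_samples_out = len(eligible)
    report.n_cases = int((eligible["STATUS"] == "case").sum())
    report.n_control_pool = int((eligible["STATUS"] == "control").sum())
    if len(eligible) == 0:
        raise NoEligibleSamplesError("no eligible samples remain after QC")
    return eligible, report


def recompute_maf(dosages: np.ndarray, sample_rows: np.ndarray) -> np.ndarray:
    """Per-variant MAF over a sample subset; missing dosages excluded.

    Returns NaN (flagged undefined) for variants with no non-missing
    dosage in the subset.
    """
    sample_rows = np.asarray(sample_rows)
    if sample_rows.size == 0:
        raise ValueError("sample subset is empty")
    sub = dosages[:, sample_rows]
    valid = sub != MISSING
    n_valid = valid.sum(axis=1)
    totals = np.where(valid, sub, 0).sum(axis=1, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_valid > 0, totals / (2.0 * n_valid), np.nan)
    return np.where(np.isnan(f), np.nan, np.minimum(f, 1.0 - f))


def minor_allele_counts(dosages: np.ndarray, sample_rows: np.ndarray) -> np.ndarray:
    """Integer minor-allele count per variant over the subset."""
    sub = dosages[:, np.asarray(sample_rows)]
    valid = sub != MISSING
    ac = np.where(valid, sub, 0).sum(axis=1, dtype=np.int64)
    total = 2 * valid.sum(axis=1)
    return np.minimum(ac, total - ac)


def filter_variants(variants: pd.DataFrame, dosages: np.ndarray,
                    analysis_rows: np.ndarray, config: QCConfig | None = None,
                    report: QCReport | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Variant QC on the analysis cohort; precedence INFO -> MAF -> MAC.

    The returned frame keeps the input variant columns, adds the
    recomputed ``MAF`` and a ``ROW`` column holding each variant's row in
    the dosage matrix (so downstream scans can address dosages after
    subsetting). Variants whose MAF is undefined (all dosages missing in
    the cohort) fail the MAF rule.
    """
    config = config or QCConfig()
    report = report or QCReport()
    report.n_variants_in = len(variants)

    rows = (variants["ROW"].to_numpy() if "ROW" in variants.columns
            else variants.index.to_numpy())
    maf = recompute_maf(dosages[rows], np.asarray(analysis_rows))
    mac = minor_allele_counts(dosages[rows], np.asarray(analysis_rows))

    info_fail = variants["INFO"].to_numpy() < config.info_min
    maf_fail = ~(maf >= config.maf_min)  # NaN counts as fail
    mac_fail = mac < config.mac_min

    removed = np.zeros(len(variants), dtype=bool)
    counts: dict[str, int] = {}
    for name, mask in (("info", info_fail), ("maf", maf_fail), ("mac", mac_fail)):
        new = mask & ~removed
        counts[name] = int(new.sum())
        removed[new] = True

    kept = variants.loc[~removed].copy()
    kept["MAF"] = maf[~removed]
    kept["ROW"] = rows[~removed]
    report.variants_removed = counts
    report.n_variants_out = len(kept)
    return kept.reset_index(drop=True), report
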