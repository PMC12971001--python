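"""End-to-end orchestration and the two designed experiments.

``run_strategy_comparison`` takes a cohort from simulation through QC,
the three control-selection designs, per-design association scans,
locus extraction and cross-strategy comparison. ``seed_stability``
repeats random selection under seeds 1..10 on a chromosome subset and
tallies locus counts; ``ratio_sweep`` does the same for matched designs
at case:control ratios 1:2..1:10. Everything is deterministic given the
configured seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cohort_qc, compare, control_select, loci as loci_mod
from .synthdata import SimulationConfig, SyntheticCohort, simulate_cohort

log = logging.getLogger("ctrlgwas")

STRATEGIES = ("all", "matched", "random")


@dataclass
class ExperimentConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: cohort_qc.QCConfig = field(default_factory=cohort_qc.QCConfig)
    loci: loci_mod.LociConfig = field(default_factory=loci_mod.LociConfig)
    assoc: assoc.AssocConfig = field(default_factory=assoc.AssocConfig)
    strategies: tuple[str, ...] = STRATEGIES
    ratio_k: int = 4
    selection_seed: int = 42
    ratio_list: tuple[int, ...] = tuple(range(2, 11))
    stability_seeds: tuple[int, ...] = tuple(range(1, 11))
    chromosome_subset: tuple[int, ...] | None = None  # None -> all
    shared_variant_qc: bool = False  # True: one variant QC on cases+full pool
    out_dir: Path | None = None

    def validate(self) -> None:
        if not self.strategies:
            raise ValueError("strategies must be non-empty")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        if not self.ratio_list:
            raise ValueError("ratio_list must be non-empty")
        if not self.stability_seeds:
            raise ValueError("stability_seeds must be non-empty")


def _stage(name: str):
    log.info("stage=%s start", name)
    return time.time()


def _subset_variants(variants: pd.DataFrame, chroms) -> pd.DataFrame:
    if chroms is None:
        return variants
    return variants[variants["CHROM"].isin(list(chroms))]


def build_design(eligible: pd.DataFrame, strategy: str, ratio_k: int,
                 selection_seed: int,
                 scores: pd.Series | None = None) -> control_select.StudyDesign:
    cfg = control_select.SelectionConfig(strategy=strategy, ratio_k=ratio_k,
                                         seed=selection_seed)
    if strategy == "all":
        return control_select.select_all(eligible)
    if strategy == "random":
        return control_select.select_random(eligible, cfg)
    cases = eligible[eligible["STATUS"] == "case"]
    pool = eligible[eligible["STATUS"] == "control"]
    if scores is None:
        scores = control_select.estimate_propensity(eligible, cfg.ps_covariates)
    return control_select.match_nearest(cases, pool, scores, cfg)


def scan_design(cohort: SyntheticCohort, eligible: pd.DataFrame,
                design: control_select.StudyDesign, config: ExperimentConfig,
                variants: pd.DataFrame | None = None) -> tuple[pd.DataFrame, list]:
    """Per-design variant QC (on the analysis cohort), GWAS, loci."""
    variants = _subset_variants(cohort.variants if variants is None else variants,
                                config.chromosome_subset)
    id_to_row = pd.Series(np.arange(len(cohort.samples)),
                          index=cohort.samples["SAMPLE_ID"])
    analysis_rows = id_to_row[design.case_ids + design.control_ids].to_numpy()
    kept, _ = cohort_qc.filter_variants(variants, cohort.dosages, analysis_rows,
                                        config.qc)
    stats = assoc.run_gwas(cohort.dosages, kept, cohort.samples, design, config.assoc)
    found = loci_mod.extract_loci(stats, config.loci)
    return stats, found


def run_strategy_comparison(config: ExperimentConfig,
                            cohort: SyntheticCohort | None = None) -> dict:
    """Simulate (or accept) a cohort and compare the configured strategies.

    Returns a report dict; writes TSV/JSON artifacts when ``out_dir`` is
    set. Deterministic given the seeds in ``config``.
    """
    config.validate()
    t0 = _stage("simulate")
    if cohort is None:
        cohort = simulate_cohort(config.sim)
    t1 = _stage("sample_qc")
    eligible, qc_report = cohort_qc.filter_samples(cohort.samples, config.qc)

    scores = None
    if "matched" in config.strategies:
        scores = control_select.estimate_propensity(eligible)

    report: dict = {"strategies": {}, "qc": qc_report.to_dict(),
                    "seeds": {"sim": config.sim.seed, "selection": config.selection_seed}}
    per_strategy_loci: dict[str, list] = {}
    per_strategy_stats: dict[str, pd.DataFrame] = {}
    for strategy in config.strategies:
        _stage(f"design[{strategy}]")
        design = build_design(eligible, strategy, config.ratio_k,
                              config.selection_seed, scores)
        _stage(f"gwas[{strategy}]")
        stats, found = scan_design(cohort, eligible, design, config)
        lam = assoc.genomic_lambda(stats) if len(stats) >= 100 else float("nan")
        balance = control_select.balance_diagnostics(design, eligible)
        report["strategies"][strategy] = {
            "n_cases": len(design.case_ids),
            "n_controls": len(design.control_ids),
            "n_total": design.n_total,
            "summary": loci_mod.summarize_stats(stats, config.loci),
            "n_loci": len(found),
            "lambda": lam,
            "mean_abs_smd_after": balance.mean_abs_smd("after"),
            "mean_abs_smd_before": balance.mean_abs_smd("before"),
            "excluded": stats.attrs.get("excluded", {}),
        }
        per_strategy_loci[strategy] = found
        per_strategy_stats[strategy] = stats
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            design.to_frame().to_csv(out / f"design_{strategy}.tsv", sep="\t", index=False)
            assoc.write_summary_stats(stats, out / f"gwas_{strategy}.tsv")
            loci_mod.loci_table(found).to_csv(out / f"loci_{strategy}.tsv",
                                              sep="\t", index=False)

    if len(config.strategies) >= 2:
        _stage("compare")
        report["comparison"] = _compare_strategies(cohort, per_strategy_loci,
                                                   config)
    else:
        report["comparison"] = {}
    if config.out_dir is not None:
        with open(Path(config.out_dir) / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    log.info("run_strategy_comparison done in %.1fs", time.time() - t0)
    return report


def _compare_strategies(cohort: SyntheticCohort, per_strategy_loci: dict,
                        config: ExperimentConfig) -> dict:
    window = config.loci.window_bp
    out: dict = {}
    names = list(per_strategy_loci)
    if len(names) == 3:
        out["venn"] = compare.venn_three(*[per_strategy_loci[n] for n in names],
                                         window_bp=window)
        out["venn_order"] = names
    variant_rows = {vid: i for i, vid in enumerate(cohort.variants["ID"])}
    if "all" in per_strategy_loci:
        ref = per_strategy_loci["all"]
        for other in names:
            if other == "all":
                continue
            lc = compare.ld_consistency(per_strategy_loci[other], ref,
                                        cohort.dosages, variant_rows,
                                        r2_threshold=0.8, window_bp=window)
            out[f"ld_rescue_{other}_vs_all"] = {
                "n_unique": lc.n_unique, "n_high_ld": lc.n_high_ld,
                "percent": lc.high_ld_percent,
            }
            shared = {L.lead_id for L in per_strategy_loci[other]} & \
                     {L.lead_id for L in ref}
            out[f"lead_overlap_{other}_vs_all"] = len(shared)
    return out


def null_variant_lambda(stats: pd.DataFrame, causal: pd.DataFrame,
                        window_bp: int = 500_000) -> float:
    """Genomic-control lambda over variants away from planted causal signals.

    Planted loci would shift the chi-square median and masquerade as
    inflation, so the stratification diagnostic excludes everything within
    the clumping window of a true causal position.
    """
    mask = np.ones(len(stats), dtype=bool)
    for _, row in causal.iterrows():
        mask &= ~((stats["CHROM"] == row["CHROM"])
                  & ((stats["GENPOS"] - row["POS"]).abs() <= window_bp))
    return assoc.genomic_lambda(stats[mask])


def null_calibration(sim_config, qc=None) -> dict:
    """Type-I rate and lambda of the scan on an effect-free cohort."""
    config = ExperimentConfig(sim=sim_config)
    if qc is not None:
        config.qc = qc
    cohort = simulate_cohort(sim_config)
    eligible, _ = cohort_qc.filter_samples(cohort.samples, config.qc)
    design = control_select.select_all(eligible)
    stats, _ = scan_design(cohort, eligible, design, config)
    return {
        "n_variants": len(stats),
        "type1_rate_p05": float((stats["LOG10P"] > -np.log10(0.05)).mean()),
        "lambda": assoc.genomic_lambda(stats),
    }


def strategy_replicates(make_sim_config, seeds, ratio_k: int = 4,
                        selection_seed: int = 42) -> pd.DataFrame:
    """Per-seed confounding diagnostics for the three designs.

    For each seed: simulate, QC, build matched / random / all designs, scan
    each, record null-variant lambda and the lead-SNP overlap of matched and
    random with the all-controls reference.
    """
    rows = []
    for seed in seeds:
        sim = make_sim_config(seed)
        config = ExperimentConfig(sim=sim, ratio_k=ratio_k,
                                  selection_seed=selection_seed)
        cohort = simulate_cohort(sim)
        eligible, _ = cohort_qc.filter_samples(cohort.samples, config.qc)
        scores = control_select.estimate_propensity(eligible)
        rec = {"seed": seed}
        leads = {}
        for strategy in ("matched", "random", "all"):
            design = build_design(eligible, strategy, ratio_k, selection_seed,
                                  scores)
            stats, found = scan_design(cohort, eligible, design, config)
            rec[f"lambda_{strategy}"] = null_variant_lambda(
                stats, cohort.truth["causal"], config.loci.window_bp)
            rec[f"n_loci_{strategy}"] = len(found)
            leads[strategy] = {L.lead_id for L in found}
        rec["conc_matched"] = len(leads["matched"] & leads["all"])
        rec["conc_random"] = len(leads["random"] & leads["all"])
        rows.append(rec)
        log.info("replicate seed=%d lambda m/r/a %.3f/%.3f/%.3f conc %d/%d",
                 seed, rec["lambda_matched"], rec["lambda_random"],
                 rec["lambda_all"], rec["conc_matched"], rec["conc_random"])
    return pd.DataFrame(rows)


def planted_recovery(make_sim_config, seeds, ratio_k: int = 4,
                     window_bp: int = 500_000) -> dict:
    """Fraction of planted causal loci recovered within the clumping window.

    Per seed the matched 1:k design is scanned and every planted causal
    position is checked for a detected locus whose lead falls within
    +/- window of it.
    """
    hits = 0
    total = 0
    for seed in seeds:
        sim = make_sim_config(seed)
        config = ExperimentConfig(sim=sim, ratio_k=ratio_k)
        cohort = simulate_cohort(sim)
        eligible, _ = cohort_qc.filter_samples(cohort.samples, config.qc)
        design = build_design(eligible, "matched", ratio_k, config.selection_seed)
        _, found = scan_design(cohort, eligible, design, config)
        for _, row in cohort.truth["causal"].iterrows():
            total += 1
            if any(L.chrom == row["CHROM"]
                   and abs(L.lead_pos - row["POS"]) <= window_bp for L in found):
                hits += 1
    return {"recovered": hits, "planted": total,
            "recovery_rate": hits / total if total else float("nan")}


def ratio_plateau(make_sim_config, seeds, ratio_list=tuple(range(2, 11))) -> dict:
    """Mean locus count per ratio and the early/late marginal gains.

    Averages ratio_sweep over seeds and contrasts the mean per-step gain up
    to 1:6 with the mean gain beyond it (the diminishing-returns check).
    """
    tables = []
    for seed in seeds:
        config = ExperimentConfig(sim=make_sim_config(seed), ratio_list=tuple(ratio_list))
        tables.append(ratio_sweep(config).set_index("RATIO_K")["N_LOCI"])
    mean_counts = pd.concat(tables, axis=1).mean(axis=1)
    gains = mean_counts.diff().dropna()
    early = float(gains[gains.index <= 6].mean())
    late = float(gains[gains.index > 6].mean())
    return {"mean_counts": mean_counts.to_dict(), "early_gain": early,
            "late_gain": late}


def seed_stability(config: ExperimentConfig,
                   cohort: SyntheticCohort | None = None) -> dict:
    """Random-selection stability: locus count per seed on a chromosome subset."""
    config.validate()
    if cohort is None:
        cohort = simulate_cohort(config.sim)
    eligible, _ = cohort_qc.filter_samples(cohort.samples, config.qc)
    counts: dict[int, int] = {}
    for seed in config.stability_seeds:
        cfg = control_select.SelectionConfig(strategy="random",
                                             ratio_k=config.ratio_k, seed=seed)
        design = control_select.select_random(eligible, cfg)
        _, found = scan_design(cohort, eligible, design, config)
        counts[seed] = len(found)
        log.info("stability seed=%d loci=%d", seed, len(found))
    values = list(counts.values())
    modal = max(set(values), key=values.count)
    return {
        "counts": counts,
        "modal_count": modal,
        "deviating_seeds": [s for s, c in counts.items() if c != modal],
        "spread": max(values) - min(values),
    }


def ratio_sweep(config: ExperimentConfig,
                cohort: SyntheticCohort | None = None) -> pd.DataFrame:
    """Locus count per matched case:control ratio (the plateau experiment)."""
    config.validate()
    if cohort is None:
        cohort = simulate_cohort(config.sim)
    eligible, _ = cohort_qc.filter_samples(cohort.samples, config.qc)
    cases = eligible[eligible["STATUS"] == "case"]
    pool = eligible[eligible["STATUS"] == "control"]
    max_k = len(pool) // max(len(cases), 1)
    ratios = [k for k in config.ratio_list if k <= max_k]
    if len(ratios) < len(config.ratio_list):
        log.warning("ratio list truncated to 1:%d (pool %d, cases %d)",
                    max_k, len(pool), len(cases))
    scores = control_select.estimate_propensity(eligible)
    rows = []
    for k in ratios:
        cfg = control_select.SelectionConfig(strategy="matched", ratio_k=k,
                                             seed=config.selection_seed)
        design = control_select.match_nearest(cases, pool, scores, cfg)
        _, found = scan_design(cohort, eligible, design, config)
        rows.append({"RATIO_K": k, "N_TOTAL": design.n_total, "N_LOCI": len(found)})
        log.info("ratio k=%d loci=%d", k, len(found))
    return pd.DataFrame(rows)
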