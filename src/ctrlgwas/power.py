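"""Analytic and empirical power for the additive allelic case-control test.

The analytic engine is the standard normal approximation to the log
odds-ratio estimate of a 2x2 allelic table: with control risk-allele
frequency p0 (odds q0 = p0/(1-p0)) the case frequency under a per-allele
odds ratio OR is p1 = OR*q0 / (1 + OR*q0), the variance of the log-OR is

    V = 1/(2*n_cases*p1*(1-p1)) + 1/(2*n_controls*p0*(1-p0)),

and two-sided power at level alpha is
Phi(|ln OR|/sqrt(V) - z_{1-alpha/2}) + Phi(-|ln OR|/sqrt(V) - z_{1-alpha/2}).

``empirical_power`` is the Monte-Carlo counterpart: it samples
case/control genotype counts from the exact retrospective logistic model
(case genotype distribution proportional to HWE(p0) * OR^g) and runs the
same Wald test the genome scan uses on the aggregated 6-cell data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import fit_logistic


@dataclass
class PowerQuery:
    n_cases: int
    n_controls: int
    maf: float
    odds_ratio: float
    alpha: float = 5e-8

    def validate(self) -> None:
        # risk-allele frequency; values above 0.5 parametrize a major risk
        # allele (equivalently a protective minor allele with OR -> 1/OR)
        if not (0 < self.maf < 1):
            raise ValueError(f"maf must be in (0, 1), got {self.maf}")
        if self.odds_ratio <= 0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")


def case_allele_frequency(p0: float, odds_ratio: float) -> float:
    q0 = p0 / (1.0 - p0)
    return odds_ratio * q0 / (1.0 + odds_ratio * q0)


def analytic_power(query: PowerQuery) -> float:
    """Two-sided power of the additive allelic test (normal approximation)."""
    query.validate()
    p0 = query.maf
    p1 = case_allele_frequency(p0, query.odds_ratio)
    v = (1.0 / (2.0 * query.n_cases * p1 * (1.0 - p1))
         + 1.0 / (2.0 * query.n_controls * p0 * (1.0 - p0)))
    z_crit = norm.ppf(1.0 - query.alpha / 2.0)
    ncp = abs(math.log(query.odds_ratio)) / math.sqrt(v)
    return float(norm.cdf(ncp - z_crit) + norm.cdf(-ncp - z_crit))


def power_curve(n_cases: int, ratio_k: int, maf_grid, or_list,
                alpha: float = 5e-8) -> pd.DataFrame:
    """Plot-ready MAF x OR power table with n_controls = ratio_k * n_cases."""
    maf_grid = list(maf_grid)
    or_list = list(or_list)
    if not maf_grid or not or_list:
        raise ValueError("maf_grid and or_list must be non-empty")
    rows = [
        {"MAF": maf, "OR": orr,
         "POWER": analytic_power(PowerQuery(n_cases, ratio_k * n_cases, maf, orr, alpha))}
        for orr in or_list for maf in maf_grid
    ]
    return pd.DataFrame(rows)


def _case_genotype_probs(p0: float, odds_ratio: float) -> np.ndarray:
    """Case genotype distribution under retrospective sampling of the
    additive logistic model: P(g|case) proportional to HWE(p0) * OR^g."""
    hwe = np.array([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0 ** 2])
    w = hwe * odds_ratio ** np.arange(3)
    return w / w.sum()


def empirical_power(query: PowerQuery, n_reps: int = 2_000,
                    rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo power of the Wald dosage test at the query's settings.

    Each replicate draws genotype counts for cases and controls and fits
    the dosage-only logistic model on the aggregated six cells; a success
    is a Wald chi-square exceeding the two-sided alpha threshold.
    """
    query.validate()
    rng = rng or np.random.default_rng()
    p0 = query.maf
    probs_ctrl = np.array([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0 ** 2])
    probs_case = _case_genotype_probs(p0, query.odds_ratio)
    chi_crit = norm.ppf(1.0 - query.alpha / 2.0) ** 2

    X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]] * 2)
    y = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    case_draws = rng.multinomial(query.n_cases, probs_case, size=n_reps)
    ctrl_draws = rng.multinomial(query.n_controls, probs_ctrl, size=n_reps)
    hits = 0
    for rep in range(n_reps):
        w = np.concatenate([case_draws[rep], ctrl_draws[rep]]).astype(float)
        mask = w > 0
        fit = fit_logistic(y[mask], X[mask], weights=w[mask], tol=1e-8, max_iter=50)
        if not fit.converged:
            continue
        se2 = fit.cov[1, 1]
        if not np.isfinite(se2) or se2 <= 0:
            continue
        if fit.beta[1] ** 2 / se2 > chi_crit:
            hits += 1
    return hits / n_reps


def resource_reduction(n_full: int, n_sub: int, complexity_exponent: float = 1.0) -> int:
    """Percent compute saved by analysing n_sub of n_full samples, for an
    O(N^exponent) algorithm; rounded to the nearest integer percent."""
    if not (0 < n_sub <= n_full):
        raise ValueError("need 0 < n_sub <= n_full")
    if complexity_exponent < 1:
        raise ValueError("complexity_exponent must be >= 1")
    return int(round(100.0 * (1.0 - (n_sub / n_full) ** complexity_exponent)))
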