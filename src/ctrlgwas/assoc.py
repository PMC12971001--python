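"""Covariate-adjusted per-variant association scan.

The engine is a plain maximum-likelihood logistic regression fitted by
iteratively reweighted least squares (IRLS); each variant's additive
dosage is tested with a 1-df Wald chi-square, adjusting for the standard
13 covariates (recruitment age, assessment centre, genotyping chip, 10
principal components). Output mimics the familiar whole-genome
regression summary-statistics layout: CHROM GENPOS ID ALLELE0 ALLELE1
A1FREQ N BETA SE CHISQ LOG10P.

p-values are computed in log space, so signals far beyond ``1e-300``
keep a finite LOG10P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .synthdata import MISSING

# median of a central 1-df chi-square
CHI2_MEDIAN_1DF = 0.4549364

DEFAULT_COVARIATES = ["age", "centre", "chip"] + [f"PC{i}" for i in range(1, 11)]


class SeparationError(RuntimeError):
    """The likelihood has no finite maximizer (perfect separation)."""


def chisq_to_log10p(chisq) -> np.ndarray | float:
    """-log10 of the two-sided p for a 1-df chi-square, in log space.

    Uses sf(x) = 2 * Phi(-sqrt(x)); the normal log-survival stays accurate
    far beyond where the p-value itself underflows (log10p > 300).
    """
    return -(math.log(2.0) + norm.logsf(np.sqrt(chisq))) / math.log(10.0)


@dataclass
class AssocConfig:
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    mac_min: int = 5
    irls_tol: float = 1e-8
    irls_max_iter: int = 25


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    loglik: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic(y: np.ndarray, X: np.ndarray, *, weights: np.ndarray | None = None,
                 beta0: np.ndarray | None = None, tol: float = 1e-8,
                 max_iter: int = 25) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS (Newton-Raphson).

    ``weights`` are prior counts (for aggregated data); the covariance is
    the inverse observed information. Divergence of the linear predictor
    beyond +/-30 for all observations of a class marks non-convergence
    rather than raising, so a genome scan can tally and move on.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    w_prior = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = w_prior * mu * (1.0 - mu)
        # guard against zero-weight collapse
        w = np.maximum(w, 1e-12)
        z = w_prior * (y - mu)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ z
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            H = H + np.eye(p) * 1e-8
            step = np.linalg.solve(H, g)
        # damp huge steps (early iterations on separated-ish data)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step = step * (10.0 / norm)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 100.0:  # runaway: separation
            break

    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(w_prior * mu * (1.0 - mu), 1e-12)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(w_prior * (y * np.log(np.clip(mu, 1e-300, 1)) +
                                     (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1)))))
    return LogisticFit(beta=beta, cov=cov, converged=converged, n_iter=it, loglik=ll)


def build_covariate_matrix(samples: pd.DataFrame,
                           covariates: Sequence[str] = DEFAULT_COVARIATES,
                           add_intercept: bool = True) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix for the requested covariates.

    ``age`` enters as-is, ``centre``/``chip`` as indicator contrasts with
    the most frequent level as reference, PCs as-is. Constant columns are
    dropped (they carry no information and break the Newton solve).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(samples)))
        names.append("intercept")
    for cov in covariates:
        if cov == "age":
            cols.append(samples["AGE"].to_numpy(float))
            names.append("age")
        elif cov in ("centre", "chip"):
            key = cov.upper()
            levels = samples[key].value_counts()
            ref = levels.index[0]
            for lev in sorted(l for l in levels.index if l != ref):
                cols.append((samples[key] == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        elif cov.startswith("PC"):
            cols.append(samples[cov].to_numpy(float))
            names.append(cov)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = np.column_stack(cols)
    keep = [i for i in range(X.shape[1])
            if names[i] == "intercept" or X[:, i].std() > 0]
    return X[:, keep], [names[i] for i in keep]


def run_gwas(dosages: np.ndarray, variants: pd.DataFrame, samples: pd.DataFrame,
             design, config: AssocConfig | None = None) -> pd.DataFrame:
    """Wald scan of every variant on the given study design.

    ``design`` is a StudyDesign (case/control id lists); ``variants`` may be
    a QC-filtered subset carrying the original row indices of ``dosages`` in
    a ``ROW`` column (defaults to its positional index). Untestable variants
    (MAC below threshold, zero variance, non-convergence) are excluded; the
    per-reason tally is attached as ``result.attrs['excluded']``.
    """
    config = config or AssocConfig()
    id_to_row = pd.Series(np.arange(len(samples)), index=samples["SAMPLE_ID"])
    try:
        case_rows = id_to_row[design.case_ids].to_numpy()
        ctrl_rows = id_to_row[design.control_ids].to_numpy()
    except KeyError as exc:
        raise ValueError(f"design sample id not present in cohort: {exc}") from exc
    rows = np.concatenate([case_rows, ctrl_rows])
    y = np.concatenate([np.ones(len(case_rows)), np.zeros(len(ctrl_rows))])
    sub = samples.iloc[rows]
    X, _ = build_covariate_matrix(sub, config.covariates)
    null_fit = fit_logistic(y, X, tol=config.irls_tol, max_iter=config.irls_max_iter)
    if not null_fit.converged:
        raise SeparationError("covariate-only null model did not converge")

    var_rows = variants["ROW"].to_numpy() if "ROW" in variants.columns else variants.index.to_numpy()
    Xg = np.column_stack([X, np.zeros(len(rows))])
    warm = np.append(null_fit.beta, 0.0)
    gcol = X.shape[1]

    records = []
    excluded = {"low_mac": 0, "zero_variance": 0, "non_convergent": 0}
    for out_i, vrow in enumerate(var_rows):
        d = dosages[vrow, rows].astype(float)
        miss = d == MISSING
        if miss.any():
            keep = ~miss
            d_use = d[keep]
            X_use = np.column_stack([X[keep], d_use])
            y_use = y[keep]
        else:
            d_use = d
            Xg[:, gcol] = d
            X_use = Xg
            y_use = y
        n_use = d_use.size
        ac = d_use.sum()
        mac = min(ac, 2 * n_use - ac)
        if mac < config.mac_min:
            excluded["low_mac"] += 1
            continue
        if d_use.std() == 0:
            excluded["zero_variance"] += 1
            continue
        fit = fit_logistic(y_use, X_use, beta0=warm, tol=config.irls_tol,
                           max_iter=config.irls_max_iter)
        if not fit.converged or not np.isfinite(fit.cov[gcol, gcol]) or fit.cov[gcol, gcol] <= 0:
            excluded["non_convergent"] += 1
            continue
        beta = fit.beta[gcol]
        se = math.sqrt(fit.cov[gcol, gcol])
        chisq = (beta / se) ** 2
        log10p = float(chisq_to_log10p(chisq))
        v = variants.iloc[out_i]
        records.append((int(v["CHROM"]), int(v["POS"]), v["ID"], v["ALLELE0"],
                        v["ALLELE1"], ac / (2 * n_use), n_use, beta, se, chisq, log10p))

    out = pd.DataFrame(records, columns=["CHROM", "GENPOS", "ID", "ALLELE0", "ALLELE1",
                                         "A1FREQ", "N", "BETA", "SE", "CHISQ", "LOG10P"])
    out = out.sort_values(["CHROM", "GENPOS"], kind="mergesort").reset_index(drop=True)
    out.attrs["excluded"] = excluded
    out.attrs["meta"] = {
        "strategy": getattr(design, "strategy", "unknown"),
        "seed": getattr(design, "seed", None),
        "n_cases": len(case_rows),
        "n_controls": len(ctrl_rows),
    }
    return out


def genomic_lambda(stats: pd.DataFrame | np.ndarray) -> float:
    """Genomic-control inflation factor: median chi-square over its null median."""
    chisq = stats["CHISQ"].to_numpy() if isinstance(stats, pd.DataFrame) else np.asarray(stats)
    if chisq.size < 100:
        raise ValueError(f"need >= 100 test statistics for a stable lambda, got {chisq.size}")
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> Path:
    """REGENIE-flavoured TSV with '##' metadata header records."""
    path = Path(path)
    meta = stats.attrs.get("meta", {})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"##{k}={v}\n")
        stats.to_csv(fh, sep="\t", index=False)
    return path


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            k, _, v = line[2:].rstrip("\n").partition("=")
            meta[k] = v
            skip += 1
    out = pd.read_csv(path, sep="\t", skiprows=skip)
    out.attrs["meta"] = meta
    return out
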