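"""Three control-selection strategies and covariate-balance diagnostics.

* ``select_all``    — every eligible non-case is a control.
* ``select_random`` — uniform sample without replacement of k controls
  per case under a fixed seed.
* nearest-neighbour propensity matching — a case-vs-pool logistic model
  on the 13 covariates gives each sample a probability-scale score;
  cases are processed hardest-first (descending score) and each takes
  its k nearest still-available pool members by absolute score
  difference, without replacement. Ties break on the smaller pool index,
  so matching is fully deterministic given the scores.

Balance is reported as standardized mean differences and empirical
quantile-quantile (eQQ) discrepancies per covariate, before (cases vs
the full pool) and after (cases vs selected controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .assoc import DEFAULT_COVARIATES, build_covariate_matrix, fit_logistic


class PoolTooSmallError(ValueError):
    pass


@dataclass
class SelectionConfig:
    strategy: str = "matched"  # {"all", "random", "matched"}
    ratio_k: int = 4
    seed: int = 42
    ps_covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    caliper: float | None = None
    case_order: str = "descending"  # or "data"
    passes: str = "batch"  # "batch": k at once per case; "sequential": k 1:1 rounds
    allow_partial: bool = False


@dataclass
class StudyDesign:
    strategy: str
    case_ids: list[str]
    control_ids: list[str]
    pairing: dict[str, list[str]] = field(default_factory=dict)
    seed: int | None = None
    ratio_k: int | None = None

    def __post_init__(self) -> None:
        cases = set(self.case_ids)
        if cases & set(self.control_ids):
            raise ValueError("control ids overlap case ids")
        if len(set(self.control_ids)) != len(self.control_ids):
            raise ValueError("duplicate control id: selection must be without replacement")

    @property
    def n_total(self) -> int:
        return len(self.case_ids) + len(self.control_ids)

    def to_frame(self) -> pd.DataFrame:
        ctrl_to_case: dict[str, str] = {}
        for case, ctrls in self.pairing.items():
            for c in ctrls:
                ctrl_to_case[c] = case
        rows = [{"SAMPLE_ID": s, "ROLE": "case", "MATCHED_CASE_ID": "",
                 "STRATEGY": self.strategy, "SEED": self.seed}
                for s in self.case_ids]
        rows += [{"SAMPLE_ID": s, "ROLE": "control",
                  "MATCHED_CASE_ID": ctrl_to_case.get(s, ""),
                  "STRATEGY": self.strategy, "SEED": self.seed}
                 for s in self.control_ids]
        return pd.DataFrame(rows)


@dataclass
class BalanceReport:
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    eqq_mean: dict[str, float]
    eqq_max: dict[str, float]
    constant_covariates: list[str]
    n_cases: int
    n_controls: int

    def mean_abs_smd(self, when: str = "after") -> float:
        d = self.smd_after if when == "after" else self.smd_before
        vals = [abs(v) for v in d.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def _split_case_pool(eligible: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cases = eligible[eligible["STATUS"] == "case"]
    pool = eligible[eligible["STATUS"] == "control"]
    return cases, pool


def select_all(eligible: pd.DataFrame) -> StudyDesign:
    """All eligible non-cases become controls."""
    cases, pool = _split_case_pool(eligible)
    if len(pool) == 0:
        raise PoolTooSmallError("eligible control pool is empty")
    return StudyDesign(strategy="all", case_ids=list(cases["SAMPLE_ID"]),
                       control_ids=list(pool["SAMPLE_ID"]))


def select_random(eligible: pd.DataFrame, config: SelectionConfig) -> StudyDesign:
    """Seeded uniform subsample of k controls per case, without replacement."""
    cases, pool = _split_case_pool(eligible)
    need = config.ratio_k * len(cases)
    if len(pool) < need:
        raise PoolTooSmallError(
            f"random selection needs {need} controls but only {len(pool)} are eligible")
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(len(pool), size=need, replace=False)
    return StudyDesign(strategy="random",
                       case_ids=list(cases["SAMPLE_ID"]),
                       control_ids=list(pool["SAMPLE_ID"].iloc[np.sort(chosen)]),
                       seed=config.seed, ratio_k=config.ratio_k)


def estimate_propensity(eligible: pd.DataFrame,
                        ps_covariates: list[str] | None = None) -> pd.Series:
    """Case-vs-pool logistic propensity score on the probability scale."""
    covs = ps_covariates or list(DEFAULT_COVARIATES)
    y = (eligible["STATUS"] == "case").to_numpy(float)
    X, _ = build_covariate_matrix(eligible, covs)
    fit = fit_logistic(y, X, tol=1e-8, max_iter=50)
    if not fit.converged:
        raise RuntimeError(
            "propensity model did not converge (possible separation); "
            "review the covariate list")
    scores = expit(X @ fit.beta)
    if np.min(scores) < 1e-12 or np.max(scores) > 1 - 1e-12:
        raise RuntimeError("propensity scores degenerate at 0/1: perfect separation; "
                           "review the covariate list")
    return pd.Series(scores, index=eligible.index, name="propensity")


def match_nearest(cases: pd.DataFrame, pool: pd.DataFrame,
                  scores: pd.Series, config: SelectionConfig) -> StudyDesign:
    """Greedy nearest-neighbour 1:k matching without replacement.

    Distance is the absolute probability-scale score difference; each
    case claims its k nearest still-available pool members (all at once
    by default, or one per round with ``passes='sequential'``). Ties are
    broken by the smaller pool row position. Deterministic given scores.
    """
    k = config.ratio_k
    n_cases = len(cases)
    if len(pool) < k * n_cases and not config.allow_partial:
        raise PoolTooSmallError(
            f"matching needs {k * n_cases} controls but only {len(pool)} are available "
            "(set allow_partial to accept incomplete matching)")

    case_scores = scores.loc[cases.index].to_numpy()
    pool_scores = scores.loc[pool.index].to_numpy()
    pool_ids = pool["SAMPLE_ID"].to_numpy()
    case_ids = cases["SAMPLE_ID"].to_numpy()

    order = np.argsort(pool_scores, kind="mergesort")  # stable: ties keep pool order
    s_sorted = pool_scores[order]
    orig = np.arange(len(pool))[order]  # pool row position of each sorted slot
    npool = len(pool)
    # linked list over sorted slots with offset-1 indexing: entry j is slot
    # j-1, so slot s reads nxt[s+1]/prv[s+1]; npool acts as right sentinel
    nxt = np.arange(0, npool + 2)   # nxt[s+1] == s+1
    prv = np.arange(-2, npool)      # prv[s+1] == s-1

    def remove(slot: int) -> None:
        r, l = nxt[slot + 1], prv[slot + 1]
        if l >= 0:
            nxt[l + 1] = r
        if r <= npool:
            prv[r + 1] = l

    def take_k(score: float, want: int, caliper: float | None) -> list[int]:
        """Sorted-slot indices of the ``want`` nearest alive pool members.

        Walks outward from the insertion point on the alive linked list;
        dead slots keep stale links that always point further outward
        through other dead slots, so the walk never skips a live one.
        """
        pos = int(np.searchsorted(s_sorted, score))
        l = pos - 1
        trail = []
        while l >= 0 and not alive[l]:
            trail.append(l)
            l = prv[l + 1]
        for t in trail:  # path compression over the dead region
            prv[t + 1] = l
        r = pos
        trail = []
        while r < npool and not alive[r]:
            trail.append(r)
            r = nxt[r + 1]
        for t in trail:
            nxt[t + 1] = r
        cand: list[tuple[float, int, int]] = []
        nl = nr = 0
        while (nl < want and l >= 0) or (nr < want and r < npool):
            if nl < want and l >= 0:
                cand.append((abs(score - s_sorted[l]), orig[l], l))
                nl += 1
                l = prv[l + 1]
            if nr < want and r < npool:
                cand.append((abs(score - s_sorted[r]), orig[r], r))
                nr += 1
                r = nxt[r + 1]
        cand.sort()
        if cand:
            # extend through exact-distance ties at the cutoff so the
            # pool-index tie-break sees every tied candidate
            dk = cand[min(want, len(cand)) - 1][0]
            while l >= 0 and abs(score - s_sorted[l]) == dk:
                cand.append((dk, orig[l], l))
                l = prv[l + 1]
            while r < npool and abs(score - s_sorted[r]) == dk:
                cand.append((dk, orig[r], r))
                r = nxt[r + 1]
            cand.sort()
        if caliper is not None:
            cand = [c for c in cand if c[0] <= caliper]
        chosen = cand[:want]
        for _, _, slot in chosen:
            alive[slot] = False
            remove(slot)
        return [slot for _, _, slot in chosen]

    alive = np.ones(npool, dtype=bool)
    n_alive = npool
    if config.case_order == "descending":
        case_order = np.argsort(-case_scores, kind="mergesort")
    elif config.case_order == "data":
        case_order = np.arange(n_cases)
    else:
        raise ValueError(f"unknown case_order {config.case_order!r}")

    pairing: dict[str, list[str]] = {cid: [] for cid in case_ids}
    rounds = k if config.passes == "sequential" else 1
    per_round = 1 if config.passes == "sequential" else k
    for _ in range(rounds):
        for ci in case_order:
            want = min(per_round, n_alive)
            if want == 0:
                break
            slots = take_k(case_scores[ci], want, config.caliper)
            n_alive -= len(slots)
            pairing[case_ids[ci]].extend(pool_ids[orig[s]] for s in slots)

    control_ids = [c for cid in case_ids for c in pairing[cid]]
    return StudyDesign(strategy="matched", case_ids=list(case_ids),
                       control_ids=control_ids, pairing=pairing,
                       seed=config.seed, ratio_k=k)


def select_controls(eligible: pd.DataFrame, config: SelectionConfig) -> StudyDesign:
    """Dispatch on ``config.strategy``."""
    if config.strategy == "all":
        return select_all(eligible)
    if config.strategy == "random":
        return select_random(eligible, config)
    if config.strategy == "matched":
        cases, pool = _split_case_pool(eligible)
        scores = estimate_propensity(eligible, config.ps_covariates)
        return match_nearest(cases, pool, scores, config)
    raise ValueError(f"unknown strategy {config.strategy!r}")


def _numeric_balance_columns(samples: pd.DataFrame,
                             covariates: list[str]) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = samples["AGE"].to_numpy(float)
        elif cov in ("centre", "chip"):
            key = cov.upper()
            for lev in sorted(samples[key].unique()):
                cols[f"{cov}[{lev}]"] = (samples[key] == lev).to_numpy(float)
        elif cov.startswith("PC"):
            cols[cov] = samples[cov].to_numpy(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return cols


def standardized_mean_difference(x_case: np.ndarray, x_ctrl: np.ndarray) -> float:
    """SMD = (mean_case - mean_ctrl) / sqrt((var_case + var_ctrl)/2); 0 if constant."""
    denom = np.sqrt((x_case.var(ddof=1) + x_ctrl.var(ddof=1)) / 2.0)
    if denom == 0:
        return 0.0
    return float((x_case.mean() - x_ctrl.mean()) / denom)


def _eqq(x_case: np.ndarray, x_ctrl: np.ndarray) -> tuple[float, float]:
    """Mean and max absolute quantile difference at the smaller group's size."""
    n = min(x_case.size, x_ctrl.size)
    q = (np.arange(n) + 0.5) / n
    qc = np.quantile(x_case, q)
    qk = np.quantile(x_ctrl, q)
    d = np.abs(qc - qk)
    return float(d.mean()), float(d.max())


def balance_diagnostics(design: StudyDesign, eligible: pd.DataFrame,
                        covariates: list[str] | None = None) -> BalanceReport:
    covs = covariates or list(DEFAULT_COVARIATES)
    by_id = eligible.set_index("SAMPLE_ID")
    cases = by_id.loc[design.case_ids].reset_index()
    pool = eligible[eligible["STATUS"] == "control"]
    selected = by_id.loc[design.control_ids].reset_index()

    smd_before: dict[str, float] = {}
    smd_after: dict[str, float] = {}
    eqq_mean: dict[str, float] = {}
    eqq_max: dict[str, float] = {}
    constant: list[str] = []
    case_cols = _numeric_balance_columns(cases, covs)
    pool_cols = _numeric_balance_columns(pool, covs)
    sel_cols = _numeric_balance_columns(selected, covs)
    for name in case_cols:
        xc = case_cols[name]
        xp = pool_cols.get(name, np.zeros(len(pool)))
        xs = sel_cols.get(name, np.zeros(len(selected)))
        if xc.std() == 0 and xs.std() == 0:
            constant.append(name)
        smd_before[name] = standardized_mean_difference(xc, xp)
        smd_after[name] = standardized_mean_difference(xc, xs)
        m, mx = _eqq(xc, xs)
        eqq_mean[name] = m
        eqq_max[name] = mx
    return BalanceReport(smd_before=smd_before, smd_after=smd_after,
                         eqq_mean=eqq_mean, eqq_max=eqq_max,
                         constant_covariates=constant,
                         n_cases=len(cases), n_controls=len(selected))
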