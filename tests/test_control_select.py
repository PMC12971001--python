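"""Control selection: strategy contracts, a naive greedy-matching oracle,
closed-form propensity checks and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ctrlgwas import cohort_qc, control_select
from ctrlgwas.control_select import (PoolTooSmallError, SelectionConfig,
                                     StudyDesign, standardized_mean_difference)


def _eligible(n_cases, n_pool, seed=0):
    rng = np.random.default_rng(seed)
    n = n_cases + n_pool
    df = pd.DataFrame(
        {
            "SAMPLE_ID": [f"S{i}" for i in range(n)],
            "REPORTED_SEX": "M",
            "GENETIC_SEX": "M",
            "STATUS": ["case"] * n_cases + ["control"] * n_pool,
            "AGE": rng.uniform(40, 70, n).round(1),
            "CENTRE": rng.choice(["C01", "C02", "C03"], n),
            "CHIP": rng.choice(["array1", "array2"], n),
        }
    )
    for k in range(1, 11):
        df[f"PC{k}"] = rng.standard_normal(n)
    return df


class TestSelectAll:
    def test_whole_pool_selected(self):
        d = control_select.select_all(_eligible(5, 10))
        assert len(d.control_ids) == 10
        assert d.n_total == 15
        assert d.pairing == {}

    def test_empty_pool_errors(self):
        df = _eligible(5, 3)
        df["STATUS"] = "case"
        with pytest.raises(PoolTooSmallError):
            control_select.select_all(df)


class TestSelectRandom:
    def test_exact_count_and_reproducibility(self):
        df = _eligible(50, 400)
        cfg = SelectionConfig(strategy="random", ratio_k=4, seed=42)
        d1 = control_select.select_random(df, cfg)
        d2 = control_select.select_random(df, cfg)
        assert len(d1.control_ids) == 200
        assert d1.control_ids == d2.control_ids
        d3 = control_select.select_random(df, SelectionConfig(strategy="random",
                                                              ratio_k=4, seed=43))
        assert set(d3.control_ids) != set(d1.control_ids)

    def test_pool_exactly_k_times_cases_takes_everyone(self):
        df = _eligible(30, 120)
        d = control_select.select_random(df, SelectionConfig(strategy="random", ratio_k=4))
        assert set(d.control_ids) == set(df.loc[df.STATUS == "control", "SAMPLE_ID"])

    def test_pool_too_small_names_requirement(self):
        df = _eligible(30, 100)
        with pytest.raises(PoolTooSmallError, match="120.*100"):
            control_select.select_random(df, SelectionConfig(strategy="random", ratio_k=4))


class TestPropensity:
    def test_null_covariates_give_flat_scores(self):
        df = _eligible(300, 2700, seed=1)
        scores = control_select.estimate_propensity(df)
        assert scores.mean() == pytest.approx(0.1, abs=0.01)
        assert scores.std() < 0.05

    def test_single_binary_covariate_matches_2x2_closed_form(self):
        # stratum rates: chip array1 cases 30/70, array2 cases 20/180
        rows = []
        for status, chip, n in [("case", "array1", 30), ("control", "array1", 40),
                                ("case", "array2", 20), ("control", "array2", 160)]:
            rows += [{"STATUS": status, "CHIP": chip}] * n
        df = pd.DataFrame(rows)
        df["SAMPLE_ID"] = [f"S{i}" for i in range(len(df))]
        df["AGE"] = 55.0
        scores = control_select.estimate_propensity(df, ps_covariates=["chip"])
        got = df.assign(ps=scores).groupby("CHIP")["ps"].mean()
        assert got["array1"] == pytest.approx(30 / 70, abs=1e-6)
        assert got["array2"] == pytest.approx(20 / 180, abs=1e-6)

    def test_confounded_cohort_separates_mean_scores(self, small_confounded):
        el, _ = cohort_qc.filter_samples(small_confounded.samples)
        scores = control_select.estimate_propensity(el)
        mean_case = scores[(el.STATUS == "case").to_numpy()].mean()
        mean_ctrl = scores[(el.STATUS == "control").to_numpy()].mean()
        assert mean_case > mean_ctrl


def oracle_greedy_match(case_scores, pool_scores, k):
    """Straightforward restatement of the matching rule: cases in descending
    score order (ties by case index), each takes its k nearest available
    controls by |score difference| with ties by smaller pool index."""
    available = list(range(len(pool_scores)))
    order = sorted(range(len(case_scores)), key=lambda i: (-case_scores[i], i))
    pairing = {}
    for ci in order:
        ranked = sorted(available,
                        key=lambda j: (abs(pool_scores[j] - case_scores[ci]), j))
        take = ranked[:k]
        pairing[ci] = take
        for j in take:
            available.remove(j)
    return pairing


class TestMatchNearest:
    def _frames(self, case_scores, pool_scores):
        cases = pd.DataFrame({"SAMPLE_ID": [f"case{i}" for i in range(len(case_scores))],
                              "STATUS": "case"})
        pool = pd.DataFrame({"SAMPLE_ID": [f"ctrl{j}" for j in range(len(pool_scores))],
                             "STATUS": "control"})
        df = pd.concat([cases, pool], ignore_index=True)
        scores = pd.Series(np.concatenate([case_scores, pool_scores]), index=df.index)
        return df.iloc[:len(case_scores)], df.iloc[len(case_scores):], scores

    def test_exact_duplicate_scores_match_their_own(self):
        case_scores = np.array([0.2, 0.5, 0.8])
        pool_scores = np.repeat(case_scores, 4) + 0.0
        cases, pool, scores = self._frames(case_scores, pool_scores)
        d = control_select.match_nearest(cases, pool, scores, SelectionConfig(ratio_k=4))
        for i, cid in enumerate(d.case_ids):
            expected = {f"ctrl{j}" for j in range(4 * i, 4 * i + 4)}
            assert set(d.pairing[cid]) == expected

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_naive_greedy_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        case_scores = rng.random(5)
        pool_scores = rng.random(20)
        if trial % 3 == 0:  # quantize to force exact-distance ties
            case_scores = np.round(case_scores, 1)
            pool_scores = np.round(pool_scores, 1)
        cases, pool, scores = self._frames(case_scores, pool_scores)
        d = control_select.match_nearest(cases, pool, scores, SelectionConfig(ratio_k=2))
        expected = oracle_greedy_match(case_scores, pool_scores, 2)
        for ci, pool_idx in expected.items():
            assert d.pairing[f"case{ci}"] == [f"ctrl{j}" for j in pool_idx]

    def test_complete_matching_sizes(self):
        rng = np.random.default_rng(3)
        cases, pool, scores = self._frames(rng.random(40), rng.random(400))
        d = control_select.match_nearest(cases, pool, scores, SelectionConfig(ratio_k=4))
        assert d.n_total == 200
        assert all(len(v) == 4 for v in d.pairing.values())
        assert len(set(d.control_ids)) == len(d.control_ids)

    def test_insufficient_pool_raises_unless_partial(self):
        rng = np.random.default_rng(4)
        cases, pool, scores = self._frames(rng.random(10), rng.random(15))
        with pytest.raises(PoolTooSmallError):
            control_select.match_nearest(cases, pool, scores, SelectionConfig(ratio_k=2))
        d = control_select.match_nearest(
            cases, pool, scores, SelectionConfig(ratio_k=2, allow_partial=True))
        assert len(d.control_ids) == 15

    def test_deterministic_given_scores(self):
        rng = np.random.default_rng(5)
        cases, pool, scores = self._frames(rng.random(8), rng.random(50))
        d1 = control_select.match_nearest(cases, pool, scores, SelectionConfig(ratio_k=3))
        d2 = control_select.match_nearest(cases, pool, scores, SelectionConfig(ratio_k=3))
        assert d1.pairing == d2.pairing

    def test_sequential_passes_mode_runs_k_rounds(self):
        rng = np.random.default_rng(6)
        cases, pool, scores = self._frames(rng.random(5), rng.random(30))
        d = control_select.match_nearest(
            cases, pool, scores, SelectionConfig(ratio_k=3, passes="sequential"))
        assert all(len(v) == 3 for v in d.pairing.values())
        assert len(set(d.control_ids)) == 15


class TestStudyDesignInvariants:
    def test_duplicate_control_rejected(self):
        with pytest.raises(ValueError, match="without replacement"):
            StudyDesign(strategy="x", case_ids=["a"], control_ids=["b", "b"])

    def test_case_control_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StudyDesign(strategy="x", case_ids=["a"], control_ids=["a"])


class TestBalance:
    def test_smd_hand_computation(self):
        x_case = np.array([1.0, 2.0, 3.0])
        x_ctrl = np.array([2.0, 4.0, 6.0])
        expected = (2.0 - 4.0) / np.sqrt((1.0 + 4.0) / 2.0)
        assert standardized_mean_difference(x_case, x_ctrl) == pytest.approx(
            expected, abs=1e-12)

    def test_identical_distributions_zero_smd(self):
        df = _eligible(30, 30, seed=7)
        df.loc[df.STATUS == "control", df.columns[4:]] = \
            df.loc[df.STATUS == "case", df.columns[4:]].to_numpy()
        d = control_select.select_all(df)
        rep = control_select.balance_diagnostics(d, df)
        assert all(abs(v) < 1e-12 for v in rep.smd_after.values())

    def test_constant_covariate_flagged_zero(self):
        df = _eligible(10, 20, seed=8)
        df["AGE"] = 60.0
        d = control_select.select_all(df)
        rep = control_select.balance_diagnostics(d, df)
        assert rep.smd_after["age"] == 0.0
        assert "age" in rep.constant_covariates

    def test_matching_beats_random_balance_under_confounding(self, small_confounded):
        el, _ = cohort_qc.filter_samples(small_confounded.samples)
        scores = control_select.estimate_propensity(el)
        cases = el[el.STATUS == "case"]
        pool = el[el.STATUS == "control"]
        dm = control_select.match_nearest(cases, pool, scores, SelectionConfig(ratio_k=4))
        dr = control_select.select_random(el, SelectionConfig(strategy="random",
                                                              ratio_k=4, seed=42))
        bm = control_select.balance_diagnostics(dm, el)
        br = control_select.balance_diagnostics(dr, el)
        assert bm.mean_abs_smd("after") < br.mean_abs_smd("after")
        # matching improves on the raw pool by a clear margin
        assert bm.mean_abs_smd("after") < 0.8 * bm.mean_abs_smd("before")
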