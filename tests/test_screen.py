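"""Retention filter, NIPALS PLS-DA, permutation VIP, t-test/BH screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mucimine.screen import (
    FilterThresholds,
    PLSDA,
    differential_ttest,
    filter_hmms,
    pls_cv_accuracy,
    pls_fit,
    pls_variable_significance,
    select_candidates,
)


def bh_stepup_oracle(p):
    """Textbook Benjamini-Hochberg step-up q-values (independent oracle)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def make_T(rows, index=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    index = index or [f"h{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=index,
                        columns=[f"s{k}" for k in range(rows.shape[1])])


class TestFilter:
    def test_spec_examples(self):
        th = FilterThresholds(16, 5)
        T = make_T([[4, 4, 4, 4, 4, 1],      # total 21, coverage 6 -> keep
                    [20, 5, 0, 0, 0, 0],     # coverage 2 -> drop
                    [4, 4, 4, 2, 1, 1]])     # total 16 exactly -> drop (strict)
        res = filter_hmms(T, th)
        assert res.retained == ["h0"]
        assert res.table.loc["h1", "subject_coverage"] == 2

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        T = make_T(rng.integers(0, 6, (8, 7)).astype(float))
        th = FilterThresholds(float(rng.integers(0, 20)), int(rng.integers(0, 7)))
        res = filter_hmms(T, th)
        brute = [h for h in T.index
                 if sum(T.loc[h]) > th.min_total_abundance
                 and sum(v > 0 for v in T.loc[h]) > th.min_subject_coverage]
        assert res.retained == brute
        stricter = filter_hmms(T, FilterThresholds(
            th.min_total_abundance + 1, th.min_subject_coverage + 1))
        assert set(stricter.retained) <= set(res.retained)


class TestPLSDA:
    def test_first_weight_matches_covariance_direction(self):
        X = np.column_stack([[1, 1, -1, -1], [1, -1, 1, -1]]).astype(float)
        y = ["case", "case", "control", "control"]
        model = pls_fit(X, y, n_components=1)
        w = model.x_weights_[:, 0]
        np.testing.assert_allclose(np.abs(w), [1.0, 0.0], atol=1e-12)

    def test_first_weight_parallel_to_xty_random(self, rng):
        for _ in range(20):
            X = rng.normal(size=(20, 8))
            y01 = rng.integers(0, 2, 20)
            while len(set(y01)) < 2:
                y01 = rng.integers(0, 2, 20)
            y = np.where(y01 == 1, "case", "control")
            model = pls_fit(X, y, 3)
            target = (X - X.mean(0)).T @ (y01 - y01.mean())
            cos = model.x_weights_[:, 0] @ target / np.linalg.norm(target)
            assert cos >= 1 - 1e-10

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.where(rng.integers(0, 2, 30) == 1, "case", "control")
        model = pls_fit(X, y, 4)
        G = model.x_scores_.T @ model.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_duplicated_feature_columns_get_equal_weights(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, x])
        y = np.where(x[:, 0] > 0, "case", "control")
        model = pls_fit(X, y, 1)
        assert abs(model.x_weights_[0, 0] - model.x_weights_[1, 0]) < 1e-10

    def test_single_feature_rank_truncation_warns(self, rng):
        X = rng.normal(size=(12, 1))
        y = np.where(X[:, 0] > 0, "case", "control")
        with pytest.warns(RuntimeWarning, match="truncated"):
            model = pls_fit(X, y, 3)
        assert model.n_components_ == 1

    def test_constant_labels_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="two group"):
            pls_fit(X, ["case"] * 10, 2)

    def test_sklearn_cross_check(self, rng):
        """Predictions agree with sklearn's PLSRegression on the same encoding."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(25, 6))
        y01 = rng.integers(0, 2, 25).astype(float)
        y = np.where(y01 == 1, "case", "control")
        ours = pls_fit(X, y, 3).decision_function(X)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y01)
        theirs = ref.predict(X).ravel()
        np.testing.assert_allclose(ours, theirs, atol=1e-8)


class TestCrossValidation:
    def test_separable_clusters_classified_perfectly(self):
        rng = np.random.default_rng(7)
        n = 100
        X = rng.normal(size=(n, 10))
        y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        X[:n // 2, 0] += 10.0  # gap of 10 sigma on one feature
        assert pls_cv_accuracy(X, y, 5, 10, seed=0) == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 10))
            y = np.where(rng.permutation(200) < 100, "case", "control")
            accs.append(pls_cv_accuracy(X, y, 1, 10, seed=seed))
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_identical_rows_per_class_trivial(self):
        X = np.vstack([np.tile([1.0, 0.0], (6, 1)), np.tile([0.0, 1.0], (6, 1))])
        y = np.array(["case"] * 6 + ["control"] * 6)
        assert pls_cv_accuracy(X, y, 1, 2, seed=0) == 1.0

    def test_reproducible_given_seed(self, rng):
        X = rng.normal(size=(40, 12))
        y = np.where(rng.integers(0, 2, 40) == 1, "case", "control")
        while len(set(y)) < 2 or min((y == "case").sum(), (y == "control").sum()) < 10:
            y = np.where(rng.integers(0, 2, 40) == 1, "case", "control")
        assert pls_cv_accuracy(X, y, 2, 5, 3) == pls_cv_accuracy(X, y, 2, 5, 3)


class TestVariableSignificance:
    def test_planted_feature_hits_small_p(self):
        rng = np.random.default_rng(5)
        n = 100
        X = rng.normal(size=(n, 51))
        y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        X[:n // 2, 0] += 3.0
        p = pls_variable_significance(X, y, 2, n_perm=999, seed=1)
        assert p[0] <= 0.01

    def test_permutation_floor(self):
        # all features share the same marginal scale; only feature 0's
        # bimodality aligns with the labels, so its VIP tops every null fit
        rng = np.random.default_rng(6)
        n = 40
        y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        X = rng.choice([-4.0, 4.0], size=(n, 10)) + rng.normal(size=(n, 10))
        X[:, 0] = np.where(y == "case", 4.0, -4.0) + rng.normal(size=n)
        p = pls_variable_significance(X, y, 1, n_perm=999, seed=2)
        assert p.min() == pytest.approx(1 / 1000)
        assert (p >= 1 / 1000).all() and (p <= 1.0).all()

    def test_requires_reasonable_n_perm(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array(["case"] * 5 + ["control"] * 5)
        with pytest.raises(ValueError):
            pls_variable_significance(X, y, 1, n_perm=10)


class TestDifferentialTtest:
    def test_closed_form_toy(self):
        T = make_T([[1, 2, 3, 4, 5, 6]])
        groups = {f"s{k}": ("case" if k < 3 else "control") for k in range(6)}
        out = differential_ttest(T, groups)
        assert out.loc["h0", "t_stat"] == pytest.approx(-3.6742346141747673)
        assert out.loc["h0", "p_raw"] == pytest.approx(0.021311641128756713)
        assert out.loc["h0", "enriched_in"] == "control"

    def test_all_3v3_integer_toys_match_closed_form(self, rng):
        from scipy import stats as ss
        groups = {f"s{k}": ("case" if k < 3 else "control") for k in range(6)}
        for _ in range(50):
            row = rng.integers(0, 10, 6).astype(float)
            out = differential_ttest(make_T([row]), groups)
            a, b = row[:3], row[3:]
            if np.var(a) + np.var(b) == 0:
                continue
            # closed-form pooled-variance t
            sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
            p = 2 * ss.t.sf(abs(t), 4)
            assert out.loc["h0", "t_stat"] == pytest.approx(t)
            assert out.loc["h0", "p_raw"] == pytest.approx(p)

    def test_identical_groups_degenerate(self):
        T = make_T([[2, 2, 2, 2, 2, 2]])
        groups = {f"s{k}": ("case" if k < 3 else "control") for k in range(6)}
        out = differential_ttest(T, groups)
        assert out.loc["h0", "t_stat"] == 0.0
        assert out.loc["h0", "p_raw"] == 1.0
        assert bool(out.loc["h0", "t_degenerate"])

    def test_bh_hand_example(self):
        T = make_T(np.vstack([
            [0.0, 0.1, 0.2, 10.0, 10.1, 10.2],
            [1, 2, 3, 4, 5, 6],
            [1, 2, 3, 3, 2, 1],
            [5, 6, 7, 1, 2, 3],
        ]))
        groups = {f"s{k}": ("case" if k < 3 else "control") for k in range(6)}
        out = differential_ttest(T, groups, fdr_alpha=0.05)
        q_oracle = bh_stepup_oracle(out["p_raw"].values)
        np.testing.assert_allclose(out["q_bh"].values, q_oracle, rtol=1e-12)
        assert (out["q_bh"].values >= out["p_raw"].values - 1e-15).all()

    def test_bh_known_vector(self):
        # q of [0.01, 0.02, 0.03, 0.04] is 0.04 everywhere by step-up
        np.testing.assert_allclose(
            bh_stepup_oracle([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bh_equivalence_random_pvectors(self, seed):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 40))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh_stepup_oracle(p), rtol=1e-12)


class TestSelectCandidates:
    def _screen(self, abund, pls, diff):
        return pd.DataFrame({
            "total_abundance": abund,
            "pls_significant": pls,
            "differential": diff,
        }, index=[f"h{i}" for i in range(len(abund))])

    def test_both_gates_required_and_ranked(self):
        scr = self._screen([5, 50, 20, 7, 1],
                           [True, True, True, False, False],
                           [True, True, False, True, False])
        cand = select_candidates(scr)
        assert list(cand.index) == ["h1", "h0"]

    def test_empty_candidate_set(self):
        scr = self._screen([1.0], [False], [False])
        assert select_candidates(scr).empty

    def test_iqr_outlier_rule(self):
        scr = self._screen([1, 1, 1, 1, 100], [True] * 5, [True] * 5)
        cand = select_candidates(scr)
        assert list(cand.index)[0] == "h4"
        assert cand["outlier"].tolist() == [True, False, False, False, False]
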