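"""Feature-selection cascade: filters, rankings, MI criteria, RFA."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from radstab.selection import (CascadeConfig, SelectorSpec,
                               bin_equal_frequency, greedy_mi_select,
                               mad_filter, mutual_info, rank_features,
                               recursive_feature_addition, score_filter,
                               select_cascade, univariate_top, welch_t)


class TestMadFilter:
    def test_zero_mad_columns_dropped(self):
        df = pd.DataFrame({"const": [2.0] * 4, "spiky": [1.0, 1.0, 1.0, 9.0],
                           "varied": [1.0, 2.0, 3.0, 4.0]})
        assert list(mad_filter(df).columns) == ["varied"]

    def test_all_dropped_raises(self):
        df = pd.DataFrame({"a": [1.0] * 5, "b": [3.0] * 5})
        with pytest.raises(ValueError):
            mad_filter(df)


class TestUnivariateTop:
    def test_keep_count_is_ceil_of_fraction(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 718)))
        df.columns = [f"f{j}" for j in range(718)]
        y = np.array([0, 1] * 10)
        assert univariate_top(df, y, 0.20).shape[1] == 144 == math.ceil(
            0.20 * 718)

    def test_perfect_separator_survives(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 15)
        df = pd.DataFrame(rng.normal(size=(30, 10)),
                          columns=[f"n{j}" for j in range(10)])
        df["sep"] = y * 10.0 + rng.normal(0, 0.01, 30)
        kept = univariate_top(df, y, 0.10)  # keeps ceil(1.1) = 2
        assert "sep" in kept.columns

    def test_ranking_matches_direct_t_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 20))
        y = np.array([0] * 5 + [1] * 5)
        t = welch_t(x, y)
        for j in range(20):
            a, b = x[y == 1, j], x[y == 0, j]
            direct = (a.mean() - b.mean()) / np.sqrt(
                a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
            assert t[j] == pytest.approx(direct, abs=1e-12)


class TestScoreFilters:
    def _sep_fixture(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 20)
        df = pd.DataFrame({"perfect": y.astype(float),
                           "noise": rng.normal(size=40)})
        return df, y

    def test_perfect_separator_ranked_first_everywhere(self):
        df, y = self._sep_fixture()
        for name in ("FSCR", "GINI", "CHSQ", "TSCR", "RELF"):
            ranked = score_filter(df, y, SelectorSpec(name))
            assert ranked.names[0] == "perfect", name

    def test_gini_perfect_split_equals_parent_impurity(self):
        df, y = self._sep_fixture()
        ranked = score_filter(df, y, SelectorSpec("GINI"))
        assert ranked.scores[0] == pytest.approx(0.5)  # balanced parent

    def test_chsq_null_calibration(self):
        from scipy.stats import chi2
        rng = np.random.default_rng(4)
        exceed = 0
        for r in range(60):
            df = pd.DataFrame({"x": rng.normal(size=200)})
            y = rng.integers(0, 2, 200)
            s = score_filter(df, y, SelectorSpec("CHSQ")).scores[0]
            exceed += s > chi2.ppf(0.99, df=9)
        assert exceed <= 6  # ~1% expected; allow generous margin

    def test_relieff_detects_xor_interaction(self):
        rng = np.random.default_rng(5)
        n = 200
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = a ^ b
        df = pd.DataFrame({
            "xor_a": a + rng.normal(0, 0.05, n),
            "xor_b": b + rng.normal(0, 0.05, n),
            "noise": rng.normal(size=n)})
        ranked = score_filter(df, y, SelectorSpec("RELF"))
        assert ranked.names.index("noise") == 2


class TestMutualInfo:
    def test_independent_product_table_zero(self):
        # exact product structure: X uniform on {0,1}, Y uniform on {0,1}
        x = np.array([0, 0, 1, 1] * 10)
        y = np.array([0, 1, 0, 1] * 10)
        assert mutual_info(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_identical_balanced_binary_is_ln2(self):
        x = np.array([0, 1] * 20)
        assert mutual_info(x, x) == pytest.approx(np.log(2), abs=1e-12)

    def test_printed_2x2_table_hand_value(self):
        # [[30,10],[10,30]]: plug-in I = sum p log p/(px py)
        x = np.repeat([0, 0, 1, 1], [30, 10, 10, 30])
        y = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
        hand = sum(c / 80 * np.log((c / 80) / (0.5 * 0.5))
                   for c in (30, 10, 10, 30))
        assert mutual_info(x, y) == pytest.approx(hand, abs=1e-12)

    def test_conditional_mi_chain(self):
        # Z = X: I(X;Y|Z) must vanish
        rng = np.random.default_rng(6)
        x = rng.integers(0, 2, 100)
        y = rng.integers(0, 2, 100)
        assert mutual_info(x, y, z=x) == pytest.approx(0.0, abs=1e-12)


class TestGreedyMi:
    def _fixture(self):
        rng = np.random.default_rng(7)
        n = 60
        y = np.array([0, 1] * 30)
        informative = y + rng.normal(0, 0.4, n)
        df = pd.DataFrame({
            "inf": informative,
            "dup": informative.copy(),
            "weak": y + rng.normal(0, 2.0, n),
            "n1": rng.normal(size=n),
            "n2": rng.normal(size=n),
            "n3": rng.normal(size=n)})
        return df, y

    def test_first_pick_is_max_relevance_for_all(self):
        df, y = self._fixture()
        rel = {c: mutual_info(df[c].to_numpy(), y) for c in df.columns}
        best = max(df.columns, key=lambda c: rel[c])
        for name in ("MIM", "MIFS", "MRMR", "JMI", "CIFE", "CMIM", "ICAP",
                     "DISR"):
            ranked = greedy_mi_select(df, y, SelectorSpec(name), k_select=3)
            assert ranked.names[0] == best, name

    def test_redundancy_penalty_defers_duplicate(self):
        df, y = self._fixture()
        for name in ("MIFS", "MRMR", "CIFE", "ICAP"):
            ranked = greedy_mi_select(df, y, SelectorSpec(name), k_select=2)
            assert ranked.names[1] != "dup", name

    def test_greedy_mrmr_equals_exhaustive_argmax(self):
        df, y = self._fixture()
        spec = SelectorSpec("MRMR")
        ranked = greedy_mi_select(df, y, spec, k_select=4)
        binned = {c: bin_equal_frequency(df[c].to_numpy(), spec.mi_bins)
                  for c in df.columns}
        selected = []
        for step in range(4):
            best_name, best_score = None, -np.inf
            for c in df.columns:          # exhaustive criterion evaluation
                if c in selected:
                    continue
                rel = mutual_info(binned[c], y)
                red = (np.mean([mutual_info(binned[c], binned[s])
                                for s in selected]) if selected else 0.0)
                score = rel - red
                if score > best_score + 1e-15:
                    best_name, best_score = c, score
            selected.append(best_name)
        assert ranked.names == selected

    def test_column_order_invariance_of_score_ranking(self):
        df, y = self._fixture()
        perm = ["n2", "inf", "weak", "n3", "dup", "n1"]
        a = score_filter(df, y, SelectorSpec("FSCR"))
        b = score_filter(df[perm], y, SelectorSpec("FSCR"))
        assert set(a.names[:2]) == set(b.names[:2])


class TestRfa:
    def test_perfect_feature_kept_duplicates_rejected(self):
        rng = np.random.default_rng(8)
        y = np.array([0, 1] * 20)
        df = pd.DataFrame({"perfect": y + rng.normal(0, 0.05, 40),
                           "copy": y + rng.normal(0, 0.05, 40),
                           "noise": rng.normal(size=40)})
        kept, trace = recursive_feature_addition(
            ["perfect", "copy", "noise"], df, y,
            LogisticRegression(max_iter=500), cv=5, seed=0)
        assert kept == ["perfect"]
        assert trace[-1] > 0.95

    def test_deterministic_given_seed(self, planted_table):
        df, y = planted_table
        args = (list(df.columns[:10]), df, y,
                LogisticRegression(max_iter=500))
        a = recursive_feature_addition(*args, cv=5, seed=3)
        b = recursive_feature_addition(*args, cv=5, seed=3)
        assert a == b

    def test_noise_ranking_stays_near_chance(self):
        rng = np.random.default_rng(9)
        aucs, sizes = [], []
        for r in range(5):
            df = pd.DataFrame(rng.normal(size=(60, 12)),
                              columns=[f"f{j}" for j in range(12)])
            y = np.array([0, 1] * 30)
            kept, trace = recursive_feature_addition(
                list(df.columns), df, y, LogisticRegression(max_iter=500),
                cv=5, seed=r)
            sizes.append(len(kept))
            aucs.append(trace[-1])
        assert np.mean(sizes) <= 4
        assert 0.35 <= np.mean(aucs) <= 0.72


class TestCascade:
    def test_nesting_of_cascade_stages(self, planted_table):
        df, y = planted_table
        t1 = mad_filter(df)
        t2 = univariate_top(t1, y, 0.20)
        selected = select_cascade(df, y, SelectorSpec("MRMR"),
                                  CascadeConfig(budget_k=5, rfa_cv=3))
        assert set(selected) <= set(t2.columns) <= set(t1.columns)

    def test_planted_features_recovered_by_mi_selectors(self, planted_table):
        df, y = planted_table
        planted = {f"f{j:02d}" for j in range(5)}
        for name in ("MIM", "MRMR", "JMI"):
            ranked = rank_features(df, y, SelectorSpec(name), k_select=10)
            assert len(planted & set(ranked.names[:10])) >= 3, name
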