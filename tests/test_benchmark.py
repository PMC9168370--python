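"""SMOTE, AUC/RSD metrics, CV evaluation, grid combinatorics, leakage."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radstab.benchmark import (CvPlan, ModelSpec, best_model,
                               cv_evaluate, label_outcomes, run_grid, smote,
                               smote_balance)
from radstab.metrics import auc_score, confusion_metrics, rsd
from radstab.selection import CascadeConfig, SelectorSpec


def brute_force_auc(y, s):
    """Exhaustive positive/negative pair counting with half-credit ties."""
    pos = s[np.asarray(y) == 1]
    neg = s[np.asarray(y) == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8])
        assert auc_score(y, s) == 0.75 == brute_force_auc(y, s)

    def test_rank_formula_equals_pair_counting(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = rng.integers(6, 31)
            y = np.zeros(n, int)
            y[: rng.integers(2, n - 1)] = 1
            rng.shuffle(y)
            s = np.round(rng.normal(size=n), 1)  # induce ties
            assert auc_score(y, s) == pytest.approx(
                brute_force_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score(np.ones(4), np.arange(4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.integers(-5, 5)),
                    min_size=4, max_size=25))
    def test_rank_formula_property(self, pairs):
        y = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs], dtype=float) / 2.0
        if y.sum() in (0, len(y)):
            return
        assert auc_score(y, s) == pytest.approx(brute_force_auc(y, s),
                                                abs=1e-12)
        # complementing the scores flips the AUC
        assert auc_score(y, -s) == pytest.approx(1 - auc_score(y, s),
                                                 abs=1e-12)


class TestRsd:
    def test_worked_example(self):
        assert rsd(np.array([0.8, 0.9, 1.0])) == pytest.approx(100 * 0.1
                                                               / 0.9)

    def test_constant_aucs_zero(self):
        assert rsd(np.array([0.7] * 10)) == 0.0

    def test_scale_invariance(self):
        a = np.array([0.6, 0.7, 0.9])
        assert rsd(a) == pytest.approx(rsd(0.5 * a))


class TestSmote:
    def test_synthetic_count(self):
        x = np.random.default_rng(1).normal(size=(5, 3))
        assert smote(x, 5, seed=0).shape == (5, 3)

    def test_convex_combination_coordinatewise(self):
        x = np.random.default_rng(2).normal(size=(6, 4))
        synth = smote(x, 20, seed=1)
        for row in synth:
            lo = x.min(axis=0) - 1e-12
            hi = x.max(axis=0) + 1e-12
            assert np.all(row >= lo) and np.all(row <= hi)

    def test_identical_points_produce_identical_synthetics(self):
        x = np.tile([[1.0, 2.0]], (2, 1))
        synth = smote(x, 4, k=1, seed=0)
        assert np.allclose(synth, [1.0, 2.0])

    def test_balance_to_parity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 5))
        y = np.array([1] * 22 + [0] * 8)
        xb, yb = smote_balance(x, y, seed=0)
        assert (yb == 0).sum() == (yb == 1).sum() == 22

    def test_too_few_minority_rejected(self):
        with pytest.raises(ValueError):
            smote(np.ones((1, 2)), 3)


def _grid_sources(n=30, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * 21 + [0] * 9)
    rng.shuffle(y)
    sources = {}
    for name, p in (("Radiomics", 40), ("BankA", 20), ("BankB", 20)):
        x = rng.standard_normal((n, p))
        x[:, 0] += 1.5 * y
        x[:, 1] += 1.0 * y
        sources[name] = pd.DataFrame(
            x, columns=[f"{name}_f{j}" for j in range(p)],
            index=[f"S{i}" for i in range(n)])
    return sources, y


class TestCvEvaluate:
    def test_separable_labels_perfect_auc(self):
        y = np.array([0, 1] * 15)
        df = pd.DataFrame({"sep": y * 2.0, "noise":
                           np.random.default_rng(4).normal(size=30)})
        rec = cv_evaluate(df, y, ModelSpec("X", SelectorSpec("TSCR"),
                                           "LogisticRegression"),
                          CvPlan(5, seed=1),
                          CascadeConfig(budget_k=2, rfa_cv=3), tiny=True)
        assert rec.mean_auc == 1.0 and rec.rsd == 0.0
        assert rec.accuracy > 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        aucs = []
        for rep in range(20):
            y = np.array([1] * 60 + [0] * 40)
            rng.shuffle(y)
            df = pd.DataFrame(rng.standard_normal((100, 15)),
                              columns=[f"f{j}" for j in range(15)])
            rec = cv_evaluate(df, y, ModelSpec("X", SelectorSpec("MIM"),
                                               "NaiveBayes"),
                              CvPlan(5, seed=rep),
                              CascadeConfig(budget_k=3, rfa=False),
                              tiny=True)
            aucs.append(rec.mean_auc)
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestGrid:
    def test_product_rule_record_counts(self):
        sources, y = _grid_sources()
        selectors = [SelectorSpec(s, budget_k=3) for s in ("MIM", "TSCR")]
        classifiers = ["NaiveBayes", "LogisticRegression", "DecisionTree"]
        df, records = run_grid(sources, y, selectors, classifiers,
                               CvPlan(4, seed=2),
                               CascadeConfig(budget_k=3, rfa=False),
                               tiny=True)
        assert len(df) == 3 * 2 * 3
        assert set(df["name"]) == {
            f"{e}_{s.name}_{c}" for e, s, c in itertools.product(
                sources, selectors, classifiers)}
        # removing one classifier follows the product rule
        df2, _ = run_grid(sources, y, selectors, classifiers[:-1],
                          CvPlan(4, seed=2),
                          CascadeConfig(budget_k=3, rfa=False), tiny=True)
        assert len(df2) == 3 * 2 * 2

    def test_best_model_prefers_auc_then_lower_rsd(self):
        from radstab.benchmark import BenchmarkRecord
        mk = lambda name, auc, r: BenchmarkRecord(
            name, [auc] * 3, auc, r, 0, 0, 0, 0, 0, [])
        records = {"a": mk("A_MIM_KNN", 0.94, 0.86),
                   "b": mk("B_MIM_KNN", 0.94, 0.26),
                   "c": mk("C_MIM_KNN", 0.90, 0.01)}
        assert best_model(records).name == "B_MIM_KNN"


class TestLeakageGuard:
    def test_test_fold_mutation_never_changes_selection(self):
        sources, y = _grid_sources(seed=7)
        table = sources["Radiomics"]
        spec = ModelSpec("Radiomics", SelectorSpec("MRMR", budget_k=4),
                         "LogisticRegression")
        plan = CvPlan(5, seed=3)
        rng = np.random.default_rng(8)
        # per-fold assertion: replacing a fold's test rows with noise must
        # leave that fold's fitted scaler+selector output untouched
        cache1 = {}
        cv_evaluate(table, y, spec, plan, CascadeConfig(budget_k=4,
                    rfa_cv=3), tiny=True, _fold_selection_cache=cache1)
        for f, (tr, te) in enumerate(plan.splits(y)):
            mutated = table.copy()
            mutated.iloc[te] = rng.standard_normal((len(te),
                                                    table.shape[1]))
            c = {}
            cv_evaluate(mutated, y, spec, plan,
                        CascadeConfig(budget_k=4, rfa_cv=3), tiny=True,
                        _fold_selection_cache=c)
            key = (spec.selector.name, f)
            assert c[key][0] == cache1[key][0]  # identical selected columns
            assert np.allclose(c[key][1], cache1[key][1], atol=1e-10)


class TestLabelOutcomes:
    def test_study_response_counts_give_dcr(self):
        codes = ["CR"] * 1 + ["PR"] * 54 + ["SD"] * 17 + ["PD"] * 31
        labels, dcr = label_outcomes(codes)
        assert labels.sum() == 72 and dcr == 69.9

    def test_all_progression(self):
        labels, dcr = label_outcomes(["PD"] * 5)
        assert dcr == 0.0 and labels.sum() == 0

    def test_all_response(self):
        labels, dcr = label_outcomes(["CR", "PR", "SD"])
        assert dcr == 100.0

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            label_outcomes(["CR", "XX"])


def test_confusion_metrics_hand_example():
    y = np.array([1, 1, 1, 0, 0])
    p = np.array([1, 0, 1, 0, 1])
    m = confusion_metrics(y, p)
    assert m["accuracy"] == pytest.approx(0.6)
    assert m["sensitivity"] == pytest.approx(2 / 3)
    assert m["specificity"] == pytest.approx(0.5)
    assert m["precision"] == pytest.approx(2 / 3)
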