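"""Selector x classifier benchmark with SMOTE-balanced stratified CV.

Every (extractor, selector, classifier) combination is one model, named
``<Extractor>_<Selector>_<Classifier>``.  Per outer CV fold the training
half is standardized (fit on train only), SMOTE-balanced, run through the
selection cascade, and the classifier is fit on the selected features; the
held-out fold is scored.  Performance is the mean of the per-fold AUCs
(rank formulation with midranks) and stability is the relative standard
deviation RSD = (sd_AUC / mean_AUC) x 100.  Confusion metrics are pooled
over folds at probability threshold 0.5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._utils import logger, subseed
from .metrics import auc_score, confusion_metrics, rsd
from .selection import CascadeConfig, SelectorSpec, select_cascade

CLASSIFIER_NAMES = (
    "NearestNeighbors", "SVC_Linear", "SVC_RBF", "GaussianProcess",
    "DecisionTree", "RandomForest", "MLP", "AdaBoost", "NaiveBayes", "QDA",
    "XGBoost", "LogisticRegression",
)


def make_classifier(name: str, seed: int = 0, tiny: bool = False):
    """Instantiate one of the 12 benchmark classifiers with pinned seeds.

    ``tiny=True`` shrinks ensemble/iteration sizes for reduced cohorts.
    """
    n_est = 25 if tiny else 100
    if name == "NearestNeighbors":
        return KNeighborsClassifier()
    if name == "SVC_Linear":
        return SVC(kernel="linear", probability=True, random_state=seed)
    if name == "SVC_RBF":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if name == "GaussianProcess":
        return GaussianProcessClassifier(random_state=seed)
    if name == "DecisionTree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "RandomForest":
        return RandomForestClassifier(n_estimators=n_est, random_state=seed)
    if name == "MLP":
        return MLPClassifier(hidden_layer_sizes=(16,) if tiny else (100,),
                             max_iter=80 if tiny else 500,
                             random_state=seed)
    if name == "AdaBoost":
        return AdaBoostClassifier(n_estimators=n_est, random_state=seed)
    if name == "NaiveBayes":
        return GaussianNB()
    if name == "QDA":
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    if name == "XGBoost":
        return XGBClassifier(n_estimators=n_est, random_state=seed,
                             verbosity=0, eval_metric="logloss")
    if name == "LogisticRegression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class ModelSpec:
    extractor: str
    selector: SelectorSpec
    classifier: str

    @property
    def name(self) -> str:
        return f"{self.extractor}_{self.selector.name}_{self.classifier}"


@dataclass(frozen=True)
class CvPlan:
    n_splits: int = 10
    seed: int = 0

    def splits(self, labels: np.ndarray) -> list[tuple[np.ndarray,
                                                       np.ndarray]]:
        y = np.asarray(labels, dtype=int)
        n_splits = min(self.n_splits, int(np.bincount(y).min()))
        if n_splits < 2:
            raise ValueError("too few samples per class to stratify folds")
        if n_splits < self.n_splits:
            logger.info("reducing CV folds from %d to %d (minority size)",
                        self.n_splits, n_splits)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=self.seed)
        return list(skf.split(np.zeros(len(y)), y))


@dataclass
class BenchmarkRecord:
    name: str
    fold_aucs: list[float]
    mean_auc: float
    rsd: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    selected_features: list[str]
    oof_pred: np.ndarray | None = None
    oof_score: np.ndarray | None = None
    seed: int = 0
    failed: bool = False

    def as_row(self) -> dict:
        return {"name": self.name, "mean_auc": self.mean_auc,
                "rsd": self.rsd, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision, "f1": self.f1,
                "n_features": len(self.selected_features),
                "failed": self.failed}


# ----------------------------------------------------------------- SMOTE

def smote(minority: np.ndarray, n_synthetic: int, k: int = 5,
          seed: int = 0) -> np.ndarray:
    """Synthetic minority rows: each is x + lambda (x_nn - x) for a random
    one of the k nearest minority neighbours, lambda ~ U(0, 1)."""
    x = np.asarray(minority, dtype=float)
    if len(x) < 2:
        raise ValueError("SMOTE needs >= 2 minority samples")
    if n_synthetic <= 0:
        return np.empty((0, x.shape[1]))
    if len(x) <= k:
        logger.info("SMOTE k reduced from %d to %d", k, len(x) - 1)
        k = len(x) - 1
    rng = np.random.default_rng(seed)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    base = rng.integers(0, len(x), size=n_synthetic)
    pick = nn[base, rng.integers(0, k, size=n_synthetic)]
    lam = rng.uniform(0.0, 1.0, size=(n_synthetic, 1))
    return x[base] + lam * (x[pick] - x[base])


def smote_balance(x: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity."""
    y = np.asarray(y, dtype=int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == n0:
        return x, y
    minority = 1 if n1 < n0 else 0
    need = abs(n0 - n1)
    synth = smote(x[y == minority], need, k=k, seed=seed)
    return (np.vstack([x, synth]),
            np.concatenate([y, np.full(len(synth), minority)]))


# ------------------------------------------------------------ evaluation

def cv_evaluate(features: pd.DataFrame, labels: np.ndarray, spec: ModelSpec,
                plan: CvPlan, cascade: CascadeConfig | None = None,
                tiny: bool = False,
                _fold_selection_cache: dict | None = None
                ) -> BenchmarkRecord:
    """Cross-validate one model.  Per fold: standardize and SMOTE the
    training half, run the selection cascade on it, fit the classifier,
    score the held-out half."""
    y = np.asarray(labels, dtype=int)
    cascade = cascade or CascadeConfig()
    splits = plan.splits(y)
    seed = subseed(plan.seed, spec.name)

    fold_aucs: list[float] = []
    oof_pred = np.full(len(y), -1, dtype=int)
    oof_score = np.full(len(y), np.nan)
    selected_union: list[str] = []
    failed = False
    for f, (tr, te) in enumerate(splits):
        try:
            cols, x_tr, y_tr, x_te = _prepare_fold(
                features, y, tr, te, spec.selector, cascade, plan.seed, f,
                _fold_selection_cache)
            clf = make_classifier(spec.classifier,
                                  seed=subseed(seed, f"fold:{f}"), tiny=tiny)
            clf.fit(x_tr, y_tr)
            s = (clf.predict_proba(x_te)[:, 1]
                 if hasattr(clf, "predict_proba")
                 else clf.decision_function(x_te))
            fold_aucs.append(auc_score(y[te], s))
            oof_score[te] = s
            oof_pred[te] = (s >= 0.5).astype(int) \
                if hasattr(clf, "predict_proba") else clf.predict(x_te)
            selected_union += [c for c in cols if c not in selected_union]
        except Exception as exc:  # classifier failure: mark, keep going
            logger.warning("model %s failed in fold %d: %s", spec.name, f,
                           exc)
            failed = True
    if not fold_aucs:
        return BenchmarkRecord(spec.name, [], np.nan, np.nan, *([np.nan] * 5),
                               [], seed=plan.seed, failed=True)
    mean_auc = float(np.mean(fold_aucs))
    conf = confusion_metrics(y[oof_pred >= 0], oof_pred[oof_pred >= 0])
    return BenchmarkRecord(
        name=spec.name, fold_aucs=fold_aucs, mean_auc=mean_auc,
        rsd=rsd(np.array(fold_aucs)), selected_features=selected_union,
        oof_pred=oof_pred, oof_score=oof_score, seed=plan.seed,
        failed=failed, **conf)


def _prepare_fold(features: pd.DataFrame, y: np.ndarray, tr: np.ndarray,
                  te: np.ndarray, selector: SelectorSpec,
                  cascade: CascadeConfig, seed: int, fold: int,
                  cache: dict | None):
    """Standardize + SMOTE + cascade on the training fold only.  The result
    is cacheable across classifiers for one (selector, fold)."""
    key = (selector.name, fold)
    if cache is not None and key in cache:
        return cache[key]
    scaler = StandardScaler().fit(features.iloc[tr])
    x_tr = scaler.transform(features.iloc[tr])
    x_te = scaler.transform(features.iloc[te])
    x_bal, y_bal = smote_balance(x_tr, y[tr], seed=subseed(seed,
                                 f"smote:{selector.name}:{fold}"))
    bal_df = pd.DataFrame(x_bal, columns=features.columns)
    cols = select_cascade(bal_df, y_bal, selector, cascade)
    idx = [features.columns.get_loc(c) for c in cols]
    out = (cols, x_bal[:, idx], y_bal, x_te[:, idx])
    if cache is not None:
        cache[key] = out
    return out


def run_grid(sources: dict[str, pd.DataFrame], labels: np.ndarray,
             selectors: list[SelectorSpec] | None = None,
             classifiers: list[str] | None = None,
             plan: CvPlan | None = None,
             cascade: CascadeConfig | None = None,
             tiny: bool = False) -> tuple[pd.DataFrame,
                                          dict[str, BenchmarkRecord]]:
    """Evaluate the full extractor x selector x classifier grid.

    Returns (records table, {model name: BenchmarkRecord}).  The per-fold
    selection cascade is shared across classifiers within one
    (source, selector) pair.
    """
    from .selection import SELECTOR_NAMES
    selectors = selectors or [SelectorSpec(n) for n in SELECTOR_NAMES]
    classifiers = classifiers or list(CLASSIFIER_NAMES)
    plan = plan or CvPlan()
    records: dict[str, BenchmarkRecord] = {}
    for src_name, table in sources.items():
        cache: dict = {}
        for sel in selectors:
            for clf in classifiers:
                spec = ModelSpec(src_name, sel, clf)
                rec = cv_evaluate(table, labels, spec, plan, cascade,
                                  tiny=tiny, _fold_selection_cache=cache)
                records[rec.name] = rec
        logger.info("benchmarked source %s (%d records so far)", src_name,
                    len(records))
    df = pd.DataFrame([r.as_row() for r in records.values()])
    return df, records


def heatmaps(records: dict[str, BenchmarkRecord], extractor: str,
             selectors: list[str], classifiers: list[str]
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AUC and RSD matrices (selectors x classifiers) for one extractor."""
    auc = pd.DataFrame(index=selectors, columns=classifiers, dtype=float)
    stab = auc.copy()
    for sel in selectors:
        for clf in classifiers:
            rec = records.get(f"{extractor}_{sel}_{clf}")
            if rec is not None:
                auc.loc[sel, clf] = rec.mean_auc
                stab.loc[sel, clf] = rec.rsd
    return auc, stab


def best_model(records: dict[str, BenchmarkRecord],
               extractor: str | None = None) -> BenchmarkRecord:
    """Optimum by max mean AUC, ties broken by lower RSD, then by model
    name order of insertion."""
    pool = [r for r in records.values()
            if not r.failed and np.isfinite(r.mean_auc)
            and (extractor is None or r.name.startswith(extractor + "_"))]
    if not pool:
        raise ValueError("no successful records")
    best = pool[0]
    for r in pool[1:]:
        if (r.mean_auc > best.mean_auc
                or (r.mean_auc == best.mean_auc and r.rsd < best.rsd)):
            best = r
    return best


# --------------------------------------------------------- outcome labels

RESPONSE_CONTROL = {"CR", "PR", "SD"}


def label_outcomes(codes: list[str]) -> tuple[np.ndarray, float]:
    """Map mRECIST response codes to binary labels (1 = disease control for
    CR/PR/SD, 0 = PD) and compute the disease control rate (one decimal)."""
    labels = []
    for c in codes:
        if c in RESPONSE_CONTROL:
            labels.append(1)
        elif c == "PD":
            labels.append(0)
        else:
            raise ValueError(f"unknown response code {c!r}")
    labels = np.array(labels, dtype=int)
    dcr = round(100.0 * labels.mean(), 1)
    return labels, dcr
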