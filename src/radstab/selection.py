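"""Multi-stage feature-selection cascade.

Dimension reduction proceeds in four steps: (1) drop features with zero
median absolute deviation; (2) keep the top 20% by absolute Welch t
statistic; (3) rank with one of 13 filter selectors — five score-based
(ReliefF, Fisher score, Gini index, chi-square, t score) and eight greedy
forward selectors from the conditional-likelihood mutual-information
framework (MIM, MIFS, MRMR, JMI, CIFE, CMIM, ICAP, DISR; criteria listed in
:func:`greedy_mi_select`); (4) recursive feature addition (RFA), a wrapper
that walks the ranking and keeps a feature iff it improves stratified
cross-validated AUC.

Mutual information uses a plug-in estimator on 10 equal-frequency bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._utils import logger
from .metrics import auc_score

SELECTOR_NAMES = ("RELF", "FSCR", "GINI", "CHSQ", "JMI", "CIFE", "DISR",
                  "MIM", "CMIM", "ICAP", "TSCR", "MRMR", "MIFS")
_MI_SELECTORS = {"JMI", "CIFE", "DISR", "MIM", "CMIM", "ICAP", "MRMR",
                 "MIFS"}
_SCORE_CAP = 1e12


@dataclass(frozen=True)
class SelectorSpec:
    name: str
    mi_bins: int = 10
    relief_k: int = 10
    relief_m: int | None = None     # None = use all samples
    budget_k: int = 30

    def validate(self) -> None:
        if self.name not in SELECTOR_NAMES:
            raise ValueError(f"unknown selector {self.name!r}")


@dataclass
class RankedFeatures:
    names: list[str]
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)


# ------------------------------------------------------------ stages 1 & 2

def mad_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Drop features whose median absolute deviation about the median is
    exactly zero."""
    if table.shape[1] == 0:
        raise ValueError("empty feature table")
    x = table.to_numpy(dtype=float)
    mad = np.median(np.abs(x - np.median(x, axis=0)), axis=0)
    keep = mad > 0
    if not keep.any():
        raise ValueError("MAD filter removed every feature")
    return table.loc[:, table.columns[keep]]


def welch_t(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Welch t statistic (class 1 minus class 0) per column."""
    y = np.asarray(labels, dtype=int)
    x1, x0 = x[y == 1], x[y == 0]
    if len(x1) < 2 or len(x0) < 2:
        raise ValueError("each class needs >= 2 samples")
    num = x1.mean(axis=0) - x0.mean(axis=0)
    den = np.sqrt(x1.var(axis=0, ddof=1) / len(x1)
                  + x0.var(axis=0, ddof=1) / len(x0))
    t = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                 np.sign(num) * _SCORE_CAP)
    return np.where((den == 0) & (num == 0), 0.0, t)


def univariate_top(table: pd.DataFrame, labels: np.ndarray,
                   fraction: float = 0.20) -> pd.DataFrame:
    """Keep the top ``ceil(fraction * p)`` features by |Welch t|."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    t = np.abs(welch_t(table.to_numpy(dtype=float), y))
    n_keep = math.ceil(fraction * table.shape[1])
    order = np.argsort(-t, kind="stable")[:n_keep]
    return table.iloc[:, np.sort(order)]


# ---------------------------------------------------- score-based selectors

def _fisher_score(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    num = np.zeros(x.shape[1])
    den = np.zeros(x.shape[1])
    mu = x.mean(axis=0)
    for c in (0, 1):
        xc = x[y == c]
        num += len(xc) * (xc.mean(axis=0) - mu) ** 2
        den += len(xc) * xc.var(axis=0)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0),
                    np.where(num > 0, _SCORE_CAP, 0.0))


def _gini_score(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Parent Gini impurity minus the best threshold-split weighted child
    impurity, per feature (thresholds at sorted midpoints)."""
    n = len(y)
    p1 = y.mean()
    parent = 1.0 - p1 ** 2 - (1 - p1) ** 2
    out = np.zeros(x.shape[1])
    n_pos = int(y.sum())
    for jf in range(x.shape[1]):
        order = np.argsort(x[:, jf], kind="stable")
        xs, ys = x[order, jf], y[order]
        cum_pos = np.cumsum(ys)[:-1]
        left_n = np.arange(1, n)
        valid = xs[1:] > xs[:-1]
        if not valid.any():
            continue
        right_n = n - left_n
        lp = cum_pos / left_n
        rp = (n_pos - cum_pos) / right_n
        child = (left_n * (1 - lp ** 2 - (1 - lp) ** 2)
                 + right_n * (1 - rp ** 2 - (1 - rp) ** 2)) / n
        out[jf] = parent - child[valid].min()
    return out


def _chi2_score(x: np.ndarray, y: np.ndarray, bins: int = 10) -> np.ndarray:
    out = np.zeros(x.shape[1])
    for jf in range(x.shape[1]):
        b = bin_equal_frequency(x[:, jf], bins)
        obs = np.zeros((b.max() + 1, 2))
        np.add.at(obs, (b, y), 1.0)
        obs = obs[obs.sum(axis=1) > 0]
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            cells = np.where(exp > 0, (obs - exp) ** 2 / np.where(
                exp > 0, exp, 1.0), 0.0)
        out[jf] = cells.sum()
    return out


def _relieff(x: np.ndarray, y: np.ndarray, k: int = 10,
             m: int | None = None, seed: int = 0) -> np.ndarray:
    """Standard ReliefF weights with k nearest hits/misses and
    range-normalized differences; by default every sample is used."""
    n, p = x.shape
    rng_span = x.max(axis=0) - x.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    xn = (x - x.min(axis=0)) / rng_span
    if m is None or m >= n:
        picks = np.arange(n)
    else:
        picks = np.random.default_rng(seed).choice(n, size=m, replace=False)
    d2 = ((xn[:, None, :] - xn[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(p)
    for i in picks:
        same = np.nonzero(y == y[i])[0]
        same = same[same != i]
        diff = np.nonzero(y != y[i])[0]
        kk_h = min(k, len(same))
        kk_m = min(k, len(diff))
        if kk_h == 0 or kk_m == 0:
            continue
        hits = same[np.argsort(d2[i, same], kind="stable")[:kk_h]]
        misses = diff[np.argsort(d2[i, diff], kind="stable")[:kk_m]]
        w -= np.abs(xn[i] - xn[hits]).sum(axis=0) / kk_h
        w += np.abs(xn[i] - xn[misses]).sum(axis=0) / kk_m
    return w / len(picks)


def score_filter(table: pd.DataFrame, labels: np.ndarray,
                 spec: SelectorSpec) -> RankedFeatures:
    """Rank features with one of the score-based selectors
    (FSCR, GINI, CHSQ, TSCR, RELF)."""
    spec.validate()
    x = table.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if spec.name == "FSCR":
        scores = _fisher_score(x, y)
    elif spec.name == "TSCR":
        scores = np.abs(welch_t(x, y))
    elif spec.name == "GINI":
        scores = _gini_score(x, y)
    elif spec.name == "CHSQ":
        scores = _chi2_score(x, y, spec.mi_bins)
    elif spec.name == "RELF":
        scores = _relieff(x, y, spec.relief_k, spec.relief_m)
    else:
        raise ValueError(f"{spec.name} is not a score-based selector")
    scores = np.clip(scores, -_SCORE_CAP, _SCORE_CAP)
    order = np.argsort(-scores, kind="stable")
    return RankedFeatures(names=[table.columns[i] for i in order],
                          scores=scores[order],
                          provenance={"selector": spec.name})


# -------------------------------------------------------- mutual information

def bin_equal_frequency(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Discretize a continuous vector into <= ``bins`` equal-frequency bins
    (integer codes from 0)."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(x, edges, right=True)


def _joint_entropy(*codes: np.ndarray) -> float:
    stacked = np.stack(codes, axis=1)
    _, counts = np.unique(stacked, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_info(x: np.ndarray, y: np.ndarray,
                z: np.ndarray | None = None, bins: int = 10) -> float:
    """Plug-in (conditional) mutual information in nats.

    Continuous ``x`` is binned to equal-frequency bins; ``y`` (and ``z``)
    must be discrete.  I(X;Y) = H(X) + H(Y) - H(X,Y); the conditional form
    averages I(X;Y|Z=z) over the empirical p(z).
    """
    xb = x if np.issubdtype(np.asarray(x).dtype, np.integer) \
        else bin_equal_frequency(np.asarray(x, dtype=float), bins)
    y = np.asarray(y)
    if z is None:
        return max(_joint_entropy(xb) + _joint_entropy(y)
                   - _joint_entropy(xb, y), 0.0)
    z = np.asarray(z)
    total = 0.0
    for zv in np.unique(z):
        sel = z == zv
        pz = sel.mean()
        total += pz * (_joint_entropy(xb[sel]) + _joint_entropy(y[sel])
                       - _joint_entropy(xb[sel], y[sel]))
    return max(total, 0.0)


def greedy_mi_select(table: pd.DataFrame, labels: np.ndarray,
                     spec: SelectorSpec, k_select: int | None = None
                     ) -> RankedFeatures:
    """Greedy forward selection under one of the eight mutual-information
    criteria.  With selected set S and relevance I(f;Y), the step score of
    a candidate f is:

    - MIM:   I(f;Y)
    - MIFS:  I(f;Y) - sum_S I(f;s)
    - MRMR:  I(f;Y) - (1/|S|) sum_S I(f;s)
    - JMI:   I(f;Y) - (1/|S|) sum_S [I(f;s) - I(f;s|Y)]
    - CIFE:  I(f;Y) - sum_S [I(f;s) - I(f;s|Y)]
    - CMIM:  min_{s in S} I(f;Y|s)
    - ICAP:  I(f;Y) - sum_S max(0, I(f;s) - I(f;s|Y))
    - DISR:  sum_S I({f,s};Y) / H({f,s},Y)

    The first pick is argmax I(f;Y) for every criterion; ties break toward
    the earlier column.
    """
    spec.validate()
    if spec.name not in _MI_SELECTORS:
        raise ValueError(f"{spec.name} is not an MI selector")
    y = np.asarray(labels, dtype=int)
    p = table.shape[1]
    k_sel = k_select if k_select is not None else spec.budget_k
    if k_sel > p:
        logger.info("selection budget %d clamped to %d features", k_sel, p)
        k_sel = p
    binned = np.stack([bin_equal_frequency(table.iloc[:, j].to_numpy(float),
                                           spec.mi_bins)
                       for j in range(p)], axis=1)
    hy = _joint_entropy(y)
    rel = np.array([mutual_info(binned[:, j], y) for j in range(p)])

    selected: list[int] = []
    sel_scores: list[float] = []
    # per selected feature s: cached vectors over all candidates
    red: list[np.ndarray] = []        # I(f;s)
    red_c: list[np.ndarray] = []      # I(f;s|Y)
    cmi_y: list[np.ndarray] = []      # I(f;Y|s)
    disr: list[np.ndarray] = []       # I({f,s};Y)/H({f,s},Y)

    for _ in range(k_sel):
        if not selected:
            crit = rel.copy()
        elif spec.name == "MIM":
            crit = rel.copy()
        elif spec.name == "MIFS":
            crit = rel - np.sum(red, axis=0)
        elif spec.name == "MRMR":
            crit = rel - np.mean(red, axis=0)
        elif spec.name == "JMI":
            crit = rel - (np.mean(red, axis=0) - np.mean(red_c, axis=0))
        elif spec.name == "CIFE":
            crit = rel - (np.sum(red, axis=0) - np.sum(red_c, axis=0))
        elif spec.name == "CMIM":
            crit = np.min(cmi_y, axis=0)
        elif spec.name == "ICAP":
            crit = rel - np.sum(np.maximum(
                0.0, np.asarray(red) - np.asarray(red_c)), axis=0)
        elif spec.name == "DISR":
            crit = np.sum(disr, axis=0)
        crit = crit.astype(float)
        crit[selected] = -np.inf
        best = int(np.argmax(crit))
        selected.append(best)
        sel_scores.append(float(crit[best]))

        s = binned[:, best]
        red.append(np.array([mutual_info(binned[:, j], s) for j in range(p)]))
        red_c.append(np.array([mutual_info(binned[:, j], s, z=y)
                               for j in range(p)]))
        if spec.name == "CMIM":
            cmi_y.append(np.array([mutual_info(binned[:, j], y, z=s)
                                   for j in range(p)]))
        if spec.name == "DISR":
            vals = np.empty(p)
            for j in range(p):
                pair = binned[:, j] * (spec.mi_bins + 1) + s
                h_all = _joint_entropy(pair, y)
                i_joint = _joint_entropy(pair) + hy - h_all
                vals[j] = max(i_joint, 0.0) / h_all if h_all > 0 else 0.0
            disr.append(vals)

    return RankedFeatures(names=[table.columns[i] for i in selected],
                          scores=np.array(sel_scores),
                          provenance={"selector": spec.name,
                                      "bins": spec.mi_bins})


def rank_features(table: pd.DataFrame, labels: np.ndarray,
                  spec: SelectorSpec, k_select: int | None = None
                  ) -> RankedFeatures:
    """Dispatch to the score-based or greedy-MI ranking for ``spec``."""
    spec.validate()
    if spec.name in _MI_SELECTORS:
        return greedy_mi_select(table, labels, spec, k_select)
    ranked = score_filter(table, labels, spec)
    if k_select is not None:
        ranked.names = ranked.names[:k_select]
        ranked.scores = ranked.scores[:k_select]
    return ranked


# ------------------------------------------------------------------- RFA

def recursive_feature_addition(ranked: Sequence[str], table: pd.DataFrame,
                               labels: np.ndarray, classifier,
                               cv: int = 10, seed: int = 0,
                               tol: float = 1e-4
                               ) -> tuple[list[str], list[float]]:
    """Walk the ranked list; keep each feature iff it improves mean
    stratified k-fold CV AUC by more than ``tol``.

    Returns (kept feature names, AUC trace after each accepted feature).
    """
    if not len(ranked):
        raise ValueError("empty ranking")
    y = np.asarray(labels, dtype=int)
    n_splits = min(cv, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few samples per class for CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    def cv_auc(cols: list[str]) -> float:
        x = table[cols].to_numpy(dtype=float)
        aucs = []
        for tr, te in splits:
            model = clone(classifier)
            model.fit(x[tr], y[tr])
            aucs.append(auc_score(y[te], _scores(model, x[te])))
        return float(np.mean(aucs))

    kept: list[str] = []
    trace: list[float] = []
    best = 0.5
    for name in ranked:
        candidate = kept + [name]
        score = cv_auc(candidate)
        if score > best + tol:
            kept, best = candidate, score
            trace.append(score)
    if not kept:  # nothing improved on chance: fall back to the top feature
        kept = [ranked[0]]
        trace = [cv_auc(kept)]
    return kept, trace


def _scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


# --------------------------------------------------------------- cascade

@dataclass(frozen=True)
class CascadeConfig:
    univariate_fraction: float = 0.20
    budget_k: int = 30
    rfa: bool = True
    rfa_cv: int = 10
    rfa_tol: float = 1e-4
    seed: int = 0


def select_cascade(table: pd.DataFrame, labels: np.ndarray,
                   spec: SelectorSpec,
                   config: CascadeConfig | None = None,
                   rfa_classifier=None) -> list[str]:
    """Run the full 4-step cascade, returning the selected feature names."""
    cfg = config or CascadeConfig()
    t1 = mad_filter(table)
    t2 = univariate_top(t1, labels, cfg.univariate_fraction)
    ranked = rank_features(t2, labels, spec, k_select=cfg.budget_k)
    if not cfg.rfa:
        return ranked.names
    clf = rfa_classifier if rfa_classifier is not None else \
        LogisticRegression(max_iter=1000)
    kept, _ = recursive_feature_addition(
        ranked.names, t2, labels, clf, cv=cfg.rfa_cv, seed=cfg.seed,
        tol=cfg.rfa_tol)
    return kept
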