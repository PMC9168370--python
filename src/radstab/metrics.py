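"""Performance metrics: rank-based AUC, confusion metrics, RSD."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formulation with
    midranks for ties."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # midranks
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray
                      ) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F1 of hard labels
    (positive class = 1).  Undefined ratios are 0 by convention."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {"accuracy": (tp + tn) / len(y), "sensitivity": sens,
            "specificity": spec, "precision": prec, "f1": f1}


def rsd(aucs: np.ndarray) -> float:
    """Relative standard deviation of cross-validated AUCs:
    (sample SD / mean) x 100."""
    a = np.asarray(aucs, dtype=float)
    mean = a.mean()
    if mean <= 0:
        raise ValueError("mean AUC must be > 0 for RSD")
    if len(a) < 2:
        return 0.0
    return float(a.std(ddof=1) / mean * 100.0)
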