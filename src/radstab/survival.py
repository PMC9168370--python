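"""Survival follow-through: Kaplan-Meier, log-rank, univariate Cox.

The predicted group fed to these analyses is the *out-of-fold* predicted
label of a chosen benchmark model, so survival stratification is assessed
without resubstitution leakage.  The Cox model maximises the Breslow
partial likelihood by Newton iteration; the hazard ratio contrasts group 0
(predicted progression) against group 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    beta: float
    se: float


def km_curve(times: np.ndarray, events: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimator: returns (event times t_i, S(t_i))."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    s = 1.0
    surv = []
    for ti in uniq:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
    return uniq, np.array(surv)


def logrank(times: np.ndarray, events: np.ndarray, group: np.ndarray
            ) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided p)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group, dtype=int)
    if len(np.unique(g)) != 2:
        raise ValueError("exactly two nonempty groups required")
    if e.sum() == 0:
        raise ValueError("no events")
    g1 = g == np.unique(g)[1]
    obs_minus_exp = 0.0
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & g1).sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_score_statistic(times: np.ndarray, events: np.ndarray,
                        group: np.ndarray) -> float:
    """Cox partial-likelihood score test statistic at beta = 0 (equals the
    log-rank chi-square on tie-free data)."""
    u, i_info = _cox_derivatives(np.asarray(times, float),
                                 np.asarray(events, int),
                                 _risk_covariate(group), beta=0.0)
    return float(u ** 2 / i_info)


def _risk_covariate(group: np.ndarray) -> np.ndarray:
    """Code group so that beta > 0 means higher hazard for group 0."""
    g = np.asarray(group, dtype=int)
    return (g == 0).astype(float)


def _cox_derivatives(t: np.ndarray, e: np.ndarray, x: np.ndarray,
                     beta: float) -> tuple[float, float]:
    """Score and information of the Breslow partial log-likelihood."""
    u = 0.0
    info = 0.0
    w = np.exp(beta * x)
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        d_idx = (t == ti) & (e == 1)
        d = int(d_idx.sum())
        s0 = float(w[at_risk].sum())
        s1 = float((w * x)[at_risk].sum())
        s2 = float((w * x * x)[at_risk].sum())
        u += float(x[d_idx].sum()) - d * s1 / s0
        info += d * (s2 / s0 - (s1 / s0) ** 2)
    return u, info


def cox_univariate(times: np.ndarray, events: np.ndarray,
                   group: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-8) -> CoxResult:
    """Univariate Cox proportional-hazards fit for a binary group covariate
    (Breslow tie handling, Newton iteration to |score| < tol), with Wald
    95% CI and p-value.  HR contrasts group 0 vs group 1."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = _risk_covariate(group)
    if len(np.unique(x)) < 2:
        raise ValueError("group has no contrast")
    for gv in np.unique(x):
        if e[x == gv].sum() == 0:
            raise ValueError("each group needs at least one event")

    beta = 0.0
    for _ in range(max_iter):
        u, info = _cox_derivatives(t, e, x, beta)
        if info <= 0:
            raise ValueError("monotone partial likelihood: no events "
                             "contrast within risk sets")
        step = u / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(u) < tol:
            break
    else:
        if abs(u) > 1e-4 or abs(beta) > 15:
            raise ValueError("Cox fit did not converge (possible complete "
                             "separation in risk sets)")
    _, info = _cox_derivatives(t, e, x, beta)
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    return CoxResult(hr=float(np.exp(beta)),
                     ci_low=float(np.exp(beta - 1.959964 * se)),
                     ci_high=float(np.exp(beta + 1.959964 * se)),
                     p=float(2 * stats.norm.sf(abs(z))),
                     n_events=int(e.sum()), beta=float(beta), se=se)


def survival_records(clinical: pd.DataFrame, oof_pred: np.ndarray
                     ) -> pd.DataFrame:
    """Join survival data with a model's out-of-fold predicted groups,
    dropping subjects without survival data."""
    df = clinical.copy()
    df["group"] = np.asarray(oof_pred, dtype=int)
    df = df[np.isfinite(df["os_time"]) & (df["group"] >= 0)]
    if (df["os_time"] <= 0).any():
        raise ValueError("os_time must be positive")
    return df[["subject_id", "os_time", "os_event", "group"]]


def analyze_survival(records: pd.DataFrame) -> dict:
    """KM curves per predicted group + log-rank + Cox, as one summary."""
    t = records["os_time"].to_numpy(float)
    e = records["os_event"].to_numpy(int)
    g = records["group"].to_numpy(int)
    chi2, p = logrank(t, e, g)
    cox = cox_univariate(t, e, g)
    curves = {}
    for gv in np.unique(g):
        ti, si = km_curve(t[g == gv], e[g == gv])
        curves[int(gv)] = (ti, si)
    return {"logrank_chi2": chi2, "logrank_p": p, "cox": cox,
            "curves": curves, "n": len(records),
            "n_events": int(e.sum())}


def plot_km(curves: dict[int, tuple[np.ndarray, np.ndarray]], path: str,
            title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for gv, (ti, si) in sorted(curves.items()):
        tt = np.concatenate([[0.0], np.repeat(ti, 2)])
        ss = np.concatenate([[1.0, 1.0], np.repeat(si, 2)[:-1]])
        ax.plot(tt, ss, label=f"predicted group {gv}")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
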