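"""Feature robustness screening: ICC across perturbation replicates.

Each feature contributes, per perturbation kind, an n-subjects x k-raters
panel (raters = original image plus one replicate per perturbation level).
Stability is scored with the two-way random-effects, single-rater,
absolute-agreement intraclass correlation ICC(2,1):

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C, MS_E are the rows (subjects), columns (raters) and
residual mean squares of the two-way ANOVA.  A feature is robust iff its
ICC reaches the cutoff (default 0.85) for every perturbation kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import logger

KINDS = ("S", "R", "Seg")


def icc_agreement(matrix: np.ndarray) -> float:
    """ICC(2,1) of one n x k panel; clipped to [-1, 1].

    A zero-variance (all-equal) matrix returns 1 by convention (logged).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("panel must be n >= 3 subjects x k >= 2 raters")
    if not np.isfinite(m).all():
        raise ValueError("non-finite entries in ICC panel")
    return float(icc_agreement_batch(m[None, :, :])[0])


def icc_agreement_batch(panels: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over an (F, n, k) array of panels."""
    p = np.asarray(panels, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("non-finite entries in ICC panels")
    _, n, k = p.shape
    grand = p.mean(axis=(1, 2), keepdims=True)
    row_m = p.mean(axis=2, keepdims=True)
    col_m = p.mean(axis=1, keepdims=True)
    ss_rows = (k * (row_m - grand) ** 2).sum(axis=(1, 2))
    ss_cols = (n * (col_m - grand) ** 2).sum(axis=(1, 2))
    ss_tot = ((p - grand) ** 2).sum(axis=(1, 2))
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (ms_r - ms_e) / denom
    degenerate = ss_tot <= 1e-30
    if degenerate.any():
        logger.info("%d zero-variance panel(s): ICC = 1 by convention",
                    int(degenerate.sum()))
    icc = np.where(degenerate, 1.0, icc)
    icc = np.where(np.isfinite(icc), icc, 0.0)
    return np.clip(icc, -1.0, 1.0)


def build_panels(tables: dict[tuple[str, float], pd.DataFrame]
                 ) -> dict[str, np.ndarray]:
    """Stack replicate feature tables into per-kind ICC panels.

    ``tables`` maps (kind, level) -> subjects x features table; the key
    ("original", 0) holds the unperturbed table, which is included as a
    rater in every kind.  Returns {kind: (F, n, k) array}.
    """
    if ("original", 0) not in tables:
        raise ValueError("missing ('original', 0) table")
    ref = tables[("original", 0)]
    for key, t in tables.items():
        if not t.index.equals(ref.index) or not t.columns.equals(ref.columns):
            raise ValueError(f"replicate {key} has mismatched subjects or "
                             "features (unbalanced panel)")
    panels: dict[str, np.ndarray] = {}
    for kind in KINDS:
        keys = sorted(k for k in tables if k[0] == kind)
        if not keys:
            continue
        raters = [ref] + [tables[k] for k in keys]
        # (k_raters, n, F) -> (F, n, k_raters)
        panels[kind] = np.stack([t.to_numpy(dtype=float) for t in raters],
                                axis=0).transpose(2, 1, 0)
    if not panels:
        raise ValueError("no perturbation replicates supplied")
    return panels


@dataclass
class RobustnessReport:
    """Per-feature ICCs for each perturbation kind plus the pass mask."""

    table: pd.DataFrame          # index = feature; ICC_S, ICC_R, ICC_Seg, pass
    cutoff: float

    @property
    def percent_robust(self) -> float:
        return 100.0 * float(self.table["pass"].mean())

    def summary(self) -> dict:
        out: dict = {"cutoff": self.cutoff,
                     "n_features": int(len(self.table)),
                     "n_robust": int(self.table["pass"].sum()),
                     "percent_robust": round(self.percent_robust, 2)}
        for kind in KINDS:
            col = f"ICC_{kind}"
            if col in self.table:
                out[col] = {"mean": float(self.table[col].mean()),
                            "sd": float(self.table[col].std(ddof=1))}
        return out


def score_robustness(tables: dict[tuple[str, float], pd.DataFrame],
                     cutoff: float = 0.85) -> RobustnessReport:
    """ICC every feature against every perturbation kind and apply the
    all-kinds cutoff rule."""
    panels = build_panels(tables)
    ref = tables[("original", 0)]
    data = {}
    for kind, panel in panels.items():
        data[f"ICC_{kind}"] = icc_agreement_batch(panel)
    df = pd.DataFrame(data, index=ref.columns)
    df["pass"] = (df[[c for c in df.columns if c.startswith("ICC_")]]
                  .min(axis=1) >= cutoff)
    return RobustnessReport(table=df, cutoff=cutoff)


def robust_filter(report: RobustnessReport,
                  cutoff: float | None = None) -> list[str]:
    """Names of features passing all perturbation kinds at >= cutoff, in
    catalogue order."""
    cut = report.cutoff if cutoff is None else cutoff
    icc_cols = [c for c in report.table.columns if c.startswith("ICC_")]
    ok = report.table[icc_cols].min(axis=1) >= cut
    names = list(report.table.index[ok])
    if not names:
        raise ValueError(f"no features pass ICC cutoff {cut}; "
                         "consider relaxing the cutoff")
    return names


def percent_robust(n_pass: int, n_total: int) -> float:
    """Robust-feature percentage, rounded to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_pass / n_total, 2)
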