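"""End-to-end orchestration: one config, seeded stages, a run manifest.

Stage order: generate -> preprocess/perturb/extract -> robustness ->
benchmark (selection happens per CV fold inside the benchmark) ->
survival.  Each stochastic stage consumes a named sub-seed derived from
the global seed by stable name hashing, so toggling a stage never shifts
another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import logger, subseed
from .benchmark import (CLASSIFIER_NAMES, CvPlan, best_model, heatmaps,
                        run_grid)
from .features import (BankConfig, CATALOGUE, bank_feature_names,
                       extract_all, feature_bank)
from .perturb import make_replicates
from .preprocess import PreprocessConfig
from .robustness import RobustnessReport, robust_filter, score_robustness
from .selection import SELECTOR_NAMES, CascadeConfig, SelectorSpec
from .survival import analyze_survival, plot_km, survival_records
from .synth import CohortConfig, PhantomCohort, generate_cohort


@dataclass
class RunConfig:
    """Everything a full run needs; (config, seed) determines all outputs."""

    seed: int = 17
    out_dir: str = "radstab_run"
    # cohort
    n_subjects: int = 40
    control_fraction: float = 72 / 103
    effect: float = 1.0
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        diameter_median_mm=16.0, diameter_log_sd=0.25,
        diameter_range_mm=(10.4, 26.0)))
    # preprocessing (crop scaled to the phantom size)
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(crop_size=32))
    # features
    n_bins: int = 32
    bank_dims: tuple[int, ...] = (512, 512, 2048, 2048, 2048, 1536)
    bank_names: tuple[str, ...] = ("BankA", "BankB", "BankC", "BankD",
                                   "BankE", "BankF")
    # robustness
    run_perturbations: bool = True
    icc_cutoff: float = 0.85
    # benchmark
    selectors: tuple[str, ...] = tuple(SELECTOR_NAMES)
    classifiers: tuple[str, ...] = tuple(CLASSIFIER_NAMES)
    cv_folds: int = 10
    cascade: CascadeConfig = field(default_factory=lambda: CascadeConfig(
        budget_k=10, rfa_cv=3))
    tiny_classifiers: bool = True

    def validate(self) -> list[str]:
        """Schema/cross-field checks; returns a list of problems."""
        problems = []
        if self.n_subjects < 4:
            problems.append("n_subjects must be >= 4")
        minority = min(self.control_fraction, 1 - self.control_fraction)
        if self.n_subjects * minority < 2:
            problems.append("fewer than 2 expected minority subjects: "
                            "cannot stratify CV folds")
        if self.n_subjects * minority < self.cv_folds:
            problems.append(
                f"cv_folds={self.cv_folds} exceeds the expected minority "
                f"count (~{self.n_subjects * minority:.1f}); folds would "
                "lack both classes")
        if self.n_subjects < 3:
            problems.append("ICC needs >= 3 subjects")
        for s in self.selectors:
            if s not in SELECTOR_NAMES:
                problems.append(f"unknown selector {s!r}")
        for c in self.classifiers:
            if c not in CLASSIFIER_NAMES:
                problems.append(f"unknown classifier {c!r}")
        if self.cv_folds < 2:
            problems.append("cv_folds must be >= 2")
        if not 0 < self.control_fraction < 1:
            problems.append("control_fraction must be in (0, 1)")
        return problems


def validate_config(config: RunConfig) -> list[str]:
    return config.validate()


def _plot_heatmap(matrix: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * matrix.shape[1],
                                    1 + 0.4 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto",
                   cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90,
                  fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.10g").encode()).hexdigest()[:16]


def extract_sources(cohort: PhantomCohort, config: RunConfig
                    ) -> tuple[dict[str, pd.DataFrame],
                               dict[tuple[str, float], pd.DataFrame]]:
    """Extract the radiomics table (original + perturbed replicates) and
    the external feature-bank sources from a cohort.

    Returns (benchmark sources, replicate tables for the ICC panels).
    """
    replicate_rows: dict[tuple[str, float], dict[str, pd.Series]] = {}
    originals = {}
    for subj in cohort.subjects:
        reps = (make_replicates(subj.volume, subj.mask, config.preprocess)
                if config.run_perturbations
                else [])
        if not reps:
            from .preprocess import preprocess_subject
            from .perturb import Replicate
            reps = [Replicate("original", 0.0, preprocess_subject(
                subj.volume, subj.mask, config.preprocess))]
        for rep in reps:
            key = ("original", 0) if rep.kind == "original" \
                else (rep.kind, rep.level)
            replicate_rows.setdefault(key, {})[subj.subject_id] = \
                extract_all(rep.stack, config.n_bins)
            if rep.kind == "original":
                originals[subj.subject_id] = rep.stack

    tables = {key: pd.DataFrame.from_dict(rows, orient="index")
              [list(CATALOGUE)]
              for key, rows in replicate_rows.items()}

    sources: dict[str, pd.DataFrame] = {
        "Radiomics": tables[("original", 0)]}
    for name, dim in zip(config.bank_names, config.bank_dims):
        bc = BankConfig(dim=dim, seed=subseed(config.seed, f"bank:{name}"))
        rows = {sid: feature_bank(stk, bc)
                for sid, stk in originals.items()}
        sources[name] = pd.DataFrame.from_dict(rows, orient="index")
        sources[name].columns = bank_feature_names(dim)
    return sources, tables


@dataclass
class RunManifest:
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, duration: float, **info) -> None:
        self.stages[stage] = {"seconds": round(duration, 2), **info}

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages, "warnings": self.warnings},
                      fh, indent=2, default=str)


def run_all(config: RunConfig) -> RunManifest:
    """Execute every enabled stage in order; outputs land in
    ``config.out_dir``."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()

    t0 = time.time()
    cohort = generate_cohort(config.n_subjects, config.control_fraction,
                             config.effect,
                             seed=subseed(config.seed, "generate"),
                             config=config.cohort)
    cohort.clinical_frame().to_csv(out / "clinical.csv", index=False)
    manifest.record("generate", time.time() - t0, n=config.n_subjects)

    t0 = time.time()
    sources, tables = extract_sources(cohort, config)
    sources["Radiomics"].to_csv(out / "features_radiomics.csv")
    manifest.record("extract", time.time() - t0,
                    n_features=sources["Radiomics"].shape[1],
                    hash=_hash_df(sources["Radiomics"]))

    labels = cohort.labels
    if config.run_perturbations:
        t0 = time.time()
        report = score_robustness(tables, cutoff=config.icc_cutoff)
        report.table.to_csv(out / "robustness.csv")
        with open(out / "robustness_summary.json", "w") as fh:
            json.dump(report.summary(), fh, indent=2)
        robust = robust_filter(report)
        sources["Radiomics"] = sources["Radiomics"][robust]
        manifest.record("robustness", time.time() - t0,
                        n_robust=len(robust),
                        percent_robust=report.percent_robust)
    else:
        manifest.warnings.append(
            "perturbation/robustness stage skipped: benchmark consumes the "
            "unfiltered feature table")
        logger.warning(manifest.warnings[-1])

    t0 = time.time()
    plan = CvPlan(n_splits=config.cv_folds,
                  seed=subseed(config.seed, "cv"))
    selectors = [SelectorSpec(s, budget_k=config.cascade.budget_k)
                 for s in config.selectors]
    bench_df, records = run_grid(sources, labels, selectors,
                                 list(config.classifiers), plan,
                                 config.cascade,
                                 tiny=config.tiny_classifiers)
    bench_df.to_csv(out / "bench.csv", index=False)
    for src in sources:
        auc_m, rsd_m = heatmaps(records, src, list(config.selectors),
                                list(config.classifiers))
        auc_m.to_csv(out / f"heatmap_auc_{src}.csv")
        rsd_m.to_csv(out / f"heatmap_rsd_{src}.csv")
        _plot_heatmap(auc_m, out / f"heatmap_auc_{src}.png",
                      f"{src}: mean CV AUC")
        _plot_heatmap(rsd_m, out / f"heatmap_rsd_{src}.png",
                      f"{src}: RSD (%)")
    manifest.record("benchmark", time.time() - t0,
                    n_records=len(bench_df), hash=_hash_df(bench_df))

    t0 = time.time()
    best = best_model(records, extractor="Radiomics")
    recs = survival_records(cohort.clinical_frame(), best.oof_pred)
    surv = analyze_survival(recs)
    plot_km(surv["curves"], str(out / "km_best_model.png"),
            title=best.name)
    with open(out / "survival.json", "w") as fh:
        json.dump({"model": best.name, "logrank_chi2": surv["logrank_chi2"],
                   "logrank_p": surv["logrank_p"],
                   "hr": surv["cox"].hr, "ci": [surv["cox"].ci_low,
                                                surv["cox"].ci_high],
                   "cox_p": surv["cox"].p, "n": surv["n"],
                   "n_events": surv["n_events"]}, fh, indent=2)
    manifest.record("survival", time.time() - t0, model=best.name,
                    logrank_p=surv["logrank_p"], hr=surv["cox"].hr)

    manifest.save(out / "manifest.json")
    return manifest
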