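"""Pluggable external feature banks.

The deep-feature branch of the benchmark is a *contract*: any numeric
feature matrix keyed by subject can serve as an extractor source.  Two
providers are included:

* a deterministic random-convolution bank (seeded 2-D filters, valid
  convolution, rectification, global max pooling, mean over slices) that
  mimics the dimensionality of common CNN embedding layers
  (D in {512, 1536, 2048});
* a loader for precomputed external features from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..preprocess import RoiStack

BANK_DIMS = (512, 1536, 2048)


@dataclass(frozen=True)
class BankConfig:
    dim: int = 512
    kernel: int = 5
    seed: int = 0

    def filters(self) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        f = rng.standard_normal((self.dim, self.kernel, self.kernel))
        return f / np.sqrt((f ** 2).sum(axis=(1, 2), keepdims=True))


def feature_bank(stack: RoiStack, config: BankConfig) -> np.ndarray:
    """D-dimensional embedding of a processed stack: for each random filter,
    ReLU of the valid 2-D convolution, global max pool, mean over slices."""
    filt = config.filters()                       # (D, k, k)
    k = config.kernel
    d = config.dim
    pooled = np.zeros((len(stack.slices), d))
    flat = filt.reshape(d, -1).T                  # (k*k, D)
    for s, img in enumerate(stack.slices):
        win = np.lib.stride_tricks.sliding_window_view(img, (k, k))
        cols = win.reshape(-1, k * k)
        resp = np.maximum(cols @ flat, 0.0)       # ReLU
        pooled[s] = resp.max(axis=0)
    return pooled.mean(axis=0)


def bank_feature_names(dim: int) -> list[str]:
    return [f"bank{dim}_f{i:04d}" for i in range(dim)]


def load_external_features(path: str, subject_ids: list[str]) -> pd.DataFrame:
    """Read a precomputed feature CSV (rows = subjects, first column =
    subject_id) and align it to the cohort order."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    missing = [s for s in subject_ids if s not in df.index]
    if missing:
        raise ValueError(f"external CSV missing subjects: {missing[:5]}")
    out = df.loc[subject_ids]
    if not np.isfinite(out.to_numpy(dtype=float)).all():
        raise ValueError("external features contain non-finite values")
    return out
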