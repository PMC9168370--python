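"""Shared fixtures: small phantom cohorts and synthetic feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radstab.preprocess import PreprocessConfig, preprocess_subject
from radstab.synth import CohortConfig, generate_cohort

SMALL_COHORT_CFG = CohortConfig(diameter_median_mm=16.0,
                                diameter_log_sd=0.25,
                                diameter_range_mm=(10.4, 26.0))
SMALL_PRE_CFG = PreprocessConfig(crop_size=32)


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject phantom cohort on small grids (fast to extract)."""
    return generate_cohort(16, effect=1.0, seed=42, config=SMALL_COHORT_CFG)


@pytest.fixture(scope="session")
def small_stack(small_cohort):
    s = small_cohort.subjects[0]
    return preprocess_subject(s.volume, s.mask, SMALL_PRE_CFG)


@pytest.fixture(scope="session")
def planted_table():
    """n=60 feature table: 5 informative features among 35 noise columns,
    plus the binary labels."""
    rng = np.random.default_rng(7)
    n = 60
    y = np.array([1] * 40 + [0] * 20)
    rng.shuffle(y)
    x = rng.standard_normal((n, 40))
    for j in range(5):
        x[:, j] += 1.2 * y
    cols = [f"f{j:02d}" for j in range(40)]
    return pd.DataFrame(x, columns=cols), y
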